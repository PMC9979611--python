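"""Harmonic and quasi-harmonic thermochemistry, free-energy table assembly,
and Boltzmann populations.

Everything is carried in wavenumbers (cm^-1); at room temperature
kT/hc ~ 207 cm^-1, so a ~900 cm^-1 relative free energy corresponds to ~1%
population.  The free-energy tables assemble a junChSF12-quality composite
electronic energy with a harmonic (double-hybrid) ZPE and thermal terms, a
VPT2 anharmonic-minus-harmonic ZPE correction, and a quasi-harmonic-minus-
harmonic T*dS correction; both correction columns are consumed as data.

Two column conventions appear in the tables:

* ``glycine`` style: dG = dG_H + dZPE(anh-H) + d(T dS)(QH-H)
* ``serine`` style:  dG = dE_rDSD + dChS + dZPE_H + dTh_H + dZPE(anh-H)
  + T dS(QH-H)

Display conversions honour 1 kJ/mol = 83.59 cm^-1 as printed in the tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import constants as const

__all__ = [
    "KT_PER_KELVIN_CM1",
    "CM1_PER_KJ_MOL",
    "kT_in_wavenumbers",
    "harmonic_zpe",
    "ho_thermal",
    "qh_entropy",
    "free_rotor_entropy",
    "EnergyLedger",
    "GLYCINE_CONVENTION",
    "SERINE_CONVENTION",
    "assemble_delta_g",
    "boltzmann_populations",
    "kj_mol_to_cm1",
    "cm1_to_kj_mol",
]

#: k_B / (h c) in cm^-1 per kelvin (CODATA, via scipy.constants).
KT_PER_KELVIN_CM1 = const.k / (const.h * const.c * 100.0)

#: Display conversion used by the amino-acid tables.
CM1_PER_KJ_MOL = 83.59


def kj_mol_to_cm1(x: float) -> float:
    return x * CM1_PER_KJ_MOL


def cm1_to_kj_mol(x: float) -> float:
    return x / CM1_PER_KJ_MOL


def kT_in_wavenumbers(temperature_K: float) -> float:
    """Thermal energy kT expressed as a wavenumber, kT/hc (cm^-1)."""
    if temperature_K <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_K}")
    return KT_PER_KELVIN_CM1 * temperature_K


def _check_frequencies(freqs) -> np.ndarray:
    nu = np.asarray(freqs, dtype=float)
    bad = np.flatnonzero(~(nu > 0))
    if bad.size:
        raise ValueError(
            f"non-positive (imaginary) frequency at mode index {bad[0]}"
        )
    return nu


def harmonic_zpe(frequencies) -> float:
    """Harmonic zero-point energy, (1/2) sum(nu), in cm^-1."""
    nu = _check_frequencies(frequencies)
    return 0.5 * float(np.sum(nu))


def ho_thermal(frequencies, temperature_K: float) -> tuple[float, float]:
    """Harmonic-oscillator thermal terms: (vibrational enthalpy beyond ZPE,
    T*S_vib), both in cm^-1 per molecule.

    Per mode with x = nu/kT: <E> - ZPE = nu / (e^x - 1) and
    T*S = kT * [x/(e^x - 1) - ln(1 - e^-x)].  As nu -> 0 the entropy diverges
    logarithmically — the failure the quasi-harmonic scheme repairs.
    """
    nu = _check_frequencies(frequencies)
    kt = kT_in_wavenumbers(temperature_K)
    x = nu / kt
    h_th = float(np.sum(nu / np.expm1(x)))
    ts = float(kt * np.sum(x / np.expm1(x) - np.log(-np.expm1(-x))))
    return h_th, ts


def _ho_entropy_per_mode(x: np.ndarray) -> np.ndarray:
    """S/k per harmonic mode at reduced frequency x = nu/kT."""
    return x / np.expm1(x) - np.log(-np.expm1(-x))


def free_rotor_entropy(
    frequencies, temperature_K: float, b_average: float = 1e-44
) -> np.ndarray:
    """Free-rotor S/k per mode.

    Each low-frequency mode is treated as a one-dimensional rotor whose moment
    mu = h / (8 pi^2 nu c) is damped toward ``b_average`` (kg m^2) so the
    entropy stays finite as nu -> 0:
    S/k = 1/2 + ln(sqrt(8 pi^3 mu' k T) / h), mu' = mu B / (mu + B).
    """
    nu = _check_frequencies(frequencies)
    nu_hz = nu * const.c * 100.0
    mu = const.h / (8.0 * math.pi**2 * nu_hz)
    mu_p = mu * b_average / (mu + b_average)
    arg = np.sqrt(8.0 * math.pi**3 * mu_p * const.k * temperature_K) / const.h
    return 0.5 + np.log(arg)


def qh_entropy(
    frequencies,
    temperature_K: float,
    cutoff_cm1: float = 100.0,
    alpha: float = 4.0,
    b_average: float = 1e-44,
) -> float:
    """Quasi-harmonic T*S_vib in cm^-1.

    Per mode a damping weight w(nu) = 1 / (1 + (cutoff/nu)^alpha) interpolates
    between the harmonic-oscillator entropy (w -> 1 well above the cutoff) and
    the free-rotor entropy (w -> 0 well below it); w(cutoff) = 1/2 exactly.
    """
    nu = _check_frequencies(frequencies)
    kt = kT_in_wavenumbers(temperature_K)
    x = nu / kt
    w = 1.0 / (1.0 + (cutoff_cm1 / nu) ** alpha)
    s_ho = _ho_entropy_per_mode(x)
    s_fr = free_rotor_entropy(nu, temperature_K, b_average)
    return float(kt * np.sum(w * s_ho + (1.0 - w) * s_fr))


# ---------------------------------------------------------------------------
# Free-energy table assembly
# ---------------------------------------------------------------------------

GLYCINE_CONVENTION = ("dG_H", "dZPE_anh_minus_H", "dTdS_QH_minus_H")
SERINE_CONVENTION = (
    "dE_rDSD", "dChS", "dZPE_H", "dTh_H", "dZPE_anh_minus_H", "TdS_QH_minus_H",
)

_CONVENTIONS = {"glycine": GLYCINE_CONVENTION, "serine": SERINE_CONVENTION}


@dataclass
class EnergyLedger:
    """Per-conformer relative energies and free-energy components (cm^-1),
    mirroring one row of the published tables.

    ``components`` maps column names (see the module conventions) to values;
    missing columns are simply absent.  ``dChS`` is the junChSF12-minus-rDSD
    difference in the serine-style tables but an absolute relative energy in
    the glycine/alanine-style ones — the table convention, not this class,
    decides how it enters dG.
    """

    name: str
    components: dict
    temperature_K: float = 298.15

    def delta_g(self, convention: str = "serine") -> float:
        return assemble_delta_g(self.components, convention)


def assemble_delta_g(components: Mapping[str, float], convention: str) -> float:
    """Exact column sum for the chosen table convention (cm^-1).

    Raises ``KeyError`` naming the first missing column.
    """
    try:
        cols = _CONVENTIONS[convention]
    except KeyError:
        raise ValueError(
            f"unknown convention {convention!r}; choose from {sorted(_CONVENTIONS)}"
        ) from None
    total = 0.0
    for col in cols:
        if col not in components or components[col] is None or (
            isinstance(components[col], float) and math.isnan(components[col])
        ):
            raise KeyError(f"missing free-energy component column {col!r}")
        total += components[col]
    return total


def boltzmann_populations(
    delta_g: Mapping[str, float],
    temperature_K: float = 298.15,
    grouping: Optional[Mapping[str, str]] = None,
    degeneracy: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Normalized populations p_i ~ g_i exp(-dG_i / (kT/hc)).

    ``grouping`` (conformer -> sink) sums basin members onto their sinks.
    ``degeneracy`` supplies optional multiplicities (e.g. a factor 2 for
    double-well conformers); default 1 for every state.
    """
    kt = kT_in_wavenumbers(temperature_K)
    names = list(delta_g)
    g = np.array([(degeneracy or {}).get(n, 1.0) for n in names])
    e = np.array([delta_g[n] for n in names], dtype=float)
    w = g * np.exp(-(e - e.min()) / kt)
    p = w / w.sum()
    pops = dict(zip(names, p))
    if grouping is not None:
        out: dict[str, float] = {}
        for n, frac in pops.items():
            out[grouping.get(n, n)] = out.get(grouping.get(n, n), 0.0) + frac
        return out
    return pops
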