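"""Composite-energy assembly, vibrational corrections to rotational constants,
linear-regression geometry scaling, and benchmark statistics.

The composite electronic energy starts from frozen-core CCSD(T)-F12 in a
triple-zeta basis, adds a complete-basis-set (CBS) increment from the
two-point n^-3 extrapolation of MP2-F12 triple/quadruple-zeta energies, and a
core-valence (CV) increment from all-electron minus frozen-core MP2-F12.

Ground-state rotational constants follow the VPT2 relation
B0 = Be - (1/2) sum_r alpha_r per inertial axis, with the vibration-rotation
interaction constants alpha_r supplied as data.  Computed bond lengths and
angles can be corrected for systematic error by the linear regression
approach (LRA), r_corrected = a * r_computed + b, with per-parameter-class
coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CompositeComponents",
    "cbs_extrapolate",
    "composite_energy",
    "vibrational_correction",
    "LRACoefficients",
    "lra_correct",
    "ComparisonReport",
    "unsigned_error_stats",
]


def cbs_extrapolate(e_x: float, e_y: float, x: int = 3, y: int = 4) -> float:
    """Two-point n^-3 complete-basis-set extrapolation.

    E_CBS = (Y^3 E_Y - X^3 E_X) / (Y^3 - X^3); exact for energies following
    E(n) = E_CBS + c n^-3.
    """
    if y <= x:
        raise ValueError(f"cardinal numbers must satisfy Y > X, got X={x}, Y={y}")
    return (y**3 * e_y - x**3 * e_x) / (y**3 - x**3)


@dataclass(frozen=True)
class CompositeComponents:
    """Absolute energies (hartree) entering the composite scheme."""

    e_ccsdt_f12_T: float
    e_mp2_T: float
    e_mp2_Q: float
    e_mp2_ae_CV: float
    e_mp2_fc_CV: float
    x: int = 3
    y: int = 4

    def __post_init__(self):
        if self.y <= self.x:
            raise ValueError("cardinals must satisfy Y > X >= 2")


def composite_energy(c: CompositeComponents) -> float:
    """CCSD(T)-F12/TZ + MP2-F12 CBS increment + core-valence increment (hartree)."""
    for name in ("e_ccsdt_f12_T", "e_mp2_T", "e_mp2_Q", "e_mp2_ae_CV", "e_mp2_fc_CV"):
        v = getattr(c, name)
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing or non-finite composite component {name!r}")
    cbs = cbs_extrapolate(c.e_mp2_T, c.e_mp2_Q, c.x, c.y)
    return c.e_ccsdt_f12_T + (cbs - c.e_mp2_T) + (c.e_mp2_ae_CV - c.e_mp2_fc_CV)


def vibrational_correction(
    be_mhz: float, alphas_mhz: Sequence[float], *, warn_fraction: float = 0.02
) -> float:
    """Ground-state rotational constant B0 = Be - (1/2) sum_r alpha_r (MHz).

    The vibrational correction is typically ~0.5% of Be; a correction beyond
    ``warn_fraction`` of Be triggers a warning (likely bad alpha input).
    """
    if not math.isfinite(be_mhz):
        raise ValueError("Be must be finite")
    b0 = be_mhz - 0.5 * float(np.sum(np.asarray(alphas_mhz, dtype=float)))
    if be_mhz != 0 and abs(b0 - be_mhz) / abs(be_mhz) > warn_fraction:
        warnings.warn(
            f"vibrational correction is {abs(b0 - be_mhz) / abs(be_mhz):.1%} of Be, "
            "far above the typical 0.5% scale"
        )
    return b0


@dataclass
class LRACoefficients:
    """Per-parameter-class slope/offset pairs for the linear regression
    approach.  The default table is the identity (a=1, b=0) for every class a
    user declares: the reference coefficient set is tabulated elsewhere and is
    loaded from user configuration.
    """

    table: dict = field(default_factory=dict)  # class -> (a, b)

    def __post_init__(self):
        for cls, (a, _b) in self.table.items():
            if a <= 0:
                raise ValueError(f"LRA slope for {cls!r} must be positive")

    @classmethod
    def identity(cls, classes: Sequence[str]) -> "LRACoefficients":
        return cls({c: (1.0, 0.0) for c in classes})


def lra_correct(r_comp: float, coeffs: LRACoefficients, parameter_class: str) -> float:
    """Affine correction a * r_comp + b for one bond/angle class."""
    if parameter_class not in coeffs.table:
        raise KeyError(
            f"no LRA coefficients for parameter class {parameter_class!r}; "
            f"known classes: {sorted(coeffs.table)}"
        )
    a, b = coeffs.table[parameter_class]
    return a * r_comp + b


@dataclass
class ComparisonReport:
    """Paired unsigned errors with their summary statistics."""

    parameter_class: str
    errors: np.ndarray
    units: str = ""

    @property
    def mue(self) -> float:
        return float(np.mean(self.errors))

    @property
    def max(self) -> float:
        return float(np.max(self.errors))

    def rounded(self, ndigits: int = 1) -> tuple[float, float]:
        """(MUE, MAX) at display precision; statistics themselves are kept at
        full precision."""
        return round(self.mue, ndigits), round(self.max, ndigits)

    def __str__(self) -> str:
        u = f" {self.units}" if self.units else ""
        return (
            f"{self.parameter_class}: n={len(self.errors)} "
            f"MUE={self.mue:.2f}{u} MAX={self.max:.2f}{u}"
        )


def unsigned_error_stats(
    values_a: Sequence[float],
    values_b: Sequence[float],
    parameter_class: str = "",
    units: str = "",
) -> ComparisonReport:
    """Per-pair |a - b| with MUE (mean) and MAX, computed at full precision."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired value lists must be 1-D and equal length")
    if a.size == 0:
        raise ValueError("need at least one pair")
    return ComparisonReport(parameter_class, np.abs(a - b), units)
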