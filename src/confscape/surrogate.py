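"""Analytic torsional energy surfaces and a brute-force minima oracle.

The evolutionary search needs a fitness function that plays the role of a
constrained semiempirical geometry optimization: given the soft torsions it
returns a relative energy (and possibly relaxed torsions).  The surfaces here
are periodic Fourier series per torsion, optional pairwise cosine couplings,
and optional Gaussian "hydrogen-bond wells" on the torus — rugged enough to
have 3^n-like staggered minima plus a few deep, narrow basins, while staying
cheap and exactly reproducible.

A file-based adapter for an external engine (write XYZ, run a command, read a
scalar energy back) implements the same evaluator contract.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .geom import wrap_array, circular_difference

__all__ = [
    "FourierTerm",
    "CouplingTerm",
    "WellTerm",
    "SurrogateSpec",
    "surrogate_energy",
    "SurrogateEvaluator",
    "local_refine",
    "grid_oracle",
    "packaged_surrogates",
    "FileEngineAdapter",
    "HARTREE_TO_CM1",
]

HARTREE_TO_CM1 = 219474.6313632


@dataclass(frozen=True)
class FourierTerm:
    """(amplitude/2) * (1 + cos(k*theta - phase)) on one torsion."""

    torsion: int
    order: int  # 1..3
    amplitude_cm1: float
    phase_deg: float = 0.0


@dataclass(frozen=True)
class CouplingTerm:
    """amplitude * cos(theta_i - phase_i) * cos(theta_j - phase_j)."""

    torsion_i: int
    torsion_j: int
    amplitude_cm1: float
    phase_i_deg: float = 0.0
    phase_j_deg: float = 0.0


@dataclass(frozen=True)
class WellTerm:
    """Attractive Gaussian well of given depth centered on the torus."""

    center_deg: tuple
    depth_cm1: float
    width_deg: float


@dataclass(frozen=True)
class SurrogateSpec:
    n_torsions: int
    fourier: tuple = ()
    couplings: tuple = ()
    wells: tuple = ()
    name: str = ""

    def __post_init__(self):
        for t in self.fourier:
            if not (0 <= t.torsion < self.n_torsions):
                raise ValueError(f"Fourier term on undefined torsion {t.torsion}")
            if t.order not in (1, 2, 3):
                raise ValueError(f"Fourier order must be 1-3, got {t.order}")
        for c in self.couplings:
            if not (0 <= c.torsion_i < self.n_torsions and 0 <= c.torsion_j < self.n_torsions):
                raise ValueError("coupling references undefined torsion")
        for w in self.wells:
            if len(w.center_deg) != self.n_torsions:
                raise ValueError("well center dimension mismatch")
            if w.depth_cm1 < 0 or w.width_deg <= 0:
                raise ValueError("well depth must be >= 0 and width > 0")


def surrogate_energy(torsions, spec: SurrogateSpec) -> float:
    """Evaluate the surface (cm^-1) at a torsion vector in degrees."""
    th = np.asarray(torsions, dtype=float)
    if th.shape != (spec.n_torsions,):
        raise ValueError(
            f"torsion vector of length {th.shape} does not match spec ({spec.n_torsions})"
        )
    rad = np.radians(th)
    e = 0.0
    for t in spec.fourier:
        e += 0.5 * t.amplitude_cm1 * (
            1.0 + math.cos(t.order * rad[t.torsion] - math.radians(t.phase_deg))
        )
    for c in spec.couplings:
        e += c.amplitude_cm1 * math.cos(
            rad[c.torsion_i] - math.radians(c.phase_i_deg)
        ) * math.cos(rad[c.torsion_j] - math.radians(c.phase_j_deg))
    for w in spec.wells:
        d = circular_difference(np.asarray(w.center_deg, dtype=float), th)
        e -= w.depth_cm1 * math.exp(-0.5 * float(np.sum(d * d)) / w.width_deg**2)
    return e


class SurrogateEvaluator:
    """Evaluator contract: torsions -> (energy cm^-1, possibly-relaxed torsions).

    With ``relax=True`` each call mimics a constrained optimization of the
    stiff degrees of freedom followed by a soft-coordinate relaxation.
    """

    def __init__(self, spec: SurrogateSpec, relax: bool = False,
                 step_tolerance: float = 1e-4):
        self.spec = spec
        self.relax = relax
        self.step_tolerance = step_tolerance
        self.n_calls = 0

    def __call__(self, torsions):
        self.n_calls += 1
        if self.relax:
            refined, e = local_refine(torsions, self.spec, self.step_tolerance)
            return e, refined
        th = wrap_array(torsions)
        return surrogate_energy(th, self.spec), th


def local_refine(
    torsions, spec: SurrogateSpec, step_tolerance: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Descend to the local minimum of the surface around a starting point.

    Derivative-free (Nelder-Mead on the unwrapped angles; the surface is
    360-periodic so unwrapped excursions are harmless).  The returned energy is
    never above the starting energy.
    """
    x0 = np.asarray(torsions, dtype=float)
    e0 = surrogate_energy(wrap_array(x0), spec)

    def f(x):
        return surrogate_energy(wrap_array(x), spec)

    res = minimize(
        f, x0, method="Nelder-Mead",
        options={"xatol": step_tolerance, "fatol": 1e-10, "maxiter": 4000},
    )
    if res.fun <= e0:
        return wrap_array(res.x), float(res.fun)
    return wrap_array(x0), e0


def grid_oracle(
    spec: SurrogateSpec,
    resolution_deg: float = 15.0,
    *,
    dedup_tol_deg: float = 5.0,
    max_points: int = 2_000_000,
) -> list[tuple[np.ndarray, float]]:
    """Exhaustive scan of the full torus, refined and deduplicated minima.

    Every grid point that is a local minimum among its 3^n - 1 grid neighbours
    (periodic) is refined; nearby endpoints merge.  Sorted by energy, global
    minimum first.
    """
    if 360.0 % resolution_deg != 0:
        raise ValueError("resolution must divide 360")
    n = spec.n_torsions
    steps = int(360.0 // resolution_deg)
    if steps**n > max_points:
        raise ValueError(
            f"{steps}^{n} grid points exceed the cost guard ({max_points})"
        )
    axes = [np.arange(steps) * resolution_deg - 180.0 for _ in range(n)]
    grids = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1)
    energies = np.array([surrogate_energy(p, spec) for p in pts]).reshape(
        [steps] * n
    )

    # grid local minima: not above any periodic neighbour, strictly below at
    # least one (the second clause drops plateaus; a globally flat surface is
    # handled by the fallback below)
    not_above = np.ones_like(energies, dtype=bool)
    below_some = np.zeros_like(energies, dtype=bool)
    for offset in _neighbor_offsets(n):
        shifted = energies
        for ax, off in enumerate(offset):
            if off:
                shifted = np.roll(shifted, off, axis=ax)
        not_above &= energies <= shifted
        below_some |= energies < shifted
    is_min = not_above & below_some
    pts_nd = pts.reshape([steps] * n + [n])
    candidates = pts_nd[is_min]
    if len(candidates) == 0:
        flat_idx = np.unravel_index(np.argmin(energies), energies.shape)
        candidates = pts_nd[flat_idx][None, :]

    minima: list[tuple[np.ndarray, float]] = []
    for cand in candidates:
        x, e = local_refine(cand, spec)
        for seen_x, seen_e in minima:
            d = circular_difference(seen_x, x)
            if float(np.sqrt(np.sum(d * d))) < dedup_tol_deg:
                break
        else:
            minima.append((x, e))
    minima.sort(key=lambda t: t[1])
    return minima


def _neighbor_offsets(n: int):
    from itertools import product

    for off in product((-1, 0, 1), repeat=n):
        if any(off):
            yield off


# ---------------------------------------------------------------------------
# Packaged test surfaces
# ---------------------------------------------------------------------------


def packaged_surrogates() -> dict[str, SurrogateSpec]:
    """Named analytic surfaces shipped with the package.

    * ``threefold_1d`` — single 3-fold rotor, the textbook staggered/eclipsed
      profile with a 1000 cm^-1 barrier.
    * ``rugged_2d`` — two coupled rotors with a tilted landscape and one deep
      hydrogen-bond-like well off the staggered lattice.
    * ``amino_3d`` — three rotors with staggered preferences of different
      strengths, two couplings and two competing wells; its low-energy minima
      mimic the handful of hydrogen-bonded conformers of a small amino acid.
    """
    specs = {}
    specs["threefold_1d"] = SurrogateSpec(
        n_torsions=1,
        fourier=(FourierTerm(0, 3, 1000.0),),
        name="threefold_1d",
    )
    specs["rugged_2d"] = SurrogateSpec(
        n_torsions=2,
        fourier=(
            FourierTerm(0, 3, 900.0),
            FourierTerm(0, 1, 250.0, phase_deg=30.0),
            FourierTerm(1, 3, 700.0),
            FourierTerm(1, 2, 180.0, phase_deg=-60.0),
        ),
        couplings=(CouplingTerm(0, 1, 150.0, 20.0, -40.0),),
        wells=(WellTerm((75.0, -65.0), 600.0, 40.0),),
        name="rugged_2d",
    )
    specs["amino_3d"] = SurrogateSpec(
        n_torsions=3,
        fourier=(
            FourierTerm(0, 3, 1100.0),
            FourierTerm(1, 3, 800.0),
            FourierTerm(1, 1, 200.0, phase_deg=45.0),
            FourierTerm(2, 3, 600.0),
            FourierTerm(2, 2, 150.0),
        ),
        couplings=(
            CouplingTerm(0, 1, 120.0, 0.0, 60.0),
            CouplingTerm(1, 2, 90.0, -30.0, 0.0),
        ),
        wells=(
            WellTerm((60.0, 180.0, -60.0), 700.0, 35.0),
            WellTerm((-60.0, 60.0, 180.0), 450.0, 30.0),
        ),
        name="amino_3d",
    )
    return specs


# ---------------------------------------------------------------------------
# External-engine file adapter
# ---------------------------------------------------------------------------


class FileEngineAdapter:
    """Evaluator backed by an external command exchanging plain-text files.

    For each call the current geometry is written as XYZ, ``command`` is run
    with the XYZ path and an output path appended, and a single scalar energy
    is parsed from the first token of the output file.  ``unit`` declares the
    energy unit of the engine ('cm-1' or 'hartree').
    """

    def __init__(
        self,
        command: Sequence[str],
        geometry_builder: Callable[[Sequence[float]], tuple[list, np.ndarray]],
        unit: str = "cm-1",
        workdir: Optional[Path] = None,
    ):
        if unit not in ("cm-1", "hartree"):
            raise ValueError(f"unknown energy unit {unit!r}")
        self.command = list(command)
        self.geometry_builder = geometry_builder
        self.unit = unit
        self.workdir = Path(workdir) if workdir else None
        self.n_calls = 0

    def __call__(self, torsions):
        from .geom import write_xyz

        self.n_calls += 1
        th = wrap_array(torsions)
        symbols, coords = self.geometry_builder(th)
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            xyz_path = Path(tmp) / "geom.xyz"
            out_path = Path(tmp) / "energy.out"
            xyz_path.write_text(write_xyz(symbols, coords, "engine input"))
            subprocess.run(
                self.command + [str(xyz_path), str(out_path)], check=True
            )
            token = out_path.read_text().split()[0]
        e = float(token)
        if self.unit == "hartree":
            e *= HARTREE_TO_CM1
        return e, th
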