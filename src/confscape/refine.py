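"""Threshold cascade, duplicate elimination, relaxation grouping, detectability.

After the evolutionary exploration, candidates pass through a cascade of
relative-energy cutoffs (2500 cm^-1 on semiempirical energies, 1500 cm^-1
after hybrid-DFT optimization, 1000 cm^-1 after the double-hybrid refinement).
Conformers separated from a more stable neighbour by an interconversion
barrier below ~400 cm^-1 relax onto that neighbour during the supersonic-jet
expansion and are grouped into its basin; surviving sinks are considered
detectable by microwave spectroscopy when their relative free energy is within
~900 cm^-1 of the global minimum (~1% room-temperature population).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .geom import Conformer, heavy_atom_rmsd, rotational_constants_from_geometry
from .thermo import boltzmann_populations

__all__ = [
    "BarrierEdge",
    "ThresholdCascade",
    "threshold_filter",
    "deduplicate",
    "relaxation_grouping",
    "detectable_set",
]


@dataclass(frozen=True)
class BarrierEdge:
    """Directed relaxation edge; the barrier is measured from the initial
    (higher) minimum up to the transition state, in cm^-1.  ``barrier=None``
    records a relaxation that is stated to occur without a printed barrier."""

    source: str
    target: str
    barrier_cm1: Optional[float] = None

    def __post_init__(self):
        if self.barrier_cm1 is not None and self.barrier_cm1 < 0:
            raise ValueError("barrier must be >= 0")


@dataclass(frozen=True)
class ThresholdCascade:
    semiempirical_cutoff: float = 2500.0
    hybrid_cutoff: float = 1500.0
    final_cutoff: float = 1000.0
    detectability_cutoff: float = 900.0
    relaxation_barrier: float = 400.0

    def __post_init__(self):
        for v in (self.semiempirical_cutoff, self.hybrid_cutoff,
                  self.final_cutoff, self.detectability_cutoff,
                  self.relaxation_barrier):
            if v <= 0:
                raise ValueError("cascade cutoffs must be positive")


def threshold_filter(
    energies: Mapping[str, float], cutoff_cm1: float
) -> list[str]:
    """Keep entries within ``cutoff_cm1`` of the pool minimum (inclusive).

    Energies are re-referenced to the pool minimum first, so absolute or
    relative inputs behave the same; the reference minimum always survives.
    """
    if not energies:
        raise ValueError("empty pool")
    emin = min(energies.values())
    return [k for k, e in energies.items() if (e - emin) <= cutoff_cm1]


def deduplicate(
    conformers: Sequence[Conformer],
    rot_tol_percent: float = 1.0,
    rmsd_tol_A: float = 0.25,
) -> list[Conformer]:
    """Merge structures that agree in all three rotational constants (within
    ``rot_tol_percent``) AND in heavy-atom RMSD (below ``rmsd_tol_A``).

    Similarity is closed transitively; each component keeps its lowest-energy
    member.  Conformers without geometry cannot be compared and pass through
    with a warning.
    """
    with_geom = [c for c in conformers if c.coords is not None]
    passthrough = [c for c in conformers if c.coords is None]
    if passthrough:
        warnings.warn(
            f"{len(passthrough)} conformer(s) without geometry passed through "
            "deduplication unchecked"
        )

    g = nx.Graph()
    g.add_nodes_from(range(len(with_geom)))
    consts = [
        rotational_constants_from_geometry(c.coords, c.masses) for c in with_geom
    ]
    for i in range(len(with_geom)):
        for j in range(i + 1, len(with_geom)):
            if _constants_close(consts[i], consts[j], rot_tol_percent) and (
                heavy_atom_rmsd(with_geom[i], with_geom[j]) < rmsd_tol_A
            ):
                g.add_edge(i, j)

    survivors = []
    for comp in nx.connected_components(g):
        best = min(comp, key=lambda i: _energy_key(with_geom[i]))
        survivors.append(with_geom[best])
    survivors.sort(key=_energy_key)
    return survivors + passthrough


def _energy_key(c: Conformer) -> float:
    if not c.energies:
        return math.inf
    return min(c.energies.values())


def _constants_close(abc1, abc2, tol_percent: float) -> bool:
    for x, y in zip(abc1, abc2):
        if math.isinf(x) or math.isinf(y):
            if x != y:
                return False
            continue
        if abs(x - y) > tol_percent / 100.0 * max(abs(x), abs(y)):
            return False
    return True


def relaxation_grouping(
    delta_g: Mapping[str, float],
    edges: Sequence[BarrierEdge],
    barrier_threshold: float = 400.0,
) -> dict[str, str]:
    """Map every conformer to its relaxation sink.

    A conformer follows any edge whose barrier is below the threshold (or
    stated without a value) toward a lower-free-energy conformer, repeatedly,
    until no escapable edge remains.  When several edges are open the one to
    the most stable target is taken.  A cycle of mutually connected minima
    collapses onto its lowest-energy member.
    """
    names = set(delta_g)
    for e in edges:
        if e.source not in names or e.target not in names:
            raise ValueError(f"edge {e.source}->{e.target} references unknown conformer")

    open_edges: dict[str, list[str]] = {}
    for e in edges:
        if e.barrier_cm1 is not None and e.barrier_cm1 >= barrier_threshold:
            continue
        if delta_g[e.target] >= delta_g[e.source]:
            continue  # only downhill relaxation
        open_edges.setdefault(e.source, []).append(e.target)

    def step(name: str) -> Optional[str]:
        targets = open_edges.get(name)
        if not targets:
            return None
        return min(targets, key=lambda t: (delta_g[t], t))

    sinks: dict[str, str] = {}
    for name in delta_g:
        seen = [name]
        current = name
        while True:
            nxt = step(current)
            if nxt is None:
                sinks[name] = current
                break
            if nxt in seen:  # cycle: lowest-energy member wins
                cyc = seen[seen.index(nxt):] + [nxt]
                sinks[name] = min(cyc, key=lambda t: (delta_g[t], t))
                break
            seen.append(nxt)
            current = nxt
    return sinks


def detectable_set(
    sinks: Mapping[str, str],
    delta_g: Mapping[str, float],
    detectability_cutoff: float = 900.0,
    temperature: float = 298.15,
) -> dict[str, float]:
    """Sinks within the detectability window, with basin-aggregated populations.

    Populations are Boltzmann fractions over the *whole* pool (each conformer
    contributes its own exp(-dG/kT) weight) summed onto the sink it relaxes
    to, mirroring how jet-cooled populations pile up on the surviving species.
    """
    emin = min(delta_g.values())
    pops = boltzmann_populations(
        {k: v - emin for k, v in delta_g.items()}, temperature
    )
    basin_pop: dict[str, float] = {}
    for name, sink in sinks.items():
        basin_pop[sink] = basin_pop.get(sink, 0.0) + pops[name]
    return {
        s: p
        for s, p in sorted(basin_pop.items(), key=lambda kv: delta_g[kv[0]])
        if delta_g[s] - emin <= detectability_cutoff
    }
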