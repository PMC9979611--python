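"""Knowledge-based enumeration and the island-model evolutionary search.

The search space is the torus of n soft torsions.  A run starts either from
the 3^n staggered guesses or from a Latin-Hypercube population, then evolves
islands independently with tournament selection, circular-arc crossover and
wrapped-Gaussian mutation, exchanging migrants on a ring at fixed intervals.
Each island keeps an elitist Hall of Fame whose best member can only improve.
The fitness of an individual is its relative energy (cm^-1, lower is better)
as returned by the evaluator, which stands for a constrained geometry
optimization of the stiff degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.stats import qmc

from .geom import wrap_array, circular_difference

__all__ = [
    "EAConfig",
    "Individual",
    "enumerate_staggered",
    "lhs_init",
    "crossover",
    "mutate",
    "select_parents",
    "migrate",
    "run_imea",
    "dedup_pool",
]

STAGGERED = (60.0, 180.0, -60.0)


@dataclass(frozen=True)
class EAConfig:
    """Run parameters; defaults follow the typical exploration budget
    (population 100 over 4 islands, 50 cycles, 4 independent runs,
    ~1000 fitness evaluations per run)."""

    population_size: int = 100
    max_cycles: int = 50
    n_islands: int = 4
    n_runs: int = 4
    tournament_size: int = 3
    crossover_prob: float = 0.7
    mutation_per_gene_prob: float = 0.2
    mutation_sigma_deg: float = 30.0
    mutation_mode: str = "gaussian"  # or "reset"
    offspring_per_island: int = 5
    migration_interval: int = 10
    n_migrants: int = 2
    hall_of_fame_size: int = 5
    rng_seed: int = 0

    def __post_init__(self):
        if self.population_size % self.n_islands:
            raise ValueError("population must divide evenly across islands")
        for p in (self.crossover_prob, self.mutation_per_gene_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mutation_mode not in ("gaussian", "reset"):
            raise ValueError(f"unknown mutation mode {self.mutation_mode!r}")

    @property
    def island_size(self) -> int:
        return self.population_size // self.n_islands


@dataclass
class Individual:
    torsions: np.ndarray
    fitness: Optional[float] = None
    island: int = -1
    eval_stamp: int = -1

    def copy(self) -> "Individual":
        return Individual(self.torsions.copy(), self.fitness, self.island, self.eval_stamp)


def enumerate_staggered(n_torsions: int) -> np.ndarray:
    """All 3^n staggered guesses: the Cartesian product of {60, 180, -60}."""
    if n_torsions == 0:
        return np.zeros((1, 0))
    return np.array(list(itertools.product(STAGGERED, repeat=n_torsions)))


def lhs_init(population_size: int, n_dims: int, seed) -> np.ndarray:
    """Latin-Hypercube population on [-180, 180)^d.

    Each dimension is cut into ``population_size`` equal strata and every
    stratum receives exactly one sample, maximizing initial torsional
    diversity.
    """
    if population_size < 1:
        raise ValueError("population_size must be >= 1")
    sampler = qmc.LatinHypercube(d=n_dims, rng=np.random.default_rng(seed))
    unit = sampler.random(population_size)
    return unit * 360.0 - 180.0


def crossover(parent_a, parent_b, rng: np.random.Generator) -> np.ndarray:
    """Circular interpolation: each gene lands on the shorter arc between parents."""
    a = wrap_array(parent_a)
    b = wrap_array(parent_b)
    if a.shape != b.shape:
        raise ValueError("parents differ in dimension")
    w = rng.random(a.shape)
    return wrap_array(a + w * circular_difference(a, b))


def mutate(
    torsions,
    rng: np.random.Generator,
    sigma_deg: float = 30.0,
    per_gene_prob: float = 0.2,
    mode: str = "gaussian",
) -> np.ndarray:
    """Independently perturb genes: wrapped Gaussian kick or uniform reset."""
    t = wrap_array(torsions).copy()
    hit = rng.random(t.shape) < per_gene_prob
    if not hit.any():
        return t
    if mode == "gaussian":
        t[hit] = t[hit] + rng.normal(0.0, sigma_deg, size=int(hit.sum()))
    elif mode == "reset":
        t[hit] = rng.uniform(-180.0, 180.0, size=int(hit.sum()))
    else:
        raise ValueError(f"unknown mutation mode {mode!r}")
    return wrap_array(t)


def select_parents(
    population: list[Individual],
    k: int,
    rng: np.random.Generator,
    tournament_size: int = 3,
) -> list[Individual]:
    """k tournament winners (drawn with replacement); lower fitness wins."""
    if not population:
        raise ValueError("empty population")
    if k > 1_000_000:
        raise ValueError("selection request unreasonably large")
    winners = []
    for _ in range(k):
        idx = rng.integers(0, len(population), size=tournament_size)
        best = min(idx, key=lambda i: population[i].fitness)
        winners.append(population[best])
    return winners


def migrate(
    islands: list[list[Individual]], rng: np.random.Generator, n_migrants: int
) -> list[list[Individual]]:
    """Ring migration: island i sends copies of its n best to island i+1,
    where they replace the n worst.  Island sizes are conserved."""
    if len(islands) < 2:
        raise ValueError("migration needs at least two islands")
    if n_migrants == 0:
        return islands
    if any(n_migrants >= len(isl) for isl in islands):
        raise ValueError("n_migrants must be smaller than every island")
    outgoing = []
    for isl in islands:
        best = sorted(isl, key=lambda ind: ind.fitness)[:n_migrants]
        outgoing.append([ind.copy() for ind in best])
    new_islands = []
    for i, isl in enumerate(islands):
        incoming = outgoing[(i - 1) % len(islands)]
        kept = sorted(isl, key=lambda ind: ind.fitness)[: len(isl) - n_migrants]
        for ind in incoming:
            ind.island = i
        new_islands.append(kept + incoming)
    return new_islands


@dataclass
class RunResult:
    """Union pool of all evaluated candidates plus provenance."""

    pool: list[Individual]
    n_evaluations: int
    n_failures: int
    hof_history: list[list[float]]  # per run: best HoF fitness per cycle
    seed: int


def run_imea(
    config: EAConfig,
    evaluator: Callable,
    n_torsions: int,
    *,
    log: Optional[Callable[[str], None]] = None,
) -> RunResult:
    """Run the full island-model search (``config.n_runs`` independent runs).

    Returns every uniquely evaluated candidate with its fitness.  Fully
    reproducible for a fixed ``config.rng_seed``: per-run generators are
    spawned from a single SeedSequence.
    """
    root = np.random.SeedSequence(config.rng_seed)
    run_seeds = root.spawn(config.n_runs)
    pool: list[Individual] = []
    n_eval = 0
    n_fail = 0
    hof_history: list[list[float]] = []

    for run_idx, seq in enumerate(run_seeds):
        rng = np.random.default_rng(seq)
        init = lhs_init(config.population_size, n_torsions, rng)

        islands: list[list[Individual]] = [[] for _ in range(config.n_islands)]
        for i, torsions in enumerate(init):
            ind = Individual(wrap_array(torsions), island=i % config.n_islands)
            islands[ind.island].append(ind)

        def evaluate(ind: Individual) -> bool:
            nonlocal n_eval, n_fail
            try:
                fitness, relaxed = evaluator(ind.torsions)
            except Exception:
                n_fail += 1
                return False
            n_eval += 1
            ind.fitness = float(fitness)
            ind.torsions = wrap_array(relaxed)
            ind.eval_stamp = n_eval
            pool.append(ind.copy())
            return True

        for isl in islands:
            isl[:] = [ind for ind in isl if evaluate(ind)]

        hofs: list[list[Individual]] = [
            sorted(isl, key=lambda ind: ind.fitness)[: config.hall_of_fame_size]
            for isl in islands
        ]
        best_per_cycle: list[float] = []

        for cycle in range(config.max_cycles):
            for i, isl in enumerate(islands):
                if not isl:
                    continue
                children = []
                parents = select_parents(
                    isl, 2 * config.offspring_per_island, rng, config.tournament_size
                )
                for j in range(config.offspring_per_island):
                    pa, pb = parents[2 * j], parents[2 * j + 1]
                    if rng.random() < config.crossover_prob:
                        child_t = crossover(pa.torsions, pb.torsions, rng)
                    else:
                        child_t = pa.torsions.copy()
                    child_t = mutate(
                        child_t, rng, config.mutation_sigma_deg,
                        config.mutation_per_gene_prob, config.mutation_mode,
                    )
                    child = Individual(child_t, island=i)
                    if evaluate(child):
                        children.append(child)
                # steady-state replacement with implicit elitism: merge and
                # truncate back to the island size
                merged = sorted(isl + children, key=lambda ind: ind.fitness)
                islands[i] = merged[: len(isl)]
                # elitist archive
                hofs[i] = sorted(
                    hofs[i] + children, key=lambda ind: ind.fitness
                )[: config.hall_of_fame_size]

            if (
                config.n_islands > 1
                and config.migration_interval > 0
                and (cycle + 1) % config.migration_interval == 0
            ):
                islands = migrate(islands, rng, config.n_migrants)

            cycle_best = min(h[0].fitness for h in hofs if h)
            best_per_cycle.append(cycle_best)
            if log:
                log(f"run {run_idx} cycle {cycle}: best {cycle_best:.2f}")

        hof_history.append(best_per_cycle)

    pool = dedup_pool(pool)
    return RunResult(pool, n_eval, n_fail, hof_history, config.rng_seed)


def dedup_pool(pool: list[Individual], tol_deg: float = 15.0) -> list[Individual]:
    """Merge near-duplicate torsion vectors (wrap-aware Euclidean distance),
    keeping the lower-energy representative.  Definitive duplicate removal,
    using rotational constants and heavy-atom RMSD, happens downstream."""
    kept: list[Individual] = []
    for ind in sorted(pool, key=lambda i: i.fitness):
        for other in kept:
            d = circular_difference(other.torsions, ind.torsions)
            if float(np.sqrt(np.sum(d * d))) < tol_deg:
                break
        else:
            kept.append(ind)
    kept.sort(key=lambda i: i.fitness)
    return kept
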