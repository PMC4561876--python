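"""Particle swarm optimizer over SNP barcodes.

Particles live in a continuous space of dimension D = 2k: the first k
components range over the SNP index interval [1, n_snps], the last k over the
genotype-code interval [1, 2]. Initialization draws every component uniformly
within its bounds; each generation applies the classic velocity/position
update with a linearly decreasing inertia weight (LDW)

    w(g) = (w_max - w_min) * (G - g) / G + w_min,        g = 0..G,
    v   <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),
    x   <- x + v,

with r1, r2 drawn independently per dimension, velocities clamped per
dimension to +/-(x_max - x_min) and positions clamped to their bounds.

A particle is scored by decoding its position to a discrete barcode (round
half away from zero, clamp, redraw duplicate SNP indices among unused ones
from the run's RNG stream, canonicalize) and evaluating the
frequency-difference fitness. pbest/gbest replacement requires strict
improvement; ties keep the incumbent. The run stops after a fixed generation
budget (no convergence early-exit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .barcode import SNPBarcode, fitness as barcode_fitness
from .genotypes import GenotypeDataset
from .stats import AssocResult, evaluate_barcode


@dataclass(frozen=True)
class PSOParams:
    """Swarm parameter set; defaults follow the standard LDW configuration."""

    population_size: int = 50
    max_generations: int = 100
    w_max: float = 0.9
    w_min: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")
        if not self.w_min < self.w_max:
            raise ValueError("w_min must be < w_max")


@dataclass
class Swarm:
    """Vectorized swarm state: (pop, D) position/velocity arrays + memories."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    gbest_barcode: Optional[SNPBarcode]
    x_min: np.ndarray          # per-dimension lower bounds
    x_max: np.ndarray          # per-dimension upper bounds
    n_snps: int
    k: int
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def v_max(self) -> np.ndarray:
        return self.x_max - self.x_min

    @property
    def v_min(self) -> np.ndarray:
        return -(self.x_max - self.x_min)


def inertia_weight(generation: int, params: PSOParams) -> float:
    """LDW inertia: w_max at generation 0, w_min at generation max_generations."""
    g_max = params.max_generations
    if g_max == 0:
        return params.w_max
    frac = (g_max - generation) / g_max
    return (params.w_max - params.w_min) * frac + params.w_min


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.floor(np.abs(x) + 0.5) * np.sign(x)


def decode_particle(position: np.ndarray, n_snps: int,
                    rng: Optional[np.random.Generator] = None) -> SNPBarcode:
    """Map a continuous position of length 2k to a canonical SNPBarcode.

    SNP dims are rounded half-away-from-zero and clamped to [1, n_snps];
    genotype dims likewise to {1, 2}. Duplicate SNP indices (possible after
    rounding) are repaired by redrawing the offending dimension uniformly
    among the unused indices, consuming the supplied RNG stream.
    """
    position = np.asarray(position, dtype=float)
    if position.size % 2 != 0:
        raise ValueError("position length must be even (k SNP dims + k code dims)")
    k = position.size // 2
    if k > n_snps:
        raise ValueError(f"k={k} exceeds panel size n_snps={n_snps}")
    snps = np.clip(_round_half_away(position[:k]), 1, n_snps).astype(int)
    codes = np.clip(_round_half_away(position[k:]), 1, 2).astype(int)
    seen: set[int] = set()
    for j in range(k):
        if snps[j] in seen:
            if rng is None:
                rng = np.random.default_rng()
            unused = [s for s in range(1, n_snps + 1) if s not in seen]
            snps[j] = unused[int(rng.integers(len(unused)))]
        seen.add(int(snps[j]))
    return SNPBarcode.from_pairs(zip(snps.tolist(), codes.tolist()))


def _bounds(n_snps: int, k: int) -> Tuple[np.ndarray, np.ndarray]:
    x_min = np.ones(2 * k)
    x_max = np.concatenate([np.full(k, float(n_snps)), np.full(k, 2.0)])
    return x_min, x_max


def initialize_swarm(params: PSOParams, n_snps: int, k: int,
                     rng: Optional[np.random.Generator] = None) -> Swarm:
    """Uniformly initialize positions within bounds and velocities within
    +/-(x_max - x_min); fully determined by ``params.seed`` unless an RNG is
    supplied."""
    if not 2 <= k <= n_snps:
        raise ValueError(f"barcode size k={k} must satisfy 2 <= k <= n_snps={n_snps}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    x_min, x_max = _bounds(n_snps, k)
    pop = params.population_size
    u = rng.random((pop, 2 * k))
    positions = x_min + u * (x_max - x_min)
    v_span = x_max - x_min
    velocities = -v_span + rng.random((pop, 2 * k)) * (2 * v_span)
    return Swarm(positions=positions, velocities=velocities,
                 pbest_positions=positions.copy(),
                 pbest_fitness=np.full(pop, -np.inf),
                 gbest_position=positions[0].copy(), gbest_fitness=-np.inf,
                 gbest_barcode=None, x_min=x_min, x_max=x_max,
                 n_snps=n_snps, k=k, rng=rng)


def _evaluate(swarm: Swarm, dataset: GenotypeDataset, direction: str,
              cache: dict) -> None:
    """Decode + score all particles; update pbest/gbest (strict improvement)."""
    for i in range(swarm.positions.shape[0]):
        bc = decode_particle(swarm.positions[i], swarm.n_snps, swarm.rng)
        key = (bc.snp_indices, bc.genotype_codes)
        f = cache.get(key)
        if f is None:
            f = barcode_fitness(dataset, bc, direction=direction)
            cache[key] = f
        if f > swarm.pbest_fitness[i]:
            swarm.pbest_fitness[i] = f
            swarm.pbest_positions[i] = swarm.positions[i]
        if f > swarm.gbest_fitness:
            swarm.gbest_fitness = f
            swarm.gbest_position = swarm.positions[i].copy()
            swarm.gbest_barcode = bc


def step(swarm: Swarm, dataset: GenotypeDataset, params: PSOParams,
         generation: int, direction: str = "protective",
         cache: Optional[dict] = None) -> Swarm:
    """One PSO generation: velocity/position update then re-evaluation.

    ``generation`` indexes the LDW schedule (1..max_generations within
    :func:`run_pso`). The swarm is updated in place and returned.
    """
    if cache is None:
        cache = {}
    w = inertia_weight(generation, params)
    pop, d = swarm.positions.shape
    r1 = swarm.rng.random((pop, d))
    r2 = swarm.rng.random((pop, d))
    swarm.velocities = (w * swarm.velocities
                        + params.c1 * r1 * (swarm.pbest_positions - swarm.positions)
                        + params.c2 * r2 * (swarm.gbest_position - swarm.positions))
    np.clip(swarm.velocities, swarm.v_min, swarm.v_max, out=swarm.velocities)
    swarm.positions = swarm.positions + swarm.velocities
    np.clip(swarm.positions, swarm.x_min, swarm.x_max, out=swarm.positions)
    _evaluate(swarm, dataset, direction, cache)
    return swarm


@dataclass(frozen=True)
class PSORun:
    """Outcome of one PSO run: best model + per-generation gbest history."""

    best: AssocResult
    history: List[Tuple[float, SNPBarcode]]
    params: PSOParams
    k: int


def run_pso(dataset: GenotypeDataset, k: int, params: Optional[PSOParams] = None,
            direction: str = "protective", alpha: float = 0.05) -> PSORun:
    """Full PSO search for the best k-SNP barcode.

    Returns the gbest barcode evaluated through the association-statistics
    layer plus the gbest (fitness, barcode) after initialization and after
    each of the ``max_generations`` update steps (history length
    ``max_generations + 1``). Bit-reproducible from ``params.seed``.
    """
    if params is None:
        params = PSOParams()
    if dataset.n_snps < k:
        raise ValueError(f"dataset has {dataset.n_snps} SNPs, need >= k={k}")
    rng = np.random.default_rng(params.seed)
    swarm = initialize_swarm(params, dataset.n_snps, k, rng=rng)
    cache: dict = {}
    _evaluate(swarm, dataset, direction, cache)
    history = [(swarm.gbest_fitness, swarm.gbest_barcode)]
    for gen in range(1, params.max_generations + 1):
        step(swarm, dataset, params, gen, direction=direction, cache=cache)
        history.append((swarm.gbest_fitness, swarm.gbest_barcode))
    best = evaluate_barcode(dataset, swarm.gbest_barcode, alpha=alpha,
                            direction=direction, on_degenerate="nan")
    return PSORun(best=best, history=history, params=params, k=k)
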