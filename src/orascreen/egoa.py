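"""Enhanced grasshopper optimization (GOA + opposition-based learning).

The grasshopper optimization algorithm moves a swarm of candidate
solutions under pairwise social forces.  The social force between two
grasshoppers at distance y is

    s(y) = f * exp(-y / l) - exp(-y)

(attraction strength f, attractive length scale l): repulsive at short
range, attractive at long range, zero at the comfort distance.  The
position update sums social terms over all other grasshoppers and pulls
toward the best solution found so far; gravity and wind-drift terms of
the general swarm model are dropped in the working update.  A comfort
coefficient

    c(t) = c_max - t * (c_max - c_min) / t_max

shrinks linearly from 1 to 1e-5, narrowing attraction/repulsion zones so
the swarm shifts from exploration to exploitation.

The enhancement is opposition-based learning (OBL): for a candidate x in
box bounds [l, u], the opposite point is x̄ = u + l - x; evaluating both
and keeping the fitter one speeds convergence.  Here OBL is applied at
initialisation (sample N, add their N opposites, keep the best N) and,
each iteration, to the current global best.

Fitness is minimised throughout.  Used downstream to tune DBN
hyperparameters with validation error as fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "GOAConfig",
    "Candidate",
    "Swarm",
    "social_force",
    "comfort_coefficient",
    "goa_update",
    "opposite",
    "obl_select",
    "egoa_optimize",
    "OptimizeResult",
]


@dataclass(frozen=True)
class Bounds:
    """Box constraints; ``integer_mask`` marks dimensions decoded by rounding."""

    lower: np.ndarray
    upper: np.ndarray
    integer_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise ValueError("lower/upper must be 1-D arrays of equal length")
        if not np.all(self.lower < self.upper):
            raise ValueError("each lower bound must be strictly below its upper bound")
        mask = (
            np.zeros(self.lower.size, dtype=bool)
            if self.integer_mask is None
            else np.asarray(self.integer_mask, dtype=bool)
        )
        if mask.shape != self.lower.shape:
            raise ValueError("integer_mask length mismatch")
        object.__setattr__(self, "integer_mask", mask)

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def decode(self, x: np.ndarray) -> np.ndarray:
        """Round integer dimensions half away from zero; search stays continuous."""
        out = np.asarray(x, dtype=float).copy()
        mask = self.integer_mask
        out[mask] = np.sign(out[mask]) * np.floor(np.abs(out[mask]) + 0.5)
        return out


@dataclass(frozen=True)
class GOAConfig:
    """Swarm size, iteration budget and social-force constants."""

    population: int = 30
    max_iterations: int = 100
    c_max: float = 1.0
    c_min: float = 0.00001
    social_intensity: float = 0.5
    attractive_length_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.c_min < self.c_max:
            raise ValueError("c_min must be below c_max")
        if self.social_intensity <= 0 or self.attractive_length_scale <= 0:
            raise ValueError("social constants must be positive")


@dataclass
class Candidate:
    """One grasshopper: a position inside the bounds and its fitness."""

    position: np.ndarray
    fitness: float = math.inf


@dataclass
class Swarm:
    candidates: list[Candidate]
    best: Candidate
    iteration: int = 0


def social_force(y: float | np.ndarray, f: float = 0.5, l_s: float = 1.5):
    """s(y) = f exp(-y/l_s) - exp(-y); negative = repulsion, positive = attraction."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("distance must be non-negative")
    out = f * np.exp(-y / l_s) - np.exp(-y)
    return float(out) if out.ndim == 0 else out


def comfort_coefficient(t: int, config: GOAConfig) -> float:
    """Linear shrink from c_max at t=0 to c_min at t=t_max."""
    if not 0 <= t <= config.max_iterations:
        raise ValueError(f"iteration {t} outside [0, {config.max_iterations}]")
    return config.c_max - t * (config.c_max - config.c_min) / config.max_iterations


def _normalised_gap(gap: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Map per-dimension distances from [0, span] into [1, 4].

    The raw social force saturates to ~0 beyond a few length units, which
    would freeze a swarm spread over wide bounds; remapping keeps every
    pair inside the force's active range.
    """
    return 1.0 + 3.0 * gap / span


def goa_update(swarm: Swarm, bounds: Bounds, config: GOAConfig) -> Swarm:
    """One synchronous position update of the whole swarm (Eq-14 style).

    x_i <- c * sum_{j != i} c * (u_d - l_d)/2 * s(gap_ij^d) * (x_j - x_i)/d_ij + T

    with d_ij the Euclidean distance, gap the per-dimension distance
    normalised into [1, 4], and T the global best.  Positions are clamped
    to the bounds; fitnesses are left stale for the caller to refresh.
    """
    c = comfort_coefficient(swarm.iteration, config)
    positions = np.array([cand.position for cand in swarm.candidates])
    n = positions.shape[0]
    span = bounds.upper - bounds.lower
    half_span = span / 2.0
    target = swarm.best.position
    new_positions = np.empty_like(positions)
    for i in range(n):
        social = np.zeros(bounds.dim)
        for j in range(n):
            if j == i:
                continue
            diff = positions[j] - positions[i]
            dist = float(np.linalg.norm(diff))
            if dist == 0.0:
                continue
            gap = _normalised_gap(np.abs(diff), span)
            social += (
                c
                * half_span
                * social_force(
                    gap, config.social_intensity, config.attractive_length_scale
                )
                * (diff / dist)
            )
        new_positions[i] = bounds.clamp(c * social + target)
    return Swarm(
        candidates=[
            Candidate(position=p, fitness=math.inf) for p in new_positions
        ],
        best=swarm.best,
        iteration=swarm.iteration,
    )


def opposite(x: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Bounds-mirrored point x̄ = u + l - x (an involution)."""
    return bounds.upper + bounds.lower - np.asarray(x, dtype=float)


def obl_select(
    candidate: Candidate, bounds: Bounds, fitness_fn: Callable[[np.ndarray], float]
) -> Candidate:
    """Keep the fitter of a candidate and its opposite; ties keep the original."""
    opp = opposite(candidate.position, bounds)
    opp_fit = float(fitness_fn(opp))
    if opp_fit < candidate.fitness:
        return Candidate(position=opp, fitness=opp_fit)
    return candidate


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float]
    n_evaluations: int
    trace: list[dict] = field(default_factory=list)


def egoa_optimize(
    fitness_fn: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: GOAConfig,
) -> OptimizeResult:
    """Minimise fitness_fn over the box by GOA with OBL elite selection.

    Initialisation samples N uniform positions plus their N opposites and
    keeps the best N.  Each iteration shrinks the comfort coefficient,
    applies the social update, re-evaluates the swarm, and replaces the
    global best by its opposite when the opposite is fitter.  The history
    records best-so-far fitness per iteration (non-increasing).  Fully
    reproducible from config.seed.  Fitness evaluations per run:
    2N + t_max + N * t_max.
    """
    rng = np.random.default_rng(config.seed)
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        return float(fitness_fn(x))

    def sample_uniform() -> np.ndarray:
        return bounds.lower + rng.random(bounds.dim) * (bounds.upper - bounds.lower)

    def safe_candidate(x: np.ndarray) -> Candidate:
        fit = evaluate(x)
        while not math.isfinite(fit):  # non-finite fitness: resample uniformly
            x = sample_uniform()
            fit = evaluate(x)
        return Candidate(position=x, fitness=fit)

    # OBL initialisation: N uniform + their N opposites, keep the best N
    primaries = [safe_candidate(sample_uniform()) for _ in range(config.population)]
    opposites = [
        safe_candidate(opposite(c.position, bounds)) for c in primaries
    ]
    pool = sorted(primaries + opposites, key=lambda c: c.fitness)
    candidates = pool[: config.population]
    best = Candidate(
        position=candidates[0].position.copy(), fitness=candidates[0].fitness
    )

    swarm = Swarm(candidates=candidates, best=best, iteration=0)
    history: list[float] = []
    trace: list[dict] = []
    for t in range(1, config.max_iterations + 1):
        swarm.iteration = t
        swarm = goa_update(swarm, bounds, config)
        for cand in swarm.candidates:
            cand.fitness = evaluate(cand.position)
            while not math.isfinite(cand.fitness):
                cand.position = sample_uniform()
                cand.fitness = evaluate(cand.position)
            if cand.fitness < swarm.best.fitness:
                swarm.best = Candidate(
                    position=cand.position.copy(), fitness=cand.fitness
                )
        swarm.best = obl_select(swarm.best, bounds, evaluate)
        history.append(swarm.best.fitness)
        trace.append(
            {
                "iteration": t,
                "c": comfort_coefficient(t, config),
                "best_fitness": swarm.best.fitness,
                "best_position": swarm.best.position.copy(),
            }
        )
    return OptimizeResult(
        best_position=swarm.best.position,
        best_fitness=swarm.best.fitness,
        history=history,
        n_evaluations=n_eval,
        trace=trace,
    )


def write_trace_csv(result: OptimizeResult, path) -> None:
    """Optimization trace as CSV: iteration, c, best_fitness, best_position."""
    import csv

    dim = result.best_position.size
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["iteration", "c", "best_fitness"] + [f"x{d+1}" for d in range(dim)]
        )
        for row in result.trace:
            writer.writerow(
                [row["iteration"], row["c"], row["best_fitness"]]
                + list(row["best_position"])
            )
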