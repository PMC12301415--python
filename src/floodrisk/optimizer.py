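"""Flood Algorithm (FLA) and Improved Flood Algorithm (IFLA).

The Flood Algorithm is a swarm-intelligence minimizer inspired by the
movement of water masses: each agent flows downhill toward the current
global best while diffusing along the difference of two random agents, and
a decaying "overflow" step periodically re-seeds the worst agents to keep
the population exploring.  The improved variant layers two enhancements on
the identical baseline step, so FLA-vs-IFLA comparisons isolate exactly
their effect:

- *sine-map initialization*: initial positions are drawn from independent
  chaotic sine-map orbits, c_{k+1} = gain * |sin(pi * c_k)|, whose
  near-uniform but space-filling itinerary spreads the first population
  more ergodically than i.i.d. uniform draws;
- *Cauchy mutation*: once per iteration the global best is perturbed with
  heavy-tailed standard-Cauchy noise at a linearly decaying scale,
  accepted only on strict improvement, enabling occasional long jumps out
  of local optima without ever degrading the best-so-far trajectory.

All randomness flows from a single integer seed; identical inputs give
bit-identical results.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ObjectiveFunction",
    "OptimizerConfig",
    "OptimizationResult",
    "TrialStatistics",
    "sine_map_sequence",
    "initialize_population",
    "cauchy_perturb",
    "optimize",
    "run_trials",
]

_SINE_GUARD = 1e-6


@dataclass(frozen=True)
class ObjectiveFunction:
    """Box-bounded continuous minimization problem.

    ``evaluate`` maps an (n, dim) array of positions to an (n,) array of
    fitness values and must be deterministic.
    """

    dim: int
    lower: np.ndarray
    upper: np.ndarray
    evaluate: Callable[[np.ndarray], np.ndarray]
    known_optimum: float | None = None
    known_position: np.ndarray | None = None
    name: str = ""

    def __post_init__(self) -> None:
        lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def __call__(self, positions: np.ndarray) -> np.ndarray:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        values = np.asarray(self.evaluate(positions), dtype=float)
        if not np.all(np.isfinite(values)):
            bad = positions[~np.isfinite(values)][0]
            raise ValueError(
                f"objective {self.name or '<anonymous>'} returned a non-finite "
                f"value at position {bad.tolist()}"
            )
        return values


@dataclass(frozen=True)
class OptimizerConfig:
    population_size: int = 30
    max_iterations: int = 500
    seed: int = 0
    variant: str = "fla"
    overflow_fraction: float = 0.1
    mutation_scale0: float = 0.1
    sine_map_gain: float = 0.99

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.variant not in ("fla", "ifla"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_position": self.best_position.tolist(),
                "best_fitness": self.best_fitness,
                "history": self.history.tolist(),
                "evaluations": self.evaluations,
            }
        )

    def history_to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "best_fitness"])
            for t, value in enumerate(self.history, start=1):
                writer.writerow([t, value])


@dataclass
class TrialStatistics:
    """Per-run best fitnesses over independent optimizer runs."""

    bests: np.ndarray
    mean: float
    sd: float
    median: float
    min: float
    max: float

    @classmethod
    def from_bests(cls, bests: Sequence[float]) -> "TrialStatistics":
        bests = np.asarray(bests, dtype=float)
        return cls(
            bests=bests,
            mean=float(bests.mean()),
            sd=float(bests.std(ddof=1)) if bests.size > 1 else 0.0,
            median=float(np.median(bests)),
            min=float(bests.min()),
            max=float(bests.max()),
        )


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def sine_map_sequence(
    c0: float,
    gain: float = 0.99,
    length: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Iterate the chaotic sine map c_{k+1} = gain * |sin(pi * c_k)|.

    Returns the ``length`` iterates after ``c0`` (``c0`` itself excluded).
    Orbits falling below 1e-6 are restarted from a fresh uniform draw: the
    map has a measure-zero absorbing orbit at 0 which would otherwise
    freeze the itinerary.
    """
    if not 0.0 < c0 < 1.0:
        raise ValueError("c0 must lie strictly inside (0, 1)")
    if not 0.0 < gain <= 1.0:
        raise ValueError("gain must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    out = np.empty(length)
    c = c0
    for k in range(length):
        c = gain * abs(math.sin(math.pi * c))
        if c < _SINE_GUARD:
            c = rng.uniform(_SINE_GUARD, 1.0 - _SINE_GUARD)
        out[k] = c
    return out


def initialize_population(
    objective: ObjectiveFunction, config: OptimizerConfig
) -> np.ndarray:
    """Seeded initial positions: sine-map orbits (ifla) or uniform (fla)."""
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, objective.dim
    if config.variant == "ifla":
        coords = np.empty((n, d))
        for j in range(d):
            c0 = rng.uniform(_SINE_GUARD, 1.0 - _SINE_GUARD)
            coords[:, j] = sine_map_sequence(c0, config.sine_map_gain, n, rng)
        positions = objective.lower + coords * (objective.upper - objective.lower)
    else:
        positions = rng.uniform(objective.lower, objective.upper, size=(n, d))
    return positions


def cauchy_perturb(
    position: np.ndarray,
    scale: np.ndarray,
    rng: np.random.Generator,
    lower: np.ndarray | None = None,
    upper: np.ndarray | None = None,
) -> np.ndarray:
    """Heavy-tailed jump: position + scale * C with C standard Cauchy.

    C is sampled by inverse CDF, C = tan(pi * (u - 1/2)) with u uniform;
    half of all draws satisfy |C| > 1, giving frequent long jumps.  The
    result is clipped to the box bounds when given.
    """
    position = np.asarray(position, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if np.any(scale < 0):
        raise ValueError("scale must be non-negative")
    u = rng.random(position.shape)
    c = np.tan(np.pi * (u - 0.5))
    out = position + scale * c
    if lower is not None:
        out = np.clip(out, lower, upper)
    return out


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def optimize(objective: ObjectiveFunction, config: OptimizerConfig) -> OptimizationResult:
    """Run FLA or IFLA for ``max_iterations`` and return the trajectory.

    One iteration: (1) every agent proposes a downhill-flow move
    x + r1*(best - x) + r2*(x_a - x_b), clipped and accepted greedily;
    (2) [ifla only] the global best receives one Cauchy mutation at scale
    mutation_scale0 * range * (1 - t/T), accepted on strict improvement;
    (3) with probability overflow_fraction * (1 - t/T) the worst
    ceil(overflow_fraction * N) agents are re-seeded uniformly.  Re-seeded
    agents carry sentinel fitness +inf and are re-evaluated through their
    next proposal, which bounds total evaluations by N*(T+1) + T.
    """
    rng = np.random.default_rng(config.seed)
    n, d, T = config.population_size, objective.dim, config.max_iterations
    lower, upper = objective.lower, objective.upper

    positions = initialize_population(objective, config)
    fitness = objective(positions)
    evaluations = n

    best_idx = int(np.argmin(fitness))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitness[best_idx])

    history = np.empty(T)
    n_overflow = math.ceil(config.overflow_fraction * n)

    for t in range(1, T + 1):
        decay = 1.0 - t / T

        # downhill flow + differential diffusion
        a = rng.integers(n, size=n)
        b = rng.integers(n, size=n)
        clash = a == b
        while np.any(clash):
            b[clash] = rng.integers(n, size=int(clash.sum()))
            clash = a == b
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        proposals = positions + r1 * (best_pos - positions) + r2 * (
            positions[a] - positions[b]
        )
        np.clip(proposals, lower, upper, out=proposals)
        prop_fit = objective(proposals)
        evaluations += n
        accept = prop_fit < fitness
        positions[accept] = proposals[accept]
        fitness[accept] = prop_fit[accept]

        idx = int(np.argmin(fitness))
        if fitness[idx] < best_fit:
            best_fit = float(fitness[idx])
            best_pos = positions[idx].copy()

        # Cauchy mutation of the global best (improved variant only)
        if config.variant == "ifla":
            scale = config.mutation_scale0 * (upper - lower) * decay
            candidate = cauchy_perturb(best_pos, scale, rng, lower, upper)
            cand_fit = float(objective(candidate[None, :])[0])
            evaluations += 1
            if cand_fit < best_fit:
                best_fit = cand_fit
                best_pos = candidate.copy()
                worst = int(np.argmax(fitness))
                positions[worst] = candidate
                fitness[worst] = cand_fit

        # overflow: re-seed the worst agents, decaying probability
        if rng.random() < config.overflow_fraction * decay:
            worst = np.argsort(fitness)[-n_overflow:]
            positions[worst] = rng.uniform(lower, upper, size=(n_overflow, d))
            fitness[worst] = np.inf

        history[t - 1] = best_fit

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=history,
        evaluations=evaluations,
    )


def run_trials(
    objective: ObjectiveFunction, config: OptimizerConfig, n_runs: int
) -> TrialStatistics:
    """Independent repeats; run k uses seed = config.seed + k."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    bests = []
    for k in range(n_runs):
        run_config = OptimizerConfig(
            population_size=config.population_size,
            max_iterations=config.max_iterations,
            seed=config.seed + k,
            variant=config.variant,
            overflow_fraction=config.overflow_fraction,
            mutation_scale0=config.mutation_scale0,
            sine_map_gain=config.sine_map_gain,
        )
        bests.append(optimize(objective, run_config).best_fitness)
    return TrialStatistics.from_bests(bests)
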