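"""Benchmark-function validation suite for the flood optimizers.

Twelve continuous test problems in the spirit of the CEC optimization
suites: unimodal, multimodal, and hybrid shifted/rotated compositions,
including Schwefel, Rosenbrock and the Lunacek bi-Rastrigin.  The suite is
fully self-contained: shifts are seeded random vectors, hybrid rotations
are seeded random orthogonal matrices, and every function carries an
analytic form with a documented global optimum so optimizer output can be
checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import ortho_group, ranksums

from .optimizer import ObjectiveFunction, OptimizerConfig, TrialStatistics, optimize

__all__ = ["BenchmarkSuite", "ComparisonResult", "make_suite", "compare_algorithms"]


# --- analytic cores: each has global minimum 0 at the stated position -------

def _sphere(z):
    return np.sum(z**2, axis=1)


def _rosenbrock(z):
    return np.sum(100.0 * (z[:, 1:] - z[:, :-1] ** 2) ** 2 + (1.0 - z[:, :-1]) ** 2, axis=1)


def _rastrigin(z):
    return np.sum(z**2 - 10.0 * np.cos(2.0 * np.pi * z) + 10.0, axis=1)


def _ackley(z):
    d = z.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(z**2, axis=1) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * z), axis=1) / d)
        + 20.0
        + np.e
    )


def _griewank(z):
    d = z.shape[1]
    i = np.arange(1, d + 1)
    return 1.0 + np.sum(z**2, axis=1) / 4000.0 - np.prod(np.cos(z / np.sqrt(i)), axis=1)


def _zakharov(z):
    d = z.shape[1]
    s = np.sum(0.5 * np.arange(1, d + 1) * z, axis=1)
    return np.sum(z**2, axis=1) + s**2 + s**4


def _levy(z):
    # minimum 0 at z = 1
    w = 1.0 + (z - 1.0) / 4.0
    term1 = np.sin(np.pi * w[:, 0]) ** 2
    term3 = (w[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[:, -1]) ** 2)
    mid = w[:, :-1]
    term2 = np.sum((mid - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * mid + 1.0) ** 2), axis=1)
    return term1 + term2 + term3


def _schwefel_peak() -> tuple[float, float]:
    """Location and height of the per-dimension Schwefel minimizer."""
    res = minimize_scalar(
        lambda x: -x * np.sin(np.sqrt(x)),
        bounds=(400.0, 440.0),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.x), float(-res.fun)


def _make_schwefel(dim: int) -> ObjectiveFunction:
    x_star, peak = _schwefel_peak()

    def evaluate(x):
        return peak * dim - np.sum(x * np.sin(np.sqrt(np.abs(x))), axis=1)

    return ObjectiveFunction(
        dim=dim,
        lower=-500.0,
        upper=500.0,
        evaluate=evaluate,
        known_optimum=0.0,
        known_position=np.full(dim, x_star),
        name="schwefel",
    )


def _make_lunacek(dim: int) -> ObjectiveFunction:
    mu0 = 2.5
    s = 1.0 - 1.0 / (2.0 * np.sqrt(dim + 20.0) - 8.2)
    mu1 = -np.sqrt((mu0**2 - 1.0) / s)

    def evaluate(x):
        sphere0 = np.sum((x - mu0) ** 2, axis=1)
        sphere1 = dim + s * np.sum((x - mu1) ** 2, axis=1)
        cosine = 10.0 * (dim - np.sum(np.cos(2.0 * np.pi * (x - mu0)), axis=1))
        return np.minimum(sphere0, sphere1) + cosine

    return ObjectiveFunction(
        dim=dim,
        lower=-5.12,
        upper=5.12,
        evaluate=evaluate,
        known_optimum=0.0,
        known_position=np.full(dim, mu0),
        name="lunacek_bi_rastrigin",
    )


def _shifted(core, name, dim, bound, core_opt, shift) -> ObjectiveFunction:
    """Shifted classical function: f(x) = core(x - shift), optimum at core_opt + shift."""

    def evaluate(x):
        return core(x - shift)

    return ObjectiveFunction(
        dim=dim,
        lower=-bound,
        upper=bound,
        evaluate=evaluate,
        known_optimum=0.0,
        known_position=core_opt + shift,
        name=name,
    )


def _hybrid(cores, name, dim, bound, shift, rotation) -> ObjectiveFunction:
    """Rotated-shifted hybrid: components act on halves of z = R @ (x - shift)."""
    split = dim // 2

    def evaluate(x):
        z = (x - shift) @ rotation.T
        return cores[0](z[:, :split]) + cores[1](z[:, split:])

    return ObjectiveFunction(
        dim=dim,
        lower=-bound,
        upper=bound,
        evaluate=evaluate,
        known_optimum=0.0,
        known_position=shift.copy(),
        name=name,
    )


@dataclass
class BenchmarkSuite:
    functions: list[ObjectiveFunction]
    dim: int
    seed: int

    def __iter__(self):
        return iter(self.functions)

    def __len__(self):
        return len(self.functions)

    def by_name(self, name: str) -> ObjectiveFunction:
        for f in self.functions:
            if f.name == name:
                return f
        raise KeyError(name)


def make_suite(dim: int = 10, seed: int = 0) -> BenchmarkSuite:
    """Build the 12-function suite at ``dim`` with seeded shifts/rotations.

    Nine classics carry a random shift drawn within 30% of their box (so the
    optimum never sits on the boundary); Schwefel and the Lunacek
    bi-Rastrigin keep their canonical off-origin optima; the three hybrids
    compose pairs of multimodal cores under a random orthogonal rotation.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(seed)

    def shift_for(bound):
        return rng.uniform(-0.3 * bound, 0.3 * bound, size=dim)

    zeros = np.zeros(dim)
    ones = np.ones(dim)
    functions = [
        _shifted(_sphere, "sphere", dim, 100.0, zeros, shift_for(100.0)),
        _shifted(_rosenbrock, "rosenbrock", dim, 30.0, ones, shift_for(10.0)),
        _shifted(_rastrigin, "rastrigin", dim, 5.12, zeros, shift_for(5.12)),
        _shifted(_ackley, "ackley", dim, 32.768, zeros, shift_for(32.768)),
        _shifted(_griewank, "griewank", dim, 600.0, zeros, shift_for(600.0)),
        _shifted(_zakharov, "zakharov", dim, 10.0, zeros, shift_for(10.0)),
        _shifted(_levy, "levy", dim, 10.0, ones, shift_for(5.0)),
        _make_schwefel(dim),
        _make_lunacek(dim),
    ]
    for name, cores in [
        ("hybrid_sphere_rastrigin", (_sphere, _rastrigin)),
        ("hybrid_ackley_griewank", (_ackley, _griewank)),
        ("hybrid_rastrigin_zakharov", (_rastrigin, _zakharov)),
    ]:
        rotation = ortho_group.rvs(dim, random_state=rng)
        shift = rng.uniform(-2.0, 2.0, size=dim)
        functions.append(_hybrid(cores, name, dim, 10.0, shift, rotation))
    return BenchmarkSuite(functions=functions, dim=dim, seed=seed)


# ---------------------------------------------------------------------------
# Algorithm comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Multi-run comparison of optimizer configurations over a suite.

    ``table``: one row per function x algorithm with run statistics.
    ``pairwise``: two-sided Wilcoxon rank-sum p-values per function and pair.
    ``per_run``: long-format per-run best fitnesses (boxplot-ready).
    ``convergence``: mean best-so-far trajectory per function x algorithm.
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    per_run: pd.DataFrame
    convergence: pd.DataFrame

    def to_csv(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(directory / "comparison_table.csv", index=False)
        self.pairwise.to_csv(directory / "pairwise_tests.csv", index=False)
        self.per_run.to_csv(directory / "per_run_bests.csv", index=False)
        self.convergence.to_csv(directory / "convergence_curves.csv", index=False)


def _label(config: OptimizerConfig, index: int, labels) -> str:
    if labels is not None:
        return labels[index]
    return config.variant


def compare_algorithms(
    suite: BenchmarkSuite,
    configs: list[OptimizerConfig],
    n_runs: int = 30,
    labels: list[str] | None = None,
) -> ComparisonResult:
    """Run every config ``n_runs`` times on every function and compare.

    Run k of every configuration uses seed = config.seed + k, so configs
    sharing a base seed are compared on paired seed streams.
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations to compare")
    rows, per_run_rows, convergence_rows, pair_rows = [], [], [], []
    bests: dict[tuple[str, str], np.ndarray] = {}
    for func in suite:
        for i, config in enumerate(configs):
            label = _label(config, i, labels)
            run_bests = []
            histories = []
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
                result = optimize(func, run_config)
                run_bests.append(result.best_fitness)
                histories.append(result.history)
            stats = TrialStatistics.from_bests(run_bests)
            bests[(func.name, label)] = stats.bests
            rows.append(
                {
                    "function": func.name,
                    "algorithm": label,
                    "mean": stats.mean,
                    "sd": stats.sd,
                    "median": stats.median,
                    "min": stats.min,
                    "max": stats.max,
                }
            )
            for k, best in enumerate(run_bests):
                per_run_rows.append(
                    {"function": func.name, "algorithm": label, "run": k, "best": best}
                )
            mean_history = np.mean(histories, axis=0)
            for t, value in enumerate(mean_history, start=1):
                convergence_rows.append(
                    {
                        "function": func.name,
                        "algorithm": label,
                        "iteration": t,
                        "mean_best": value,
                    }
                )
        label_list = [_label(c, i, labels) for i, c in enumerate(configs)]
        for i in range(len(configs)):
            for j in range(i + 1, len(configs)):
                a, b = label_list[i], label_list[j]
                stat, p = ranksums(bests[(func.name, a)], bests[(func.name, b)])
                pair_rows.append(
                    {
                        "function": func.name,
                        "algorithm_a": a,
                        "algorithm_b": b,
                        "statistic": float(stat),
                        "p_value": float(p),
                    }
                )
    return ComparisonResult(
        table=pd.DataFrame(rows),
        pairwise=pd.DataFrame(pair_rows),
        per_run=pd.DataFrame(per_run_rows),
        convergence=pd.DataFrame(convergence_rows),
    )
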