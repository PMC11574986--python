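"""Genetic-algorithm wavelength selection for PLS calibration.

Chromosomes are binary vectors over contiguous wavelength windows
(default width 2 grid points). Fitness is the cross-validated RMSE of a
PLS-1 model restricted to the switched-on windows, with the LV count
chosen by an inner argmin capped at ``max_lv``. Selection is survival
of the fittest: the better half of the population survives each
generation and is refilled by single-point crossover of randomly paired
survivors; offspring genes mutate independently. CV folds are random,
redrawn each generation from a generation-indexed seeded stream, so a
run is fully reproducible from its seed while chromosomes within one
generation compete on identical folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidParameterError, ShapeError
from .pls import _truncated_regression_vectors

__all__ = ["GaConfig", "GaResult", "build_windows", "ga_fitness", "ga_run", "expand_selection"]


@dataclass(frozen=True)
class GaConfig:
    """GA hyperparameters.

    Defaults are the settings used for the overlapped analytes in the
    reference workflow: population 50 (20 for the easiest analyte),
    50 generations, mutation rate 0.005 per gene, window width 2,
    half the windows on at initiation, stop when the whole population
    is identical, single-point crossover, random 4-subset CV repeated
    twice per generation.
    """

    population_size: int = 50
    max_generations: int = 50
    mutation_rate: float = 0.005
    window_width: int = 2
    init_on_fraction: float = 0.5
    convergence_fraction: float = 1.0
    max_lv: int = 6
    cv_subsets: int = 4
    cv_iterations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mutation_rate < 1:
            raise ConfigError("mutation_rate must be in (0, 1)")
        if self.window_width < 1:
            raise ConfigError("window_width must be >= 1")
        if self.cv_subsets < 2:
            raise ConfigError("cv_subsets must be >= 2")
        if self.population_size < 4:
            raise ConfigError("population_size must be >= 4")
        if not 0 < self.init_on_fraction <= 1:
            raise ConfigError("init_on_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GaResult:
    """Outcome of a GA run."""

    best_chromosome: np.ndarray            # bool (n_windows,)
    selected_windows: np.ndarray           # indices of on-windows
    selected_wavelengths_nm: np.ndarray    # expanded wavelength values
    best_fitness_per_generation: np.ndarray  # running best RMSECV, ug/mL
    generations_run: int
    final_population: np.ndarray           # bool (pop, n_windows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "selected_windows": self.selected_windows.tolist(),
                    "selected_wavelengths_nm": self.selected_wavelengths_nm.tolist(),
                    "best_fitness_per_generation": self.best_fitness_per_generation.tolist(),
                    "generations_run": int(self.generations_run),
                },
                fh,
            )


def build_windows(n_points: int, window_width: int) -> list[np.ndarray]:
    """Partition column indices 0..n_points-1 into consecutive windows.

    The final window is shorter when n_points is not divisible by the
    width, so the windows always cover every column exactly once.
    """
    if n_points < window_width:
        raise InvalidParameterError("n_points must be >= window_width")
    return [
        np.arange(start, min(start + window_width, n_points))
        for start in range(0, n_points, window_width)
    ]


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random balanced assignment of n samples to k folds."""
    folds = np.resize(np.arange(k), n)
    rng.shuffle(folds)
    return folds


def _cv_rmse_curve(X, y, folds, a_max) -> np.ndarray:
    """Cross-validated RMSE for LV counts 1..a_max under one fold split."""
    n = len(y)
    press = np.zeros(a_max)
    for f in np.unique(folds):
        test = folds == f
        bs, x_mean, y_mean = _truncated_regression_vectors(X[~test], y[~test], a_max)
        for a_idx, b in enumerate(bs):
            pred = y_mean + (X[test] - x_mean) @ b
            press[a_idx] += np.sum((pred - y[test]) ** 2)
    return np.sqrt(press / n)


def _fitness_rng(config: GaConfig, generation: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(1, generation))
    )


def ga_fitness(
    chromosome: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    config: GaConfig,
    generation: int = 0,
    windows: list[np.ndarray] | None = None,
) -> float:
    """Cross-validated RMSE (ug/mL) of a PLS model on the on-windows.

    All-off chromosomes score infinity and are never selected. The LV
    count is the inner argmin of the iteration-averaged CV curve, capped
    at ``min(max_lv, n_selected_columns, n - fold_size - 1)``.
    """
    chromosome = np.asarray(chromosome, dtype=bool)
    if windows is None:
        windows = build_windows(X.shape[1], config.window_width)
    if chromosome.shape != (len(windows),):
        raise ShapeError("chromosome length must equal the window count")
    if not chromosome.any():
        return float("inf")
    cols = np.concatenate([windows[i] for i in np.flatnonzero(chromosome)])
    Xs = X[:, cols]
    n = X.shape[0]
    fold_size = int(np.ceil(n / config.cv_subsets))
    a_max = int(min(config.max_lv, cols.size, n - fold_size - 1))
    if a_max < 1:
        return float("inf")
    rng = _fitness_rng(config, generation)
    curves = np.zeros(a_max)
    for _ in range(config.cv_iterations):
        folds = _fold_assignments(n, config.cv_subsets, rng)
        curves += _cv_rmse_curve(Xs, y, folds, a_max)
    return float(np.min(curves / config.cv_iterations))


def _evaluate(population, X, y, config, generation, windows):
    return np.array(
        [ga_fitness(c, X, y, config, generation, windows) for c in population]
    )


def ga_run(X: np.ndarray, y: np.ndarray, config: GaConfig, wavelengths=None) -> GaResult:
    """Run the GA and return the best chromosome ever observed.

    Stops at ``max_generations`` or when ``convergence_fraction`` of the
    population shares one chromosome. The fitness trace is the running
    best, hence non-increasing (elitist bookkeeping).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ShapeError("X and y must be row-matched")
    windows = build_windows(X.shape[1], config.window_width)
    n_win = len(windows)
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    population = rng.random((config.population_size, n_win)) < config.init_on_fraction
    for row in population:  # repair: at least one window on
        if not row.any():
            row[rng.integers(n_win)] = True

    fitness = _evaluate(population, X, y, config, 0, windows)
    best_idx = int(np.argmin(fitness))
    best_chrom = population[best_idx].copy()
    best_fit = fitness[best_idx]
    trace = [best_fit]
    generations = 0

    for gen in range(1, config.max_generations + 1):
        # convergence: a sufficient fraction of identical chromosomes
        _, counts = np.unique(population, axis=0, return_counts=True)
        if counts.max() / config.population_size >= config.convergence_fraction:
            break

        order = np.argsort(fitness, kind="stable")
        survivors = population[order[: config.population_size // 2]]
        n_children = config.population_size - survivors.shape[0]
        children = np.empty((n_children, n_win), dtype=bool)
        for c in range(n_children):
            i, j = rng.choice(survivors.shape[0], size=2, replace=False)
            cut = int(rng.integers(1, n_win)) if n_win > 1 else 0
            children[c, :cut] = survivors[i, :cut]
            children[c, cut:] = survivors[j, cut:]
        # per-gene mutation on offspring only
        flips = rng.random(children.shape) < config.mutation_rate
        children ^= flips

        population = np.vstack([survivors, children])
        fitness = _evaluate(population, X, y, config, gen, windows)
        generations = gen
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = fitness[gen_best]
            best_chrom = population[gen_best].copy()
        trace.append(best_fit)

    sel = np.flatnonzero(best_chrom)
    sel_wl = np.sort(np.concatenate([wavelengths[windows[i]] for i in sel]))
    return GaResult(
        best_chromosome=best_chrom,
        selected_windows=sel,
        selected_wavelengths_nm=sel_wl,
        best_fitness_per_generation=np.array(trace),
        generations_run=generations,
        final_population=population,
    )


def expand_selection(result: GaResult, wavelengths: np.ndarray, window_width: int = 2):
    """Expand on-windows to (sorted wavelength subset, column indices)."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    windows = build_windows(wavelengths.size, window_width)
    if result.selected_windows.size == 0:
        raise InvalidParameterError("GA result selects no windows")
    if result.selected_windows.max() >= len(windows):
        raise InvalidParameterError("selected windows exceed the grid")
    cols = np.sort(np.concatenate([windows[i] for i in result.selected_windows]))
    return wavelengths[cols], cols
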