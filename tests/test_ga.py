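"""GA wavelength selection: window arithmetic, fitness oracles,
planted-signal recovery and elitism."""

import numpy as np
import pytest

from chemocal.errors import ConfigError, InvalidParameterError, ShapeError
from chemocal.ga import GaConfig, build_windows, expand_selection, ga_fitness, ga_run


def planted_signal_problem(seed=123, n=36, n_points=80):
    """y is carried only by columns of windows 10-20; the rest is noise."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(5, 25, size=n)
    X = rng.normal(0.0, 1.0, size=(n, n_points))
    signal_cols = np.arange(20, 42)  # windows 10..20 inclusive at width 2
    loadings = rng.uniform(0.5, 1.5, size=signal_cols.size)
    X[:, signal_cols] = np.outer(y, loadings) + rng.normal(0, 0.01, (n, signal_cols.size))
    return X, y, set(range(10, 21))


class TestBuildWindows:
    @pytest.mark.parametrize("n_points,width,expected", [(180, 2, 90), (80, 2, 40)])
    def test_window_counts(self, n_points, width, expected):
        assert len(build_windows(n_points, width)) == expected

    def test_remainder_window_shorter(self):
        sizes = [len(w) for w in build_windows(5, 2)]
        assert sizes == [2, 2, 1]

    def test_windows_partition_all_columns(self):
        wins = build_windows(17, 3)
        cols = np.concatenate(wins)
        assert np.array_equal(np.sort(cols), np.arange(17))
        assert len(set(map(tuple, wins))) == len(wins)


class TestGaFitness:
    def test_all_on_noiseless_data_near_zero(self, noiseless_cal):
        # three noiseless components: 6 LVs more than suffice, so the
        # cross-validated error is numerically zero
        from chemocal.dataset import WavelengthWindow, select_window

        ds = select_window(noiseless_cal, WavelengthWindow(240, 259))
        X = ds.absorbance
        y = ds.concentrations.column("RUP")
        cfg = GaConfig(max_lv=6, seed=1)
        chrom = np.ones(10, dtype=bool)
        assert ga_fitness(chrom, X, y, cfg) < 1e-6

    def test_pure_noise_columns_score_near_sd_y(self):
        # null model: no usable signal leaves RMSECV near the SD of y
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 10))
        y = rng.uniform(5, 25, size=40)
        cfg = GaConfig(max_lv=2, seed=2)
        fit = ga_fitness(np.ones(5, dtype=bool), X, y, cfg)
        assert abs(fit - y.std()) / y.std() < 0.2

    def test_all_off_chromosome_is_infinite(self):
        X = np.random.default_rng(0).normal(size=(10, 6))
        y = np.arange(10.0)
        assert ga_fitness(np.zeros(3, dtype=bool), X, y, GaConfig()) == np.inf

    def test_same_seed_same_fitness(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(16, 12))
        y = rng.normal(size=16)
        cfg = GaConfig(seed=99)
        chrom = np.array([1, 0, 1, 1, 0, 1], dtype=bool)
        assert ga_fitness(chrom, X, y, cfg, generation=3) == ga_fitness(
            chrom, X, y, cfg, generation=3
        )

    def test_chromosome_length_must_match_windows(self):
        X = np.zeros((10, 8))
        with pytest.raises(ShapeError):
            ga_fitness(np.ones(3, dtype=bool), X, np.zeros(10), GaConfig())


class TestGaRun:
    def test_planted_signal_recovery(self):
        X, y, signal_windows = planted_signal_problem()
        cfg = GaConfig(
            population_size=50, max_generations=100, max_lv=2,
            mutation_rate=0.01, seed=5,
        )
        result = ga_run(X[:16], y[:16], cfg)
        selected = set(result.selected_windows.tolist())
        in_signal = len(selected & signal_windows) / len(selected)
        assert in_signal >= 0.8

    def test_best_fitness_trace_non_increasing(self):
        X, y, _ = planted_signal_problem(seed=7)
        result = ga_run(X, y, GaConfig(population_size=12, max_generations=10, seed=8))
        trace = result.best_fitness_per_generation
        assert np.all(np.diff(trace) <= 1e-15)

    def test_zero_generations_returns_best_of_initial_population(self):
        X, y, _ = planted_signal_problem(seed=9)
        cfg = GaConfig(population_size=8, max_generations=0, seed=10)
        result = ga_run(X, y, cfg)
        assert result.generations_run == 0
        fits = [
            ga_fitness(c, X, y, cfg, generation=0) for c in result.final_population
        ]
        assert result.best_fitness_per_generation[-1] == pytest.approx(min(fits))

    def test_run_is_deterministic(self):
        X, y, _ = planted_signal_problem(seed=11)
        cfg = GaConfig(population_size=10, max_generations=5, seed=12)
        a = ga_run(X, y, cfg)
        b = ga_run(X, y, cfg)
        assert np.array_equal(a.best_chromosome, b.best_chromosome)
        assert np.array_equal(a.best_fitness_per_generation, b.best_fitness_per_generation)

    def test_converged_population_stops_early(self):
        X, y, _ = planted_signal_problem(seed=13)
        cfg = GaConfig(population_size=8, max_generations=50, convergence_fraction=0.5, seed=14)
        result = ga_run(X, y, cfg)
        assert result.generations_run <= 50

    def test_tiny_population_rejected(self):
        with pytest.raises(ConfigError):
            GaConfig(population_size=3)


class TestExpandSelection:
    def test_thirteen_windows_give_26_wavelengths(self):
        X, y, _ = planted_signal_problem(seed=15)
        cfg = GaConfig(population_size=8, max_generations=2, seed=16)
        result = ga_run(X, y, cfg)
        wl = np.arange(221.0, 301.0)
        wavelengths, cols = expand_selection(result, wl, window_width=2)
        assert len(wavelengths) == 2 * len(result.selected_windows)
        assert np.array_equal(wavelengths, wl[cols])
        assert np.all(np.diff(wavelengths) > 0)

    def test_windows_share_no_wavelengths(self):
        wins = build_windows(80, 2)
        flat = np.concatenate(wins)
        assert len(flat) == len(set(flat.tolist()))

    def test_empty_selection_rejected(self):
        from chemocal.ga import GaResult

        empty = GaResult(
            best_chromosome=np.zeros(4, dtype=bool),
            selected_windows=np.array([], dtype=int),
            selected_wavelengths_nm=np.array([]),
            best_fitness_per_generation=np.array([np.inf]),
            generations_run=0,
            final_population=np.zeros((4, 4), dtype=bool),
        )
        with pytest.raises(InvalidParameterError):
            expand_selection(empty, np.arange(8.0), 2)
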