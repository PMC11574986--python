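"""End-to-end orchestration of the four calibration variants.

For each analyte the pipeline selects its wavelength window (the full
221-400 nm range for the spectrally isolated MON-like analyte, the
crowded 221-300 nm range for the overlapped pair), optionally runs GA
wavelength selection, fits the regression model (PLS-1 or linear ANN)
and evaluates recoveries on the validation set.

Note on the ANN variants: following the reference workflow, the
validation set is the early-stopping monitor during network training,
so ANN-mode validation statistics are not computed on fully independent
data. The PLS variants never touch the validation set during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .ann import AnnConfig, forward, init_network, scan_hidden, train_lm
from .dataset import SpectralDataset, WavelengthWindow, select_window
from .design import ANALYTES, calibration_table, validation_fixture
from .errors import InvalidParameterError
from .ga import GaConfig, expand_selection, ga_run
from .pls import fit_with_loo, predict
from .simulate import simulate_dataset
from .stats import EvaluationReport, evaluation_report, rmse

__all__ = ["PipelineConfig", "VariantResult", "VARIANTS", "simulate_default",
           "run_variant", "run_analyte"]

VARIANTS = ("pls", "ga-pls", "ann", "ga-ann")

#: Analyte wavelength windows (nm, inclusive).
DEFAULT_WINDOWS = {"MON": (221.0, 400.0), "RUP": (221.0, 300.0), "DES": (221.0, 300.0)}
#: GA population size per analyte (smaller for the easiest analyte).
DEFAULT_GA_POPULATION = {"MON": 50, "RUP": 50, "DES": 20}
#: LV cap used inside GA fitness, matching the PLS-1 model complexity.
DEFAULT_GA_MAX_LV = {"MON": 2, "RUP": 6, "DES": 6}
#: Hidden-neuron counts scanned for the ANN variants.
DEFAULT_HIDDEN_CANDIDATES = (1, 3, 5, 8, 15)


@dataclass(frozen=True)
class PipelineConfig:
    """Pipeline-wide settings; per-analyte values keyed by analyte name."""

    seed: int = 0
    noise_sd: float = 0.002
    saturation_limit: float | None = 3.0
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    ga_population: dict = field(default_factory=lambda: dict(DEFAULT_GA_POPULATION))
    ga_max_lv: dict = field(default_factory=lambda: dict(DEFAULT_GA_MAX_LV))
    ga_generations: int = 50
    ga_mutation_rate: float = 0.005
    ga_window_width: int = 2
    pls_a_max: int = 10
    hidden_candidates: tuple = DEFAULT_HIDDEN_CANDIDATES
    ann_max_epochs: int = 1000
    ann_patience: int = 6

    def to_yaml(self, path) -> None:
        d = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "saturation_limit": self.saturation_limit,
            "windows": {k: list(v) for k, v in self.windows.items()},
            "ga_population": dict(self.ga_population),
            "ga_max_lv": dict(self.ga_max_lv),
            "ga_generations": self.ga_generations,
            "ga_mutation_rate": self.ga_mutation_rate,
            "ga_window_width": self.ga_window_width,
            "pls_a_max": self.pls_a_max,
            "hidden_candidates": list(self.hidden_candidates),
            "ann_max_epochs": self.ann_max_epochs,
            "ann_patience": self.ann_patience,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "windows" in d:
            d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
        if "hidden_candidates" in d:
            d["hidden_candidates"] = tuple(d["hidden_candidates"])
        return cls(**d)


@dataclass(frozen=True)
class VariantResult:
    """Fitted model plus evaluation for one analyte under one variant."""

    analyte: str
    variant: str
    report: EvaluationReport
    n_lv: int | None = None
    hidden_neurons: int | None = None
    selected_wavelengths_nm: np.ndarray | None = None
    model: object = None


def simulate_default(config: PipelineConfig):
    """Simulate the standard calibration and validation datasets."""
    cal = simulate_dataset(
        calibration_table(),
        noise_sd=config.noise_sd,
        saturation_limit=config.saturation_limit,
        seed=config.seed,
    )
    val = simulate_dataset(
        validation_fixture(),
        noise_sd=config.noise_sd,
        saturation_limit=config.saturation_limit,
        seed=config.seed + 1,
    )
    return cal, val


def _analyte_seed(config: PipelineConfig, analyte: str) -> int:
    return (config.seed * 7 + ANALYTES.index(analyte) + 1) % (2**31 - 1)


def run_analyte(
    cal: SpectralDataset,
    val: SpectralDataset,
    analyte: str,
    variant: str,
    config: PipelineConfig,
) -> VariantResult:
    """Window -> (optional GA) -> model fit -> validation report."""
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    lo, hi = config.windows[analyte]
    window = WavelengthWindow(lo, hi)
    cal_w = select_window(cal, window)
    val_w = select_window(val, window)
    X_cal, X_val = cal_w.absorbance, val_w.absorbance
    y_cal = cal_w.concentrations.column(analyte)
    y_val = val_w.concentrations.column(analyte)
    wavelengths = cal_w.wavelengths_nm
    seed = _analyte_seed(config, analyte)

    selected_wl = None
    if variant.startswith("ga-"):
        ga_cfg = GaConfig(
            population_size=config.ga_population[analyte],
            max_generations=config.ga_generations,
            mutation_rate=config.ga_mutation_rate,
            window_width=config.ga_window_width,
            max_lv=config.ga_max_lv[analyte],
            seed=seed,
        )
        result = ga_run(X_cal, y_cal, ga_cfg, wavelengths=wavelengths)
        selected_wl, cols = expand_selection(result, wavelengths, config.ga_window_width)
        X_cal, X_val = X_cal[:, cols], X_val[:, cols]

    if variant in ("pls", "ga-pls"):
        model, curve = fit_with_loo(X_cal, y_cal, config.pls_a_max, analyte=analyte)
        pred_val = predict(model, X_val)
        report = evaluation_report(
            pred_val,
            y_val,
            analyte=analyte,
            model=variant,
            rmsec=rmse(predict(model, X_cal), y_cal),
            rmsecv=float(curve.rmsecv[model.n_lv - 1]),
        )
        return VariantResult(
            analyte=analyte,
            variant=variant,
            report=report,
            n_lv=model.n_lv,
            selected_wavelengths_nm=selected_wl,
            model=model,
        )

    ann_cfg = AnnConfig(
        max_epochs=config.ann_max_epochs, patience=config.ann_patience, seed=seed
    )
    hidden, _scan = scan_hidden(X_cal, y_cal, X_val, y_val, config.hidden_candidates, ann_cfg)
    ann_cfg = replace(ann_cfg, hidden_neurons=hidden)
    net = train_lm(init_network(X_cal.shape[1], ann_cfg), X_cal, y_cal, X_val, y_val, ann_cfg)
    pred_val = forward(net, X_val)
    report = evaluation_report(
        pred_val,
        y_val,
        analyte=analyte,
        model=variant,
        rmsec=rmse(forward(net, X_cal), y_cal),
    )
    return VariantResult(
        analyte=analyte,
        variant=variant,
        report=report,
        hidden_neurons=hidden,
        selected_wavelengths_nm=selected_wl,
        model=net,
    )


def run_variant(
    cal: SpectralDataset,
    val: SpectralDataset,
    variant: str,
    config: PipelineConfig | None = None,
) -> dict[str, VariantResult]:
    """Run one variant for every analyte in the dataset."""
    config = config or PipelineConfig()
    return {
        analyte: run_analyte(cal, val, analyte, variant, config)
        for analyte in cal.concentrations.analyte_names
    }
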