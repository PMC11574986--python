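"""Spectral dataset container, CSV round-trip, windowing and centering.

The pipeline currency is a sample x wavelength absorbance matrix on a
uniform 1.0 nm grid, paired with a per-mixture concentration table. The
CSV layout mirrors how bench spectrophotometer exports are usually
organized: a spectra file whose first column is ``wavelength_nm`` with
one column per mixture, and a concentration file keyed by
``mixture_id``. Wavelength matching is exact (no interpolation): all
datasets are assumed to share the instrument's 1.0 nm grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ConcentrationTable
from .errors import GridError, IdMismatchError, InvalidParameterError, ShapeError, WindowError

__all__ = [
    "SpectralDataset",
    "WavelengthWindow",
    "read_dataset",
    "write_dataset",
    "select_window",
    "mean_center",
]


@dataclass(frozen=True)
class WavelengthWindow:
    """Inclusive wavelength bounds in nm.

    Both endpoints count: 221-400 nm on a 1.0 nm grid selects 180
    columns and 221-300 nm selects 80.
    """

    min_nm: float
    max_nm: float

    def __post_init__(self) -> None:
        if self.min_nm > self.max_nm:
            raise WindowError(f"empty window: {self.min_nm} > {self.max_nm}")


@dataclass(frozen=True)
class SpectralDataset:
    """Absorbance spectra with matched concentrations.

    ``saturated_mask`` flags points clipped at the detector limit; it is
    informational and is not persisted by the CSV writer (a freshly read
    dataset has an all-False mask).
    """

    wavelengths_nm: np.ndarray  # (p,), strictly increasing
    absorbance: np.ndarray      # (n, p)
    concentrations: ConcentrationTable
    saturated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.ndim != 2 or ab.shape[1] != wl.size:
            raise ShapeError("absorbance must be samples x wavelengths")
        if np.any(np.diff(wl) <= 0):
            raise GridError("wavelengths must be strictly increasing and unique")
        if not np.all(np.isfinite(ab)):
            raise InvalidParameterError("absorbance must be finite")
        if ab.shape[0] != self.concentrations.n_mixtures:
            raise ShapeError("one spectrum per concentration row required")
        if self.saturated_mask is None:
            object.__setattr__(self, "saturated_mask", np.zeros(ab.shape, dtype=bool))
        elif np.asarray(self.saturated_mask).shape != ab.shape:
            raise ShapeError("saturated_mask must match absorbance shape")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]


def write_dataset(dataset: SpectralDataset, spectra_path, conc_path) -> None:
    """Write the two-file CSV representation (spectra + concentrations)."""
    spectra = pd.DataFrame(
        dataset.absorbance.T,
        columns=[f"mix_{i}" for i in dataset.concentrations.mixture_ids],
    )
    spectra.insert(0, "wavelength_nm", dataset.wavelengths_nm)
    # %.17g keeps the float64 round trip bit-exact
    spectra.to_csv(spectra_path, index=False, float_format="%.17g")
    dataset.concentrations.write_csv(conc_path)


def read_dataset(spectra_path, conc_path) -> SpectralDataset:
    """Read the two-file CSV representation back into a dataset.

    Samples are matched by mixture_id; a spectrum without a
    concentration row (or vice versa) raises :class:`IdMismatchError`.
    """
    spectra = pd.read_csv(spectra_path, float_precision="round_trip")
    if spectra.columns[0] != "wavelength_nm":
        raise GridError("first spectra column must be wavelength_nm")
    wl = spectra["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise GridError("wavelength column must be strictly increasing")

    conc_df = pd.read_csv(conc_path, float_precision="round_trip")
    if "mixture_id" not in conc_df.columns:
        raise IdMismatchError("concentration file must contain a mixture_id column")
    conc_ids = conc_df["mixture_id"].to_numpy(dtype=int)

    spec_ids = []
    for col in spectra.columns[1:]:
        name = col.removeprefix("mix_")
        try:
            spec_ids.append(int(name))
        except ValueError as exc:
            raise IdMismatchError(f"cannot parse mixture id from column {col!r}") from exc
    spec_ids = np.asarray(spec_ids)

    if set(spec_ids) != set(conc_ids):
        missing = sorted(set(spec_ids) ^ set(conc_ids))
        raise IdMismatchError(f"mixture ids differ between files: {missing}")

    # align concentration rows to spectra column order
    order = {mid: k for k, mid in enumerate(conc_ids)}
    rows = [order[mid] for mid in spec_ids]
    analytes = tuple(
        c.removesuffix("_ugml") for c in conc_df.columns if c != "mixture_id"
    )
    conc = ConcentrationTable(
        mixture_ids=spec_ids,
        concentrations=conc_df.drop(columns="mixture_id").to_numpy(dtype=float)[rows],
        analyte_names=analytes,
    )
    absorbance = spectra.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectralDataset(wavelengths_nm=wl, absorbance=absorbance, concentrations=conc)


def select_window(dataset: SpectralDataset, window: WavelengthWindow) -> SpectralDataset:
    """Restrict the dataset to wavelengths inside an inclusive window."""
    keep = (dataset.wavelengths_nm >= window.min_nm) & (
        dataset.wavelengths_nm <= window.max_nm
    )
    if not np.any(keep):
        raise WindowError(
            f"window {window.min_nm}-{window.max_nm} nm selects no grid points"
        )
    return replace(
        dataset,
        wavelengths_nm=dataset.wavelengths_nm[keep],
        absorbance=dataset.absorbance[:, keep],
        saturated_mask=dataset.saturated_mask[:, keep],
    )


def mean_center(X: np.ndarray, y: np.ndarray):
    """Column-center X and y; return (Xc, yc, x_mean, y_mean).

    The stored means reverse the transform at prediction time.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ShapeError("mean_center requires a 2-D X with at least 2 rows")
    if y.shape != (X.shape[0],):
        raise ShapeError("y must be a vector row-matched to X")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    return X - x_mean, y - y_mean, x_mean, y_mean
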