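"""Beer-Lambert simulation of three-component UV absorbance spectra.

Synthetic stand-in for instrument data: each component contributes a sum
of Gaussian absorptivity bands (per ug/mL), mixtures obey the
Beer-Lambert law (absorbance linear in concentration at unit path
length), and the detector adds white noise and clips above a saturation
limit. The default phantom components emulate the qualitative structure
of the MON/RUP/DES ternary system: the MON-like component has an
isolated band above 330 nm where the other two are dark, while the
RUP-like and DES-like components are severely overlapped in 240-290 nm
(pairwise cosine similarity of their pure spectra on 221-300 nm above
0.95). All three absorb strongly below ~215 nm, so spectra saturate
below 221 nm at working concentrations — the region a practitioner
discards before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import SpectralDataset
from .design import ConcentrationTable
from .errors import InvalidParameterError, ShapeError

__all__ = [
    "ComponentSpectrum",
    "default_grid",
    "pure_spectrum",
    "default_phantoms",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ComponentSpectrum:
    """Pure-component absorptivity model: Gaussian bands plus a baseline.

    Each band is ``(center_nm, width_nm, peak_absorptivity)`` with the
    peak absorptivity in absorbance units per ug/mL at unit path length.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        for center, width, peak in self.bands:
            if width <= 0:
                raise InvalidParameterError(f"band width must be > 0 (got {width})")
            if peak < 0:
                raise InvalidParameterError(f"peak absorptivity must be >= 0 (got {peak})")


def default_grid() -> np.ndarray:
    """The instrument grid: 200-400 nm at 1.0 nm (201 points)."""
    return np.arange(200.0, 401.0, 1.0)


def pure_spectrum(component: ComponentSpectrum, grid: np.ndarray) -> np.ndarray:
    """Evaluate a component's absorptivity on a wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("grid must be nonempty")
    out = np.full(grid.shape, float(component.baseline))
    for center, width, peak in component.bands:
        out += peak * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
    return out


def default_phantoms() -> tuple[ComponentSpectrum, ComponentSpectrum, ComponentSpectrum]:
    """Three phantom components with the qualitative MON/RUP/DES layout.

    MON-phantom: an isolated band at 350 nm (unique spectral handle)
    plus a band at 270 nm inside the crowded region. RUP- and
    DES-phantoms: near-coincident band pairs in 244-274 nm, essentially
    dark above 300 nm. All three share a strong far-UV band near
    205-210 nm that drives detector saturation below 221 nm.
    """
    mon = ComponentSpectrum(
        name="MON",
        bands=(
            (350.0, 18.0, 0.055),
            (270.0, 15.0, 0.040),
            (206.0, 7.0, 0.200),
        ),
    )
    rup = ComponentSpectrum(
        name="RUP",
        bands=(
            (246.0, 13.0, 0.048),
            (272.0, 9.0, 0.035),
            (206.0, 7.0, 0.170),
        ),
    )
    des = ComponentSpectrum(
        name="DES",
        bands=(
            (244.0, 13.0, 0.046),
            (274.0, 9.0, 0.030),
            (207.0, 7.0, 0.170),
        ),
    )
    return mon, rup, des


def simulate_dataset(
    table: ConcentrationTable,
    phantoms=None,
    noise_sd: float = 0.002,
    saturation_limit: float | None = 3.0,
    seed: int = 0,
) -> SpectralDataset:
    """Simulate mixture spectra for every row of a concentration table.

    absorbance[i, l] = sum_j conc[i, j] * pure_j(l) + N(0, noise_sd),
    then clipped at ``saturation_limit`` (pass None to disable) with
    clipped points flagged in ``saturated_mask``.

    Noise streams are derived per sample from the global seed by
    counter offset, so a sample's noise never depends on how many rows
    the table has or on row order.
    """
    if phantoms is None:
        phantoms = default_phantoms()
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if saturation_limit is not None and saturation_limit <= 0:
        raise InvalidParameterError("saturation_limit must be > 0")
    if len(phantoms) != table.concentrations.shape[1]:
        raise ShapeError(
            f"{table.concentrations.shape[1]} concentration columns but "
            f"{len(phantoms)} phantom components"
        )

    grid = default_grid()
    pure = np.stack([pure_spectrum(c, grid) for c in phantoms])  # (k, p)
    clean = table.concentrations @ pure  # Beer-Lambert mixing

    absorbance = clean.copy()
    if noise_sd > 0:
        for i in range(absorbance.shape[0]):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
            absorbance[i] += rng.normal(0.0, noise_sd, size=grid.size)

    if saturation_limit is not None:
        mask = absorbance > saturation_limit
        absorbance = np.where(mask, saturation_limit, absorbance)
    else:
        mask = np.zeros(absorbance.shape, dtype=bool)

    return SpectralDataset(
        wavelengths_nm=grid,
        absorbance=absorbance,
        concentrations=table,
        saturated_mask=mask,
    )
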