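"""Spectral simulator: Beer-Lambert linearity, phantom layout, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemocal.design import ConcentrationTable, calibration_table
from chemocal.errors import InvalidParameterError, ShapeError
from chemocal.simulate import (
    ComponentSpectrum,
    default_grid,
    default_phantoms,
    pure_spectrum,
    simulate_dataset,
)


class TestPureSpectrum:
    def test_gaussian_maximum_at_center(self, grid):
        comp = ComponentSpectrum("x", bands=((250.0, 10.0, 0.3),), baseline=0.05)
        spec = pure_spectrum(comp, grid)
        assert spec[np.argwhere(grid == 250.0)[0, 0]] == pytest.approx(0.35)

    def test_no_bands_gives_baseline(self, grid):
        assert np.all(pure_spectrum(ComponentSpectrum("x", bands=()), grid) == 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        bands=st.lists(
            st.tuples(
                st.floats(210, 390), st.floats(1, 40), st.floats(0, 1)
            ),
            min_size=1,
            max_size=4,
        )
    )
    def test_band_additivity(self, bands):
        grid = default_grid()
        total = pure_spectrum(ComponentSpectrum("x", bands=tuple(bands)), grid)
        parts = sum(
            pure_spectrum(ComponentSpectrum("b", bands=(b,)), grid) for b in bands
        )
        assert np.allclose(total, parts, atol=1e-12)

    def test_invalid_band_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            ComponentSpectrum("x", bands=((250.0, 0.0, 0.3),))


class TestDefaultPhantoms:
    def test_overlapped_pair_cosine_similarity(self, pure_matrix, grid):
        # RUP- and DES-phantoms are nearly collinear in the crowded region
        w = (grid >= 221) & (grid <= 300)
        rup, des = pure_matrix[1, w], pure_matrix[2, w]
        cos = rup @ des / (np.linalg.norm(rup) * np.linalg.norm(des))
        assert cos > 0.95

    def test_overlapped_pair_dark_above_300(self, pure_matrix, grid):
        up = grid >= 301
        for k in (1, 2):
            assert pure_matrix[k, up].max() < 0.01 * pure_matrix[k].max()

    def test_isolated_band_above_330(self, grid, phantoms):
        mon = phantoms[0]
        assert any(center > 330 for center, _, _ in mon.bands)
        assert any(center < 300 for center, _, _ in mon.bands)
        up = (grid >= 301)
        assert pure_spectrum(mon, grid)[up].max() > 0.01

    def test_saturation_region_below_221(self, pure_matrix, grid):
        # every calibration mixture exceeds the 3.0 AU limit below 221 nm
        clean = calibration_table().concentrations @ pure_matrix
        below = grid < 221
        assert clean[:, below].max(axis=1).min() > 3.0
        assert clean[:, ~below].max() < 3.0


class TestSimulateDataset:
    def test_noiseless_is_exact_linear_combination(self, noiseless_cal, pure_matrix):
        expected = noiseless_cal.concentrations.concentrations @ pure_matrix
        assert np.allclose(noiseless_cal.absorbance, expected, atol=1e-12)

    def test_homogeneity(self, pure_matrix):
        table = calibration_table()
        doubled = ConcentrationTable(
            mixture_ids=table.mixture_ids,
            concentrations=2 * table.concentrations,
            analyte_names=table.analyte_names,
        )
        a = simulate_dataset(table, noise_sd=0, saturation_limit=None, seed=0)
        b = simulate_dataset(doubled, noise_sd=0, saturation_limit=None, seed=0)
        assert np.allclose(b.absorbance, 2 * a.absorbance)

    def test_seed_determinism(self):
        table = calibration_table()
        a = simulate_dataset(table, seed=42)
        b = simulate_dataset(table, seed=42)
        assert np.array_equal(a.absorbance, b.absorbance)
        c = simulate_dataset(table, seed=43)
        assert not np.array_equal(a.absorbance, c.absorbance)

    def test_noise_stream_independent_of_row_count(self):
        # sample i's noise is a function of (seed, i), not of table size
        table = calibration_table()
        sub = ConcentrationTable(
            mixture_ids=table.mixture_ids[:5],
            concentrations=table.concentrations[:5],
            analyte_names=table.analyte_names,
        )
        full = simulate_dataset(table, noise_sd=0.01, saturation_limit=None, seed=7)
        part = simulate_dataset(sub, noise_sd=0.01, saturation_limit=None, seed=7)
        assert np.array_equal(full.absorbance[:5], part.absorbance)

    def test_saturation_clips_and_flags(self):
        ds = simulate_dataset(calibration_table(), noise_sd=0, saturation_limit=2.0, seed=0)
        assert ds.absorbance.max() <= 2.0
        assert ds.saturated_mask.any()
        clean = simulate_dataset(calibration_table(), noise_sd=0, saturation_limit=None, seed=0)
        assert np.array_equal(ds.saturated_mask, clean.absorbance > 2.0)

    def test_saturation_monotone_in_concentration(self, pure_matrix):
        table = calibration_table()
        more = ConcentrationTable(
            mixture_ids=table.mixture_ids,
            concentrations=table.concentrations * 1.5,
            analyte_names=table.analyte_names,
        )
        a = simulate_dataset(table, noise_sd=0, saturation_limit=3.0, seed=0)
        b = simulate_dataset(more, noise_sd=0, saturation_limit=3.0, seed=0)
        assert np.all(b.saturated_mask[a.saturated_mask])

    def test_phantom_count_mismatch_rejected(self, phantoms):
        with pytest.raises(ShapeError):
            simulate_dataset(calibration_table(), phantoms=phantoms[:2])

    def test_ols_against_pure_spectra_recovers_concentrations(
        self, noiseless_cal, pure_matrix, grid
    ):
        # independent oracle for every downstream model
        sel = grid >= 221
        coef, *_ = np.linalg.lstsq(
            pure_matrix[:, sel].T, noiseless_cal.absorbance[:, sel].T, rcond=None
        )
        assert np.allclose(coef.T, noiseless_cal.concentrations.concentrations, atol=1e-9)
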