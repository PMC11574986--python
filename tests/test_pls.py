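"""PLS-1 engine: oracles (pseudoinverse, brute-force LOO, scikit-learn),
monotonicity and the LV selection rule."""

import numpy as np
import pytest

from chemocal.dataset import WavelengthWindow, select_window
from chemocal.errors import DeflationCollapseError, InvalidParameterError
from chemocal.pls import (
    CvCurve,
    PlsModel,
    fit_pls1,
    fit_with_loo,
    loo_rmsecv,
    predict,
    select_n_lv,
)


@pytest.fixture(scope="module")
def windowed(noiseless_cal):
    return select_window(noiseless_cal, WavelengthWindow(221, 400))


class TestFitPredict:
    def test_noiseless_three_components_exact_with_three_lvs(self, windowed):
        X = windowed.absorbance
        for analyte in ("MON", "RUP", "DES"):
            y = windowed.concentrations.column(analyte)
            model = fit_pls1(X, y, n_lv=3, analyte=analyte)
            assert np.allclose(predict(model, X), y, atol=1e-6)

    def test_constant_y_gives_zero_regression_vector(self, windowed):
        X = windowed.absorbance
        y = np.full(X.shape[0], 7.0)
        model = fit_pls1(X, y, n_lv=2)
        assert np.allclose(model.regression_vector, 0, atol=1e-10)
        assert np.allclose(predict(model, X), 7.0)

    def test_training_residuals_monotone_in_lv(self, noisy_cal):
        ds = select_window(noisy_cal, WavelengthWindow(221, 300))
        X = ds.absorbance
        y = ds.concentrations.column("RUP")
        sse = []
        for a in range(1, 9):
            m = fit_pls1(X, y, a)
            sse.append(np.sum((predict(m, X) - y) ** 2))
        assert all(b <= a + 1e-10 for a, b in zip(sse, sse[1:]))

    def test_full_rank_pls_matches_least_squares(self):
        # n_lv = min(n-1, p) reproduces least squares on a tall full-rank problem
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = fit_pls1(X, y, n_lv=4)
        Xc = X - X.mean(axis=0)
        b = np.linalg.pinv(Xc) @ (y - y.mean())
        pred_ls = y.mean() + Xc @ b
        assert np.allclose(predict(model, X), pred_ls, atol=1e-8)

    def test_agreement_with_sklearn_on_random_matrix(self):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        for a in (1, 2, 3):
            ours = predict(fit_pls1(X, y, a), X)
            ref = sklearn_pls.PLSRegression(n_components=a, scale=False).fit(X, y)
            assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_rank_deficient_collapse(self):
        X = np.outer(np.arange(6.0), np.ones(4))  # rank 1 after centering
        y = np.arange(6.0)
        with pytest.raises(DeflationCollapseError):
            fit_pls1(X, y, n_lv=3)

    def test_predict_at_x_mean_returns_y_mean(self, windowed):
        X = windowed.absorbance
        y = windowed.concentrations.column("MON")
        model = fit_pls1(X, y, 3)
        assert predict(model, model.x_mean[None, :])[0] == pytest.approx(model.y_mean)

    def test_n_lv_bounds_enforced(self, windowed):
        X = windowed.absorbance
        y = windowed.concentrations.column("MON")
        with pytest.raises(InvalidParameterError):
            fit_pls1(X, y, 0)
        with pytest.raises(InvalidParameterError):
            fit_pls1(X, y, X.shape[0])

    def test_json_round_trip(self, windowed, tmp_path):
        X = windowed.absorbance
        model = fit_pls1(X, windowed.concentrations.column("MON"), 2, analyte="MON")
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PlsModel.from_json(path)
        assert back.n_lv == 2 and back.analyte == "MON"
        assert np.allclose(back.regression_vector, model.regression_vector)
        assert np.allclose(predict(back, X), predict(model, X))


class TestLooRmsecv:
    def test_matches_brute_force_on_small_fixture(self):
        # oracle: explicitly refit one independent model per left-out sample
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        a_max = 3
        curve = loo_rmsecv(X, y, a_max)
        for a in range(1, a_max + 1):
            press = 0.0
            for i in range(5):
                keep = np.arange(5) != i
                m = fit_pls1(X[keep], y[keep], a)
                press += (predict(m, X[i][None, :])[0] - y[i]) ** 2
            assert curve.rmsecv[a - 1] == pytest.approx(np.sqrt(press / 5), abs=1e-10)

    def test_duplicating_samples_never_hurts(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 4))
        y = X @ rng.normal(size=4) + 0.05 * rng.normal(size=6)
        base = loo_rmsecv(X, y, 3).rmsecv
        dup = loo_rmsecv(np.vstack([X, X]), np.concatenate([y, y]), 3).rmsecv
        assert np.all(dup <= base + 1e-10)

    def test_curve_length_and_bounds(self, windowed):
        X = windowed.absorbance
        y = windowed.concentrations.column("DES")
        curve = loo_rmsecv(X, y, 6)
        assert len(curve.rmsecv) == 6 and np.all(curve.rmsecv >= 0)
        with pytest.raises(InvalidParameterError):
            loo_rmsecv(X[:2], y[:2], 1)


class TestSelectNLv:
    @pytest.mark.parametrize(
        "rmsecv,expected",
        [((3.0, 1.0, 2.0), 2), ((1.0, 1.0, 1.0), 1), ((3.0, 2.0, 1.0), 3)],
    )
    def test_argmin_with_tie_toward_fewer(self, rmsecv, expected):
        curve = CvCurve(n_lv_grid=np.arange(1, len(rmsecv) + 1), rmsecv=np.array(rmsecv))
        assert select_n_lv(curve) == expected

    def test_loo_selection_stays_small_on_design(self, noisy_cal):
        # k = 3 chemical components: LOO picks at most k + 1 LVs at study noise
        ds = select_window(noisy_cal, WavelengthWindow(221, 400))
        model, _ = fit_with_loo(ds.absorbance, ds.concentrations.column("MON"), a_max=10)
        assert 1 <= model.n_lv <= 4
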