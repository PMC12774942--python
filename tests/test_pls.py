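"""NIPALS PLS1: fit invariants, oracle equivalence, CV and metrics."""

import numpy as np
import pytest

from nirlod import (
    CVResult,
    InstrumentProfile,
    PreprocessOptions,
    SyntheticConfig,
    evaluate,
    loocv,
    pls_fit,
    pls_predict,
    preprocess_chain,
    select_lvs,
    simulate_dataset,
)
from nirlod.synthetic import VITEXIN_BANDS


class TestPLSFit:
    def test_weights_orthonormal_scores_orthogonal(self, rng):
        X, y = rng.normal(size=(30, 120)), rng.normal(size=30)
        m = pls_fit(X, y, 6)
        np.testing.assert_allclose(m.W.T @ m.W, np.eye(6), atol=1e-8)
        TtT = m.T.T @ m.T
        off = TtT - np.diag(np.diag(TtT))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(TtT)).max()

    def test_b_reproduces_deflation_fit(self, rng):
        X, y = rng.normal(size=(25, 60)), rng.normal(size=25)
        m = pls_fit(X, y, 4)
        # deflation-path fitted values: y_mean + T q
        path = m.y_mean + m.T @ m.q
        compact = pls_predict(m, X)
        np.testing.assert_allclose(path, compact, atol=1e-8)

    def test_single_channel_equals_ols_slope(self, rng):
        x = rng.normal(size=20)
        y = 2.0 * x + rng.normal(size=20) * 0.1
        m = pls_fit(x[:, None], y, 1)
        xc, yc = x - x.mean(), y - y.mean()
        assert m.b[0] == pytest.approx((xc @ yc) / (xc @ xc), abs=1e-12)

    def test_full_rank_fit_equals_ols_projection(self, rng):
        n, p = 12, 5
        X, y = rng.normal(size=(n, p)), rng.normal(size=n)
        m = pls_fit(X, y, p)
        Xc = X - X.mean(0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(
            pls_predict(m, X), y.mean() + Xc @ beta, atol=1e-8
        )

    def test_matches_reference_pls_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(20):
            X, y = rng.normal(size=(40, 200)), rng.normal(size=40)
            m = pls_fit(X, y, 5)
            ref = sklearn.PLSRegression(n_components=5, scale=False).fit(X, y)
            b_ref = ref.coef_.reshape(-1)
            assert np.linalg.norm(m.b - b_ref) < 1e-6 * np.linalg.norm(b_ref)

    def test_rank_deficient_raises(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=20))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            pls_fit(X, X @ rng.normal(size=20), 3)

    def test_nonfinite_rejected(self, rng):
        X = rng.normal(size=(10, 5))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pls_fit(X, rng.normal(size=10), 1)


class TestPredict:
    def test_calibration_predictions_equal_fitted(self, rng):
        X, y = rng.normal(size=(20, 40)), rng.normal(size=20)
        m = pls_fit(X, y, 3)
        np.testing.assert_allclose(
            pls_predict(m, X), m.y_mean + (X - m.x_mean) @ m.b
        )

    def test_mean_spectrum_predicts_mean_y(self, rng):
        X, y = rng.normal(size=(20, 40)), rng.normal(size=20)
        m = pls_fit(X, y, 3)
        out = pls_predict(m, np.vstack([m.x_mean] * 3))
        np.testing.assert_allclose(out, m.y_mean, atol=1e-10)

    def test_noiseless_single_analyte_exact_recovery(self):
        profile = InstrumentProfile("clean", 10000.0, 4000.0, 400, 8.0, 0.0)
        cfg = SyntheticConfig(
            n_samples=20,
            analyte_bands={"vitexin": list(VITEXIN_BANDS)},
            matrix_components=(),
            gain_sd=0.0, offset_sd=0.0, slope_sd=0.0,
            n_replicates=1, seed=3,
        )
        spectra, table = simulate_dataset(cfg, profile)
        y = table.y("vitexin")
        opts = PreprocessOptions(scatter="none")
        X, _ = preprocess_chain(spectra.absorbance, y, opts)
        m = pls_fit(X, y, 1)
        assert np.abs(pls_predict(m, X) - y).max() < 1e-6

    def test_shape_mismatch_rejected(self, rng):
        m = pls_fit(rng.normal(size=(10, 20)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="channel"):
            pls_predict(m, rng.normal(size=(2, 19)))


class TestLOOCV:
    def test_one_segment_per_sample(self, fitted_default):
        cv = fitted_default["cv"]
        n = fitted_default["averaged"].n_samples
        assert len(cv.segments) == n == 50
        assert all(len(s) == 1 for s in cv.segments)
        assert all(len(d["residuals"]) == n for d in cv.per_A)

    def test_duplicated_rows_make_cv_match_calibration(self, rng):
        # every held-out sample has an identical twin in the training fold;
        # with a rank-3 latent structure an A=3 model fits exactly, so the
        # held-out error collapses onto the calibration error
        scores = rng.normal(size=(12, 3))
        load = rng.normal(size=(3, 20))
        X = scores @ load + 1e-8 * rng.normal(size=(12, 20))
        y = scores @ np.array([1.0, 2.0, 3.0])
        Xd, yd = np.vstack([X, X]), np.concatenate([y, y])
        opts = PreprocessOptions(derivative=False, scatter="none")
        cv = loocv(Xd, yd, 3, opts)
        Xp, _ = preprocess_chain(Xd, yd, opts)
        model = pls_fit(Xp, yd, 3)
        rmsec = evaluate(model, Xp, yd, "calibration").rmse
        assert cv.rmsecv(3) == pytest.approx(rmsec, abs=1e-5 * yd.std())
        assert cv.rmsecv(3) < 1e-5 * yd.std()

    def test_matches_bruteforce_fold_recomputation(self, rng):
        # independent oracle: sklearn PLS refitted per fold
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = rng.normal(size=(15, 30)), rng.normal(size=15)
        opts = PreprocessOptions(derivative=False, scatter="none")
        cv = loocv(X, y, 3, opts)
        for A in (1, 2, 3):
            preds = []
            for i in range(15):
                mask = np.ones(15, bool)
                mask[i] = False
                ref = sklearn.PLSRegression(n_components=A, scale=False)
                ref.fit(X[mask], y[mask])
                preds.append(ref.predict(X[i : i + 1]).item())
            rmse = np.sqrt(np.mean((y - np.array(preds)) ** 2))
            assert cv.rmsecv(A) == pytest.approx(rmse, rel=1e-8)

    def test_cv_curve_has_interior_optimum_on_default_data(self, fitted_default):
        cv = fitted_default["cv"]
        curve = [d["rmsecv"] for d in cv.per_A]
        assert min(curve) < curve[0]  # adding LVs helps at first
        assert cv.chosen_A >= 2

    def test_a_max_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="A_max"):
            loocv(rng.normal(size=(5, 10)), rng.normal(size=5), 4,
                  PreprocessOptions(derivative=False, scatter="none"))


class TestSelectLVs:
    def _cv(self, rmsecvs):
        per_A = [
            {"A": i + 1, "rmsecv": v, "r2cv": 0.0, "residuals": np.zeros(3)}
            for i, v in enumerate(rmsecvs)
        ]
        return CVResult(per_A=per_A, chosen_A=1, segments=[])

    def test_within_tolerance_of_minimum_prefers_small_A(self):
        assert select_lvs(self._cv([1.0, 0.5, 0.499, 0.498])) == 2

    def test_large_final_drop_selects_argmin(self):
        assert select_lvs(self._cv([1.0, 0.9, 0.8, 0.2])) == 4

    def test_ties_break_to_smallest_A(self):
        assert select_lvs(self._cv([0.7, 0.7, 0.7])) == 1


class TestEvaluate:
    def test_perfect_prediction(self, rng):
        X, y = rng.normal(size=(10, 4)), None
        m = pls_fit(X, X @ np.ones(4), 4)
        met = evaluate(m, X, X @ np.ones(4), "calibration")
        assert met.r2 == pytest.approx(1.0, abs=1e-10)
        assert met.rmse == pytest.approx(0.0, abs=1e-8)

    def test_hand_computed_example(self):
        # y = {1,2,3,4}, yhat = {1,2,3,5}: SS_res=1, SS_tot=5
        class Stub:
            x_mean = np.zeros(1)
            y_mean = 0.0
            b = np.ones(1)

        X = np.array([[1.0], [2.0], [3.0], [5.0]])
        met = evaluate(Stub(), X, np.array([1.0, 2.0, 3.0, 4.0]), "testset")
        assert met.rmse == pytest.approx(0.5)
        assert met.r2 == pytest.approx(0.8)

    def test_constant_y_rejected(self, rng):
        m = pls_fit(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(ValueError, match="variance"):
            evaluate(m, rng.normal(size=(5, 4)), np.full(5, 1.0), "testset")


class TestParameterRecovery:
    def test_default_synthetic_calibration_is_accurate(self, fitted_default):
        """Milled benchtop data: R2CV > 0.9, RMSECV < 10% of the 0.3-10 span."""
        cv = fitted_default["cv"]
        assert cv.r2cv() > 0.9
        assert cv.rmsecv() < 0.1 * (10.0 - 0.3)
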