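"""Pretreatment chain: SG derivative, SNV/MSC, OSC and the fitted record."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nirlod import (
    PreprocessOptions,
    PretreatmentRecord,
    msc,
    osc_apply,
    osc_fit,
    preprocess_chain,
    sg_second_derivative,
    snv,
)
from nirlod.preprocess import DegenerateSpectrumError


class TestSGSecondDerivative:
    def test_quadratic_gives_constant_second_derivative(self):
        x = np.arange(40.0)
        a = 0.37
        d = sg_second_derivative((a * x**2)[None, :])[0]
        np.testing.assert_allclose(d, 2 * a, atol=1e-9)

    def test_linear_ramp_gives_zero(self):
        x = np.arange(30.0)
        d = sg_second_derivative((3.0 * x + 1.0)[None, :])[0]
        np.testing.assert_allclose(d, 0.0, atol=1e-10)

    def test_matches_bruteforce_local_polyfit(self, rng):
        row = rng.normal(size=80)
        window, polyorder, half = 9, 2, 4
        d = sg_second_derivative(row[None, :], window, polyorder)[0]
        rel = np.arange(-half, half + 1, dtype=float)
        for i in range(half, 80 - half):
            coeffs = np.polyfit(rel, row[i - half : i + half + 1], polyorder)
            assert d[i] == pytest.approx(2 * coeffs[0], abs=1e-10)

    def test_channel_count_preserved(self, rng):
        X = rng.normal(size=(3, 25))
        assert sg_second_derivative(X).shape == X.shape

    @pytest.mark.parametrize("window,polyorder", [(8, 2), (5, 5), (3, 4)])
    def test_invalid_parameters_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            sg_second_derivative(np.zeros((1, 30)), window, polyorder)

    @settings(deadline=None, max_examples=25)
    @given(
        x=arrays(float, 40, elements=st.floats(-10, 10)),
        z=arrays(float, 40, elements=st.floats(-10, 10)),
        alpha=st.floats(-3, 3),
        beta=st.floats(-3, 3),
    )
    def test_linearity(self, x, z, alpha, beta):
        lhs = sg_second_derivative((alpha * x + beta * z)[None, :])[0]
        rhs = (
            alpha * sg_second_derivative(x[None, :])[0]
            + beta * sg_second_derivative(z[None, :])[0]
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestSNV:
    @settings(deadline=None, max_examples=30)
    @given(arrays(float, (3, 24), elements=st.floats(-5, 5)))
    def test_rows_have_mean_zero_sd_one(self, X):
        if np.any(X.std(axis=1, ddof=1) < 1e-6 * (np.abs(X).max() + 1)):
            return
        out = snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        r = rng.normal(size=40)
        np.testing.assert_allclose(
            snv(r[None, :]), snv((2.5 * r + 7.0)[None, :]), atol=1e-10
        )

    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            snv(np.array([[1.0, 2.0, 3.0]]))[0], [-1.0, 0.0, 1.0], atol=1e-14
        )

    def test_constant_row_raises_naming_row(self):
        X = np.vstack([np.arange(10.0), np.full(10, 4.0)])
        with pytest.raises(DegenerateSpectrumError, match="1"):
            snv(X)


class TestMSC:
    def test_reference_row_unchanged(self, rng):
        ref = rng.normal(size=30)
        X = np.vstack([ref, rng.normal(size=30)])
        out = msc(X, reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_affine_transform_of_reference_recovered(self, rng):
        ref = rng.normal(size=30)
        out = msc((2.0 * ref + 5.0)[None, :], reference=ref)
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        ref = rng.normal(size=50)
        X = rng.normal(size=(4, 50))
        out = msc(X, reference=ref)
        design = np.column_stack([np.ones(50), ref])
        for i in range(4):
            a, b = np.linalg.lstsq(design, X[i], rcond=None)[0]
            np.testing.assert_allclose(out[i], (X[i] - a) / b, atol=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            msc(np.random.default_rng(0).normal(size=(2, 20)), np.full(20, 3.0))


class TestOSC:
    def _confounded(self, rng, n=30, p=60):
        # zero-mean y and u so the orthogonality survives column centering
        y = rng.normal(size=n)
        y -= y.mean()
        u = rng.normal(size=n)
        u -= u.mean()
        u -= y * (y @ u) / (y @ y)  # u orthogonal to y
        v1 = rng.normal(size=p)
        v2 = rng.normal(size=p)
        v2 -= v1 * (v1 @ v2) / (v1 @ v1)  # v2 orthogonal to v1
        X = np.outer(y, v1) + np.outer(u, v2)
        return X, y, u, v1, v2

    def test_removed_score_orthogonal_to_y(self, rng):
        X, y = rng.normal(size=(25, 70)), rng.normal(size=25)
        rec = osc_fit(X, y)
        t = rec.osc_scores[:, 0]
        assert abs(np.corrcoef(t, y)[0, 1]) < 1e-8

    def test_nothing_orthogonal_to_remove(self, rng):
        y = rng.normal(size=20)
        v = rng.normal(size=40)
        X = np.outer(y, v) + 1e-7 * rng.normal(size=(20, 40))
        rec = osc_fit(X, y)
        t = rec.osc_scores[:, 0]
        total = np.sum((X - X.mean(0)) ** 2)
        removed = (t @ t) * (rec.osc_loadings[:, 0] @ rec.osc_loadings[:, 0])
        assert removed / total < 1e-8

    def test_constructed_confounder_identified(self, rng):
        X, y, u, v1, v2 = self._confounded(rng)
        rec = osc_fit(X, y)
        p = rec.osc_loadings[:, 0]
        cos = abs(p @ v2) / (np.linalg.norm(p) * np.linalg.norm(v2))
        assert cos > 0.99
        corrected = osc_apply(rec, X)
        target = np.outer(y, v1)  # y and u are zero-mean, so X is centered
        assert (
            np.linalg.norm(corrected - corrected.mean(0) - target)
            < 1e-6 * np.linalg.norm(target)
        )

    def test_apply_consistent_with_fit_deflation(self, rng):
        X, y = rng.normal(size=(20, 50)), rng.normal(size=20)
        rec = osc_fit(X, y)
        applied = osc_apply(rec, X)
        internal = (X - X.mean(0)) - rec.osc_scores @ rec.osc_loadings.T
        np.testing.assert_allclose(
            applied - applied.mean(0), internal, atol=1e-10
        )

    def test_apply_idempotent(self, rng):
        X, y = rng.normal(size=(20, 50)), rng.normal(size=20)
        rec = osc_fit(X, y)
        once = osc_apply(rec, X)
        twice = osc_apply(rec, once)
        assert np.linalg.norm(twice - once) < 1e-8 * np.linalg.norm(once)

    def test_spectrum_in_removed_direction_annihilated(self, rng):
        X, y = rng.normal(size=(20, 50)), rng.normal(size=20)
        rec = osc_fit(X, y)
        w, p = rec.osc_weights[:, 0], rec.osc_loadings[:, 0]
        probe = np.outer(np.ones(1), p)  # spectrum along the removed loading
        out = osc_apply(rec, probe)
        # component along p is reduced by the deflation
        before = abs(probe[0] @ p) / (p @ p)
        after = abs(out[0] @ p) / (p @ p)
        assert after < before

    def test_frobenius_norm_not_increased(self, rng):
        X, y = rng.normal(size=(25, 60)), rng.normal(size=25)
        corrected = osc_apply(osc_fit(X, y), X)
        assert (
            np.linalg.norm(corrected - corrected.mean(0))
            <= np.linalg.norm(X - X.mean(0)) + 1e-12
        )

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            osc_fit(rng.normal(size=(10, 20)), np.full(10, 2.0))

    def test_too_many_components_rejected(self, rng):
        X = np.outer(rng.normal(size=10), rng.normal(size=20))
        with pytest.raises(ValueError, match="rank"):
            osc_fit(X, rng.normal(size=10), n_components=2)

    def test_channel_mismatch_rejected(self, rng):
        rec = osc_fit(rng.normal(size=(15, 30)), rng.normal(size=15))
        with pytest.raises(ValueError, match="channel"):
            osc_apply(rec, rng.normal(size=(3, 29)))


class TestChain:
    def test_all_off_is_identity(self, rng):
        X = rng.normal(size=(5, 30))
        out, record = preprocess_chain(
            X, options=PreprocessOptions(derivative=False, scatter="none")
        )
        np.testing.assert_array_equal(out, X)
        assert record.steps == []

    def test_osc_off_leaves_no_weights(self, rng):
        X = rng.normal(size=(5, 30))
        _, record = preprocess_chain(X, options=PreprocessOptions())
        assert not record.has_osc

    def test_record_reproduces_training_matrix(self, default_dataset):
        _, averaged, table = default_dataset
        y = table.y("vitexin")
        opts = PreprocessOptions(osc=True)
        X, record = preprocess_chain(averaged.absorbance, y, opts)
        np.testing.assert_array_equal(record.transform(averaged.absorbance), X)

    def test_heldout_uses_calibration_osc_not_refit(self, default_dataset):
        _, averaged, table = default_dataset
        y = table.y("vitexin")
        opts = PreprocessOptions(osc=True)
        cal, held = averaged.absorbance[:40], averaged.absorbance[40:]
        _, record = preprocess_chain(cal, y[:40], opts)
        via_record = record.transform(held)
        refit, _ = preprocess_chain(held, y[40:], opts)  # deliberate leak
        assert not np.allclose(via_record, refit)

    def test_record_json_roundtrip(self, default_dataset):
        _, averaged, table = default_dataset
        y = table.y("vitexin")
        _, record = preprocess_chain(
            averaged.absorbance, y, PreprocessOptions(osc=True)
        )
        back = PretreatmentRecord.from_json(record.to_json())
        np.testing.assert_array_equal(
            back.transform(averaged.absorbance),
            record.transform(averaged.absorbance),
        )

    def test_step_order_enforced(self):
        with pytest.raises(ValueError, match="order"):
            PretreatmentRecord(steps=[("snv", {}), ("sg_second_derivative", {})])
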