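import numpy as np
import pytest
from scipy import stats

import leafspec.selection as sel
from leafspec import (
    band_significance,
    fit_plsr,
    iterative_band_selection,
    loo_validate,
    predict,
    select_nlv,
)


class TestLooValidate:
    def test_noiseless_linear_response_validates_perfectly(self):
        x = np.linspace(0, 1, 8)[:, None]
        y = 3.0 * x.ravel() + 0.5
        loo = loo_validate(x, y, nlv_max=1)
        assert loo.r2_val[0] >= 0.999

    def test_held_out_predictions_match_bruteforce_refits(self, rng):
        X = rng.standard_normal((4, 2))
        y = rng.standard_normal(4)
        loo = loo_validate(X, y, nlv_max=1)
        for i in range(4):
            keep = np.arange(4) != i
            m = fit_plsr(X[keep], y[keep], nlv_max=1)
            assert loo.predictions[i, 0] == predict(m, X[i:i + 1], 1)[0]

    def test_response_independent_of_predictors_gives_negative_r2(self):
        rng = np.random.default_rng(42)
        medians = []
        for _ in range(200):
            X = rng.standard_normal((12, 5))
            y = rng.standard_normal(12)
            loo = loo_validate(X, y)
            medians.append(loo.r2_val[select_nlv(loo) - 1])
        assert np.median(medians) < 0

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            loo_validate(rng.standard_normal((3, 2)), np.arange(3.0))

    def test_component_count_capped_by_fold_size(self, rng):
        X = rng.standard_normal((6, 10))
        y = rng.standard_normal(6)
        loo = loo_validate(X, y, nlv_max=15)
        assert loo.nlv_available == 3  # n - 3


class TestSelectNlv:
    def test_argmin_of_validation_curve(self):
        loo = _loo_with_rmse([0.5, 0.3, 0.4])
        assert select_nlv(loo) == 2

    def test_tie_broken_toward_fewer_components(self):
        loo = _loo_with_rmse([0.5, 0.3, 0.3])
        assert select_nlv(loo) == 2

    def test_single_entry(self):
        assert select_nlv(_loo_with_rmse([0.5])) == 1


def _loo_with_rmse(values):
    values = np.asarray(values, dtype=float)
    k = values.size
    return sel.LooResult(np.zeros((4, k)), values, np.zeros(k),
                         np.zeros((4, k, 1)))


class TestBandSignificance:
    def test_zero_variance_nonzero_mean_is_significant(self):
        coefs = np.full((5, 1), 0.7)
        p, sig = band_significance(coefs)
        assert p[0] == 0.0 and sig[0]

    def test_sign_symmetric_coefficients_not_significant(self):
        coefs = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        p, sig = band_significance(coefs)
        assert p[0] > 0.9 and not sig[0]

    def test_zero_variance_zero_mean_gets_p_one(self):
        p, sig = band_significance(np.zeros((4, 1)))
        assert p[0] == 1.0 and not sig[0]

    def test_matches_t_distribution_oracle(self):
        coefs = np.array([1.0, 1.2, 0.8, 1.1, 0.9])[:, None]
        t = coefs.mean() / (coefs.std(ddof=1) / np.sqrt(5))
        expected = 2.0 * stats.t.sf(abs(t), df=4)
        p, sig = band_significance(coefs, alpha=0.1)
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert sig[0]

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            band_significance(np.ones((2, 3)))


class TestIterativeBandSelection:
    def test_all_bands_significant_stops_immediately(self, rng):
        z = rng.standard_normal(15)
        X = np.column_stack([z, 0.8 * z, -z]) + 0.01 * rng.standard_normal((15, 3))
        y = z + 0.05 * rng.standard_normal(15)
        res = iterative_band_selection(X, y)
        assert res.stop_reason == "all_significant"
        assert res.iterations == 1
        assert res.band_mask.all()

    def test_planted_signal_retained_and_validation_not_degraded(self):
        rng = np.random.default_rng(3)
        n, p = 30, 200
        X = rng.standard_normal((n, p))
        planted = np.arange(90, 100)
        z = rng.standard_normal(n)
        X[:, planted] += 2.0 * z[:, None]
        y = z + 0.3 * rng.standard_normal(n)
        res = iterative_band_selection(X, y)
        assert res.band_mask[planted].sum() >= 8
        assert res.final_metrics.rmse_val <= res.metrics[0].rmse_val
        counts = [m.n_bands for m in res.metrics]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_crop_that_worsens_validation_is_discarded(self, rng, monkeypatch):
        # significance stub nominates a pure-noise band; cropping to it
        # must raise RMSE_val, so the pre-crop model is returned
        X = rng.standard_normal((12, 3))
        y = 2.0 * X[:, 0] + 0.05 * rng.standard_normal(12)

        def fake_significance(coefs, alpha=0.1):
            n_bands = coefs.shape[1]
            sig = np.zeros(n_bands, dtype=bool)
            sig[-1] = True  # keep only the last (noise) band
            return np.where(sig, 0.0, 0.5), sig

        monkeypatch.setattr(sel, "band_significance", fake_significance)
        res = iterative_band_selection(X, y)
        assert res.stop_reason == "no_improvement"
        assert res.band_mask.all()  # pre-crop model returned
        assert len(res.metrics) == 1

    def test_no_significant_band_retains_all_bands(self, rng, monkeypatch):
        X = rng.standard_normal((12, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(12)

        def none_significant(coefs, alpha=0.1):
            n_bands = coefs.shape[1]
            return np.ones(n_bands), np.zeros(n_bands, dtype=bool)

        monkeypatch.setattr(sel, "band_significance", none_significant)
        res = iterative_band_selection(X, y)
        assert res.band_mask.all()
        assert res.stop_reason == "no_improvement"

    def test_iteration_cap_reported(self, rng, monkeypatch):
        X = rng.standard_normal((14, 30))
        z = rng.standard_normal(14)
        X += z[:, None]
        y = z + 0.1 * rng.standard_normal(14)

        calls = {"n": 0}
        real_evaluate = sel._evaluate

        def drop_one(coefs, alpha=0.1):
            n_bands = coefs.shape[1]
            sig = np.ones(n_bands, dtype=bool)
            sig[0] = False
            return np.where(sig, 0.0, 1.0), sig

        def shrinking_rmse(X_, y_, mask, nlv_max, scale):
            calls["n"] += 1
            loo, nlv, model, metrics = real_evaluate(X_, y_, mask, nlv_max, scale)
            metrics.rmse_val = 1.0 / calls["n"]  # force strict improvement
            return loo, nlv, model, metrics

        monkeypatch.setattr(sel, "band_significance", drop_one)
        monkeypatch.setattr(sel, "_evaluate", shrinking_rmse)
        res = iterative_band_selection(X, y, max_iterations=3)
        assert res.stop_reason == "max_iterations"
        assert res.iterations == 4  # three accepted crops after the first pass

    def test_band_filter_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20, 50))
        y = rng.permutation(X[:, 0])  # global null by permutation
        loo1 = loo_validate(X, y, nlv_max=5)
        loo2 = loo_validate(X, y, nlv_max=5)
        p1, s1 = band_significance(loo1.coefs_at(select_nlv(loo1)))
        p2, s2 = band_significance(loo2.coefs_at(select_nlv(loo2)))
        assert np.array_equal(p1, p2)
        assert np.array_equal(s1, s2)
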