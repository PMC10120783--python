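"""SIMPLS, Δr, TSR imputation, component selection, permutation inference."""

import numpy as np
import pandas as pd
import pytest

from widefc import experiments as ex
from widefc import plsr


def _zs(A):
    return plsr.zscore_columns(A)[0]


class TestSimpls:
    def test_noiseless_single_component(self, rng):
        # X carries a single latent factor, y is exactly linear in it
        t = rng.normal(size=100)
        X = np.outer(t, rng.normal(size=10))
        y = X @ rng.normal(size=10)
        X0, Y0 = _zs(X), _zs(y[:, None])
        est = plsr.SIMPLSRegression(1).fit(X0, Y0)
        pred = est.predict(X0)
        ss_res = ((Y0 - pred) ** 2).sum()
        ss_tot = (Y0**2).sum()
        assert 1 - ss_res / ss_tot > 0.999

    def test_full_rank_equals_ols_predictions(self, rng):
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=80)
        est = plsr.SIMPLSRegression(6).fit(X, y[:, None])
        Xi = np.column_stack([X, np.ones(80)])
        beta = np.linalg.lstsq(Xi, y, rcond=None)[0]
        np.testing.assert_allclose(est.predict(X).ravel(), Xi @ beta, atol=1e-8)

    def test_residuals_orthogonal_to_scores(self, rng):
        X = rng.normal(size=(60, 8))
        Y = rng.normal(size=(60, 2))
        est = plsr.SIMPLSRegression(3).fit(X, Y)
        assert np.abs(est.x_residuals_.T @ est.x_scores_).max() < 1e-8

    def test_matches_reference_pls_predictions(self, rng):
        """Cross-check against an independent PLS implementation (NIPALS)."""
        from sklearn.cross_decomposition import PLSRegression

        # SIMPLS and NIPALS coincide for a single response
        X = rng.normal(size=(120, 9))
        y = X[:, :3] @ rng.normal(size=3) + 0.3 * rng.normal(size=120)
        mine = plsr.SIMPLSRegression(3).fit(X, y[:, None])
        ref = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(mine.predict(X), ref.predict(X), atol=1e-8)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError):
            plsr.SIMPLSRegression(1).fit(rng.normal(size=(20, 3)), np.ones((20, 1)))


class TestDeltaR:
    def test_full_rank_single_y_equals_ols_slopes(self, rng):
        X = rng.normal(size=(200, 5))
        y = X @ rng.normal(size=5) + 0.5 * rng.normal(size=200)
        X0, sx = plsr.zscore_columns(X)[0], plsr.zscore_columns(X)[2]
        Y0, sy = plsr.zscore_columns(y[:, None])[0], plsr.zscore_columns(y[:, None])[2]
        f = plsr._simpls(X0, Y0, 5)
        dr = plsr.delta_r(f["x_loadings"], f["y_loadings"], 200, sx, sy)
        ols = np.array([np.polyfit(y, X[:, j], 1)[0] for j in range(5)])
        np.testing.assert_allclose(dr[:, 0], ols, atol=1e-6)

    def test_independent_y_gives_null_slopes(self, rng):
        n = 5000
        X = rng.normal(size=(n, 8))
        y = rng.normal(size=n)
        f = plsr._simpls(_zs(X), _zs(y[:, None]), 3)
        dr = plsr.delta_r(f["x_loadings"], f["y_loadings"], n,
                          X.std(0, ddof=1), np.array([y.std(ddof=1)]))
        assert np.abs(dr).max() < 3.0 / np.sqrt(n)

    def test_fc_speed_slope_recovered_from_generator(self):
        """Planted edge-correlation slope per cm/s recovered through the
        full window + PLSR stack."""
        cohort = ex.simulate_window_cohort(
            n_mice=1, n_pairs=4, windows_per_period=5000, speed_fc_slope=0.02,
            walk_speeds=(2.0, 4.0, 6.0, 8.0), pupil_missing=0.0, seed=5)
        m = cohort[0]
        sel = (m["meta"]["period_label"] == "walk").to_numpy()
        res = plsr.continuous_regression(m["z"][sel], m["meta"][sel],
                                        parameters=("speed",), mc_reps=3)
        e = ex.planted_edge_index(4)
        slope = res.delta_r[e, res.param_names.index("speed")]
        assert abs(slope - 0.02) < 0.005

    def test_zero_sigma_y_rejected(self, rng):
        with pytest.raises(ValueError):
            plsr.delta_r(rng.normal(size=(3, 1)), rng.normal(size=(1, 1)), 10,
                         np.ones(3), np.zeros(1))


class TestTsrImpute:
    def test_no_missing_returns_input(self, rng):
        M = rng.normal(size=(20, 4))
        out, info = plsr.tsr_impute(M)
        np.testing.assert_array_equal(out, M)
        assert info["n_iter"] == 0

    def test_exact_linear_dependence_recovered(self, rng):
        a, b = rng.normal(size=(2, 300))
        pupil = 2 * a - 0.5 * b
        M = np.column_stack([a, b, pupil])
        miss = rng.random(300) < 0.2
        M2 = M.copy()
        M2[miss, 2] = np.nan
        out, _ = plsr.tsr_impute(M2)
        assert np.abs(out[miss, 2] - pupil[miss]).max() < 1e-6
        # observed entries untouched
        np.testing.assert_array_equal(out[~miss], M[~miss])

    def test_beats_mean_imputation_under_factor_model(self, rng):
        F = rng.normal(size=(400, 2))
        L = rng.normal(size=(2, 6))
        X = F @ L + 0.1 * rng.normal(size=(400, 6))
        miss = rng.random(400) < 0.25
        Xm = X.copy()
        Xm[miss, 5] = np.nan
        out, _ = plsr.tsr_impute(Xm)
        rmse_tsr = np.sqrt(np.mean((out[miss, 5] - X[miss, 5]) ** 2))
        rmse_mean = np.sqrt(np.mean((np.nanmean(Xm[:, 5]) - X[miss, 5]) ** 2))
        assert rmse_tsr < rmse_mean

    def test_all_missing_column_rejected(self, rng):
        M = rng.normal(size=(10, 3))
        M[:, 1] = np.nan
        with pytest.raises(ValueError):
            plsr.tsr_impute(M)

    def test_max_pcs_honored(self, rng):
        M = rng.normal(size=(50, 30))
        M[rng.random(50) < 0.2, 0] = np.nan
        _, info = plsr.tsr_impute(M, max_iter=5)
        assert info["n_pcs"] <= 10


class TestSelectNcomp:
    def test_recovers_planted_two_component_structure(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            T = r.normal(size=(300, 2))
            X = T @ r.normal(size=(2, 20))
            Y = T @ r.normal(size=(2, 3)) + 0.3 * r.normal(size=(300, 3))
            c, _ = plsr.select_ncomp(_zs(X), _zs(Y), seed=s)
            hits += c == 2
        assert hits >= 8

    def test_pure_noise_selects_one(self, rng):
        X = rng.normal(size=(200, 10))
        Y = rng.normal(size=(200, 2))
        c, _ = plsr.select_ncomp(_zs(X), _zs(Y), seed=0)
        assert c == 1

    def test_c_max_honored(self, rng):
        X = rng.normal(size=(150, 30))
        Y = X[:, :15] @ rng.normal(size=(15, 2))
        c, tab = plsr.select_ncomp(_zs(X), _zs(Y), seed=0)
        assert c <= 10
        assert tab["n_components"].max() <= 10

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            plsr.select_ncomp(rng.normal(size=(15, 3)), rng.normal(size=(15, 1)))

    def test_stratified_folds_balance_labels(self, rng):
        labels = np.r_[np.zeros(40, int), np.ones(60, int)]
        folds = plsr._contiguous_folds(100, 10, np.random.default_rng(0), labels)
        for f in folds:
            share = labels[f].mean()
            assert abs(share - 0.6) <= 0.1 + 1e-9


class TestContinuousRegression:
    def _mouse(self, **kw):
        return ex.simulate_window_cohort(n_mice=1, n_pairs=2, windows_per_period=150,
                                         **kw)[0]

    def test_constant_speed_dropped_in_rest(self):
        m = self._mouse(seed=0, speed_jitter=0.0)
        sel = (m["meta"]["period_label"] == "rest").to_numpy()
        res = plsr.continuous_regression(m["z"][sel], m["meta"][sel], mc_reps=3)
        assert "speed" in res.dropped_params
        assert "duration" in res.param_names

    def test_residual_refit_slopes_vanish(self):
        m = self._mouse(seed=1, pupil_missing=0.0)
        sel = (m["meta"]["period_label"] == "walk").to_numpy()
        res = plsr.continuous_regression(m["z"][sel], m["meta"][sel],
                                        parameters=("duration", "pupil"), mc_reps=3)
        # refitting a removed parameter on the residuals finds nothing
        dur = m["meta"][sel]["duration"].to_numpy()
        resid = res.x_residuals - res.x_residuals.mean(axis=0)
        dc = dur - dur.mean()
        # normalized refit slopes are statistical zero (the removed-parameter
        # direction is orthogonal to the residuals up to y-noise leakage)
        corr = np.abs(resid.T @ dc) / (np.linalg.norm(resid, axis=0) * np.linalg.norm(dc))
        assert corr.max() < 3.0 / np.sqrt(len(dur))

    def test_all_constant_parameters_rejected(self, rng):
        meta = pd.DataFrame({"mean_speed": np.zeros(50), "mean_abs_accel": np.zeros(50),
                             "duration": np.ones(50), "mean_pupil": np.ones(50)})
        with pytest.raises(ValueError):
            plsr.continuous_regression(rng.normal(size=(50, 5)), meta, mc_reps=2, folds=5)


class TestCategoricalRegression:
    def test_label_swap_flips_contrast(self, rng):
        a = rng.normal(size=(120, 6))
        b = rng.normal(size=(120, 6)) + 0.3
        r1 = plsr.categorical_regression(a, b, seed=0, mc_reps=3)
        r2 = plsr.categorical_regression(b, a, seed=0, mc_reps=3)
        np.testing.assert_allclose(r1.contrast, -r2.contrast, atol=1e-8)

    def test_single_period_rejected(self, rng):
        with pytest.raises(ValueError):
            plsr.categorical_regression(rng.normal(size=(0, 4)), rng.normal(size=(10, 4)))

    def test_contrast_measures_mean_shift(self, rng):
        shift = 0.4
        a = 0.3 * rng.normal(size=(400, 5))
        b = 0.3 * rng.normal(size=(400, 5))
        b[:, 2] += shift
        res = plsr.categorical_regression(a, b, seed=0, mc_reps=3)
        # each dummy column's slope equals the between-period mean change,
        # so the B-minus-A contrast doubles it
        assert res.contrast[2] / 2 == pytest.approx(shift, abs=0.1)


class TestFluorescenceRegression:
    def test_scale_invariance_in_percent_units(self):
        m = ex.simulate_window_cohort(n_mice=1, n_pairs=2, windows_per_period=150,
                                      activation_offset=5.0, seed=3,
                                      pupil_missing=0.0)[0]
        sel = (m["meta"]["period_label"] == "walk").to_numpy()
        r1 = plsr.fluorescence_regression(m["dff"][sel], m["meta"][sel],
                                          parameters=("duration", "pupil"), mc_reps=3)
        r2 = plsr.fluorescence_regression(m["dff"][sel], m["meta"][sel],
                                          parameters=("duration", "pupil"), mc_reps=3)
        np.testing.assert_allclose(r1.delta_r, r2.delta_r)


class TestPermutationSignificance:
    def _fits(self, shift=0.0, n_mice=3, seed=0):
        cohort = ex.simulate_window_cohort(n_mice=n_mice, n_pairs=2,
                                           windows_per_period=120,
                                           edge_shift_r=shift, seed=seed)
        return [ex.fit_rest_walk(m, "fc", mc_reps=3) for m in cohort]

    def test_null_count_honored(self):
        fits = self._fits()
        sig = plsr.permutation_significance(fits, n_perm=50, seed=0, contrast=True)
        assert sig.n_permutations == 50
        assert sig.observed.shape == fits[0].contrast.shape

    def test_deterministic_in_seed(self):
        fits = self._fits()
        s1 = plsr.permutation_significance(fits, n_perm=30, seed=4, contrast=True)
        s2 = plsr.permutation_significance(fits, n_perm=30, seed=4, contrast=True)
        np.testing.assert_array_equal(s1.p_values, s2.p_values)
        np.testing.assert_array_equal(s1.fdr_mask, s2.fdr_mask)

    def test_planted_effect_detected_with_sign(self):
        fits = self._fits(shift=np.tanh(0.5), n_mice=4, seed=2)
        sig = plsr.permutation_significance(fits, n_perm=100, seed=0, contrast=True)
        e = ex.planted_edge_index(2)
        assert sig.fdr_mask[e]
        assert sig.observed[e] > 0


class TestActivationFcRelation:
    def _per_mouse(self, r_identity=True, n_mice=7, n_pairs=16, n_comp=6, seed=0):
        rng = np.random.default_rng(seed)
        per_mouse = []
        for _ in range(n_mice):
            fam = {}
            for family in ("across-periods", "speed", "accel", "duration", "pupil"):
                comps = []
                for _ in range(n_comp):
                    df = rng.normal(size=2 * n_pairs)
                    dc = df.copy() if r_identity else rng.normal(size=2 * n_pairs)
                    comps.append({"dfluor": df, "dconn": dc})
                fam[family] = comps
            per_mouse.append(fam)
        return per_mouse

    def test_eighty_relationships_tested(self):
        pairs = [(2 * k + 1, 2 * k + 2) for k in range(16)]
        out = plsr.activation_fc_relation(self._per_mouse(), pairs)
        assert len(out) == 80

    def test_df_is_mice_minus_one(self):
        pairs = [(2 * k + 1, 2 * k + 2) for k in range(16)]
        out = plsr.activation_fc_relation(self._per_mouse(n_mice=7), pairs)
        assert (out["df"] == 6).all()

    def test_identity_relation_is_significant(self):
        pairs = [(2 * k + 1, 2 * k + 2) for k in range(16)]
        out = plsr.activation_fc_relation(self._per_mouse(r_identity=True), pairs)
        assert np.allclose(out["mean_r"], 1.0)
        assert out["significant"].all()

    def test_small_family_skipped(self):
        pairs = [(1, 2)]
        per_mouse = self._per_mouse(n_pairs=1, n_comp=2)
        out = plsr.activation_fc_relation(per_mouse, pairs)
        assert len(out) == 0

    def test_node_total_connectivity_is_edge_mean(self, rng):
        n = 6
        vals = rng.normal(size=n * (n - 1) // 2)
        total = plsr.node_total_connectivity(vals, n)
        iu = np.triu_indices(n, k=1)
        manual = np.mean([vals[k] for k in range(len(vals)) if 0 in (iu[0][k], iu[1][k])])
        assert total[0] == pytest.approx(manual)
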