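import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ppiscale as pps
import ppiscale.group as grp
from ppiscale.exceptions import InsufficientDataError


def features_frame(X, groups, cols=grp.FEATURES_5D):
    f = pd.DataFrame(np.asarray(X, float), columns=cols)
    f["group"] = groups
    f["animal_id"] = [f"r{i}" for i in range(len(f))]
    return f


def null_features(rng, n=24, cols=grp.FEATURES_5D):
    return features_frame(
        rng.standard_normal((n, len(cols))),
        ["a"] * (n // 2) + ["b"] * (n // 2),
        cols,
    )


class TestLda:
    def test_matches_sklearn_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(0)
        X = rng.standard_normal((24, 5))
        X[12:, 0] += 1.5
        f = features_frame(X, ["a"] * 12 + ["b"] * 12)
        res = grp.lda_condition(f)
        Z = grp.standardize_features(X)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(Z, f["group"])
        mine = (Z @ res.normal + res.offset) > 0
        assert np.array_equal(mine, sk.predict(Z) == "b")
        cos = np.dot(res.normal, sk.coef_[0]) / (
            np.linalg.norm(res.normal) * np.linalg.norm(sk.coef_[0])
        )
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_separation_in_alpha_concentrates_weight(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5)) * 0.2
        X[10:, 3] += 5.0  # alpha column offset of >= 5 pooled SDs
        f = features_frame(X, ["a"] * 10 + ["b"] * 10)
        res = grp.lda_condition(f)
        w = np.abs(res.normal) / np.linalg.norm(res.normal)
        assert np.argmax(w) == 3 and w[3] > 0.8
        # after standardization a >=5-SD offset puts every animal ~1 unit
        # from the hyperplane, far above the ~0.3 typical of null data
        assert res.mean_abs_distance > 0.8

    def test_one_animal_per_group_rejected(self):
        f = features_frame(np.eye(2, 5), ["a", "b"])
        with pytest.raises(InsufficientDataError):
            grp.lda_condition(f)

    def test_distance_invariant_to_feature_order_and_affine(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 5))
        X[10:] += 0.8
        y = ["a"] * 10 + ["b"] * 10
        d0 = grp.lda_condition(features_frame(X, y)).mean_abs_distance
        perm = rng.permutation(5)
        d1 = grp.lda_condition(features_frame(X[:, perm], y)).mean_abs_distance
        d2 = grp.lda_condition(
            features_frame(X * [2, 5, 0.1, 3, 7] + [1, -4, 0, 2, 9], y)
        ).mean_abs_distance
        assert d1 == pytest.approx(d0, abs=1e-10)
        assert d2 == pytest.approx(d0, abs=1e-10)


class TestPermutationDistance:
    def test_perfect_separation_strongly_significant(self):
        # a 10-SD offset dominates: almost no permuted labeling reaches the
        # observed distance (near-mislabelings can tie it in pooled-SD
        # units, so the p-value floor 1/(n_perm+1) is approached, not met)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 5))
        X[6:, 0] += 10.0
        f = features_frame(X, ["a"] * 6 + ["b"] * 6)
        res = grp.permutation_distance_test(f, n_perm=500, seed=0)
        assert res.permutation_p < 0.05

    def test_null_p_not_small(self):
        rng = np.random.default_rng(4)
        ps = [
            grp.permutation_distance_test(
                null_features(rng), n_perm=200, seed=i
            ).permutation_p
            for i in range(20)
        ]
        # under the null p is ~uniform: its mean is near 0.5
        assert 0.25 < np.mean(ps) < 0.75

    def test_batched_statistic_matches_direct_fit(self):
        rng = np.random.default_rng(5)
        X = grp.standardize_features(rng.standard_normal((16, 5)))
        y1 = np.array([False] * 8 + [True] * 8)
        batch = grp._batched_distance_stat(X, y1[None, :])
        w, b = grp._lda_fit(X, y1)
        assert batch[0] == pytest.approx(grp._mean_abs_distance(X, w, b), rel=1e-8)

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(match="resolution"):
            grp.permutation_distance_test(null_features(rng), n_perm=50, seed=0)


class TestLoocv:
    def test_matches_sklearn_loocv(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(7)
        X = rng.standard_normal((18, 5))
        X[9:, 1] += 1.0
        f = features_frame(X, ["a"] * 9 + ["b"] * 9)
        mine = grp.loocv_accuracy(f)
        Z = grp.standardize_features(X)
        y = f["group"].to_numpy()
        hits = []
        for i in range(len(f)):
            tr = np.ones(len(f), bool)
            tr[i] = False
            m = LinearDiscriminantAnalysis(solver="lsqr").fit(Z[tr], y[tr])
            hits.append(m.predict(Z[[i]])[0] == y[i])
        assert mine == pytest.approx(np.mean(hits))

    def test_perfectly_separated_accuracy_one(self):
        X = np.tile([[0.0, 1.0, 2.0, 3.0, 4.0]], (8, 1))
        X[4:, 0] = 10.0
        X += np.random.default_rng(8).normal(0, 1e-3, X.shape)
        f = features_frame(X, ["a"] * 4 + ["b"] * 4)
        acc, p = grp.loocv_accuracy_test(f, n_perm=300, seed=1)
        assert acc == 1.0
        assert p < 0.05

    def test_identical_groups_near_chance(self):
        rng = np.random.default_rng(9)
        accs = [grp.loocv_accuracy(null_features(rng)) for _ in range(30)]
        assert abs(np.mean(accs) - 0.5) < 0.12
        # chance-level accuracy should not look significant
        f = null_features(np.random.default_rng(10))
        _, p = grp.loocv_accuracy_test(f, n_perm=300, seed=2)
        assert p > 0.05


class TestRatioMultiplicity:
    def test_extremes(self):
        assert grp.ratio_multiplicity_test(0, 13, seed=0) > 0.4
        assert grp.ratio_multiplicity_test(13, 13, n_boot=1000, seed=0) == pytest.approx(
            1 / 1001
        )

    def test_matches_exact_binomial_tail(self):
        # 6 of 13 conditions at alpha = 0.05: exact tail ~2e-6
        p = grp.ratio_multiplicity_test(6, 13, n_boot=10_000, seed=1)
        exact = stats.binom.sf(5, 13, 0.05)
        assert p < 1e-4
        assert abs(p - exact) < 3e-4  # within Monte-Carlo error of ~0

    @pytest.mark.parametrize("k,n", [(1, 5), (2, 13), (3, 15)])
    def test_oracle_equivalence_moderate_counts(self, k, n):
        p = grp.ratio_multiplicity_test(k, n, n_boot=20_000, seed=2)
        exact = stats.binom.sf(k - 1, n, 0.05)
        assert abs(p - exact) < 4 * np.sqrt(exact * (1 - exact) / 20_000) + 1e-4


class TestPca:
    def test_coupled_features_opposite_sign_weights(self):
        rng = np.random.default_rng(11)
        n = 200
        mmax = rng.standard_normal(n)
        thr = rng.standard_normal(n)
        alpha = -0.8 * mmax + 0.3 * rng.standard_normal(n)
        beta = -0.8 * thr + 0.3 * rng.standard_normal(n)
        f = features_frame(
            np.column_stack([mmax, thr, alpha, beta]),
            ["a"] * n,
            cols=grp.FEATURES_4D,
        )
        out = grp.pca_condition(f, n_perm=300, seed=0)
        w = out["pc1_weights"]
        assert np.sign(w["alpha"]) == -np.sign(w["m_max"])
        assert np.sign(w["beta"]) == -np.sign(w["threshold"])
        assert out["permutation_p"] < 0.05

    def test_independent_features_not_significant(self):
        rng = np.random.default_rng(12)
        f = features_frame(
            rng.standard_normal((100, 4)), ["a"] * 100, cols=grp.FEATURES_4D
        )
        out = grp.pca_condition(f, n_perm=300, seed=1)
        assert out["permutation_p"] > 0.05
        assert out["pc1_variance_fraction"] < 0.45

    def test_collinear_pair_dominates(self):
        rng = np.random.default_rng(13)
        x = rng.standard_normal(50)
        f = features_frame(
            np.column_stack([x, x, rng.standard_normal(50), rng.standard_normal(50)]),
            ["a"] * 50,
            cols=grp.FEATURES_4D,
        )
        out = grp.pca_condition(f, n_perm=100, seed=2)
        assert out["pc1_variance_fraction"] >= 0.5


class TestCorrelations:
    def _cohort_features(self, rho, n, seed, condition=(14.0, 100.0)):
        rng = np.random.default_rng(seed)
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        return pd.DataFrame(
            {
                "prepulse_db": condition[0],
                "delay_ms": condition[1],
                "m_max": 2.0 + 0.35 * z[:, 0],
                "threshold": 10.0 + 4.0 * rng.standard_normal(n),
                "alpha": np.clip(0.8 + 0.06 * z[:, 1], 0, 1),
                "beta": np.clip(0.9 + 0.03 * rng.standard_normal(n), 0, 1),
                "animal_id": [f"r{i}" for i in range(n)],
            }
        )

    @pytest.mark.parametrize("rho", [-0.6, 0.0])
    def test_mean_sample_r_tracks_generative_rho(self, rho):
        rs = []
        for rep in range(200):
            f = self._cohort_features(rho, 24, seed=1000 + rep)
            out = grp.scaling_baseline_correlation(f)
            rs.append(out[out["response"] == "alpha"]["r"].iloc[0])
        tol = 0.1 if rho != 0 else 0.05
        assert abs(np.mean(rs) - rho) < tol

    def test_two_animals_degenerate(self):
        f = self._cohort_features(0.0, 2, seed=3)
        out = grp.scaling_baseline_correlation(f)
        assert out["degenerate"].all()


class TestJitterCorrelationMachinery:
    def test_within_animal_null_handles_zero_noise(self, example_curve):
        from conftest import make_noiseless_summaries

        sc = {(6.0, 100.0): (0.85, 0.95)}
        summ = make_noiseless_summaries(example_curve, sc, sem=0.0)
        res = pps.StartleScalingModel(summ, animal_id="a").fit()
        out = grp.within_animal_null(res, n_refit=30, seed=0)
        # degenerate (constant) refits give undefined correlations, not a crash
        assert len(out) == 2
        assert out["r"].isna().all()

    def test_jitter_robustness_strong_correlation(self, small_cohort_fits):
        _, _, results, _ = small_cohort_fits
        out = grp.correlation_jitter_robustness(results, n_refit=25, seed=0)
        assert {"observed_r", "zero_crossing_fraction"} <= set(out.columns)
        assert (out["n_refits_used"] > 0).all()

    def test_within_animal_null_noisy_fit(self, small_cohort_fits):
        _, _, results, _ = small_cohort_fits
        res = next(iter(results.values()))
        out = grp.within_animal_null(res, n_refit=60, seed=1)
        assert np.isfinite(out["r"]).all()
        assert out["r"].between(-1, 1).all()


class TestAncova:
    def _features(self, rng, n_per=12, alpha_offset=0.0, slope_b=None):
        n = 2 * n_per
        mmax = rng.normal(2.0, 0.35, n)
        thr = rng.normal(10, 4, n)
        slope = -0.15
        alpha = 0.8 + slope * (mmax - 2.0) + rng.normal(0, 0.04, n)
        if slope_b is not None:
            alpha[n_per:] = 0.8 + slope_b * (mmax[n_per:] - 2.0) + rng.normal(
                0, 0.04, n_per
            )
        alpha[n_per:] += alpha_offset
        beta = 0.9 - 0.01 * (thr - 10) + rng.normal(0, 0.03, n)
        return pd.DataFrame(
            {
                "alpha": alpha, "beta": beta, "m_max": mmax, "threshold": thr,
                "group": ["m"] * n_per + ["f"] * n_per,
                "animal_id": [f"r{i}" for i in range(n)],
            }
        )

    def test_group_offset_detected(self):
        detected = 0
        for rep in range(40):
            f = self._features(np.random.default_rng(rep), alpha_offset=0.1)
            res = [r for r in grp.ancova_scaling(f) if r.response == "alpha"][0]
            if res.group_p is not None and res.group_p < 0.05:
                detected += 1
        assert detected > 20  # majority of replicates

    def test_interaction_halts_main_effect(self):
        halted = 0
        for rep in range(30):
            f = self._features(np.random.default_rng(500 + rep), slope_b=0.25)
            res = [r for r in grp.ancova_scaling(f) if r.response == "alpha"][0]
            if res.interaction_p is not None and res.interaction_p <= 0.05:
                assert res.group_p is None
                halted += 1
        assert halted > 15

    def test_covariate_imbalance_excluded(self):
        rng = np.random.default_rng(99)
        f = self._features(rng)
        f.loc[f["group"] == "f", "m_max"] += 2.0
        res = [r for r in grp.ancova_scaling(f) if r.response == "alpha"][0]
        assert res.excluded
        assert "covariate" in res.exclusion_reason
        assert res.group_p is None

    def test_f_test_matches_design_matrix_oracle(self):
        # group-effect p from statsmodels equals the explicit GLM F-test
        rng = np.random.default_rng(17)
        f = self._features(rng)
        res = [r for r in grp.ancova_scaling(f) if r.response == "alpha"][0]
        y = f["alpha"].to_numpy()
        g = (f["group"] == "m").to_numpy(float)
        X_full = np.column_stack([np.ones(len(f)), g, f["m_max"]])
        X_red = np.column_stack([np.ones(len(f)), f["m_max"]])

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return np.sum((y - X @ beta) ** 2)

        df2 = len(f) - X_full.shape[1]
        F = (rss(X_red) - rss(X_full)) / (rss(X_full) / df2)
        p_oracle = stats.f.sf(F, 1, df2)
        assert abs(res.group_p - p_oracle) < 1e-8


class TestScalingVsStimulusSlopes:
    def test_generated_trend_recovered(self):
        # alpha decreasing with prepulse level -> negative alpha slope,
        # i.e. positive percent-startle-scaling slope
        spec = pps.CohortSpec(groups=(("wt", 8),), seed=21)
        _, scalings = pps.sample_animal_params(spec)
        scalings = scalings.rename(columns={})
        out = grp.scaling_vs_stimulus_slopes(scalings, vary="prepulse_db")
        assert out["tests"]["alpha_slope"]["mean"] < 0
        assert out["tests"]["alpha_slope"]["p"] < 0.01

    def test_constant_scalings_centered_at_zero(self):
        rng = np.random.default_rng(22)
        rows = []
        for a in range(10):
            for p in (3.0, 6.0, 10.0, 14.0, 18.0):
                rows.append(
                    {
                        "animal_id": f"r{a}", "prepulse_db": p, "delay_ms": 100.0,
                        "alpha": 0.8 + rng.normal(0, 0.02),
                        "beta": 0.9 + rng.normal(0, 0.02),
                    }
                )
        out = grp.scaling_vs_stimulus_slopes(pd.DataFrame(rows), vary="prepulse_db")
        assert abs(out["tests"]["alpha_slope"]["mean"]) < 0.01

    def test_two_conditions_skipped(self):
        rows = [
            {"animal_id": "r0", "prepulse_db": p, "delay_ms": 100.0,
             "alpha": 0.8, "beta": 0.9}
            for p in (6.0, 14.0)
        ]
        with pytest.warns(match="skipped"):
            out = grp.scaling_vs_stimulus_slopes(pd.DataFrame(rows))
        assert out["slopes"].empty
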