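import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from gradientshift.inference import (bh_fdr, compare_interaction_models,
                                     fit_mixed_model, group_covariate_tmap,
                                     regionwise_analysis, wilcoxon_paired,
                                     wilcoxon_vs_zero)
from gradientshift.io import AnalysisMask


def enumeration_wilcoxon_p(values):
    """Brute-force exact two-sided p: enumerate all sign assignments."""
    x = np.asarray(values, float)
    x = x[x != 0]
    ranks = st.rankdata(np.abs(x))
    w_obs = ranks[x > 0].sum()
    n = len(x)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_three_values(self):
        res = wilcoxon_vs_zero([1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(0.25, abs=1e-12)
        assert res.method == "exact"

    def test_symmetric_pair_p_one(self):
        res = wilcoxon_vs_zero([-1.0, 1.0, 2.0, -2.0])
        assert res.p_raw == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 7, 10, 12])
    def test_exact_matches_enumeration(self, n, rng):
        for _ in range(5):
            x = np.round(rng.standard_normal(n), 2)
            x = x[x != 0]
            if len(x) < 3:
                continue
            res = wilcoxon_vs_zero(x)
            assert res.p_raw == pytest.approx(enumeration_wilcoxon_p(x),
                                              abs=1e-12)

    def test_exact_with_ties_matches_enumeration(self, rng):
        x = np.array([0.5, 0.5, -0.5, 1.0, 1.0, 2.0, -1.0, 3.0])
        res = wilcoxon_vs_zero(x)
        assert res.p_raw == pytest.approx(enumeration_wilcoxon_p(x), abs=1e-12)

    def test_approx_close_to_exact_at_n20(self, rng):
        for _ in range(10):
            x = rng.standard_normal(20)
            exact = wilcoxon_vs_zero(x).p_raw
            approx = float(st.wilcoxon(x, correction=True,
                                       method="approx").pvalue)
            assert abs(exact - approx) < 0.01

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            wilcoxon_vs_zero([0.0, 0.0, 0.0])

    def test_paired_reduces_to_differences(self, rng):
        look = rng.standard_normal(15)
        shift = 0.8
        res_paired = wilcoxon_paired(look, look + shift)
        res_diff = wilcoxon_vs_zero(np.full(15, shift))
        assert res_paired.p_raw == pytest.approx(res_diff.p_raw)

    def test_identical_pairs_error(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="nonzero differences"):
            wilcoxon_paired(x, x)

    def test_bonferroni_family_of_15(self):
        res = wilcoxon_vs_zero([1.0, 2.0, 3.0, 4.0], family_size=15)
        assert res.p_adjusted == pytest.approx(min(1.0, 15 * res.p_raw))


class TestMixedModelWrapper:
    def test_noiseless_single_group_ols(self):
        x = np.linspace(0, 1, 20)
        data = pd.DataFrame({"y": 2 + 3 * x, "x": x, "study_id": "only"})
        res = fit_mixed_model(data, "y", ["x"])
        assert res.criterion == "OLS"
        assert res.params.loc["Intercept", "estimate"] == pytest.approx(2, abs=1e-8)
        assert res.params.loc["x", "estimate"] == pytest.approx(3, abs=1e-8)

    def test_missing_rows_dropped_and_counted(self, rng):
        n = 40
        data = pd.DataFrame({
            "y": rng.standard_normal(n), "x": rng.standard_normal(n),
            "study_id": np.repeat(["a", "b"], n // 2)})
        data.loc[:4, "y"] = np.nan
        res = fit_mixed_model(data, "y", ["x"])
        assert res.n_dropped == 5 and res.n_obs == n - 5

    def test_collinear_columns_named(self, rng):
        n = 30
        x = rng.standard_normal(n)
        data = pd.DataFrame({"y": rng.standard_normal(n), "x1": x,
                             "x2": 2 * x, "study_id": np.repeat(["a", "b"], 15)})
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            fit_mixed_model(data, "y", ["x1", "x2"])

    def test_r2_bounds_and_ci_brackets(self, cohort):
        from gradientshift import build_behavior_table, projection_table, shift_table
        from gradientshift.model import GradientShiftModel
        beh = build_behavior_table(cohort.trials, cohort.covariates)
        shifts = shift_table(projection_table(cohort.maps, cohort.basis))
        res = GradientShiftModel.from_tables(shifts, beh).fit().result
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1
        p = res.params
        assert ((p["ci_low"] <= p["estimate"]) & (p["estimate"] <= p["ci_high"])).all()


class TestInteractionLadder:
    def test_equal_loglik_aic_gap_is_2k(self):
        # direct AIC arithmetic on the reported columns
        from gradientshift.inference import MixedModelResult  # noqa: F401
        # two models with identical loglik differing by 3 parameters
        ll = -100.0
        aic_small = 2 * 10 - 2 * ll
        aic_large = 2 * 13 - 2 * ll
        assert aic_large - aic_small == 6.0

    def test_row_count_and_best_flag(self, cohort):
        from gradientshift import build_behavior_table, projection_table, shift_table
        beh = build_behavior_table(cohort.trials, cohort.covariates)
        shifts = shift_table(projection_table(cohort.maps, cohort.basis))
        data = shifts.merge(beh.reset_index(), on="subject_id")
        ladder = compare_interaction_models(data, max_order=5)
        assert len(ladder) == 5
        assert ladder["is_best"].sum() == 1
        # parameter counts: 9, +10 two-way, +10 three-way, +5, +1
        assert ladder["n_fixed"].tolist() == [9, 19, 29, 34, 35]

    def test_nesting_never_decreases_loglik(self, cohort):
        from gradientshift import build_behavior_table, projection_table, shift_table
        beh = build_behavior_table(cohort.trials, cohort.covariates)
        shifts = shift_table(projection_table(cohort.maps, cohort.basis))
        data = shifts.merge(beh.reset_index(), on="subject_id")
        ladder = compare_interaction_models(data, max_order=3)
        ll = ladder[ladder["estimable"]]["loglik"].to_numpy()
        assert np.all(np.diff(ll) >= -1e-6)

    def test_small_sample_flagged_unestimable(self, rng):
        n = 20
        data = pd.DataFrame({
            "success_z": rng.standard_normal(n),
            **{f"dG{k}": rng.standard_normal(n) for k in range(1, 6)},
            "reactivity": rng.standard_normal(n),
            "age": rng.integers(20, 60, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
            "study_id": np.repeat(["a", "b"], n // 2)})
        ladder = compare_interaction_models(data, max_order=5)
        assert not ladder.loc[ladder["order"] >= 3, "estimable"].any()
        assert ladder.loc[ladder["order"] == 1, "estimable"].all()


def brute_force_bh(p, q):
    """Step-up scan: largest k with p_(k) <= k*q/m; reject the k smallest."""
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    kmax = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kmax = k
    reject[order[:kmax]] = True
    return reject


class TestBH:
    def test_worked_example_all_rejected(self):
        reject, _ = bh_fdr([0.01, 0.02, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_none(self):
        reject, _ = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_matches_step_up_oracle(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            reject, _ = bh_fdr(p, q=0.05)
            assert np.array_equal(reject, brute_force_bh(p, 0.05))

    def test_empirical_fdr_controlled(self, rng):
        # mixed null/alternative p-vectors: realized FDR stays near q
        q = 0.05
        fdp = []
        for _ in range(500):
            p_null = rng.random(40)
            p_alt = rng.beta(0.08, 1.0, size=10)
            p = np.concatenate([p_null, p_alt])
            is_null = np.arange(50) < 40
            reject, _ = bh_fdr(p, q=q)
            n_rej = reject.sum()
            fdp.append((reject & is_null).sum() / n_rej if n_rej else 0.0)
        assert np.mean(fdp) <= q + 0.02


class TestRegionwise:
    def test_absent_regions_propagate(self, rng):
        n = 40
        behavior = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "study_id": np.repeat(["a", "b"], n // 2),
            "success_z": rng.standard_normal(n),
            "reactivity": rng.standard_normal(n),
            "age": rng.integers(20, 60, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float)}).set_index("subject_id")
        rows = []
        for rid in (1, 2):
            for i in range(n):
                dg = np.nan if rid == 2 else rng.standard_normal()
                rows.append({"subject_id": f"s{i}", "family": "cortical",
                             "region_id": rid, "dG": dg})
        table = regionwise_analysis(pd.DataFrame(rows), behavior)
        assert np.isnan(table.loc[table["region_id"] == 2, "p_raw"]).all()
        assert table.loc[table["region_id"] == 1, "p_raw"].notna().all()


class TestCovariateTmap:
    def _mask(self, n):
        return AnalysisMask(indices=np.arange(n), grid_shape=(n, 1, 1))

    def test_hand_computed_voxel(self):
        y = np.array([[1.0], [2.0], [2.0]])
        x = np.array([1.0, 2.0, 3.0])
        res = group_covariate_tmap(y, x, self._mask(1), min_cluster=1)
        assert res.beta[0] == pytest.approx(0.5, abs=1e-12)
        assert res.t[0] == pytest.approx(1.732, abs=1e-3)
        assert res.df == 1

    def test_constant_outcome_t_zero(self):
        y = np.ones((5, 3))
        x = np.arange(5.0)
        res = group_covariate_tmap(y, x, self._mask(3))
        assert np.allclose(res.t, 0.0)

    def test_matches_per_voxel_regression_loop(self, rng):
        n, v = 20, 50
        Y = rng.standard_normal((n, v))
        x = rng.standard_normal(n)
        res = group_covariate_tmap(Y, x, self._mask(v))
        X = np.column_stack([np.ones(n), x])
        for j in range(v):
            beta, rss = np.linalg.lstsq(X, Y[:, j], rcond=None)[:2]
            se = np.sqrt(rss[0] / (n - 2) / np.sum((x - x.mean()) ** 2))
            assert res.beta[j] == pytest.approx(beta[1], abs=1e-10)
            assert res.t[j] == pytest.approx(beta[1] / se, abs=1e-10)

    def test_cluster_detection_face_adjacency(self, rng):
        # plant a strong effect in a contiguous block of voxels
        n, shape = 30, (6, 6, 1)
        v = 36
        mask = AnalysisMask(indices=np.arange(v), grid_shape=shape)
        x = rng.standard_normal(n)
        Y = 0.05 * rng.standard_normal((n, v))
        block = [0, 1, 6, 7]          # 2x2 face-connected block
        Y[:, block] += np.outer(x, np.ones(len(block)))
        res = group_covariate_tmap(Y, x, mask, voxel_p=0.001, min_cluster=2)
        assert len(res.clusters) >= 1
        top = res.clusters.iloc[0]
        assert top["sign"] == "positive" and top["size"] >= 4

    def test_constant_covariate_error(self):
        with pytest.raises(ValueError, match="constant"):
            group_covariate_tmap(np.zeros((4, 2)), np.ones(4), self._mask(2))
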