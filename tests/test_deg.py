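"""Differential expression: fold changes, t-tests, BH, DEG calling, set comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import toxmod as tm
from toxmod.deg import bh_adjust

LN2 = np.log(2.0)


def bh_brute_force(p: np.ndarray) -> np.ndarray:
    """Independent BH step-up oracle: sort, scale by m/rank, cumulative min."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _expr_from_arrays(treat: np.ndarray, ctrl: np.ndarray, log_base="log2"):
    genes = [f"g{i}" for i in range(treat.shape[0])]
    t_ids = [f"T{i}" for i in range(treat.shape[1])]
    c_ids = [f"C{i}" for i in range(ctrl.shape[1])]
    df = pd.DataFrame(np.hstack([treat, ctrl]), index=genes, columns=t_ids + c_ids)
    expr = tm.ExpressionMatrix(df, log_base)
    return expr, tm.Contrast("t_vs_c", t_ids, c_ids)


class TestComputeFoldChanges:
    def test_forced_arithmetic_log2_means(self):
        treat = np.full((1, 4), 4.0)
        ctrl = np.full((1, 4), 3.0)
        # perturb within cohorts so the t-test is defined but means are exact
        treat += np.array([-0.1, 0.1, -0.1, 0.1])
        ctrl += np.array([-0.1, 0.1, -0.1, 0.1])
        expr, contrast = _expr_from_arrays(treat, ctrl)
        fc = tm.compute_fold_changes(expr, contrast)
        assert fc.loc["g0", "fc_log2"] == pytest.approx(1.0)
        assert fc.loc["g0", "fc_ln"] == pytest.approx(0.6931, abs=1e-4)

    def test_identical_cohorts_give_zero_fc_and_p_one(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0]])
        expr, contrast = _expr_from_arrays(vals, vals.copy())
        fc = tm.compute_fold_changes(expr, contrast)
        assert fc.loc["g0", "fc_ln"] == 0.0
        assert fc.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_pooled_t_matches_closed_form(self):
        """5 vs 5 with hand-computed pooled-variance t on 8 df."""
        treat = np.array([[10.1, 10.4, 9.8, 10.2, 10.0]])
        ctrl = np.array([[9.2, 9.5, 9.1, 9.4, 9.3]])
        expr, contrast = _expr_from_arrays(treat, ctrl, log_base="natural")
        fc = tm.compute_fold_changes(expr, contrast)
        mt, mc = treat.mean(), ctrl.mean()
        s2 = (((treat - mt) ** 2).sum() + ((ctrl - mc) ** 2).sum()) / 8
        t_hand = (mt - mc) / np.sqrt(s2 * (1 / 5 + 1 / 5))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=8)
        assert fc.loc["g0", "t_stat"] == pytest.approx(t_hand)
        assert fc.loc["g0", "p_value"] == pytest.approx(p_hand)
        assert fc.loc["g0", "fc_ln"] == pytest.approx(mt - mc)

    def test_zero_variance_nonzero_difference_is_maximally_significant(self):
        treat = np.full((1, 3), 5.0)
        ctrl = np.full((1, 3), 3.0)
        expr, contrast = _expr_from_arrays(treat, ctrl)
        fc = tm.compute_fold_changes(expr, contrast)
        assert fc.loc["g0", "p_value"] > 0
        assert fc.loc["g0", "p_value"] < 1e-300

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            tm.Contrast("x", ["T0"], ["C0", "C1"])

    def test_q_at_least_p(self, small_expr, small_contrast):
        fc = tm.compute_fold_changes(small_expr, small_contrast)
        assert (fc["q_value"] >= fc["p_value"] - 1e-12).all()


class TestBHAdjust:
    def test_hand_example_m3(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ties(self):
        np.testing.assert_allclose(bh_adjust([0.5, 0.5, 0.5]), [0.5, 0.5, 0.5])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("n", [10, 1000, 10_000])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        p = rng.random(n) ** rng.uniform(0.5, 2)
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_property_matches_oracle_and_monotone(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_brute_force(p), rtol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestEffectConversion:
    def test_study_cutoff_rounds_to_printed_fold_change(self):
        assert round(tm.effect_to_fold_change(0.60), 1) == 1.8

    def test_zero_is_unit_fold_change(self):
        assert tm.effect_to_fold_change(0.0) == 1.0

    def test_inverse_pair(self):
        assert tm.effect_to_fold_change(np.log(1.5)) == pytest.approx(1.5)


class TestDeriveEffectCutoff:
    def test_degenerate_null_zero_cutoff(self):
        vals = np.tile(np.array([[3.0], [5.0]]), (1, 6))
        df = pd.DataFrame(vals, index=["g0", "g1"], columns=[f"C{i}" for i in range(6)])
        expr = tm.ExpressionMatrix(df, "log2")
        assert tm.derive_effect_cutoff(expr, df.columns, seed=0) == 0.0

    def test_median_definition(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.normal(8, 1, size=(50, 6)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"C{i}" for i in range(6)],
        )
        expr = tm.ExpressionMatrix(df, "natural")
        med = tm.derive_effect_cutoff(expr, df.columns, confidence=0.5, n_splits=40, seed=1)
        q95 = tm.derive_effect_cutoff(expr, df.columns, confidence=0.95, n_splits=40, seed=1)
        assert 0 < med < q95

    def test_recovers_analytic_gaussian_quantile(self):
        # 3v3 split of 6 controls: fc_ln ~ N(0, sd^2 * 2/3); choose sd so the
        # 95% quantile of |fc_ln| is 0.60: 1.96 * sd * sqrt(2/3) = 0.60.
        sd = 0.60 / (1.959964 * np.sqrt(2 / 3))
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            rng.normal(0.0, sd, size=(4000, 6)),
            index=[f"g{i}" for i in range(4000)],
            columns=[f"C{i}" for i in range(6)],
        )
        expr = tm.ExpressionMatrix(df, "natural")
        cutoff = tm.derive_effect_cutoff(expr, df.columns, confidence=0.95, n_splits=50, seed=3)
        assert cutoff == pytest.approx(0.60, abs=0.05)

    def test_too_few_controls_rejected(self, small_expr):
        with pytest.raises(ValueError, match=">= 4"):
            tm.derive_effect_cutoff(small_expr, ["C1", "C2", "C3"])


class TestCallDegs:
    def test_dual_cutoff_inclusion_and_direction(self):
        table = pd.DataFrame(
            {
                "gene_id": ["up_gene", "weak_gene", "down_gene", "nonsig"],
                "fc_ln": [0.70, 0.30, -0.90, 1.5],
                "q_value": [0.005, 0.005, 0.001, 0.5],
            }
        ).set_index("gene_id", drop=False)
        degs = tm.call_degs(table, q_max=0.01, min_effect=0.60)
        assert degs.members == {"up_gene", "down_gene"}
        assert degs.directions == {"up_gene": "up", "down_gene": "down"}

    def test_null_cohorts_rarely_yield_degs(self):
        zero_seeds = 0
        for seed in range(10):
            spec = tm.SyntheticSpec(n_genes=5000, seed=seed)
            expr, _, contrast, _ = tm.generate_null_dataset(spec)
            fc = tm.compute_fold_changes(expr, contrast)
            if len(tm.call_degs(fc)) == 0:
                zero_seeds += 1
        assert zero_seeds >= 8

    def test_monotone_in_thresholds(self, null_cohort):
        _, _, _, fc = null_cohort
        loose = tm.call_degs(fc, q_max=0.5, min_effect=0.1).members
        tight = tm.call_degs(fc, q_max=0.05, min_effect=0.4).members
        assert tight <= loose

    def test_power_monotone_in_effect_size(self):
        """Recall of truly affected genes grows with the injected effect."""
        coll = tm.GeneSetCollection({"hit": [f"g{i:05d}" for i in range(100)]})
        recalls = []
        for delta in (0.5, 0.7, 1.0):
            rec = []
            for seed in range(20):
                spec = tm.SyntheticSpec(
                    n_genes=2000,
                    effects={"hit": tm.EffectSpec(delta, up_fraction=1.0)},
                    seed=seed,
                )
                expr, _, contrast, truth = tm.generate_dataset(spec, coll)
                fc = tm.compute_fold_changes(expr, contrast)
                degs = tm.call_degs(fc)
                true_pos = truth.log2_fold_change[truth.log2_fold_change != 0].index
                rec.append(len(degs.members & set(true_pos)) / len(true_pos))
            recalls.append(np.mean(rec))
        assert recalls[0] < recalls[1] < recalls[2]


class TestSetComparisons:
    def test_overlap_matrix_hand_count(self):
        mat = tm.overlap_matrix({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        assert mat.loc["x", "x"] == 3 and mat.loc["y", "y"] == 3
        assert mat.loc["x", "y"] == 2 == mat.loc["y", "x"]

    def test_overlap_matrix_symmetric_and_bounded(self):
        rng = np.random.default_rng(9)
        sets = {
            f"s{i}": set(rng.choice(200, size=rng.integers(5, 60), replace=False))
            for i in range(4)
        }
        mat = tm.overlap_matrix(sets)
        assert (mat.to_numpy() == mat.to_numpy().T).all()
        diag = np.diag(mat.to_numpy())
        for i in range(4):
            for j in range(4):
                assert mat.iloc[i, j] <= min(diag[i], diag[j])

    def test_overlap_needs_two_sets(self):
        with pytest.raises(ValueError):
            tm.overlap_matrix({"only": {"a"}})

    def test_venn_enumerated_example(self):
        regions = tm.venn_partition({"1", "2"}, {"2", "3"}, {"3"})
        assert regions == {
            "a_only": 1, "b_only": 0, "c_only": 0,
            "ab": 1, "ac": 0, "bc": 1, "abc": 0,
        }

    def test_venn_identical_sets(self):
        s = {"a", "b", "c", "d"}
        regions = tm.venn_partition(s, set(s), set(s))
        assert regions["abc"] == 4
        assert sum(regions.values()) == 4

    def test_venn_disjoint_sets_and_union_sum(self):
        a, b, c = {"1", "2"}, {"3"}, {"4", "5", "6"}
        regions = tm.venn_partition(a, b, c)
        assert (regions["a_only"], regions["b_only"], regions["c_only"]) == (2, 1, 3)
        assert sum(regions.values()) == len(a | b | c)
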