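import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from mirprofiler.diffexpr import (
    ComparisonSet,
    DERecord,
    bh_fdr,
    intersect_axes,
    rank_top,
    run_comparison,
    run_covariate_comparison,
    welch_anova,
    welch_t,
)
from mirprofiler.preprocess import floor_and_log, percentile_shift
from mirprofiler.synthetic import generate_dataset
from tests.conftest import make_matrix, make_sheet
from tests.oracles import bh_stepup, permutation_t_p, welch_t_formula


class TestWelchT:
    def test_identical_groups_give_zero_statistic(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_constant_equal_groups_degenerate_convention(self):
        t, df, p = welch_t([2, 2, 2], [2, 2, 2])
        assert (t, p) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 2, 9)
        t, df, p = welch_t(a, b)
        t0, df0, p0 = welch_t_formula(a, b)
        assert t == pytest.approx(t0)
        assert df == pytest.approx(df0)
        assert p == pytest.approx(p0)

    def test_permutation_oracle_bounds_strong_separation(self):
        a, b = [10, 11, 12, 13], [1, 2, 3]
        p_perm = permutation_t_p(a, b)
        assert p_perm == pytest.approx(1 / 35)  # unique most-extreme split
        _, _, p = welch_t(a, b)
        assert p < p_perm < 0.05

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=5), rng.normal(1, 1, size=7)
        t_ab, _, p_ab = welch_t(a, b)
        t_ba, _, p_ba = welch_t(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="2 values"):
            welch_t([1.0], [1, 2, 3])

    def test_null_calibration_at_nominal_alpha(self):
        # 10,000 null replicates, n=5 vs 5: rejection rate at 0.05
        rng = np.random.default_rng(2024)
        a = rng.normal(size=(10_000, 5))
        b = rng.normal(size=(10_000, 5))
        p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        assert 0.04 <= (p < 0.05).mean() <= 0.06


class TestWelchAnova:
    def test_identical_groups(self):
        f, df1, df2, p = welch_anova([[1, 2, 3]] * 3)
        assert f == 0.0 and p == 1.0

    def test_two_groups_routed_to_welch_t(self):
        with pytest.raises(ValueError, match="welch_t"):
            welch_anova([[1, 2], [3, 4]])

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_independent_implementation(self, seed):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(seed)
        groups = [rng.normal(0, 1, 6), rng.normal(0.3, 2, 9), rng.normal(1, 3, 12)]
        f, df1, df2, p = welch_anova(groups)
        frame = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pingouin.welch_anova(data=frame, dv="y", between="g").iloc[0]
        assert f == pytest.approx(ref["F"])
        assert df2 == pytest.approx(ref["ddof2"])
        assert p == pytest.approx(ref["p_unc"])

    def test_null_calibration_unequal_variances(self):
        rng = np.random.default_rng(99)
        rej = 0
        n = 10_000
        for _ in range(n):
            g = [rng.normal(0, 1, 5), rng.normal(0, 2, 8), rng.normal(0, 3, 12)]
            rej += welch_anova(g)[3] < 0.05
        assert 0.04 <= rej / n <= 0.06


class TestBhFdr:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 21))
        np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _two_class_sheet(n1, n2, c1="BRCA1-C", c2="BRCA1-N"):
    labels = {f"a{i}": c1 for i in range(n1)} | {f"b{i}": c2 for i in range(n2)}
    return make_sheet(labels), list(labels)


class TestRunComparison:
    def test_and_rule_requires_both_thresholds(self):
        # p0: highly significant but FC < 1.5; p1: called; fillers give BH a family
        rng = np.random.default_rng(13)
        n1 = n2 = 8
        values = rng.normal(0, 1, size=(30, n1 + n2))
        values[0, :n1] += 0.4  # FC 2^0.4 = 1.32, precise (tiny noise)
        values[0] = values[0] * 0.01 + np.array([0.4] * n1 + [0.0] * n2)
        values[1, :n1] += 3.0
        sheet, samples = _two_class_sheet(n1, n2)
        em = make_matrix(values, samples=samples, scale="normalized")
        records, cset = run_comparison(em, sheet, "BRCA1-C", "BRCA1-N")
        r0 = records[0]
        assert r0.fdr_q < 0.05 and r0.fc_magnitude < 1.5 and not r0.called
        assert records[1].called and records[1].direction == "up"
        assert "p1" in cset.up

    def test_zero_variance_probe_logged_not_fatal(self):
        values = np.vstack([np.zeros(8), np.random.default_rng(1).normal(size=8)])
        sheet, samples = _two_class_sheet(4, 4)
        em = make_matrix(values, samples=samples, scale="normalized")
        records, _ = run_comparison(em, sheet, "BRCA1-C", "BRCA1-N")
        assert records[0].p_value == 1.0 and not records[0].called

    def test_null_data_rarely_yields_calls(self):
        rng = np.random.default_rng(21)
        sheet, samples = _two_class_sheet(10, 10)
        em = make_matrix(rng.normal(size=(100, 20)), samples=samples, scale="normalized")
        _, cset = run_comparison(em, sheet, "BRCA1-C", "BRCA1-N")
        assert cset.n_total == 0

    def test_unknown_class_rejected(self):
        sheet, samples = _two_class_sheet(2, 2)
        em = make_matrix(np.ones((2, 4)), samples=samples, scale="normalized")
        with pytest.raises(ValueError):
            run_comparison(em, sheet, "BRCA1-C", "nope")

    def test_planted_design_recovery(self, planted):
        cfg, ds, normalized = planted
        sens = {}
        prec = {}
        sets = {}
        for axis, (c, n) in {
            "axis1": ("BRCA1-C", "BRCA1-N"),
            "axis2": ("BRCA2-C", "BRCA2-N"),
        }.items():
            _, cset = run_comparison(normalized, ds.sheet, c, n)
            truth = ds.truth.de_set(c, n)
            tp = sum(1 for p in cset.called if p in truth and cset.direction_of(p) == truth[p])
            sens[axis] = tp / len(truth)
            prec[axis] = tp / cset.n_total
            sets[axis] = cset
        assert min(sens.values()) >= 0.9
        assert min(prec.values()) >= 0.9
        inter = intersect_axes(sets["axis1"], sets["axis2"])
        shared_truth = set(ds.truth.de_axis("BRCA1-C:BRCA1-N")) & set(
            ds.truth.de_axis("BRCA2-C:BRCA2-N")
        )
        tp = len(inter.shared.called & shared_truth)
        assert tp / len(shared_truth) >= 0.9
        assert tp / max(1, inter.shared.n_total) >= 0.9


class TestCovariateComparison:
    def _her2_setup(self, seed=31, n_affected=85):
        rng = np.random.default_rng(seed)
        n_samples = 20
        labels, her2 = {}, {}
        for i in range(n_samples):
            labels[f"t{i}"] = "BRCA1-C" if i % 2 else "BRCA2-C"
            her2[f"t{i}"] = "pos" if i < n_samples // 2 else "neg"
        sheet = make_sheet(labels)
        sheet.data["HER2"] = [her2[s] for s in sheet.sample_ids]
        values = rng.normal(size=(200, n_samples))
        values[:n_affected, : n_samples // 2] += 3.0  # HER2 effect crossing classes
        em = make_matrix(values, samples=sheet.sample_ids, scale="normalized")
        return em, sheet

    def test_planted_her2_effect_recovered(self):
        em, sheet = self._her2_setup()
        _, cset = run_covariate_comparison(em, sheet, "HER2", ("pos", "neg"))
        planted_set = {f"p{i}" for i in range(85)}
        assert 80 <= cset.n_total <= 90
        assert len(set(cset.up) & planted_set) >= 80

    def test_constant_covariate_rejected(self):
        em, sheet = self._her2_setup()
        sheet.data["ER"] = "neg"
        with pytest.raises(ValueError, match="fewer than 2"):
            run_covariate_comparison(em, sheet, "ER", ("pos", "neg"))

    def test_null_covariate_yields_no_calls(self):
        em, sheet = self._her2_setup(n_affected=0)
        _, cset = run_covariate_comparison(em, sheet, "HER2", ("pos", "neg"))
        assert cset.n_total == 0


def _record(probe, q, fc, direction="up", comparison="c"):
    log2fc = np.log2(fc) * (1 if direction == "up" else -1)
    return DERecord(probe, comparison, 0, 0, log2fc, q, q, called=True)


class TestRankTop:
    def test_fdr_then_fold_change_tiebreak(self):
        records = [_record("a", 0.01, 5), _record("b", 0.01, 8), _record("c", 0.001, 2)]
        top = rank_top(records, k=3)["up"]
        assert [r.probe_id for r in top] == ["c", "b", "a"]

    def test_k_larger_than_list(self):
        records = [_record("a", 0.01, 5)]
        assert len(rank_top(records, k=10)["up"]) == 1

    def test_shuffle_invariance_with_probe_id_tiebreak(self):
        rng = np.random.default_rng(17)
        records = [_record(f"p{i}", 0.01, 2.0) for i in range(9)]
        expected = [f"p{i}" for i in range(9)]
        for _ in range(3):
            rng.shuffle(records)
            assert [r.probe_id for r in rank_top(records, k=9)["up"]] == expected


class TestIntersectAxes:
    def test_shared_and_specific_partition(self):
        a = ComparisonSet("A", up=["x"], down=["y"])
        b = ComparisonSet("B", up=["x", "z"])
        inter = intersect_axes(a, b)
        assert inter.shared.up == ["x"]
        assert inter.only_a.down == ["y"]
        assert inter.only_b.up == ["z"]
        assert inter.direction_conflicts == []

    def test_direction_conflict_excluded_and_reported(self):
        a = ComparisonSet("A", up=["x"])
        b = ComparisonSet("B", down=["x"])
        inter = intersect_axes(a, b)
        assert inter.shared.n_total == 0
        assert inter.direction_conflicts == ["x"]
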