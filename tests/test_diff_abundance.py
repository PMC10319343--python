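"""Differential abundance: filtering, normalization, testing, fold changes."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedcycle import diff_abundance as da
from seedcycle import synthetic
from tests.conftest import make_table

AB = da.Comparison("A", "B")


class TestFilterProteins:
    @staticmethod
    def table_with(peptides: int, n_missing: int):
        row = [0.0] * n_missing + [10.0] * (10 - n_missing)
        design = {f"A_{i}": "A" for i in range(5)} | {f"B_{i}": "B" for i in range(5)}
        return make_table({"P": row}, design, peptides={"P": peptides})

    def test_single_peptide_protein_removed(self):
        out = da.filter_proteins(self.table_with(peptides=1, n_missing=0), AB)
        assert out.protein_ids == []

    def test_exactly_four_missing_is_retained(self):
        out = da.filter_proteins(self.table_with(peptides=2, n_missing=4), AB)
        assert out.protein_ids == ["P"]

    def test_five_missing_removed_unless_budget_raised(self):
        table = self.table_with(peptides=2, n_missing=5)
        assert da.filter_proteins(table, AB).protein_ids == []
        assert da.filter_proteins(table, AB, max_missing=5).protein_ids == ["P"]

    def test_only_comparison_samples_counted(self):
        # missing values confined to a third condition do not count
        design = {f"{c}_{i}": c for c in "ABC" for i in range(2)}
        values = {"P": [10.0, 11.0, 12.0, 13.0, 0.0, 0.0]}
        table = make_table(values, design)
        out = da.filter_proteins(table, AB, max_missing=0)
        assert out.protein_ids == ["P"]
        assert out.samples == ["A_0", "A_1", "B_0", "B_1"]


class TestNormalizeRobustZ:
    def test_single_sample_hand_example(self):
        """log2 values 1..5: median 3, MAD 1 -> z = +-1.349, +-0.674, 0."""
        design = {"s1": "A", "s2": "A"}
        # two identical samples so the pooled t machinery stays happy
        vals = [2.0 ** v for v in (1, 2, 3, 4, 5)]
        table = make_table({f"p{i}": [v, v] for i, v in enumerate(vals)}, design)
        out = da.normalize_robust_z(table)
        z = (out["s1"] - 3.0) / (da.MAD_TO_SD * 1.0)  # undo the grand rescale
        assert np.allclose(z, [-1.349, -0.674, 0.0, 0.674, 1.349], atol=1e-3)

    def test_per_sample_median_equals_grand_median(self):
        rng = np.random.default_rng(0)
        design = {f"s{i}": "A" for i in range(3)} | {f"t{i}": "B" for i in range(3)}
        table = make_table(
            {f"p{i}": list(2 ** (15 + rng.standard_normal(6))) for i in range(41)},
            design,
        )
        out = da.normalize_robust_z(table)
        grand = np.median(out.to_numpy())
        assert np.allclose(out.median(axis=0), grand, atol=1e-9)

    def test_rank_preserving_within_sample(self):
        rng = np.random.default_rng(1)
        design = {"s1": "A", "s2": "A"}
        table = make_table(
            {f"p{i}": list(2 ** (12 + 3 * rng.random(2))) for i in range(20)}, design
        )
        out = da.normalize_robust_z(table)
        for s in table.samples:
            raw_order = table.intensities[s].rank()
            assert (out[s].rank() == raw_order).all()

    def test_missing_entries_stay_missing(self):
        design = {"s1": "A", "s2": "A"}
        table = make_table({"p0": [0.0, 8.0], "p1": [4.0, 2.0], "p2": [2.0, 4.0],
                            "p3": [8.0, 16.0]}, design)
        out = da.normalize_robust_z(table)
        assert math.isnan(out.loc["p0", "s1"]) and not math.isnan(out.loc["p0", "s2"])


class TestPooledT:
    def test_hand_example(self):
        res = da.pooled_t_test([1, 2, 3], [4, 5, 6])
        assert res.df == 4
        assert res.t_stat == pytest.approx(-3.674, abs=1e-3)

    def test_identical_groups(self):
        res = da.pooled_t_test([2.0, 2.0], [2.0, 2.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_insufficient_data_is_absent_not_error(self):
        assert da.pooled_t_test([1.0], [1.0, 2.0]) is None

    def test_matches_reference_implementation(self):
        """1000 random instances agree with the textbook equal-variance t."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 9))
            ours = da.pooled_t_test(a, b)
            ref_t, ref_p = sps.ttest_ind(a, b, equal_var=True)
            assert abs(ours.t_stat - ref_t) < 1e-10
            assert abs(ours.p_value - ref_p) < 1e-10


class TestLog2FoldChange:
    def test_simple_ratio(self):
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        table = make_table({"P": [2.0, 2.0, 8.0, 8.0]}, design)
        lfc, pseudo = da.log2_fold_change(table, "P", AB)
        assert lfc == pytest.approx(2.0) and not pseudo

    def test_pseudo_fc_uses_condition_floor(self):
        """Second condition absent; floor = mean of the 10% smallest B means."""
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        values = {"target": [40.0, 40.0, 0.0, 0.0]}
        for i, m in enumerate([10.0, 20.0, 30.0, 40.0, 50.0]):
            values[f"bg{i}"] = [m, m, m, m]
        table = make_table(values, design)
        assert da.pseudo_floor(table, "B") == pytest.approx(10.0)
        lfc, pseudo = da.log2_fold_change(table, "target", AB)
        assert pseudo and lfc == pytest.approx(math.log2(10.0 / 40.0))

    def test_antisymmetric_under_reversal(self, toy_table):
        for pid in ["p0", "p3", "p_absent"]:
            fwd, _ = da.log2_fold_change(toy_table, pid, AB)
            rev, _ = da.log2_fold_change(toy_table, pid, AB.reversed())
            assert fwd == pytest.approx(-rev)

    def test_pseudo_magnitude_grows_with_present_mean(self):
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        lfcs = []
        for mean_a in (40.0, 80.0, 160.0):
            values = {"target": [mean_a, mean_a, 0.0, 0.0],
                      "bg": [30.0, 30.0, 10.0, 10.0]}
            lfc, pseudo = da.log2_fold_change(make_table(values, design), "target", AB)
            assert pseudo
            lfcs.append(abs(lfc))
        assert lfcs == sorted(lfcs)

    def test_both_conditions_missing_rejected(self):
        design = {"a1": "A", "b1": "B"}
        table = make_table({"P": [0.0, 0.0], "Q": [1.0, 1.0]}, design)
        with pytest.raises(ValueError, match="both"):
            da.log2_fold_change(table, "P", AB)


class TestAdjustBH:
    def test_hand_example(self):
        assert np.allclose(da.adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert da.adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        adj = da.adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(50)
        assert np.allclose(da.adjust_bh(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            da.adjust_bh([0.5, 1.5])


class TestClassify:
    @pytest.mark.parametrize(
        "adj_p,lfc,expected",
        [(0.04, 1.2, da.ACCUMULATED), (0.04, -0.5, da.NOT_SIGNIFICANT),
         (0.04, -1.2, da.DEPLETED), (0.2, 3.0, da.NOT_SIGNIFICANT)],
    )
    def test_threshold_rules(self, adj_p, lfc, expected):
        stat = da.ProteinStat("P", 1.0, 1.0, lfc, False, adj_p=adj_p, p_value=adj_p)
        assert da.classify_significance(stat) == expected

    def test_pseudo_detected_only_in_second(self):
        stat = da.ProteinStat("P", None, 10.0, 3.0, True)
        assert da.classify_significance(stat) == da.ONLY_IN_SECOND

    def test_pseudo_detected_only_in_first(self):
        stat = da.ProteinStat("P", 10.0, None, -3.0, True)
        assert da.classify_significance(stat) == da.ONLY_IN_FIRST


class TestRunComparison:
    def test_spiked_protein_recovered(self):
        cfg = synthetic.ProteomeSimConfig(
            n_proteins=60, conditions=["A", "B"], replicate_sd=0.3,
            log2_effect_sizes={"P00007": {"B": 3.0}}, seed=11,
        )
        res = da.run_comparison(synthetic.simulate_intensity_table(cfg), AB)
        by_id = {s.protein_id: s for s in res.stats}
        assert by_id["P00007"].sig_class == da.ACCUMULATED

    def test_absent_pair_lands_in_only_in_one_tally(self):
        cfg = synthetic.ProteomeSimConfig(
            n_proteins=60, conditions=["A", "B"], replicate_sd=0.3,
            absent_pairs=[("P00003", "B")], seed=12,
        )
        res = da.run_comparison(synthetic.simulate_intensity_table(cfg), AB)
        by_id = {s.protein_id: s for s in res.stats}
        assert by_id["P00003"].sig_class == da.ONLY_IN_FIRST
        assert res.summary["only_in_first"] == 1

    def test_null_table_yields_no_discoveries(self):
        cfg = synthetic.ProteomeSimConfig(
            n_proteins=500, conditions=["A", "B"], replicate_sd=0.5, seed=13,
        )
        res = da.run_comparison(synthetic.simulate_intensity_table(cfg), AB)
        assert res.summary["accumulated"] + res.summary["depleted"] <= 2
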