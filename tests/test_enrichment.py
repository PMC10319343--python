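"""Enrichment score, permutation significance, and over-representation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedcycle import enrichment as enr
from seedcycle.io import GeneSetCollection


def brute_force_es(scores, member_flags, weight=1.0):
    """Plain-python running-sum oracle for the enrichment score."""
    n = len(scores)
    n_hits = sum(member_flags)
    hit_total = sum(abs(s) ** weight for s, m in zip(scores, member_flags) if m)
    running, value, best = [], 0.0, 0.0
    for s, m in zip(scores, member_flags):
        if m:
            value += (abs(s) ** weight / hit_total) if hit_total > 0 else 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        running.append(value)
        if abs(value) > abs(best):
            best = value
    return best


def series(scores):
    return pd.Series(scores, index=[f"g{i}" for i in range(len(scores))])


class TestEnrichmentScore:
    def test_top_two_members_reach_unity(self):
        ranked = series([3.0, 2.0, 1.0, -1.0, -2.0])
        es, running = enr.enrichment_score(ranked, ["g0", "g1"])
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(3 / 5) and running[1] == pytest.approx(1.0)

    def test_all_members_give_unity(self):
        ranked = series([3.0, 2.0, 1.0])
        es, _ = enr.enrichment_score(ranked, ["g0", "g1", "g2"])
        assert es == pytest.approx(1.0)

    def test_no_members_present_rejected(self):
        with pytest.raises(ValueError, match="no gene-set member"):
            enr.enrichment_score(series([1.0, 2.0]), ["absent"])

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_brute_force_on_all_small_instances(self, weight):
        """Exhaustive member subsets for N <= 8 agree with the python oracle."""
        rng = np.random.default_rng(5)
        for n in range(3, 9):
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = series(scores)
            for flags in itertools.product([0, 1], repeat=n):
                if not any(flags):
                    continue
                members = [f"g{i}" for i, f in enumerate(flags) if f]
                es, _ = enr.enrichment_score(ranked, members, weight)
                assert es == pytest.approx(brute_force_es(scores, flags, weight), abs=1e-12)
                assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12

    def test_affine_invariance_at_weight_zero(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=12)
        ranked = series(scores)
        members = ["g1", "g4", "g7"]
        es0, _ = enr.enrichment_score(ranked, members, weight_exponent=0.0)
        es1, _ = enr.enrichment_score(3.0 * ranked + 0.5, members, weight_exponent=0.0)
        assert es0 == pytest.approx(es1)

    def test_sign_flips_under_negation(self):
        """Antisymmetry holds whenever the running-sum extrema are untied."""
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 50:
            n = int(rng.integers(5, 12))
            ranked = series(rng.normal(size=n))
            k = int(rng.integers(1, n))
            members = list(rng.choice(ranked.index, size=k, replace=False))
            _, running = enr.enrichment_score(ranked, members)
            if abs(running.max() + running.min()) < 1e-9:
                continue  # tied +/- extrema: the extremum sign is ambiguous
            es_pos, _ = enr.enrichment_score(ranked, members)
            es_neg, _ = enr.enrichment_score(-ranked, members)
            assert es_neg == pytest.approx(-es_pos, abs=1e-9)
            checked += 1


class TestPermutationNes:
    def test_seed_reproducible(self):
        ranked = series(np.random.default_rng(1).normal(size=30))
        r1 = enr.permutation_nes(ranked, ["g0", "g1", "g2"], n_perm=200, seed=9)
        r2 = enr.permutation_nes(ranked, ["g0", "g1", "g2"], n_perm=200, seed=9)
        assert (r1.nes, r1.p_value) == (r2.nes, r2.p_value)

    def test_p_bounded_below_by_permutation_count(self):
        ranked = series(np.linspace(5, -5, 40))
        res = enr.permutation_nes(ranked, [f"g{i}" for i in range(5)], n_perm=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_nes_sign_matches_es(self):
        ranked = series(np.linspace(5, -5, 40))
        top = enr.permutation_nes(ranked, [f"g{i}" for i in range(5)], n_perm=199, seed=3)
        bottom = enr.permutation_nes(ranked, [f"g{i}" for i in range(35, 40)],
                                     n_perm=199, seed=3)
        assert top.es > 0 and top.nes > 0
        assert bottom.es < 0 and bottom.nes < 0

    def test_top_loaded_set_detected(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        scores[:8] += 4.0  # spiked members concentrate at the top
        ranked = series(np.sort(scores)[::-1])
        res = enr.permutation_nes(ranked, [f"g{i}" for i in range(8)],
                                  n_perm=999, seed=5)
        assert res.nes > 0 and res.p_value <= 0.05


class TestGseaPreranked:
    def test_size_bounds_and_adjustment(self):
        rng = np.random.default_rng(10)
        ranked = series(rng.normal(size=50))
        coll = GeneSetCollection()
        coll.add("small", "below min", ["g0", "g1"])
        coll.add("ok", "in range", [f"g{i}" for i in range(10)])
        df = enr.gsea_preranked(ranked, coll, n_perm=99, seed=1, min_size=5)
        assert list(df["set_name"]) == ["ok"]
        assert "adj_p" in df.columns


class TestHypergeometric:
    @staticmethod
    def tail_oracle(k, N, K, n):
        """Exhaustive hypergeometric upper tail via binomial coefficients."""
        return sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
        )

    def test_degenerate_selection_equals_background(self):
        coll = GeneSetCollection()
        coll.add("S", "d", ["a", "b", "c"])
        df = enr.hypergeometric_enrichment(["a", "b", "c"], ["a", "b", "c"], coll)
        assert df["p_value"].iloc[0] == pytest.approx(1.0)
        assert df["fold_enrichment"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        background = [f"x{i}" for i in range(20)]
        coll = GeneSetCollection()
        coll.add("S", "d", background[:10])  # K = 10 of N = 20
        selected = background[:5] + background[10:15]  # k = 5 of n = 10
        df = enr.hypergeometric_enrichment(selected, background, coll)
        assert df["p_value"].iloc[0] == pytest.approx(self.tail_oracle(5, 20, 10, 10))

    def test_empty_intersection(self):
        coll = GeneSetCollection()
        coll.add("S", "d", ["z1", "z2"])
        df = enr.hypergeometric_enrichment(["a"], ["a", "b", "z1", "z2"], coll)
        assert df["fold_enrichment"].iloc[0] == 0.0
        assert df["p_value"].iloc[0] == 1.0

    def test_selection_outside_background_rejected(self):
        coll = GeneSetCollection()
        coll.add("S", "d", ["a"])
        with pytest.raises(ValueError, match="subset"):
            enr.hypergeometric_enrichment(["q"], ["a", "b"], coll)
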