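import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stressclock.datatypes import IntervalSet, ProbeManifest
from stressclock.enrichment import (
    annotate_tss,
    count_overlap,
    distance_to_nearest,
    fisher_exact_2x2,
    nested_background_compare,
    ora_hypergeometric,
    permutation_enrichment,
)
from stressclock.errors import ValidationError


def _manifest(positions, chrom="chr1"):
    ids = [f"cg{i}" for i in range(len(positions))]
    return ProbeManifest(
        pd.DataFrame(
            {"chrom": chrom, "pos": positions},
            index=pd.Index(ids, name="probe_id"),
        )
    )


class TestCountOverlap:
    def test_coordinate_conversion(self, one_peak):
        man = _manifest([150])  # 1-based 150 -> 0-based 149, inside [100, 200)
        assert count_overlap(["cg0"], man, one_peak) == 1

    def test_half_open_boundary(self, one_peak):
        man = _manifest([201])  # 0-based 200 is excluded
        assert count_overlap(["cg0"], man, one_peak) == 0

    def test_pad_arithmetic(self, one_peak):
        man = _manifest([206])  # 0-based 205, inside [90, 210) with pad=10
        assert count_overlap(["cg0"], man, one_peak, pad=0) == 0
        assert count_overlap(["cg0"], man, one_peak, pad=10) == 1

    def test_invariant_to_interval_order_and_splitting(self):
        man = _manifest([150, 250, 350])
        whole = IntervalSet.from_records([("chr1", 100, 400)])
        split = IntervalSet.from_records(
            [("chr1", 300, 400), ("chr1", 100, 200), ("chr1", 200, 300)]
        )
        q = ["cg0", "cg1", "cg2"]
        assert count_overlap(q, man, whole) == count_overlap(q, man, split) == 3

    def test_probe_without_coordinates(self, one_peak):
        man = ProbeManifest(
            pd.DataFrame(
                {"chrom": ["chr1"], "pos": [np.nan]},
                index=pd.Index(["cg0"], name="probe_id"),
            )
        )
        with pytest.raises(ValidationError, match="without coordinates"):
            count_overlap(["cg0"], man, one_peak)


class TestPermutationEnrichment:
    @staticmethod
    def _toy():
        # 10 CpGs at 100*i; one peak covers the first four
        man = _manifest([100 * (i + 1) for i in range(10)])
        peaks = IntervalSet.from_records([("chr1", 0, 401)])
        return man, peaks

    def test_exact_upper_tail_matches_enumeration(self):
        man, peaks = self._toy()
        probes = man.probe_ids
        member = {p: count_overlap([p], man, peaks) for p in probes}
        # exhaustive enumeration oracle over all C(10,3) query sets
        hits = [
            sum(member[p] for p in combo)
            for combo in itertools.combinations(probes, 3)
        ]
        exact_p = sum(h >= 3 for h in hits) / len(hits)
        assert exact_p == pytest.approx(4 / 120)
        query = [p for p in probes if member[p]][:3]
        res = permutation_enrichment(query, probes, man, peaks, n_perm=10_000, seed=5)
        assert res.observed == 3
        mc_se = math.sqrt(exact_p * (1 - exact_p) / res.n_perm)
        assert abs(res.p_perm - exact_p) < 3 * mc_se

    def test_null_moments_match_hypergeometric(self):
        man, peaks = self._toy()
        res = permutation_enrichment(
            man.probe_ids[:3], man.probe_ids, man, peaks, n_perm=10_000, seed=6
        )
        n, m, k = 10, 4, 3
        mean = k * m / n
        var = k * (m / n) * (1 - m / n) * (n - k) / (n - 1)
        assert mean == pytest.approx(1.2)
        se_mean = math.sqrt(var / res.n_perm)
        assert abs(res.null_mean - mean) < 3 * se_mean
        se_var = var * math.sqrt(2 / (res.n_perm - 1))
        assert abs(res.null_sd**2 - var) < 3 * se_var

    def test_seeded_runs_reproducible(self):
        man, peaks = self._toy()
        r1 = permutation_enrichment(man.probe_ids[:3], man.probe_ids, man, peaks, 500, seed=7)
        r2 = permutation_enrichment(man.probe_ids[:3], man.probe_ids, man, peaks, 500, seed=7)
        assert r1 == r2

    def test_p_floor_is_add_one(self):
        man, peaks = self._toy()
        res = permutation_enrichment(
            man.probe_ids[:4], man.probe_ids, man, peaks, n_perm=1000, seed=8
        )
        assert res.p_perm >= 1 / 1001

    def test_background_smaller_than_query_rejected(self):
        man, peaks = self._toy()
        with pytest.raises(ValidationError, match="smaller"):
            permutation_enrichment(man.probe_ids, man.probe_ids[:3], man, peaks)

    def test_stray_query_flagged(self):
        man, peaks = self._toy()
        with pytest.warns(UserWarning, match="not in background"):
            permutation_enrichment(
                man.probe_ids[:2], man.probe_ids[2:], man, peaks, n_perm=50, seed=0
            )


class TestNestedBackgrounds:
    def test_identical_backgrounds_agree(self):
        man = _manifest([100 * (i + 1) for i in range(40)])
        peaks = IntervalSet.from_records([("chr1", 0, 1000)])
        comp = nested_background_compare(
            man.probe_ids[:5], man.probe_ids, man.probe_ids, man, peaks,
            n_perm=4000, seed=1,
        )
        n, m, k = 40, 10, 5  # 0-based positions 99..999 fall inside [0, 1000)
        var = k * (m / n) * (1 - m / n) * (n - k) / (n - 1)
        se = math.sqrt(2 * var / 4000)
        assert abs(comp.vs_outer.null_mean - comp.vs_inner.null_mean) < 3 * se

    def test_planted_inner_enrichment_detected(self):
        # inner background 3x enriched in peak membership over the outer
        rng = np.random.default_rng(2)
        n = 600
        man = _manifest([1000 * (i + 1) for i in range(n)])
        inner = man.probe_ids[:200]
        member = np.concatenate([rng.random(200) < 0.45, rng.random(400) < 0.15])
        peaks = IntervalSet.from_records(
            [("chr1", 1000 * (i + 1) - 10, 1000 * (i + 1) + 10) for i in np.nonzero(member)[0]]
        )
        comp = nested_background_compare(
            inner[:100], inner, man.probe_ids, man, peaks, n_perm=1000, seed=3
        )
        assert comp.inner_vs_outer_p <= 0.01
        assert comp.inner_rate > comp.outer_rate


class TestDistance:
    def test_inside_is_zero(self, one_peak):
        man = _manifest([150])
        d = distance_to_nearest(["cg0"], man, one_peak)
        assert d.loc["cg0", "distance_bp"] == 0

    def test_right_side_positive(self, one_peak):
        man = _manifest([251])  # 0-based 250; last covered base 199 -> +51
        d = distance_to_nearest(["cg0"], man, one_peak)
        assert d.loc["cg0", "distance_bp"] == 51

    def test_left_side_negative(self, one_peak):
        man = _manifest([91])  # 0-based 90; interval starts at 100 -> -10
        d = distance_to_nearest(["cg0"], man, one_peak)
        assert d.loc["cg0", "distance_bp"] == -10

    def test_no_peak_on_chromosome(self, one_peak):
        man = _manifest([500], chrom="chr9")
        d = distance_to_nearest(["cg0"], man, one_peak)
        assert np.isnan(d.loc["cg0", "distance_bp"])

    def test_nearest_of_two(self):
        man = _manifest([350])  # 0-based 349; peaks [100,200) and [360,400)
        peaks = IntervalSet.from_records([("chr1", 100, 200), ("chr1", 360, 400)])
        d = distance_to_nearest(["cg0"], man, peaks)
        assert d.loc["cg0", "distance_bp"] == -11


class TestTss:
    def test_distance_linkage(self):
        man = _manifest([1419])
        tss = pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"], "tss_pos": [1000]})
        ann = annotate_tss(["cg0"], man, tss, max_dist=1500)
        assert ann.genes == ["G1"]
        assert ann.links.iloc[0]["distance_bp"] == 419

    def test_beyond_max_dist_unlinked(self):
        man = _manifest([5000])
        tss = pd.DataFrame({"gene": ["G1"], "chrom": ["chr1"], "tss_pos": [1000]})
        ann = annotate_tss(["cg0"], man, tss, max_dist=1500)
        assert ann.genes == []

    def test_multiple_genes_linked(self):
        man = _manifest([1000])
        tss = pd.DataFrame(
            {"gene": ["G1", "G2"], "chrom": ["chr1", "chr1"], "tss_pos": [900, 1100]}
        )
        ann = annotate_tss(["cg0"], man, tss, max_dist=1500)
        assert ann.genes == ["G1", "G2"]
        assert ann.mean_distance == pytest.approx(100.0)


def _fisher_oracle(a, b, c, d, alternative):
    """Exact p by hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        for x in range(lo, hi + 1)
    }
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_one_sided_by_hand(self):
        _, p = fisher_exact_2x2(3, 1, 1, 3, alternative="greater")
        assert p == pytest.approx(17 / 70)

    def test_identical_rows(self):
        _, p = fisher_exact_2x2(5, 5, 5, 5)
        assert p == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(0, 0, 0, 0)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_on_margin_grid(self, alternative):
        rng = np.random.default_rng(10)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d), alternative=alternative)
            assert p == pytest.approx(
                _fisher_oracle(int(a), int(b), int(c), int(d), alternative), abs=1e-9
            )


def _hypergeom_oracle(k, big_m, set_size, n_query):
    """P(overlap >= k) by direct combinatorial summation."""
    total = math.comb(big_m, n_query)
    acc = 0
    for x in range(k, min(set_size, n_query) + 1):
        acc += math.comb(set_size, x) * math.comb(big_m - set_size, n_query - x)
    return acc / total


class TestOra:
    def test_hypergeometric_sum_by_hand(self):
        universe = [f"g{i}" for i in range(20)]
        sets = {"S": universe[:5]}
        query = universe[2:7]  # overlap = 3
        res = ora_hypergeometric(query, universe, sets, min_set=5)
        assert res.loc["S", "overlap"] == 3
        assert res.loc["S", "p"] == pytest.approx(1126 / 15504)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_hypergeometric(universe[10:15], universe, {"S": universe[:5]})
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(12)]
        res = ora_hypergeometric(universe, universe, {"S": universe[:6]}, min_set=5)
        assert res.loc["S", "overlap"] == 6
        assert res.loc["S", "p"] == pytest.approx(1.0)

    def test_small_sets_skipped(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_hypergeometric(universe[:5], universe, {"tiny": universe[:3]}, min_set=5)
        assert len(res) == 0

    def test_stray_query_genes_dropped_with_warning(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="outside the universe"):
            res = ora_hypergeometric(
                universe[:3] + ["ghost"], universe, {"S": universe[:5]}, min_set=5
            )
        assert res.loc["S", "overlap"] == 3

    def test_matches_enumeration_on_margin_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            big_m = int(rng.integers(8, 30))
            universe = [f"g{i}" for i in range(big_m)]
            set_size = int(rng.integers(5, big_m + 1))
            n_query = int(rng.integers(1, big_m + 1))
            members = list(rng.choice(universe, size=set_size, replace=False))
            query = list(rng.choice(universe, size=n_query, replace=False))
            res = ora_hypergeometric(query, universe, {"S": members}, min_set=5)
            k = len(set(query) & set(members))
            assert res.loc["S", "p"] == pytest.approx(
                _hypergeom_oracle(k, big_m, set_size, n_query), abs=1e-9
            )
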