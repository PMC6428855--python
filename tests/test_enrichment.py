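"""Enrichment statistics: unique fractions, composition, bins, trajectories."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexseed import (
    SamplePool,
    bin_by_copy_number,
    build_pool,
    build_trajectories,
    cluster_by_hamming,
    hamming,
    nucleotide_composition,
    pool_overlap,
    unique_fraction,
)

pool_strategy = st.dictionaries(
    st.text(alphabet="ACGT", min_size=6, max_size=6),
    st.integers(min_value=1, max_value=50_000),
    min_size=1,
    max_size=40,
).map(lambda counts: SamplePool(counts=counts))


class TestUniqueFraction:
    def test_distinct_and_singleton_modes(self):
        pool = SamplePool(counts={"A": 1, "C": 2})
        assert unique_fraction(pool, "distinct") == pytest.approx(2 / 3)
        assert unique_fraction(pool, "singleton") == pytest.approx(1 / 2)

    def test_all_singletons_both_modes_one(self):
        pool = SamplePool(counts={"A": 1, "C": 1, "G": 1})
        assert unique_fraction(pool, "distinct") == 1.0
        assert unique_fraction(pool, "singleton") == 1.0

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            unique_fraction(SamplePool(counts={}))

    def test_matches_recount_on_multinomial_pool(self, multinomial_pool):
        pool, draws = multinomial_pool
        assert unique_fraction(pool, "distinct") == len(set(draws)) / len(draws)


class TestComposition:
    def test_by_copies_weighting(self, small_pool):
        comp = nucleotide_composition(small_pool, "by_copies")
        # column 0: all A; column 1: C twice, A once; column 2: G twice, A once
        np.testing.assert_allclose(comp.freqs[:, 0], [1, 0, 0, 0])
        np.testing.assert_allclose(comp.freqs[:, 1], [1 / 3, 2 / 3, 0, 0])
        np.testing.assert_allclose(comp.freqs[:, 2], [1 / 3, 0, 2 / 3, 0])

    def test_by_distinct_weighting(self, small_pool):
        comp = nucleotide_composition(small_pool, "by_distinct")
        np.testing.assert_allclose(comp.freqs[:, 1], [1 / 2, 1 / 2, 0, 0])

    def test_uniform_pool_within_binomial_bound(self, rng):
        """1e4 uniform draws: every entry within 5 sd of 0.25."""
        seqs = ["".join(rng.choice(list("ACGT"), size=15)) for _ in range(10_000)]
        comp = nucleotide_composition(build_pool(seqs), "by_copies")
        sd = np.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(comp.freqs - 0.25) < 5 * sd)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(pool=pool_strategy)
    def test_columns_sum_to_one(self, pool):
        for weighting in ("by_copies", "by_distinct"):
            comp = nucleotide_composition(pool, weighting)
            np.testing.assert_allclose(comp.freqs.sum(axis=0), 1.0, atol=1e-9)


class TestCopyNumberBinning:
    def test_boundary_values_fall_in_lower_bin(self):
        pool = SamplePool(
            counts={
                "AAAAAA": 10,
                "CCCCCC": 11,
                "GGGGGG": 100,
                "TTTTTT": 101,
                "ACACAC": 10_000,
                "GTGTGT": 10_001,
            }
        )
        binning = bin_by_copy_number(pool)
        assert binning.distinct_per_bin == (1, 2, 1, 1, 1)

    def test_single_sequence(self):
        binning = bin_by_copy_number(SamplePool(counts={"ACGT": 5}))
        assert binning.distinct_per_bin == (1, 0, 0, 0, 0)
        assert binning.copy_share_per_bin == (1.0, 0, 0, 0, 0)

    def test_matches_brute_force_binning(self, multinomial_pool):
        pool, _ = multinomial_pool
        binning = bin_by_copy_number(pool)
        edges = [(1, 10), (11, 100), (101, 1000), (1001, 10_000), (10_001, float("inf"))]
        expected_distinct = tuple(
            sum(1 for n in pool.counts.values() if lo <= n <= hi) for lo, hi in edges
        )
        expected_share = tuple(
            sum(n for n in pool.counts.values() if lo <= n <= hi) / pool.total_copies
            for lo, hi in edges
        )
        assert binning.distinct_per_bin == expected_distinct
        np.testing.assert_allclose(binning.copy_share_per_bin, expected_share)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(pool=pool_strategy)
    def test_shares_sum_to_one_and_distinct_conserved(self, pool):
        binning = bin_by_copy_number(pool)
        assert sum(binning.distinct_per_bin) == pool.n_distinct
        assert sum(binning.copy_share_per_bin) == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(pool_a=pool_strategy, pool_b=pool_strategy)
    def test_binning_consistent_under_pool_merge(self, pool_a, pool_b):
        merged_counts = dict(pool_a.counts)
        for seq, n in pool_b.counts.items():
            merged_counts[seq] = merged_counts.get(seq, 0) + n
        merged = SamplePool(counts=merged_counts)
        binning = bin_by_copy_number(merged)
        edges = [(1, 10), (11, 100), (101, 1000), (1001, 10_000), (10_001, float("inf"))]
        expected = tuple(
            sum(1 for n in merged_counts.values() if lo <= n <= hi) for lo, hi in edges
        )
        assert binning.distinct_per_bin == expected


class TestPoolOverlap:
    def test_union_denominator(self):
        a = SamplePool(counts={"AA": 1, "CC": 1})
        b = SamplePool(counts={"CC": 3, "GG": 1})
        assert pool_overlap(a, b, "union") == pytest.approx(1 / 3)

    def test_identical_pools_full_overlap(self):
        a = SamplePool(counts={"AA": 1, "CC": 2})
        for denom in ("union", "A", "B"):
            assert pool_overlap(a, a, denom) == 1.0

    def test_matches_set_oracle_on_random_pools(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(400)]
        a = build_pool(rng.choice(seqs, size=500))
        b = build_pool(rng.choice(seqs, size=500))
        sa, sb = set(a.counts), set(b.counts)
        assert pool_overlap(a, b, "union") == len(sa & sb) / len(sa | sb)
        assert pool_overlap(a, b, "A") == len(sa & sb) / len(sa)


class TestTrajectories:
    def _pools(self, specs):
        return [
            SamplePool(counts=counts, cycle=cycle, tissue="tumour")
            for cycle, counts in specs
        ]

    def test_fold_on_frequencies_without_pseudocount(self):
        # frequency 2e-4 -> 8e-4 gives fold 4
        pools = self._pools(
            [(0, {"AAAA": 2, "CCCC": 9998}), (1, {"AAAA": 8, "CCCC": 9992})]
        )
        traj = build_trajectories(pools, pseudocount=0.0)["AAAA"]
        assert traj.folds[0] == pytest.approx(4.0)

    def test_absent_then_present_finite_fold(self):
        pools = self._pools([(0, {"CCCC": 100}), (1, {"AAAA": 10, "CCCC": 90})])
        traj = build_trajectories(pools, pseudocount=0.5)["AAAA"]
        assert traj.frequencies[0] == 0.0
        assert np.isfinite(traj.folds[0]) and traj.folds[0] > 0

    def test_unordered_cycles_raise(self):
        pools = self._pools([(1, {"AAAA": 1}), (0, {"AAAA": 1})])
        with pytest.raises(ValueError, match="increasing"):
            build_trajectories(pools)

    def test_folds_match_hand_computed_ratios(self):
        """Five sequences over three cycles vs explicit spreadsheet arithmetic."""
        c0 = {"AA": 10, "CC": 20, "GG": 30, "TT": 35, "AC": 5}  # total 100
        c1 = {"AA": 30, "CC": 20, "GG": 60, "TT": 80, "AC": 10}  # total 200
        c2 = {"AA": 120, "CC": 20, "GG": 120, "TT": 100, "AC": 40}  # total 400
        pools = self._pools([(0, c0), (1, c1), (2, c2)])
        trajs = build_trajectories(pools, pseudocount=0.0)
        for seq in c0:
            f0, f1, f2 = c0[seq] / 100, c1[seq] / 200, c2[seq] / 400
            assert trajs[seq].folds == pytest.approx((f1 / f0, f2 / f1))
            assert trajs[seq].frequencies == pytest.approx((f0, f1, f2))


class TestHammingDenoiser:
    def test_child_merged_into_dominant_parent(self):
        pool = SamplePool(counts={"AAAA": 100, "AAAT": 2})
        out = cluster_by_hamming(pool, max_dist=1, min_parent_ratio=10)
        assert out.counts == {"AAAA": 102}

    def test_distant_sequences_untouched(self):
        pool = SamplePool(counts={"AAAA": 100, "TTTT": 2})
        out = cluster_by_hamming(pool, max_dist=1, min_parent_ratio=10)
        assert out.counts == pool.counts

    def test_total_copies_conserved(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(150)]
        pool = build_pool(rng.choice(seqs, size=5000))
        out = cluster_by_hamming(pool, max_dist=2, min_parent_ratio=5)
        assert out.total_copies == pool.total_copies

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        """Greedy parent/child merge identical to a literal reimplementation."""
        parents = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(30)]
        counts = {}
        for p in parents:
            counts[p] = counts.get(p, 0) + int(rng.integers(50, 500))
            for _ in range(rng.integers(0, 4)):  # children 1 mismatch away
                pos = rng.integers(0, 8)
                child = p[:pos] + rng.choice(list("ACGT")) + p[pos + 1 :]
                if child not in counts:
                    counts[child] = int(rng.integers(1, 10))
        pool = SamplePool(counts=counts)

        def oracle(counts, max_dist, ratio):
            order = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            merged, absorbed = {}, set()
            for seq, n in order:
                if seq in absorbed:
                    continue
                merged[seq] = n
                for child, m in order:
                    if child == seq or child in absorbed or child in merged:
                        continue
                    if merged[seq] >= ratio * m and hamming(seq, child) <= max_dist:
                        merged[seq] += m
                        absorbed.add(child)
            return merged

        out = cluster_by_hamming(pool, max_dist=1, min_parent_ratio=10)
        assert out.counts == oracle(counts, 1, 10)


def test_enrichment_reduces_distinct_fraction():
    """Concentrating copies (squaring counts) lowers the distinct fraction."""
    rng = np.random.default_rng(3)
    seqs = ["".join(rng.choice(list("ACGT"), size=10)) for _ in range(2000)]
    pool = build_pool(rng.choice(seqs, size=20_000))
    enriched_weights = np.array([n**3 for n in pool.counts.values()], dtype=float)
    enriched_draw = rng.choice(
        list(pool.counts), size=20_000, p=enriched_weights / enriched_weights.sum()
    )
    enriched = build_pool(enriched_draw)
    assert unique_fraction(enriched, "distinct") < unique_fraction(pool, "distinct")
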