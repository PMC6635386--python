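from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from meiohic.assoc import (
    annotate_peaks_to_features,
    compartment_occupancy_enrichment,
    counts_to_cpm,
    expression_group_comparison,
    hypergeometric_enrichment_bh,
    peak_set_overlap,
    permutation_mean_zscore,
)
from meiohic.domains import CompartmentProfile
from meiohic.layout import GenomeLayout
from meiohic.stats import bh_adjust, rank_sum_test


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand",
                                       "start", "end"])


class TestAnnotation:
    GENES = genes_frame([
        ("g1", "c1", 10_000, "+", 10_000, 14_000),
        ("g2", "c1", 30_000, "-", 26_000, 30_001),
        ("g3", "c1", 50_000, "+", 50_000, 54_000),
    ])

    def test_upstream_promoter_plus_strand(self):
        peaks = peaks_frame([("c1", 9_500, 9_900)])  # [TSS-500, TSS-100)
        cats, _ = annotate_peaks_to_features(peaks, self.GENES)
        assert cats.iloc[0] == "promoter"

    def test_minus_strand_promoter_is_downstream_in_genome(self):
        peaks = peaks_frame([("c1", 30_500, 30_700)])  # inside (tss, tss+2kb]
        cats, _ = annotate_peaks_to_features(peaks, self.GENES)
        assert cats.iloc[0] == "promoter"

    def test_priority_and_enumeration_oracle(self):
        """Category counts match a brute-force interval check for a toy set."""
        peaks = peaks_frame([
            ("c1", 9_500, 9_900),    # g1 promoter
            ("c1", 11_000, 11_200),  # g1 body
            ("c1", 31_000, 31_100),  # g2 promoter (minus strand)
            ("c1", 27_000, 27_100),  # g2 body
            ("c1", 70_000, 70_100),  # intergenic
        ])
        cats, _ = annotate_peaks_to_features(peaks, self.GENES)

        def oracle(start, end):
            for _, g in self.GENES.iterrows():
                if g.strand == "+":
                    ps, pe = g.tss - 2000, g.tss
                else:
                    ps, pe = g.tss + 1, g.tss + 2001
                if start < pe and ps < end:
                    return "promoter"
            for _, g in self.GENES.iterrows():
                if start < g.end and g.start < end:
                    return "gene_body"
            return "intergenic"

        expected = [oracle(p.start, p.end) for _, p in peaks.iterrows()]
        assert cats.tolist() == expected
        assert cats.value_counts().sum() == len(peaks)

    def test_symmetric_mode_catches_downstream_of_plus(self):
        peaks = peaks_frame([("c1", 10_500, 10_700)])  # downstream of + TSS
        up, _ = annotate_peaks_to_features(peaks, self.GENES)
        sym, _ = annotate_peaks_to_features(peaks, self.GENES,
                                            promoter_mode="symmetric")
        assert up.iloc[0] == "gene_body"
        assert sym.iloc[0] == "promoter"

    def test_tss_distance_strand_oriented(self):
        peaks = peaks_frame([("c1", 9_000, 9_100)])  # 950 bp upstream of g1
        _, dists = annotate_peaks_to_features(peaks, self.GENES)
        assert dists[0] == pytest.approx(-950)


class TestPeakOverlap:
    def test_identical_sets(self):
        a = peaks_frame([("c1", 0, 100), ("c1", 500, 600)])
        res = peak_set_overlap({"A": a, "B": a.copy()})
        full = res[(res["overlaps_with"] != "none")]
        assert full.groupby("set")["count"].sum().tolist() == [2, 2]

    def test_disjoint_sets(self):
        a = peaks_frame([("c1", 0, 100)])
        b = peaks_frame([("c1", 500, 600)])
        res = peak_set_overlap({"A": a, "B": b})
        assert (res["overlaps_with"] == "none").all()

    def test_one_peak_spanning_two(self):
        """Asymmetric counting: the spanning A peak counts once, both
        spanned B peaks count."""
        a = peaks_frame([("c1", 0, 1_000)])
        b = peaks_frame([("c1", 100, 200), ("c1", 700, 800)])
        res = peak_set_overlap({"A": a, "B": b}).set_index(["set", "overlaps_with"])
        assert res.loc[("A", "B"), "count"] == 1
        assert res.loc[("B", "A"), "count"] == 2

    def test_min_overlap_threshold(self):
        a = peaks_frame([("c1", 0, 100)])
        b = peaks_frame([("c1", 99, 200)])
        touching = peak_set_overlap({"A": a, "B": b}, min_overlap=1)
        strict = peak_set_overlap({"A": a, "B": b}, min_overlap=10)
        assert touching.set_index(["set", "overlaps_with"]).loc[("A", "B"), "count"] == 1
        assert (strict["overlaps_with"] == "none").all()

    def test_three_sets_patterns(self):
        a = peaks_frame([("c1", 0, 100)])
        b = peaks_frame([("c1", 50, 150)])
        c = peaks_frame([("c1", 90, 190)])
        res = peak_set_overlap({"A": a, "B": b, "C": c})
        idx = res.set_index(["set", "overlaps_with"])["count"]
        assert idx.loc[("A", "B+C")] == 1
        assert idx.loc[("B", "A+C")] == 1

    def test_counts_bounded_by_set_size(self):
        rng = np.random.default_rng(0)
        a = peaks_frame([("c1", int(s), int(s) + 50)
                         for s in sorted(rng.choice(10_000, 30, replace=False) * 100)])
        b = peaks_frame([("c1", int(s), int(s) + 50)
                         for s in sorted(rng.choice(10_000, 40, replace=False) * 100)])
        res = peak_set_overlap({"A": a, "B": b})
        per_set = res.groupby("set")["count"].sum()
        assert per_set["A"] == 30 and per_set["B"] == 40


class TestPermutationZ:
    LAYOUT = GenomeLayout(("c1", "c2"), (5_000_000, 5_000_000), 50_000)

    def _random_peaks(self, rng, n=40):
        rows = []
        for _ in range(n):
            c = rng.choice(["c1", "c2"])
            s = int(rng.integers(0, 4_999_000))
            rows.append((c, s, s + 500))
        return peaks_frame(rows)

    def test_constant_track_degenerate(self):
        rng = np.random.default_rng(0)
        res = permutation_mean_zscore(
            np.ones(self.LAYOUT.n_bins), self._random_peaks(rng), self.LAYOUT,
            n_perm=100, seed=1,
        )
        assert res.z == 0.0
        assert res.p == 1.0

    def test_planted_enrichment_high_z(self):
        """Peaks at top-decile track bins give a strongly positive Z."""
        rng = np.random.default_rng(7)
        track = rng.normal(size=self.LAYOUT.n_bins)
        top = np.argsort(track)[-20:]
        rows = []
        for b in top:
            chrom, s, _ = self.LAYOUT.bin_span(int(b))
            rows.append((chrom, s, s + 100))
        res = permutation_mean_zscore(track, peaks_frame(rows), self.LAYOUT,
                                      n_perm=500, seed=7)
        assert res.z > 3
        assert res.p < 0.05

    def test_flank_profile_peaks_at_zero_shift(self):
        rng = np.random.default_rng(3)
        track = rng.normal(size=self.LAYOUT.n_bins)
        top = np.argsort(track)[-25:]
        rows = []
        for b in top:
            chrom, s, _ = self.LAYOUT.bin_span(int(b))
            rows.append((chrom, s, s + 100))
        res = permutation_mean_zscore(track, peaks_frame(rows), self.LAYOUT,
                                      n_perm=300, seed=5, flank=250_000)
        center = np.argmax(res.flank_z)
        assert res.flank_shifts[center] == 0
        assert res.flank_shifts.min() == -250_000
        assert res.flank_shifts.max() == 250_000

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        track = rng.normal(size=self.LAYOUT.n_bins)
        pk = self._random_peaks(rng)
        r1 = permutation_mean_zscore(track, pk, self.LAYOUT, n_perm=100, seed=9)
        r2 = permutation_mean_zscore(track, pk, self.LAYOUT, n_perm=100, seed=9)
        assert r1.z == r2.z and r1.p == r2.p


class TestOccupancyEnrichment:
    LAYOUT = GenomeLayout(("c1",), (10_000_000,), 50_000)

    def _profile(self, labels):
        return CompartmentProfile(layout=self.LAYOUT, e1=np.zeros(200),
                                  labels=np.asarray(labels, dtype="<U2"))

    def test_all_a_degenerate(self):
        prof = self._profile(["A"] * 200)
        peaks = peaks_frame([("c1", 1_000, 1_200)])
        frac, p = compartment_occupancy_enrichment(peaks, prof, n_perm=100, seed=0)
        assert frac == 1.0 and p == 1.0

    def test_planted_enrichment_detected(self):
        """200 peaks placed 80% in A on a half-A genome: p < 0.01."""
        labels = np.array(["A"] * 100 + ["B"] * 100, dtype="<U2")
        prof = self._profile(labels)
        rng = np.random.default_rng(2)
        rows = []
        for i in range(200):
            b = int(rng.integers(0, 100)) if i < 160 else int(rng.integers(100, 200))
            rows.append(("c1", b * 50_000 + 100, b * 50_000 + 300))
        frac, p = compartment_occupancy_enrichment(peaks_frame(rows), prof,
                                                   n_perm=2_000, seed=3)
        assert frac == pytest.approx(0.8)
        assert p < 0.01

    def test_random_peaks_match_genome_fraction(self):
        labels = np.array(["A"] * 100 + ["B"] * 100, dtype="<U2")
        prof = self._profile(labels)
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(400):
            b = int(rng.integers(0, 200))
            rows.append(("c1", b * 50_000 + 100, b * 50_000 + 300))
        frac, p = compartment_occupancy_enrichment(peaks_frame(rows), prof,
                                                   n_perm=1_000, seed=5)
        lo, hi = sps.binom.interval(0.99, 400, 0.5)
        assert lo / 400 <= frac <= hi / 400
        assert p > 0.01


class TestRankSum:
    def test_identical_multisets_p_one(self):
        _, p, d = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert d == 0

    def test_exact_enumeration_oracle(self):
        """{1,2,3} vs {4,5,6}: enumerate all C(6,3)=20 assignments; the
        most extreme rank sum has two-sided p = 2/20."""
        x = [1, 2, 3]
        y = [4, 5, 6]
        stat, p, d = rank_sum_test(x, y)
        pooled = sorted(x + y)
        obs_rank_sum = sum(pooled.index(v) + 1 for v in x)
        more_extreme = 0
        total = 0
        for idx in combinations(range(6), 3):
            rs = sum(i + 1 for i in idx)
            total += 1
            if abs(rs - 10.5) >= abs(obs_rank_sum - 10.5):
                more_extreme += 1
        assert total == 20
        assert p == pytest.approx(more_extreme / total)
        assert p == pytest.approx(0.1)
        assert d == -1

    def test_large_shift_power_and_direction(self):
        rng = np.random.default_rng(0)
        a = np.exp(rng.normal(3, 0.5, 50))  # 10x shift on the log scale
        b = np.exp(rng.normal(0.7, 0.5, 50))
        _, p, d = rank_sum_test(a, b)
        assert p < 1e-6
        assert d == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_expression_table_wrapper(self):
        expr = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(6)],
            "fpkm": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        stat, p, d = expression_group_comparison(
            expr, ["g3", "g4", "g5"], ["g0", "g1", "g2"]
        )
        assert p == pytest.approx(0.1)
        assert d == 1


class TestCpm:
    def test_forced_arithmetic(self):
        counts = pd.DataFrame({"gene_id": ["a", "b", "c"], "ct": [3, 7, 90]})
        cpm = counts_to_cpm(counts)
        assert cpm["ct"].tolist() == [30_000.0, 70_000.0, 900_000.0]

    def test_two_equal_counts(self):
        counts = pd.DataFrame({"gene_id": ["a", "b"], "ct": [1, 1]})
        cpm = counts_to_cpm(counts)
        assert cpm["ct"].tolist() == [500_000.0, 500_000.0]

    def test_zero_gene_and_column_sum(self):
        counts = pd.DataFrame({"gene_id": ["a", "b", "c"], "ct": [0, 10, 30]})
        cpm = counts_to_cpm(counts)
        assert cpm["ct"].iloc[0] == 0.0
        assert cpm["ct"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            counts_to_cpm(pd.DataFrame({"gene_id": ["a"], "ct": [0]}))


class TestHypergeomBh:
    def test_term_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        res = hypergeometric_enrichment_bh({"T": set(universe)},
                                           {f"g{i}" for i in range(8)}, universe)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_combinatorial_oracle(self):
        """N=20, K=5, n=8, k=4: p = P(X=4) + P(X=5) by direct enumeration."""
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        selected = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(10, 14)}
        res = hypergeometric_enrichment_bh({"T": term}, selected, universe)

        def pmf(k, N, K, n):
            return comb(K, k) * comb(N - K, n - k) / comb(N, n)

        expected = pmf(4, 20, 5, 8) + pmf(5, 20, 5, 8)
        assert res["k"].iloc[0] == 4
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_bh_stepup_enumeration_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        q = bh_adjust(p)
        m = 4
        # independent step-up: q_i = min over j >= i of p_(j) * m / j
        expected = [min(p[j] * m / (j + 1) for j in range(i, m)) for i in range(m)]
        assert np.allclose(q, expected)

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bh_invariants(self, pvals):
        p = np.asarray(pvals)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment_bh({"T": {"a"}}, {"zzz"}, {"a", "b"})

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment_bh({"T": {"a"}}, set(), set())
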