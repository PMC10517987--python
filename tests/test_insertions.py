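"""Insertion post-processing: elbow threshold, merging, annotation, profiles."""

import numpy as np
import pytest
from scipy import stats

from captes.insertions import (
    EnrichmentResult,
    InsertionCall,
    annotate_context,
    apply_support_threshold,
    elbow_threshold,
    genebody_profile,
    merge_calls,
    oncogene_enrichment,
    relative_insertion_frequency,
)
from captes.models import GeneModel, GenomeInterval, TELocus, TranscriptModel
from captes.synth import simulate_support_mixture
from oracles import chi2_2x2


def call(pos, support=5, family="Alu", chrom="chr1"):
    return InsertionCall(chrom=chrom, position=pos, family=family, support=support)


def gene(gene_id, start, end, strand="+", chrom="chr1"):
    iv = GenomeInterval(chrom, start, end, strand)
    t = TranscriptModel(f"{gene_id}.1", gene_id, iv, [iv])
    return GeneModel(gene_id, iv, [t])


class TestElbowThreshold:
    def test_matches_chord_distance_bruteforce(self):
        # survival curve N(s) for s = 1..10
        n = [1000, 300, 120, 80, 70, 65, 62, 60, 59, 58]
        supports = []
        for s in range(1, 11):
            count = n[s - 1] - (n[s] if s < 10 else 0)
            supports.extend([s] * count)
        # brute-force chord distances
        x0, y0, x1, y1 = 1.0, n[0], 10.0, n[-1]
        dx, dy = x1 - x0, y1 - y0
        norm = (dx**2 + dy**2) ** 0.5
        dists = [
            abs(dy * (s - x0) - dx * (n[s - 1] - y0)) / norm for s in range(1, 11)
        ]
        expected = 1 + int(np.argmax(dists))
        assert elbow_threshold(supports) == expected

    def test_linear_curve_returns_one(self):
        supports = []
        for s in range(1, 6):
            supports.extend([s] * 10)  # N(s) decreases linearly
        assert elbow_threshold(supports) == 1

    def test_scaling_counts_preserves_argmax(self):
        rng = np.random.default_rng(31)
        supports = rng.geometric(0.5, size=300).tolist() + [15] * 20
        once = elbow_threshold(supports)
        scaled = elbow_threshold(supports * 10)
        assert once == scaled

    def test_degenerate_distinct_values(self):
        assert elbow_threshold([3, 3, 5]) == 1

    def test_planted_knee_recovered_in_95_percent_of_replicates(self):
        hits = 0
        for rep in range(200):
            supports, knee = simulate_support_mixture(seed=rep)
            if abs(elbow_threshold(supports) - knee) <= 1:
                hits += 1
        assert hits >= 190


class TestMergeCalls:
    def test_within_gap_merges_and_sums_support(self):
        out = merge_calls([call(1000, 5), call(1150, 3)])
        assert len(out) == 1
        assert out[0].support == 8
        assert len(out[0].merged_from) == 2

    def test_beyond_gap_stays_separate(self):
        out = merge_calls([call(1000), call(1300)])
        assert len(out) == 2

    def test_transitive_chaining(self):
        out = merge_calls([call(1000, 1), call(1180, 1), call(1360, 1)])
        assert len(out) == 1
        assert out[0].support == 3

    def test_families_do_not_merge(self):
        out = merge_calls([call(1000, 2, "Alu"), call(1050, 2, "L1")])
        assert len(out) == 2

    def test_merged_position_is_support_weighted_median(self):
        out = merge_calls([call(1000, 1), call(1100, 8), call(1190, 1)])
        assert out[0].position == 1100

    def test_idempotent(self):
        rng = np.random.default_rng(41)
        calls = [call(int(p)) for p in np.sort(rng.integers(0, 100_000, 200))]
        once = merge_calls(calls)
        twice = merge_calls(once)
        assert [(c.position, c.support) for c in once] == [
            (c.position, c.support) for c in twice
        ]

    def test_matches_bruteforce_single_linkage(self):
        rng = np.random.default_rng(43)
        positions = sorted(int(p) for p in rng.integers(0, 50_000, 150))
        calls = [call(p, 1) for p in positions]
        merged = merge_calls(calls)
        # brute-force cluster count: break where consecutive gap > 200
        n_clusters = 1 + sum(
            1 for a, b in zip(positions, positions[1:]) if b - a > 200
        )
        assert len(merged) == n_clusters
        assert sum(c.support for c in merged) == len(calls)


class TestThreshold:
    def test_family_defaults(self):
        calls = [call(1000, 6, "Alu"), call(5000, 5, "Alu"), call(9000, 5, "L1")]
        kept = apply_support_threshold(calls)
        assert [(c.family, c.support) for c in kept] == [("Alu", 6), ("L1", 5)]


class TestAnnotateContext:
    def test_genic_intergenic_and_boundary(self):
        genes = [gene("g1", 1000, 2000)]
        calls = [call(1500), call(2500), call(2000)]  # inside, outside, at half-open end
        annotate_context(calls, genes, {"g1"})
        assert [c.context for c in calls] == ["genic", "intergenic", "intergenic"]
        assert calls[0].gene_ids == ["g1"]
        assert calls[0].in_oncogene is True


class TestOncogeneEnrichment:
    def _setup(self, a, n1, b, n2):
        onc = gene("onc1", 0, 1_000_000)
        other = gene("bg1", 2_000_000, 9_000_000)
        calls = [call(500, 10) for _ in range(a)] + [
            call(3_000_000 + i * 1000, 10) for i in range(n1 - a)
        ]
        annotate_context(calls, [onc, other], {"onc1"})
        tes = [
            TELocus(GenomeInterval("chr1", 100 + i * 50, 140 + i * 50, "+"), "Alu", "AluY", 10.0)
            for i in range(b)
        ] + [
            TELocus(
                GenomeInterval("chr1", 2_500_000 + i * 1000, 2_500_040 + i * 1000, "+"),
                "Alu",
                "AluY",
                10.0,
            )
            for i in range(n2 - b)
        ]
        return calls, tes, [onc, other]

    def test_fold_arithmetic(self):
        calls, tes, genes = self._setup(20, 100, 50, 1000)
        (res,) = oncogene_enrichment({"Alu": calls}, tes, genes, {"onc1"})
        assert res.fold == pytest.approx((20 / 100) / (50 / 1000))

    def test_chi2_matches_independent_formula_and_scipy(self):
        calls, tes, genes = self._setup(20, 100, 50, 1000)
        (res,) = oncogene_enrichment({"Alu": calls}, tes, genes, {"onc1"})
        manual = chi2_2x2(20, 80, 50, 950)
        assert res.chi2_stat == pytest.approx(manual)
        chi2, p, _, _ = stats.chi2_contingency(
            [[20, 80], [50, 950]], correction=False
        )
        assert res.p_value == pytest.approx(p)

    def test_equal_proportions_give_fold_one_chi2_zero(self):
        calls, tes, genes = self._setup(10, 100, 100, 1000)
        (res,) = oncogene_enrichment({"Alu": calls}, tes, genes, {"onc1"})
        assert res.fold == pytest.approx(1.0)
        assert res.chi2_stat == pytest.approx(0.0, abs=1e-9)

    def test_significance_follows_adjusted_p(self):
        assert EnrichmentResult("Alu", 4.0, 25.0, 1e-6, 0.01).significant
        assert not EnrichmentResult("Alu", 4.0, 2.0, 0.2, 0.3).significant


class TestGenebodyProfile:
    def test_plus_strand_bins(self):
        g = gene("g1", 10_000, 20_000)  # body 10 kb
        prof = genebody_profile([call(10_050)], [g])
        assert prof.sum() == 1
        assert prof[10] == 1  # first body bin
        prof = genebody_profile([call(9_500)], [g])
        assert prof[5] == 1  # upstream bin 5 (bins 0-9 span -1000..TSS)
        prof = genebody_profile([call(20_400)], [g])
        assert prof[110 + 4] == 1  # downstream bin 4

    def test_minus_strand_mirrors_plus(self):
        gp = gene("gp", 10_000, 20_000, "+")
        gm = gene("gm", 10_000, 20_000, "-")
        # 500 nt upstream of the TSS in both orientations
        assert genebody_profile([call(9_500)], [gp])[5] == 1
        assert genebody_profile([call(20_499)], [gm])[5] == 1
        # 50 nt into the body
        assert genebody_profile([call(10_050)], [gp])[10] == 1
        assert genebody_profile([call(19_949)], [gm])[10] == 1

    def test_conservation_of_counted_calls(self):
        rng = np.random.default_rng(51)
        g = gene("g1", 50_000, 80_000)
        calls = [call(int(p)) for p in rng.integers(0, 150_000, 300)]
        prof = genebody_profile(calls, [g])
        in_window = sum(1 for c in calls if 49_000 <= c.position < 81_000)
        assert prof.sum() == in_window

    def test_outside_window_not_counted(self):
        g = gene("g1", 10_000, 20_000)
        assert genebody_profile([call(8_000)], [g]).sum() == 0


class TestRelativeFrequency:
    def test_per_gene_difference(self):
        genes = [gene("g1", 1000, 2000), gene("g2", 5000, 6000)]
        case = annotate_context([call(1500), call(1600), call(1700), call(5500)], genes)
        control = annotate_context([call(1500)], genes)
        out = relative_insertion_frequency(case, control)
        assert out == {"g1": 2, "g2": 1}

    def test_total_equals_difference_of_genic_totals(self):
        rng = np.random.default_rng(61)
        genes = [gene(f"g{i}", i * 10_000, i * 10_000 + 4000) for i in range(5)]
        case = annotate_context(
            [call(int(p)) for p in rng.integers(0, 60_000, 100)], genes
        )
        control = annotate_context(
            [call(int(p)) for p in rng.integers(0, 60_000, 80)], genes
        )
        out = relative_insertion_frequency(case, control)
        n_case = sum(1 for c in case if c.context == "genic")
        n_control = sum(1 for c in control if c.context == "genic")
        assert sum(out.values()) == n_case - n_control
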