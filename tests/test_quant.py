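"""Fractional counting, filtering, BH adjustment, and differential tests."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from captes.models import AlignmentRecord, CaptesError, GenomeInterval, ValidationError
from captes.quant import (
    bh_adjust,
    differential,
    filter_low_expression,
    fractional_counts,
    median_of_ratios_normalize,
    relative_noncanonical_count,
    type_contribution,
)
from oracles import bh_bruteforce


def aln(read_id, start, end, x=1, chrom="chr1"):
    return AlignmentRecord(
        read_id, GenomeInterval(chrom, start, end), num_alignments_for_read=x
    )


def feats(*spans):
    return [(f"F{i}", GenomeInterval("chr1", s, e)) for i, (s, e) in enumerate(spans)]


def nb_counts(mu, rng, disp=0.05):
    shape = 1.0 / disp
    lam = rng.gamma(shape, np.asarray(mu) / shape)
    return rng.poisson(lam)


class TestFractionalCounts:
    def test_unique_read_full_overlap_counts_one(self):
        col = fractional_counts([aln("r1", 100, 200)], feats((50, 250)))
        assert col["F0"] == 1.0

    def test_multimapper_split_by_alignments_and_features(self):
        # read with x=2: alignment A overlaps F0 and F1, alignment B only F0
        alignments = [
            aln("r1", 100, 200, x=2),  # overlaps F0 (100) and F1 (100)
            aln("r1", 1000, 1100, x=2),  # overlaps F0b region -> F2
        ]
        features = feats((100, 200), (150, 260), (950, 1150))
        col = fractional_counts(alignments, features)
        # A: y=2 -> F0 += 1/4, F1 += 1/4; B: y=1 -> F2 += 1/2
        assert col["F0"] == pytest.approx(0.25)
        assert col["F1"] == pytest.approx(0.25)
        assert col["F2"] == pytest.approx(0.5)
        assert col.sum() == pytest.approx(1.0)

    def test_overlap_below_min_contributes_nothing(self):
        col = fractional_counts([aln("r1", 100, 200)], feats((181, 400)))  # 19 nt
        assert col["F0"] == 0.0
        col = fractional_counts([aln("r1", 100, 200)], feats((180, 400)))  # 20 nt
        assert col["F0"] == 1.0

    def test_min_overlap_validated(self):
        with pytest.raises(ValidationError):
            fractional_counts([], feats((0, 10)), min_overlap=0)

    def test_inconsistent_multimap_count_rejected(self):
        with pytest.raises(ValidationError):
            fractional_counts(
                [aln("r1", 0, 50, x=1), aln("r1", 100, 150, x=2)], feats((0, 2000))
            )

    def test_conservation_over_random_configurations(self):
        """Reads whose alignments all touch >= 1 feature contribute exactly 1."""
        rng = np.random.default_rng(77)
        features = feats(*[(int(s), int(s) + 500) for s in rng.integers(0, 50_000, 40) ])
        alignments = []
        for ri in range(200):
            x = int(rng.integers(1, 4))
            for _ in range(x):
                start = int(rng.integers(0, 50_000))
                alignments.append(aln(f"r{ri}", start, start + 400, x=x))
        col = fractional_counts(alignments, features)
        # per-read contribution is 1 iff every alignment overlaps a feature
        trees = [(iv.start, iv.end) for _f, iv in features]

        def touches(a):
            return any(
                min(a.target.end, e) - max(a.target.start, s) >= 20 for s, e in trees
            )

        expected = 0.0
        by_read = {}
        for a in alignments:
            by_read.setdefault(a.read_id, []).append(a)
        for read_alns in by_read.values():
            hit = [touches(a) for a in read_alns]
            expected += sum(hit) / len(read_alns)
        assert col.sum() == pytest.approx(expected)
        assert col.sum() <= len(by_read) + 1e-9


class TestFilterLowExpression:
    def test_boundary_counts(self):
        m = pd.DataFrame(
            {"s1": [3, 2], "s2": [3, 3], "s3": [3, 3], "s4": [0, 0]},
            index=["keep", "drop"],
        )
        out = filter_low_expression(m)
        assert list(out.index) == ["keep"]

    def test_matches_bruteforce_on_random_matrix(self):
        rng = np.random.default_rng(88)
        m = pd.DataFrame(
            rng.poisson(2.0, size=(500, 6)),
            index=[f"f{i}" for i in range(500)],
        )
        out = filter_low_expression(m)
        expected = [
            i for i in m.index if int((m.loc[i] >= 3).sum()) >= 3
        ]
        assert list(out.index) == expected

    def test_min_samples_validated(self):
        m = pd.DataFrame({"s1": [1], "s2": [1]})
        with pytest.raises(ValidationError):
            filter_low_expression(m, min_samples=3)


class TestBHAdjust:
    def test_hand_computed_example(self):
        # p(k)*m/k = (.04, .04, .04, .04) after step-up
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_adjusted_dominates_raw_and_is_rank_monotone(self):
        rng = np.random.default_rng(99)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels_and_bruteforce_battery(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, ref, atol=1e-12)
        p = rng.uniform(size=25)
        assert np.allclose(bh_adjust(p), bh_bruteforce(list(p)))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestDifferential:
    def _null_matrix(self, seed, n=100, k=3):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(4, 1, size=n)
        m = np.column_stack([nb_counts(mu, rng) for _ in range(2 * k)])
        return pd.DataFrame(m, index=[f"f{i}" for i in range(n)])

    def test_identical_groups_are_null(self):
        m = pd.DataFrame(
            {"a": [10, 20], "b": [11, 19], "c": [10, 20], "d": [11, 19]},
            index=["f1", "f2"],
        )
        res = differential(m, {"a": "A", "b": "A", "c": "B", "d": "B"})
        for r in res:
            assert abs(r.log2_fc) < 0.2
            assert not r.is_significant

    def test_label_swap_negates_fold_changes(self):
        m = self._null_matrix(5)
        g1 = ["A"] * 3 + ["B"] * 3
        g2 = ["B"] * 3 + ["A"] * 3
        r1 = differential(m, g1)
        r2 = differential(m, g2)
        for a, b in zip(r1, r2):
            assert a.log2_fc == pytest.approx(-b.log2_fc)

    def test_null_type_one_error_controlled(self):
        """Raw p < 0.05 in at most 7.5% of 500 null features (seed 3)."""
        m = self._null_matrix(3, n=500)
        res = differential(m, ["A"] * 3 + ["B"] * 3)
        frac = np.mean([r.p_value < 0.05 for r in res])
        assert frac <= 0.075

    def test_power_on_planted_eightfold_changes(self):
        """>= 45 of 50 features at true log2 fold change 3 are called (seed 11)."""
        rng = np.random.default_rng(11)
        n_bg, n_de = 450, 50
        mu_bg = rng.lognormal(4, 1, size=n_bg)
        mu_de = rng.lognormal(5, 0.5, size=n_de)
        cols = {}
        for j in range(3):
            cols[f"ctl{j}"] = np.concatenate([nb_counts(mu_bg, rng), nb_counts(mu_de, rng)])
        for j in range(3):
            cols[f"case{j}"] = np.concatenate(
                [nb_counts(mu_bg, rng), nb_counts(mu_de * 8, rng)]
            )
        m = pd.DataFrame(
            cols, index=[f"bg{i}" for i in range(n_bg)] + [f"de{i}" for i in range(n_de)]
        )
        res = differential(m, {c: ("A" if c.startswith("ctl") else "B") for c in m})
        de_called = sum(r.is_significant for r in res if r.feature_id.startswith("de"))
        assert de_called >= 45

    def test_size_factors_absorb_depth_differences(self):
        rng = np.random.default_rng(6)
        base = rng.lognormal(4, 1, size=200)
        m = pd.DataFrame(
            {
                "s1": nb_counts(base, rng),
                "s2": nb_counts(base * 2, rng),  # doubled depth
            },
            index=[f"f{i}" for i in range(200)],
        )
        _norm, factors = median_of_ratios_normalize(m)
        assert factors["s2"] / factors["s1"] == pytest.approx(2.0, rel=0.1)


class TestContribution:
    @pytest.mark.parametrize(
        "dn,dc,expected",
        [
            (30.0, 10.0, (0.75, 0.25)),
            (10.0, 0.0, (1.0, 0.0)),
            (30.0, -10.0, (1.5, -0.5)),
        ],
    )
    def test_ratio_of_difference_values(self, dn, dc, expected):
        out = type_contribution(dn, dc)
        assert out == pytest.approx(expected)
        assert sum(out) == pytest.approx(1.0)

    def test_zero_total_is_undefined(self):
        with pytest.raises(CaptesError):
            type_contribution(5.0, -5.0)


class TestRelativeCounts:
    def test_case_minus_control_with_missing_genes(self):
        out = relative_noncanonical_count({"g1": 5, "g2": 1}, {"g1": 2, "g3": 4})
        assert out == {"g1": 3, "g2": 1, "g3": -4}

    def test_linearity(self):
        rng = np.random.default_rng(14)
        case = {f"g{i}": int(rng.integers(0, 10)) for i in range(30)}
        control = {f"g{i}": int(rng.integers(0, 10)) for i in range(5, 35)}
        out = relative_noncanonical_count(case, control)
        assert sum(out.values()) == sum(case.values()) - sum(control.values())
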