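"""Expression quantification with fractional multimapper counting.

A read with x genomic alignments, each of which overlaps y features by
at least ``min_overlap`` aligned bases, contributes 1/(x*y) to every
such feature: the read's unit of weight is split evenly first across
its alignments and then across the features each alignment touches.
Counting is unstranded.  This mirrors featureCounts run with
``-f -O --minOverlap 20 -M --fraction -s 0 -L``.

Differential expression uses median-of-ratios normalisation followed by
a two-sided moderated t-test on log2(normalised count + 0.5) — the
per-feature variance is shrunk toward the across-feature mean, which
stabilises small-replicate comparisons — with Benjamini-Hochberg
adjustment; a feature is called significant when |log2 fold change| > 1
and adjusted p < 0.05.  The test engine is pluggable (a plain Welch
test is provided); this is a deliberately simple, fully documented
stand-in for a negative-binomial GLM, adequate at the moderate
replicate numbers and strong effects it is used for here.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import AlignmentRecord, CaptesError, GenomeInterval, ValidationError

__all__ = [
    "DiffResult",
    "fractional_counts",
    "filter_low_expression",
    "bh_adjust",
    "median_of_ratios_normalize",
    "differential",
    "type_contribution",
    "relative_noncanonical_count",
    "spearman",
    "pearson",
]


@dataclass(frozen=True)
class DiffResult:
    feature_id: str
    log2_fc: float
    p_value: float
    p_adjusted: float
    is_significant: bool


def fractional_counts(
    alignments: Sequence[AlignmentRecord],
    features: Sequence[tuple[str, GenomeInterval]],
    min_overlap: int = 20,
) -> pd.Series:
    """One column of fractional counts over ``features``.

    ``features`` are (id, interval) pairs; overlap is measured in
    aligned bases (summed over an alignment's blocks) and must reach
    ``min_overlap``.  Alignments overlapping no feature contribute
    nothing.  The multimapping count x is taken from each record and
    must be consistent within a read.
    """
    if min_overlap < 1:
        raise ValidationError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, (fid, iv) in enumerate(features):
        trees[iv.chrom].addi(iv.start, iv.end, idx)
    counts = np.zeros(len(features), dtype=float)

    x_of_read: dict[str, int] = {}
    for a in alignments:
        x = x_of_read.setdefault(a.read_id, a.num_alignments_for_read)
        if x != a.num_alignments_for_read:
            raise ValidationError(
                f"inconsistent num_alignments_for_read for read {a.read_id}"
            )

    for a in alignments:
        overlap_by_feature: dict[int, int] = defaultdict(int)
        for block in a.aligned_blocks:
            for hit in trees[block.chrom].overlap(block.start, block.end):
                ov = min(block.end, hit.end) - max(block.start, hit.begin)
                if ov > 0:
                    overlap_by_feature[hit.data] += ov
        touched = [i for i, ov in overlap_by_feature.items() if ov >= min_overlap]
        y = len(touched)
        if y == 0:
            continue
        w = 1.0 / (a.num_alignments_for_read * y)
        for i in touched:
            counts[i] += w
    return pd.Series(counts, index=[fid for fid, _iv in features], name="count")


def filter_low_expression(
    matrix: pd.DataFrame, min_count: float = 3.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep features counted at least ``min_count`` in ``min_samples`` samples."""
    if min_samples > matrix.shape[1]:
        raise ValidationError(
            f"min_samples={min_samples} exceeds sample count {matrix.shape[1]}"
        )
    keep = (matrix >= min_count).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def median_of_ratios_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalisation.

    Size factors are the per-sample median of count ratios to the
    geometric-mean reference feature, computed over features with
    nonzero counts in every sample.  Returns (normalised matrix, size
    factors).  Falls back to library-size factors when no feature is
    everywhere-nonzero.
    """
    values = matrix.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_values = np.log(values)
    finite = np.all(np.isfinite(log_values), axis=1)
    if finite.sum() == 0:
        totals = values.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        log_ref = log_values[finite].mean(axis=1)
        factors = np.exp(np.median(log_values[finite] - log_ref[:, None], axis=0))
    factors = pd.Series(factors, index=matrix.columns, name="size_factor")
    return matrix / factors, factors


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def _moderated_t_pvalues(
    ref: np.ndarray, alt: np.ndarray, prior_df: float = 4.0
) -> np.ndarray:
    """Per-feature moderated t-test on log-scale matrices.

    Pooled within-group variances are shrunk toward their across-feature
    mean with ``prior_df`` pseudo-degrees of freedom, which stabilises
    the denominator at small replicate numbers; the t statistic gains
    the prior degrees of freedom.  ``ref``/``alt`` are features x
    samples.
    """
    n1, n2 = ref.shape[1], alt.shape[1]
    df_resid = n1 + n2 - 2
    s2 = (
        np.var(ref, axis=1, ddof=1) * (n1 - 1) + np.var(alt, axis=1, ddof=1) * (n2 - 1)
    ) / df_resid
    s2_prior = float(np.mean(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    diff = alt.mean(axis=1) - ref.mean(axis=1)
    denom = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    p = np.ones(ref.shape[0])
    ok = denom > 0
    t = np.zeros_like(p)
    t[ok] = diff[ok] / denom[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_resid + prior_df)
    p[~ok & (diff != 0)] = 0.0
    return p


def differential(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    fc_cut: float = 1.0,
    alpha: float = 0.05,
    test: Callable[[np.ndarray, np.ndarray], float] | None = None,
    pseudocount: float = 0.5,
) -> list[DiffResult]:
    """Two-group differential test on a pre-filtered count matrix.

    ``groups`` assigns each sample (column) to one of exactly two
    labels; the first label in sorted order is the reference, so
    positive log2 fold changes mean higher expression in the second
    group.  ``test`` may replace the default moderated t-test with any
    per-feature two-sample test on the log2-normalised counts (e.g.
    ``_welch_p``).
    """
    if not isinstance(groups, Mapping):
        groups = dict(zip(matrix.columns, groups))
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    ref_cols = [c for c in matrix.columns if groups[c] == labels[0]]
    alt_cols = [c for c in matrix.columns if groups[c] == labels[1]]
    if len(ref_cols) < 2 or len(alt_cols) < 2:
        raise ValidationError("need >= 2 samples per group")
    normalized, _factors = median_of_ratios_normalize(matrix)
    log_norm = np.log2(normalized + pseudocount)
    ref_mat = log_norm[ref_cols].to_numpy()
    alt_mat = log_norm[alt_cols].to_numpy()
    fcs = (
        np.log2(normalized[alt_cols].mean(axis=1) + pseudocount)
        - np.log2(normalized[ref_cols].mean(axis=1) + pseudocount)
    ).to_numpy()
    if test is None:
        pvals = _moderated_t_pvalues(ref_mat, alt_mat).tolist()
    else:
        pvals = [test(ref_mat[i], alt_mat[i]) for i in range(ref_mat.shape[0])]
    adjusted = bh_adjust(pvals)
    results = []
    for fid, fc, p, padj in zip(matrix.index, fcs, pvals, adjusted):
        results.append(
            DiffResult(
                feature_id=str(fid),
                log2_fc=fc,
                p_value=p,
                p_adjusted=float(padj),
                is_significant=bool(abs(fc) > fc_cut and padj < alpha),
            )
        )
    return results


def type_contribution(
    delta_noncanonical: float, delta_canonical: float
) -> tuple[float, float]:
    """Share of a gene's expression change carried by each transcript type.

    Returns (noncanonical share, canonical share); each is the type's
    expression difference divided by the summed differences, so the two
    always sum to one.  When the deltas have opposite signs a share can
    fall outside [0, 1]; it is reported as-is.
    """
    total = delta_noncanonical + delta_canonical
    if total == 0:
        raise CaptesError("summed expression change is zero; contribution undefined")
    return delta_noncanonical / total, delta_canonical / total


def relative_noncanonical_count(
    case_counts: Mapping[str, int], control_counts: Mapping[str, int]
) -> dict[str, int]:
    """Case-minus-control noncanonical transcript count per gene."""
    genes = set(case_counts) | set(control_counts)
    return {g: case_counts.get(g, 0) - control_counts.get(g, 0) for g in sorted(genes)}


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    return float(stats.spearmanr(x, y).statistic)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    return float(stats.pearsonr(x, y).statistic)
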