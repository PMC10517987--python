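"""Post-processing of candidate TE insertion calls.

Raw calls (chrom, position, family, supporting reads) from an upstream
insertion caller are

1. merged when within 200 bp of each other (single-linkage per
   chromosome and family; the merged position is the support-weighted
   median of the members, the merged support their sum);
2. thresholded on supporting reads, either at a fixed family default
   (Alu 6, L1 5) or at a data-driven elbow of the
   calls-retained-vs-threshold curve (the point of maximum
   perpendicular distance to the chord, a Kneedle-style rule);
3. annotated as genic/intergenic and flagged when inside an oncogene.

Downstream summaries: oncogene enrichment against the expressed-TE
background (chi-squared on the 2x2 table, BH-adjusted across families),
a strand-aware gene-body insertion profile (10 upstream + 100 body +
10 downstream windows), and per-gene case-minus-control insertion
counts.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .models import GeneModel, TELocus, ValidationError
from .quant import bh_adjust

__all__ = [
    "InsertionCall",
    "EnrichmentResult",
    "elbow_threshold",
    "merge_calls",
    "apply_support_threshold",
    "annotate_context",
    "oncogene_enrichment",
    "genebody_profile",
    "relative_insertion_frequency",
    "DEFAULT_SUPPORT_THRESHOLDS",
    "DEFAULT_MERGE_GAP",
]

DEFAULT_MERGE_GAP = 200
# Family defaults for the minimum supporting-read count, used when the
# elbow is not estimated from the data.
DEFAULT_SUPPORT_THRESHOLDS = {"Alu": 6, "L1": 5}


@dataclass
class InsertionCall:
    chrom: str
    position: int
    family: str
    support: int
    merged_from: list["InsertionCall"] = field(default_factory=list)
    context: str | None = None  # 'genic' or 'intergenic'
    gene_ids: list[str] = field(default_factory=list)
    in_oncogene: bool = False

    def __post_init__(self):
        if self.support < 1:
            raise ValidationError("insertion support must be >= 1")


def elbow_threshold(supports: Sequence[int]) -> int:
    """Support cutoff at the knee of the retained-calls curve.

    Builds N(s) = number of calls with support >= s for s = 1..max and
    returns the s with maximum perpendicular distance to the straight
    line from (1, N(1)) to (s_max, N(s_max)); ties resolve to the
    smaller s.  With fewer than three distinct support values there is
    no knee and the threshold falls back to 1.
    """
    if not supports:
        raise ValidationError("no support values")
    if len(set(supports)) < 3:
        return 1
    s_max = max(supports)
    s_grid = np.arange(1, s_max + 1)
    counts = np.asarray(supports)
    n = np.array([(counts >= s).sum() for s in s_grid], dtype=float)
    # perpendicular distance of each (s, N(s)) to the chord
    x0, y0 = float(s_grid[0]), n[0]
    x1, y1 = float(s_grid[-1]), n[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (s_grid - x0) - dx * (n - y0)) / norm
    return int(s_grid[int(np.argmax(dist))])


def _weighted_median(positions: Sequence[int], weights: Sequence[int]) -> int:
    order = np.argsort(positions, kind="mergesort")
    pos = np.asarray(positions)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = w.sum() / 2.0
    return int(pos[int(np.searchsorted(cum, half))])


def merge_calls(
    calls: Sequence[InsertionCall], max_gap: int = DEFAULT_MERGE_GAP
) -> list[InsertionCall]:
    """Single-linkage merge of calls within ``max_gap`` bp, per chrom+family.

    Consecutive calls at distance <= ``max_gap`` chain into one
    cluster, so a run of closely spaced calls can merge transitively.
    Merged support is the sum of the members' support; the merged
    position is their support-weighted median.
    """
    by_group: dict[tuple[str, str], list[InsertionCall]] = defaultdict(list)
    for c in calls:
        by_group[(c.chrom, c.family)].append(c)
    merged = []
    for (chrom, family), group in by_group.items():
        group = sorted(group, key=lambda c: c.position)
        cluster: list[InsertionCall] = []
        for c in group + [None]:  # type: ignore[list-item]
            if cluster and (c is None or c.position - cluster[-1].position > max_gap):
                if len(cluster) == 1:
                    merged.append(cluster[0])
                else:
                    merged.append(
                        InsertionCall(
                            chrom=chrom,
                            position=_weighted_median(
                                [m.position for m in cluster],
                                [m.support for m in cluster],
                            ),
                            family=family,
                            support=sum(m.support for m in cluster),
                            merged_from=list(cluster),
                        )
                    )
                cluster = []
            if c is not None:
                cluster.append(c)
    merged.sort(key=lambda c: (c.chrom, c.position, c.family))
    return merged


def apply_support_threshold(
    calls: Sequence[InsertionCall],
    thresholds: Mapping[str, int] | None = None,
    estimate: bool = False,
) -> list[InsertionCall]:
    """Drop calls below the per-family support threshold.

    When ``estimate`` is true the threshold of each family is computed
    by :func:`elbow_threshold` from that family's supports; otherwise
    ``thresholds`` (default Alu 6, L1 5) is used.
    """
    if thresholds is None:
        thresholds = DEFAULT_SUPPORT_THRESHOLDS
    if estimate:
        by_family: dict[str, list[int]] = defaultdict(list)
        for c in calls:
            by_family[c.family].append(c.support)
        thresholds = {fam: elbow_threshold(sup) for fam, sup in by_family.items()}
    return [c for c in calls if c.support >= thresholds.get(c.family, 1)]


def annotate_context(
    calls: Sequence[InsertionCall],
    genes: Sequence[GeneModel],
    oncogenes: set[str] | None = None,
) -> list[InsertionCall]:
    """Mark each call genic/intergenic and record overlapped gene ids.

    A call is genic when its position falls inside any gene's union
    span (half-open, so a position at the very end of a span is
    intergenic).  All overlapped genes are recorded; the oncogene flag
    is set when any of them is in ``oncogenes``.
    """
    oncogenes = oncogenes or set()
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_chrom[g.interval.chrom].append(g)
    for c in calls:
        hits = [
            g.gene_id
            for g in by_chrom[c.chrom]
            if g.interval.start <= c.position < g.interval.end
        ]
        c.gene_ids = sorted(hits)
        c.context = "genic" if hits else "intergenic"
        c.in_oncogene = any(g in oncogenes for g in hits)
    return list(calls)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    fold: float
    chi2_stat: float
    p_value: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


def oncogene_enrichment(
    calls_by_family: Mapping[str, Sequence[InsertionCall]],
    expressed_tes: Sequence[TELocus],
    oncogene_intervals: Sequence[GeneModel],
    oncogenes: set[str],
) -> list[EnrichmentResult]:
    """Oncogene enrichment of insertions vs the expressed-TE background.

    For each family, fold = (insertions in oncogenes / all insertions)
    over (expressed TEs in oncogenes / all expressed TEs); the p-value
    comes from a chi-squared test (no continuity correction) on the
    corresponding 2x2 table, BH-adjusted across the families tested.
    """
    onc_genes = [g for g in oncogene_intervals if g.gene_id in oncogenes]

    def in_oncogene_te(te: TELocus) -> bool:
        iv = te.interval
        return any(
            g.interval.chrom == iv.chrom
            and g.interval.start < iv.end
            and iv.start < g.interval.end
            for g in onc_genes
        )

    results = []
    pvals = []
    for family in sorted(calls_by_family):
        calls = calls_by_family[family]
        if not calls:
            raise ValidationError(f"no insertion calls for family {family}")
        fam_tes = [t for t in expressed_tes if t.family == family] or list(expressed_tes)
        a = sum(1 for c in calls if c.in_oncogene)
        n1 = len(calls)
        b = sum(1 for t in fam_tes if in_oncogene_te(t))
        n2 = len(fam_tes)
        fold = (a / n1) / (b / n2) if b > 0 else float("inf")
        table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
        results.append((family, fold, float(chi2)))
        pvals.append(float(p))
    adjusted = bh_adjust(pvals)
    return [
        EnrichmentResult(category=fam, fold=fold, chi2_stat=chi2, p_value=p, p_adjusted=float(padj))
        for (fam, fold, chi2), p, padj in zip(results, pvals, adjusted)
    ]


def genebody_profile(
    calls: Sequence[InsertionCall],
    genes: Sequence[GeneModel],
    flank: int = 1000,
    flank_bins: int = 10,
    body_bins: int = 100,
) -> np.ndarray:
    """Strand-aware metagene profile of insertion positions.

    Returns a vector of ``flank_bins + body_bins + flank_bins`` counts
    ordered 5' to 3': upstream flank (bin 0 farthest from the TSS),
    gene body (bin = floor(body_bins * relative position)), downstream
    flank.  Calls outside the flank+body window of a gene are not
    counted; a call inside several genes contributes to each.
    """
    total_bins = 2 * flank_bins + body_bins
    profile = np.zeros(total_bins, dtype=int)
    bin_size = flank / flank_bins
    for g in genes:
        iv = g.interval
        strand = iv.strand
        if strand not in ("+", "-"):
            raise ValidationError(f"gene {g.gene_id} is unstranded")
        for c in calls:
            if c.chrom != iv.chrom:
                continue
            pos = c.position
            if strand == "+":
                rel = pos - iv.start  # < 0 means upstream
                body_len = len(iv)
            else:
                rel = (iv.end - 1) - pos
                body_len = len(iv)
            if -flank <= rel < 0:
                b = int((rel + flank) // bin_size)
                profile[min(b, flank_bins - 1)] += 1
            elif 0 <= rel < body_len:
                b = int(body_bins * rel / body_len)
                profile[flank_bins + min(b, body_bins - 1)] += 1
            elif body_len <= rel < body_len + flank:
                b = int((rel - body_len) // bin_size)
                profile[flank_bins + body_bins + min(b, flank_bins - 1)] += 1
    return profile


def relative_insertion_frequency(
    case_calls: Iterable[InsertionCall], control_calls: Iterable[InsertionCall]
) -> dict[str, int]:
    """Per-gene case-minus-control insertion counts (annotated calls)."""
    case = Counter(g for c in case_calls for g in c.gene_ids)
    control = Counter(g for c in control_calls for g in c.gene_ids)
    genes = set(case) | set(control)
    return {g: case.get(g, 0) - control.get(g, 0) for g in sorted(genes)}
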