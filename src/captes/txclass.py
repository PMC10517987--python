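"""Classification of assembled transcripts against a reference annotation.

Each assembled transcript receives

* a class code — a simplified transcript-comparison code: full match,
  intron retention, novel junction, intronic, intergenic, or other
  genic overlap;
* a genomic-context category — genic, intronic, intergenic, or
  spanning (straddling a gene boundary);
* a transcription-pattern set — intron retention, noncanonical
  splicing, alternative TSS and/or alternative TES (the latter two
  require an intronic/intergenic transcript starting/ending inside a
  TE);
* its TE overlaps with a role per TE: ``tss``/``tes`` when the TE
  contains the strand-aware first/last transcribed base, ``internal``
  otherwise.

TE-transcript overlap uses the transcript's full genomic span (one or
more base pairs suffice) and ignores the TE's strand; an exon-only mode
is available via ``exonic_only=True``.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .models import GeneModel, GenomeInterval, TELocus, TranscriptModel, ValidationError

__all__ = [
    "ClassCode",
    "ContextCategory",
    "PatternCategory",
    "ClassifiedTranscript",
    "AnnotationIndex",
    "assign_class_code",
    "assign_context",
    "te_overlap_roles",
    "assign_patterns",
    "classify_transcripts",
    "hosting_genes",
    "te_key",
    "DEFAULT_END_TOLERANCE",
]

DEFAULT_END_TOLERANCE = 100  # nt slack on transcript ends for a full match


class ClassCode(str, enum.Enum):
    FULL_MATCH = "full_match"
    INTRON_RETENTION = "intron_retention"
    NOVEL_JUNCTION = "novel_junction"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    GENIC_OTHER = "genic_other"


class ContextCategory(str, enum.Enum):
    GENIC = "genic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    SPANNING = "spanning"


class PatternCategory(str, enum.Enum):
    INTRON_RETENTION = "intron_retention"
    NONCANONICAL_SPLICING = "noncanonical_splicing"
    ALT_TSS = "alt_tss"
    ALT_TES = "alt_tes"
    NONE = "none"


def te_key(locus: TELocus) -> tuple[str, int, int, str]:
    iv = locus.interval
    return (iv.chrom, iv.start, iv.end, locus.subfamily)


@dataclass
class ClassifiedTranscript:
    transcript: TranscriptModel
    code: ClassCode
    context: ContextCategory
    patterns: set[PatternCategory] = field(default_factory=set)
    te_overlaps: list[tuple[TELocus, str]] = field(default_factory=list)
    hosting_gene: str | None = None

    @property
    def is_te_containing(self) -> bool:
        return bool(self.te_overlaps)

    @property
    def is_canonical(self) -> bool:
        return self.code is ClassCode.FULL_MATCH


class AnnotationIndex:
    """Chrom-keyed interval indexes over a reference annotation."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = genes
        self.gene_spans: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.introns: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.transcripts: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.junctions: dict[tuple[str, str], set[tuple[int, int]]] = defaultdict(set)
        for g in genes:
            iv = g.interval
            self.gene_spans[iv.chrom].addi(iv.start, iv.end, g)
            for t in g.transcripts:
                self.transcripts[iv.chrom].addi(t.interval.start, t.interval.end, t)
                for j in t.junctions:
                    self.junctions[(iv.chrom, t.strand)].add(j)
            for intr in g.introns:
                self.introns[iv.chrom].addi(intr.start, intr.end, g)

    def overlapping_genes(self, iv: GenomeInterval) -> list[GeneModel]:
        return sorted(
            {h.data.gene_id: h.data for h in self.gene_spans[iv.chrom].overlap(iv.start, iv.end)}.values(),
            key=lambda g: (g.interval.start, g.gene_id),
        )

    def overlapping_transcripts(self, iv: GenomeInterval) -> list[TranscriptModel]:
        return sorted(
            (h.data for h in self.transcripts[iv.chrom].overlap(iv.start, iv.end)),
            key=lambda t: (t.interval.start, t.transcript_id),
        )

    def enclosing_introns(self, iv: GenomeInterval) -> list[GenomeInterval]:
        out = []
        for h in self.introns[iv.chrom].overlap(iv.start, iv.end):
            if h.begin <= iv.start and iv.end <= h.end:
                out.append(GenomeInterval(iv.chrom, h.begin, h.end))
        return out


def assign_class_code(
    t: TranscriptModel,
    index: AnnotationIndex,
    end_tolerance: int = DEFAULT_END_TOLERANCE,
) -> ClassCode:
    """Assign the (single) class code of a transcript vs the reference.

    Precedence: full match > intron retention > novel junction >
    intronic > intergenic > other genic overlap.  A full match requires
    an identical splice-junction chain on the same strand with both
    ends within ``end_tolerance`` nt (nanopore ends are ragged).
    """
    if not t.exons:
        raise ValidationError(f"transcript {t.transcript_id} has no exons")
    iv = t.interval
    ref_txs = index.overlapping_transcripts(iv)
    same_strand = [r for r in ref_txs if r.strand == t.strand]

    for r in same_strand:
        if (
            r.junctions == t.junctions
            and abs(r.interval.start - iv.start) <= end_tolerance
            and abs(r.interval.end - iv.end) <= end_tolerance
        ):
            return ClassCode.FULL_MATCH

    for r in same_strand:
        for intron in r.introns:
            for exon in t.exons:
                if exon.start <= intron.start and intron.end <= exon.end:
                    return ClassCode.INTRON_RETENTION

    genes = index.overlapping_genes(iv)
    same_strand_gene = any(g.interval.strand == t.strand for g in genes)
    if same_strand_gene:
        known = index.junctions[(iv.chrom, t.strand)]
        if any(j not in known for j in t.junctions):
            return ClassCode.NOVEL_JUNCTION

    if index.enclosing_introns(iv):
        return ClassCode.INTRONIC
    if not genes:
        return ClassCode.INTERGENIC
    return ClassCode.GENIC_OTHER


def assign_context(t: TranscriptModel, index: AnnotationIndex) -> ContextCategory:
    """Genomic-context category from the transcript's full span.

    intergenic: no gene-span overlap; intronic: fully inside one
    reference intron; spanning: overlaps both genic and intergenic
    space; genic: inside gene regions but not fully within an intron.
    """
    iv = t.interval
    genes = index.overlapping_genes(iv)
    if not genes:
        return ContextCategory.INTERGENIC
    if index.enclosing_introns(iv):
        return ContextCategory.INTRONIC
    covered = _union_cover(genes, iv)
    if not covered:
        return ContextCategory.SPANNING
    return ContextCategory.GENIC


def _union_cover(genes: list[GeneModel], iv: GenomeInterval) -> bool:
    """True if the union of gene spans covers ``iv`` entirely."""
    spans = sorted(
        (g.interval.start, g.interval.end) for g in genes if g.interval.chrom == iv.chrom
    )
    pos = iv.start
    for start, end in spans:
        if start > pos:
            return False
        pos = max(pos, end)
        if pos >= iv.end:
            return True
    return pos >= iv.end


def te_overlap_roles(
    t: TranscriptModel,
    te_loci: list[TELocus],
    exonic_only: bool = False,
) -> list[tuple[TELocus, str]]:
    """TE loci overlapping the transcript, each with its positional role.

    A TE containing the first transcribed base gets role ``tss``, one
    containing the last gets ``tes`` (both when it contains both ends),
    anything else overlapping by >= 1 bp is ``internal``.  TE strand is
    ignored.
    """
    iv = t.interval
    out: list[tuple[TELocus, str]] = []
    for locus in te_loci:
        te_iv = locus.interval
        if te_iv.chrom != iv.chrom:
            continue
        if exonic_only:
            ov = sum(e.overlap_length(te_iv) for e in t.exons)
        else:
            ov = iv.overlap_length(te_iv)
        if ov < 1:
            continue
        roles = []
        if te_iv.start <= t.tss < te_iv.end:
            roles.append("tss")
        if te_iv.start <= t.tes < te_iv.end:
            roles.append("tes")
        if not roles:
            roles = ["internal"]
        out.extend((locus, role) for role in roles)
    return out


def assign_patterns(
    code: ClassCode, roles: list[tuple[TELocus, str]]
) -> set[PatternCategory]:
    """Collapse the class code + TE roles into transcription patterns.

    Alternative TSS/TES require the transcript to be fully intronic or
    intergenic *and* to start/end inside a TE; they may co-occur.
    """
    patterns: set[PatternCategory] = set()
    if code is ClassCode.INTRON_RETENTION:
        patterns.add(PatternCategory.INTRON_RETENTION)
    elif code is ClassCode.NOVEL_JUNCTION:
        patterns.add(PatternCategory.NONCANONICAL_SPLICING)
    elif code in (ClassCode.INTRONIC, ClassCode.INTERGENIC):
        role_set = {role for _te, role in roles}
        if "tss" in role_set:
            patterns.add(PatternCategory.ALT_TSS)
        if "tes" in role_set:
            patterns.add(PatternCategory.ALT_TES)
    if not patterns:
        patterns.add(PatternCategory.NONE)
    return patterns


def classify_transcripts(
    transcripts: list[TranscriptModel],
    genes: list[GeneModel],
    te_loci: list[TELocus],
    end_tolerance: int = DEFAULT_END_TOLERANCE,
    exonic_only: bool = False,
) -> list[ClassifiedTranscript]:
    """Run the full classification over an assembled transcript set."""
    index = AnnotationIndex(genes)
    out = []
    for t in transcripts:
        code = assign_class_code(t, index, end_tolerance)
        context = assign_context(t, index)
        roles = te_overlap_roles(t, te_loci, exonic_only=exonic_only)
        patterns = assign_patterns(code, roles)
        overlapping = index.overlapping_genes(t.interval)
        hosting = None
        if overlapping:
            hosting = max(
                overlapping, key=lambda g: (g.interval.overlap_length(t.interval), g.gene_id)
            ).gene_id
        out.append(
            ClassifiedTranscript(
                transcript=t,
                code=code,
                context=context,
                patterns=patterns,
                te_overlaps=roles,
                hosting_gene=hosting,
            )
        )
    return out


def hosting_genes(
    classified: list[ClassifiedTranscript], genes: list[GeneModel]
) -> dict[tuple[str, int, int, str], set[str]]:
    """Map each overlapped TE locus to its TE-hosting genes.

    A gene hosts a TE when any of its annotated transcripts, or any
    TE-containing assembled transcript attributed to it, overlaps the
    TE by at least one base pair.
    """
    result: dict[tuple[str, int, int, str], set[str]] = defaultdict(set)
    for ct in classified:
        for locus, _role in ct.te_overlaps:
            key = te_key(locus)
            result.setdefault(key, set())
            if ct.hosting_gene is not None:
                result[key].add(ct.hosting_gene)
    for g in genes:
        for t in g.transcripts:
            for key in list(result):
                chrom, start, end, _sub = key
                if (
                    t.interval.chrom == chrom
                    and t.interval.start < end
                    and start < t.interval.end
                ):
                    result[key].add(g.gene_id)
    return dict(result)
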