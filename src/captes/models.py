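"""Core domain types shared by every pipeline stage.

All genomic coordinates are 0-based, half-open (``[start, end)``), the
BED convention.  GTF input/output is converted at the parsing boundary
(see :mod:`captes.io`), so no other module ever handles 1-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CaptesError",
    "ValidationError",
    "ParseError",
    "GenomeInterval",
    "TEConsensus",
    "TELocus",
    "TranscriptModel",
    "GeneModel",
    "ReadRecord",
    "AlignmentRecord",
    "VALID_STRANDS",
    "DNA_ALPHABET",
]

VALID_STRANDS = frozenset({"+", "-", "."})
DNA_ALPHABET = frozenset("ACGTN")


class CaptesError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(CaptesError):
    """A domain object violated one of its invariants."""


class ParseError(CaptesError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class TEConsensus:
    """A repeat subfamily consensus sequence (e.g. AluY, L1Hs)."""

    name: str
    family: str  # "Alu", "L1", or other
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"empty consensus sequence for {self.name}")
        seq = self.sequence.upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"consensus {self.name} contains invalid symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TELocus:
    """A genomic copy of a repeat, annotated with divergence and age.

    ``milli_div`` is mismatches per kilobase relative to the subfamily
    consensus (the RepeatMasker "milliDiv" column is percent divergence
    times ten).  ``age_myr`` and ``is_young`` are filled in by
    :mod:`captes.teannot`.
    """

    interval: GenomeInterval
    family: str
    subfamily: str
    milli_div: float
    age_myr: float | None = None
    is_young: bool | None = None

    def __post_init__(self):
        if not (0.0 <= self.milli_div <= 1000.0):
            raise ValidationError(
                f"milli_div {self.milli_div} outside [0, 1000] for "
                f"{self.subfamily} at {self.interval.chrom}:{self.interval.start}"
            )


@dataclass
class TranscriptModel:
    """An exon-structured transcript with strand-aware TSS/TES.

    ``tss`` is the first transcribed base and ``tes`` the last, both as
    0-based genomic positions: on '+' these are ``start`` and ``end-1``
    of the transcript span, on '-' the reverse.
    """

    transcript_id: str
    gene_id: str | None
    interval: GenomeInterval
    exons: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has no exons")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValidationError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        for e in exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise ValidationError(
                    f"exon chrom/strand mismatch in {self.transcript_id}"
                )
        if exons[0].start != self.interval.start or exons[-1].end != self.interval.end:
            raise ValidationError(
                f"transcript {self.transcript_id} span does not match its exons"
            )
        self.exons = exons

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        if self.strand == "-":
            return self.interval.end - 1
        raise ValidationError(
            f"transcript {self.transcript_id} is unstranded; TSS undefined"
        )

    @property
    def tes(self) -> int:
        if self.strand == "+":
            return self.interval.end - 1
        if self.strand == "-":
            return self.interval.start
        raise ValidationError(
            f"transcript {self.transcript_id} is unstranded; TES undefined"
        )

    @property
    def introns(self) -> list[GenomeInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(
                    GenomeInterval(self.interval.chrom, a.end, b.start, self.strand)
                )
        return out

    @property
    def junctions(self) -> frozenset[tuple[int, int]]:
        """Intron (donor, acceptor) coordinates; the splice-site chain."""
        return frozenset((i.start, i.end) for i in self.introns)

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene: the union span of its transcript isoforms."""

    gene_id: str
    interval: GenomeInterval
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_oncogene: bool = False

    @property
    def introns(self) -> list[GenomeInterval]:
        """All distinct per-transcript introns of this gene."""
        seen: dict[tuple[int, int], GenomeInterval] = {}
        for t in self.transcripts:
            for i in t.introns:
                seen[(i.start, i.end)] = i
        return [seen[k] for k in sorted(seen)]


@dataclass
class ReadRecord:
    """A (filtered) sequencing read with optional run metadata."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None
    mean_quality: float | None = None
    channel: int | None = None
    start_time_s: float | None = None

    def __post_init__(self):
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ValidationError(
                    f"read {self.read_id}: quality/sequence length mismatch"
                )
            if self.mean_quality is None:
                self.mean_quality = float(sum(self.qualities)) / max(
                    1, len(self.qualities)
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One genomic alignment of a read.

    ``num_alignments_for_read`` is the multimapping count x used by the
    fractional 1/(x*y) counting rule; it must agree across all records
    of one read.
    """

    read_id: str
    target: GenomeInterval
    is_primary: bool = True
    num_alignments_for_read: int = 1
    aligned_blocks: list[GenomeInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.num_alignments_for_read < 1:
            raise ValidationError(
                f"read {self.read_id}: num_alignments_for_read must be >= 1"
            )
        if not self.aligned_blocks:
            self.aligned_blocks = [self.target]
        for b in self.aligned_blocks:
            if b.chrom != self.target.chrom or not (
                self.target.start <= b.start and b.end <= self.target.end
            ):
                raise ValidationError(
                    f"read {self.read_id}: aligned block outside target span"
                )


def clone_interval(iv: GenomeInterval, **kwargs) -> GenomeInterval:
    return replace(iv, **kwargs)
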