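"""Readers and writers for the standard formats the pipeline touches.

GTF is converted between its native 1-based inclusive coordinates and
the internal 0-based half-open convention at this boundary; BED and the
tabular alignment dialect are already half-open and pass through
unchanged.

The alignment TSV dialect (one row per alignment) is::

    read_id  chrom  start  end  strand  n_alignments  blocks

where ``blocks`` is a comma-separated list of ``start-end`` pairs in
genomic coordinates (half-open).  It carries exactly the fields the
counting and classification stages need from a BAM; :func:`read_alignments`
also accepts BAM/SAM via pysam when available.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    AlignmentRecord,
    GeneModel,
    GenomeInterval,
    ParseError,
    ReadRecord,
    TEConsensus,
    TELocus,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "parse_gtf",
    "write_gtf",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "read_bed",
    "write_bed",
    "read_fasta_consensus",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments_tsv",
    "write_alignments_tsv",
    "read_sequencing_summary",
    "write_sequencing_summary",
    "mean_read_quality",
    "filter_reads",
]


# ---------------------------------------------------------------------------
# GTF


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(path: str | Path) -> tuple[list[GeneModel], list[TranscriptModel]]:
    """Read exon features from a GTF into gene and transcript models.

    Coordinates are converted from 1-based inclusive to 0-based
    half-open.  Transcript spans, introns, and gene union spans are
    derived from the exon chains; explicit ``gene``/``transcript`` rows
    are ignored (exons are authoritative).  Output is deterministically
    ordered by (chrom, start, id).
    """
    exons_by_tx: dict[str, list[GenomeInterval]] = {}
    gene_of_tx: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i = int(start) - 1  # 1-based inclusive -> 0-based half-open
                end_i = int(end)
            except ValueError:
                raise ParseError(f"non-integer coordinates {start!r}/{end!r}", lineno)
            attrs = _parse_gtf_attributes(attr)
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise ParseError("exon without transcript_id", lineno)
            try:
                iv = GenomeInterval(chrom, start_i, end_i, strand)
            except ValidationError as exc:
                raise ParseError(str(exc), lineno)
            exons_by_tx.setdefault(tx_id, []).append(iv)
            if "gene_id" in attrs:
                gene_of_tx[tx_id] = attrs["gene_id"]

    transcripts = []
    for tx_id, exons in exons_by_tx.items():
        exons = sorted(exons, key=lambda e: e.start)
        span = GenomeInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_of_tx.get(tx_id),
                interval=span,
                exons=exons,
            )
        )
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.transcript_id))

    genes: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        if t.gene_id is not None:
            genes.setdefault(t.gene_id, []).append(t)
    gene_models = []
    for gene_id, txs in genes.items():
        start = min(t.interval.start for t in txs)
        end = max(t.interval.end for t in txs)
        strand = txs[0].interval.strand
        gene_models.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomeInterval(txs[0].interval.chrom, start, end, strand),
                transcripts=txs,
            )
        )
    gene_models.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return gene_models, transcripts


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(
            transcripts, key=lambda t: (t.interval.chrom, t.interval.start, t.transcript_id)
        ):
            gene = t.gene_id if t.gene_id is not None else t.transcript_id
            for e in t.exons:
                attrs = f'gene_id "{gene}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            "captes",
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def parse_repeatmasker_out(path: str | Path) -> list[TELocus]:
    """Parse a RepeatMasker ``.out`` annotation into TE loci.

    The divergence column (percent) is multiplied by ten to give
    milliDiv; orientation 'C' maps to the '-' strand.  Coordinates in
    the file are 1-based inclusive and are converted.
    """
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score")):
                continue  # header lines
            fields = stripped.split()
            if len(fields) < 11:
                raise ParseError(
                    f"expected >=11 whitespace-separated columns, got {len(fields)}",
                    lineno,
                )
            try:
                div_pct = float(fields[1])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                orient = fields[8]
                name = fields[9]
                cls_family = fields[10]
            except ValueError as exc:
                raise ParseError(str(exc), lineno)
            strand = "-" if orient == "C" else "+"
            family = cls_family.split("/")[0]
            loci.append(
                TELocus(
                    interval=GenomeInterval(chrom, start, end, strand),
                    family=family,
                    subfamily=name,
                    milli_div=div_pct * 10.0,
                )
            )
    return loci


def write_repeatmasker_out(loci: Sequence[TELocus], path: str | Path) -> None:
    """Write TE loci in RepeatMasker ``.out`` layout (inverse of the parser)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, locus in enumerate(loci, 1):
            iv = locus.interval
            orient = "C" if iv.strand == "-" else "+"
            fh.write(
                f"  225 {locus.milli_div / 10.0:5.1f}  0.0  0.0  {iv.chrom} "
                f"{iv.start + 1} {iv.end} (0) {orient} {locus.subfamily} "
                f"{locus.family}/{locus.family} 1 {len(iv)} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomeInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED needs at least 3 columns", lineno)
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                out.append(
                    GenomeInterval(fields[0], int(fields[1]), int(fields[2]), strand)
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno)
    return out


def read_bed_te(path: str | Path) -> list[TELocus]:
    """BED6+ with name = ``family:subfamily`` and score = milliDiv."""
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError("TE BED needs 6 columns", lineno)
            family, _, subfamily = fields[3].partition(":")
            try:
                loci.append(
                    TELocus(
                        interval=GenomeInterval(
                            fields[0], int(fields[1]), int(fields[2]), fields[5]
                        ),
                        family=family,
                        subfamily=subfamily or family,
                        milli_div=float(fields[4]),
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno)
    return loci


def write_bed(intervals: Iterable[GenomeInterval], path: str | Path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def write_bed_te(loci: Iterable[TELocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            iv = locus.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{locus.family}:{locus.subfamily}\t{locus.milli_div:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ (via Biopython)


def read_fasta_consensus(path: str | Path, family_map=None) -> list[TEConsensus]:
    """Load consensus sequences; family inferred from the name prefix
    (``Alu*`` -> Alu, ``L1*`` -> L1) unless ``family_map`` overrides it."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if family_map and name in family_map:
            family = family_map[name]
        elif name.upper().startswith("ALU"):
            family = "Alu"
        elif name.upper().startswith("L1"):
            family = "L1"
        else:
            family = "other"
        out.append(TEConsensus(name=name, family=family, sequence=str(rec.seq)))
    return out


def write_fasta(records: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = list(rec.letter_annotations["phred_quality"])
        reads.append(ReadRecord(read_id=rec.id, sequence=str(rec.seq), qualities=quals))
    return reads


def write_fastq(reads: Sequence[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        quals = r.qualities
        if quals is None:
            q = int(round(r.mean_quality)) if r.mean_quality is not None else 20
            quals = [q] * len(r.sequence)
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = quals
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------------------
# Alignment TSV dialect

_ALN_HEADER = "read_id\tchrom\tstart\tend\tstrand\tn_alignments\tblocks"


def write_alignments_tsv(alignments: Sequence[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_ALN_HEADER + "\n")
        for a in alignments:
            blocks = ",".join(f"{b.start}-{b.end}" for b in a.aligned_blocks)
            fh.write(
                f"{a.read_id}\t{a.target.chrom}\t{a.target.start}\t{a.target.end}\t"
                f"{a.target.strand}\t{a.num_alignments_for_read}\t{blocks}\n"
            )


def read_alignments_tsv(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(f"expected 7 columns, got {len(fields)}", lineno)
            read_id, chrom, start, end, strand, n_aln, blocks = fields
            try:
                target = GenomeInterval(chrom, int(start), int(end), strand)
                block_ivs = []
                for part in blocks.split(","):
                    b0, _, b1 = part.partition("-")
                    block_ivs.append(GenomeInterval(chrom, int(b0), int(b1), strand))
                out.append(
                    AlignmentRecord(
                        read_id=read_id,
                        target=target,
                        num_alignments_for_read=int(n_aln),
                        aligned_blocks=block_ivs,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno)
    return out


# ---------------------------------------------------------------------------
# Sequencing summary TSV


def write_sequencing_summary(rows: Sequence[tuple[str, int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchannel\tstart_time\n")
        for read_id, channel, start_time in rows:
            fh.write(f"{read_id}\t{channel}\t{start_time:g}\n")


def read_sequencing_summary(path: str | Path) -> list[tuple[str, int, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("sequencing summary needs 3 columns", lineno)
            rows.append((fields[0], int(fields[1]), float(fields[2])))
    return rows


# ---------------------------------------------------------------------------
# Read filtering


def mean_read_quality(qualities: Sequence[int], method: str = "arithmetic") -> float:
    """Mean per-read quality.

    ``arithmetic`` averages Phred scores directly (the default).
    ``error_rate`` averages error probabilities and converts back to a
    Phred score, which penalises low-quality stretches more strongly.
    """
    if not qualities:
        return 0.0
    if method == "arithmetic":
        return float(sum(qualities)) / len(qualities)
    if method == "error_rate":
        mean_p = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
        return -10.0 * math.log10(mean_p)
    raise ValueError(f"unknown quality method {method!r}")


def filter_reads(
    reads: Sequence[ReadRecord],
    min_quality: float = 7.0,
    min_length: int = 300,
) -> list[ReadRecord]:
    """Quality/length read filter (both thresholds inclusive).

    Keeps reads with mean quality >= ``min_quality`` and length >=
    ``min_length``, preserving input order.
    """
    out = []
    for r in reads:
        if r.mean_quality is None:
            raise ValidationError(f"read {r.read_id} has no mean_quality")
        if r.mean_quality >= min_quality and len(r) >= min_length:
            out.append(r)
    return out
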