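"""Synthetic data with known ground truth for every pipeline stage.

The generator builds, from a single integer seed:

* a random genome with gene models (2-5 exons each) and TE loci —
  consensus copies mutated to a drawn milliDiv and planted in exons,
  introns, and intergenic space, with the placement recorded;
* a transcriptome of canonical isoforms plus noncanonical transcripts
  constructed per pattern (intron retention, noncanonical splicing,
  alternative TSS/TES initiated or terminated inside a TE), each with
  its truth label;
* long reads sampled as transcript suffixes — a configurable fraction
  start inside a TE segment, emulating Cas9-released fragments — with
  substitution errors only, so every read's genomic origin is exactly
  known and alignment records are emitted without an external aligner;
* spike-in reads (synthetic TE cDNA = bacterial-like carrier + Alu),
  a configurable fraction of which are chimeras with host cDNA;
* sequencing-summary rows (channel, start time) and insertion-call
  tables with planted support-count regimes.

All randomness flows from ``numpy.random.default_rng(seed)`` streams,
so a fixed seed reproduces every byte of output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import reverse_complement
from .insertions import InsertionCall
from .models import (
    AlignmentRecord,
    CaptesError,
    GeneModel,
    GenomeInterval,
    ReadRecord,
    TEConsensus,
    TELocus,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SimulatedReference",
    "SimulatedTranscriptome",
    "SimulatedReads",
    "simulate_reference",
    "simulate_transcripts",
    "simulate_reads",
    "simulate_spikeins",
    "make_host_detector",
    "simulate_sequencing_summary",
    "simulate_insertion_calls",
    "simulate_support_mixture",
    "spliced_sequence",
    "spliced_to_genomic_blocks",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))

PATTERNS = ("intron_retention", "noncanonical_splicing", "alt_tss", "alt_tes")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults emulate a small capTEs-style run: most reads start inside
    a target TE (the enrichment signature), a ~2% substitution error
    rate, and a ~2% spike-in side-reaction rate.
    """

    seed: int = 1
    chrom: str = "chr1"
    genome_length: int = 2_000_000
    n_genes: int = 40
    n_te_loci: int = 300
    te_family_mix: dict[str, float] = field(
        default_factory=lambda: {"Alu": 0.7, "L1": 0.3}
    )
    read_error_rate: float = 0.02
    head_te_fraction: float = 0.7
    n_reads: int = 2000
    n_noncanonical: int = 60
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {
            "intron_retention": 0.30,
            "noncanonical_splicing": 0.25,
            "alt_tss": 0.25,
            "alt_tes": 0.20,
        }
    )
    spikein_count: int = 3
    n_spike_reads: int = 500
    hybrid_fraction: float = 0.022

    def __post_init__(self):
        for name, mix in (("te_family_mix", self.te_family_mix), ("pattern_mix", self.pattern_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"{name} proportions sum to {total}, not 1")
        for frac in (self.read_error_rate, self.head_te_fraction, self.hybrid_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")


@dataclass
class SimulatedReference:
    genome: dict[str, str]
    genes: list[GeneModel]
    te_loci: list[TELocus]
    consensi: list[TEConsensus]
    te_truth: pd.DataFrame  # te_id, chrom, start, end, family, subfamily, milli_div, placement


@dataclass
class SimulatedTranscriptome:
    transcripts: list[TranscriptModel]
    truth: pd.DataFrame  # transcript_id, kind, pattern, context, te_id, gene_id


@dataclass
class SimulatedReads:
    reads: list[ReadRecord]
    alignments: list[AlignmentRecord]
    truth: pd.DataFrame  # read_id, transcript_id, head_te, te_id, spliced_start


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.where(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _mutate_exact(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions at exactly round(len * rate) distinct positions, so a
    planted TE copy realises its drawn milliDiv precisely."""
    k = int(round(len(seq) * rate))
    if k <= 0:
        return seq
    arr = np.array(list(seq))
    for i in rng.choice(arr.size, size=k, replace=False):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Reference


def _make_consensi(rng: np.random.Generator) -> list[TEConsensus]:
    return [
        TEConsensus(name="AluY", family="Alu", sequence=_random_seq(rng, 300)),
        TEConsensus(name="L1Hs", family="L1", sequence=_random_seq(rng, 1200)),
    ]


def simulate_reference(config: SimulationConfig) -> SimulatedReference:
    """Genome + genes + planted TE loci with recorded placement truth.

    TE loci are consensus copies (possibly 5'-truncated, >= 150 bp)
    mutated to a drawn milliDiv (10% of loci young at < 5, the rest
    10-150) and written into exons, introns, and intergenic gaps.
    """
    rng = np.random.default_rng(config.seed)
    consensi = _make_consensi(rng)
    cons_by_family = {c.family: c for c in consensi}
    genome = list(_random_seq(rng, config.genome_length))

    # --- genes: non-overlapping, 2-5 exons
    genes: list[GeneModel] = []
    slot = config.genome_length // config.n_genes
    if slot < 8000:
        raise CaptesError("genome too small for the requested gene count")
    for gi in range(config.n_genes):
        base = gi * slot + 500
        n_exons = int(rng.integers(2, 6))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = base
        for _e in range(n_exons):
            exon_len = int(rng.integers(150, 401))
            exons.append((pos, pos + exon_len))
            pos += exon_len + int(rng.integers(700, 2001))
        end = exons[-1][1]
        if end >= (gi + 1) * slot - 200:
            raise CaptesError("genome too small to place gene exon chains")
        gene_id = f"GENE{gi:04d}"
        exon_ivs = [GenomeInterval(config.chrom, s, e, strand) for s, e in exons]
        tx = TranscriptModel(
            transcript_id=f"{gene_id}.1",
            gene_id=gene_id,
            interval=GenomeInterval(config.chrom, exons[0][0], end, strand),
            exons=exon_ivs,
        )
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomeInterval(config.chrom, exons[0][0], end, strand),
                transcripts=[tx],
            )
        )

    # --- candidate TE slots
    occupied: list[tuple[int, int]] = []

    def free(start: int, end: int) -> bool:
        return all(e0 >= end or e1 <= start for e0, e1 in occupied)

    families = sorted(config.te_family_mix)
    fam_probs = np.array([config.te_family_mix[f] for f in families])
    placements = ["exonic", "intronic", "intergenic"]
    place_probs = np.array([0.2, 0.4, 0.4])

    te_loci: list[TELocus] = []
    truth_rows = []
    attempts = 0
    while len(te_loci) < config.n_te_loci and attempts < config.n_te_loci * 60:
        attempts += 1
        family = families[int(rng.choice(len(families), p=fam_probs))]
        cons = cons_by_family[family]
        placement = placements[int(rng.choice(3, p=place_probs))]
        if placement == "exonic":
            g = genes[int(rng.integers(0, len(genes)))]
            exon = g.transcripts[0].exons[int(rng.integers(0, len(g.transcripts[0].exons)))]
            room = len(exon) - 4
            if room < 150:
                continue
            te_len = min(len(cons), room, int(rng.integers(150, 261)))
            start = exon.start + 2
        elif placement == "intronic":
            g = genes[int(rng.integers(0, len(genes)))]
            introns = g.transcripts[0].introns
            intron = introns[int(rng.integers(0, len(introns)))]
            room = len(intron) - 120  # keep slack for alt-TSS/TES transcripts
            if room < 150:
                continue
            te_len = min(len(cons), room, 300)
            start = intron.start + 60
        else:
            gap_idx = int(rng.integers(0, config.n_genes))
            gap_start = genes[gap_idx].interval.end + 400
            gap_end = (
                genes[gap_idx + 1].interval.start - 400
                if gap_idx + 1 < len(genes)
                else config.genome_length - 400
            )
            if gap_end - gap_start < 1600:
                continue
            te_len = min(len(cons), 300 if family == "Alu" else 600)
            start = int(rng.integers(gap_start, gap_end - te_len - 700))
        end = start + te_len
        # intergenic TEs get wide clearance so alt-TSS/TES transcripts
        # built on them cannot brush a neighbouring locus
        margin_lo, margin_hi = (500, 700) if placement == "intergenic" else (60, 60)
        if not free(start - margin_lo, end + margin_hi):
            continue
        # 10% of loci young (< 5 milliDiv); the rest capped at 120 so the
        # divergence seen by the scanner (copy + read errors) stays well
        # below the 18% reporting rule
        if rng.random() < 0.1:
            milli_div = float(rng.uniform(0.0, 5.0))
        else:
            milli_div = float(rng.uniform(10.0, 120.0))
        strand = "+" if rng.random() < 0.5 else "-"
        copy = _mutate_exact(cons.sequence[:te_len], milli_div / 1000.0, rng)
        genome[start:end] = list(copy if strand == "+" else reverse_complement(copy))
        occupied.append((start, end))
        te_id = f"TE{len(te_loci):04d}"
        te_loci.append(
            TELocus(
                interval=GenomeInterval(config.chrom, start, end, strand),
                family=family,
                subfamily=cons.name,
                milli_div=milli_div,
            )
        )
        truth_rows.append(
            {
                "te_id": te_id,
                "chrom": config.chrom,
                "start": start,
                "end": end,
                "family": family,
                "subfamily": cons.name,
                "milli_div": milli_div,
                "placement": placement,
            }
        )
    if len(te_loci) < config.n_te_loci:
        raise CaptesError(
            f"could only place {len(te_loci)}/{config.n_te_loci} TE loci; "
            "increase genome_length"
        )
    return SimulatedReference(
        genome={config.chrom: "".join(genome)},
        genes=genes,
        te_loci=te_loci,
        consensi=consensi,
        te_truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Transcripts


def spliced_sequence(genome: dict[str, str], t: TranscriptModel) -> str:
    """5'->3' transcript sequence from the genome."""
    chrom_seq = genome[t.interval.chrom]
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


def spliced_to_genomic_blocks(
    t: TranscriptModel, s_start: int, s_end: int
) -> list[GenomeInterval]:
    """Genomic blocks covered by spliced positions [s_start, s_end)."""
    if not 0 <= s_start < s_end <= t.spliced_length():
        raise ValidationError("spliced range outside transcript")
    exons = t.exons if t.strand != "-" else list(reversed(t.exons))
    blocks = []
    offset = 0
    for e in exons:
        e_len = len(e)
        lo = max(s_start - offset, 0)
        hi = min(s_end - offset, e_len)
        if lo < hi:
            if t.strand == "-":
                blocks.append(
                    GenomeInterval(e.chrom, e.end - hi, e.end - lo, t.strand)
                )
            else:
                blocks.append(
                    GenomeInterval(e.chrom, e.start + lo, e.start + hi, t.strand)
                )
        offset += e_len
    return sorted(blocks, key=lambda b: b.start)


def _te_lookup(ref: SimulatedReference) -> dict[tuple[int, int], str]:
    return {
        (row.start, row.end): row.te_id for row in ref.te_truth.itertuples()
    }


def _intron_of(gene: GeneModel, te: TELocus) -> GenomeInterval | None:
    for intron in gene.transcripts[0].introns:
        if intron.start <= te.interval.start and te.interval.end <= intron.end:
            return intron
    return None


def simulate_transcripts(
    ref: SimulatedReference, config: SimulationConfig
) -> SimulatedTranscriptome:
    """Canonical isoforms plus noncanonical transcripts built per pattern.

    Constructions (all unambiguous by design):

    * intron retention — an isoform with one intron's flanking exons
      merged into a single exon spanning the intron, preferring introns
      that contain a TE;
    * noncanonical splicing — an internal donor site shifted 30 nt into
      its exon, creating a junction absent from the annotation;
    * alternative TSS — a monoexonic '+' transcript starting inside an
      intronic or intergenic TE and ending before the region ends;
    * alternative TES — likewise but ending inside the TE.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom
    transcripts: list[TranscriptModel] = []
    rows = []
    for g in ref.genes:
        t = g.transcripts[0]
        transcripts.append(t)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "kind": "canonical",
                "pattern": "none",
                "context": "genic",
                "te_id": None,
                "gene_id": g.gene_id,
            }
        )

    te_ids = _te_lookup(ref)
    intronic_tes = []
    intergenic_tes = []
    gene_of_intronic: dict[int, GeneModel] = {}
    for i, (locus, row) in enumerate(zip(ref.te_loci, ref.te_truth.itertuples())):
        if row.placement == "intronic":
            for g in ref.genes:
                if _intron_of(g, locus) is not None:
                    intronic_tes.append(i)
                    gene_of_intronic[i] = g
                    break
        elif row.placement == "intergenic":
            intergenic_tes.append(i)

    # integer allocation per pattern, largest remainders fill the slack
    raw = {p: config.n_noncanonical * config.pattern_mix.get(p, 0.0) for p in PATTERNS}
    alloc = {p: int(raw[p]) for p in PATTERNS}
    for p in sorted(PATTERNS, key=lambda p: raw[p] - alloc[p], reverse=True):
        if sum(alloc.values()) >= config.n_noncanonical:
            break
        alloc[p] += 1

    used_tes: set[int] = set()
    counter = 0

    def emit(t: TranscriptModel, pattern: str, context: str, te_id, gene_id):
        nonlocal counter
        counter += 1
        transcripts.append(t)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "kind": "noncanonical",
                "pattern": pattern,
                "context": context,
                "te_id": te_id,
                "gene_id": gene_id,
            }
        )

    # --- intron retention
    candidates = [i for i in intronic_tes]
    rng.shuffle(candidates)
    n_ir = alloc["intron_retention"]
    if len(candidates) < n_ir:
        raise CaptesError("pattern intron_retention: not enough intronic TE placements")
    for i in candidates[:n_ir]:
        locus = ref.te_loci[i]
        g = gene_of_intronic[i]
        base = g.transcripts[0]
        intron = _intron_of(g, locus)
        new_exons = []
        skip = False
        for a, b in zip(base.exons, base.exons[1:]):
            if a.end == intron.start and b.start == intron.end:
                skip = True
        if not skip:
            raise CaptesError("pattern intron_retention: intron not flanked by exons")
        merged = []
        k = 0
        while k < len(base.exons):
            e = base.exons[k]
            if e.end == intron.start:
                nxt = base.exons[k + 1]
                merged.append(GenomeInterval(chrom, e.start, nxt.end, base.strand))
                k += 2
            else:
                merged.append(e)
                k += 1
        tid = f"NC{counter:04d}.ir"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=None,
            interval=GenomeInterval(chrom, merged[0].start, merged[-1].end, base.strand),
            exons=merged,
        )
        used_tes.add(i)
        emit(t, "intron_retention", "genic", te_ids[(locus.interval.start, locus.interval.end)], g.gene_id)

    # --- noncanonical splicing: shift a donor site 30 nt into its exon
    n_ns = alloc["noncanonical_splicing"]
    gene_pool = [g for g in ref.genes if len(g.transcripts[0].exons) >= 2]
    rng.shuffle(gene_pool)
    if len(gene_pool) < n_ns:
        raise CaptesError("pattern noncanonical_splicing: not enough multi-exon genes")
    for g in gene_pool[:n_ns]:
        base = g.transcripts[0]
        exons = list(base.exons)
        first = exons[0]
        if len(first) <= 80:
            raise CaptesError("pattern noncanonical_splicing: first exon too short")
        exons[0] = GenomeInterval(chrom, first.start, first.end - 30, base.strand)
        tid = f"NC{counter:04d}.ns"
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=None,
            interval=GenomeInterval(chrom, exons[0].start, exons[-1].end, base.strand),
            exons=exons,
        )
        emit(t, "noncanonical_splicing", "genic", None, g.gene_id)

    # --- alternative TSS / TES inside intronic or intergenic TEs
    def region_of(i: int) -> tuple[GenomeInterval, str]:
        locus = ref.te_loci[i]
        if i in gene_of_intronic:
            return _intron_of(gene_of_intronic[i], locus), "intronic"
        iv = locus.interval
        return GenomeInterval(chrom, iv.start - 350, iv.end + 650), "intergenic"

    pool = [i for i in intronic_tes + intergenic_tes if i not in used_tes]
    rng.shuffle(pool)
    n_tss, n_tes = alloc["alt_tss"], alloc["alt_tes"]
    made_tss = made_tes = 0
    for i in pool:
        if made_tss >= n_tss and made_tes >= n_tes:
            break
        locus = ref.te_loci[i]
        region, context = region_of(i)
        te_iv = locus.interval
        want_tss = made_tss < n_tss
        # the other transcript end must clear the TE by >= 50 nt so that
        # exactly one of alt_tss/alt_tes applies
        if want_tss:
            start = te_iv.start + min(40, max(0, len(te_iv) - 160))
            end = min(region.end - 10, max(te_iv.end + 150, start + 450))
            if end - te_iv.end < 50 or end - start < 300:
                continue
            suffix, pattern = ".tss", "alt_tss"
        else:
            end = te_iv.end - 20
            start = max(region.start + 10, min(te_iv.start - 150, end - 450))
            if te_iv.start - start < 50 or end - start < 300:
                continue
            suffix, pattern = ".tes", "alt_tes"
        tid = f"NC{counter:04d}{suffix}"
        iv = GenomeInterval(chrom, start, end, "+")
        t = TranscriptModel(transcript_id=tid, gene_id=None, interval=iv, exons=[iv])
        used_tes.add(i)
        if want_tss:
            made_tss += 1
        else:
            made_tes += 1
        emit(
            t,
            pattern,
            context,
            te_ids[(te_iv.start, te_iv.end)],
            gene_of_intronic[i].gene_id if i in gene_of_intronic else None,
        )
    if made_tss < n_tss or made_tes < n_tes:
        raise CaptesError(
            "pattern alt_tss/alt_tes: not enough suitable intronic/intergenic TEs"
        )

    return SimulatedTranscriptome(transcripts=transcripts, truth=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Reads


def _te_spliced_spans(
    ref: SimulatedReference, txome: SimulatedTranscriptome, min_len: int = 40
) -> dict[int, list[tuple[int, int]]]:
    """Per transcript index, spliced-coordinate spans of every exonic TE
    segment of at least ``min_len`` bases."""
    spans: dict[int, list[tuple[int, int]]] = {}
    te_intervals = [t.interval for t in ref.te_loci]
    for ti, t in enumerate(txome.transcripts):
        offset = 0
        exons = t.exons if t.strand != "-" else list(reversed(t.exons))
        for e in exons:
            for te_iv in te_intervals:
                lo = max(e.start, te_iv.start)
                hi = min(e.end, te_iv.end)
                if hi - lo < min_len:
                    continue
                if t.strand == "-":
                    s_start = offset + (e.end - hi)
                else:
                    s_start = offset + (lo - e.start)
                spans.setdefault(ti, []).append((s_start, s_start + (hi - lo)))
            offset += len(e)
    return spans


def _head_candidates(
    txome: SimulatedTranscriptome, te_spans: dict[int, list[tuple[int, int]]]
) -> list[tuple[int, int, int]]:
    """(transcript index, spliced TE start, spliced TE end) triples where a
    read starting at the TE keeps >= 150 TE bases and >= 300 nt of read."""
    out = []
    for ti, spans in te_spans.items():
        length = txome.transcripts[ti].spliced_length()
        for s_start, s_end in spans:
            if s_end - s_start >= 150 and length - s_start >= 300:
                out.append((ti, s_start, s_end))
    return sorted(out)


def _clean_background_starts(
    txome: SimulatedTranscriptome, te_spans: dict[int, list[tuple[int, int]]]
) -> dict[int, np.ndarray]:
    """Per-transcript start positions whose reads are off-target: they
    avoid beginning inside (or within 50 nt upstream of) any TE segment
    and leave >= 300 nt of read."""
    out = {}
    for ti, t in enumerate(txome.transcripts):
        length = t.spliced_length()
        ok = np.ones(max(length - 300 + 1, 0), dtype=bool)
        for s_start, s_end in te_spans.get(ti, []):
            # 50 nt on-target window plus a 150 nt buffer: a co-optimal
            # local alignment can extend a hit's start a little leftward
            lo = max(0, s_start - 200)
            hi = min(len(ok), s_end - 45)
            ok[lo:hi] = False
        starts = np.where(ok)[0]
        if starts.size:
            out[ti] = starts
    return out


def simulate_reads(
    ref: SimulatedReference,
    txome: SimulatedTranscriptome,
    config: SimulationConfig,
) -> SimulatedReads:
    """Transcript-suffix reads with known origins.

    A ``head_te_fraction`` share of reads start exactly at a TE segment
    of a transcript (the Cas9-cut emulation); the rest start at
    positions that keep the first 50 nt TE-free.  Errors are
    substitutions at ``read_error_rate``; qualities are drawn around
    Q20.  Alignment records carry the true genomic blocks.
    """
    rng = np.random.default_rng(config.seed + 2)
    te_spans = _te_spliced_spans(ref, txome)
    head_cands = _head_candidates(txome, te_spans)
    if not head_cands:
        raise CaptesError("no TE-head read candidates; increase TE density")
    bg_starts = _clean_background_starts(txome, te_spans)
    if not bg_starts:
        raise CaptesError("no off-target read start positions available")
    bg_tx = sorted(bg_starts)

    seqs = {ti: spliced_sequence(ref.genome, t) for ti, t in enumerate(txome.transcripts)}
    te_ids = _te_lookup(ref)
    te_by_span: dict[tuple[int, int, int], str] = {}
    for ti, s0, s1 in head_cands:
        blocks = spliced_to_genomic_blocks(txome.transcripts[ti], s0, s1)
        for b in blocks:
            for (g0, g1), tid in te_ids.items():
                if b.start >= g0 and b.end <= g1:
                    te_by_span[(ti, s0, s1)] = tid

    reads, alignments, rows = [], [], []
    for ri in range(config.n_reads):
        read_id = f"read{ri:06d}"
        head = rng.random() < config.head_te_fraction
        if head:
            ti, s0, s1 = head_cands[int(rng.integers(0, len(head_cands)))]
            start = s0
            te_id = te_by_span.get((ti, s0, s1))
        else:
            ti = bg_tx[int(rng.integers(0, len(bg_tx)))]
            starts = bg_starts[ti]
            start = int(starts[int(rng.integers(0, starts.size))])
            te_id = None
        t = txome.transcripts[ti]
        seq = seqs[ti][start:]
        seq = _mutate(seq, config.read_error_rate, rng)
        quals = rng.integers(14, 28, size=len(seq)).tolist()
        reads.append(ReadRecord(read_id=read_id, sequence=seq, qualities=quals))
        blocks = spliced_to_genomic_blocks(t, start, t.spliced_length())
        alignments.append(
            AlignmentRecord(
                read_id=read_id,
                target=GenomeInterval(
                    t.interval.chrom, blocks[0].start, blocks[-1].end, t.strand
                ),
                num_alignments_for_read=1,
                aligned_blocks=blocks,
            )
        )
        rows.append(
            {
                "read_id": read_id,
                "transcript_id": t.transcript_id,
                "head_te": head,
                "te_id": te_id,
                "spliced_start": start,
            }
        )
    return SimulatedReads(
        reads=reads, alignments=alignments, truth=pd.DataFrame(rows)
    )


# ---------------------------------------------------------------------------
# Spike-ins


def simulate_spikeins(
    ref: SimulatedReference,
    txome: SimulatedTranscriptome,
    config: SimulationConfig,
) -> tuple[list[TEConsensus], list[ReadRecord], pd.DataFrame]:
    """Spike-in library and reads, a fraction of which are host chimeras.

    Each spike-in signature is a random carrier sequence (emulating the
    bacterial half of the synthetic TE cDNA) joined to the Alu
    consensus.  A hybrid read appends >= 200 nt of host transcript
    sequence to the spike-in — the ligation side reaction.
    """
    if config.spikein_count < 1:
        raise ValidationError("spikein_count must be >= 1")
    rng = np.random.default_rng(config.seed + 3)
    alu = next(c for c in ref.consensi if c.family == "Alu")
    spikes = []
    for i in range(config.spikein_count):
        carrier = _random_seq(rng, 400)
        spikes.append(
            TEConsensus(name=f"spike{i}", family="other", sequence=carrier + alu.sequence)
        )
    host_seqs = [spliced_sequence(ref.genome, t) for t in txome.transcripts]
    reads, rows = [], []
    for ri in range(config.n_spike_reads):
        spike = spikes[int(rng.integers(0, len(spikes)))]
        seq = spike.sequence
        hybrid = rng.random() < config.hybrid_fraction
        if hybrid:
            host = host_seqs[int(rng.integers(0, len(host_seqs)))]
            frag_len = int(rng.integers(200, 301))
            start = int(rng.integers(0, max(1, len(host) - frag_len)))
            seq = seq + host[start : start + frag_len]
        seq = _mutate(seq, config.read_error_rate, rng)
        read_id = f"spike_read{ri:05d}"
        reads.append(
            ReadRecord(
                read_id=read_id,
                sequence=seq,
                qualities=rng.integers(14, 28, size=len(seq)).tolist(),
            )
        )
        rows.append({"read_id": read_id, "spike": spike.name, "is_hybrid": hybrid})
    return spikes, reads, pd.DataFrame(rows)


def make_host_detector(
    ref: SimulatedReference, txome: SimulatedTranscriptome, k: int = 25, min_hits: int = 2
):
    """Host-cDNA detector for side-reaction measurement.

    Indexes all transcript ``k``-mers; a read contains host sequence
    when at least ``min_hits`` exact host k-mers occur outside its
    detected spike-in segments.  At a 2% substitution rate a 50 nt host
    stretch retains several exact 25-mers, while spike-in carrier
    sequence shares none with the transcriptome.
    """
    kmers: set[str] = set()
    for t in txome.transcripts:
        seq = spliced_sequence(ref.genome, t)
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])

    def detector(read: ReadRecord, spike_hits) -> bool:
        masked = np.zeros(len(read.sequence), dtype=bool)
        for h in spike_hits:
            masked[h.hit_start : h.hit_end] = True
        hits = 0
        seq = read.sequence
        i = 0
        while i < len(seq) - k + 1:
            if not masked[i : i + k].any() and seq[i : i + k] in kmers:
                hits += 1
                if hits >= min_hits:
                    return True
                i += k
            else:
                i += 1
        return False

    return detector


# ---------------------------------------------------------------------------
# Sequencing summary and insertion calls


def simulate_sequencing_summary(
    n_reads: int,
    n_channels: int = 100,
    duration_min: float = 60.0,
    seed: int = 0,
) -> list[tuple[str, int, float]]:
    """Uniform read starts over ``duration_min`` across pore channels."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_reads):
        rows.append(
            (
                f"read{i:06d}",
                int(rng.integers(1, n_channels + 1)),
                float(rng.uniform(0.0, duration_min * 60.0)),
            )
        )
    return rows


def simulate_insertion_calls(
    truth: list[tuple[str, int, str, int]],
    n_noise: int = 200,
    genome_length: int = 2_000_000,
    chrom: str = "chr1",
    seed: int = 0,
) -> tuple[list[InsertionCall], pd.DataFrame]:
    """Raw insertion calls from planted truth plus low-support noise.

    Each truth entry ``(chrom, position, family, support)`` is emitted
    as 1-3 member calls jittered within +/- 80 bp whose supports sum to
    the planted support; noise calls have support 1-3 at random
    positions.
    """
    rng = np.random.default_rng(seed)
    calls = []
    rows = []
    for chrom_t, pos, family, support in truth:
        n_members = int(rng.integers(1, min(3, support) + 1))
        splits = np.sort(rng.choice(np.arange(1, support), size=n_members - 1, replace=False)) if n_members > 1 else np.array([], dtype=int)
        parts = np.diff(np.concatenate([[0], splits, [support]]))
        for part in parts:
            jitter = int(rng.integers(-80, 81))
            calls.append(
                InsertionCall(
                    chrom=chrom_t,
                    position=max(0, pos + jitter),
                    family=family,
                    support=int(part),
                )
            )
        rows.append({"chrom": chrom_t, "position": pos, "family": family, "support": support})
    for _ in range(n_noise):
        calls.append(
            InsertionCall(
                chrom=chrom,
                position=int(rng.integers(0, genome_length)),
                family="Alu" if rng.random() < 0.7 else "L1",
                support=int(rng.integers(1, 4)),
            )
        )
    rng.shuffle(calls)
    return calls, pd.DataFrame(rows)


def simulate_support_mixture(
    n_noise: int = 2000,
    n_signal: int = 120,
    noise_p: float = 0.6,
    signal_low: int = 20,
    signal_high: int = 40,
    seed: int = 0,
) -> tuple[list[int], int]:
    """Two-regime support-count mixture with an analytically planted knee.

    Noise supports are geometric(p) (a fast-decaying false-positive
    regime); signal supports are uniform on [signal_low, signal_high]
    (a plateau of real insertions).  The knee of the survival curve
    N(s) sits where the expected noise tail crosses the signal count:
    n_noise * (1-p)^(s-1) = n_signal, solved for s and rounded.
    """
    rng = np.random.default_rng(seed)
    noise = rng.geometric(noise_p, size=n_noise)
    signal = rng.integers(signal_low, signal_high + 1, size=n_signal)
    supports = np.concatenate([noise, signal]).tolist()
    knee = 1 + np.log(n_signal / n_noise) / np.log(1.0 - noise_p)
    return supports, int(round(knee))


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write a complete input set for the pipeline CLI."""
    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    ref = simulate_reference(config)
    txome = simulate_transcripts(ref, config)
    sim_reads = simulate_reads(ref, txome, config)
    spikes, spike_reads, spike_truth = simulate_spikeins(ref, txome, config)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "assembled": outdir / "assembled.gtf",
        "te_bed": outdir / "te.bed",
        "te_out": outdir / "te.out",
        "consensus": outdir / "consensus.fa",
        "reads": outdir / "reads.fastq",
        "alignments": outdir / "alignments.tsv",
        "spikein": outdir / "spikein.fa",
        "spike_reads": outdir / "spike_reads.fastq",
        "summary": outdir / "sequencing_summary.tsv",
    }
    cio.write_fasta(ref.genome, paths["genome"])
    cio.write_gtf([t for g in ref.genes for t in g.transcripts], paths["annotation"])
    cio.write_gtf(txome.transcripts, paths["assembled"])
    cio.write_bed_te(ref.te_loci, paths["te_bed"])
    cio.write_repeatmasker_out(ref.te_loci, paths["te_out"])
    cio.write_fasta([(c.name, c.sequence) for c in ref.consensi], paths["consensus"])
    cio.write_fastq(sim_reads.reads, paths["reads"])
    cio.write_alignments_tsv(sim_reads.alignments, paths["alignments"])
    cio.write_fasta([(s.name, s.sequence) for s in spikes], paths["spikein"])
    cio.write_fastq(spike_reads, paths["spike_reads"])
    cio.write_sequencing_summary(
        simulate_sequencing_summary(config.n_reads, seed=config.seed + 4), paths["summary"]
    )
    ref.te_truth.to_csv(outdir / "truth" / "te_loci.tsv", sep="\t", index=False)
    txome.truth.to_csv(outdir / "truth" / "transcripts.tsv", sep="\t", index=False)
    sim_reads.truth.to_csv(outdir / "truth" / "reads.tsv", sep="\t", index=False)
    spike_truth.to_csv(outdir / "truth" / "spike_reads.tsv", sep="\t", index=False)
    return paths
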