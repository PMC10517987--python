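"""Domain types, format round trips, and the read filter."""

import numpy as np
import pytest

from captes.io import (
    filter_reads,
    mean_read_quality,
    parse_gtf,
    parse_repeatmasker_out,
    read_alignments_tsv,
    read_bed_te,
    read_fastq,
    write_alignments_tsv,
    write_bed_te,
    write_fastq,
    write_gtf,
    write_repeatmasker_out,
)
from captes.models import (
    AlignmentRecord,
    GenomeInterval,
    ReadRecord,
    TELocus,
    TranscriptModel,
    ValidationError,
)


class TestGenomeInterval:
    def test_rejects_inverted_and_empty_intervals(self):
        with pytest.raises(ValidationError):
            GenomeInterval("chr1", 100, 100)
        with pytest.raises(ValidationError):
            GenomeInterval("chr1", 200, 100)
        with pytest.raises(ValidationError):
            GenomeInterval("chr1", 0, 10, "x")

    def test_half_open_abutment_does_not_overlap(self):
        a = GenomeInterval("chr1", 0, 100)
        b = GenomeInterval("chr1", 100, 200)
        assert not a.overlaps(b)
        assert a.overlap_length(b) == 0


class TestTranscriptModel:
    def _two_exon(self, strand):
        exons = [
            GenomeInterval("chr1", 0, 100, strand),
            GenomeInterval("chr1", 200, 300, strand),
        ]
        return TranscriptModel("t1", "g1", GenomeInterval("chr1", 0, 300, strand), exons)

    def test_plus_strand_tss_tes(self):
        t = self._two_exon("+")
        assert (t.tss, t.tes) == (0, 299)

    def test_minus_strand_swaps_tss_tes(self):
        t = self._two_exon("-")
        assert (t.tss, t.tes) == (299, 0)

    def test_introns_are_exon_complement(self):
        t = self._two_exon("+")
        assert [(i.start, i.end) for i in t.introns] == [(100, 200)]
        assert t.junctions == frozenset({(100, 200)})

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            TranscriptModel(
                "t1",
                "g1",
                GenomeInterval("chr1", 0, 150, "+"),
                [GenomeInterval("chr1", 0, 100, "+"), GenomeInterval("chr1", 90, 150, "+")],
            )


class TestGTF:
    def test_coordinates_convert_from_one_based(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        genes, txs = parse_gtf(gtf)
        (t,) = txs
        assert [(e.start, e.end) for e in t.exons] == [(0, 100), (200, 300)]
        assert (t.tss, t.tes) == (0, 299)
        assert genes[0].gene_id == "g1"

    def test_minus_strand_tss(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\tx\texon\t1\t100\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t201\t300\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        _, (t,) = parse_gtf(gtf)
        assert (t.tss, t.tes) == (299, 0)

    def test_empty_file_gives_empty_lists(self, tmp_path):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        genes, txs = parse_gtf(gtf)
        assert genes == [] and txs == []

    def test_parse_write_parse_is_identity(self, transcriptome, tmp_path):
        path = tmp_path / "roundtrip.gtf"
        write_gtf(transcriptome.transcripts, path)
        _, parsed = parse_gtf(path)
        path2 = tmp_path / "roundtrip2.gtf"
        write_gtf(parsed, path2)
        assert path.read_text() == path2.read_text()
        by_id = {t.transcript_id: t for t in parsed}
        for t in transcriptome.transcripts:
            p = by_id[t.transcript_id]
            assert [(e.start, e.end) for e in p.exons] == [
                (e.start, e.end) for e in t.exons
            ]
            assert p.strand == t.strand

    def test_malformed_line_reports_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\tonly\tthree\n")
        with pytest.raises(Exception, match="line 1"):
            parse_gtf(gtf)


class TestRepeatMaskerOut:
    def test_divergence_percent_becomes_millidiv(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            "   SW  perc ...\nscore  div. ...\n\n"
            "  463 1.5 0.0 0.0 chr1 101 400 (0) + AluY SINE/Alu 1 300 (0) 1\n"
        )
        (locus,) = parse_repeatmasker_out(path)
        assert locus.milli_div == 15.0
        assert (locus.interval.start, locus.interval.end) == (100, 400)
        assert locus.interval.strand == "+"

    def test_c_orientation_maps_to_minus(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(
            "   SW ...\nscore ...\n\n"
            "  463 2.0 0.0 0.0 chr2 11 250 (0) C L1HS LINE/L1 1 240 (0) 1\n"
        )
        (locus,) = parse_repeatmasker_out(path)
        assert locus.interval.strand == "-"
        assert locus.family == "LINE"

    def test_three_record_roundtrip(self, tmp_path):
        loci = [
            TELocus(GenomeInterval("chr1", 100, 400, "+"), "Alu", "AluY", 15.0),
            TELocus(GenomeInterval("chr1", 1000, 1240, "-"), "L1", "L1Hs", 42.0),
            TELocus(GenomeInterval("chr2", 5, 160, "+"), "Alu", "AluSx", 118.0),
        ]
        path = tmp_path / "rm.out"
        write_repeatmasker_out(loci, path)
        parsed = parse_repeatmasker_out(path)
        for a, b in zip(loci, parsed):
            assert a.interval == b.interval
            assert a.subfamily == b.subfamily
            assert a.milli_div == pytest.approx(b.milli_div)


class TestTabularFormats:
    def test_te_bed_roundtrip(self, reference, tmp_path):
        path = tmp_path / "te.bed"
        write_bed_te(reference.te_loci, path)
        parsed = read_bed_te(path)
        assert len(parsed) == len(reference.te_loci)
        for a, b in zip(reference.te_loci, parsed):
            assert a.interval == b.interval and a.family == b.family

    def test_alignment_tsv_roundtrip(self, sim_reads, tmp_path):
        path = tmp_path / "aln.tsv"
        write_alignments_tsv(sim_reads.alignments[:50], path)
        parsed = read_alignments_tsv(path)
        for a, b in zip(sim_reads.alignments[:50], parsed):
            assert a.read_id == b.read_id
            assert a.target == b.target
            assert [(x.start, x.end) for x in a.aligned_blocks] == [
                (x.start, x.end) for x in b.aligned_blocks
            ]

    def test_fastq_roundtrip(self, sim_reads, tmp_path):
        path = tmp_path / "r.fastq"
        write_fastq(sim_reads.reads[:20], path)
        parsed = read_fastq(path)
        for a, b in zip(sim_reads.reads[:20], parsed):
            assert a.sequence == b.sequence
            assert a.qualities == b.qualities


class TestFilterReads:
    def _read(self, length, quality):
        return ReadRecord("r", "A" * length, mean_quality=quality)

    @pytest.mark.parametrize(
        "length,quality,kept",
        [
            (299, 20.0, False),  # one base short
            (300, 7.0, True),  # both thresholds inclusive
            (300, 6.9, False),
            (5000, 7.0, True),
        ],
    )
    def test_inclusive_boundaries(self, length, quality, kept):
        assert bool(filter_reads([self._read(length, quality)])) is kept

    def test_matches_bruteforce_on_random_reads(self):
        rng = np.random.default_rng(42)
        reads = [
            ReadRecord(
                f"r{i}",
                "A" * int(rng.integers(100, 600)),
                mean_quality=float(rng.uniform(2, 20)),
            )
            for i in range(100)
        ]
        out = filter_reads(reads)
        expect = [r for r in reads if r.mean_quality >= 7 and len(r) >= 300]
        assert [r.read_id for r in out] == [r.read_id for r in expect]

    def test_output_is_subsequence_of_input(self, sim_reads):
        out = filter_reads(sim_reads.reads, min_quality=19, min_length=400)
        it = iter(r.read_id for r in sim_reads.reads)
        assert all(any(x == o.read_id for x in it) for o in out)

    def test_quality_method_divergence(self):
        quals = [30, 2, 30, 2]
        arith = mean_read_quality(quals)
        err = mean_read_quality(quals, method="error_rate")
        assert arith == pytest.approx(16.0)
        assert err < arith  # error-probability mean punishes low-Q bases


class TestAlignmentRecord:
    def test_block_outside_target_rejected(self):
        with pytest.raises(ValidationError):
            AlignmentRecord(
                "r",
                GenomeInterval("chr1", 100, 200),
                aligned_blocks=[GenomeInterval("chr1", 50, 150)],
            )

    def test_multimap_count_must_be_positive(self):
        with pytest.raises(ValidationError):
            AlignmentRecord("r", GenomeInterval("chr1", 0, 10), num_alignments_for_read=0)
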