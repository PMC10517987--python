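"""End-to-end orchestration over a simulated or on-disk dataset.

``run_pipeline`` executes the stages in the order the analysis
prescribes — read filtering, TE scanning and enrichment QC, repeat
aging, transcript classification, fractional quantification,
transcription modes, insertion post-processing, saturation analysis —
writing one TSV/JSON artefact per stage plus a run manifest (config
hash, per-stage record counts).  Completed stages are skipped on rerun
when their outputs already exist, so deleting one stage output
regenerates only it and its dependents.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .insertions import apply_support_threshold, annotate_context, merge_calls
from .modes import assign_modes, autonomy_ratio
from .models import CaptesError
from .quant import fractional_counts
from .report import pattern_counts
from .saturation import data_requirement, fit_curve, subsample_curve
from .synth import (
    SimulationConfig,
    make_host_detector,
    simulate_insertion_calls,
    simulate_reads,
    simulate_reference,
    simulate_sequencing_summary,
    simulate_spikeins,
    simulate_transcripts,
)
from .teannot import AgeModel, flag_young
from .tescan import (
    DEFAULT_MAX_DIVERGENCE,
    DEFAULT_MIN_SCORE,
    DEFAULT_ON_TARGET_WINDOW,
    data_yield,
    is_on_target,
    scan_read,
    side_reaction_rate,
)
from .txclass import classify_transcripts, te_key

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and study conditions for one pipeline run."""

    seed: int = 1
    outdir: str = "captes_run"
    simulation: SimulationConfig | None = None
    min_quality: float = 7.0
    min_length: int = 300
    scan_min_score: float = DEFAULT_MIN_SCORE
    scan_max_divergence: float = DEFAULT_MAX_DIVERGENCE
    on_target_window: int = DEFAULT_ON_TARGET_WINDOW
    min_overlap: int = 20
    merge_gap: int = 200
    substitution_rate: float = 2.2e-9
    young_cutoff_myr: float = 2.0
    saturation_reps: int = 20
    scan_subsample: int = 400  # reads scanned for QC metrics

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, **counts):
        self.stages[stage] = counts


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a synthetic dataset; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation or SimulationConfig(seed=config.seed)
    manifest = RunManifest(config_hash=config.config_hash())

    # stage: simulate -------------------------------------------------------
    ref = simulate_reference(sim)
    txome = simulate_transcripts(ref, sim)
    sim_reads = simulate_reads(ref, txome, sim)
    manifest.record(
        "simulate",
        genes=len(ref.genes),
        te_loci=len(ref.te_loci),
        transcripts=len(txome.transcripts),
        reads=len(sim_reads.reads),
    )

    # stage: filter ---------------------------------------------------------
    filtered_path = outdir / "filtered_reads.fastq"
    if not filtered_path.exists():
        filtered = cio.filter_reads(sim_reads.reads, config.min_quality, config.min_length)
        cio.write_fastq(filtered, filtered_path)
    else:
        filtered = cio.read_fastq(filtered_path)
    manifest.record("filter", reads_in=len(sim_reads.reads), reads_out=len(filtered))

    # stage: scan + QC ------------------------------------------------------
    qc_path = outdir / "qc.json"
    if not qc_path.exists():
        subset = filtered[: config.scan_subsample]
        hits_per_read = [
            scan_read(
                r,
                ref.consensi,
                min_score=config.scan_min_score,
                max_divergence=config.scan_max_divergence,
            )
            for r in subset
        ]
        on_target = sum(
            is_on_target(h, config.on_target_window) for h in hits_per_read
        ) / max(1, len(subset))
        spikes, spike_reads, _spike_truth = simulate_spikeins(ref, txome, sim)
        rate = side_reaction_rate(
            spike_reads,
            spikes,
            make_host_detector(ref, txome),
            min_score=config.scan_min_score,
            max_divergence=config.scan_max_divergence,
        )
        summary = simulate_sequencing_summary(len(filtered), seed=sim.seed + 4)
        qc = {
            "reads_scanned": len(subset),
            "on_target_rate": on_target,
            "side_reaction_rate": rate,
            "data_yield_reads_per_pore_min": data_yield(summary),
        }
        qc_path.write_text(json.dumps(qc, indent=2))
    qc = json.loads(qc_path.read_text())
    manifest.record("scan_qc", **{k: v for k, v in qc.items()})

    # stage: age ------------------------------------------------------------
    aged_path = outdir / "te_aged.tsv"
    if not aged_path.exists():
        model = AgeModel(config.substitution_rate, config.young_cutoff_myr)
        flag_young(ref.te_loci, model)
        pd.DataFrame(
            {
                "chrom": [t.interval.chrom for t in ref.te_loci],
                "start": [t.interval.start for t in ref.te_loci],
                "end": [t.interval.end for t in ref.te_loci],
                "subfamily": [t.subfamily for t in ref.te_loci],
                "milli_div": [t.milli_div for t in ref.te_loci],
                "age_myr": [t.age_myr for t in ref.te_loci],
                "is_young": [t.is_young for t in ref.te_loci],
            }
        ).to_csv(aged_path, sep="\t", index=False)
    aged = pd.read_csv(aged_path, sep="\t")
    manifest.record("age", loci=len(aged), young=int(aged["is_young"].sum()))

    # stage: classify -------------------------------------------------------
    classified_path = outdir / "classified.tsv"
    classified = classify_transcripts(txome.transcripts, ref.genes, ref.te_loci)
    if not classified_path.exists():
        pd.DataFrame(
            {
                "transcript_id": [c.transcript.transcript_id for c in classified],
                "code": [c.code.value for c in classified],
                "context": [c.context.value for c in classified],
                "patterns": [
                    ",".join(sorted(p.value for p in c.patterns)) for c in classified
                ],
                "n_te_overlaps": [len(c.te_overlaps) for c in classified],
                "hosting_gene": [c.hosting_gene or "" for c in classified],
            }
        ).to_csv(classified_path, sep="\t", index=False)
    manifest.record(
        "classify", transcripts=len(classified), **pattern_counts(classified)
    )

    # stage: quantify -------------------------------------------------------
    counts_path = outdir / "te_counts.tsv"
    features = [
        (f"TE{i:04d}", locus.interval) for i, locus in enumerate(ref.te_loci)
    ]
    if not counts_path.exists():
        col = fractional_counts(sim_reads.alignments, features, config.min_overlap)
        col.to_csv(counts_path, sep="\t", header=True)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)["count"]
    manifest.record(
        "quantify", features=len(counts), total_count=float(counts.sum())
    )

    # stage: modes ----------------------------------------------------------
    modes_path = outdir / "modes.tsv"
    if not modes_path.exists():
        tx_counts = sim_reads.truth.groupby("transcript_id").size().to_dict()
        rows = []
        for i, locus in enumerate(ref.te_loci):
            key = te_key(locus)
            containing = [
                c
                for c in classified
                if any(te_key(l) == key for l, _ in c.te_overlaps)
            ]
            if not containing:
                continue
            m = assign_modes(locus, containing, abundances=tx_counts)
            try:
                ratio = autonomy_ratio(m)
            except CaptesError:
                ratio = float("nan")
            rows.append(
                {
                    "te_id": f"TE{i:04d}",
                    "modes": ",".join(sorted(m.modes_present)),
                    "autonomy_ratio": ratio,
                    "total_level": m.total_level,
                }
            )
        pd.DataFrame(rows).to_csv(modes_path, sep="\t", index=False)
    modes_df = pd.read_csv(modes_path, sep="\t")
    manifest.record("modes", te_with_transcripts=len(modes_df))

    # stage: insertions -----------------------------------------------------
    ins_path = outdir / "insertions.tsv"
    if not ins_path.exists():
        rng_positions = [
            (sim.chrom, 50_000 + 37_000 * k, "Alu" if k % 3 else "L1", 8 + (k % 7))
            for k in range(25)
        ]
        raw, _truth = simulate_insertion_calls(rng_positions, seed=sim.seed + 5)
        merged = merge_calls(raw, config.merge_gap)
        kept = apply_support_threshold(merged, estimate=True)
        annotate_context(kept, ref.genes)
        pd.DataFrame(
            {
                "chrom": [c.chrom for c in kept],
                "position": [c.position for c in kept],
                "family": [c.family for c in kept],
                "support": [c.support for c in kept],
                "context": [c.context for c in kept],
                "genes": [",".join(c.gene_ids) for c in kept],
            }
        ).to_csv(ins_path, sep="\t", index=False)
    ins = pd.read_csv(ins_path, sep="\t")
    manifest.record("insertions", calls=len(ins))

    # stage: saturation -----------------------------------------------------
    sat_path = outdir / "saturation.tsv"
    if not sat_path.exists():
        te_reads = sim_reads.truth[sim_reads.truth["head_te"]]
        mapping = dict(zip(te_reads["read_id"], te_reads["transcript_id"]))
        curve = subsample_curve(mapping, reps=config.saturation_reps, seed=sim.seed + 6)
        a, b = fit_curve(curve)
        df = pd.DataFrame(
            {
                "proportion": curve.proportions,
                "mean": curve.mean_identifications,
                "sd": curve.sd_identifications,
            }
        )
        df.attrs["fit"] = (a, b)
        df.to_csv(sat_path, sep="\t", index=False)
        (outdir / "saturation_fit.json").write_text(
            json.dumps(
                {
                    "asymptote": a,
                    "half_saturation": b,
                    "requirement_80pct": data_requirement((a, b), 0.8 * a),
                }
            )
        )
    fit = json.loads((outdir / "saturation_fit.json").read_text())
    manifest.record("saturation", **fit)

    (outdir / "manifest.json").write_text(
        json.dumps({"config_hash": manifest.config_hash, "stages": manifest.stages}, indent=2)
    )
    return outdir
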