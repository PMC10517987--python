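"""Transcription modes of target TE loci.

Every transcript containing a TE locus is assigned exactly one mode at
that locus:

* **autonomous** — the transcript is fully intronic or intergenic and
  its first transcribed base lies inside the TE, i.e. the TE's own
  promoter drives transcription;
* **intron retention** — the transcript retains an intron and the TE
  overlap lies strictly downstream (strand-aware) of the transcript's
  start;
* **passive** — anything else (the TE rides along inside a host
  transcript).

Precedence is autonomous > intron retention > passive, so a TE that
both contains the TSS and sits in a retained intron counts as
autonomous.  The autonomy ratio of a locus is the summed (normalised)
abundance of its autonomous transcripts over the summed abundance of
all transcripts containing the locus, ranging from 0 (purely passive)
to 1 (fully autonomous).  A transcript containing several TE loci is
credited in full to each locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .models import CaptesError, TELocus
from .txclass import ClassifiedTranscript, ContextCategory, PatternCategory, te_key

__all__ = ["TELocusModes", "assign_modes", "autonomy_ratio", "mode_contribution", "MODES"]

MODES = ("autonomous", "intron_retention", "passive")


@dataclass
class TELocusModes:
    te: TELocus
    mode_transcripts: dict[str, set[str]] = field(
        default_factory=lambda: {m: set() for m in MODES}
    )
    mode_levels: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in MODES})
    total_level: float = 0.0

    @property
    def modes_present(self) -> set[str]:
        return {m for m, txs in self.mode_transcripts.items() if txs}

    @property
    def is_multimodal(self) -> bool:
        return len(self.modes_present) > 1


def _mode_of(te: TELocus, ct: ClassifiedTranscript) -> str:
    t = ct.transcript
    te_iv = te.interval
    contains_tss = te_iv.start <= t.tss < te_iv.end
    if contains_tss and ct.context in (ContextCategory.INTRONIC, ContextCategory.INTERGENIC):
        return "autonomous"
    if PatternCategory.INTRON_RETENTION in ct.patterns:
        # TE overlap strictly 3' of the first transcribed base
        if t.strand == "-":
            downstream = te_iv.end <= t.tss  # te_iv.end is exclusive
        else:
            downstream = te_iv.start > t.tss
        if downstream and not contains_tss:
            return "intron_retention"
    return "passive"


def assign_modes(
    te: TELocus,
    classified: Sequence[ClassifiedTranscript],
    abundances: Mapping[str, float] | None = None,
) -> TELocusModes:
    """Partition the transcripts containing ``te`` into modes.

    ``abundances`` maps transcript id to normalised expression; when
    given, per-mode and total levels are accumulated.  Transcripts that
    do not overlap the TE are ignored with a warning.
    """
    key = te_key(te)
    result = TELocusModes(te=te)
    for ct in classified:
        if not any(te_key(locus) == key for locus, _role in ct.te_overlaps):
            warnings.warn(
                f"transcript {ct.transcript.transcript_id} does not overlap TE "
                f"{te.subfamily}@{te.interval.chrom}:{te.interval.start}; ignored",
                stacklevel=2,
            )
            continue
        mode = _mode_of(te, ct)
        tid = ct.transcript.transcript_id
        result.mode_transcripts[mode].add(tid)
        if abundances is not None:
            level = float(abundances.get(tid, 0.0))
            result.mode_levels[mode] += level
            result.total_level += level
    return result


def autonomy_ratio(modes: TELocusModes, abundances: Mapping[str, float] | None = None) -> float:
    """Autonomous abundance over total TE-containing abundance, in [0, 1]."""
    if abundances is not None:
        auto = sum(abundances.get(t, 0.0) for t in modes.mode_transcripts["autonomous"])
        total = sum(
            abundances.get(t, 0.0) for txs in modes.mode_transcripts.values() for t in txs
        )
    else:
        auto = modes.mode_levels["autonomous"]
        total = modes.total_level
    if total <= 0:
        raise CaptesError("total TE-containing abundance is zero; ratio undefined")
    return auto / total


def mode_contribution(modes: TELocusModes, host_gene_level: float) -> dict[str, float]:
    """Per-mode abundance relative to the host gene's overall expression."""
    if host_gene_level <= 0:
        raise CaptesError("host gene level must be positive")
    contributions = {m: modes.mode_levels[m] / host_gene_level for m in MODES}
    if sum(contributions.values()) > 1.0 + 1e-9:
        warnings.warn(
            "mode contributions exceed the host gene level; some transcripts "
            "may not be attributed to this gene",
            stacklevel=2,
        )
    return contributions
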