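"""Summary statistics reported by the pipeline.

Small arithmetic utilities used when comparing locus catalogues between
methods and when summarising the transcript-pattern taxonomy.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

from .models import ValidationError
from .txclass import ClassifiedTranscript, PatternCategory

__all__ = [
    "detection_rate",
    "pattern_counts",
    "splicing_mediated_total",
]


def detection_rate(n_detected: int, n_union: int) -> tuple[float, int]:
    """Detection rate (%) and undetected count of a method vs a union catalogue.

    ``n_detected`` is the number of loci the method found; ``n_union``
    the number found by any method.  Returns (100 * detected/union,
    union - detected).
    """
    if n_union <= 0:
        raise ValidationError("union catalogue is empty")
    if n_detected > n_union:
        raise ValidationError("detected count exceeds the union count")
    return 100.0 * n_detected / n_union, n_union - n_detected


def pattern_counts(
    classified: Iterable[ClassifiedTranscript],
) -> dict[str, int]:
    """Number of noncanonical transcripts per transcription pattern.

    A transcript with several patterns (alt TSS + alt TES) counts once
    under each.
    """
    counts: Counter[str] = Counter()
    for ct in classified:
        if ct.is_canonical:
            continue
        for p in ct.patterns:
            counts[p.value] += 1
    return dict(counts)


def splicing_mediated_total(counts: Mapping[str, int]) -> int:
    """Splicing-mediated noncanonical transcripts: intron retention plus
    noncanonical splicing junction transcripts."""
    return counts.get(PatternCategory.INTRON_RETENTION.value, 0) + counts.get(
        PatternCategory.NONCANONICAL_SPLICING.value, 0
    )
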