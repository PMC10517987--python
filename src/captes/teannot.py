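"""Repeat aging from milliDivergence under the Jukes-Cantor model.

A TE copy's divergence from its subfamily consensus (milliDiv,
mismatches per kb) is corrected for multiple substitutions with the
Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) and converted to an age
in million years by dividing by a neutral substitution rate.  The copy
is treated as a single lineage diverging from the (ancestral) consensus,
so age = d / mu; the default rate mu = 2.2e-9 substitutions per site
per year is the conventional human neutral rate.  Both the rate and the
young-TE cutoff (2 Myr) are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .models import TELocus, ValidationError

__all__ = [
    "AgeModel",
    "jc_distance",
    "te_age_myr",
    "flag_young",
    "young_milli_div_cutoff",
    "SaturationError",
]


class SaturationError(ValidationError):
    """Observed divergence is at or past the JC saturation point (p >= 3/4)."""


@dataclass(frozen=True)
class AgeModel:
    """Substitution rate (per site per year) and the young-TE age cutoff."""

    substitution_rate: float = 2.2e-9
    young_cutoff_myr: float = 2.0

    def __post_init__(self):
        if self.substitution_rate <= 0 or self.young_cutoff_myr <= 0:
            raise ValidationError("rate and cutoff must be positive")


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance for an observed mismatch proportion ``p``."""
    if not 0.0 <= p < 0.75:
        raise SaturationError(f"mismatch proportion {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def te_age_myr(milli_div: float, model: AgeModel = AgeModel()) -> float:
    """Age in million years from milliDiv (mismatches per kb)."""
    d = jc_distance(milli_div / 1000.0)
    return d / model.substitution_rate / 1e6


def young_milli_div_cutoff(model: AgeModel = AgeModel()) -> float:
    """The milliDiv below which a locus is younger than the cutoff.

    Inverts the JC formula at d = cutoff_myr * 1e6 * mu.
    """
    d = model.young_cutoff_myr * 1e6 * model.substitution_rate
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    return p * 1000.0


def flag_young(
    loci: Sequence[TELocus], model: AgeModel = AgeModel()
) -> list[TELocus]:
    """Fill ``age_myr`` and ``is_young`` (strict: age < cutoff) in place."""
    for locus in loci:
        locus.age_myr = te_age_myr(locus.milli_div, model)
        locus.is_young = locus.age_myr < model.young_cutoff_myr
    return list(loci)
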