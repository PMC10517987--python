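"""Saturation analysis of TE-containing transcript discovery.

Reads are subsampled without replacement at proportions 0.05..1.00 in
steps of 0.05, 50 replicates per proportion; at each draw the number of
distinct transcripts identified by the sampled reads is recorded.  The
mean curve is fitted with a two-parameter saturating hyperbola
y = a*x / (b + x) (a = asymptotic number of identifiable transcripts,
b = half-saturation data amount), which is then inverted to extrapolate
the data amount required for a target identification count:
x = b*t / (a - t), converted to gigabases via the mean per-read yield.

For validation, the expected number of distinct transcripts in a
sample of k of N reads has the closed hypergeometric-complement form
E[S_k] = sum_t [1 - C(N - n_t, k) / C(N, k)] over transcripts t with
n_t supporting reads; the Monte-Carlo means must agree with it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gammaln

from .models import CaptesError, ValidationError

__all__ = [
    "SaturationCurve",
    "subsample_curve",
    "fit_curve",
    "data_requirement",
    "expected_distinct",
    "DEFAULT_PROPORTIONS",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))


@dataclass
class SaturationCurve:
    proportions: np.ndarray
    replicates: int
    mean_identifications: np.ndarray
    sd_identifications: np.ndarray
    n_reads: int
    fitted_params: tuple[float, float] | None = None  # (a, b)

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.mean_identifications = np.asarray(self.mean_identifications, dtype=float)
        self.sd_identifications = np.asarray(self.sd_identifications, dtype=float)
        if np.any(np.diff(self.proportions) <= 0):
            raise ValidationError("proportions must be strictly increasing")
        if np.any(self.mean_identifications < 0):
            raise ValidationError("mean identifications must be non-negative")


def subsample_curve(
    read_to_transcript: Mapping[str, str],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    reps: int = 50,
    seed: int = 0,
) -> SaturationCurve:
    """Monte-Carlo saturation curve of distinct-transcript discovery.

    ``read_to_transcript`` maps each TE-containing read to the
    transcript it identifies.  For every proportion p, ``reps`` draws
    of round(p*N) reads are taken without replacement and the number of
    distinct transcripts among them recorded.  At p = 1 the draw is the
    whole read set, so the mean equals the total distinct count and the
    sd is 0.
    """
    if not read_to_transcript:
        raise ValidationError("empty read-to-transcript mapping")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    proportions = np.asarray(sorted(proportions), dtype=float)
    if proportions.size == 0:
        raise ValidationError("empty proportion grid")
    if proportions[0] <= 0 or proportions[-1] > 1:
        raise ValidationError("proportions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    # encode transcripts as integers for fast distinct counting
    tx_ids = {t: i for i, t in enumerate(sorted(set(read_to_transcript.values())))}
    labels = np.array([tx_ids[t] for _r, t in sorted(read_to_transcript.items())])
    n = labels.size
    means, sds = [], []
    for p in proportions:
        k = int(round(p * n))
        k = max(k, 0)
        if k == 0:
            means.append(0.0)
            sds.append(0.0)
            continue
        counts = np.empty(reps, dtype=float)
        for r in range(reps):
            idx = rng.choice(n, size=k, replace=False)
            counts[r] = np.unique(labels[idx]).size
        means.append(float(counts.mean()))
        sds.append(float(counts.std(ddof=0)))
    return SaturationCurve(
        proportions=proportions,
        replicates=reps,
        mean_identifications=np.array(means),
        sd_identifications=np.array(sds),
        n_reads=n,
    )


def expected_distinct(transcript_read_counts: Sequence[int], k: int) -> float:
    """Exact E[distinct transcripts] in a draw of ``k`` of N reads.

    Hypergeometric complement: each transcript with n_t reads is missed
    with probability C(N - n_t, k) / C(N, k).
    """
    counts = np.asarray(transcript_read_counts, dtype=int)
    n_total = int(counts.sum())
    if not 0 <= k <= n_total:
        raise ValidationError(f"k={k} outside [0, {n_total}]")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for n_t in counts:
        if n_total - n_t < k:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(n_total - n_t, k) - log_comb(n_total, k))
    return float(total)


def _hyperbola(x, a, b):
    return a * x / (b + x)


def fit_curve(
    curve: SaturationCurve, x_units: Sequence[float] | None = None
) -> tuple[float, float]:
    """Least-squares fit of y = a*x/(b + x) to the mean curve.

    ``x_units`` overrides the x-axis (e.g. gigabases instead of
    subsampling proportion); by default the proportion grid is used.
    Returns (a, b), both positive, and stores them on the curve.
    """
    if curve.proportions.size < 5:
        raise ValidationError("need >= 5 grid points to fit")
    x = np.asarray(x_units, dtype=float) if x_units is not None else curve.proportions
    y = curve.mean_identifications
    a0 = max(float(y[-1]), 1.0)
    b0 = max(float(x[len(x) // 4]), 1e-6)
    try:
        params, _cov = curve_fit(
            _hyperbola, x, y, p0=(a0 * 1.2, b0), bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise CaptesError(f"saturation fit did not converge: {exc}")
    a, b = float(params[0]), float(params[1])
    curve.fitted_params = (a, b)
    return a, b


def data_requirement(
    params: tuple[float, float],
    target_identifications: float,
    gb_per_unit: float = 1.0,
) -> float:
    """Data amount (in Gb) needed to reach a target identification count.

    Inverts the fitted hyperbola: x = b*t / (a - t).  ``gb_per_unit``
    converts the fit's x-units (proportion or reads) to gigabases.
    The target must lie below the fitted asymptote ``a``.
    """
    a, b = params
    if target_identifications >= a:
        raise CaptesError(
            f"target {target_identifications} is at or above the asymptote {a}; unreachable"
        )
    if target_identifications < 0:
        raise ValidationError("target must be non-negative")
    x = b * target_identifications / (a - target_identifications)
    return x * gb_per_unit
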