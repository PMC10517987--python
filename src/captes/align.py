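"""Affine-gap Smith-Waterman local alignment.

The scanner uses a simple DNA scheme (match 5, mismatch -5, gap open
-10, gap extend -5): the open score is charged for the first base of a
gap and the extend score for each subsequent base, so a gap of length L
costs 10 + 5*(L-1).  `N` never matches anything, including another `N`.

The forward fill is numba-compiled; the traceback is done in Python on
the returned score matrices.  Among co-optimal alignments the one with
the smallest ``(query_start, target_start)`` is reported, which makes
results deterministic and reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .models import ValidationError

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "local_align",
    "reverse_complement",
    "DEFAULT_SCHEME",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base encoding: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores; penalties are non-positive by convention."""

    match: float = 5.0
    mismatch: float = -5.0
    gap_open: float = -10.0
    gap_extend: float = -5.0

    def __post_init__(self):
        if self.match <= 0:
            raise ValidationError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("mismatch/gap scores must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class LocalAlignment:
    """Result of one local alignment (all coordinates 0-based half-open)."""

    score: float
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0
    n_aligned: int = 0
    n_mismatch: int = 0
    n_gap_positions: int = 0

    @property
    def divergence(self) -> float:
        """Mismatch fraction over aligned (non-gap) columns."""
        if self.n_aligned == 0:
            return 0.0
        return self.n_mismatch / self.n_aligned

    @property
    def is_empty(self) -> bool:
        return self.n_aligned == 0 and self.n_gap_positions == 0


NEG_INF = np.float64(-1e18)


@njit(cache=True)
def _sw_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), NEG_INF, np.float64)  # gap in query (consumes target)
    F = np.full((n + 1, m + 1), NEG_INF, np.float64)  # gap in target (consumes query)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            f = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            if qi == 4 or t[j - 1] == 4:
                s = mismatch
            elif qi == t[j - 1]:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


def _traceback(H, E, F, q, t, scheme, i, j):
    """Walk back from endpoint (i, j) in state H; returns path stats."""
    match, mismatch = scheme.match, scheme.mismatch
    gap_open, gap_extend = scheme.gap_open, scheme.gap_extend
    n_match = n_mismatch = n_gap = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0.0:
                break
            qi, tj = q[i - 1], t[j - 1]
            s = mismatch if (qi == 4 or tj == 4 or qi != tj) else match
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                if s == match:
                    n_match += 1
                else:
                    n_mismatch += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # numerical impossibility guard
                raise AssertionError("traceback failed")
        elif state == "E":
            n_gap += 1
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            n_gap += 1
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"
    return i, j, n_match, n_mismatch, n_gap


def local_align(
    query: str, target: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> LocalAlignment:
    """Best local alignment of ``query`` against ``target``.

    Returns an empty alignment with score 0 when either sequence is
    empty or no positive-scoring alignment exists.  Co-optimal
    alignments are resolved to the smallest ``(query_start,
    target_start, query_end, target_end)``.
    """
    if not query or not target:
        return LocalAlignment(score=0.0)
    q = _encode(query)
    t = _encode(target)
    H, E, F = _sw_fill(
        q, t, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
    )
    best = H.max()
    if best <= 0.0:
        return LocalAlignment(score=0.0)
    endpoints = np.argwhere(H == best)
    candidates = []
    for i_end, j_end in endpoints:
        i0, j0, n_match, n_mismatch, n_gap = _traceback(
            H, E, F, q, t, scheme, int(i_end), int(j_end)
        )
        candidates.append(
            (
                i0,
                j0,
                int(i_end),
                int(j_end),
                n_match,
                n_mismatch,
                n_gap,
            )
        )
    i0, j0, i1, j1, n_match, n_mismatch, n_gap = min(candidates)
    return LocalAlignment(
        score=float(best),
        query_start=i0,
        query_end=i1,
        target_start=j0,
        target_end=j1,
        n_aligned=n_match + n_mismatch,
        n_mismatch=n_mismatch,
        n_gap_positions=n_gap,
    )
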