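"""Association-number statistics: F_n / F_w, averages, unimer fractions,
and the main-peak/tail decomposition.

For aggregate counts c(A) pooled over frames (A = association number,
unit bins starting at 1):

* number fraction      F_n(A) = c(A) / sum_A c(A)
* weight fraction      F_w(A) = A c(A) / sum_A A c(A)
* number average       <A>_n = sum A F_n(A)
* weight average       <A>_w = sum A^2 c(A) / sum A c(A)

f_1 is the number fraction of unimers; f_low additionally includes the low
associates up to the interior minimum of the (smoothed) F_n between the
unimer peak and the main associate peak.  The main-peak/tail split of F_w
is placed at the maximum of the discrete second derivative of the
smoothed F_w beyond its mode — where the convex shoulder of the main peak
hands over to the slowly decaying tail of rod-like associates.

Smoothing is a centred moving average over 3 bins by default (window
configurable); ties in minima or curvature maxima resolve to the smallest
A for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .aggregates import AggregateSet

__all__ = [
    "DistributionSet",
    "compute_distributions",
    "unimer_fractions",
    "split_main_tail",
    "smooth",
]


@dataclass
class DistributionSet:
    """Histogram pair over association numbers plus summary statistics."""

    A: np.ndarray  # unit bins 1..A_max
    F_n: np.ndarray
    F_w: np.ndarray
    An_avg: float
    Aw_avg: float
    f_1: float
    f_low: float
    split_As: int
    n_frames: int = 1

    def summary(self) -> dict:
        return {
            "An_avg": self.An_avg,
            "Aw_avg": self.Aw_avg,
            "f_1": self.f_1,
            "f_low": self.f_low,
            "split_As": self.split_As,
        }


def smooth(y: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average with edge truncation (window must be odd)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1 or len(y) < 2:
        return np.asarray(y, dtype=float)
    half = window // 2
    out = np.empty(len(y))
    for i in range(len(y)):
        lo, hi = max(0, i - half), min(len(y), i + half + 1)
        out[i] = np.mean(y[lo:hi])
    return out


def _histogram(aggsets: list[AggregateSet]) -> np.ndarray:
    sizes = np.concatenate([s.sizes for s in aggsets]) if aggsets else np.array([], int)
    if sizes.size == 0:
        raise ValueError("no aggregates to histogram")
    counts = np.bincount(sizes)[1:]  # drop the empty A=0 bin
    return counts.astype(float)


def compute_distributions(
    aggsets: list[AggregateSet], window: int = 3
) -> DistributionSet:
    """Pool aggregate sizes over frames into F_n/F_w and summary statistics.

    Frame order never matters (pure pooling).  Raises if no frame holds any
    aggregate.
    """
    counts = _histogram(aggsets)
    A = np.arange(1, len(counts) + 1, dtype=np.int64)
    F_n = counts / counts.sum()
    wk = A * counts
    F_w = wk / wk.sum()
    An_avg = float((A * F_n).sum())
    Aw_avg = float((A * A * counts).sum() / wk.sum())
    f_1, f_low = unimer_fractions(A, F_n, window=window)
    split = split_main_tail(A, F_w, window=window)
    return DistributionSet(
        A=A, F_n=F_n, F_w=F_w, An_avg=An_avg, Aw_avg=Aw_avg,
        f_1=f_1, f_low=f_low, split_As=split, n_frames=len(aggsets),
    )


def unimer_fractions(
    A: np.ndarray, F_n: np.ndarray, window: int = 3
) -> tuple[float, float]:
    """Number fractions of unimers (f_1) and of unimers-plus-low-associates (f_low).

    f_low sums F_n up to the interior minimum of the smoothed F_n between
    the unimer peak and the main associate peak.  When no interior minimum
    exists (monotone or unimodal-at-1 distributions) f_low falls back to
    f_1 with a warning.
    """
    A = np.asarray(A)
    F_n = np.asarray(F_n, dtype=float)
    f_1 = float(F_n[0]) if A[0] == 1 else 0.0
    s = smooth(F_n, window)
    if len(A) < 3:
        return f_1, f_1
    # first interior turning point of the smoothed curve: the dip between
    # the unimer peak and the associate peak (ties resolve to smallest A)
    for m in range(1, len(s) - 1):
        if s[m] <= s[m - 1] and s[m] < s[m + 1]:
            break
    else:
        warnings.warn("no interior minimum between unimer and associate peaks; "
                      "f_low = f_1", stacklevel=2)
        return f_1, f_1
    f_low = float(F_n[: m + 1].sum())
    return f_1, f_low


def split_main_tail(A: np.ndarray, F_w: np.ndarray, window: int = 3) -> int:
    """Main-peak/tail boundary of the weight distribution.

    Returns the association number at the maximum of the discrete second
    derivative of the smoothed F_w beyond the main-peak mode; masses at or
    below the split belong to the main peak (roughly spherical micelles),
    masses above it to the tail (elongated associates).  A distribution
    with no interior structure past its mode returns the largest A with a
    warning.
    """
    A = np.asarray(A)
    F_w = np.asarray(F_w, dtype=float)
    if len(A) < 3:
        warnings.warn("distribution too short to split; returning max A", stacklevel=2)
        return int(A[-1])
    s = smooth(F_w, window)
    mode = int(np.argmax(s))
    if mode == 0:
        warnings.warn("weight distribution has no main associate peak; "
                      "returning max A", stacklevel=2)
        return int(A[-1])
    if mode >= len(A) - 2:
        warnings.warn("no region beyond the main peak; returning max A", stacklevel=2)
        return int(A[-1])
    d2 = np.diff(s, 2)  # d2[k] is curvature at index k+1
    region = d2[mode:]  # curvature at indices mode+1 .. len-2
    k = int(np.argmax(region))  # ties -> smallest A
    return int(A[mode + 1 + k])
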