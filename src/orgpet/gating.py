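"""Amplitude-based optimal respiratory gating (ORG).

Given a surrogate amplitude trace and a duty cycle (the fraction of acquired
data to keep), ORG scans candidate lower limits L; for each L the upper limit
U is the smallest value such that [L, U] contains the prescribed fraction of
samples, and the optimal window is the one minimizing the width W = U - L.
Frames whose amplitude falls inside the window form the gated reconstruction.

``optimal_amplitude_window`` is the O(n log n) sorted sliding window;
``brute_force_window`` is the exhaustive O(n^2) search over all sample-value
pairs and exists as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import FrameStack, PhantomImage, RespiratoryTrace, sum_frames

__all__ = [
    "GatingWindow",
    "optimal_amplitude_window",
    "brute_force_window",
    "select_frames",
    "gated_image",
]


@dataclass(frozen=True)
class GatingWindow:
    """Amplitude window [L, U] with width W = U - L and the achieved duty."""

    lower_L_mm: float
    upper_U_mm: float
    width_W_mm: float
    achieved_duty: float

    def __post_init__(self) -> None:
        if self.upper_U_mm < self.lower_L_mm:
            raise ValueError("upper limit must be >= lower limit")
        if abs(self.width_W_mm - (self.upper_U_mm - self.lower_L_mm)) > 1e-12:
            raise ValueError("width_W_mm must equal U - L")
        if not (0.0 < self.achieved_duty <= 1.0):
            raise ValueError("achieved_duty must lie in (0, 1]")


def _required_count(n: int, duty: float) -> int:
    if not (0.0 < duty <= 1.0):
        raise ValueError("duty must lie in (0, 1]")
    # ceil with guard against float fuzz on exact multiples
    return min(n, max(1, math.ceil(duty * n - 1e-12)))


def _window_from_limits(amps: np.ndarray, lo: float, hi: float) -> GatingWindow:
    inside = int(np.count_nonzero((amps >= lo) & (amps <= hi)))
    return GatingWindow(float(lo), float(hi), float(hi - lo), inside / len(amps))


def optimal_amplitude_window(trace: RespiratoryTrace, duty: float) -> GatingWindow:
    """Smallest window [L, U] covering at least ceil(duty * n) samples.

    L and U are attained sample amplitudes; ties in minimal width are broken
    by the smallest L (the end-expiration side).  Sorted sliding window of
    size k = ceil(duty * n).
    """
    amps = np.asarray(trace.amplitudes_mm, dtype=np.float64)
    n = len(amps)
    if n < 2:
        raise ValueError("trace needs at least 2 samples")
    k = _required_count(n, duty)
    a = np.sort(amps)
    widths = a[k - 1 :] - a[: n - k + 1]
    i = int(np.argmin(widths))  # first occurrence -> smallest L (a is sorted)
    return _window_from_limits(amps, a[i], a[i + k - 1])


def brute_force_window(trace: RespiratoryTrace, duty: float) -> GatingWindow:
    """Exhaustive search over all ordered sample-value pairs (test oracle).

    Same contract as :func:`optimal_amplitude_window`; intended for n <= 5000.
    """
    amps = np.asarray(trace.amplitudes_mm, dtype=np.float64)
    n = len(amps)
    if n < 2:
        raise ValueError("trace needs at least 2 samples")
    k = _required_count(n, duty)
    a = np.sort(amps)
    # coverage of [a[i], a[j]] counting duplicates on both ends
    lo_idx = np.searchsorted(a, a, side="left")
    hi_idx = np.searchsorted(a, a, side="right")
    counts = hi_idx[None, :] - lo_idx[:, None]  # counts[i, j] for pair (a[i], a[j])
    widths = a[None, :] - a[:, None]
    valid = (widths >= 0) & (counts >= k)
    if not valid.any():
        raise ValueError("no window satisfies the duty requirement")
    w = np.where(valid, widths, np.inf)
    best_w = w.min()
    ii, jj = np.nonzero(w <= best_w + 0.0)
    order = np.lexsort((a[jj], a[ii]))  # smallest L, then smallest U
    i, j = ii[order[0]], jj[order[0]]
    return _window_from_limits(amps, a[i], a[j])


def select_frames(trace: RespiratoryTrace, window: GatingWindow) -> np.ndarray:
    """Indices of trace samples with amplitude inside the closed window."""
    amps = np.asarray(trace.amplitudes_mm, dtype=np.float64)
    return np.nonzero((amps >= window.lower_L_mm) & (amps <= window.upper_U_mm))[0]


def gated_image(stack: FrameStack, duty: float) -> PhantomImage:
    """ORG image: mean over the frames inside the optimal amplitude window."""
    window = optimal_amplitude_window(stack.trace, duty)
    return sum_frames(stack, select_frames(stack.trace, window))
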