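"""Apex-frame detection by binary search over strain sums.

The apex frame is where facial action amplitude peaks within a clip.  The
search keeps an interval [lo, hi] of strain-series positions, compares the
inclusive strain sums of the two halves [lo, mid] and [mid, hi], and keeps
the heavier half (ties keep the upper half).  On a unimodal strain series
this homes in on the peak to within one frame in O(log N) comparisons.

As published, the halving loop can stall once the interval has shrunk to
two entries (mid == lo and the "keep upper" branch no longer shrinks it);
we terminate at interval width <= 1 and return the endpoint with the larger
strain value, which preserves the comparison logic and guarantees
termination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .strain import StrainSeries


class ApexError(ValueError):
    pass


@dataclass
class ApexSearchState:
    """Trace of one binary apex search, for diagnostics and tests."""

    result: int = -1
    iterations: int = 0
    trace: list[tuple[int, int]] = field(default_factory=list)
    no_motion: bool = False


def _as_values(series) -> np.ndarray:
    v = series.values if isinstance(series, StrainSeries) else np.asarray(series, float)
    if v.ndim != 1 or v.size == 0:
        raise ApexError("strain series must be a non-empty 1-D array")
    if (v < 0).any():
        raise ApexError("strain series must be non-negative")
    return v


def binary_apex_search(series, state: ApexSearchState | None = None) -> int:
    """Position of the apex in the strain series (binary search).

    Returns a *series* position; the apex frame of the clip is
    ``StrainSeries.frame_of(position)`` (the later frame of the pair).
    """
    v = _as_values(series)
    if state is None:
        state = ApexSearchState()
    if not v.any():
        warnings.warn("no motion detected: strain series is all zero", stacklevel=2)
        state.no_motion = True
    lo, hi = 0, v.size - 1
    state.trace.append((lo, hi))
    while hi - lo > 1:
        mid = (lo + hi) // 2
        sum1 = v[lo : mid + 1].sum()  # inclusive [lo, mid]
        sum2 = v[mid : hi + 1].sum()  # inclusive [mid, hi]
        if sum1 <= sum2:
            lo = mid
        else:
            hi = mid
        state.iterations += 1
        state.trace.append((lo, hi))
    # interval width <= 1: pick the larger endpoint, ties keep the upper
    result = hi if (lo != hi and v[lo] <= v[hi]) else lo
    if lo != hi:
        state.iterations += 1
    state.result = result
    return result


def brute_force_apex(series) -> int:
    """Exact argmax of the strain series (first position on ties).

    Independent reference for the binary search; linear scan by definition.
    """
    v = _as_values(series)
    return int(np.argmax(v))


def apex_frame(series, method: str = "binary") -> int:
    """Apex frame index of the clip (frame coordinates, not series position)."""
    pos = binary_apex_search(series) if method == "binary" else brute_force_apex(series)
    return StrainSeries.frame_of(pos)
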