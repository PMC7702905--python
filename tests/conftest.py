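import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment


def support_jaccards(W, supports, thresh=0.1):
    """Best-assignment Jaccard overlap of learned W columns vs planted supports.

    A column's support is its entries above ``thresh`` of the column max.
    """
    k = W.shape[1]
    J = np.zeros((k, len(supports)))
    for a in range(k):
        sup = set(np.flatnonzero(W[:, a] > thresh * W[:, a].max()))
        for b, s in enumerate(supports):
            s = set(s)
            J[a, b] = len(sup & s) / len(sup | s)
    rows, cols = linear_sum_assignment(-J)
    return J[rows, cols]


def random_unimodal_series(rng, min_len=8, max_len=256):
    """Strictly unimodal peak-dominated series with a random peak position.

    Values decay by a factor of at least 2 per step away from the peak, the
    concentration a localized motion burst produces in a strain series.
    Under that dominance the peak value exceeds the sum of all others, so
    the half-sum comparison of the binary apex search provably tracks the
    peak (flat-peaked unimodal series carry no such guarantee).
    """
    n = int(rng.integers(min_len, max_len + 1))
    peak = int(rng.integers(0, n))
    scale = rng.uniform(1.0, 10.0)
    series = np.empty(n)
    series[peak] = scale
    for k in range(peak - 1, -1, -1):
        series[k] = series[k + 1] * rng.uniform(0.25, 0.5)
    for k in range(peak + 1, n):
        series[k] = series[k - 1] * rng.uniform(0.25, 0.5)
    return series, peak


def landmarks_template(points_overrides=None, frame_size=(600, 800)):
    """A valid 68-point layout with selected indices overridden for a test."""
    from microexpr.synth import synthetic_landmarks

    lm = synthetic_landmarks(frame_size)
    if points_overrides:
        pts = lm.points.copy()
        for idx, (x, y) in points_overrides.items():
            pts[idx] = (x, y)
        from microexpr.roi import LandmarkSet

        lm = LandmarkSet(points=pts, frame_size=frame_size)
    return lm


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
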