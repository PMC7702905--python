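"""Optical strain from dense optical flow.

Optical strain measures non-rigid deformation: it is built from the spatial
derivatives of the flow field, so a rigid translation (spatially constant
flow) produces zero strain while localized muscle motion produces a strain
peak at the moving region's boundary.  Per-frame strain sums over the facial
RoIs are the signal the apex-frame search operates on.

Two tensor conventions are supported.  The default ("printed") uses

    eps_xx = dvx/dx            eps_yx = (dvx/dy + dvy/dx) / 2
    eps_xy = (dvx/dx + dvy/dy) / 2   eps_yy = dvy/dy

i.e. the off-diagonal eps_xy is half the divergence.  The "symmetric"
convention instead sets eps_xy = eps_yx (the standard infinitesimal strain
tensor).  The scalar strain is the root-sum-of-squares of the four
components in either convention.

Axes: x is horizontal (columns), y vertical (rows).  Derivatives use central
differences in the interior and one-sided differences at borders, which are
exact on linear flow fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .containers import FrameSequence
from .roi import RoIBox


class StrainError(ValueError):
    pass


@dataclass
class FlowField:
    """Per-pixel displacement between two frames (pixels/frame)."""

    v_x: np.ndarray
    v_y: np.ndarray

    def __post_init__(self) -> None:
        self.v_x = np.asarray(self.v_x, dtype=float)
        self.v_y = np.asarray(self.v_y, dtype=float)
        if self.v_x.shape != self.v_y.shape or self.v_x.ndim != 2:
            raise StrainError("v_x and v_y must be 2-D arrays of equal shape")
        if not (np.isfinite(self.v_x).all() and np.isfinite(self.v_y).all()):
            raise StrainError("flow field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.v_x.shape


@dataclass
class StrainField:
    """The four strain-tensor components and the scalar strain magnitude."""

    eps_xx: np.ndarray
    eps_yx: np.ndarray
    eps_xy: np.ndarray
    eps_yy: np.ndarray
    eps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eps is None:
            self.eps = strain_magnitude(self)


@dataclass
class StrainSeries:
    """Per-frame-pair RoI strain sums for a clip of N frames.

    ``values[i]`` summarizes motion from frame i to frame i+1, i.e. it is
    indexed to the *later* frame i+1 of the pair; there are N-1 entries.
    ``per_roi`` optionally keeps a per-RoI breakdown for diagnostics.
    """

    values: np.ndarray
    per_roi: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise StrainError("strain series must be a non-empty 1-D array")
        if (self.values < 0).any():
            raise StrainError("strain sums must be non-negative")

    def __len__(self) -> int:
        return self.values.size

    @staticmethod
    def frame_of(series_index: int) -> int:
        """Convert a series position to the (later) frame index it describes."""
        return series_index + 1


FlowEstimator = Callable[[np.ndarray, np.ndarray], FlowField]


def tvl1_flow(frame0: np.ndarray, frame1: np.ndarray) -> FlowField:
    """Default dense variational (TV-L1) flow estimator."""
    from skimage.registration import optical_flow_tvl1

    v_row, v_col = optical_flow_tvl1(
        np.asarray(frame0, dtype=float), np.asarray(frame1, dtype=float)
    )
    return FlowField(v_x=v_col, v_y=v_row)


def strain_tensor(flow: FlowField, convention: str = "printed") -> StrainField:
    """Strain-tensor components of a flow field.

    ``convention`` is "printed" (default, eps_xy = half-divergence) or
    "symmetric" (eps_xy = eps_yx).
    """
    if flow.v_x.shape[0] < 2 or flow.v_x.shape[1] < 2:
        raise StrainError("flow field must be at least 2x2 pixels")
    dvx_dy, dvx_dx = np.gradient(flow.v_x)
    dvy_dy, dvy_dx = np.gradient(flow.v_y)
    eps_xx = dvx_dx
    eps_yy = dvy_dy
    eps_yx = 0.5 * (dvx_dy + dvy_dx)
    if convention == "printed":
        eps_xy = 0.5 * (dvx_dx + dvy_dy)
    elif convention == "symmetric":
        eps_xy = eps_yx
    else:
        raise StrainError(f"unknown strain convention: {convention!r}")
    return StrainField(eps_xx=eps_xx, eps_yx=eps_yx, eps_xy=eps_xy, eps_yy=eps_yy)


def strain_magnitude(t: StrainField) -> np.ndarray:
    """Pixelwise scalar strain: root-sum-of-squares of the four components."""
    return np.sqrt(t.eps_xx**2 + t.eps_yx**2 + t.eps_xy**2 + t.eps_yy**2)


def _roi_mask(shape: tuple[int, int], boxes: Sequence[RoIBox],
              exclude_border: int) -> np.ndarray:
    """Boolean union of the RoI boxes, minus a border frame of the image."""
    mask = np.zeros(shape, dtype=bool)
    for b in boxes:
        mask[b.top : b.bottom, b.left : b.right] = True
    if exclude_border > 0:
        k = exclude_border
        mask[:k, :] = False
        mask[-k:, :] = False
        mask[:, :k] = False
        mask[:, -k:] = False
    return mask


def sequence_strain(
    seq: FrameSequence,
    boxes: Sequence[RoIBox],
    flow_fn: FlowEstimator = tvl1_flow,
    convention: str = "printed",
    exclude_border: int = 1,
) -> StrainSeries:
    """Per-frame-pair strain sums over the union of the RoI boxes.

    ``flow_fn`` maps (frame_prev, frame_next) to a FlowField; analytic flows
    can be injected to bypass estimation.  Border pixels of the image are
    excluded from the sums (``exclude_border`` pixels, 0 to disable) because
    one-sided derivatives there are noisier.
    """
    n = len(seq)
    if n < 2:
        raise StrainError("need at least 2 frames")
    shape = seq.frame_shape
    union = _roi_mask(shape, boxes, exclude_border)
    tags = [b.region_tag for b in boxes]
    per_roi = {t: np.zeros(n - 1) for t in tags}
    values = np.zeros(n - 1)
    for f in range(1, n):
        try:
            flow = flow_fn(seq.frames[f - 1], seq.frames[f])
        except Exception as exc:  # noqa: BLE001 - annotate with frame index
            raise StrainError(f"flow estimation failed for frame pair "
                              f"({f - 1}, {f}): {exc}") from exc
        if flow.shape != shape:
            raise StrainError(f"flow shape {flow.shape} != frame shape {shape} "
                              f"at frame pair ({f - 1}, {f})")
        eps = strain_tensor(flow, convention=convention).eps
        values[f - 1] = eps[union].sum()
        for b, t in zip(boxes, tags):
            m = _roi_mask(shape, [b], exclude_border)
            per_roi[t][f - 1] = eps[m].sum()
    return StrainSeries(values=values, per_roi=per_roi)
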