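"""Facial regions of interest from 68-point landmarks.

Three RoIs drive the whole pipeline: the two eye regions and the mouth.
Their extents are derived from two anatomical distances, D_eye (between the
inner eye corners) and D_mouth (between the mouth corners), so the crop
geometry scales with the face:

* eye boxes: lateral margin of D_eye/4 on each side of the eye landmark
  x-extent, bottom D_eye/5 below the lowest eye landmark, top at the highest
  eyebrow landmark of that side;
* mouth box: D_mouth/5 beyond each mouth corner, D_mouth/4 above the highest
  and D_mouth/7 below the lowest mouth landmark.

Landmarks follow the iBUG 68-point numbering (0-based): brows 17-26, eyes
36-47 with inner corners 39/42, mouth 48-67 with corners 48/54.  Landmarks
are detected externally (e.g. dlib) on the first frame of a clip and reused
for every frame, since head displacement within a micro-expression clip is
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np
from skimage.transform import downscale_local_mean, resize

# iBUG 68-point index groups (0-based)
LEFT_BROW = slice(17, 22)
RIGHT_BROW = slice(22, 27)
LEFT_EYE = slice(36, 42)
RIGHT_EYE = slice(42, 48)
MOUTH = slice(48, 68)
INNER_EYE_CORNERS = (39, 42)
MOUTH_CORNERS = (48, 54)

DEFAULT_EYE_SIZE = (80, 90)  # (height, width)
DEFAULT_MOUTH_SIZE = (70, 150)


class RoiError(ValueError):
    pass


@dataclass
class LandmarkSet:
    """68 facial landmarks, (x, y) pixel coordinates, plus the frame size."""

    points: np.ndarray  # (68, 2) as (x, y)
    frame_size: tuple[int, int]  # (height, width)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (68, 2):
            raise RoiError(f"expected 68 (x, y) points, got shape {self.points.shape}")
        h, w = self.frame_size
        x, y = self.points[:, 0], self.points[:, 1]
        if (x < 0).any() or (y < 0).any() or (x > w).any() or (y > h).any():
            raise RoiError("landmarks fall outside the frame bounds")


@dataclass(frozen=True)
class RoIBox:
    """Half-open pixel box [top, bottom) x [left, right), 0-based."""

    top: int
    bottom: int
    left: int
    right: int
    region_tag: str

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise RoiError(f"degenerate RoI box for {self.region_tag}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bottom - self.top, self.right - self.left

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.top : self.bottom, self.left : self.right]


@dataclass
class RoIStack:
    """The three normalized RoI images for one frame."""

    left_eye: np.ndarray
    right_eye: np.ndarray
    mouth: np.ndarray

    def mirrored(self) -> "RoIStack":
        """The RoI stack of the horizontally mirrored face.

        Mirroring swaps the roles of the two eyes (the mirrored left-eye
        region is the flipped right-eye region) and flips the mouth.
        """
        return RoIStack(
            left_eye=np.fliplr(self.right_eye),
            right_eye=np.fliplr(self.left_eye),
            mouth=np.fliplr(self.mouth),
        )


def compute_distances(landmarks: LandmarkSet) -> tuple[float, float]:
    """Return (D_eye, D_mouth): inner-eye-corner and mouth-corner distances."""
    p = landmarks.points
    d_eye = float(np.linalg.norm(p[INNER_EYE_CORNERS[0]] - p[INNER_EYE_CORNERS[1]]))
    d_mouth = float(np.linalg.norm(p[MOUTH_CORNERS[0]] - p[MOUTH_CORNERS[1]]))
    if d_eye <= 0 or d_mouth <= 0:
        raise RoiError("degenerate landmark geometry")
    return d_eye, d_mouth


def _clamp_box(top: float, bottom: float, left: float, right: float,
               frame_size: tuple[int, int], tag: str) -> RoIBox:
    # maximal enclosing integer box: floor top/left, ceil bottom/right
    h, w = frame_size
    t = max(0, floor(top))
    b = min(h, ceil(bottom))
    l = max(0, floor(left))
    r = min(w, ceil(right))
    if t >= b or l >= r:
        raise RoiError(f"RoI box for {tag} collapsed after clamping to frame")
    return RoIBox(t, b, l, r, tag)


def eye_boxes(landmarks: LandmarkSet) -> tuple[RoIBox, RoIBox]:
    """Boxes for the left and right eye regions (brow included)."""
    d_eye, _ = compute_distances(landmarks)
    p = landmarks.points
    out = []
    for tag, eye_sl, brow_sl in (
        ("left_eye", LEFT_EYE, LEFT_BROW),
        ("right_eye", RIGHT_EYE, RIGHT_BROW),
    ):
        eye = p[eye_sl]
        brow = p[brow_sl]
        left = eye[:, 0].min() - d_eye / 4.0
        right = eye[:, 0].max() + d_eye / 4.0
        bottom = eye[:, 1].max() + d_eye / 5.0
        top = brow[:, 1].min()
        out.append(_clamp_box(top, bottom, left, right, landmarks.frame_size, tag))
    return out[0], out[1]


def mouth_box(landmarks: LandmarkSet) -> RoIBox:
    """Box for the mouth region."""
    _, d_mouth = compute_distances(landmarks)
    mouth = landmarks.points[MOUTH]
    cx = landmarks.points[MOUTH_CORNERS[0], 0], landmarks.points[MOUTH_CORNERS[1], 0]
    left = min(cx) - d_mouth / 5.0
    right = max(cx) + d_mouth / 5.0
    top = mouth[:, 1].min() - d_mouth / 4.0
    bottom = mouth[:, 1].max() + d_mouth / 7.0
    return _clamp_box(top, bottom, left, right, landmarks.frame_size, "mouth")


def all_boxes(landmarks: LandmarkSet) -> tuple[RoIBox, RoIBox, RoIBox]:
    le, re = eye_boxes(landmarks)
    return le, re, mouth_box(landmarks)


def _resample(img: np.ndarray, target: tuple[int, int], method: str = "bilinear") -> np.ndarray:
    """Resample a crop to the target (height, width).

    Identity when already at target size; area (block) averaging for exact
    integer down-sampling; otherwise bilinear interpolation.
    """
    img = np.asarray(img, dtype=float)
    if img.shape == tuple(target):
        return img.copy()
    th, tw = target
    h, w = img.shape
    if method == "bilinear" and h % th == 0 and w % tw == 0:
        return downscale_local_mean(img, (h // th, w // tw))
    order = {"nearest": 0, "bilinear": 1}.get(method)
    if order is None:
        raise RoiError(f"unknown resampling method: {method!r}")
    out = resize(img, target, order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, None)


def crop_and_normalize(
    frame: np.ndarray,
    boxes: tuple[RoIBox, RoIBox, RoIBox],
    eye_size: tuple[int, int] = DEFAULT_EYE_SIZE,
    mouth_size: tuple[int, int] = DEFAULT_MOUTH_SIZE,
    resample: str = "bilinear",
) -> RoIStack:
    """Crop the three RoIs from a frame and resample to the configured sizes."""
    frame = np.asarray(frame, dtype=float)
    le, re, mo = boxes
    crops = []
    for box, size in ((le, eye_size), (re, eye_size), (mo, mouth_size)):
        c = box.crop(frame)
        if c.size == 0:
            raise RoiError(f"empty crop for {box.region_tag}")
        crops.append(_resample(c, tuple(size), resample))
    return RoIStack(left_eye=crops[0], right_eye=crops[1], mouth=crops[2])


def read_landmarks(path, frame_size: tuple[int, int]) -> LandmarkSet:
    """Read a landmark file: 68 lines of 'x y' in pixels, iBUG order."""
    pts = np.loadtxt(path, dtype=float)
    if pts.shape != (68, 2):
        raise RoiError(f"landmark file {path} must contain 68 'x y' rows")
    return LandmarkSet(points=pts, frame_size=frame_size)
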