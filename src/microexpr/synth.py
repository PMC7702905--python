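"""Seeded synthetic-fixture generators.

Real micro-expression corpora are licensed downloads, so every pipeline
stage is exercised on generated inputs that carry the statistical structure
the stage assumes: part-based non-negative data with known supports for the
factorizers, frame sequences with planted unimodal motion and analytic
flows for strain/apex detection, separable labeled features for the
classifier, and macro/micro pairs with planted combination weights for the
MtM solver.  Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix, FrameSequence
from .roi import LandmarkSet, RoIStack
from .strain import FlowField


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# planted part-based data (factorization ground truth)

@dataclass
class PlantedFactors:
    """D = W_true H_true with spatially disjoint non-negative parts."""

    W_true: np.ndarray  # (pixels, n_parts)
    H_true: np.ndarray  # (n_parts, n_samples)
    D: np.ndarray
    part_supports: list[np.ndarray]  # pixel index sets, pairwise disjoint
    image_shape: tuple[int, int]


def make_parts_data(n_parts: int, image_shape: tuple[int, int],
                    n_samples: int, seed: int = 0) -> PlantedFactors:
    """Disjoint Gaussian-bump parts mixed with Uniform(0.2, 1) weights.

    The image is tiled into a near-square grid of cells, one part per cell:
    a Gaussian bump truncated to the cell interior, so part supports are
    pairwise disjoint by construction and D has rank n_parts generically.
    """
    h, w = image_shape
    rng = np.random.default_rng(seed)
    ncol = int(np.ceil(np.sqrt(n_parts)))
    nrow = int(np.ceil(n_parts / ncol))
    ch, cw = h // nrow, w // ncol
    if ch < 3 or cw < 3:
        raise SynthError("image too small for the requested number of parts")
    if n_samples < n_parts:
        raise SynthError("need n_samples >= n_parts")
    W = np.zeros((h * w, n_parts))
    supports = []
    yy, xx = np.mgrid[0:h, 0:w]
    for p in range(n_parts):
        r, c = divmod(p, ncol)
        top, left = r * ch, c * cw
        cy = top + ch / 2 + rng.uniform(-ch / 8, ch / 8)
        cx = left + cw / 2 + rng.uniform(-cw / 8, cw / 8)
        sigma = 0.30 * min(ch, cw)
        # Gaussian bump on a pedestal: support is the (near-binary) cell
        # interior, so learned and planted supports are threshold-robust
        bump = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
        cell = np.zeros((h, w), dtype=bool)
        cell[top + 1 : top + ch - 1, left + 1 : left + cw - 1] = True
        bump = np.where(cell, 0.4 + 0.6 * bump, 0.0)
        W[:, p] = bump.ravel()
        supports.append(np.flatnonzero(W[:, p]))
    # sparse non-negative mixing: every part appears alone in a few samples
    # and each remaining sample activates a random subset of parts, the way
    # a facial sample activates a few muscle actions; dense all-positive
    # mixing would leave the factorization non-identifiable
    H = rng.uniform(0.2, 1.0, size=(n_parts, n_samples))
    mask = rng.random((n_parts, n_samples)) < 0.5
    dead = ~mask.any(axis=0)
    mask[rng.integers(0, n_parts, dead.sum()), np.flatnonzero(dead)] = True
    mask[:, :n_parts] = np.eye(n_parts, dtype=bool)
    H *= mask
    D = W @ H
    for a in range(n_parts):
        for b in range(a + 1, n_parts):
            assert not np.intersect1d(supports[a], supports[b]).size
    return PlantedFactors(W_true=W, H_true=H, D=D, part_supports=supports,
                          image_shape=(h, w))


# ---------------------------------------------------------------------------
# synthetic face sequence with planted motion (strain / apex ground truth)

@dataclass
class MotionScript:
    """Planted motion: per-frame blob offsets and analytic per-pair flows.

    ``displacements[i]`` is the signed horizontal motion from frame i to
    i+1; its magnitude is strictly unimodal with the maximum at the pair
    ending at ``apex_frame``.  ``flows[i]`` is the matching analytic flow.
    """

    n_frames: int
    apex_frame: int
    amplitudes: np.ndarray  # (N,) offset of the mouth blob per frame
    displacements: np.ndarray  # (N-1,)
    blob_center: tuple[float, float]  # (x, y) at rest
    blob_sigma: float
    flows: list[FlowField] = field(default_factory=list)


def synthetic_landmarks(shape: tuple[int, int]) -> LandmarkSet:
    """A plausible 68-point layout (iBUG order) for a frame of given shape."""
    h, w = shape
    pts = np.zeros((68, 2))
    # jaw 0-16: lower half ellipse
    t = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = 0.5 * w + 0.38 * w * np.cos(t)
    pts[0:17, 1] = 0.45 * h - 0.45 * h * np.sin(t)
    # brows 17-21 (left), 22-26 (right): shallow arcs
    for sl, cx in ((slice(17, 22), 0.33), (slice(22, 27), 0.67)):
        xs = np.linspace(cx - 0.10, cx + 0.10, 5) * w
        pts[sl, 0] = xs
        pts[sl, 1] = 0.30 * h - 0.02 * h * np.sin(np.linspace(0, np.pi, 5))
    # nose 27-35
    pts[27:31, 0] = 0.5 * w
    pts[27:31, 1] = np.linspace(0.40, 0.55, 4) * h
    pts[31:36, 0] = np.linspace(0.45, 0.55, 5) * w
    pts[31:36, 1] = 0.60 * h
    # eyes 36-41 (left), 42-47 (right): hexagons; inner corners at 39 / 42
    ang = np.array([180, 120, 60, 0, 300, 240]) * np.pi / 180
    for sl, cx, flip in ((slice(36, 42), 0.35, 1.0), (slice(42, 48), 0.65, -1.0)):
        pts[sl, 0] = cx * w + flip * 0.06 * w * np.cos(ang)
        pts[sl, 1] = 0.40 * h - 0.025 * h * np.sin(ang)
    # mouth 48-67: outer 12 + inner 8 ellipse; corners at 48 / 54
    ang_out = np.linspace(np.pi, -np.pi, 12, endpoint=False)
    pts[48:60, 0] = 0.5 * w + 0.10 * w * np.cos(ang_out)
    pts[48:60, 1] = 0.75 * h - 0.045 * h * np.sin(ang_out)
    ang_in = np.linspace(np.pi, -np.pi, 8, endpoint=False)
    pts[60:68, 0] = 0.5 * w + 0.06 * w * np.cos(ang_in)
    pts[60:68, 1] = 0.75 * h - 0.02 * h * np.sin(ang_in)
    pts[:, 0] = np.clip(pts[:, 0], 0, w - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, h - 1)
    return LandmarkSet(points=pts, frame_size=(h, w))


def _gauss(yy, xx, cy, cx, sigma, amp=1.0):
    return amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))


def make_motion_sequence(
    n_frames: int = 16,
    apex_frame: int = 7,
    shape: tuple[int, int] = (120, 160),
    seed: int = 0,
    disp_max: float = 2.0,
) -> tuple[FrameSequence, MotionScript, LandmarkSet]:
    """Synthetic face clip whose mouth blob moves most into the apex frame.

    Per-pair displacement magnitudes ramp up linearly to the apex pair and
    decay geometrically after it, so the strain series is strictly unimodal
    with its peak at series position apex_frame - 1 (the pair ending at the
    apex frame).  Analytic flows are exported so strain tests need no flow
    estimator.
    """
    if not (2 <= apex_frame <= n_frames - 2):
        raise SynthError("apex_frame must lie in [2, n_frames - 2]")
    h, w = shape
    lm = synthetic_landmarks(shape)
    rng = np.random.default_rng(seed)
    # signed per-pair displacements d[f] for pair (f, f+1), f = 0..N-2;
    # |d| peaks at the pair ending at apex_frame
    d = np.zeros(n_frames - 1)
    for f in range(1, apex_frame + 1):
        d[f - 1] = f / apex_frame
    rho = 0.7
    for f in range(apex_frame + 1, n_frames):
        d[f - 1] = -0.8 * rho ** (f - apex_frame - 1)
    d *= disp_max
    amplitudes = np.concatenate([[0.0], np.cumsum(d)])
    cy, cx = 0.75 * h, 0.5 * w  # rest mouth-blob center
    sigma = 0.035 * min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    background = 0.25 + 0.1 * xx / w + 0.05 * yy / h
    eye_blobs = (
        _gauss(yy, xx, 0.40 * h, 0.35 * w, sigma, 0.8)
        + _gauss(yy, xx, 0.40 * h, 0.65 * w, sigma, 0.8)
    )
    noise = rng.normal(0.0, 1e-3, size=(h, w))
    frames = np.empty((n_frames, h, w))
    for f in range(n_frames):
        frames[f] = np.clip(
            background + eye_blobs
            + _gauss(yy, xx, cy, cx + amplitudes[f], sigma, 1.0) + noise,
            0.0, None,
        )
    flows = []
    for f in range(n_frames - 1):
        mask = _gauss(yy, xx, cy, cx + amplitudes[f], 3 * sigma, 1.0) > np.exp(-0.5)
        flows.append(FlowField(v_x=np.where(mask, d[f], 0.0),
                               v_y=np.zeros((h, w))))
    seq = FrameSequence(frames=frames, subject="synthetic", label="",
                        apex=apex_frame, name=f"motion_seed{seed}")
    script = MotionScript(n_frames=n_frames, apex_frame=apex_frame,
                          amplitudes=amplitudes, displacements=d,
                          blob_center=(cx, cy), blob_sigma=sigma, flows=flows)
    return seq, script, lm


# ---------------------------------------------------------------------------
# labeled non-negative features (classifier ground truth)

def make_classed_features(
    n_classes: int,
    n_subjects: int,
    dim: int,
    separation: float,
    seed: int = 0,
    n_per: int = 3,
    noise_sigma: float = 1.0,
) -> FeatureMatrix:
    """Non-negative features with class templates, subject offsets and noise.

    Each column is clip(template_class * separation + offset_subject +
    noise, 0); classes become linearly separable when separation greatly
    exceeds noise_sigma.  ``n_per`` samples per (class, subject) pair.
    """
    if n_classes < 2:
        raise SynthError("need at least 2 classes")
    if separation <= 0:
        raise SynthError("separation must be > 0")
    rng = np.random.default_rng(seed)
    templates = rng.uniform(0.0, 1.0, size=(dim, n_classes))
    offsets = rng.normal(0.0, 0.3, size=(dim, n_subjects))
    cols, labels, subjects, ids = [], [], [], []
    i = 0
    for s in range(n_subjects):
        for c in range(n_classes):
            for _ in range(n_per):
                v = (templates[:, c] * separation + offsets[:, s]
                     + rng.normal(0.0, noise_sigma, size=dim))
                cols.append(np.clip(v, 0.0, None))
                labels.append(f"emo{c}")
                subjects.append(f"subj{s}")
                ids.append(f"sample{i:05d}")
                i += 1
    F = np.column_stack(cols)
    fm = FeatureMatrix(F=F, labels=np.array(labels, dtype=object),
                       subjects=np.array(subjects, dtype=object),
                       provenance=np.full(len(labels), "original", dtype=object),
                       sample_ids=np.array(ids, dtype=object))
    assert fm.F.min() >= 0
    return fm


def make_classed_roi_stacks(
    n_classes: int,
    n_subjects: int,
    eye_size: tuple[int, int] = (10, 12),
    mouth_size: tuple[int, int] = (9, 15),
    separation: float = 10.0,
    seed: int = 0,
    n_per: int = 3,
) -> tuple[list[RoIStack], list[str], list[str], list[str]]:
    """Per-sample RoI stacks whose appearance encodes the class.

    Convenience wrapper over :func:`make_classed_features` that reshapes
    class-structured non-negative vectors into the three RoI images, for
    end-to-end pipeline tests without real face data.
    """
    dims = [eye_size[0] * eye_size[1], eye_size[0] * eye_size[1],
            mouth_size[0] * mouth_size[1]]
    fms = [make_classed_features(n_classes, n_subjects, d, separation,
                                 seed=seed + j, n_per=n_per)
           for j, d in enumerate(dims)]
    stacks = []
    for i in range(fms[0].n_samples):
        stacks.append(RoIStack(
            left_eye=fms[0].F[:, i].reshape(eye_size),
            right_eye=fms[1].F[:, i].reshape(eye_size),
            mouth=fms[2].F[:, i].reshape(mouth_size),
        ))
    f0 = fms[0]
    return (stacks, list(f0.labels), list(f0.subjects), list(f0.sample_ids))


# ---------------------------------------------------------------------------
# macro/micro feature pairs with planted combination weights (MtM)

@dataclass
class MacroMicroPair:
    """Macro and micro feature sets plus the planted per-emotion pieces."""

    X: FeatureMatrix  # macro: ref columns then probe columns, per emotion
    Y: FeatureMatrix  # micro
    planted: dict  # emo -> dict(X_ref, X_probe, H_star, Y_emo)


def make_macro_micro_pair(
    emotions: list[str],
    ref_count: int = 6,
    feature_dims: tuple[int, int] = (30, 20),
    seed: int = 0,
    probe_count: int | None = None,
) -> MacroMicroPair:
    """Per emotion: X_ref random positive, X_probe = X_ref @ H_star.

    H_star is planted non-negative, so a fixed-basis non-negative solver can
    reach (near-)zero residual; Y columns are random non-negative micro
    features paired with the reference columns.
    """
    if ref_count < 2:
        raise SynthError("ref_count must be >= 2")
    probe_count = probe_count or ref_count
    macro_dim, micro_dim = feature_dims
    rng = np.random.default_rng(seed)
    planted = {}
    x_parts, y_parts = [], []
    for emo in emotions:
        X_ref = rng.uniform(0.1, 1.0, size=(macro_dim, ref_count))
        H_star = rng.uniform(0.2, 1.0, size=(ref_count, probe_count))
        X_probe = X_ref @ H_star
        Y_emo = rng.uniform(0.1, 1.0, size=(micro_dim, ref_count))
        planted[emo] = {"X_ref": X_ref, "X_probe": X_probe,
                        "H_star": H_star, "Y_emo": Y_emo}
        n_x = ref_count + probe_count
        x_parts.append(FeatureMatrix(
            F=np.hstack([X_ref, X_probe]),
            labels=np.full(n_x, emo, dtype=object),
            subjects=np.array([f"mac{emo}{i}" for i in range(n_x)], dtype=object),
            provenance=np.full(n_x, "original", dtype=object),
            sample_ids=np.array([f"x_{emo}_{i:04d}" for i in range(n_x)],
                                dtype=object)))
        y_parts.append(FeatureMatrix(
            F=Y_emo,
            labels=np.full(ref_count, emo, dtype=object),
            subjects=np.array([f"mic{emo}{i}" for i in range(ref_count)],
                              dtype=object),
            provenance=np.full(ref_count, "original", dtype=object),
            sample_ids=np.array([f"y_{emo}_{i:04d}" for i in range(ref_count)],
                                dtype=object)))
    return MacroMicroPair(X=FeatureMatrix.concat(x_parts),
                          Y=FeatureMatrix.concat(y_parts), planted=planted)
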