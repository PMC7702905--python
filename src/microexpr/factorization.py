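"""KL-divergence NMF and local NMF (LNMF) via multiplicative updates.

A non-negative data matrix D (m pixels x n samples) is factored as D ~ WH
with W (m x r) a non-negative basis whose columns sum to 1 and H (r x n)
non-negative coefficients; the H columns are the per-sample features.  The
loss is the (generalized) KL divergence

    KL(D || WH) = sum_ij  d_ij log(d_ij / (WH)_ij) - d_ij + (WH)_ij.

LNMF adds locality/orthogonality constraints so the learned bases cover
small, non-overlapping facial parts; its published update rule shares the
same multiplicative skeleton and, in its classical derivation, places a
square root on the H update.  Three variants are exposed:

* ``nmf_kl``       — standard KL multiplicative updates;
* ``lnmf_printed`` — the update skeleton without the square root (default);
* ``lnmf_sqrt``    — H <- sqrt(H * W^T(D/WH)), the classical LNMF form.

Every iteration re-normalizes W columns to sum 1; the H rows absorb the
normalization factors so the product WH (and hence the objective) is
unchanged by the re-scaling.  With W column-normalized the printed H update
equals the standard KL update, so ``nmf_kl``/``lnmf_printed`` coincide and
are monotone in the KL objective.

The locality weights alpha/beta of the penalized LNMF objective are carried
in the config for documentation but do not enter these updates, matching
the published algorithm, which drops them from the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import FeatureMatrix
from .roi import RoIStack

VARIANTS = ("nmf_kl", "lnmf_printed", "lnmf_sqrt")


class FactorizationError(ValueError):
    pass


@dataclass
class LNMFConfig:
    """Solver settings shared by all factorization variants.

    alpha/beta are the locality and orthogonality weights of the penalized
    LNMF objective (documented, not used by the default updates); tol is the
    relative objective-change stopping threshold; epsilon guards every
    denominator and log argument.
    """

    alpha: float = 1.0
    beta: float = 1.0
    max_iter: int = 2000
    tol: float = 1e-6
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0 or self.epsilon <= 0:
            raise FactorizationError("alpha, beta and epsilon must be > 0")
        if self.max_iter < 1:
            raise FactorizationError("max_iter must be >= 1")


@dataclass
class FactorModel:
    """Result of one factorization run."""

    W: np.ndarray
    H: np.ndarray
    rank: int
    variant: str
    seed: int
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def basis_sparsity(self) -> float:
        """Mean fraction of near-zero W entries (below 1e-3 of column max)."""
        thresh = 1e-3 * self.W.max(axis=0, keepdims=True)
        return float((self.W < thresh).mean())

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def kl_divergence(X: np.ndarray, Y: np.ndarray, epsilon: float = 1e-12) -> float:
    """Generalized KL divergence sum(x log(x/y) - x + y), with 0 log 0 = 0."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise FactorizationError(f"shape mismatch: {X.shape} vs {Y.shape}")
    Ys = np.maximum(Y, epsilon)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.where(X > 0, X * np.log(np.maximum(X, epsilon) / Ys), 0.0)
    return float(np.sum(logterm - X + Y))


def _validate_input(D: np.ndarray, r: int) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise FactorizationError("D must be a 2-D matrix")
    if D.size == 0:
        raise FactorizationError("D is empty")
    if D.min() < 0:
        raise FactorizationError("D must be non-negative")
    if not (1 <= r <= min(D.shape)):
        raise FactorizationError(f"rank {r} invalid for shape {D.shape}")
    return D


def _init_factors(m: int, n: int, r: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    # H init is drawn per-row and broadcast across columns: the H update is
    # column-separable, and a column-position-independent init makes features
    # equivariant under sample reordering
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.1, 1.1, size=(m, r))
    H = np.repeat(rng.uniform(0.1, 1.1, size=(r, 1)), n, axis=1)
    W /= W.sum(axis=0, keepdims=True)
    return W, H


def _iterate(D: np.ndarray, W: np.ndarray, H: np.ndarray, variant: str,
             eps: float) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative update sweep: H step, W step, re-normalization."""
    WH = W @ H + eps
    ratio = D / WH
    if variant == "lnmf_sqrt":
        H = np.sqrt(H * (W.T @ ratio))
    else:
        H = H * (W.T @ ratio)
    WH = W @ H + eps
    W = W * ((D / WH) @ H.T)
    W = W / (H.sum(axis=1)[None, :] + eps)
    # column normalization; H rows absorb the scale so WH is unchanged
    # (guard only against an exactly-zero column so sums stay 1 to rounding)
    colsum = np.maximum(W.sum(axis=0), eps)
    W = W / colsum
    H = H * colsum[:, None]
    return W, H


def _fit(D: np.ndarray, r: int, cfg: LNMFConfig, variant: str, seed: int) -> FactorModel:
    D = _validate_input(D, r)
    W, H = _init_factors(D.shape[0], D.shape[1], r, seed)
    trace = [kl_divergence(D, W @ H, cfg.epsilon)]
    for _ in range(cfg.max_iter):
        W, H = _iterate(D, W, H, variant, cfg.epsilon)
        obj = kl_divergence(D, W @ H, cfg.epsilon)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and abs(prev - obj) / prev < cfg.tol:
            break
    return FactorModel(W=W, H=H, rank=r, variant=variant, seed=seed,
                       objective_trace=np.asarray(trace))


def nmf_fit(D: np.ndarray, r: int, cfg: LNMFConfig | None = None,
            seed: int = 0) -> FactorModel:
    """Fit KL-divergence NMF with multiplicative updates."""
    return _fit(D, r, cfg or LNMFConfig(), "nmf_kl", seed)


def lnmf_fit(D: np.ndarray, r: int, cfg: LNMFConfig | None = None,
             seed: int = 0, variant: str = "lnmf_printed") -> FactorModel:
    """Fit LNMF; ``variant`` is 'lnmf_printed' (default) or 'lnmf_sqrt'."""
    if variant not in ("lnmf_printed", "lnmf_sqrt"):
        raise FactorizationError(f"unknown LNMF variant: {variant!r}")
    return _fit(D, r, cfg or LNMFConfig(), variant, seed)


def encode_with_fixed_basis(W: np.ndarray, D_new: np.ndarray,
                            cfg: LNMFConfig | None = None,
                            seed: int = 0) -> np.ndarray:
    """Coefficients for new samples under a frozen basis W.

    Iterates the multiplicative H update with W fixed; used for mirrored
    samples and leakage-free per-fold encoding of held-out samples.
    """
    cfg = cfg or LNMFConfig()
    W = np.asarray(W, dtype=float)
    D_new = np.asarray(D_new, dtype=float)
    single = D_new.ndim == 1
    if single:
        D_new = D_new[:, None]
    if D_new.shape[0] != W.shape[0]:
        raise FactorizationError(
            f"dimension mismatch: W has {W.shape[0]} rows, D_new {D_new.shape[0]}")
    if D_new.min() < 0:
        raise FactorizationError("D_new must be non-negative")
    rng = np.random.default_rng(seed)
    H = np.repeat(rng.uniform(0.1, 1.1, size=(W.shape[1], 1)),
                  D_new.shape[1], axis=1)
    prev = kl_divergence(D_new, W @ H, cfg.epsilon)
    for _ in range(cfg.max_iter):
        WH = W @ H + cfg.epsilon
        H = H * (W.T @ (D_new / WH)) / (W.sum(axis=0)[:, None] + cfg.epsilon)
        obj = kl_divergence(D_new, W @ H, cfg.epsilon)
        if prev > 0 and abs(prev - obj) / prev < cfg.tol:
            break
        prev = obj
    return H[:, 0] if single else H


def stacks_to_matrices(stacks: Sequence[RoIStack]) -> dict[str, np.ndarray]:
    """Vectorize per-sample RoI stacks into three (pixels x samples) matrices."""
    if not stacks:
        raise FactorizationError("no samples")
    shapes = {(s.left_eye.shape, s.right_eye.shape, s.mouth.shape) for s in stacks}
    if len(shapes) != 1:
        raise FactorizationError("inconsistent RoI sizes across samples")
    return {
        "left_eye": np.column_stack([s.left_eye.ravel() for s in stacks]),
        "right_eye": np.column_stack([s.right_eye.ravel() for s in stacks]),
        "mouth": np.column_stack([s.mouth.ravel() for s in stacks]),
    }


def extract_features(
    apex_rois: Sequence[RoIStack],
    ranks: tuple[int, int, int],
    cfg: LNMFConfig | None = None,
    labels: Optional[Sequence] = None,
    subjects: Optional[Sequence] = None,
    sample_ids: Optional[Sequence] = None,
    add_mirrored: bool = False,
    seed: int = 0,
    variant: str = "lnmf_printed",
) -> tuple[FeatureMatrix, dict[str, FactorModel]]:
    """Per-RoI LNMF features, concatenated row-wise.

    One LNMF run per RoI (left eye, right eye, mouth) with the configured
    ranks; the three coefficient matrices are stacked into a feature matrix
    of height r_le + r_re + r_mouth.  With ``add_mirrored`` each sample's
    horizontally mirrored RoI stack is appended as an extra column of the
    data matrices before factorization (provenance 'mirrored', same subject
    and label as its source).
    """
    cfg = cfg or LNMFConfig()
    n = len(apex_rois)
    if n < 2:
        raise FactorizationError("need at least 2 samples")
    labels = list(labels) if labels is not None else [""] * n
    subjects = list(subjects) if subjects is not None else [""] * n
    sample_ids = list(sample_ids) if sample_ids is not None else [f"s{i:05d}" for i in range(n)]
    stacks = list(apex_rois)
    provenance = ["original"] * n
    if add_mirrored:
        stacks += [s.mirrored() for s in apex_rois]
        labels = labels + list(labels)
        subjects = subjects + list(subjects)
        sample_ids = sample_ids + [f"{sid}_mir" for sid in sample_ids]
        provenance += ["mirrored"] * n
    mats = stacks_to_matrices(stacks)
    models: dict[str, FactorModel] = {}
    blocks = []
    for (tag, r), sub_seed in zip(
        zip(("left_eye", "right_eye", "mouth"), ranks), (seed, seed + 1, seed + 2)
    ):
        model = lnmf_fit(mats[tag], r, cfg, seed=sub_seed, variant=variant)
        models[tag] = model
        blocks.append(model.H)
    F = np.vstack(blocks)
    fm = FeatureMatrix(F=F, labels=np.asarray(labels, dtype=object),
                       subjects=np.asarray(subjects, dtype=object),
                       provenance=np.asarray(provenance, dtype=object),
                       sample_ids=np.asarray(sample_ids, dtype=object))
    return fm, models
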