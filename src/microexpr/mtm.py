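"""Macro-to-micro (MtM) feature augmentation.

Micro-expression datasets are tiny; macro-expression datasets are not.  MtM
augmentation expresses held-out macro-expression features (X_probe) as
combinations of reference macro features (X_ref) of the same emotion, then
applies the same combination weights to emotion-matched micro-expression
features Y to synthesize new micro samples:

    X_probe ~ X_ref H        Y_new = Y H

The original baseline solves H through the SVD of the stacked matrix
M = [X_ref; Y]: U is split row-wise into macro/micro blocks R_x/R_y, H is
the least-squares solution of X_probe = R_x H and Y_new = R_y H.  Because U
is orthogonal, H (and hence Y_new) generally contains negative entries, so
the synthesized samples violate the non-negativity that NMF/LNMF features
require — the motivation for the improved path.

The improved MtM keeps everything non-negative: H is solved by fixed-basis
non-negative least squares (multiplicative updates with X_ref frozen), and
Y_new = Y H is a product of non-negative factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import FeatureMatrix


class MtMError(ValueError):
    pass


@dataclass
class MtMConfig:
    max_iter: int = 2000
    tol: float = 1e-10
    epsilon: float = 1e-12
    loss: str = "frobenius"  # or "kl"


@dataclass
class MtMResult:
    """Solved weights and generated micro features for one emotion."""

    emo: str
    H_emo: np.ndarray  # (ref_count, probe_count), >= 0
    Y_new: np.ndarray  # (feature_dim, probe_count), >= 0
    residual: float  # ||X_probe - X_ref H||_F / ||X_probe||_F
    residual_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SvdMtMModel:
    """SVD factorization of the stacked macro/micro matrix (baseline)."""

    M: np.ndarray
    U: np.ndarray
    S: np.ndarray
    Vt: np.ndarray
    R_x: np.ndarray
    R_y: np.ndarray


def split_ref_probe(X_emo: np.ndarray, fraction: float = 0.5,
                    seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint column split into (X_ref, X_probe).

    ``fraction`` is the reference share; on odd counts the probe gets the
    floor (e.g. 3 columns at 0.5 -> 2 ref + 1 probe).
    """
    X_emo = np.asarray(X_emo, dtype=float)
    n = X_emo.shape[1]
    if n < 2:
        raise MtMError("need at least 2 columns to split")
    n_probe = int(np.floor(n * (1.0 - fraction)))
    n_probe = min(max(n_probe, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    ref_idx = np.sort(perm[: n - n_probe])
    probe_idx = np.sort(perm[n - n_probe :])
    return X_emo[:, ref_idx], X_emo[:, probe_idx]


def solve_weights(X_ref: np.ndarray, X_probe: np.ndarray,
                  cfg: MtMConfig | None = None, seed: int = 0) -> MtMResult:
    """Non-negative H minimizing ||X_probe - X_ref H|| with X_ref frozen.

    Frobenius loss uses the multiplicative update
    H <- H * (X_ref^T X_probe) / (X_ref^T X_ref H); the KL form reuses the
    fixed-basis KL update.  The residual trace is recorded per iteration.
    """
    cfg = cfg or MtMConfig()
    X_ref = np.asarray(X_ref, dtype=float)
    X_probe = np.asarray(X_probe, dtype=float)
    if X_ref.shape[0] != X_probe.shape[0]:
        raise MtMError("X_ref and X_probe must have equal row counts")
    if X_ref.min() < 0 or X_probe.min() < 0:
        raise MtMError("MtM inputs must be non-negative")
    probe_norm = np.linalg.norm(X_probe)
    rng = np.random.default_rng(seed)
    H = rng.uniform(0.1, 1.1, size=(X_ref.shape[1], X_probe.shape[1]))
    if probe_norm == 0.0:
        # zero target: the minimizer is H = 0, residual defined as 0
        H = np.zeros_like(H)
        return MtMResult(emo="", H_emo=H, Y_new=np.empty((0, H.shape[1])),
                         residual=0.0, residual_trace=np.zeros(1))
    trace = []
    if cfg.loss == "frobenius":
        XtX = X_ref.T @ X_ref
        XtP = X_ref.T @ X_probe
        prev = np.inf
        for _ in range(cfg.max_iter):
            H = H * XtP / (XtX @ H + cfg.epsilon)
            res = np.linalg.norm(X_probe - X_ref @ H) / probe_norm
            trace.append(res)
            if abs(prev - res) < cfg.tol:
                break
            prev = res
    elif cfg.loss == "kl":
        colsum = X_ref.sum(axis=0)[:, None] + cfg.epsilon
        prev = np.inf
        for _ in range(cfg.max_iter):
            WH = X_ref @ H + cfg.epsilon
            H = H * (X_ref.T @ (X_probe / WH)) / colsum
            res = np.linalg.norm(X_probe - X_ref @ H) / probe_norm
            trace.append(res)
            if abs(prev - res) < cfg.tol:
                break
            prev = res
    else:
        raise MtMError(f"unknown loss: {cfg.loss!r}")
    return MtMResult(emo="", H_emo=H, Y_new=np.empty((0, H.shape[1])),
                     residual=trace[-1], residual_trace=np.asarray(trace))


def generate_micro(Y_emo: np.ndarray, H_emo: np.ndarray) -> np.ndarray:
    """Synthesize micro features: Y_new = Y_emo H_emo (non-negative)."""
    Y_emo = np.asarray(Y_emo, dtype=float)
    H_emo = np.asarray(H_emo, dtype=float)
    if Y_emo.shape[1] != H_emo.shape[0]:
        raise MtMError(f"dimension mismatch: Y has {Y_emo.shape[1]} columns, "
                       f"H has {H_emo.shape[0]} rows")
    if Y_emo.min() < 0 or H_emo.min() < 0:
        raise MtMError("generate_micro requires non-negative inputs")
    return Y_emo @ H_emo


def _cycle_columns(Y: FeatureMatrix, count: int) -> np.ndarray:
    """Micro columns sorted by sample id, recycled round-robin to ``count``."""
    order = np.argsort(Y.sample_ids.astype(str), kind="stable")
    idx = order[np.arange(count) % order.size]
    return Y.F[:, idx]


def mtm_transform(
    X: FeatureMatrix,
    Y: FeatureMatrix,
    emotions: list[str] | None = None,
    fraction: float = 0.5,
    seed: int = 0,
    cfg: MtMConfig | None = None,
) -> tuple[FeatureMatrix, list[MtMResult]]:
    """Per-emotion MtM augmentation: split -> pair -> solve -> generate.

    For each emotion, the macro features are split into reference/probe
    halves, micro samples of that emotion are recycled round-robin to match
    the reference count, weights are solved non-negatively and applied to
    the micro columns.  Emotions with no micro samples or fewer than two
    macro samples are skipped with a warning.  Generated columns carry the
    emotion label, subject id 'mtm' and provenance 'mtm_augmented'.
    """
    cfg = cfg or MtMConfig()
    if emotions is None:
        emotions = sorted(set(X.labels) & set(Y.labels))
    parts: list[FeatureMatrix] = []
    results: list[MtMResult] = []
    for k, emo in enumerate(emotions):
        X_emo = X.F[:, X.labels == emo]
        y_mask = Y.labels == emo
        if X_emo.shape[1] < 2 or not y_mask.any():
            warnings.warn(f"emotion {emo!r} skipped: needs >=2 macro and >=1 "
                          f"micro samples", stacklevel=2)
            continue
        X_ref, X_probe = split_ref_probe(X_emo, fraction=fraction, seed=seed + k)
        Y_emo = _cycle_columns(Y.select(y_mask), X_ref.shape[1])
        res = solve_weights(X_ref, X_probe, cfg, seed=seed + k)
        res.emo = emo
        res.Y_new = generate_micro(Y_emo, res.H_emo)
        results.append(res)
        n_new = res.Y_new.shape[1]
        parts.append(FeatureMatrix(
            F=res.Y_new,
            labels=np.full(n_new, emo, dtype=object),
            subjects=np.full(n_new, "mtm", dtype=object),
            provenance=np.full(n_new, "mtm_augmented", dtype=object),
            sample_ids=np.array([f"mtm_{emo}_{i:04d}" for i in range(n_new)],
                                dtype=object),
        ))
    if not parts:
        raise MtMError("no emotion produced any augmented samples")
    return FeatureMatrix.concat(parts), results


def svd_mtm_model(X_ref: np.ndarray, Y: np.ndarray) -> SvdMtMModel:
    """SVD of the stacked [X_ref; Y] matrix, split into macro/micro blocks."""
    X_ref = np.asarray(X_ref, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X_ref.shape[1] != Y.shape[1]:
        raise MtMError("X_ref and Y must have equal column counts")
    M = np.vstack([X_ref, Y])
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    mx = X_ref.shape[0]
    return SvdMtMModel(M=M, U=U, S=S, Vt=Vt, R_x=U[:mx], R_y=U[mx:])


def svd_mtm(X_ref: np.ndarray, Y: np.ndarray, X_probe: np.ndarray) -> np.ndarray:
    """Baseline SVD-based MtM: Y_new = R_y H with H solved from X_probe = R_x H.

    The output may contain negative entries (it usually does on generic
    inputs), which is why the non-negative path above exists.
    """
    model = svd_mtm_model(X_ref, Y)
    X_probe = np.asarray(X_probe, dtype=float)
    if X_probe.shape[0] != model.R_x.shape[0]:
        raise MtMError("X_probe row count must match X_ref")
    rank = np.linalg.matrix_rank(model.R_x)
    if rank < model.R_x.shape[1]:
        warnings.warn("R_x is rank-deficient; using pseudo-inverse "
                      "(solution may be inaccurate)", stacklevel=2)
    H, *_ = np.linalg.lstsq(model.R_x, X_probe, rcond=None)
    return model.R_y @ H
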