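"""One-vs-one polynomial-kernel SVM and subject-wise cross-validation.

Multi-class recognition uses n(n-1)/2 pairwise binary SVMs with the
polynomial kernel K(x_i, x_j) = (gamma x_i^T x_j + alpha)^d and majority
voting (ties broken toward the lowest class index).  Evaluation is
leave-one-subject-out: all samples of one subject form the test fold and
everything else trains the classifier.  Mirrored and MtM-augmented samples
may strengthen training folds but never appear in a test fold, and no
sample sharing the test subject's id is ever trained on — both constraints
are machine-checked on every fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.svm import SVC

from .containers import FeatureMatrix


class ClassifyError(ValueError):
    pass


@dataclass
class KernelConfig:
    """Polynomial-kernel hyperparameters (gamma x^T y + alpha)^degree.

    ``coef_alpha`` is the additive constant (sklearn's coef0).  Named
    profiles carry the per-dataset defaults: (4, 0, 4) and (4, 0, 1).
    """

    gamma: float = 4.0
    coef_alpha: float = 0.0
    degree: int = 4
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ClassifyError("gamma must be > 0")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ClassifyError("degree must be an integer >= 1")

    @staticmethod
    def profile(name: str) -> "KernelConfig":
        profiles = {
            "casme2": KernelConfig(gamma=4.0, coef_alpha=0.0, degree=4),
            "samm": KernelConfig(gamma=4.0, coef_alpha=0.0, degree=1),
        }
        if name not in profiles:
            raise ClassifyError(f"unknown kernel profile: {name!r}")
        return profiles[name]


@dataclass
class EvalProtocol:
    """Cross-validation settings: fold mode, repeat count, base seed."""

    mode: str = "subject"  # or "sample"
    n_runs: int = 5
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("subject", "sample"):
            raise ClassifyError("mode must be 'subject' or 'sample'")
        if self.n_runs < 1:
            raise ClassifyError("n_runs must be >= 1")


@dataclass
class EvalReport:
    """Cross-validated results: confusion counts, accuracy, per-run detail."""

    classes: list
    confusion: np.ndarray  # mean over runs; rows true, cols predicted
    accuracy: float  # mean over runs
    per_run: list[dict] = field(default_factory=list)
    folds: list = field(default_factory=list)  # test subject ids


def poly_kernel(x_i: np.ndarray, x_j: np.ndarray, cfg: KernelConfig) -> float:
    """(gamma x_i^T x_j + alpha)^degree for two feature vectors."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ClassifyError("feature vectors must have equal length")
    return float((cfg.gamma * x_i @ x_j + cfg.coef_alpha) ** cfg.degree)


@dataclass
class OvoSvmModel:
    """n(n-1)/2 pairwise polynomial SVMs with lowest-index tie-breaking."""

    svc: SVC
    classes: list

    @property
    def n_binary_classifiers(self) -> int:
        k = len(self.classes)
        return k * (k - 1) // 2

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote over the pairwise decisions; ties -> lowest class index."""
        dec = self.svc.decision_function(np.asarray(X, dtype=float))
        if dec.ndim == 1:  # two classes: single pairwise decision
            dec = dec[:, None]
        k = len(self.classes)
        votes = np.zeros((dec.shape[0], k))
        col = 0
        for i in range(k):
            for j in range(i + 1, k):
                votes[:, i] += dec[:, col] > 0
                votes[:, j] += dec[:, col] <= 0
                col += 1
        winners = np.argmax(votes, axis=1)  # first max -> lowest class index
        return np.asarray(self.classes, dtype=object)[winners]


def train_ovo_svm(F: FeatureMatrix, cfg: KernelConfig) -> OvoSvmModel:
    """Train the one-vs-one polynomial SVM on all columns of F."""
    classes = sorted(set(F.labels))
    if len(classes) < 2:
        raise ClassifyError("need at least 2 classes")
    svc = SVC(kernel="poly", gamma=cfg.gamma, coef0=cfg.coef_alpha,
              degree=cfg.degree, C=cfg.C, decision_function_shape="ovo")
    svc.fit(F.F.T, F.labels.astype(str))
    # sklearn orders pairwise decisions by its own sorted classes_, which for
    # string labels matches our sorted() ordering
    return OvoSvmModel(svc=svc, classes=[str(c) for c in sorted(svc.classes_)])


def _fold_masks(F: FeatureMatrix, mode: str):
    """Yield (fold_id, train_mask, test_mask) with hygiene applied."""
    original = F.provenance == "original"
    if mode == "subject":
        subjects = sorted({s for s, o in zip(F.subjects, original) if o})
        for s in subjects:
            test = (F.subjects == s) & original
            if not test.any():
                warnings.warn(f"subject {s!r} has no original samples; fold "
                              f"skipped", stacklevel=3)
                continue
            train = F.subjects != s
            yield s, train, test
    else:  # leave-one-sample-out
        for i in np.flatnonzero(original):
            test = np.zeros(F.n_samples, dtype=bool)
            test[i] = True
            train = ~test
            # mirrored twin of the held-out sample must not train
            twin = F.sample_ids == f"{F.sample_ids[i]}_mir"
            train &= ~twin
            yield F.sample_ids[i], train, test


def _check_fold(F: FeatureMatrix, fold_id, train: np.ndarray, test: np.ndarray,
                mode: str) -> None:
    if (F.provenance[test] != "original").any():
        raise ClassifyError(f"fold {fold_id}: non-original sample in test fold")
    if mode == "subject" and np.isin(np.flatnonzero(train),
                                     np.flatnonzero(F.subjects == fold_id)).any():
        raise ClassifyError(f"fold {fold_id}: test subject leaked into training")


def loso_evaluate(
    F: FeatureMatrix,
    cfg: KernelConfig,
    protocol: EvalProtocol | None = None,
    feature_builder: Optional[Callable[[int], FeatureMatrix]] = None,
) -> EvalReport:
    """Leave-one-subject-out evaluation, averaged over repeated runs.

    ``feature_builder(seed)``, when given, rebuilds the feature matrix per
    run (re-seeding factorization inits and MtM splits); otherwise all runs
    score the same features and are identical.  Accuracy is the mean over
    runs; the confusion matrix is the per-run mean (rows sum to per-class
    original counts).
    """
    protocol = protocol or EvalProtocol()
    per_run = []
    folds_seen: list = []
    classes: list = []
    for run in range(protocol.n_runs):
        Fr = feature_builder(protocol.base_seed + run) if feature_builder else F
        if not classes:
            classes = sorted(set(Fr.labels))
        idx = {str(c): i for i, c in enumerate(classes)}
        confusion = np.zeros((len(classes), len(classes)))
        folds = []
        for fold_id, train, test in _fold_masks(Fr, protocol.mode):
            _check_fold(Fr, fold_id, train, test, protocol.mode)
            model = train_ovo_svm(Fr.select(train), cfg)
            pred = model.predict(Fr.F[:, test].T)
            for t, p in zip(Fr.labels[test], pred):
                confusion[idx[str(t)], idx[str(p)]] += 1
            folds.append(fold_id)
        if len(folds) < 2:
            raise ClassifyError("need at least 2 folds (subjects)")
        total = confusion.sum()
        per_run.append({
            "accuracy": float(np.trace(confusion) / total),
            "confusion": confusion,
            "seed": protocol.base_seed + run,
        })
        folds_seen = folds
    acc = float(np.mean([r["accuracy"] for r in per_run]))
    mean_conf = np.mean([r["confusion"] for r in per_run], axis=0)
    return EvalReport(classes=classes, confusion=mean_conf, accuracy=acc,
                      per_run=per_run, folds=folds_seen)
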