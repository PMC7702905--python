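"""Shared in-memory containers for sequences and feature matrices."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

PROVENANCES = ("original", "mirrored", "mtm_augmented")


@dataclass
class FrameSequence:
    """An ordered grayscale frame stack for one expression clip.

    Frames are float arrays of identical shape (height, width), values >= 0.
    ``apex`` is an optional ground-truth / detected apex frame index.
    """

    frames: np.ndarray  # (N, H, W)
    subject: str = ""
    label: str = ""
    apex: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) stack")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite values")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class FeatureMatrix:
    """Column-per-sample feature store with classification metadata.

    ``F`` is (d, n) non-negative; per-column arrays carry the emotion label,
    subject id, provenance tag ('original' | 'mirrored' | 'mtm_augmented')
    and a sample id.
    """

    F: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    provenance: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (features x samples)")
        n = self.F.shape[1]
        self.labels = np.asarray(self.labels, dtype=object)
        self.subjects = np.asarray(self.subjects, dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(n)], dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        for name, arr in (
            ("labels", self.labels),
            ("subjects", self.subjects),
            ("provenance", self.provenance),
            ("sample_ids", self.sample_ids),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per column (expected {n})")
        bad = set(self.provenance) - set(PROVENANCES)
        if bad:
            raise ValueError(f"unknown provenance tags: {sorted(bad)}")
        if self.F.size and self.F.min() < 0:
            raise ValueError("feature matrix must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.F.shape[1]

    @property
    def dim(self) -> int:
        return self.F.shape[0]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            self.F[:, mask],
            self.labels[mask],
            self.subjects[mask],
            self.provenance[mask],
            self.sample_ids[mask],
        )

    @staticmethod
    def concat(parts: Sequence["FeatureMatrix"]) -> "FeatureMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        dims = {p.dim for p in parts}
        if len(dims) != 1:
            raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
        return FeatureMatrix(
            np.hstack([p.F for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.subjects for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.sample_ids for p in parts]),
        )

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "subject": self.subjects,
                "label": self.labels,
                "provenance": self.provenance,
            }
        )
        feats = pd.DataFrame(
            self.F.T, columns=[f"f_{i}" for i in range(self.dim)]
        )
        return pd.concat([meta, feats], axis=1)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "FeatureMatrix":
        required = ["sample_id", "subject", "label", "provenance"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        fcols = [c for c in df.columns if c.startswith("f_")]
        if not fcols:
            raise ValueError("no feature columns (f_0, f_1, ...) found")
        fcols = sorted(fcols, key=lambda c: int(c[2:]))
        return FeatureMatrix(
            df[fcols].to_numpy(dtype=float).T,
            df["label"].to_numpy(dtype=object),
            df["subject"].astype(str).to_numpy(dtype=object),
            df["provenance"].to_numpy(dtype=object),
            df["sample_id"].astype(str).to_numpy(dtype=object),
        )
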