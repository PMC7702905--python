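"""Readers and writers for frames, landmarks, features and models.

Frame input is a directory of lexicographically ordered PNG/JPEG images (or
a video file when an ffmpeg-capable imageio plugin is available); RGB input
is converted to grayscale with the standard luma weights.  Feature matrices
travel as CSV with a metadata header (sample_id, subject, label,
provenance, f_0...), lossless to full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .containers import FeatureMatrix, FrameSequence
from .factorization import FactorModel
from .strain import StrainSeries

IMAGE_EXTS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
LUMA = np.array([0.299, 0.587, 0.114])


class IOError_(ValueError):
    pass


def _to_gray(img: np.ndarray, name: str) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        return img[:, :, :3] @ LUMA
    raise IOError_(f"unsupported image layout {img.shape} in {name}")


def read_sequence(path, subject: str = "", label: str = "") -> FrameSequence:
    """Read a clip from an image directory (or video file) as grayscale."""
    path = Path(path)
    frames = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in IMAGE_EXTS)
        if not files:
            raise IOError_(f"no image files in {path}")
        for p in files:
            try:
                img = iio.imread(p)
            except Exception as exc:  # noqa: BLE001
                raise IOError_(f"unreadable frame {p}: {exc}") from exc
            frames.append(_to_gray(img, p.name))
    elif path.is_file():
        try:
            for i, img in enumerate(iio.imiter(path)):
                frames.append(_to_gray(img, f"{path.name}[{i}]"))
        except Exception as exc:  # noqa: BLE001
            raise IOError_(f"cannot decode video {path}: {exc}") from exc
        if not frames:
            raise IOError_(f"no frames decoded from {path}")
    else:
        raise IOError_(f"no such file or directory: {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise IOError_(f"inconsistent frame shape in {path}: {sorted(shapes)}")
    return FrameSequence(frames=np.stack(frames), subject=subject,
                         label=label, name=path.name)


def write_feature_matrix(path, fm: FeatureMatrix) -> None:
    fm.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_feature_matrix(path) -> FeatureMatrix:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise IOError_(f"empty feature file: {path}") from exc
    try:
        return FeatureMatrix.from_frame(df)
    except ValueError as exc:
        raise IOError_(f"invalid feature file {path}: {exc}") from exc


def write_strain_series(path, series: StrainSeries) -> None:
    """CSV cache of per-frame strain sums: columns frame_index, eps_sum."""
    df = pd.DataFrame({
        "frame_index": [StrainSeries.frame_of(i) for i in range(len(series))],
        "eps_sum": series.values,
    })
    df.to_csv(path, index=False, float_format="%.17g")


def read_strain_series(path) -> StrainSeries:
    df = pd.read_csv(path)
    if "eps_sum" not in df.columns:
        raise IOError_(f"missing eps_sum column in {path}")
    return StrainSeries(values=df["eps_sum"].to_numpy(dtype=float))


def write_factor_model(outdir, model: FactorModel) -> None:
    """Serialize as W.csv + H.csv plus a JSON sidecar with run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "W.csv", model.W, delimiter=",")
    np.savetxt(outdir / "H.csv", model.H, delimiter=",")
    meta = {
        "rank": model.rank,
        "variant": model.variant,
        "seed": model.seed,
        "objective_trace": [float(v) for v in model.objective_trace],
    }
    (outdir / "model.json").write_text(json.dumps(meta, indent=1))


def read_factor_model(outdir) -> FactorModel:
    outdir = Path(outdir)
    meta = json.loads((outdir / "model.json").read_text())
    W = np.loadtxt(outdir / "W.csv", delimiter=",", ndmin=2)
    H = np.loadtxt(outdir / "H.csv", delimiter=",", ndmin=2)
    return FactorModel(W=W, H=H, rank=meta["rank"], variant=meta["variant"],
                       seed=meta["seed"],
                       objective_trace=np.asarray(meta["objective_trace"]))
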