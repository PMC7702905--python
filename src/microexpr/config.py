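"""Pipeline configuration with named dataset profiles.

Flat, typed key-value configuration (YAML on disk, dotted keys); CLI flags
override file values.  Profiles bundle the per-dataset defaults: RoI sizes,
per-RoI factorization ranks, and kernel hyperparameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .classify import KernelConfig
from .factorization import LNMFConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    profile: str = "casme2"
    # roi
    eye_size: tuple[int, int] = (80, 90)
    mouth_size: tuple[int, int] = (70, 150)
    resample: str = "bilinear"
    # strain / apex
    strain_convention: str = "printed"  # or "symmetric"
    flow_method: str = "tvl1"
    exclude_border: int = 1
    # factorization
    ranks: tuple[int, int, int] = (40, 40, 80)
    variant: str = "lnmf_printed"
    max_iter: int = 2000
    tol: float = 1e-6
    epsilon: float = 1e-12
    fit_per_fold: bool = False
    macro_rank: int = 200  # whole-image NMF rank for the macro profile
    macro_image: tuple[int, int] = (48, 48)
    # classifier
    gamma: float = 4.0
    coef_alpha: float = 0.0
    degree: int = 4
    C: float = 1.0
    fold_mode: str = "subject"
    n_runs: int = 5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        self.eye_size = tuple(self.eye_size)  # type: ignore[assignment]
        self.mouth_size = tuple(self.mouth_size)  # type: ignore[assignment]
        self.ranks = tuple(self.ranks)  # type: ignore[assignment]
        if len(self.ranks) != 3 or any(r < 1 for r in self.ranks):
            raise ConfigError("ranks must be three integers >= 1")
        if any(s < 1 for s in (*self.eye_size, *self.mouth_size)):
            raise ConfigError("RoI sizes must be positive")
        if self.strain_convention not in ("printed", "symmetric"):
            raise ConfigError("strain_convention must be 'printed' or 'symmetric'")
        if self.variant not in ("lnmf_printed", "lnmf_sqrt", "nmf_kl"):
            raise ConfigError(f"unknown factorization variant {self.variant!r}")
        # delegate numeric validation to the owning modules
        self.lnmf()
        self.kernel()

    def lnmf(self) -> LNMFConfig:
        return LNMFConfig(max_iter=self.max_iter, tol=self.tol,
                          epsilon=self.epsilon)

    def kernel(self) -> KernelConfig:
        return KernelConfig(gamma=self.gamma, coef_alpha=self.coef_alpha,
                            degree=self.degree, C=self.C)

    @property
    def feature_dim(self) -> int:
        return sum(self.ranks)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


PROFILES: dict[str, dict] = {
    # micro-expression corpus with ranks 40/40/80 (feature height 160)
    # and kernel (gamma, alpha, degree) = (4, 0, 4)
    "casme2": dict(profile="casme2", ranks=(40, 40, 80),
                   gamma=4.0, coef_alpha=0.0, degree=4),
    # high-resolution corpus profile: ranks 120/120/110 (height 350),
    # kernel degree 1
    "samm": dict(profile="samm", ranks=(120, 120, 110),
                 gamma=4.0, coef_alpha=0.0, degree=1),
    # macro-expression pretraining profile: whole 48x48 images, plain NMF
    # at rank 200 (no RoI split)
    "ck_macro": dict(profile="ck_macro", variant="nmf_kl",
                     macro_rank=200, macro_image=(48, 48)),
}


def load_profile(name: str, **overrides) -> PipelineConfig:
    if name not in PROFILES:
        raise ConfigError(f"unknown profile {name!r}; "
                          f"choose from {sorted(PROFILES)}")
    kw = dict(PROFILES[name])
    kw.update(overrides)
    return PipelineConfig(**kw)


def load_config(path=None, profile: str = "casme2", **overrides) -> PipelineConfig:
    """Load a YAML config (flat dotted or plain keys); overrides win."""
    kw = dict(PROFILES.get(profile, {}))
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a key-value mapping")
        for key, value in raw.items():
            kw[str(key).rsplit(".", 1)[-1]] = value
    kw.update(overrides)
    try:
        return PipelineConfig(**kw)
    except TypeError as exc:
        raise ConfigError(f"invalid config key: {exc}") from exc
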