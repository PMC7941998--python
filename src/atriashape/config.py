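"""Run configuration: one serialisable record of every knob and seed.

Every random operation in the pipeline (cohort generation, sampled
permutations, cross-validation splits) draws its seed from here; a config
without the needed seeds is rejected so runs are reproducible by
construction.  Configs round-trip through YAML unchanged, and a content hash
of the canonical serialisation is written to every output manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .synthetic import CohortSpec


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    band_mm: float = 5.0      # analysis narrow band around the template surface
    soi_band_mm: float = 3.0  # voxel-to-vertex projection distance
    seed: int | None = None


@dataclass
class AffineConfig:
    iterations: int = 100
    gate_dice: float = 0.85
    band_mm: float = 10.0  # metric band around the fixed surface
    stride: int = 2        # band sample decimation
    drift_penalty: float = 1e-3  # minimal-deformation prior weight (mm^-2)


@dataclass
class BsplineConfig:
    grid_mm: float = 10.0
    levels: int = 1
    max_iter: int = 60
    regularization: float = 0.01  # bending-energy weight
    gate_dice: float = 0.9
    band_mm: float = 10.0
    stride: int = 2
    drift_penalty: float = 1e-3


@dataclass
class RegistrationConfig:
    atlas_mode: str = "similarity"  # similarity | affine | affine+nonrigid
    affine: AffineConfig = field(default_factory=AffineConfig)
    bspline: BsplineConfig = field(default_factory=BsplineConfig)


@dataclass
class FeaturesConfig:
    nonrigid_only: bool = False


@dataclass
class ModelBlock:
    runs: int = 100
    folds: int = 5
    seed: int | None = None
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 1.0
    wilcoxon_alpha: float = 0.05

    def xgb_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "subsample": self.subsample,
        }


@dataclass
class RunConfig:
    spacing_mm: float = 2.0  # common isotropic working resolution
    stats: StatsConfig = field(default_factory=StatsConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ModelBlock = field(default_factory=ModelBlock)
    synthetic: CohortSpec = field(default_factory=CohortSpec)

    def require_seeds(self, *blocks: str) -> None:
        """Refuse to run a stage whose seed is absent."""
        for b in blocks:
            if b == "stats" and self.stats.seed is None:
                raise ConfigError("stats.seed is required (sampled permutations)")
            if b == "model" and self.model.seed is None:
                raise ConfigError("model.seed is required (CV splits)")
            if b == "synthetic" and self.synthetic.seed is None:
                raise ConfigError("synthetic.seed is required (cohort generation)")

    def with_seed(self, seed: int) -> "RunConfig":
        """Override every stage seed from one integer."""
        cfg = from_dict(to_dict(self))
        cfg.stats.seed = seed
        cfg.model.seed = seed
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=seed)
        return cfg


def to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def tuples_to_lists(obj):
        if isinstance(obj, dict):
            return {k: tuples_to_lists(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [tuples_to_lists(v) for v in obj]
        return obj

    return tuples_to_lists(d)


_NESTED: dict[type, dict[str, type]] = {
    RunConfig: {
        "stats": StatsConfig,
        "registration": RegistrationConfig,
        "features": FeaturesConfig,
        "model": ModelBlock,
        "synthetic": CohortSpec,
    },
    RegistrationConfig: {"affine": AffineConfig, "bspline": BsplineConfig},
}


def _build(cls, data: dict):
    kwargs = {}
    nested = _NESTED.get(cls, {})
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in nested:
            value = _build(nested[f.name], value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise ConfigError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**kwargs)


def from_dict(data: dict) -> RunConfig:
    try:
        return _build(RunConfig, data or {})
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(data)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 of the canonical JSON serialisation."""
    canon = json.dumps(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
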