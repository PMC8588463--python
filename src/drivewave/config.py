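"""Single-document YAML configuration with a strict schema.

One `PipelineConfig` fully determines a pipeline run; unknown keys are
rejected so that typos fail loudly, and the SHA-256 hash of the canonical
YAML serialization stamps every artifact for provenance.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocess import PreprocessConfig

__all__ = [
    "ArtifactConfig",
    "SynthesisConfig",
    "SpectraConfig",
    "TrainingConfig",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


@dataclass(frozen=True)
class ArtifactConfig:
    blink_rate_hz: float = 0.2
    emg_burst_rate_hz: float = 0.1
    line_amp_uV: float = 2.0


@dataclass(frozen=True)
class SynthesisConfig:
    """Generator settings; per-state band means/SDs default to the built-in
    state profiles when not overridden."""

    seed: int = 0
    fs: float = 1000.0
    n_subjects: int = 17
    total_power_uV2: float = 400.0
    states: dict = field(default_factory=dict)  # state -> {band: [mean, sd]}
    epochs_per_subject: dict = field(default_factory=dict)
    artifacts: ArtifactConfig | None = None


@dataclass(frozen=True)
class SpectraConfig:
    segment_s: float = 2.0
    overlap: float = 0.5
    window: str = "hamming"


@dataclass(frozen=True)
class TrainingConfig:
    models: tuple = ("knn", "discriminant", "svm_rbf",
                     "tree_gain_ratio", "tree_univariate")
    task: str = "multiclass"  # or "<state_a>-vs-<state_b>"
    cv_k: int = 10
    repeats: int = 1
    weighting: bool = True
    n_train_subjects: int = 12
    train_subjects: tuple | None = None
    test_subjects: tuple | None = None
    importances: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spectra: SpectraConfig = field(default_factory=SpectraConfig)
    training: TrainingConfig | None = field(default_factory=TrainingConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, d: dict | None, path: str):
    if d is None:
        return cls()
    if not isinstance(d, dict):
        raise ValueError(f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if cls is PipelineConfig and k == "training" and v is None:
            kwargs[k] = None
            continue
        sub = _SUBSECTIONS.get((cls, k))
        if sub is not None:
            kwargs[k] = _build(sub, v, f"{path}.{k}")
        elif isinstance(v, list):
            kwargs[k] = tuple(v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


_SUBSECTIONS = {
    (PipelineConfig, "synthesis"): SynthesisConfig,
    (PipelineConfig, "preprocess"): PreprocessConfig,
    (PipelineConfig, "spectra"): SpectraConfig,
    (PipelineConfig, "training"): TrainingConfig,
    (SynthesisConfig, "artifacts"): ArtifactConfig,
}


def load_config(path: str | Path | None = None, text: str | None = None) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML."""
    if text is None:
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if "training" in doc and doc["training"] is None:
        cfg = _build(PipelineConfig, {k: v for k, v in doc.items()
                                      if k != "training"}, "config")
        return dataclasses.replace(cfg, training=None)
    return _build(PipelineConfig, doc, "config")


def config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
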