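"""Pipeline configuration: defaults, YAML loading, validation, hashing.

The default :class:`PipelineConfig` reproduces the published hyperparameter
set exactly: mixed gaps {0, 1}; autoencoder 800/650/500/300 mirrored with
Adadelta; FC head 50/25/1 trained with SGD (lr 0.0025, decay 1e-6, momentum
0.6, batch 12), dropout 0.2/0.3, max-norm 3, init U[-0.05, 0.05]; 6:1
sample re-weighting; linear SVM with C = 2 and 5:1 class weights; 10-fold
cross-validation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .embed_classify import SVMConfig, TSNESettings
from .errors import ConfigError
from .network import AutoencoderConfig, FineTuneConfig

__all__ = ["PipelineConfig", "load_config", "resolve_config", "config_hash"]


@dataclass
class PipelineConfig:
    """Fully resolved settings for the end-to-end pipeline."""

    gaps: tuple[int, ...] = (0, 1)
    autoencoder: AutoencoderConfig = field(default_factory=AutoencoderConfig)
    fine_tune: FineTuneConfig = field(default_factory=FineTuneConfig)
    tsne: TSNESettings = field(default_factory=TSNESettings)
    svm: SVMConfig = field(default_factory=SVMConfig)
    positive_sample_weight: float = 6.0
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.gaps) != (0, 1):
            raise ConfigError(
                "the mixed feature vector is defined on gaps (0, 1); "
                f"got {self.gaps}"
            )
        if self.positive_sample_weight <= 0:
            raise ConfigError("positive_sample_weight must be positive")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be at least 2")


_SECTION_TYPES = {
    "autoencoder": AutoencoderConfig,
    "fine_tune": FineTuneConfig,
    "tsne": TSNESettings,
    "svm": SVMConfig,
}


def _build_section(cls, values: dict, section: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - field_names
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in values.items()
    }
    try:
        return cls(**coerced)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def resolve_config(raw: dict | None) -> PipelineConfig:
    """Build a validated config from a (possibly partial) mapping.

    Unknown keys are rejected by name; omitted keys take the published
    defaults.
    """
    raw = dict(raw or {})
    top_fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "gaps":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return PipelineConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` or an empty file gives the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at top level")
    return resolve_config(raw)


def config_to_dict(config: PipelineConfig) -> dict:
    """Fully resolved, JSON-serializable view of the config."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in vars(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if hasattr(obj, "tolist"):
            return obj.tolist()
        return obj

    return convert(config)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash identifying a resolved configuration."""
    payload = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
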