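"""Hierarchical run configuration with schema validation and stable hashing.

Every tunable default of the pipelines lives here under one nested
mapping, so a single YAML file (plus a seed) reproduces a run.  Unknown
keys are rejected — typos fail loudly rather than silently falling back
to defaults — and the config hash is invariant to key order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .features import ValidationError
from .handwriting import HandwritingConfig
from .net import ModelConfig, TrainHyper
from .speech import SpeechConfig
from .synth import CohortSpec

__all__ = ["RunConfig", "default_config_dict", "config_hash"]

_SECTIONS = {
    "speech": SpeechConfig,
    "handwriting": HandwritingConfig,
    "model": ModelConfig,
    "training": TrainHyper,
    "cohort": CohortSpec,
}


def default_config_dict() -> dict:
    return {name: dataclasses.asdict(cls()) for name, cls in _SECTIONS.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_hash(cfg: dict) -> str:
    """Order-invariant sha256 digest of a config mapping (first 16 hex chars)."""
    return hashlib.sha256(
        json.dumps(_jsonable(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]


class RunConfig:
    """Validated bundle of per-module configs.

    Construct from a nested dict (or YAML file) overriding any subset of
    defaults; access the typed per-module configs as attributes
    (``.speech``, ``.handwriting``, ``.model``, ``.training``,
    ``.cohort``).
    """

    def __init__(self, overrides: dict | None = None):
        overrides = overrides or {}
        defaults = default_config_dict()
        unknown = set(overrides) - set(defaults)
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")
        merged = {}
        for section, base in defaults.items():
            sub = dict(base)
            over = overrides.get(section, {})
            bad = set(over) - set(base)
            if bad:
                raise ValidationError(
                    f"unknown keys in config section {section!r}: {sorted(bad)}"
                )
            sub.update(over)
            merged[section] = sub
        self.as_dict = merged
        for section, cls in _SECTIONS.items():
            kwargs = dict(merged[section])
            fields = {f.name for f in dataclasses.fields(cls)}
            kwargs = {k: v for k, v in kwargs.items() if k in fields}
            # dataclass fields that are tuples arrive as lists from YAML
            for f in dataclasses.fields(cls):
                if isinstance(getattr(cls(), f.name, None), tuple) and f.name in kwargs:
                    kwargs[f.name] = tuple(kwargs[f.name])
            setattr(self, section, cls(**kwargs))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config root must be a mapping")
        return cls(data)

    @property
    def hash(self) -> str:
        return config_hash(self.as_dict)
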