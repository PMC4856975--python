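"""Declarative configuration: TOML file defaults overridden by CLI flags.

Precedence is flags > config file > built-in defaults. Values are validated
at load time against the preconditions of the operations that consume them.
"""

from __future__ import annotations

import os
import tomllib
from dataclasses import dataclass, field

from .errors import ConfigurationError

DEFAULT_CONFIG_PATH = os.path.expanduser("~/.bundlekit.toml")

_DEFAULTS = {
    "pseudocount": 1.0,
    "gap_threshold": 0.5,
    "kernel_matrix": "BLOSUM62",
    "gap_score": -4.0,
    "gap_gap_score": 0.0,
    "curvature": 0.35,
    "seed": 0,
    "svm_c": 1.0,
}

_VALIDATORS = {
    "pseudocount": lambda v: v >= 0,
    "gap_threshold": lambda v: 0 <= v < 1,
    "curvature": lambda v: 0 <= v <= 0.5,
    "svm_c": lambda v: v > 0,
    "seed": lambda v: isinstance(v, int),
    "kernel_matrix": lambda v: isinstance(v, str),
    "gap_score": lambda v: isinstance(v, (int, float)),
    "gap_gap_score": lambda v: isinstance(v, (int, float)),
}


@dataclass
class Config:
    values: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def get(self, key: str):
        return self.values[key]

    def override(self, key: str, value) -> None:
        """Apply a flag-level override (highest precedence)."""
        if value is not None:
            self._check(key, value)
            self.values[key] = value

    @staticmethod
    def _check(key, value):
        validator = _VALIDATORS.get(key)
        if validator is not None and not validator(value):
            raise ConfigurationError(f"invalid config value {key} = {value!r}")


def load_config(path: str | None = None) -> Config:
    """Load config defaults, optionally overlaid with a TOML file."""
    cfg = Config()
    candidate = path or (DEFAULT_CONFIG_PATH if os.path.exists(DEFAULT_CONFIG_PATH) else None)
    if candidate is None:
        return cfg
    try:
        with open(candidate, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"config file not found: {candidate}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigurationError(f"malformed config file {candidate}: {exc}") from exc
    for key, value in data.items():
        if key not in _DEFAULTS:
            raise ConfigurationError(f"unknown config key {key!r} in {candidate}")
        Config._check(key, value)
        cfg.values[key] = value
    return cfg
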