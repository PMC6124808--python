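"""Default configuration loading and deep-merging of user overrides."""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_DEFAULTS_CACHE: dict[str, Any] | None = None


def load_defaults() -> dict[str, Any]:
    """Return a fresh copy of the packaged default configuration."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        text = resources.files("spectraldcm").joinpath("defaults.yaml").read_text()
        _DEFAULTS_CACHE = yaml.safe_load(text)
    return copy.deepcopy(_DEFAULTS_CACHE)


def merge_config(overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge ``overrides`` onto the packaged defaults.

    Unknown keys (at any depth where the defaults define a mapping) are
    rejected so that typos do not silently fall back to defaults.
    """
    base = load_defaults()
    if overrides:
        _merge_into(base, overrides, path="")
    return base


def _merge_into(base: dict, overrides: Mapping, path: str) -> None:
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, Mapping):
                raise ConfigError(f"expected a mapping at {here!r}")
            _merge_into(base[key], value, here)
        else:
            base[key] = value
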