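"""Run configuration: every tunable of the three-stage detector in one place.

Defaults follow the method's stated parameter choices (``a1=2``, ``a2=1``,
``gp=0.5``, block size 8, closing disk radius 5, noise factor 0.1); values the
method leaves open (iteration budget, histogram bins, expansion threshold) are
package choices documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid parameter values."""


@dataclass
class RunConfig:
    # block decomposition
    block_size: int = 8
    # grayscale conversion: "printed" uses the 0.299/0.583/0.116 weights,
    # "bt601" the ITU-R BT.601 weights 0.299/0.587/0.114
    gray_variant: str = "printed"
    # SIFT seeding
    contrast_threshold: float = 0.04
    edge_threshold: float = 10.0
    # equilibrium optimization matching
    a1: float = 2.0
    a2: float = 1.0
    gp: float = 0.5
    max_iter: int = 20
    lambda_floor: float = 1e-6
    threshold: float = 127.5  # white/black binarization intensity
    f_variant: str = "printed"  # or "canonical"
    # color histogram matching expansion
    n_bins: int = 32
    distance_threshold: float = 0.1
    max_rounds: int = 50
    closing_radius: int = 5
    # image-level verdict
    min_region_pixels: int = 64
    # synthetic forgery generation
    noise_sigma: float = 0.1
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ConfigError("block_size must be >= 2")
        if self.gray_variant not in ("printed", "bt601"):
            raise ConfigError(f"unknown gray_variant {self.gray_variant!r}")
        if self.f_variant not in ("printed", "canonical"):
            raise ConfigError(f"unknown f_variant {self.f_variant!r}")
        if self.a1 <= 0:
            raise ConfigError("a1 must be positive")
        if not 0.0 <= self.gp <= 1.0:
            raise ConfigError("gp must lie in [0, 1]")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.lambda_floor <= 0:
            raise ConfigError("lambda_floor must be positive")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.distance_threshold < 0:
            raise ConfigError("distance_threshold must be >= 0")
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if self.closing_radius < 1:
            raise ConfigError("closing_radius must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")

    def replace(self, **overrides: Any) -> "RunConfig":
        """Return a copy with the given fields overridden (validated)."""
        return dataclasses.replace(self, **overrides)


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Unknown keys are rejected rather than ignored, so a typo in a config file
    cannot silently fall back to a default.
    """
    values: dict[str, Any] = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
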