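"""Pipeline configuration: a plain YAML mapping, strictly validated.

Every knob that papers over an underdetermined methodological choice
(period anchoring, baseline window, counterfactual anchor mode,
significance level, classification bands, robust-SE flavor) is a named key
here, so each such decision is visible and overridable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "PipelineConfig", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


_TOP_KEYS = {
    "output_dir", "seed", "alpha", "period_width", "anchor_year",
    "baseline_window", "anchor_mode", "class_better", "class_worse",
    "subregion_source", "paths", "synthetic",
}
_PATH_KEYS = {"observations", "covariates", "scenarios", "registry"}


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    seed: int = 0
    alpha: float = 0.05
    period_width: int = 5
    anchor_year: int = 2000
    baseline_window: tuple[int, int | None] = (2015, None)
    anchor_mode: str = "window_average"  # or "latest"
    class_better: float = 0.1
    class_worse: float = -0.1
    subregion_source: str = "covariates"  # or "printed"
    paths: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    raw_text: str = ""  # original YAML text, hashed into the run manifest

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.period_width < 1:
            raise ConfigError("period_width must be >= 1")
        if self.anchor_mode not in {"window_average", "latest"}:
            raise ConfigError(f"unknown anchor_mode {self.anchor_mode!r}")
        if self.subregion_source not in {"covariates", "printed"}:
            raise ConfigError(f"unknown subregion_source {self.subregion_source!r}")
        if self.class_worse > self.class_better:
            raise ConfigError("class_worse must not exceed class_better")
        unknown = set(self.paths) - _PATH_KEYS
        if unknown:
            raise ConfigError(f"unknown path key(s): {sorted(unknown)}")

    def path(self, key: str) -> Path | None:
        p = self.paths.get(key)
        return Path(p) if p else None

    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.raw_text.encode("utf-8")).hexdigest()


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config file, apply keyword overrides, and validate.

    Unknown keys raise :class:`ConfigError` before any computation.
    """
    data: dict = {}
    text = ""
    if path is not None:
        text = Path(path).read_text("utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "baseline_window" in data and data["baseline_window"] is not None:
        lo, hi = data["baseline_window"]
        data["baseline_window"] = (int(lo), None if hi is None else int(hi))
    cfg = PipelineConfig(**data, raw_text=text)
    cfg.validate()
    return cfg
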