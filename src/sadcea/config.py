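"""Run configuration for the command-line interface."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the field."""


@dataclass(frozen=True)
class RunConfig:
    """Validated settings of one analysis run."""

    out_dir: str = "sadcea_out"
    posterior_file: str | None = None
    n_iter: int = 10_000
    seed: int = 20150101
    threshold_start: float = 0.0
    threshold_stop: float = 50_000.0
    threshold_step: float = 250.0
    wtp_threshold: float = 20_000.0
    scenarios: tuple[str, ...] = ()
    report_precision: int = 2

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be at least 1")
        if self.threshold_step <= 0:
            raise ConfigError("threshold_step must be positive")
        if self.threshold_stop < self.threshold_start:
            raise ConfigError("threshold_stop must be >= threshold_start")
        if self.wtp_threshold < 0:
            raise ConfigError("wtp_threshold must be nonnegative")
        if self.report_precision < 0:
            raise ConfigError("report_precision must be nonnegative")
        object.__setattr__(self, "scenarios", tuple(self.scenarios))

    @property
    def thresholds(self) -> np.ndarray:
        return np.arange(
            self.threshold_start, self.threshold_stop + self.threshold_step / 2, self.threshold_step
        )

    @property
    def out_path(self) -> Path:
        return Path(self.out_dir)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (``None``/empty: defaults)."""
    if path is None:
        return RunConfig()
    raw: Mapping[str, Any] | None = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
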