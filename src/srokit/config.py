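"""Run configuration: one flat mapping covering every tunable stage knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .bhc import BhcConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys in config files are rejected.

    Defaults follow the published analysis where it states a value (1000
    bootstrap samples; discretization thresholds -1/+1) and the package's
    documented choices elsewhere.
    """

    seed: int = 0
    n_bootstrap: int = 1000
    variance_mode: str = "raw"          # "raw" | "of_mean"
    down_threshold: float = -1.0
    up_threshold: float = 1.0
    alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    conc: float = 1.0
    cut_threshold: float = 0.5
    open_gap: float = -11.0
    extend_gap: float = -1.0
    matrix: str = "BLOSUM62"
    long_loop_min: int = 30

    def __post_init__(self) -> None:
        if not self.down_threshold < self.up_threshold:
            raise ValueError("discretization thresholds must be ordered")
        if self.variance_mode not in ("raw", "of_mean"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        self.alpha = tuple(self.alpha)

    def bhc_config(self) -> BhcConfig:
        return BhcConfig(
            alpha=self.alpha, conc=self.conc, cut_threshold=self.cut_threshold
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML config file; fail fast on unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)
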