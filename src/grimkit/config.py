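"""Run configuration: YAML loading with strict key checking."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings for a full analysis run.

    Unknown keys are rejected at load time; referenced input paths must
    exist.  ``landmark_mapping`` translates pose-estimation bodypart names
    into the canonical vocabulary; ``tasting_events`` holds per-animal
    tasting timestamps (seconds) for tastant frame selection.
    """

    input_paths: list[str] = field(default_factory=list)
    landmark_mapping: dict[str, str] = field(default_factory=dict)
    tasting_events: dict[str, list[float]] = field(default_factory=dict)
    tastant_window_s: float = 5.0
    alpha: float = 0.05
    bonferroni_m: int = 1
    posthoc_method: str = "tukey"
    pca_standardize: bool = True
    parallel_iterations: int = 1000
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    umap_metric: str = "euclidean"
    confidence_threshold: float = 0.6
    seed: Optional[int] = None
    output_dir: str = "."

    def validate(self) -> None:
        for p in self.input_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input path does not exist: {p}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, Mapping):
        raise ValueError("run config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
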