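"""Run configuration: one declarative YAML file with schema validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable parameters of the end-to-end pipeline.

    Defaults mirror the reference analysis: 3 ms rate-smoothing SD; 10 ms
    label kernel with cutoff 0.05; cPCA benchmark 0.2; SVM C = 1 and
    eps = 1e-3; 10-fold trial-level CV; TC thresholds 25 with sweep 10-40.
    """

    rate_sd_ms: float = 3.0
    label_kernel_sd_ms: float = 10.0
    label_cutoff: float = 0.05
    detector_window_ms: int = 10
    detector_k: float = 6.0
    benchmark: float = 0.2
    svm_c: float = 1.0
    svm_eps: float = 1e-3
    cv_folds: int = 10
    seed: int = 0
    tc_threshold_x: float = 25.0
    tc_threshold_y: float = 25.0
    tc_sweep_min: int = 10
    tc_sweep_max: int = 40
    tc_run_sweep: bool = False
    velocity_jitter_sd: float = 0.0
    use_truth_labels: bool = False
    per_trial_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        positive = ["rate_sd_ms", "label_kernel_sd_ms", "label_cutoff",
                    "detector_window_ms", "detector_k", "svm_c", "svm_eps",
                    "tc_threshold_x", "tc_threshold_y"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        if self.benchmark < 0:
            raise ParameterError("benchmark must be >= 0")
        if self.tc_sweep_max < self.tc_sweep_min:
            raise ParameterError("tc_sweep_max must be >= tc_sweep_min")
        if self.velocity_jitter_sd < 0:
            raise ParameterError("velocity_jitter_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
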