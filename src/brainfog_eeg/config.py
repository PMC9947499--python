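"""Run configuration: one YAML-serializable object covering every stage.

A single master seed drives the whole run; each stochastic stage draws from
a named stream derived from it, so changing one stage's randomness never
perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .avalanche import DetectionConfig
from .preprocess import PipelineConfig
from .synth import CohortSpec, default_cohort_specs

__all__ = ["RunConfig", "derive_seed", "derive_rng"]


def derive_seed(master_seed: int, stream: str) -> int:
    """A stable sub-seed (< 2**31) for a named stage stream."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=tuple(stream.encode()))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def derive_rng(master_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stream))


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    seed: int = 0
    out_dir: str = "run_output"
    log_level: str = "INFO"

    # synthetic cohorts
    n_subjects: int = 8
    delta_sigma: float = 0.15
    duration_s: float = 120.0
    fs: float = 250.0
    n_channels: int = 137
    cascade_rate_hz: float = 3.0
    cascade_max_duration: int = 25
    event_amplitude_sd: float = 20.0
    noise_sd_uv: float = 10.0
    n_trials_per_paradigm: int = 40

    # preprocessing / detection / classification
    pipeline: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    test_fraction: float = 0.3
    n_folds: int = 6
    shrinkage: float = 0.1

    def cohort_specs(self) -> list[CohortSpec]:
        return default_cohort_specs(
            delta_sigma=self.delta_sigma,
            n_subjects=self.n_subjects,
            noise_sd_uv=self.noise_sd_uv,
        )

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(**self.pipeline)

    def detection_config(self) -> DetectionConfig:
        det = dict(self.detection)
        if "sweep_multipliers" in det:
            det["sweep_multipliers"] = tuple(det["sweep_multipliers"])
        return DetectionConfig(**det)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def digest(self) -> str:
        """Content hash of the canonical YAML form."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()
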