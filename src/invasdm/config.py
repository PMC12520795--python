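"""Declarative run configuration for the end-to-end pipeline.

A single YAML document drives a full run: landscape geometry, truth
coefficients, sampling sizes, coordinate-uncertainty thresholds,
pseudo-absence design, cross-validation design, algorithm registry
selection, ensemble schemes, metric options and one global seed from which
every stage seed is derived. Configs round-trip losslessly through
``to_dict``/``from_dict``/YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class LandscapeConfig:
    n_rows: int = 60
    n_cols: int = 60
    cell_size_m: float = 1000.0
    n_predictors: int = 6
    smoothness: float = 3.0
    correlated_pair: list = field(default_factory=lambda: ["L1", "L2"])
    pair_correlation: float = 0.85
    na_fraction: float = 0.02
    invasive_region: str = "invasive"
    native_region: str = "native"
    invasive_fraction: float = 0.65  # fraction of columns assigned to the invasive range


@dataclass
class TruthConfig:
    coefficients: dict = field(default_factory=lambda: {"L1": 2.0, "L3": -1.0})
    intercept: float = -0.5


@dataclass
class SamplingConfig:
    n_invasive: int = 800
    n_native: int = 150
    n_effort_observations: int = 20000
    effort_concentration: float = 1.5  # how strongly observers cluster
    # upper end of the heavy-tailed native-range CU mixture; scale it down
    # with the landscape so uncertainty buffers do not swallow the region
    native_cu_tail_max_m: float = 15000.0


@dataclass
class CUConfig:
    max_cu_m: dict = field(default_factory=lambda: {"invasive": 1000.0, "native": 15000.0})
    keep_missing: bool = False


@dataclass
class PAConfig:
    n_sets: int = 10
    mode: dict = field(default_factory=lambda: {"invasive": "cell", "native": "buffer"})


@dataclass
class CVConfig:
    train_frac: float = 0.7
    n_reps: int = 10


@dataclass
class MetricsConfig:
    boyce_window: float = 0.1
    boyce_windows: int = 101


@dataclass
class ImportanceConfig:
    n_shuffles: int = 9


@dataclass
class OverlapConfig:
    species: dict = field(default_factory=lambda: {"focal_a": 40, "focal_b": 12})
    n_survey_points: int = 150


@dataclass
class RunConfig:
    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    truth: TruthConfig = field(default_factory=TruthConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    cu: CUConfig = field(default_factory=CUConfig)
    pa: PAConfig = field(default_factory=PAConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    algorithms: list = field(default_factory=lambda: ["rf", "gbm", "cta", "ann"])
    hyperparams: dict = field(default_factory=dict)  # per-algorithm overrides
    ensemble_schemes: list = field(default_factory=lambda: ["EMmean", "EMca", "EMwmean"])
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    importance: ImportanceConfig = field(default_factory=ImportanceConfig)
    overlap: OverlapConfig = field(default_factory=OverlapConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sections = {
            "landscape": LandscapeConfig,
            "truth": TruthConfig,
            "sampling": SamplingConfig,
            "cu": CUConfig,
            "pa": PAConfig,
            "cv": CVConfig,
            "metrics": MetricsConfig,
            "importance": ImportanceConfig,
            "overlap": OverlapConfig,
        }
        kwargs = {}
        for key, val in d.items():
            if key in sections:
                kwargs[key] = sections[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def demo_config() -> RunConfig:
    """The bundled small-landscape demo configuration."""
    path = Path(__file__).parent / "data" / "demo.yaml"
    return RunConfig.from_yaml(path)
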