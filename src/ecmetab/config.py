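"""Pipeline configuration: every threshold the workflow applies, in one place.

Defaults follow the published workflow: a two-step blank filter at fold
change > 1.2 / < 0.8 with an uncorrected Welch p < 0.05, a QC CV cut at
20%, dose-response calls at |r_s| > 0.7 with BH q < 0.05, annotation
tolerances of +/-15 ppm and +/-0.2 min (0.7 min for targeted extraction),
component score weights 100/60/50/20 with a 70% acceptance score, the
"<1% of group median" low-value outlier rule, and the two-of-three
experiment consistency requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ScoreWeights", "read_config", "write_config"]


@dataclass(frozen=True)
class ScoreWeights:
    """Relative weights of the annotation composite-score components."""

    mass: float = 100.0
    isotope_abundance: float = 60.0
    isotope_spacing: float = 50.0
    rt: float = 20.0


@dataclass
class PipelineConfig:
    # blank filter
    fc_up: float = 1.2
    fc_down: float = 0.8
    alpha: float = 0.05
    blank_statistic: str = "mean"  # "median" for the protocol-rating preset
    # QC handling
    qc_cv_max: float = 0.20
    loess_span: float = 0.75
    loess_degree: int = 2
    min_qc: int = 5
    # dose-response screen
    rs_min: float = 0.7
    q_max: float = 0.05
    outlier_fraction: float = 0.01
    min_experiments: int = 2
    bh_per_mode: bool = True
    # annotation
    mass_tol_ppm: float = 15.0
    rt_tol_match: float = 0.2
    rt_tol_targeted: float = 0.7
    isotope_abundance_tol: float = 0.25  # relative intensity deviation
    isotope_spacing_tol_mda: float = 5.0
    score_weights: ScoreWeights = field(default_factory=ScoreWeights)
    score_min: float = 70.0  # percent
    annotation_rule: str = "two_of_three"  # or "score_and_two"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # fc_up == 1 is allowed so the protocol-rating rule (strict FC > 1)
        # is expressible; the proof-of-concept default keeps fc_up > 1.
        if not (0 < self.fc_down < 1 <= self.fc_up):
            raise ValueError("require 0 < fc_down < 1 <= fc_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.rs_min <= 1):
            raise ValueError("rs_min must be in (0, 1]")
        if not (0 < self.q_max < 1):
            raise ValueError("q_max must be in (0, 1)")
        for name in ("qc_cv_max", "mass_tol_ppm", "rt_tol_match",
                     "rt_tol_targeted", "outlier_fraction", "loess_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")
        if self.blank_statistic not in ("mean", "median"):
            raise ValueError(f"unknown blank_statistic {self.blank_statistic!r}")
        if self.annotation_rule not in ("two_of_three", "score_and_two"):
            raise ValueError(f"unknown annotation_rule {self.annotation_rule!r}")

    # -- presets ----------------------------------------------------------

    @classmethod
    def protocol_rating(cls, **overrides) -> "PipelineConfig":
        """Preset for protocol comparison: median fold change > 1, p < 0.05.

        Used when rating sample-preparation protocols against each other;
        the proof-of-concept preset (the dataclass defaults) instead uses
        mean fold change > 1.2.
        """
        overrides.setdefault("fc_up", 1.0)  # classification uses strict fc > fc_up
        overrides.setdefault("blank_statistic", "median")
        return cls(**overrides)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "score_weights" in d and isinstance(d["score_weights"], dict):
            d["score_weights"] = ScoreWeights(**d["score_weights"])
        return cls(**d)


def read_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a flat YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
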