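"""Run configuration: one YAML file drives the whole pipeline.

Every analysis threshold is surfaced here with its standard default
(probe missingness 1%, metabolite missing-or-zero 20%, participant
missingness 5%, EWAS top fraction 1%, tenfold cross-validation, Bonferroni
alpha 0.05, 4:1 train/test split, top-5000 CpGs for enrichment).  Unknown
keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .simdata import SimConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    outdir: str = "epimetab_run"
    seed: int = 0
    delimiter: str = "\t"

    # stage parameters
    simulate: SimConfig = field(default_factory=SimConfig)
    max_probe_missing_rate: float = 0.01
    max_metabolite_missing_or_zero: float = 0.20
    max_sample_missing_rate: float = 0.05
    knn_k: int = 10
    drug_list: tuple[str, ...] = ()
    train_fraction: float = 0.8
    top_fraction: float = 0.01
    folds: int = 10
    lambda_rule: str = "min"
    bonferroni_alpha: float = 0.05
    clock_feature_space: str = "surrogate"
    alpha_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0)
    top_k_cpgs: int = 5000
    annotation_path: str | None = None

    def validate(self) -> None:
        for name, lo, hi in (
            ("max_probe_missing_rate", 0.0, 1.0),
            ("max_metabolite_missing_or_zero", 0.0, 1.0),
            ("max_sample_missing_rate", 0.0, 1.0),
            ("top_fraction", 0.0, 1.0),
            ("bonferroni_alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name} must be in [{lo}, {hi}], got {v!r}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError(f"train_fraction must be in (0, 1), got {self.train_fraction!r}")
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.knn_k < 1:
            raise ValidationError("knn_k must be >= 1")
        if self.top_k_cpgs < 1:
            raise ValidationError("top_k_cpgs must be >= 1")
        if self.clock_feature_space not in ("surrogate", "metabolite"):
            raise ValidationError("clock_feature_space must be 'surrogate' or 'metabolite'")
        if self.lambda_rule not in ("min", "1se"):
            raise ValidationError("lambda_rule must be 'min' or '1se'")
        for a in self.alpha_grid:
            if not (0.0 <= a <= 1.0):
                raise ValidationError("alpha_grid entries must be in [0, 1]")
        self.simulate.validate()

    @property
    def out(self) -> Path:
        return Path(self.outdir)


def _from_mapping(cls, data: dict, context: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(f"unknown {context} key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "simulate":
            if not isinstance(value, dict):
                raise ValidationError("'simulate' must be a mapping")
            if "age_range" in value:
                value = {**value, "age_range": tuple(value["age_range"])}
            if "risk_effects" in value and value["risk_effects"] is None:
                value = {**value, "risk_effects": {}}
            kwargs[key] = _from_mapping(SimConfig, value, "simulate")
        elif isinstance(value, list) and key in ("alpha_grid", "drug_list"):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys error."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValidationError("run config must be a YAML mapping")
    cfg = _from_mapping(RunConfig, raw, "config")
    cfg.validate()
    return cfg
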