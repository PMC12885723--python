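"""Analysis configuration shared by the mediation screen and the pipeline.

Defaults mirror the conventional screening settings for relaxed-threshold
cytokine/metabolite MR: instruments at P < 1e-5, LD clumping at r2 >= 0.001
within a 10,000 kb window, a per-SNP F > 10 weak-instrument screen, gating
at alpha = 0.05 on the primary IVW p-value, and a multiplicative
random-effects IVW model.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Optional

import yaml

__all__ = ["AnalysisConfig", "ConfigError"]


class ConfigError(ValueError):
    """An analysis configuration value is out of its valid range."""


@dataclass
class AnalysisConfig:
    instrument_p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    alpha: float = 0.05
    ivw_model: str = "random"
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 20240401
    #: reverse-direction instrument threshold; None -> same as forward
    reverse_p_threshold: Optional[float] = None
    exposure_dialect: str = "generic"
    outcome_dialect: str = "generic"
    mediator_dialect: str = "generic"
    exposure_n: Optional[int] = None
    outcome_n: Optional[int] = None
    mediator_n: Optional[int] = None
    #: apply no multiple-testing correction by default (raw p < alpha gates);
    #: "bonferroni" or "fdr_bh" may be selected for the screening stages
    multiple_testing: str = "none"

    def __post_init__(self) -> None:
        if not (0 < self.instrument_p_threshold < 1):
            raise ConfigError("instrument_p_threshold must lie in (0, 1)")
        if not (0 < self.clump_r2 <= 1):
            raise ConfigError("clump_r2 must lie in (0, 1]")
        if self.clump_window_kb < 0:
            raise ConfigError("clump_window_kb must be non-negative")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.ivw_model not in ("fixed", "random"):
            raise ConfigError("ivw_model must be 'fixed' or 'random'")
        if self.presso_n_sim < 100:
            raise ConfigError("presso_n_sim must be at least 100")
        if self.n_boot < 2:
            raise ConfigError("n_boot must be at least 2")
        if self.reverse_p_threshold is not None and not (0 < self.reverse_p_threshold < 1):
            raise ConfigError("reverse_p_threshold must lie in (0, 1)")
        if self.multiple_testing not in ("none", "bonferroni", "fdr_bh"):
            raise ConfigError("multiple_testing must be none, bonferroni or fdr_bh")

    @property
    def reverse_threshold(self) -> float:
        return (
            self.instrument_p_threshold
            if self.reverse_p_threshold is None
            else self.reverse_p_threshold
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)
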