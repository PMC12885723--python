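"""Two-step MR mediation: product-of-coefficients effect and mediated proportion.

The mediated effect of an exposure on an outcome through a mediator is the
product beta1 * beta2 of the exposure->mediator and mediator->outcome causal
estimates; the mediated proportion is that product divided by the total
effect beta of the exposure on the outcome.  The screening cascade mirrors a
cytokine -> metabolite -> disease analysis:

1. forward MR exposure -> outcome (IVW); keep exposures with p < alpha;
2. reverse MR outcome -> exposure; require p >= alpha (no reverse causality);
3. MR mediator -> outcome; keep p < alpha and drop mediators with pleiotropy
   evidence (Egger intercept p < alpha or MR-PRESSO global p < alpha);
4. MR exposure -> mediator; keep p < alpha;
5. product mediation for every surviving (exposure, mediator) pair.

All gating uses the primary IVW p-value; every intermediate estimate and
drop reason is logged.  Proportions outside [0, 100]% — the suppression
pattern where the product opposes the total effect — are reported verbatim
with ``consistent_direction`` false rather than truncated.
"""
from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .estimators import MREstimate, egger, ivw, wald_ratio
from .gwas_io import SummaryStats, harmonize
from .instruments import filter_weak, select_instruments
from .sensitivity import mr_presso

__all__ = ["MediationResult", "ScreenResult", "product_mediation", "two_step_screen"]


@dataclass
class MediationResult:
    """Product-method mediation summary for one exposure/mediator/outcome path."""

    exposure: str
    mediator: str
    outcome: str
    total_beta: float
    step1_beta: float  # exposure -> mediator
    step2_beta: float  # mediator -> outcome
    product: float = field(init=False)
    proportion: float = field(init=False)  # fraction of the total effect
    consistent_direction: bool = field(init=False)
    product_se: Optional[float] = None

    def __post_init__(self) -> None:
        self.product = self.step1_beta * self.step2_beta
        if self.total_beta == 0:
            self.proportion = float("nan")
        else:
            self.proportion = self.product / self.total_beta
        self.consistent_direction = (
            math.copysign(1.0, self.product) == math.copysign(1.0, self.total_beta)
            if self.product != 0 and self.total_beta != 0
            else self.product == 0
        )

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def product_mediation(
    total_beta: float,
    step1_beta: float,
    step2_beta: float,
    *,
    exposure: str = "",
    mediator: str = "",
    outcome: str = "",
    step1_se: Optional[float] = None,
    step2_se: Optional[float] = None,
) -> MediationResult:
    """Mediated effect beta1*beta2 and mediated proportion (beta1*beta2)/beta.

    A zero ``total_beta`` leaves the proportion undefined (NaN, with a
    warning); the product is still returned.  When both step standard errors
    are supplied, a delta-method SE for the product,
    sqrt(beta1^2 * se2^2 + beta2^2 * se1^2), is attached.
    """
    res = MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        total_beta=total_beta,
        step1_beta=step1_beta,
        step2_beta=step2_beta,
    )
    if total_beta == 0:
        warnings.warn("total effect is zero; mediated proportion undefined", stacklevel=2)
    elif not res.consistent_direction and res.product != 0:
        warnings.warn(
            f"{exposure}/{mediator}: mediated effect opposes the total effect "
            "(suppression); proportion reported verbatim",
            stacklevel=2,
        )
    if step1_se is not None and step2_se is not None:
        res.product_se = math.sqrt(
            step1_beta**2 * step2_se**2 + step2_beta**2 * step1_se**2
        )
    return res


@dataclass
class ScreenResult:
    """Surviving mediation paths plus a stage-by-stage audit log."""

    results: list  # MediationResult
    log: list  # dicts: stage, exposure/trait, action, detail

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)


def _trait_seed(base_seed: int, *names: str) -> int:
    """Stable per-pair sub-seed below 2**31."""
    h = zlib.crc32("|".join(names).encode())
    return (base_seed * 1000003 + h) % (2**31 - 1)


def _mr_between(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: AnalysisConfig,
    p_threshold: Optional[float] = None,
):
    """Instrument selection + harmonization + IVW between two traits.

    Returns (estimate | None, harmonized | None, detail) where ``detail``
    explains a None estimate.
    """
    p = config.instrument_p_threshold if p_threshold is None else p_threshold
    inst = select_instruments(
        exposure,
        p_threshold=p,
        clump_r2=config.clump_r2,
        clump_window_kb=config.clump_window_kb,
    )
    inst = filter_weak(inst, config.f_min)
    if inst.k == 0:
        return None, None, "no_instruments"
    hs = harmonize(inst, outcome)
    k = len(hs)
    if k == 0:
        return None, hs, "no_harmonized_pairs"
    if k == 1:
        row = hs.pairs.iloc[0]
        est = wald_ratio(
            row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"],
            exposure=hs.exposure_name, outcome=hs.outcome_name,
        )
        return est, hs, f"k=1 (wald)"
    model = config.ivw_model if k >= 2 else "fixed"
    return ivw(hs, model=model), hs, f"k={k}"


def _pleiotropic(hs, config: AnalysisConfig) -> Optional[str]:
    """Pleiotropy-exclusion rule: Egger intercept p or PRESSO global p < alpha."""
    k = len(hs)
    if k >= 3:
        fit = egger(hs)
        if fit.intercept_pval < config.alpha:
            return f"egger_intercept_p={fit.intercept_pval:.4g}"
    if k >= 4:
        presso = mr_presso(
            hs,
            n_sim=config.presso_n_sim,
            significance=config.alpha,
            seed=_trait_seed(config.seed, hs.exposure_name, hs.outcome_name, "presso"),
        )
        if presso.global_pval < config.alpha:
            return f"presso_global_p={presso.global_pval:.4g}"
    return None


def two_step_screen(
    exposures: list[SummaryStats],
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    config: AnalysisConfig | None = None,
) -> ScreenResult:
    """Run the full two-step mediation screening cascade (see module docs)."""
    config = config or AnalysisConfig()
    log: list[dict] = []
    results: list[MediationResult] = []

    def note(stage, trait, action, detail="", pval=None, beta=None):
        log.append(
            {
                "stage": stage,
                "trait": trait,
                "action": action,
                "detail": detail,
                "pval": pval,
                "beta": beta,
            }
        )

    surviving_exposures: list[tuple[SummaryStats, MREstimate]] = []
    for exp in exposures:
        est, _, detail = _mr_between(exp, outcome, config)
        if est is None:
            note("1_forward", exp.trait_name, "screen_failure", detail)
            continue
        if est.pval >= config.alpha:
            note("1_forward", exp.trait_name, "drop_not_significant", detail, est.pval, est.beta)
            continue
        note("1_forward", exp.trait_name, "keep", detail, est.pval, est.beta)
        rev, _, rev_detail = _mr_between(
            outcome, exp, config, p_threshold=config.reverse_threshold
        )
        if rev is not None and rev.pval < config.alpha:
            note("2_reverse", exp.trait_name, "drop_reverse_causality", rev_detail, rev.pval, rev.beta)
            continue
        note(
            "2_reverse",
            exp.trait_name,
            "keep",
            rev_detail if rev is not None else "outcome_has_no_instruments",
            None if rev is None else rev.pval,
            None if rev is None else rev.beta,
        )
        surviving_exposures.append((exp, est))

    surviving_mediators: list[tuple[SummaryStats, MREstimate]] = []
    for med in mediators:
        est, hs, detail = _mr_between(med, outcome, config)
        if est is None:
            note("3_mediator_outcome", med.trait_name, "screen_failure", detail)
            continue
        if est.pval >= config.alpha:
            note("3_mediator_outcome", med.trait_name, "drop_not_significant", detail, est.pval, est.beta)
            continue
        pleio = _pleiotropic(hs, config)
        if pleio is not None:
            note("3_mediator_outcome", med.trait_name, "drop_pleiotropy", pleio, est.pval, est.beta)
            continue
        note("3_mediator_outcome", med.trait_name, "keep", detail, est.pval, est.beta)
        surviving_mediators.append((med, est))

    for exp, total in surviving_exposures:
        for med, step2 in surviving_mediators:
            step1, _, detail = _mr_between(exp, med, config)
            pair = f"{exp.trait_name}->{med.trait_name}"
            if step1 is None:
                note("4_exposure_mediator", pair, "screen_failure", detail)
                continue
            if step1.pval >= config.alpha:
                note("4_exposure_mediator", pair, "drop_not_significant", detail, step1.pval, step1.beta)
                continue
            note("4_exposure_mediator", pair, "keep", detail, step1.pval, step1.beta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = product_mediation(
                    total.beta,
                    step1.beta,
                    step2.beta,
                    exposure=exp.trait_name,
                    mediator=med.trait_name,
                    outcome=outcome.trait_name,
                    step1_se=step1.se,
                    step2_se=step2.se,
                )
            note(
                "5_mediation",
                pair,
                "result",
                f"proportion_pct={res.proportion_pct:.3f}",
                beta=res.product,
            )
            results.append(res)

    return ScreenResult(results=results, log=log)


_MEDIATION_COLUMNS = [
    "exposure", "mediator", "outcome", "beta_total", "beta1", "beta2",
    "product", "proportion_pct", "consistent_direction",
]


def write_mediation_table(results: list[MediationResult], path) -> None:
    rows = [
        {
            "exposure": r.exposure, "mediator": r.mediator, "outcome": r.outcome,
            "beta_total": r.total_beta, "beta1": r.step1_beta, "beta2": r.step2_beta,
            "product": r.product, "proportion_pct": r.proportion_pct,
            "consistent_direction": r.consistent_direction,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=_MEDIATION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
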