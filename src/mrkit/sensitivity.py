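"""Heterogeneity and pleiotropy diagnostics for an MR analysis.

Cochran's Q tests homogeneity of the per-SNP Wald ratios against a
chi-square with k-1 df.  The MR-Egger intercept (from :mod:`.estimators`)
flags directional pleiotropy.  MR-PRESSO detects individual pleiotropic
outliers by comparing each SNP's leave-one-out IVW residual against a
parametric Monte-Carlo null, with a global residual-sum-of-squares test and
a distortion test for the estimate shift after outlier removal.
Leave-one-out re-estimation and funnel-plot data round out the report.

All Monte-Carlo p-values use the (1 + b) / (1 + n) estimator, so a p-value
of exactly zero cannot occur.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import (
    InsufficientInstrumentsError,
    MREstimate,
    _arrays,
    _ivw_fit,
    egger,
    ivw,
)

__all__ = [
    "PressoResult",
    "SensitivityReport",
    "cochran_q",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
    "full_report",
]


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_indices: list
    outlier_pvals: list  # Bonferroni-adjusted, one per SNP
    distortion_pval: Optional[float]
    n_sim: int
    seed: int


@dataclass
class SensitivityReport:
    q: Optional[float]
    q_df: Optional[int]
    q_pval: Optional[float]
    egger_intercept: Optional[float]
    egger_intercept_se: Optional[float]
    egger_intercept_pval: Optional[float]
    presso: Optional[PressoResult]
    loo: list  # (variant_id, MREstimate)
    funnel: list  # (ratio, precision)

    def to_json(self, path) -> None:
        doc = {
            "q": self.q,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_se": self.egger_intercept_se,
            "egger_intercept_pval": self.egger_intercept_pval,
            "presso": None if self.presso is None else asdict(self.presso),
            "loo": [
                {"variant_id": vid, **{k: v for k, v in asdict(est).items()}}
                for vid, est in self.loo
            ],
            "funnel": [{"ratio": r, "precision": p} for r, p in self.funnel],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=float)


def cochran_q(pairs) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q over per-SNP Wald ratios.

    Q = sum_i w_i (ratio_i - beta_ivw)^2 with w_i = bx_i^2 / sy_i^2; the
    p-value is the upper tail of chi-square with k - 1 df.
    """
    bx, sx, by, sy, _, _ = _arrays(pairs)
    k = bx.size
    if k < 2:
        raise InsufficientInstrumentsError(f"cochran_q needs at least 2 pairs, got {k}")
    _, _, q = _ivw_fit(bx, by, sy)
    q_df = k - 1
    return float(q), q_df, float(sps.chi2.sf(q, q_df))


def _loo_theta(bx, by, w):
    """Leave-one-out IVW slopes for every SNP at once (via totals)."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    pairs,
    n_sim: int = 1000,
    significance: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    The observed statistic is the inverse-variance weighted residual sum of
    squares of leave-one-out IVW predictions.  Its null distribution comes
    from ``n_sim`` parametric datasets with effects drawn around the fitted
    values at the observed standard errors.  Per-SNP outlier p-values are
    Bonferroni-adjusted over k; SNPs below ``significance`` after adjustment
    are outliers.  The distortion p-value compares the observed shift between
    the all-SNP and outlier-free IVW estimates with its simulated null.
    """
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    bx, sx, by, sy, _, _ = _arrays(pairs)
    k = bx.size
    if k < 4:
        raise InsufficientInstrumentsError(f"mr_presso needs at least 4 pairs, got {k}")

    w = 1.0 / sy**2
    theta_loo = _loo_theta(bx, by, w)
    resid = by - theta_loo * bx
    stat_obs = w * resid**2
    rss_obs = float(stat_obs.sum())

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))

    sxy = (w * bx_sim * by_sim).sum(axis=1, keepdims=True)
    sxx = (w * bx_sim * bx_sim).sum(axis=1, keepdims=True)
    theta_loo_sim = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    resid_sim = by_sim - theta_loo_sim * bx_sim
    stat_sim = w * resid_sim**2
    rss_sim = stat_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_raw = (1 + (stat_sim >= stat_obs[None, :]).sum(axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * k)
    outliers = np.flatnonzero(p_adj < significance)

    distortion_pval = None
    if outliers.size and outliers.size < k:
        keep = np.ones(k, dtype=bool)
        keep[outliers] = False
        theta_full = float(np.sum(w * bx * by) / np.sum(w * bx * bx))
        theta_out = float(np.sum((w * bx * by)[keep]) / np.sum((w * bx * bx)[keep]))
        d_obs = theta_full - theta_out
        theta_full_sim = sxy[:, 0] / sxx[:, 0]
        theta_out_sim = (w * bx_sim * by_sim)[:, keep].sum(axis=1) / (
            w * bx_sim * bx_sim
        )[:, keep].sum(axis=1)
        d_sim = theta_full_sim - theta_out_sim
        distortion_pval = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))

    return PressoResult(
        global_rss=rss_obs,
        global_pval=global_pval,
        outlier_indices=[int(i) for i in outliers],
        outlier_pvals=[float(p) for p in p_adj],
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(pairs, model: str = "random") -> list[tuple[str, MREstimate]]:
    """IVW re-estimates with each SNP removed in turn (input order kept)."""
    bx, sx, by, sy, exp_name, out_name = _arrays(pairs)
    if isinstance(pairs, pd.DataFrame):
        ids = pairs["variant_id"].astype(str).tolist()
    else:
        ids = pairs.pairs["variant_id"].astype(str).tolist()
    k = bx.size
    if k < 3:
        raise InsufficientInstrumentsError(f"leave_one_out needs at least 3 pairs, got {k}")
    from .estimators import _normal_estimate

    mask = ~np.eye(k, dtype=bool)
    out = []
    for i in range(k):
        m = mask[i]
        beta, se, q = _ivw_fit(bx[m], by[m], sy[m])
        if model == "random":
            se *= np.sqrt(max(1.0, q / (k - 2)))
        est = _normal_estimate(f"ivw_{model}", beta, se, k - 1, exp_name, out_name)
        out.append((ids[i], est))
    return out


def funnel_data(pairs) -> list[tuple[float, float]]:
    """Per-SNP (Wald ratio, precision) pairs for a funnel plot.

    Precision is the reciprocal of the ratio's first-order SE, |bx| / sy.
    """
    bx, sx, by, sy, _, _ = _arrays(pairs)
    ratios = by / bx
    precision = np.abs(bx) / sy
    return [(float(r), float(p)) for r, p in zip(ratios, precision)]


def full_report(
    pairs,
    presso_n_sim: int = 1000,
    seed: int | None = None,
    significance: float = 0.05,
    loo_model: str = "random",
) -> SensitivityReport:
    """Assemble the complete sensitivity report a study would tabulate.

    Components whose instrument minimum is not met (Q needs 2 pairs, Egger 3,
    MR-PRESSO 4) are reported as None rather than raising.
    """
    k = len(pairs.pairs) if hasattr(pairs, "pairs") else len(pairs)
    q = q_df = q_pval = None
    if k >= 2:
        q, q_df, q_pval = cochran_q(pairs)
    eg_i = eg_se = eg_p = None
    if k >= 3:
        fit = egger(pairs)
        eg_i, eg_se, eg_p = fit.intercept, fit.intercept_se, fit.intercept_pval
    presso = None
    if k >= 4:
        presso = mr_presso(pairs, n_sim=presso_n_sim, significance=significance, seed=seed)
    loo = leave_one_out(pairs, model=loo_model) if k >= 3 else []
    return SensitivityReport(
        q=q,
        q_df=q_df,
        q_pval=q_pval,
        egger_intercept=eg_i,
        egger_intercept_se=eg_se,
        egger_intercept_pval=eg_p,
        presso=presso,
        loo=loo,
        funnel=funnel_data(pairs) if k >= 1 else [],
    )
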