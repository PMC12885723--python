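"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized exposure/outcome effect pairs and return a
causal log-odds (or SD-unit) estimate with a 95% confidence interval and its
odds-ratio transform:

* Wald ratio — the single-SNP building block, beta_out / beta_exp with a
  first-order delta standard error.
* IVW — inverse-variance weighted combination of the Wald ratios,
  equivalently a zero-intercept weighted regression of outcome on exposure
  effects; the multiplicative random-effects variant scales the SE by
  sqrt(max(1, Q / (k - 1))).
* MR-Egger — the same regression with a free intercept; a nonzero intercept
  indicates directional horizontal pleiotropy, and the slope remains a valid
  causal estimate under the InSIDE assumption.  Inference uses a t
  distribution with k - 2 df and a multiplicative overdispersion floor.
* Weighted median — consistent when instruments carrying at least half the
  weight are valid; bootstrap standard error.
* Simple/weighted mode — the argmax of a kernel-smoothed density of the
  per-SNP ratios; bootstrap standard error.

Confidence intervals use the normal 97.5% quantile 1.959964 except MR-Egger,
which uses the small-sample t quantile.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "Z95",
    "MREstimate",
    "EggerFit",
    "InsufficientInstrumentsError",
    "DegenerateInstrumentError",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimate",
    "to_odds_ratio",
]

Z95 = 1.959964


class InsufficientInstrumentsError(ValueError):
    """Fewer harmonized pairs than the estimator's minimum."""


class DegenerateInstrumentError(ValueError):
    """An instrument with zero exposure effect cannot form a Wald ratio."""


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (beta) and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    exposure: str = ""
    outcome: str = ""
    or_: float = field(init=False)
    or_low: float = field(init=False)
    or_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.or_low = math.exp(self.ci_low)
        self.or_high = math.exp(self.ci_high)


@dataclass
class EggerFit:
    """MR-Egger slope estimate plus the intercept pleiotropy test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate: (OR, 95% lower, 95% upper)."""
    if se < 0:
        raise ValueError("se must be non-negative")
    return math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se)


def _normal_estimate(method, beta, se, n_snp, exposure="", outcome="") -> MREstimate:
    pval = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(min(pval, 1.0)),
        n_snp=int(n_snp),
        exposure=exposure,
        outcome=outcome,
    )


def _arrays(pairs):
    """Extract (bx, sx, by, sy, names) from a HarmonizedSet or DataFrame."""
    if isinstance(pairs, pd.DataFrame):
        df, exp, out = pairs, "", ""
    else:
        df, exp, out = pairs.pairs, pairs.exposure_name, pairs.outcome_name
    return (
        df["beta_exp"].to_numpy(dtype=float),
        df["se_exp"].to_numpy(dtype=float),
        df["beta_out"].to_numpy(dtype=float),
        df["se_out"].to_numpy(dtype=float),
        exp,
        out,
    )


def _require(k: int, minimum: int, method: str) -> None:
    if k < minimum:
        raise InsufficientInstrumentsError(
            f"{method} needs at least {minimum} instruments, got {k}"
        )


def wald_ratio(beta_exp, se_exp, beta_out, se_out, exposure="", outcome="") -> MREstimate:
    """Single-SNP causal estimate beta_out/beta_exp (first-order delta SE)."""
    if beta_exp == 0:
        raise DegenerateInstrumentError("beta_exp is zero")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _normal_estimate("wald", beta, se, 1, exposure, outcome)


def _ivw_fit(bx, by, sy):
    """Zero-intercept WLS of by on bx with weights 1/sy^2.

    Returns (beta, fixed-effect se, Q).  Q is Cochran's heterogeneity
    statistic over the per-SNP ratios with weights bx^2/sy^2 — identical to
    the weighted residual sum of squares of this regression.
    """
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(pairs, model: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    ``model="fixed"`` needs one pair (where it collapses to the Wald ratio);
    ``model="random"`` (multiplicative random effects) needs two and scales
    the SE by sqrt(max(1, Q / (k - 1))).
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    bx, sx, by, sy, exp, out = _arrays(pairs)
    k = bx.size
    _require(k, 1 if model == "fixed" else 2, f"ivw_{model}")
    beta, se, q = _ivw_fit(bx, by, sy)
    if model == "random":
        se *= math.sqrt(max(1.0, q / (k - 1)))
    return _normal_estimate(f"ivw_{model}", beta, se, k, exp, out)


def _orient(bx, by):
    """Reflect each pair so the exposure effect is non-negative."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def egger(pairs) -> EggerFit:
    """MR-Egger: weighted regression of by on bx with a free intercept.

    Pairs are pre-oriented to bx >= 0 (the estimator is not invariant to
    per-SNP sign flips).  Standard errors apply a multiplicative
    overdispersion scale floored at 1; p-values use t with k - 2 df.
    """
    bx, sx, by, sy, exp, out = _arrays(pairs)
    k = bx.size
    _require(k, 3, "egger")
    bx, by = _orient(bx, by)
    w = 1.0 / sy**2
    fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
    sigma2 = float(fit.scale)  # weighted RSS / (k - 2)
    cov_unscaled = np.asarray(fit.normalized_cov_params)
    scale = max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov_unscaled) * scale)
    df = k - 2
    tq = sps.t.ppf(0.975, df)

    slope_b, slope_se = float(fit.params[1]), float(ses[1])
    slope_p = float(2.0 * sps.t.sf(abs(slope_b) / slope_se, df))
    slope = MREstimate(
        method="egger",
        beta=slope_b,
        se=slope_se,
        ci_low=slope_b - tq * slope_se,
        ci_high=slope_b + tq * slope_se,
        pval=slope_p,
        n_snp=k,
        exposure=exp,
        outcome=out,
    )
    int_b, int_se = float(fit.params[0]), float(ses[0])
    int_p = float(2.0 * sps.t.sf(abs(int_b) / int_se, df)) if int_se > 0 else 1.0
    return EggerFit(slope=slope, intercept=int_b, intercept_se=int_se, intercept_pval=int_p)


def _weighted_median_point(ratios, weights):
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    csum = np.cumsum(w)
    p = (csum - 0.5 * w) / csum[-1]
    if p[0] >= 0.5:
        return float(r[0])
    if p[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(p, 0.5, side="right")) - 1
    if p[j] == 0.5:
        return float(r[j])
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - p[j]) / (p[j + 1] - p[j]))


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot, seed):
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        est[b] = point_fn(bxb, byb, sy)
    return float(np.std(est, ddof=1))


def weighted_median(pairs, n_boot: int = 1000, seed: int | None = None) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    The estimate is where the normalized cumulative inverse-variance weights
    of the ratio estimates (variance sy^2/bx^2) cross one half, linearly
    interpolated; the SE comes from a seeded parametric bootstrap.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    bx, sx, by, sy, exp, out = _arrays(pairs)
    k = bx.size
    _require(k, 3, "weighted_median")

    def point(bx_, by_, sy_):
        return _weighted_median_point(by_ / bx_, bx_**2 / sy_**2)

    beta = point(bx, by, sy)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    return _normal_estimate("weighted_median", beta, se, k, exp, out)


def _mode_bandwidth(ratios, factor):
    """Modified Silverman rule: 0.9 * min(sd, IQR/1.349) * k^(-1/5)."""
    s = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    q75, q25 = np.percentile(ratios, [75, 25])
    iqr = float(q75 - q25)
    candidates = [v for v in (s, iqr / 1.349) if v > 0]
    if not candidates:
        return 0.0
    return 0.9 * min(candidates) * ratios.size ** (-0.2) * factor


def _mode_point(ratios, weights, factor, grid_size=512):
    h = _mode_bandwidth(ratios, factor)
    if h <= 0:  # point mass
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    z = (grid[:, None] - ratios[None, :]) / h
    dens = (weights[None, :] * np.exp(-0.5 * z * z)).sum(axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimate(
    pairs,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Mode (density argmax) of the per-SNP Wald ratios.

    A normal-kernel density of the ratios is evaluated on a 512-point grid
    spanning [min - 3h, max + 3h]; the weighted variant weights each kernel
    by the ratio's inverse variance.  SE by seeded parametric bootstrap.
    """
    if seed is None:
        raise ValueError("mode_estimate requires an explicit seed")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    bx, sx, by, sy, exp, out = _arrays(pairs)
    k = bx.size
    _require(k, 3, "mode")

    def point(bx_, by_, sy_):
        ratios = by_ / bx_
        w = bx_**2 / sy_**2 if weighted else np.ones_like(ratios)
        return _mode_point(ratios, w / w.sum(), bandwidth_factor)

    beta = point(bx, by, sy)
    se = _bootstrap_se(point, bx, sx, by, sy, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(method, beta, se, k, exp, out)
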