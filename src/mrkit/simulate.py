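"""Synthetic GWAS summary-statistics generator with known causal truth.

Summary statistics are simulated directly — no individual-level genotypes —
which is all a two-sample MR analysis consumes.  For SNP j with effect-allele
frequency EAF_j and a GWAS of N individuals, the standard error of a
standardized per-allele effect is 1 / sqrt(2 * EAF_j * (1 - EAF_j) * N); the
observed effect is the true effect plus normal noise at that SE.  Exposure
and outcome noise are independent (non-overlapping samples).

Scenario knobs mirror the structures an MR study must survive: horizontal
pleiotropy (balanced zero-mean or directional constant-sign, on a configured
fraction of SNPs, independent of instrument strength so InSIDE holds by
construction), palindromic A/T / C/G allele pairs, block-structured LD with
correlated true effects inside blocks, a mediator chain
exposure -> mediator -> outcome plus a direct path, and reverse causation
from the outcome's own instruments.

Default cohort sizes follow a cytokine (N=14,824) / metabolite (N=8,299) /
binary-disease (3,880 cases vs 381,977 controls) design; binary outcomes use
the effective sample size 4 / (1/cases + 1/controls).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gwas_io import COLUMNS, SummaryStats
from .instruments import LDMatrix

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_pair",
    "simulate_mediation",
    "write_fixture",
    "read_fixture",
]

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Study-design parameters for the generator.

    ``effect_dist`` sets the per-SNP true exposure effect magnitude:
    ``("uniform", lo, hi)`` draws uniformly (default 0.03-0.25 SD per allele,
    the weak-to-strong span of protein/metabolite QTLs: F roughly 4-470 at
    the default cohort sizes, so the F > 10 screen bites), and
    ``("halfnormal", scale)`` draws |N(0, scale^2)|.  Effects are positive so
    a directional pleiotropy scenario keeps its sign after the conventional
    orientation of pairs.
    """

    seed: int
    n_snp: int = 100
    n_snp_outcome: int = 100
    n_exposure: int = 14_824
    n_mediator: int = 8_299
    n_outcome: Optional[int] = None  # overrides the case/control effective N
    n_cases: int = 3_880
    n_controls: int = 381_977
    theta: float = 0.0
    theta1: Optional[float] = None
    theta2: Optional[float] = None
    direct_effect: float = 0.0
    reverse_theta: float = 0.0
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.1
    prop_invalid: float = 0.0
    eaf_range: tuple = (0.1, 0.9)
    effect_dist: tuple = ("uniform", 0.03, 0.25)
    ld_blocks: Optional[tuple] = None  # (block_size, within_block_r2)
    palindromic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        for name in ("prop_invalid", "palindromic_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_exposure", "n_mediator"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be at least 100")
        if self.n_outcome is not None and self.n_outcome < 100:
            raise ValueError("n_outcome must be at least 100")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy must be none, balanced or directional")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must satisfy 0 < lo < hi < 1")
        if self.effect_dist[0] not in ("uniform", "halfnormal"):
            raise ValueError("effect_dist must be ('uniform', lo, hi) or ('halfnormal', scale)")
        if self.ld_blocks is not None:
            size, r2 = self.ld_blocks
            if size < 1 or not (0 <= r2 <= 1):
                raise ValueError("ld_blocks must be (block_size >= 1, r2 in [0, 1])")
        if self.n_snp < 1:
            raise ValueError("n_snp must be at least 1")

    @property
    def effective_n_outcome(self) -> float:
        """Effective N for the binary outcome: 4 / (1/cases + 1/controls)."""
        if self.n_outcome is not None:
            return float(self.n_outcome)
        return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated dataset."""

    theta: float
    theta1: Optional[float] = None
    theta2: Optional[float] = None
    direct_effect: float = 0.0
    per_snp_pleiotropy: list = field(default_factory=list)

    @property
    def true_total(self) -> Optional[float]:
        if self.theta1 is None or self.theta2 is None:
            return None
        return self.direct_effect + self.theta1 * self.theta2

    @property
    def true_proportion(self) -> Optional[float]:
        total = self.true_total
        if total is None or total == 0:
            return None
        return self.theta1 * self.theta2 / total


def _standard_error(eaf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _draw_effects(rng: np.random.Generator, dist: tuple, size: int) -> np.ndarray:
    if dist[0] == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    return np.abs(rng.normal(0.0, dist[1], size))


def _alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    n_pal = int(round(palindromic_fraction * n))
    pal_idx = rng.choice(n, size=n_pal, replace=False) if n_pal else np.array([], dtype=int)
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_mask = np.zeros(n, dtype=bool)
    pal_mask[pal_idx] = True
    pal_pick = rng.integers(0, len(_PALINDROMIC), n)
    non_pick = rng.integers(0, len(_NONPALINDROMIC), n)
    for i in range(n):
        ea[i], oa[i] = _PALINDROMIC[pal_pick[i]] if pal_mask[i] else _NONPALINDROMIC[non_pick[i]]
    return ea, oa, pal_mask


@dataclass
class _SnpPanel:
    """Shared per-SNP attributes (identical across the traits of one study)."""

    ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ea: np.ndarray
    oa: np.ndarray
    eaf: np.ndarray
    palindromic: np.ndarray


def _panel(rng, cfg, prefix: str, n: int, pos_offset: int = 0) -> _SnpPanel:
    eaf = rng.uniform(cfg.eaf_range[0], cfg.eaf_range[1], n)
    ea, oa, pal = _alleles(rng, n, cfg.palindromic_fraction)
    ids = [f"{prefix}_{i + 1:05d}" for i in range(n)]
    pos = (np.arange(n) + pos_offset) * 100_000 + 1
    return _SnpPanel(ids, np.full(n, "1", dtype=object), pos, ea, oa, eaf, pal)


def _observe(rng, panel: _SnpPanel, true_beta: np.ndarray, n_sample: float) -> pd.DataFrame:
    from scipy import stats as sps

    se = _standard_error(panel.eaf, n_sample)
    beta = rng.normal(true_beta, se)
    z = beta / se
    pval = np.clip(2.0 * sps.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "variant_id": panel.ids,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "effect_allele": panel.ea,
            "other_allele": panel.oa,
            "eaf": panel.eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": int(round(n_sample)),
        },
        columns=COLUMNS,
    )


def _exposure_effects_and_ld(rng, cfg) -> tuple[np.ndarray, Optional[LDMatrix], list]:
    """True exposure effects; with LD blocks, non-lead SNPs replicate the
    lead effect scaled by sqrt(r2) and the matrix is block diagonal."""
    gamma = _draw_effects(rng, cfg.effect_dist, cfg.n_snp)
    ld = None
    ids = [f"exp_{i + 1:05d}" for i in range(cfg.n_snp)]
    if cfg.ld_blocks is not None:
        size, r2 = cfg.ld_blocks
        r = math.sqrt(r2)
        mat = np.eye(cfg.n_snp)
        for start in range(0, cfg.n_snp, size):
            stop = min(start + size, cfg.n_snp)
            gamma[start + 1 : stop] = r * gamma[start]
            block = slice(start, stop)
            mat[block, block] = np.where(np.eye(stop - start, dtype=bool), 1.0, r2)
        ld = LDMatrix(ids, mat)
    return gamma, ld, ids


def _pleiotropy(rng, cfg, n: int) -> np.ndarray:
    alpha = np.zeros(n)
    n_invalid = int(round(cfg.prop_invalid * n))
    if cfg.pleiotropy == "none" or n_invalid == 0:
        return alpha
    idx = rng.choice(n, size=n_invalid, replace=False)
    if cfg.pleiotropy == "directional":
        alpha[idx] = cfg.pleiotropy_magnitude
    else:  # balanced: zero mean
        alpha[idx] = rng.normal(0.0, cfg.pleiotropy_magnitude, n_invalid)
    return alpha


def simulate_pair(config: SimulationConfig):
    """Simulate an exposure/outcome GWAS pair with true effect ``theta``.

    Returns (exposure, outcome, truth, ld).  Both tables cover the union of
    the exposure's instruments and the outcome's own instruments, so both
    forward and reverse MR are meaningful; outcome instruments affect the
    exposure only through ``reverse_theta``.
    """
    rng = np.random.default_rng(config.seed)
    gamma, ld, _ = _exposure_effects_and_ld(rng, config)
    exp_panel = _panel(rng, config, "exp", config.n_snp)
    out_panel = _panel(rng, config, "out", config.n_snp_outcome, pos_offset=config.n_snp + 1000)
    alpha = _pleiotropy(rng, config, config.n_snp)
    delta = _draw_effects(rng, config.effect_dist, config.n_snp_outcome)

    n_out = config.effective_n_outcome
    exp_tab = pd.concat(
        [
            _observe(rng, exp_panel, gamma, config.n_exposure),
            _observe(rng, out_panel, config.reverse_theta * delta, config.n_exposure),
        ],
        ignore_index=True,
    )
    out_tab = pd.concat(
        [
            _observe(rng, exp_panel, config.theta * gamma + alpha, n_out),
            _observe(rng, out_panel, delta, n_out),
        ],
        ignore_index=True,
    )
    exposure = SummaryStats("exposure", exp_tab, "continuous", config.n_exposure)
    outcome = SummaryStats("outcome", out_tab, "binary", int(round(n_out)))
    truth = SimTruth(
        theta=config.theta,
        direct_effect=config.direct_effect,
        per_snp_pleiotropy=[float(a) for a in alpha],
    )
    return exposure, outcome, truth, ld


def simulate_mediation(config: SimulationConfig):
    """Simulate an exposure/mediator/outcome triple with a causal chain.

    Effects compose as: exposure SNPs act on the mediator with theta1 * gamma
    and on the outcome with (direct_effect + theta1 * theta2) * gamma;
    mediator SNPs act on the outcome with theta2 * gamma_m and not on the
    exposure; outcome SNPs act on the exposure only via ``reverse_theta``.

    Returns (exposure, mediator, outcome, truth, ld).
    """
    if config.theta1 is None or config.theta2 is None:
        raise ValueError("simulate_mediation requires theta1 and theta2")
    rng = np.random.default_rng(config.seed)
    gamma, ld, _ = _exposure_effects_and_ld(rng, config)
    exp_panel = _panel(rng, config, "exp", config.n_snp)
    med_panel = _panel(rng, config, "med", config.n_snp, pos_offset=config.n_snp + 1000)
    out_panel = _panel(
        rng, config, "out", config.n_snp_outcome, pos_offset=2 * config.n_snp + 2000
    )
    gamma_m = _draw_effects(rng, config.effect_dist, config.n_snp)
    delta = _draw_effects(rng, config.effect_dist, config.n_snp_outcome)
    alpha = _pleiotropy(rng, config, config.n_snp)

    t1, t2 = config.theta1, config.theta2
    total = config.direct_effect + t1 * t2
    n_out = config.effective_n_outcome

    exp_tab = pd.concat(
        [
            _observe(rng, exp_panel, gamma, config.n_exposure),
            _observe(rng, med_panel, np.zeros(config.n_snp), config.n_exposure),
            _observe(rng, out_panel, config.reverse_theta * delta, config.n_exposure),
        ],
        ignore_index=True,
    )
    med_tab = pd.concat(
        [
            _observe(rng, exp_panel, t1 * gamma, config.n_mediator),
            _observe(rng, med_panel, gamma_m, config.n_mediator),
            _observe(rng, out_panel, np.zeros(config.n_snp_outcome), config.n_mediator),
        ],
        ignore_index=True,
    )
    out_tab = pd.concat(
        [
            _observe(rng, exp_panel, total * gamma + alpha, n_out),
            _observe(rng, med_panel, t2 * gamma_m, n_out),
            _observe(rng, out_panel, delta, n_out),
        ],
        ignore_index=True,
    )
    exposure = SummaryStats("exposure", exp_tab, "continuous", config.n_exposure)
    mediator = SummaryStats("mediator", med_tab, "continuous", config.n_mediator)
    outcome = SummaryStats("outcome", out_tab, "binary", int(round(n_out)))
    truth = SimTruth(
        theta=total,
        theta1=t1,
        theta2=t2,
        direct_effect=config.direct_effect,
        per_snp_pleiotropy=[float(a) for a in alpha],
    )
    return exposure, mediator, outcome, truth, ld


def write_fixture(directory, exposure, outcome, truth, mediator=None, ld=None) -> None:
    """Write a simulated study to a directory of generic-dialect TSVs.

    Layout: exposure.tsv, outcome.tsv, optional mediator.tsv, optional
    ld.tsv, truth.json.  Output is byte-identical for identical inputs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, stats in (("exposure", exposure), ("outcome", outcome), ("mediator", mediator)):
        if stats is None:
            continue
        stats.table.to_csv(directory / f"{name}.tsv", sep="\t", index=False, float_format="%.12g")
    if ld is not None:
        ld.to_tsv(directory / "ld.tsv")
    doc = {
        "theta": truth.theta,
        "theta1": truth.theta1,
        "theta2": truth.theta2,
        "direct_effect": truth.direct_effect,
        "per_snp_pleiotropy": truth.per_snp_pleiotropy,
        "true_total": truth.true_total,
        "true_proportion": truth.true_proportion,
    }
    with open(directory / "truth.json", "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_fixture(directory):
    """Read back a fixture directory written by :func:`write_fixture`."""
    from .gwas_io import read_summary_stats

    directory = Path(directory)
    exposure = read_summary_stats(directory / "exposure.tsv", trait_name="exposure")
    outcome = read_summary_stats(
        directory / "outcome.tsv", trait_name="outcome", trait_type="binary"
    )
    mediator = None
    if (directory / "mediator.tsv").exists():
        mediator = read_summary_stats(directory / "mediator.tsv", trait_name="mediator")
    ld = LDMatrix.from_tsv(directory / "ld.tsv") if (directory / "ld.tsv").exists() else None
    with open(directory / "truth.json") as fh:
        doc = json.load(fh)
    truth = SimTruth(
        theta=doc["theta"],
        theta1=doc["theta1"],
        theta2=doc["theta2"],
        direct_effect=doc["direct_effect"],
        per_snp_pleiotropy=doc["per_snp_pleiotropy"],
    )
    return exposure, outcome, mediator, truth, ld
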