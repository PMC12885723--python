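"""Genetic instrument selection and strength statistics.

Instruments are chosen by a p-value screen followed by greedy LD clumping
(most significant variant first; later variants are discarded when their r2
with an already-accepted variant reaches the clumping threshold within the
distance window).  Instrument strength uses the variance explained per SNP,
R2 = 2 * EAF * (1 - EAF) * beta^2, and the F statistic
F = R2 * (N - K - 1) / (K * (1 - R2)); F > 10 is the conventional
weak-instrument screen.

LD is an explicit input matrix of pairwise r2 rather than an external
reference panel, so the package has no binary dependency; the simulator
produces block-structured matrices for testing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .gwas_io import SummaryStats

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "select_instruments",
    "variant_r2",
    "f_statistic",
    "filter_weak",
]


@dataclass
class LDMatrix:
    """Labelled symmetric matrix of pairwise squared correlations."""

    variant_ids: list
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match variant_ids")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-8 or self.r2.max() > 1 + 1e-8:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t", index_label="variant_id", float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col="variant_id")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with per-variant strength.

    ``per_variant_f`` treats each SNP as its own one-instrument model (K=1);
    ``aggregate_f`` plugs the summed R2 and the full K into the same formula.
    Variants without a usable EAF carry NaN R2/F and do not contribute to the
    totals.
    """

    exposure_name: str
    table: pd.DataFrame
    sample_size: int

    def __post_init__(self) -> None:
        eaf = self.table["eaf"].to_numpy(dtype=float)
        beta = self.table["beta"].to_numpy(dtype=float)
        n = self.table["n"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            r2 = 2.0 * eaf * (1.0 - eaf) * beta**2
            f = r2 * (n - 2.0) / (1.0 - r2)
        self.per_variant_r2 = r2
        self.per_variant_f = f

    @property
    def k(self) -> int:
        return len(self.table)

    @property
    def total_r2(self) -> float:
        return float(np.nansum(self.per_variant_r2))

    @property
    def aggregate_f(self) -> float:
        if self.k == 0:
            return float("nan")
        return f_statistic(self.total_r2, self.sample_size, self.k)

    def __len__(self) -> int:
        return self.k


def variant_r2(eaf: float, beta: float) -> float:
    """Variance in the exposure explained by one SNP: 2*EAF*(1-EAF)*beta^2."""
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must lie in (0, 1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Instrument-strength F: R2 * (N - K - 1) / (K * (1 - R2))."""
    if not (0 <= r2_total < 1):
        raise ValueError(f"r2_total must lie in [0, 1), got {r2_total}")
    if k < 1:
        raise ValueError("k must be at least 1")
    if n <= k + 1:
        raise ValueError(f"n must exceed k + 1 (n={n}, k={k})")
    return r2_total * (n - k - 1.0) / (k * (1.0 - r2_total))


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 1e-5,
    ld: Optional[LDMatrix] = None,
    clump_r2: float = 0.001,
    clump_window_kb: float = 10_000.0,
) -> InstrumentSet:
    """Select instruments by significance and greedy LD clumping.

    Survivors of the ``pval < p_threshold`` screen are sorted by ascending
    p-value (ties broken by variant_id) and accepted greedily: a candidate is
    discarded when its r2 with an already-accepted variant is >= ``clump_r2``
    and the two lie within ``clump_window_kb`` (the window test is skipped
    when either position is absent).  Without an LD matrix — or for variants
    missing from it — variants are treated as independent, with a warning.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    if not (0 < clump_r2 <= 1):
        raise ValueError("clump_r2 must lie in (0, 1]")
    if clump_window_kb < 0:
        raise ValueError("clump_window_kb must be non-negative")

    df = stats.table[stats.table["pval"] < p_threshold]
    df = df.sort_values(["pval", "variant_id"], kind="mergesort").reset_index(drop=True)

    if ld is not None and len(df):
        missing = [v for v in df["variant_id"] if v not in ld]
        if missing:
            warnings.warn(
                f"{len(missing)} candidate variant(s) absent from the LD matrix; "
                "treated as independent",
                stacklevel=2,
            )

    accepted: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        clumped = False
        if ld is not None and row.variant_id in ld:
            for j in accepted:
                other = df.iloc[j]
                if other["variant_id"] not in ld:
                    continue
                r2 = ld.lookup(row.variant_id, other["variant_id"])
                if r2 < clump_r2:
                    continue
                within = True  # positions absent -> clump on r2 alone
                if pd.notna(row.pos) and pd.notna(other["pos"]):
                    same_chrom = (
                        pd.isna(row.chrom) or pd.isna(other["chrom"]) or row.chrom == other["chrom"]
                    )
                    within = same_chrom and abs(int(row.pos) - int(other["pos"])) <= clump_window_kb * 1000
                if within:
                    clumped = True
                    break
        if not clumped:
            accepted.append(i)

    table = df.iloc[accepted].reset_index(drop=True)
    sample_size = int(np.median(table["n"])) if len(table) else (stats.default_n or 0)
    return InstrumentSet(stats.trait_name, table, sample_size)


def filter_weak(instruments: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Drop variants whose single-SNP F statistic is <= ``f_min``.

    Variants with no usable EAF (NaN F) cannot be screened and are retained
    with a warning, matching the policy of keeping them for estimation while
    excluding them from variance-explained bookkeeping.
    """
    f = instruments.per_variant_f
    undecided = np.isnan(f)
    if undecided.any():
        warnings.warn(
            f"{int(undecided.sum())} variant(s) lack EAF; F not computable, retained",
            stacklevel=2,
        )
    keep = undecided | (f > f_min)
    table = instruments.table[keep].reset_index(drop=True)
    sample_size = int(np.median(table["n"])) if len(table) else instruments.sample_size
    return replace(instruments, table=table, sample_size=sample_size)
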