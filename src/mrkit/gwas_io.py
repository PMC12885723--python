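"""GWAS summary-statistics data model, dialect-aware I/O and allele harmonization.

Summary associations are held as a pandas table with one row per variant
(identifier, alleles, effect-allele frequency, per-allele effect ``beta``, its
standard error, p-value and sample size).  Readers understand three header
dialects (a generic tab-separated layout, FinnGen release files and
GWAS-catalog harmonised files).  :func:`harmonize` aligns an exposure
instrument set with an outcome GWAS to a common effect allele, discarding
palindromic variants (allele pair A/T or C/G) outright because their strand
orientation cannot be resolved from summary data alone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "EmptyInputError",
    "VariantAssociation",
    "SummaryStats",
    "HarmonizedSet",
    "read_summary_stats",
    "harmonize",
    "write_results_table",
    "read_results_table",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order used throughout the package
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

# column maps: source header -> canonical name.  Several sources may map onto
# the same canonical column (e.g. variant_id/hm_rsid); the first one present
# in the file wins.
_DIALECTS = {
    "generic": {c: c for c in COLUMNS},
    "finngen": {
        "rsids": "variant_id",
        "#chrom": "chrom",
        "chrom": "chrom",
        "pos": "pos",
        "alt": "effect_allele",
        "ref": "other_allele",
        "af_alt": "eaf",
        "beta": "beta",
        "sebeta": "se",
        "pval": "pval",
        "n": "n",
    },
    "gwascatalog": {
        "variant_id": "variant_id",
        "hm_rsid": "variant_id",
        "chromosome": "chrom",
        "base_pair_location": "pos",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "effect_allele_frequency": "eaf",
        "beta": "beta",
        "standard_error": "se",
        "p_value": "pval",
        "n": "n",
    },
}

#: canonical columns that must be recoverable from the file
_REQUIRED = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pval"]


class FormatError(ValueError):
    """A summary-statistics file does not conform to the declared dialect."""


class EmptyInputError(ValueError):
    """No valid variant rows remained after parsing."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be inferred."""
    return COMPLEMENT.get(effect_allele) == other_allele


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-effect-allele change in the trait: log-odds for binary
    traits, SD units for continuous ones.  ``eaf`` is the effect-allele
    frequency; it may be NaN, in which case the variant is still usable for
    estimation but excluded from variance-explained (R2/F) computations.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float = float("nan")
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: alleles must be single bases A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must lie in (0, 1]")
        if self.n < 2:
            raise ValueError(f"{self.variant_id}: n must be at least 2")
        if np.isfinite(self.eaf) and not (0 < self.eaf < 1):
            raise ValueError(f"{self.variant_id}: eaf must lie in (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class SummaryStats:
    """A trait's GWAS summary statistics (one row per variant).

    ``table`` uses the canonical :data:`COLUMNS`; ``variant_id`` values are
    unique (first occurrence kept when the source file repeats an identifier).
    """

    trait_name: str
    table: pd.DataFrame
    trait_type: str = "continuous"  # or "binary"
    default_n: Optional[int] = None
    n_skipped: int = 0
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.table["variant_id"].duplicated().any():
            raise ValueError("variant_id values must be unique")

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.table["variant_id"])

    @property
    def records(self) -> Iterator[VariantAssociation]:
        for row in self.table.itertuples(index=False):
            yield VariantAssociation(
                variant_id=row.variant_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=int(row.n),
                eaf=float(row.eaf) if pd.notna(row.eaf) else float("nan"),
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                pos=None if pd.isna(row.pos) else int(row.pos),
            )

    def get(self, variant_id: str) -> VariantAssociation:
        sub = self.table[self.table["variant_id"] == variant_id]
        if sub.empty:
            raise KeyError(variant_id)
        return next(SummaryStats(self.trait_name, sub, self.trait_type).records)

    @classmethod
    def from_records(
        cls,
        trait_name: str,
        records: Iterable[VariantAssociation],
        trait_type: str = "continuous",
        default_n: Optional[int] = None,
    ) -> "SummaryStats":
        rows = [
            {
                "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pval": r.pval, "n": r.n,
            }
            for r in records
        ]
        return cls(trait_name, pd.DataFrame(rows, columns=COLUMNS), trait_type, default_n)


def read_summary_stats(
    path,
    dialect: str = "generic",
    *,
    trait_name: Optional[str] = None,
    trait_type: str = "continuous",
    default_n: Optional[int] = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistics file in a known dialect.

    Rows violating the per-variant invariants (non-ACGT or identical alleles,
    se <= 0, p outside (0, 1], n < 2) are skipped and counted in
    ``n_skipped``.  An out-of-range or missing effect-allele frequency does
    not disqualify a row: it is stored as NaN with a warning, since the MR
    estimators do not need it (only R2/F do).  When the file lacks a sample
    size column every row falls back to ``default_n``.

    Raises
    ------
    FormatError
        if a required column for the dialect is missing (the message names
        the canonical column), or no sample-size information is available.
    EmptyInputError
        if no valid rows remain.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"rsids": str, "variant_id": str, "hm_rsid": str})
    colmap = _DIALECTS[dialect]

    out = pd.DataFrame(index=raw.index)
    for src, canon in colmap.items():
        if src in raw.columns and canon not in out.columns:
            out[canon] = raw[src]
    missing = [c for c in _REQUIRED if c not in out.columns]
    if missing:
        raise FormatError(
            f"{path.name}: dialect {dialect!r} is missing required column(s) {missing}"
        )
    for canon in COLUMNS:
        if canon not in out.columns:
            out[canon] = np.nan
    out = out[COLUMNS]

    out["variant_id"] = out["variant_id"].astype(str)
    for col in ("beta", "se", "pval", "eaf"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["pos"] = pd.to_numeric(out["pos"], errors="coerce").astype("Int64")
    out["n"] = pd.to_numeric(out["n"], errors="coerce")
    if out["n"].isna().all():
        if default_n is None:
            raise FormatError(f"{path.name}: no sample-size column 'n' and no default_n given")
        out["n"] = default_n
    else:
        out["n"] = out["n"].fillna(default_n if default_n is not None else np.nan)
    out["effect_allele"] = out["effect_allele"].astype(str).str.upper()
    out["other_allele"] = out["other_allele"].astype(str).str.upper()

    bad_eaf = out["eaf"].notna() & ~((out["eaf"] > 0) & (out["eaf"] < 1))
    if bad_eaf.any():
        warnings.warn(
            f"{path.name}: {int(bad_eaf.sum())} row(s) with eaf outside (0,1); "
            "kept for estimation but excluded from R2/F",
            stacklevel=2,
        )
        out.loc[bad_eaf, "eaf"] = np.nan

    valid = (
        out["effect_allele"].isin(VALID_ALLELES)
        & out["other_allele"].isin(VALID_ALLELES)
        & (out["effect_allele"] != out["other_allele"])
        & out["beta"].notna()
        & (out["se"] > 0)
        & (out["pval"] > 0)
        & (out["pval"] <= 1)
        & (out["n"] >= 2)
    )
    n_skipped = int((~valid).sum())
    out = out[valid]

    dup = out["variant_id"].duplicated()
    n_dup = int(dup.sum())
    if n_dup:
        warnings.warn(
            f"{path.name}: {n_dup} duplicated variant_id row(s); first occurrence kept",
            stacklevel=2,
        )
        out = out[~dup]

    if out.empty:
        raise EmptyInputError(f"{path.name}: no valid variant rows")
    out = out.reset_index(drop=True)
    out["n"] = out["n"].astype(int)
    return SummaryStats(
        trait_name=trait_name or path.stem,
        table=out,
        trait_type=trait_type,
        default_n=default_n,
        n_skipped=n_skipped,
        n_duplicates=n_dup,
    )


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a common effect allele.

    ``pairs`` columns: variant_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, flipped.  ``dropped`` columns: variant_id, reason in
    {palindromic, missing_in_outcome, allele_mismatch}.
    """

    exposure_name: str
    outcome_name: str
    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        variant_ids=None,
        eaf_exp=None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Convenience constructor for already-aligned effect pairs."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        k = beta_exp.size
        if variant_ids is None:
            variant_ids = [f"snp_{i + 1:04d}" for i in range(k)]
        pairs = pd.DataFrame(
            {
                "variant_id": list(variant_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_exp": np.full(k, np.nan) if eaf_exp is None else np.asarray(eaf_exp, float),
                "flipped": np.zeros(k, dtype=bool),
            }
        )
        return cls(exposure_name, outcome_name, pairs)


def _exposure_frame(exposure) -> tuple[str, pd.DataFrame]:
    """Accept SummaryStats, InstrumentSet-like (has .table) or a DataFrame."""
    if isinstance(exposure, SummaryStats):
        return exposure.trait_name, exposure.table
    if hasattr(exposure, "table"):
        return getattr(exposure, "exposure_name", "exposure"), exposure.table
    return "exposure", exposure


def harmonize(exposure_instruments, outcome: SummaryStats) -> HarmonizedSet:
    """Align exposure and outcome effects to the same effect allele.

    Per exposure variant: absent from the outcome GWAS -> dropped
    (missing_in_outcome); palindromic -> dropped regardless of allele
    frequency; same allele pair -> kept as is; swapped alleles -> outcome
    beta negated (flipped); strand complement (possibly swapped) -> resolved
    by complementing the outcome alleles, then as above; anything else ->
    dropped (allele_mismatch).
    """
    exp_name, exp_df = _exposure_frame(exposure_instruments)
    if len(exp_df) == 0:
        raise EmptyInputError("exposure instrument set is empty")
    out_df = outcome.table.set_index("variant_id")

    pair_rows = []
    drop_rows = []
    for row in exp_df.itertuples(index=False):
        vid = row.variant_id
        if vid not in out_df.index:
            drop_rows.append((vid, "missing_in_outcome"))
            continue
        ea, oa = row.effect_allele, row.other_allele
        if is_palindromic(ea, oa):
            drop_rows.append((vid, "palindromic"))
            continue
        orow = out_df.loc[vid]
        oea, ooa = orow["effect_allele"], orow["other_allele"]
        if (oea, ooa) not in ((ea, oa), (oa, ea)):
            # try the other strand
            oea, ooa = COMPLEMENT.get(oea, "?"), COMPLEMENT.get(ooa, "?")
        if (oea, ooa) == (ea, oa):
            beta_out, flipped = float(orow["beta"]), False
        elif (oea, ooa) == (oa, ea):
            beta_out, flipped = -float(orow["beta"]), True
        else:
            drop_rows.append((vid, "allele_mismatch"))
            continue
        pair_rows.append(
            {
                "variant_id": vid,
                "beta_exp": float(row.beta),
                "se_exp": float(row.se),
                "beta_out": beta_out,
                "se_out": float(orow["se"]),
                "eaf_exp": float(row.eaf) if pd.notna(row.eaf) else np.nan,
                "flipped": flipped,
            }
        )

    pairs = pd.DataFrame(
        pair_rows,
        columns=["variant_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "flipped"],
    )
    dropped = pd.DataFrame(drop_rows, columns=["variant_id", "reason"])
    return HarmonizedSet(exp_name, outcome.trait_name, pairs, dropped)


_RESULT_COLUMNS = [
    "exposure", "outcome", "method", "n_snp", "beta", "se",
    "or", "or_ci_low", "or_ci_high", "pval",
]


def write_results_table(estimates, path) -> None:
    """Write causal estimates as a TSV (one row per method).

    Values round-trip through :func:`read_results_table` at 10 significant
    digits.
    """
    rows = [
        {
            "exposure": e.exposure, "outcome": e.outcome, "method": e.method,
            "n_snp": e.n_snp, "beta": e.beta, "se": e.se,
            "or": e.or_, "or_ci_low": e.or_low, "or_ci_high": e.or_high,
            "pval": e.pval,
        }
        for e in estimates
    ]
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
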