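import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrkit import HarmonizedSet, SummaryStats

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_pairs():
    """Factory for a HarmonizedSet from plain effect arrays."""

    def _make(beta_exp, beta_out, se_out, se_exp=None, **kw):
        beta_exp = np.asarray(beta_exp, dtype=float)
        if se_exp is None:
            se_exp = np.full_like(beta_exp, 0.01)
        return HarmonizedSet.from_arrays(beta_exp, se_exp, beta_out, se_out, **kw)

    return _make


def exposure_panel(stats: SummaryStats) -> SummaryStats:
    """Restrict a simulated trait's table to the exposure's own instruments."""
    sub = stats.table[stats.table["variant_id"].str.startswith("exp_")]
    return SummaryStats(stats.trait_name, sub.reset_index(drop=True), stats.trait_type)


@pytest.fixture
def generic_tsv(tmp_path):
    """Write a small generic-dialect summary-stats TSV; returns the path."""

    def _write(rows, name="stats.tsv", columns=None):
        columns = columns or [
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n",
        ]
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    return _write
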