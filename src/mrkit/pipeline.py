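"""End-to-end orchestration: bidirectional MR and the mediation screen.

``run_bidirectional`` reads an exposure and an outcome GWAS, runs instrument
selection, the weak-instrument screen, harmonization, all five estimators
and the full sensitivity report in the forward direction, then repeats with
the roles swapped.  ``run_mediation`` reads directories of exposure and
mediator GWAS files and executes the two-step mediation screen.  Both write
a bundle of TSV/JSON artifacts plus a line-oriented audit log (stage, trait,
counts) and the resolved configuration, so a run can be reproduced from its
own output directory.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .config import AnalysisConfig
from .estimators import (
    MREstimate,
    egger,
    ivw,
    mode_estimate,
    wald_ratio,
    weighted_median,
)
from .gwas_io import (
    HarmonizedSet,
    SummaryStats,
    harmonize,
    read_summary_stats,
    write_results_table,
)
from .instruments import InstrumentSet, LDMatrix, filter_weak, select_instruments
from .mediation import ScreenResult, two_step_screen, write_mediation_table
from .sensitivity import SensitivityReport, full_report

__all__ = ["DirectionResult", "analyze_direction", "run_bidirectional", "run_mediation"]


def _sub_seed(base: int, *names: str) -> int:
    return (base * 1000003 + zlib.crc32("|".join(names).encode())) % (2**31 - 1)


@dataclass
class DirectionResult:
    """One direction of a bidirectional analysis."""

    exposure_name: str
    outcome_name: str
    estimable: bool
    reason: str = ""
    instruments: Optional[InstrumentSet] = None
    harmonized: Optional[HarmonizedSet] = None
    estimates: list = field(default_factory=list)  # MREstimate
    sensitivity: Optional[SensitivityReport] = None

    @property
    def primary(self) -> Optional[MREstimate]:
        """The primary IVW estimate (first ivw_* entry, else the Wald ratio)."""
        for est in self.estimates:
            if est.method.startswith("ivw"):
                return est
        return self.estimates[0] if self.estimates else None


def analyze_direction(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: AnalysisConfig | None = None,
    ld: Optional[LDMatrix] = None,
    p_threshold: Optional[float] = None,
    log: Optional[list] = None,
) -> DirectionResult:
    """Select instruments, harmonize and estimate exposure -> outcome."""
    config = config or AnalysisConfig()
    log = log if log is not None else []
    name = f"{exposure.trait_name}->{outcome.trait_name}"
    p = config.instrument_p_threshold if p_threshold is None else p_threshold

    inst = select_instruments(
        exposure, p_threshold=p, ld=ld,
        clump_r2=config.clump_r2, clump_window_kb=config.clump_window_kb,
    )
    log.append(f"instruments\t{name}\tselected={inst.k}\tp_threshold={p:g}")
    inst = filter_weak(inst, config.f_min)
    log.append(f"instruments\t{name}\tafter_f_filter={inst.k}\tf_min={config.f_min:g}")
    if inst.k == 0:
        log.append(f"direction\t{name}\tnot_estimable\tno_instruments")
        return DirectionResult(exposure.trait_name, outcome.trait_name, False, "no_instruments")

    hs = harmonize(inst, outcome)
    drops = hs.dropped["reason"].value_counts().to_dict() if len(hs.dropped) else {}
    log.append(f"harmonize\t{name}\tpairs={len(hs)}\tdropped={drops}")
    k = len(hs)
    if k == 0:
        log.append(f"direction\t{name}\tnot_estimable\tno_harmonized_pairs")
        return DirectionResult(
            exposure.trait_name, outcome.trait_name, False, "no_harmonized_pairs", inst, hs
        )

    estimates: list[MREstimate] = []
    if k == 1:
        row = hs.pairs.iloc[0]
        estimates.append(
            wald_ratio(
                row["beta_exp"], row["se_exp"], row["beta_out"], row["se_out"],
                exposure=hs.exposure_name, outcome=hs.outcome_name,
            )
        )
    else:
        primary = ivw(hs, model=config.ivw_model)
        estimates.append(primary)
        other = "fixed" if config.ivw_model == "random" else "random"
        estimates.append(ivw(hs, model=other))
    if k >= 3:
        estimates.append(egger(hs).slope)
        seed = _sub_seed(config.seed, name)
        estimates.append(weighted_median(hs, n_boot=config.n_boot, seed=seed))
        estimates.append(
            mode_estimate(hs, weighted=False, n_boot=config.n_boot, seed=seed + 1)
        )
        estimates.append(
            mode_estimate(hs, weighted=True, n_boot=config.n_boot, seed=seed + 2)
        )
    for est in estimates:
        log.append(
            f"estimate\t{name}\t{est.method}\tbeta={est.beta:.6g}\tse={est.se:.6g}"
            f"\tp={est.pval:.4g}\tn_snp={est.n_snp}"
        )

    sens = None
    if k >= 2:
        sens = full_report(
            hs,
            presso_n_sim=config.presso_n_sim,
            seed=_sub_seed(config.seed, name, "presso"),
            significance=config.alpha,
            loo_model=config.ivw_model,
        )
        log.append(
            f"sensitivity\t{name}\tq_pval={sens.q_pval:.4g}"
            f"\tegger_intercept_pval={'NA' if sens.egger_intercept_pval is None else format(sens.egger_intercept_pval, '.4g')}"
            f"\tpresso_global_pval={'NA' if sens.presso is None else format(sens.presso.global_pval, '.4g')}"
        )
    return DirectionResult(
        exposure.trait_name, outcome.trait_name, True, f"k={k}", inst, hs, estimates, sens
    )


def _write_direction(result: DirectionResult, out_dir: Path, tag: str) -> None:
    if not result.estimable:
        return
    if result.sensitivity is not None:
        result.sensitivity.to_json(out_dir / f"sensitivity_{tag}.json")
        loo_rows = [
            {"variant_id": vid, "beta": est.beta, "se": est.se, "pval": est.pval}
            for vid, est in result.sensitivity.loo
        ]
        pd.DataFrame(loo_rows, columns=["variant_id", "beta", "se", "pval"]).to_csv(
            out_dir / f"loo_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        pd.DataFrame(result.sensitivity.funnel, columns=["ratio", "precision"]).to_csv(
            out_dir / f"funnel_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
        )
    if result.harmonized is not None:
        result.harmonized.pairs.to_csv(
            out_dir / f"harmonized_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
        )
        result.harmonized.dropped.to_csv(
            out_dir / f"dropped_{tag}.tsv", sep="\t", index=False
        )


def run_bidirectional(
    exposure_path,
    outcome_path,
    config: AnalysisConfig | None = None,
    out_dir=None,
    ld_path=None,
) -> tuple[DirectionResult, DirectionResult]:
    """Forward and reverse MR between two GWAS files, with a report bundle.

    A direction with zero usable instruments is reported as not estimable;
    this is an expected outcome, not an error.
    """
    config = config or AnalysisConfig()
    exposure = read_summary_stats(
        exposure_path, dialect=config.exposure_dialect, default_n=config.exposure_n
    )
    outcome = read_summary_stats(
        outcome_path, dialect=config.outcome_dialect,
        trait_type="binary", default_n=config.outcome_n,
    )
    ld = LDMatrix.from_tsv(ld_path) if ld_path else None

    log: list[str] = []
    forward = analyze_direction(exposure, outcome, config, ld=ld, log=log)
    reverse = analyze_direction(
        outcome, exposure, config, p_threshold=config.reverse_threshold, log=log
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results_table(
            forward.estimates + reverse.estimates, out_dir / "estimates.tsv"
        )
        _write_direction(forward, out_dir, "forward")
        _write_direction(reverse, out_dir, "reverse")
        config.to_yaml(out_dir / "config.yaml")
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
    return forward, reverse


def run_mediation(
    exposures_dir,
    mediators_dir,
    outcome_path,
    config: AnalysisConfig | None = None,
    out_dir=None,
) -> ScreenResult:
    """Two-step mediation screen over directories of GWAS files."""
    config = config or AnalysisConfig()

    def read_dir(directory, dialect, default_n):
        files = sorted(Path(directory).glob("*.tsv"))
        return [
            read_summary_stats(f, dialect=dialect, default_n=default_n) for f in files
        ]

    exposures = read_dir(exposures_dir, config.exposure_dialect, config.exposure_n)
    mediators = read_dir(mediators_dir, config.mediator_dialect, config.mediator_n)
    outcome = read_summary_stats(
        outcome_path, dialect=config.outcome_dialect,
        trait_type="binary", default_n=config.outcome_n,
    )
    screen = two_step_screen(exposures, mediators, outcome, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mediation_table(screen.results, out_dir / "mediation.tsv")
        screen.log_frame().to_csv(
            out_dir / "screen_log.tsv", sep="\t", index=False, float_format="%.10g"
        )
        config.to_yaml(out_dir / "config.yaml")
    return screen
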