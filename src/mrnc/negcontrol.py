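"""Negative-control-outcome MR pipeline.

The diagnostic runs two extra MR analyses alongside any exposure->outcome
study: (a) exposure -> negative control, and (b) outcome -> negative
control (the outcome's own genome-wide-significant SNPs become the
instruments).  The negative control is a phenotype determined before the
exposure and outcome — so it cannot truly be affected by either — but
subject to the same confounding (e.g. tanning ability or hair colour
against uncorrected population stratification).  A non-null estimate
therefore signals instrument confounding, and the pattern across
estimators separates the two mechanisms: a signal that survives the
outlier-robust weighted median/mode points to a bias shared by ALL
instruments (stratification), whereas a signal the robust estimators
erase points to a minority of pleiotropic outliers.

Flags are advisory: the flagging level alpha is a heuristic indication
that results warrant further investigation, not a hard cut-off, and no
multiple-testing correction is applied.  Choosing a genuinely
predetermined, confounding-exposed negative control is the caller's
responsibility; nothing here validates it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_data import (
    DEFAULT_EAF_WINDOW,
    DEFAULT_MIN_INSTRUMENTS,
    GENOME_WIDE_SIG,
    GwasRecord,
    HarmonizationError,
    InsufficientInstrumentsError,
    harmonize,
    select_instruments,
)
from .estimators import (
    DEFAULT_N_BOOT,
    DEFAULT_PHI,
    MrEstimate,
    estimates_table,
    ivw,
    mr_egger,
    weighted_median,
    weighted_mode,
)

logger = logging.getLogger("mrnc")

ALL_METHODS = ("IVW", "MR-Egger", "weighted-median", "weighted-mode")

FLAG_NO_SIGNAL = "no_signal"
FLAG_OUTLIER = "signal_outlier_pattern"
FLAG_SHARED = "signal_shared_pattern"


@dataclass
class RunConfig:
    """Run parameters shared across every analysis in one report."""

    p_threshold: float = GENOME_WIDE_SIG
    min_count: int = DEFAULT_MIN_INSTRUMENTS
    palindrome_policy: str = "drop_ambiguous"
    eaf_window: float = DEFAULT_EAF_WINDOW
    n_boot: int = DEFAULT_N_BOOT
    phi: float = DEFAULT_PHI
    alpha: float = 0.05
    ivw_model: str = "mre"
    methods: tuple[str, ...] = ALL_METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if "IVW" not in self.methods:
            raise ValueError("IVW is mandatory and must be among methods")


@dataclass
class MrResultSet:
    """All estimator outputs for one exposure/outcome pair."""

    exposure_label: str
    outcome_label: str
    estimates: list[MrEstimate]
    j_used: int
    dropped_summary: dict = field(default_factory=dict)

    def get(self, method: str) -> MrEstimate | None:
        for est in self.estimates:
            if est.method == method:
                return est
        return None

    @property
    def ivw(self) -> MrEstimate:
        est = self.get("IVW")
        if est is None:
            raise ValueError("result set lacks its mandatory IVW entry")
        return est


@dataclass
class NegControlReport:
    """Diagnostic bundle for an exposure/outcome/negative-control study."""

    triples: list[tuple[str, MrResultSet]]  # (analysis_role, results)
    flags: list[str]
    alpha: float
    narrative: list[dict] = field(default_factory=list)


def run_mr_suite(
    exposure_records: Sequence[GwasRecord],
    outcome_records: Sequence[GwasRecord],
    config: RunConfig,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> MrResultSet:
    """Select instruments, harmonize, and run the estimator suite.

    IVW always runs; MR-Egger, weighted median and weighted mode require
    J >= 3 and are skipped with a logged notice below that.  Deterministic
    given inputs, config and config.seed.
    """
    instruments = select_instruments(
        exposure_records, config.p_threshold, config.min_count, label=exposure_label
    )
    try:
        hset = harmonize(
            instruments,
            outcome_records,
            palindrome_policy=config.palindrome_policy,
            eaf_window=config.eaf_window,
            exposure_label=exposure_label,
            outcome_label=outcome_label,
        )
    except HarmonizationError as exc:
        raise HarmonizationError(f"{exposure_label} -> {outcome_label}: {exc}") from exc

    reasons: dict[str, int] = {}
    for _, reason in hset.dropped:
        reasons[reason] = reasons.get(reason, 0) + 1

    estimates: list[MrEstimate] = [ivw(hset, model=config.ivw_model)]
    sensitivity = [m for m in config.methods if m != "IVW"]
    if hset.n_snps < 3 and sensitivity:
        logger.info(
            "%s -> %s: J=%d < 3, skipping sensitivity estimators %s",
            exposure_label, outcome_label, hset.n_snps, sensitivity,
        )
    else:
        for method in sensitivity:
            if method == "MR-Egger":
                estimates.append(mr_egger(hset))
            elif method == "weighted-median":
                estimates.append(
                    weighted_median(hset, n_boot=config.n_boot, seed=config.seed)
                )
            elif method == "weighted-mode":
                estimates.append(
                    weighted_mode(hset, phi=config.phi, n_boot=config.n_boot,
                                  seed=config.seed)
                )
    return MrResultSet(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        estimates=estimates,
        j_used=hset.n_snps,
        dropped_summary=reasons,
    )


def flag_stratification(result_set: MrResultSet, alpha: float = 0.05) -> str:
    """Classify one result set's negative-control signal.

    ``no_signal`` when the IVW p-value is >= alpha.  Otherwise the signal
    is ``signal_shared_pattern`` when it survives the outlier-robust
    estimators — at least one of weighted median/mode is significant with
    IVW's sign, or both merely share IVW's sign (direction consistency) —
    since a bias common to all instruments (stratification) is exactly
    what those estimators cannot remove.  Anything else is
    ``signal_outlier_pattern``.  When no sensitivity estimator is
    available (J < 3) a significant IVW stands unchallenged and is
    flagged shared.  Advisory, not a hard cut-off.
    """
    ivw_est = result_set.ivw
    if ivw_est.pval >= alpha:
        return FLAG_NO_SIGNAL
    ivw_sign = np.sign(ivw_est.beta)
    robust = [result_set.get("weighted-median"), result_set.get("weighted-mode")]
    robust = [est for est in robust if est is not None]
    if not robust:
        return FLAG_SHARED
    same_sign = [np.sign(est.beta) == ivw_sign for est in robust]
    significant_same = any(
        s and est.pval < alpha for s, est in zip(same_sign, robust)
    )
    if significant_same or all(same_sign):
        return FLAG_SHARED
    return FLAG_OUTLIER


def run_negative_control_analysis(
    exposure_records: Sequence[GwasRecord],
    outcome_records: Sequence[GwasRecord],
    nc_records_list: Sequence[Sequence[GwasRecord]],
    config: RunConfig,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    nc_labels: Sequence[str] | None = None,
) -> NegControlReport:
    """Run both negative-control sensitivity analyses per negative control.

    For each negative-control summary set: (a) MR of the exposure on the
    negative control, and (b) MR of the outcome on the negative control,
    the outcome's own genome-wide-significant SNPs serving as instruments.
    When the outcome lacks enough significant SNPs, (b) is recorded as
    not assessable rather than failing the run.  Evidence from multiple
    negative controls is presented side by side, never aggregated.
    """
    if not nc_records_list:
        raise ValueError("at least one negative-control summary set is required")
    if nc_labels is None:
        nc_labels = [f"negative_control_{i + 1}" for i in range(len(nc_records_list))]

    triples: list[tuple[str, MrResultSet]] = []
    flags: list[str] = []
    narrative: list[dict] = []
    for nc_records, nc_label in zip(nc_records_list, nc_labels):
        rs = run_mr_suite(
            exposure_records, nc_records, config,
            exposure_label=exposure_label, outcome_label=nc_label,
        )
        triples.append(("exposure_on_nc", rs))
        flags.append(flag_stratification(rs, config.alpha))

        try:
            rs_b = run_mr_suite(
                outcome_records, nc_records, config,
                exposure_label=outcome_label, outcome_label=nc_label,
            )
        except InsufficientInstrumentsError as exc:
            narrative.append(
                {
                    "analysis": "outcome_on_nc",
                    "negative_control": nc_label,
                    "status": "not assessable",
                    "detail": str(exc),
                }
            )
            continue
        triples.append(("outcome_on_nc", rs_b))
        flags.append(flag_stratification(rs_b, config.alpha))

    narrative.append(
        {
            "flag_rule": (
                "no_signal if IVW p >= alpha; signal_shared_pattern if a robust "
                "estimator (weighted median/mode) is significant with IVW's sign "
                "or both share IVW's sign; otherwise signal_outlier_pattern"
            ),
            "alpha": config.alpha,
        }
    )
    return NegControlReport(triples=triples, flags=flags, alpha=config.alpha,
                            narrative=narrative)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.10g}"


def render_report(report: NegControlReport, out_dir) -> None:
    """Write the report as deterministic TSVs.

    ``estimates.tsv`` follows the standard layout (Exposure, No. SNPs,
    Est. method, Effect, Std error, P-value, CI bounds); ``forest.tsv``
    holds one (label, beta, ci_low, ci_high) row per estimate for forest
    plotting; ``flags.tsv`` one advisory flag per analysis;
    ``narrative.json`` the machine-readable notes.  Byte output is a pure
    function of the report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables = []
    for role, rs in report.triples:
        t = estimates_table(rs.exposure_label, rs.estimates)
        t.insert(0, "Analysis", role)
        t.insert(2, "Outcome", rs.outcome_label)
        tables.append(t)
    est = pd.concat(tables, ignore_index=True)
    for col in ("Effect", "Std error", "P-value", "CI lower", "CI upper"):
        est[col] = est[col].map(_fmt)
    est.to_csv(out / "estimates.tsv", sep="\t", index=False)

    forest_rows = []
    for role, rs in report.triples:
        for e in rs.estimates:
            forest_rows.append(
                {
                    "label": f"{rs.exposure_label} on {rs.outcome_label} [{e.method}]",
                    "beta": _fmt(e.beta),
                    "ci_low": _fmt(e.ci_low),
                    "ci_high": _fmt(e.ci_high),
                }
            )
    pd.DataFrame(forest_rows).to_csv(out / "forest.tsv", sep="\t", index=False)

    flag_rows = [
        {
            "analysis": role,
            "exposure": rs.exposure_label,
            "outcome": rs.outcome_label,
            "n_snps": rs.j_used,
            "ivw_pval": _fmt(rs.ivw.pval),
            "flag": flag,
            "alpha": report.alpha,
        }
        for (role, rs), flag in zip(report.triples, report.flags)
    ]
    pd.DataFrame(flag_rows).to_csv(out / "flags.tsv", sep="\t", index=False)

    with open(out / "narrative.json", "w") as fh:
        json.dump(report.narrative, fh, indent=2, sort_keys=True)
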