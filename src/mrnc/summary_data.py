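"""Reading, filtering and harmonizing GWAS summary statistics.

Two-sample summary-data Mendelian randomization compares per-SNP
associations with an exposure (gamma_j, se sigma_gamma_j) against per-SNP
associations with an outcome (Gamma_j, se sigma_Gamma_j) estimated in an
independent sample.  Before any estimator can run, the two summary sets
must be expressed on a common effect allele per SNP.  This module provides
the record type, instrument selection at genome-wide significance, and the
allele harmonization step, plus delimited-text I/O in the MR Base dialect.

SNP identity is by rsID only; positions and strand annotations are ignored.
LD clumping is deliberately not performed here: instruments are assumed
approximately independent, and ensuring that (e.g. by clumping upstream
against a reference panel) is the caller's responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrnc")

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names for summary-statistics tables
CANONICAL_COLUMNS = (
    "SNP",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "samplesize",
)

GENOME_WIDE_SIG = 5e-8
DEFAULT_MIN_INSTRUMENTS = 5
DEFAULT_EAF_WINDOW = 0.08


class SummaryDataError(ValueError):
    """Malformed or unusable summary-statistics input."""


class InsufficientInstrumentsError(SummaryDataError):
    """Fewer genome-wide-significant SNPs than the required minimum."""

    def __init__(self, found: int, required: int, label: str = ""):
        self.found = found
        self.required = required
        prefix = f"{label}: " if label else ""
        super().__init__(
            f"{prefix}insufficient instruments: found {found} "
            f"genome-wide significant SNPs, require at least {required}"
        )


class HarmonizationError(SummaryDataError):
    """No SNP pair survived harmonization."""


@dataclass
class GwasRecord:
    """One SNP's association summary with a single phenotype.

    ``beta`` is the per-allele effect of ``effect_allele`` on the
    phenotype; ``se`` its standard error.  ``eaf`` (effect-allele
    frequency) and ``n`` may be missing (``None``).  A missing p-value is
    reconstructed as the two-sided normal tail of beta/se.  ``flag``
    carries quality markers (e.g. ``"not_assessable"`` for monomorphic
    SNPs in simulated scans); flagged records are never used as
    instruments.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float | None = None
    n: int | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.flag is not None:
            return  # marker records carry no usable statistics
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise SummaryDataError(
                f"{self.snp_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryDataError(f"{self.snp_id}: effect and other allele identical")
        if not np.isfinite(self.se) or self.se <= 0:
            raise SummaryDataError(f"{self.snp_id}: se must be positive, got {self.se}")
        if self.pval is None or not np.isfinite(self.pval):
            self.pval = float(2.0 * stats.norm.sf(abs(self.beta / self.se)))
        self.pval = float(min(max(self.pval, np.nextafter(0.0, 1.0)), 1.0))

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class HarmonizedInstrumentSet:
    """Matched exposure/outcome per-SNP pairs on a common effect allele."""

    snp_ids: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exposure_beta = np.asarray(self.exposure_beta, dtype=float)
        self.exposure_se = np.asarray(self.exposure_se, dtype=float)
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float)
        self.outcome_se = np.asarray(self.outcome_se, dtype=float)
        j = len(self.snp_ids)
        arrays = (self.exposure_beta, self.exposure_se, self.outcome_beta, self.outcome_se)
        if not all(a.shape == (j,) for a in arrays):
            raise SummaryDataError("harmonized arrays must share length J")
        if j < 1:
            raise HarmonizationError("nothing to harmonize: zero retained pairs")
        if np.any(self.exposure_se <= 0) or np.any(self.outcome_se <= 0):
            raise SummaryDataError("all standard errors must be positive")
        if len(set(self.snp_ids)) != j:
            raise SummaryDataError("duplicate snp_ids in harmonized set")
        retained = set(self.snp_ids)
        if any(sid in retained for sid, _ in self.dropped):
            raise SummaryDataError("snp_id appears both retained and dropped")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


def _coerce_float(value) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparseable numeric {value!r}")
    return None if np.isnan(out) else out


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> list[GwasRecord]:
    """Read a delimited summary-statistics table into GwasRecords.

    ``column_map`` maps file headers to the canonical fields
    (SNP, effect_allele, other_allele, eaf, beta, se, pval, samplesize);
    canonical headers need no mapping.  Rows with non-positive SE,
    malformed alleles or unparseable numerics are skipped and counted.
    eaf, pval and samplesize columns are optional.
    """
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise SummaryDataError(f"{path}: cannot parse summary table: {exc}") from exc
    if column_map:
        table = table.rename(columns=dict(column_map))
    missing = {"SNP", "effect_allele", "other_allele", "beta", "se"} - set(table.columns)
    if missing:
        raise SummaryDataError(f"{path}: missing required columns {sorted(missing)}")

    records: list[GwasRecord] = []
    skipped = 0
    for row in table.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(table.columns, row))
        try:
            n_raw = _coerce_float(d.get("samplesize"))
            rec = GwasRecord(
                snp_id=str(d["SNP"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                eaf=_coerce_float(d.get("eaf")),
                beta=_float_required(d["beta"]),
                se=_float_required(d["se"]),
                pval=_coerce_float(d.get("pval")),
                n=int(n_raw) if n_raw is not None else None,
            )
        except (SummaryDataError, ValueError, KeyError):
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("%s: skipped %d unparseable/invalid rows", label or path, skipped)
    if not records:
        raise SummaryDataError(f"{path}: no parseable summary rows")
    return records


def _float_required(value) -> float:
    out = float(value)
    if np.isnan(out):
        raise ValueError("missing required numeric")
    return out


def select_instruments(
    records: Sequence[GwasRecord],
    p_threshold: float = GENOME_WIDE_SIG,
    min_count: int = DEFAULT_MIN_INSTRUMENTS,
    label: str = "",
) -> list[GwasRecord]:
    """Keep genome-wide-significant SNPs as instruments.

    Records with ``pval < p_threshold`` survive; duplicates by rsID are
    resolved to the smallest p-value; input order is preserved among
    survivors; flagged (not-assessable) records are excluded.  Raises
    :class:`InsufficientInstrumentsError` when fewer than ``min_count``
    survive.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0,1)")
    best: dict[str, GwasRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.flag is not None or rec.pval is None or rec.pval >= p_threshold:
            continue
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        elif rec.pval < best[rec.snp_id].pval:
            best[rec.snp_id] = rec
    survivors = [best[sid] for sid in order]
    if len(survivors) < min_count:
        raise InsufficientInstrumentsError(len(survivors), min_count, label)
    return survivors


def _swap(beta: float, eaf: float | None) -> tuple[float, float | None]:
    """Re-express a record on the opposite allele: negate beta, mirror eaf."""
    return -beta, (None if eaf is None else 1.0 - eaf)


def harmonize(
    exposure_instruments: Sequence[GwasRecord],
    outcome_records: Sequence[GwasRecord],
    palindrome_policy: str = "drop_ambiguous",
    eaf_window: float = DEFAULT_EAF_WINDOW,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Align outcome records to the exposure's effect alleles.

    For each exposure instrument found among the outcome records:
    direct allele match is kept as-is; swapped alleles negate the outcome
    beta and mirror its eaf; a strand-complement match is complemented
    first and then treated the same way.  Palindromic SNPs (A/T, G/C)
    cannot be resolved from alleles: under ``drop_ambiguous`` they are
    kept only when both effect-allele frequencies are available, fall
    outside ``0.5 +/- eaf_window``, and lie on the same side of 0.5
    (orientation then taken as already aligned); frequency-discordant or
    uninformative palindromes are dropped.  Under ``drop_all`` every
    palindrome is dropped.  Exposure SNPs absent from the outcome set are
    recorded as dropped with reason "not found".
    """
    if palindrome_policy not in ("drop_ambiguous", "drop_all"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure_instruments or not outcome_records:
        raise SummaryDataError("harmonize requires non-empty exposure and outcome sets")

    by_id = {}
    for rec in outcome_records:
        if rec.flag is None:
            by_id.setdefault(rec.snp_id, rec)

    kept_ids: list[str] = []
    eb, es, ob, os_ = [], [], [], []
    dropped: list[tuple[str, str]] = []

    for exp in exposure_instruments:
        out = by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "not found"))
            continue

        if exp.is_palindromic:
            if palindrome_policy == "drop_all":
                dropped.append((exp.snp_id, "palindromic"))
                continue
            if {out.effect_allele, out.other_allele} != {exp.effect_allele, exp.other_allele}:
                dropped.append((exp.snp_id, "allele mismatch"))
                continue
            lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
            if (
                exp.eaf is None
                or out.eaf is None
                or lo <= exp.eaf <= hi
                or lo <= out.eaf <= hi
            ):
                dropped.append((exp.snp_id, "palindromic, ambiguous frequency"))
                continue
            if (exp.eaf < 0.5) != (out.eaf < 0.5):
                dropped.append((exp.snp_id, "palindromic, discordant frequency"))
                continue
            beta_out, se_out = out.beta, out.se
        else:
            o_ea, o_oa = out.effect_allele, out.other_allele
            if (o_ea, o_oa) == (exp.effect_allele, exp.other_allele):
                beta_out, se_out = out.beta, out.se
            elif (o_oa, o_ea) == (exp.effect_allele, exp.other_allele):
                beta_out, _ = _swap(out.beta, out.eaf)
                se_out = out.se
            else:
                c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
                if (c_ea, c_oa) == (exp.effect_allele, exp.other_allele):
                    beta_out, se_out = out.beta, out.se
                elif (c_oa, c_ea) == (exp.effect_allele, exp.other_allele):
                    beta_out, _ = _swap(out.beta, out.eaf)
                    se_out = out.se
                else:
                    dropped.append((exp.snp_id, "allele mismatch"))
                    continue

        kept_ids.append(exp.snp_id)
        eb.append(exp.beta)
        es.append(exp.se)
        ob.append(beta_out)
        os_.append(se_out)

    if not kept_ids:
        raise HarmonizationError(
            f"nothing to harmonize between {exposure_label} and {outcome_label}: "
            f"0 of {len(exposure_instruments)} instruments retained"
        )
    return HarmonizedInstrumentSet(
        snp_ids=kept_ids,
        exposure_beta=np.array(eb),
        exposure_se=np.array(es),
        outcome_beta=np.array(ob),
        outcome_se=np.array(os_),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        dropped=dropped,
    )


def write_harmonized(hset: HarmonizedInstrumentSet, path) -> None:
    """Write a harmonized set as TSV, plus a ``<path>.dropped.tsv`` sidecar.

    Numeric fields round-trip bit-for-bit (written with repr precision).
    """
    df = pd.DataFrame(
        {
            "SNP": hset.snp_ids,
            "exposure_beta": hset.exposure_beta,
            "exposure_se": hset.exposure_se,
            "outcome_beta": hset.outcome_beta,
            "outcome_se": hset.outcome_se,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    side = pd.DataFrame(hset.dropped, columns=["SNP", "reason"])
    side.to_csv(f"{path}.dropped.tsv", sep="\t", index=False)


def read_harmonized(
    path, exposure_label: str = "exposure", outcome_label: str = "outcome"
) -> HarmonizedInstrumentSet:
    """Read back a TSV written by :func:`write_harmonized`."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    try:
        side = pd.read_csv(f"{path}.dropped.tsv", sep="\t")
        dropped = [(str(s), str(r)) for s, r in zip(side["SNP"], side["reason"])]
    except FileNotFoundError:
        dropped = []
    return HarmonizedInstrumentSet(
        snp_ids=[str(s) for s in df["SNP"]],
        exposure_beta=df["exposure_beta"].to_numpy(),
        exposure_se=df["exposure_se"].to_numpy(),
        outcome_beta=df["outcome_beta"].to_numpy(),
        outcome_se=df["outcome_se"].to_numpy(),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        dropped=dropped,
    )


def write_summary_stats(records: Sequence[GwasRecord], path) -> None:
    """Write GwasRecords as a canonical-column TSV (MR Base dialect)."""
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "samplesize": r.n,
                "flag": r.flag or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
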