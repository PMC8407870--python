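"""Two-sample summary-data MR estimators: IVW, MR-Egger, weighted median,
weighted mode.

All estimators consume a :class:`~mrnc.summary_data.HarmonizedInstrumentSet`
holding per-SNP exposure associations (gamma_j, sigma_gamma_j) and outcome
associations (Gamma_j, sigma_Gamma_j).  The per-SNP causal estimate is the
Wald ratio Gamma_j / gamma_j with first-order standard error
sigma_Gamma_j / |gamma_j|; the estimators differ in how they pool the
ratios and hence in which invalid-instrument patterns they tolerate:

* IVW assumes every instrument is valid; equivalent to the zero-intercept
  weighted regression of Gamma on gamma with weights 1/sigma_Gamma^2.
* MR-Egger adds an intercept absorbing average directional pleiotropy
  under the InSIDE assumption (pleiotropic effect independent of
  instrument strength).
* The weighted median is consistent when valid instruments carry more
  than half the weight; the weighted mode when the largest cluster of
  ratios is the valid one.  Both are therefore robust to a minority of
  outlying invalid SNPs — but not to a bias shared by ALL instruments,
  such as uncorrected population stratification.

Median and mode standard errors come from a parametric bootstrap that
resamples both betas from normal distributions; an explicit seed is
required, there is no hidden global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedInstrumentSet

Z95 = 1.96  # normal 95% multiplier used for IVW/median/mode intervals
MODE_GRID_POINTS = 512
DEFAULT_N_BOOT = 1000
DEFAULT_PHI = 1.0

P_FLOOR = 5e-324  # smallest subnormal: keeps p in (0,1] in exact-fit cases


class EstimationError(ValueError):
    """Estimator preconditions violated (too few or degenerate instruments)."""


@dataclass
class InstrumentRatio:
    """Single-SNP Wald ratio with its first-order SE and normalized weight."""

    snp_id: str
    ratio: float
    ratio_se: float
    weight: float = 1.0


@dataclass
class MrEstimate:
    """One estimator's causal-effect estimate.

    ``intercept`` fields are populated for MR-Egger only.  ``se`` may be
    exactly 0 in degenerate exact-fit cases (e.g. collinear Egger input),
    in which case the p-value is floored at the smallest positive float.
    """

    method: str
    beta: float
    se: float
    pval: float
    ci_low: float
    ci_high: float
    n_snps: int
    model_detail: str = ""
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None


def _two_sided_normal_p(beta: float, se: float) -> float:
    if se == 0:
        return P_FLOOR
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), P_FLOOR))


def wald_ratio(
    exposure_beta: float,
    exposure_se: float,
    outcome_beta: float,
    outcome_se: float,
    snp_id: str = "",
) -> InstrumentRatio:
    """Single-SNP causal estimate Gamma/gamma with SE sigma_Gamma/|gamma|.

    The first-order delta-method SE ignores uncertainty in gamma (the
    NO-Measurement-Error approximation); gamma = 0 is a degenerate
    instrument and raises.
    """
    if exposure_beta == 0:
        raise EstimationError(f"degenerate instrument {snp_id or '?'}: exposure beta is 0")
    if exposure_se <= 0 or outcome_se <= 0:
        raise EstimationError("standard errors must be positive")
    return InstrumentRatio(
        snp_id=snp_id,
        ratio=outcome_beta / exposure_beta,
        ratio_se=outcome_se / abs(exposure_beta),
    )


def compute_ratios(hset: HarmonizedInstrumentSet) -> list[InstrumentRatio]:
    """Per-SNP Wald ratios with inverse-variance weights normalized to 1."""
    ratios = [
        wald_ratio(gb, gs, ob, os_, snp_id=sid)
        for sid, gb, gs, ob, os_ in zip(
            hset.snp_ids, hset.exposure_beta, hset.exposure_se,
            hset.outcome_beta, hset.outcome_se,
        )
    ]
    w = np.array([1.0 / r.ratio_se**2 for r in ratios])
    w /= w.sum()
    for r, wi in zip(ratios, w):
        r.weight = float(wi)
    return ratios


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(hset: HarmonizedInstrumentSet, model: str = "mre") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    beta = sum(w_j gamma_j Gamma_j) / sum(w_j gamma_j^2), w_j = 1/sigma_Gamma_j^2
    — the zero-intercept weighted regression of Gamma on gamma.  Under the
    default multiplicative-random-effects model the fixed-effect SE is
    inflated by max(1, sqrt(Q/(J-1))) with Q the weighted residual sum of
    squares; p is two-sided normal.  J = 1 collapses to the Wald ratio.
    """
    if model not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = hset.n_snps
    if j == 0:
        raise EstimationError("empty instrument set")
    g, sg = hset.exposure_beta, hset.exposure_se
    G, sG = hset.outcome_beta, hset.outcome_se
    if j == 1:
        r = wald_ratio(g[0], sg[0], G[0], sG[0], snp_id=hset.snp_ids[0])
        p = _two_sided_normal_p(r.ratio, r.ratio_se)
        return MrEstimate(
            method="IVW", beta=r.ratio, se=r.ratio_se, pval=p,
            ci_low=r.ratio - Z95 * r.ratio_se, ci_high=r.ratio + Z95 * r.ratio_se,
            n_snps=1, model_detail="single-SNP Wald ratio (first-order SE)",
        )
    w = 1.0 / sG**2
    denom = float(np.sum(w * g**2))
    if denom == 0:
        raise EstimationError("all exposure betas are zero")
    beta = float(np.sum(w * g * G)) / denom
    se_fixed = denom**-0.5
    detail = "fixed-effect"
    se = se_fixed
    if model == "mre":
        q = float(np.sum(w * (G - beta * g) ** 2))
        infl = max(1.0, np.sqrt(q / (j - 1)))
        se = se_fixed * infl
        detail = f"multiplicative random effects (inflation {infl:.4f})"
    p = _two_sided_normal_p(beta, se)
    return MrEstimate(
        method="IVW", beta=beta, se=se, pval=p,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        n_snps=j, model_detail=detail,
    )


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def mr_egger(hset: HarmonizedInstrumentSet) -> MrEstimate:
    """Weighted regression of Gamma on gamma with an intercept.

    Exposure effects are first oriented so every gamma_j > 0 (flipping
    both betas where needed) — required for the intercept to estimate
    average directional pleiotropy.  Weights are 1/sigma_Gamma_j^2; SEs
    carry the residual inflation factor max(1, sqrt(Q'/(J-2))); p-values
    and the 95% CI use the t distribution with J-2 degrees of freedom.
    """
    j = hset.n_snps
    if j < 3:
        raise EstimationError(f"MR-Egger requires at least 3 instruments, got {j}")
    sign = np.where(hset.exposure_beta < 0, -1.0, 1.0)
    g = hset.exposure_beta * sign
    G = hset.outcome_beta * sign
    sG = hset.outcome_se
    if np.any(g == 0):
        raise EstimationError("degenerate instrument: exposure beta is 0")
    w = 1.0 / sG**2
    sw, swg, swgg = w.sum(), (w * g).sum(), (w * g * g).sum()
    det = sw * swgg - swg**2
    if det <= 0 or np.isclose(det / (sw * swgg), 0.0, atol=1e-12):
        raise EstimationError("singular Egger design: oriented exposure betas all equal")
    swG, swgG = (w * G).sum(), (w * g * G).sum()
    slope = (sw * swgG - swg * swG) / det
    intercept = (swgg * swG - swg * swgG) / det
    resid = G - intercept - slope * g
    q = float(np.sum(w * resid**2))
    infl = max(1.0, np.sqrt(q / (j - 2)))
    se_slope = float(np.sqrt(sw / det)) * infl
    se_int = float(np.sqrt(swgg / det)) * infl
    df = j - 2
    tcrit = float(stats.t.ppf(0.975, df))

    def t_p(b, s):
        if s == 0:
            return P_FLOOR
        return float(max(2.0 * stats.t.sf(abs(b) / s, df), P_FLOOR))

    return MrEstimate(
        method="MR-Egger", beta=float(slope), se=se_slope, pval=t_p(slope, se_slope),
        ci_low=float(slope) - tcrit * se_slope, ci_high=float(slope) + tcrit * se_slope,
        n_snps=j,
        model_detail=f"gamma oriented positive; residual inflation {infl:.4f}; t({df})",
        intercept=float(intercept), intercept_se=se_int,
        intercept_pval=t_p(intercept, se_int),
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Breakpoint-interpolated weighted median.

    Sort ratios ascending; with normalized weights w and cumulative sums
    S_j, breakpoints are p_j = S_j - w_j/2; the estimate interpolates the
    sorted ratios linearly at p = 0.5, clamped to the extremes.
    """
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, r))


def _resample(hset: HarmonizedInstrumentSet, n_boot: int, rng: np.random.Generator):
    """Parametric bootstrap draws of (gamma*, Gamma*), shape (n_boot, J)."""
    g = rng.normal(hset.exposure_beta, hset.exposure_se, size=(n_boot, hset.n_snps))
    G = rng.normal(hset.outcome_beta, hset.outcome_se, size=(n_boot, hset.n_snps))
    return g, G


def weighted_median(
    hset: HarmonizedInstrumentSet,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-median MR estimate with parametric-bootstrap SE.

    Consistent when instruments carrying >= 50% of the inverse-variance
    weight are valid.  ``seed`` is mandatory.
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    j = hset.n_snps
    if j < 3:
        raise EstimationError(f"weighted median requires at least 3 instruments, got {j}")
    ratios = compute_ratios(hset)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = _weighted_median_point(r, w)

    rng = np.random.default_rng(seed)
    g_b, G_b = _resample(hset, n_boot, rng)
    boot = np.empty(n_boot)
    se_out = hset.outcome_se
    for b in range(n_boot):
        rb = G_b[b] / g_b[b]
        wb = (np.abs(g_b[b]) / se_out) ** 2
        boot[b] = _weighted_median_point(rb, wb)
    se = float(np.std(boot, ddof=1))
    p = _two_sided_normal_p(beta, se)
    return MrEstimate(
        method="weighted-median", beta=beta, se=se, pval=p,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        n_snps=j, model_detail=f"parametric bootstrap SE ({n_boot} reps, seed {seed})",
    )


# ---------------------------------------------------------------------------
# Weighted mode
# ---------------------------------------------------------------------------

def _mode_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: phi * 0.9 * min(sd, MAD/0.6745) * J^(-1/5).

    A non-positive MAD term falls back to the sd (and vice versa); both
    zero means all ratios coincide and the bandwidth is 0.
    """
    j = len(r)
    sd = float(np.std(r, ddof=1))
    mad = float(np.median(np.abs(r - np.median(r)))) / 0.6745
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return phi * 0.9 * min(scales) * j ** (-1.0 / 5.0)


def _weighted_mode_point(r: np.ndarray, w: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(r, phi)
    lo, hi = float(r.min()), float(r.max())
    if h == 0.0 or lo == hi:
        return float(r[0]) if lo == hi else float(np.median(r))
    grid = np.linspace(lo, hi, MODE_GRID_POINTS)
    dens = w @ np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)
    return float(grid[int(np.argmax(dens))])  # argmax -> smallest grid point on ties


def weighted_mode(
    hset: HarmonizedInstrumentSet,
    phi: float = DEFAULT_PHI,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> MrEstimate:
    """Weighted-mode MR estimate (kernel-density argmax over Wald ratios).

    Consistent when the largest weighted cluster of ratios comes from
    valid instruments (ZEro Modal Pleiotropy Assumption).  Density is the
    inverse-variance-weighted Gaussian kernel smooth of the ratios with
    the modified-Silverman bandwidth scaled by ``phi``, maximized over a
    512-point grid spanning the ratio range; SE from the same parametric
    bootstrap as the weighted median.  ``seed`` is mandatory.
    """
    if seed is None:
        raise ValueError("weighted_mode requires an explicit seed")
    j = hset.n_snps
    if j < 3:
        raise EstimationError(f"weighted mode requires at least 3 instruments, got {j}")
    ratios = compute_ratios(hset)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = _weighted_mode_point(r, w, phi)

    rng = np.random.default_rng(seed)
    g_b, G_b = _resample(hset, n_boot, rng)
    se_out = hset.outcome_se
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rb = G_b[b] / g_b[b]
        wb = (np.abs(g_b[b]) / se_out) ** 2
        boot[b] = _weighted_mode_point(rb, wb / wb.sum(), phi)
    se = float(np.std(boot, ddof=1))
    p = _two_sided_normal_p(beta, se)
    return MrEstimate(
        method="weighted-mode", beta=beta, se=se, pval=p,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        n_snps=j,
        model_detail=(
            f"bandwidth factor {phi}; parametric bootstrap SE ({n_boot} reps, seed {seed})"
        ),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def estimates_table(exposure_label: str, estimates: Sequence[MrEstimate]) -> pd.DataFrame:
    """Render estimates in the standard report layout:
    Exposure, No. SNPs, Est. method, Effect, Std error, P-value, 95% CI bounds.
    """
    rows = []
    for est in estimates:
        rows.append(
            {
                "Exposure": exposure_label,
                "No. SNPs": est.n_snps,
                "Est. method": est.method,
                "Effect": est.beta,
                "Std error": est.se,
                "P-value": est.pval,
                "CI lower": est.ci_low,
                "CI upper": est.ci_high,
            }
        )
    return pd.DataFrame(rows)
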