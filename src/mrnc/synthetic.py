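"""Stratified-population GWAS simulator for negative-control MR testing.

The generative model realizes the textbook population-stratification
mechanism: a cohort is a mixture of K subpopulations whose allele
frequencies drifted apart (Balding-Nichols F-model) and whose phenotype
means differ.  Exposure X, outcome Y and a negative-control phenotype NC
all load on the same subpopulation mean shift mu_s, so an unadjusted
association scan picks up a spurious, frequency-differentiation-driven
component at EVERY differentiated SNP — the shared-bias signature that
negative-control MR is designed to detect.  The negative control has no
genotype dependence by construction (it is "determined at birth"); an
optional pleiotropy mechanism instead wires a minority of causal SNPs
directly into NC (or Y), producing the contrasting outlier-driven signal
that robust estimators absorb.

Model, per individual i in subpopulation s(i) with dosages g_ij:

    X_i  = sum_j gamma_j g_ij + c_X mu_{s(i)} + eps_X
    NC_i =                      c_N mu_{s(i)} + eps_N  (+ alpha g_ij, pleiotropy)
    Y_i  = beta X_i           + c_Y mu_{s(i)} + eps_Y

True effects gamma_j are shifted half-normal (alleles coded
exposure-increasing, magnitudes bounded away from zero the way
genome-wide-significant instrument sets are), so directional pleiotropy
with a positive mean alpha is meaningful.  Subpopulation
frequencies p_{j,s} ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
p_j, variance F p(1-p).

Two-sample summary sets are produced by drawing two independent cohorts
from one shared truth (frequencies + effects); all randomness flows from
explicit seeds, there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .summary_data import GwasRecord

FREQ_CLIP = 1e-4

SCENARIO_NAMES = ("null", "causal", "stratified", "stratified_adjusted", "pleiotropy")


class SimulationError(ValueError):
    """Infeasible simulation configuration or degenerate realization."""


@dataclass
class SimConfig:
    """Generative parameters for one stratified cohort.

    Defaults are the desk-scale preset: 10,000 individuals, 300 SNPs of
    which 100 affect the exposure, 3 equal subpopulations at F_ST = 0.05.
    ``mu_subpop`` are zero-mean subpopulation phenotype shifts (units of
    the residual SD); ``strat_x/y/nc`` scale how strongly each phenotype
    loads on them.  ``pleiotropy_frac`` of the causal SNPs get a direct
    per-allele effect ``pleiotropy_effect`` on ``pleiotropy_target``.
    """

    n_individuals: int = 10_000
    n_snps: int = 300
    n_causal: int = 100
    k_subpops: int = 3
    subpop_props: tuple[float, ...] | None = None
    fst: float = 0.05
    anc_freq_range: tuple[float, float] = (0.1, 0.9)
    gamma_sd: float = 0.1
    gamma_min: float = 0.25
    beta_xy: float = 0.0
    strat_x: float = 0.0
    strat_y: float = 0.0
    strat_nc: float = 0.0
    mu_subpop: tuple[float, ...] | None = None
    noise_sds: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pleiotropy_frac: float = 0.0
    pleiotropy_effect: float = 0.0
    pleiotropy_effect_sd: float = 0.0
    pleiotropy_target: str = "nc"
    palindrome_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subpop_props is None:
            self.subpop_props = tuple([1.0 / self.k_subpops] * self.k_subpops)
        self.subpop_props = tuple(float(p) for p in self.subpop_props)
        if len(self.subpop_props) != self.k_subpops:
            raise SimulationError("subpop_props length must equal k_subpops")
        if abs(sum(self.subpop_props) - 1.0) > 1e-12:
            raise SimulationError("subpop_props must sum to 1")
        if any(p <= 0 for p in self.subpop_props):
            raise SimulationError("subpop_props must all be positive")
        if self.mu_subpop is None:
            mu = np.linspace(-1.0, 1.0, self.k_subpops)
            mu -= np.average(mu, weights=self.subpop_props)
            self.mu_subpop = tuple(mu)
        self.mu_subpop = tuple(float(m) for m in self.mu_subpop)
        if len(self.mu_subpop) != self.k_subpops:
            raise SimulationError("mu_subpop length must equal k_subpops")
        if abs(float(np.average(self.mu_subpop, weights=self.subpop_props))) > 1e-12:
            raise SimulationError("mu_subpop must be zero-mean under subpop_props")
        if not 0.0 <= self.fst < 1.0:
            raise SimulationError("fst must lie in [0,1)")
        if self.n_causal > self.n_snps:
            raise SimulationError("n_causal cannot exceed n_snps")
        lo, hi = self.anc_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise SimulationError("anc_freq_range must sit within (0.05, 0.95)")
        if not 0.0 <= self.pleiotropy_frac <= 1.0:
            raise SimulationError("pleiotropy_frac must lie in [0,1]")
        if self.pleiotropy_target not in ("nc", "y"):
            raise SimulationError("pleiotropy_target must be 'nc' or 'y'")


@dataclass
class SimTruth:
    """Shared ground truth behind one or more simulated cohorts."""

    anc_freqs: np.ndarray          # (n_snps,)
    subpop_freqs: np.ndarray       # (k_subpops, n_snps)
    gamma: np.ndarray              # (n_snps,), zero off the causal set
    causal_idx: np.ndarray
    pleiotropy_idx: np.ndarray
    pleiotropy_alphas: np.ndarray  # per-SNP direct effects, aligned to pleiotropy_idx
    alleles: list[tuple[str, str]]  # (effect, other) per SNP
    config: SimConfig


@dataclass
class SimulatedCohort:
    """Realized genotypes and phenotypes for one cohort."""

    genotypes: np.ndarray          # (n, m) dosages in {0,1,2}
    subpop_labels: np.ndarray      # (n,)
    phenotypes: dict               # keys X, Y, NC
    truth: SimTruth


def draw_subpop_frequencies(
    anc_freq: float, fst: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around an ancestral one.

    F = 0 returns the ancestral frequency exactly for all k; otherwise
    draws Beta(p(1-F)/F, (1-p)(1-F)/F) per subpopulation (mean p,
    variance F p(1-p)), clipped away from fixation.
    """
    if not 0.0 < anc_freq < 1.0:
        raise SimulationError("ancestral frequency must lie in (0,1)")
    if not 0.0 <= fst < 1.0:
        raise SimulationError("fst must lie in [0,1)")
    if fst == 0.0:
        return np.full(k, anc_freq)
    scale = (1.0 - fst) / fst
    draws = rng.beta(anc_freq * scale, (1.0 - anc_freq) * scale, size=k)
    return np.clip(draws, FREQ_CLIP, 1.0 - FREQ_CLIP)


def make_truth(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw the population-level truth: frequencies, effects, allele labels."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lo, hi = config.anc_freq_range
    anc = rng.uniform(lo, hi, size=config.n_snps)
    subpop = np.vstack(
        [draw_subpop_frequencies(p, config.fst, config.k_subpops, rng) for p in anc]
    ).T
    causal = np.sort(rng.choice(config.n_snps, size=config.n_causal, replace=False))
    gamma = np.zeros(config.n_snps)
    # shifted half-normal, coded on the exposure-increasing allele: real
    # instrument sets are genome-wide-significant hits, i.e. effects bounded
    # away from zero; a floor keeps desk-scale selection from being
    # dominated by winner's-curse threshold artifacts
    gamma[causal] = config.gamma_min + np.abs(
        rng.normal(0.0, config.gamma_sd, size=config.n_causal))
    n_pleio = int(round(config.pleiotropy_frac * config.n_causal))
    pleio = (
        np.sort(rng.choice(causal, size=n_pleio, replace=False))
        if n_pleio > 0
        else np.array([], dtype=int)
    )
    # directional-on-average, per-SNP heterogeneous pleiotropy: a constant
    # alpha across all instruments would be a shared shift in ratio space,
    # not an outlier mechanism
    alphas = rng.normal(config.pleiotropy_effect, config.pleiotropy_effect_sd,
                        size=n_pleio)
    palindromic = rng.random(config.n_snps) < config.palindrome_frac
    alleles = [("A", "T") if pal else ("A", "G") for pal in palindromic]
    return SimTruth(
        anc_freqs=anc,
        subpop_freqs=subpop,
        gamma=gamma,
        causal_idx=causal,
        pleiotropy_idx=pleio,
        pleiotropy_alphas=alphas,
        alleles=alleles,
        config=config,
    )


def simulate_cohort(
    config: SimConfig,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedCohort:
    """Realize one cohort (genotypes + phenotypes) from the truth.

    With no ``truth``/``rng`` supplied everything derives from
    ``config.seed``, so identical configs give identical cohorts.
    """
    ss = np.random.SeedSequence(config.seed).spawn(2)
    if truth is None:
        truth = make_truth(config, np.random.default_rng(ss[0]))
    if rng is None:
        rng = np.random.default_rng(ss[1])

    n, m, k = config.n_individuals, config.n_snps, config.k_subpops
    labels = rng.choice(k, size=n, p=config.subpop_props)
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        raise SimulationError(
            f"infeasible config: subpopulation(s) {np.where(counts == 0)[0].tolist()} "
            f"received zero individuals at n={n}"
        )
    # Binomial(2, p) as two summed Bernoulli draws; float32 keeps the
    # uniform generation fast at desk scale without statistical cost.
    p_rows = truth.subpop_freqs[labels].astype(np.float32)  # (n, m)
    u = rng.random((2, n, m), dtype=np.float32)
    genotypes = (u[0] < p_rows).view(np.int8) + (u[1] < p_rows).view(np.int8)

    mu = np.asarray(config.mu_subpop)[labels]
    sx, sy, snc = config.noise_sds
    x = genotypes @ truth.gamma + config.strat_x * mu + rng.normal(0.0, sx, n)
    nc = config.strat_nc * mu + rng.normal(0.0, snc, n)
    y = config.beta_xy * x + config.strat_y * mu + rng.normal(0.0, sy, n)
    if truth.pleiotropy_idx.size:
        direct = genotypes[:, truth.pleiotropy_idx].astype(np.float64) @ truth.pleiotropy_alphas
        if config.pleiotropy_target == "nc":
            nc = nc + direct
        else:
            y = y + direct
    return SimulatedCohort(
        genotypes=genotypes,
        subpop_labels=labels,
        phenotypes={"X": x, "Y": y, "NC": nc},
        truth=truth,
    )


def _adjustment_matrix(cohort: SimulatedCohort, adjustment: str) -> np.ndarray:
    """Covariate matrix (with intercept) for the association scan."""
    n = cohort.genotypes.shape[0]
    ones = np.ones((n, 1))
    if adjustment == "none":
        return ones
    if adjustment == "subpop_labels":
        k = cohort.truth.config.k_subpops
        dummies = (cohort.subpop_labels[:, None] == np.arange(1, k)[None, :]).astype(float)
        return np.hstack([ones, dummies])
    if adjustment.startswith("pcs:"):
        k = int(adjustment.split(":", 1)[1])
        if not 0 < k < n:
            raise SimulationError("pcs:k requires 0 < k < n_individuals")
        gc = cohort.genotypes - cohort.genotypes.mean(axis=0)
        # top-k PCs via the m x m cross-product (m << n)
        _, vecs = np.linalg.eigh(gc.T @ gc)
        scores = gc @ vecs[:, -k:]
        return np.hstack([ones, scores])
    raise SimulationError(f"unknown adjustment {adjustment!r}")


def run_gwas(
    cohort: SimulatedCohort,
    phenotype: str = "X",
    adjustment: str = "none",
) -> list[GwasRecord]:
    """Per-SNP OLS scan of a phenotype on dosage plus adjustment covariates.

    ``adjustment`` is ``none``, ``subpop_labels`` (true indicators) or
    ``pcs:k`` (top k principal components of the centered genotype
    matrix).  Covariates are projected out of both phenotype and dosages
    (Frisch-Waugh), then each SNP is a simple regression on the
    residuals.  Monomorphic SNPs are emitted flagged ``not_assessable``.
    Effect/other alleles come from the shared truth; eaf is the observed
    dosage mean / 2.
    """
    if phenotype not in cohort.phenotypes:
        raise SimulationError(f"unknown phenotype {phenotype!r}")
    y = np.asarray(cohort.phenotypes[phenotype], dtype=float)
    if np.ptp(y) == 0:
        raise SimulationError(f"phenotype {phenotype} is constant; cannot run GWAS")
    g = cohort.genotypes.astype(float)
    n, m = g.shape
    cov = _adjustment_matrix(cohort, adjustment)
    q_cols = cov.shape[1]
    qmat, _ = np.linalg.qr(cov)
    y_res = y - qmat @ (qmat.T @ y)
    g_res = g - qmat @ (qmat.T @ g)

    sxx = np.einsum("ij,ij->j", g_res, g_res)
    sxy = g_res.T @ y_res
    syy = float(y_res @ y_res)
    dof = n - q_cols - 1
    eaf = g.mean(axis=0) / 2.0

    records: list[GwasRecord] = []
    mono = sxx <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / dof / np.where(mono, 1.0, sxx))
    tstat = np.abs(beta) / se
    pval = 2.0 * stats.t.sf(tstat, dof)
    for j in range(m):
        ea, oa = cohort.truth.alleles[j]
        if mono[j] or se[j] <= 0 or not np.isfinite(se[j]):
            records.append(
                GwasRecord(
                    snp_id=f"rs{j + 1}", effect_allele=ea, other_allele=oa,
                    eaf=float(eaf[j]), beta=float("nan"), se=float("nan"),
                    pval=None, n=n, flag="not_assessable",
                )
            )
            continue
        records.append(
            GwasRecord(
                snp_id=f"rs{j + 1}", effect_allele=ea, other_allele=oa,
                eaf=float(eaf[j]), beta=float(beta[j]), se=float(se[j]),
                pval=float(max(pval[j], 5e-324)), n=n,
            )
        )
    return records


_SCENARIO_PRESETS: dict[str, dict] = {
    # beta/strat/pleiotropy magnitudes are artifact choices calibrated so
    # the detection-power and mechanism-contrast properties are stable at
    # desk scale; see docs/methods.md.
    # "no stratification" presets set F=0 outright: even without phenotype
    # mean shifts, drifted causal-allele frequencies stratify a polygenic
    # exposure by themselves, which would contaminate these baselines.
    "null": dict(beta_xy=0.0, fst=0.0),
    "causal": dict(beta_xy=0.05, fst=0.0),
    "stratified": dict(beta_xy=0.05, strat_x=1.0, strat_y=1.0, strat_nc=1.0),
    "stratified_adjusted": dict(beta_xy=0.05, strat_x=1.0, strat_y=1.0, strat_nc=1.0),
    "pleiotropy": dict(beta_xy=0.05, fst=0.0, pleiotropy_frac=0.3,
                       pleiotropy_effect=0.08, pleiotropy_effect_sd=0.12),
}

SCENARIO_ADJUSTMENT = {name: "none" for name in SCENARIO_NAMES}
SCENARIO_ADJUSTMENT["stratified_adjusted"] = "subpop_labels"


def make_scenario(
    name: str,
    overrides: Mapping | None = None,
    seed: int = 0,
) -> tuple[list[GwasRecord], list[GwasRecord], list[GwasRecord], SimTruth]:
    """Build (exposure, outcome, negative-control) summary sets + truth.

    Presets: ``null`` (no causal effect, no structure), ``causal``
    (beta != 0, no stratification), ``stratified`` (all three phenotypes
    load on the subpopulation shifts, unadjusted scans),
    ``stratified_adjusted`` (same cohorts, scans adjusted for the true
    labels), ``pleiotropy`` (no stratification; 30% of causal SNPs act
    directly on the negative control).  The two-sample design draws the
    exposure cohort and the outcome/NC cohort independently from one
    shared truth.  ``overrides`` patches SimConfig fields; an
    ``adjustment`` key overrides the scan adjustment.
    """
    if name not in SCENARIO_NAMES:
        raise SimulationError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    params = dict(_SCENARIO_PRESETS[name])
    adjustment = SCENARIO_ADJUSTMENT[name]
    if overrides:
        overrides = dict(overrides)
        adjustment = overrides.pop("adjustment", adjustment)
        params.update(overrides)
    config = SimConfig(seed=seed, **params)

    ss = np.random.SeedSequence(seed).spawn(3)
    truth = make_truth(config, np.random.default_rng(ss[0]))
    cohort_a = simulate_cohort(config, truth=truth, rng=np.random.default_rng(ss[1]))
    cohort_b = simulate_cohort(config, truth=truth, rng=np.random.default_rng(ss[2]))

    exposure = run_gwas(cohort_a, "X", adjustment)
    outcome = run_gwas(cohort_b, "Y", adjustment)
    nc = run_gwas(cohort_b, "NC", adjustment)
    return exposure, outcome, nc, truth
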