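import numpy as np
import pytest
from scipy import stats

from mrnc import (
    EstimationError,
    estimates_table,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrnc.estimators import _weighted_median_point, _weighted_mode_point, _mode_bandwidth

from conftest import make_hset, random_hset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def wls_oracle(gamma, Gamma, weights, intercept):
    """Weighted least squares via numpy lstsq on the sqrt-weighted design."""
    gamma, Gamma, weights = map(np.asarray, (gamma, Gamma, weights))
    sw = np.sqrt(weights)
    if intercept:
        design = np.column_stack([np.ones_like(gamma), gamma])
    else:
        design = gamma[:, None]
    coef, *_ = np.linalg.lstsq(design * sw[:, None], Gamma * sw, rcond=None)
    return coef


def weighted_median_oracle(ratios, weights):
    """Brute-force interpolation at the 0.5 breakpoint, pure python."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    bps = []
    for r, w in pairs:
        cum += w
        bps.append((cum - w / 2) / total)
    rs = [r for r, _ in pairs]
    if 0.5 <= bps[0]:
        return rs[0]
    if 0.5 >= bps[-1]:
        return rs[-1]
    for i in range(len(bps) - 1):
        if bps[i] <= 0.5 <= bps[i + 1]:
            frac = (0.5 - bps[i]) / (bps[i + 1] - bps[i])
            return rs[i] + frac * (rs[i + 1] - rs[i])
    raise AssertionError("unreachable")


def weighted_mode_oracle(ratios, weights, phi=1.0, resolution=10):
    """Grid search at `resolution` x the estimator's grid density."""
    r = np.asarray(ratios)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    h = _mode_bandwidth(r, phi)
    grid = np.linspace(r.min(), r.max(), 512 * resolution)
    dens = [float(np.sum(w * np.exp(-0.5 * ((x - r) / h) ** 2))) for x in grid]
    return float(grid[int(np.argmax(dens))])


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(0.5, 0.02, 0.1, 0.05)
        assert r.ratio == pytest.approx(0.2)
        assert r.ratio_se == pytest.approx(0.1)

    def test_negative_exposure_beta_uses_abs_for_se(self):
        r = wald_ratio(-0.5, 0.02, 0.1, 0.05)
        assert r.ratio == pytest.approx(-0.2)
        assert r.ratio_se == pytest.approx(0.1)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.02, 0.1, 0.05)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

class TestIvw:
    def test_micro_example_fixed(self, micro_hset):
        est = ivw(micro_hset, model="fixed")
        assert est.beta == pytest.approx(0.275)          # 55/200 by hand
        assert est.se == pytest.approx(200 ** -0.5)      # 0.0707107
        assert est.ci_low == pytest.approx(0.275 - 1.96 * 200 ** -0.5)

    def test_single_snp_collapses_to_wald_ratio(self):
        h = make_hset([0.5], [0.02], [0.1], [0.05])
        est = ivw(h)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.n_snps == 1

    def test_all_zero_outcome_betas_give_zero(self):
        h = make_hset([0.5, 0.8, 1.0], [0.02] * 3, [0.0] * 3, [0.05] * 3)
        assert ivw(h).beta == 0.0

    def test_mre_se_never_below_fixed(self):
        for seed in range(50):
            h = random_hset(np.random.default_rng(seed), j=8)
            assert ivw(h, "mre").se >= ivw(h, "fixed").se - 1e-15

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_zero_intercept_wls_oracle(self, seed):
        h = random_hset(np.random.default_rng(seed), j=10)
        est = ivw(h, model="fixed")
        (slope,) = wls_oracle(h.exposure_beta, h.outcome_beta,
                              1 / h.outcome_se**2, intercept=False)
        assert est.beta == pytest.approx(slope, abs=1e-10)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

class TestMrEgger:
    def test_collinear_triple_exact_fit(self):
        h = make_hset([1, 2, 3], [0.02] * 3, [0.3, 0.5, 0.7], [0.05, 0.04, 0.03])
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.intercept == pytest.approx(0.1, abs=1e-12)
        # zero residuals: dispersion floored at 1, so the SE is the pure
        # design SE and the point estimates are exact
        q = np.sum((h.outcome_beta - est.intercept - est.beta * h.exposure_beta) ** 2)
        assert q == pytest.approx(0.0, abs=1e-20)

    def test_constant_outcome_shift_moves_intercept_only(self):
        rng = np.random.default_rng(3)
        h = random_hset(rng, j=8)
        base = mr_egger(h)
        shifted = make_hset(h.exposure_beta, h.exposure_se,
                            h.outcome_beta + 0.25 * np.sign(h.exposure_beta),
                            h.outcome_se)
        # shift is +c after the positive-orientation flip
        est = mr_egger(shifted)
        assert est.beta == pytest.approx(base.beta, abs=1e-10)
        assert est.intercept == pytest.approx(base.intercept + 0.25, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_two_parameter_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = random_hset(rng, j=6)
        est = mr_egger(h)
        sign = np.where(h.exposure_beta < 0, -1, 1)
        icept, slope = wls_oracle(h.exposure_beta * sign, h.outcome_beta * sign,
                                  1 / h.outcome_se**2, intercept=True)
        assert est.beta == pytest.approx(slope, abs=1e-10)
        assert est.intercept == pytest.approx(icept, abs=1e-10)

    def test_degenerate_design_raises(self):
        h = make_hset([0.5, 0.5, -0.5], [0.02] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        with pytest.raises(EstimationError, match="singular"):
            mr_egger(h)

    def test_too_few_instruments(self):
        h = make_hset([0.5, 1.0], [0.02] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(EstimationError):
            mr_egger(h)

    def test_pvalues_use_t_reference(self):
        rng = np.random.default_rng(11)
        h = random_hset(rng, j=5)
        est = mr_egger(h)
        expect = 2 * stats.t.sf(abs(est.beta) / est.se, 3)
        assert est.pval == pytest.approx(expect, rel=1e-10)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

class TestWeightedMedian:
    def test_equal_weight_middle_breakpoint(self):
        assert _weighted_median_point(np.array([0.1, 0.2, 0.6]),
                                      np.ones(3)) == pytest.approx(0.2)

    def test_equal_weight_interpolation(self):
        # breakpoints at 0.125/0.375/0.625/0.875; 0.5 interpolates to 0.3
        assert _weighted_median_point(np.array([0.1, 0.2, 0.4, 0.5]),
                                      np.ones(4)) == pytest.approx(0.3)

    def test_dominant_weight_limit(self):
        eps = 1e-9
        r = np.array([0.1, 0.2, 0.9])
        w = np.array([eps, eps, 1 - 2 * eps])
        assert _weighted_median_point(r, w) == pytest.approx(0.9, abs=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        j = rng.integers(3, 30)
        ratios = rng.normal(size=j)
        weights = rng.uniform(0.1, 5, j)
        assert _weighted_median_point(ratios, weights) == pytest.approx(
            weighted_median_oracle(ratios.tolist(), weights.tolist()), abs=1e-12
        )

    def test_estimate_through_full_api(self):
        h = make_hset([1, 1, 1, 1], [0.02] * 4, [0.1, 0.2, 0.4, 0.5], [0.1] * 4)
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se > 0

    def test_seed_is_mandatory(self, micro_hset):
        h = make_hset([0.5, 1.0, 0.8], [0.02] * 3, [0.15, 0.25, 0.2], [0.05] * 3)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(h, n_boot=10)

    def test_bootstrap_reproducible_to_last_bit(self):
        rng = np.random.default_rng(5)
        h = random_hset(rng, j=6)
        a = weighted_median(h, n_boot=200, seed=99)
        b = weighted_median(h, n_boot=200, seed=99)
        assert a.se == b.se and a.beta == b.beta


# ---------------------------------------------------------------------------
# Weighted mode
# ---------------------------------------------------------------------------

class TestWeightedMode:
    def test_identical_ratios_returned_exactly(self):
        h = make_hset([1, 1, 1], [0.02] * 3, [0.3, 0.3, 0.3], [0.05, 0.05, 0.05])
        est = weighted_mode(h, n_boot=50, seed=2)
        assert est.beta == pytest.approx(0.3)

    def test_outlier_ignored(self):
        h = make_hset([1, 1, 1, 1], [0.02] * 4, [0.2, 0.21, 0.19, 5.0], [0.05] * 4)
        est = weighted_mode(h, n_boot=50, seed=3)
        assert abs(est.beta - 0.2) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_grid_oracle_within_one_step(self, seed):
        rng = np.random.default_rng(seed)
        ratios = np.concatenate([rng.normal(0.2, 0.02, 6), rng.normal(1.0, 0.1, 3)])
        weights = rng.uniform(0.5, 2, 9)
        weights = weights / weights.sum()
        est = _weighted_mode_point(ratios, weights, phi=1.0)
        oracle = weighted_mode_oracle(ratios, weights)
        step = (ratios.max() - ratios.min()) / 511
        assert abs(est - oracle) <= step

    def test_weight_normalization_invariance(self):
        rng = np.random.default_rng(8)
        ratios = rng.normal(size=6)
        weights = rng.uniform(0.1, 1, 6)
        a = _weighted_mode_point(ratios, weights / weights.sum(), 1.0)
        b = _weighted_mode_point(ratios, 2 * weights / weights.sum(), 1.0)
        assert a == b

    def test_bootstrap_reproducible(self):
        h = random_hset(np.random.default_rng(13), j=5)
        a = weighted_mode(h, n_boot=100, seed=7)
        b = weighted_mode(h, n_boot=100, seed=7)
        assert a.se == b.se


# ---------------------------------------------------------------------------
# Cross-estimator properties
# ---------------------------------------------------------------------------

BOOT = dict(n_boot=100, seed=17)


def run_all(h):
    return {
        "IVW": ivw(h),
        "MR-Egger": mr_egger(h),
        "weighted-median": weighted_median(h, **BOOT),
        "weighted-mode": weighted_mode(h, **BOOT),
    }


class TestEquivariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_outcome_scale_equivariance(self, seed):
        h = random_hset(np.random.default_rng(seed), j=8)
        c = 3.7
        scaled = make_hset(h.exposure_beta, h.exposure_se,
                           c * h.outcome_beta, c * h.outcome_se)
        for m, est in run_all(h).items():
            est_c = run_all(scaled)[m]
            assert est_c.beta == pytest.approx(c * est.beta, rel=1e-6, abs=1e-9), m
            assert est_c.se == pytest.approx(c * est.se, rel=1e-6, abs=1e-9), m

    @pytest.mark.parametrize("seed", range(5))
    def test_outcome_sign_equivariance(self, seed):
        h = random_hset(np.random.default_rng(seed), j=8)
        neg = make_hset(h.exposure_beta, h.exposure_se,
                        -h.outcome_beta, h.outcome_se)
        for m, est in run_all(h).items():
            est_n = run_all(neg)[m]
            assert est_n.beta == pytest.approx(-est.beta, rel=1e-6, abs=1e-9), m


class TestRobustnessContrast:
    """A minority of shifted ratios moves IVW but not the weighted median;
    a shift shared by every ratio moves all four estimators."""

    def _base(self, rng, j=10):
        gamma = rng.uniform(0.3, 1.0, j)
        return gamma, 0.2 * gamma + rng.normal(0, 0.01, j)

    def test_minority_shift_moves_ivw_not_median(self):
        rng = np.random.default_rng(21)
        gamma, Gamma = self._base(rng)
        Gamma_bad = Gamma.copy()
        Gamma_bad[:2] += 1.5 * gamma[:2]  # minority of weight far off
        h = make_hset(gamma, np.full(10, 0.02), Gamma_bad, np.full(10, 0.01))
        med = weighted_median(h, n_boot=500, seed=4)
        assert abs(med.beta - 0.2) < 2 * med.se
        assert ivw(h).beta - 0.2 > 4 * med.se

    def test_shared_shift_moves_every_estimator(self):
        rng = np.random.default_rng(22)
        gamma, Gamma = self._base(rng)
        h_null = make_hset(gamma, np.full(10, 0.02), Gamma, np.full(10, 0.01))
        h_shift = make_hset(gamma, np.full(10, 0.02), Gamma + 0.5 * gamma,
                            np.full(10, 0.01))
        for m, est in run_all(h_shift).items():
            base = run_all(h_null)[m]
            assert est.beta - base.beta > 0.4, m


def test_estimates_table_layout(micro_hset):
    est = ivw(micro_hset)
    table = estimates_table("BMI", [est])
    assert list(table.columns) == ["Exposure", "No. SNPs", "Est. method",
                                   "Effect", "Std error", "P-value",
                                   "CI lower", "CI upper"]
    assert table.iloc[0]["No. SNPs"] == 2
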