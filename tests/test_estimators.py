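"""Core MR estimators against closed forms and independent regression oracles."""

import numpy as np
import pytest
from scipy import stats

from helpers import make_pair, make_set, random_set, weighted_median_oracle, wls_oracle
from pwmr.errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from pwmr.estimators import (
    Z95,
    estimate_auto,
    egger,
    ivw,
    primary_estimate,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    def test_formula(self):
        est = wald_ratio(make_pair("rs1", 0.5, 0.02, 0.25, 0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.ci_low == pytest.approx(0.5 - Z95 * 0.2)
        assert est.n_snp == 1 and est.method == "wald"

    def test_zero_numerator(self):
        assert wald_ratio(make_pair("rs1", 0.5, 0.02, 0.0, 0.1)).beta == 0.0

    def test_negative_exposure_effect_keeps_se_positive(self):
        est = wald_ratio(make_pair("rs1", -0.5, 0.02, 0.25, 0.1))
        assert est.beta == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.2)

    def test_degenerate_instrument(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_pair("rs1", 0.0, 0.02, 0.25, 0.1))


class TestIvw:
    def test_consensus_ratio(self):
        s = make_set([1.0, 2.0], [0.01, 0.01], [0.3, 0.6], [0.1, 0.2])
        est = ivw(s, mode="fixed")
        assert est.beta == pytest.approx(0.3)
        assert est.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_snps(self):
        s = make_set([1.0, 1.0], [0.01, 0.01], [0.2, 0.4], [0.1, 0.1])
        est = ivw(s, mode="fixed")
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))
        assert est.q_stat == pytest.approx(2.0)
        assert est.q_pvalue == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_random_mode_floors_scale_at_one(self):
        s = make_set([1.0, 2.0], [0.01, 0.01], [0.3, 0.6], [0.1, 0.2])
        assert ivw(s, "random").se == pytest.approx(ivw(s, "fixed").se)  # Q = 0
        s2 = make_set([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.3, 0.8], [0.1] * 3)
        est = ivw(s2, "random")
        q = est.q_stat
        assert est.se == pytest.approx(ivw(s2, "fixed").se * np.sqrt(q / 2))

    def test_single_snp_directs_to_wald(self):
        s = make_set([1.0], [0.01], [0.3], [0.1])
        with pytest.raises(InsufficientInstrumentsError, match="wald"):
            ivw(s)

    def test_equal_weights_reduce_to_ols_through_origin(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 8)
        by = 0.4 * bx + rng.normal(0, 0.02, 8)
        s = make_set(bx, np.full(8, 0.01), by, np.full(8, 0.05))
        beta_ols = float(np.sum(bx * by) / np.sum(bx**2))
        assert ivw(s, "fixed").beta == pytest.approx(beta_ols, abs=1e-12)


class TestEgger:
    def test_exact_fit_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3])
        s = make_set(bx, [0.01] * 3, 0.4 * bx, [0.05, 0.07, 0.1])
        est = egger(s)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        s = make_set(bx, [0.01] * 4, 0.1 + 0.4 * bx, [0.05] * 4)
        est = egger(s)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.1, abs=1e-12)

    def test_orientation_invariance(self):
        """Flipping an instrument's allele coding must not change the fit."""
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.05 + 0.4 * bx * np.sign(bx)  # affine in |bx| after orientation
        by = by * np.sign(bx)
        s = make_set(bx, [0.01] * 4, by, [0.05] * 4)
        s_flipped = make_set(-bx, [0.01] * 4, -by, [0.05] * 4)
        assert egger(s).beta == pytest.approx(egger(s_flipped).beta, abs=1e-12)

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            k = 10
            bx = rng.uniform(0.05, 0.5, k)
            by = 0.02 + 0.35 * bx + rng.normal(0, 0.03, k)
            sy = rng.uniform(0.03, 0.1, k)
            s = make_set(bx, np.full(k, 0.01), by, sy)
            est = egger(s)
            X = np.column_stack([np.ones(k), bx])
            coef, se_unit, sigma2 = wls_oracle(X, by, 1.0 / sy**2)
            assert est.beta == pytest.approx(coef[1], abs=1e-10)
            assert est.egger_intercept == pytest.approx(coef[0], abs=1e-10)
            scale = max(sigma2, 1.0)
            assert est.se == pytest.approx(se_unit[1] * np.sqrt(scale), abs=1e-10)
            assert est.egger_intercept_se == pytest.approx(
                se_unit[0] * np.sqrt(scale), abs=1e-10
            )

    def test_insufficient_and_collinear(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_set([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.05] * 2))
        with pytest.raises(CollinearityError):
            egger(make_set([0.2, 0.2, -0.2], [0.01] * 3, [0.1, 0.1, -0.1], [0.05] * 3))

    def test_intercept_pvalues_uniform_under_balanced_pleiotropy(self):
        """With zero-mean pleiotropy the intercept test should be well
        calibrated: p-values approximately uniform over replicates."""
        rng = np.random.default_rng(7)
        k = 20
        bx_true = np.linspace(0.05, 0.25, k)
        pvals = []
        for _ in range(500):
            by = 0.3 * bx_true + rng.normal(0.0, 0.05, k) + rng.normal(0, 0.05, k)
            s = make_set(bx_true, np.full(k, 1e-4), by, np.full(k, 0.05))
            pvals.append(egger(s).egger_intercept_pvalue)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestWeightedMedian:
    def test_symmetric_median(self):
        s = make_set([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 3.0], [0.1] * 3)
        assert weighted_median(s, seed=0).beta == pytest.approx(2.0)

    def test_outlier_robustness(self):
        s = make_set([1.0, 1.0, 1.0], [0.01] * 3, [1.0, 2.0, 100.0], [0.1] * 3)
        assert weighted_median(s, seed=0).beta == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_cumulative_weight_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = 5
        bx = rng.uniform(0.1, 0.5, k)
        by = rng.normal(0.3 * bx, 0.1)
        sy = rng.uniform(0.02, 0.2, k)
        s = make_set(bx, np.full(k, 0.01), by, sy)
        expected = weighted_median_oracle(by / bx, (bx / sy) ** 2)
        assert weighted_median(s, seed=0).beta == pytest.approx(expected, abs=1e-12)

    def test_recovers_effect_with_minority_invalid_instruments(self):
        """Consistent when instruments carrying < 50% of weight are invalid."""
        k = 10
        bx = np.full(k, 0.3)
        by = 0.3 * bx
        by[:4] += 0.3  # 40% of weight carries pleiotropy
        s = make_set(bx, np.full(k, 0.001), by, np.full(k, 0.05))
        assert weighted_median(s, seed=1).beta == pytest.approx(0.3, abs=0.02)

    def test_bootstrap_se_reproducible_and_errors(self):
        s = make_set([0.2, 0.3, 0.4], [0.01] * 3, [0.08, 0.11, 0.13], [0.05] * 3)
        a = weighted_median(s, seed=5)
        b = weighted_median(s, seed=5)
        assert a.se == b.se
        with pytest.raises(ValueError):
            weighted_median(s, n_boot=10, seed=0)
        with pytest.raises(DegenerateInstrumentError):
            weighted_median(
                make_set([0.2, 0.0, 0.4], [0.01] * 3, [0.1] * 3, [0.05] * 3), seed=0
            )


class TestEstimateAuto:
    def test_rule_table(self):
        one = make_set([0.5], [0.01], [0.25], [0.1])
        ests = estimate_auto(one)
        assert [e.method for e in ests] == ["wald"] and ests[0].primary

        two = make_set([0.5, 0.4], [0.01] * 2, [0.25, 0.2], [0.1] * 2)
        ests = estimate_auto(two)
        assert [e.method for e in ests] == ["ivw_random"]

        three = make_set([0.5, 0.4, 0.3], [0.01] * 3, [0.25, 0.2, 0.14], [0.1] * 3)
        ests = estimate_auto(three, seed=0)
        assert [e.method for e in ests] == [
            "ivw_random",
            "ivw_fixed",
            "egger",
            "weighted_median",
        ]
        assert primary_estimate(ests).method == "ivw_random"
        assert ests[0].q_pvalue is not None
        assert ests[2].egger_intercept_pvalue is not None


@pytest.mark.parametrize("c", [2.0, -0.5, 10.0])
def test_scale_equivariance(c):
    """Rescaling the exposure (betas and SEs by c) divides every causal
    estimate by c."""
    rng = np.random.default_rng(11)
    k = 6
    bx = rng.uniform(0.1, 0.4, k)
    sx = np.full(k, 0.01)
    by = rng.normal(0.3 * bx, 0.02)
    sy = rng.uniform(0.05, 0.1, k)
    s1 = make_set(bx, sx, by, sy)
    s2 = make_set(c * bx, np.abs(c) * sx, by, sy)
    assert ivw(s2, "fixed").beta == pytest.approx(ivw(s1, "fixed").beta / c)
    assert ivw(s2, "random").beta == pytest.approx(ivw(s1, "random").beta / c)
    assert egger(s2).beta == pytest.approx(egger(s1).beta / c)
    assert weighted_median(s2, seed=3).beta == pytest.approx(
        weighted_median(s1, seed=3).beta / c
    )
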