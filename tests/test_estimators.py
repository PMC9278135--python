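"""The six causal estimators: worked examples, oracles, and invariances."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrkit import (
    EstimationError,
    egger,
    harmonized_from_arrays,
    ivw,
    max_likelihood,
    raps,
    wald_ratios,
    weighted_median,
)
from mrkit.estimators import WaldRatios, weighted_median_point


def hset(beta_x, se_x, beta_y, se_y):
    return harmonized_from_arrays(beta_x, se_x, beta_y, se_y)


def ratios_from(ratio, se_ratio):
    ratio = np.asarray(ratio, float)
    return WaldRatios(
        snp_ids=np.array([f"rs{i}" for i in range(ratio.size)]),
        ratio=ratio,
        se_ratio=np.asarray(se_ratio, float),
    )


class TestWaldRatios:
    def test_direct_formula(self):
        h = hset([0.1], [0.01], [0.05], [0.02])
        r = wald_ratios(h)
        assert r.ratio[0] == pytest.approx(0.5)
        assert r.se_ratio[0] == pytest.approx(0.2)
        assert r.weight[0] == pytest.approx(25.0)

    def test_negative_exposure_effect(self):
        r = wald_ratios(hset([-0.1], [0.01], [0.05], [0.02]))
        assert r.ratio[0] == pytest.approx(-0.5)
        assert r.se_ratio[0] == pytest.approx(0.2)  # SE uses |beta_x|

    def test_zero_beta_x_raises_naming_the_snp(self):
        with pytest.raises(EstimationError, match="rs2"):
            wald_ratios(hset([0.1, 0.0], [0.01] * 2, [0.05] * 2, [0.02] * 2))

    def test_order_preserved(self, make_hset):
        h, _ = make_hset(0, k_snp=6)
        r = wald_ratios(h)
        assert list(r.snp_ids) == h.instruments["snp_id"].tolist()


class TestIVW:
    def test_single_ratio_identity(self):
        est = ivw(ratios_from([0.37], [0.11]), model="fixed")
        assert est.beta == pytest.approx(0.37)
        assert est.se == pytest.approx(0.11)

    def test_equal_weights_unweighted_mean(self):
        est = ivw(ratios_from([0.2, 0.4, 0.6], [0.1] * 3), model="fixed")
        assert est.beta == pytest.approx(0.4)

    def test_matches_wls_through_origin_oracle(self, rng):
        """IVW fixed == WLS of beta_y on beta_x through origin, weights se_y^-2."""
        for _ in range(20):
            k = rng.integers(2, 30)
            bx = rng.normal(0.05, 0.01, k)
            by = rng.normal(0.002, 0.01, k)
            sy = rng.uniform(0.005, 0.05, k)
            fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
            est = ivw(
                wald_ratios(hset(bx, np.full(k, 1e-6), by, sy)), model="fixed"
            )
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
            # fixed-effect SE: no residual-variance scaling
            se_oracle = float(fit.bse[0] / np.sqrt(fit.scale))
            assert est.se == pytest.approx(se_oracle, rel=1e-10)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(30):
            k = int(rng.integers(2, 15))
            r = ratios_from(rng.normal(0, 1, k), rng.uniform(0.05, 1, k))
            assert ivw(r, model="fixed").se <= ivw(r, model="random").se + 1e-15

    def test_auto_selects_fixed_under_homogeneity(self):
        est = ivw(ratios_from([0.1, 0.11, 0.09], [0.1] * 3), model="auto")
        assert est.method == "ivw_fixed"

    def test_auto_selects_random_under_heterogeneity(self):
        est = ivw(ratios_from([0.5, -0.5, 1.5, -1.5], [0.01] * 4), model="auto")
        assert est.method == "ivw_random"

    def test_or_scale_is_exp_of_beta_scale(self):
        est = ivw(ratios_from([0.2, 0.4], [0.1, 0.1]), model="fixed")
        assert est.or_point == pytest.approx(np.exp(est.beta))
        assert est.or_low == pytest.approx(np.exp(est.ci_low))
        assert est.or_high == pytest.approx(np.exp(est.ci_high))
        assert est.or_low < est.or_point < est.or_high

    def test_k1_random_rejected(self):
        with pytest.raises(EstimationError):
            ivw(ratios_from([0.1], [0.1]), model="random")


class TestEgger:
    def test_recovers_noise_free_line(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        by = 0.01 + 0.5 * bx
        res = egger(hset(bx, np.full(4, 0.01), by, np.full(4, 0.01)))
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.estimate.beta == pytest.approx(0.5, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        bx = rng.uniform(0.02, 0.1, 12)
        by = 0.005 + 0.3 * bx + rng.normal(0, 0.01, 12)
        sy = rng.uniform(0.005, 0.02, 12)
        res = egger(hset(bx, np.full(12, 1e-4), by, sy))
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=sy**-2.0).fit()
        assert res.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.estimate.beta == pytest.approx(fit.params[1], rel=1e-10)
        # overdispersion scale floored at 1: SE >= fixed-weights SE
        fixed_se = fit.bse / np.sqrt(fit.scale)
        assert res.intercept_se >= fixed_se[0] - 1e-15

    def test_orientation_invariance(self):
        bx = np.array([0.02, 0.05, 0.08, 0.11])
        by = 0.01 + 0.5 * bx
        base = egger(hset(bx, np.full(4, 0.01), by, np.full(4, 0.01)))
        bx2, by2 = bx.copy(), by.copy()
        bx2[1] *= -1
        by2[1] *= -1
        flipped = egger(hset(bx2, np.full(4, 0.01), by2, np.full(4, 0.01)))
        assert flipped.estimate.beta == pytest.approx(base.estimate.beta)
        assert flipped.intercept == pytest.approx(base.intercept)

    def test_collinear_design_rejected(self):
        with pytest.raises(EstimationError, match="zero variance|collinear"):
            egger(hset([0.05] * 4, [0.01] * 4, [0.02] * 4, [0.01] * 4))

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            egger(hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))


class TestWeightedMedian:
    def test_equal_weight_interpolation(self):
        # hand enumeration: s = (1/6, 3/6, 5/6); 0.5 hits the middle ratio
        assert weighted_median_point(
            np.array([0.2, 0.5, 0.9]), np.ones(3)
        ) == pytest.approx(0.5)

    def test_unequal_weights_hand_case(self):
        # weights 1,1,2 -> s = (0.125, 0.375, 0.75); interp(0.5) between r2,r3
        got = weighted_median_point(np.array([0.1, 0.2, 0.6]), np.array([1, 1, 2.0]))
        expect = 0.2 + (0.5 - 0.375) / (0.75 - 0.375) * 0.4
        assert got == pytest.approx(expect)

    def test_constant_ratios_return_constant(self):
        est = weighted_median(
            ratios_from([0.3] * 5, [1e-6] * 5), n_boot=100, seed=0
        )
        assert est.beta == pytest.approx(0.3)
        assert est.se < 1e-5

    def test_robust_to_minority_contamination(self, make_hset):
        """Mean-zero large offsets on 49% of instruments leave the median
        near truth while IVW is thrown far off in its own-SE units."""
        wm, iv = [], []
        for r in range(60):
            h, truth = make_hset(
                5000 + r, k_snp=51, beta_true=0.05, pleiotropy_mode="balanced",
                pleiotropy_sd=0.02, pleiotropy_frac=25 / 51,
            )
            ratios = wald_ratios(h)
            wm.append(weighted_median(ratios, n_boot=200, seed=r).beta)
            iv.append(ivw(ratios, model="fixed"))
        wm = np.array(wm)
        assert abs(wm.mean() - 0.05) < 2 * wm.std(ddof=1) / np.sqrt(len(wm))
        mean_abs_z = np.mean([abs(e.beta - 0.05) / e.se for e in iv])
        assert mean_abs_z > 2.0

    def test_seed_required_and_reproducible(self):
        r = ratios_from([0.1, 0.2, 0.3, 0.4], [0.05] * 4)
        with pytest.raises(EstimationError):
            weighted_median(r, n_boot=100, seed=None)
        a = weighted_median(r, n_boot=200, seed=11)
        b = weighted_median(r, n_boot=200, seed=11)
        assert a == b


class TestMaxLikelihood:
    def test_single_instrument_equals_wald_ratio(self):
        h = hset([0.1], [0.01], [0.05], [0.02])
        est = max_likelihood(h)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_sign_equivariance(self, make_hset):
        h, _ = make_hset(3, k_snp=10)
        base = max_likelihood(h)
        neg = h.instruments.copy()
        neg["beta_y"] *= -1
        h2 = hset(neg["beta_x"], neg["se_x"], neg["beta_y"], neg["se_y"])
        assert max_likelihood(h2).beta == pytest.approx(-base.beta, abs=1e-8)

    def test_noise_free_exposure_limit_matches_ivw(self, rng):
        bx = rng.uniform(0.03, 0.1, 10)
        by = 0.05 * bx + rng.normal(0, 0.005, 10)
        sy = np.full(10, 0.005)
        h = hset(bx, np.full(10, 1e-9), by, sy)
        ml = max_likelihood(h)
        iv = ivw(wald_ratios(h), model="fixed")
        assert ml.beta == pytest.approx(iv.beta, abs=1e-6)
        assert ml.se == pytest.approx(iv.se, rel=1e-4)


class TestRaps:
    def test_noise_free_exposure_reduces_to_ivw(self, rng):
        bx = rng.uniform(0.03, 0.1, 10)
        by = 0.05 * bx + rng.normal(0, 0.005, 10)
        sy = np.full(10, 0.005)
        h = hset(bx, np.full(10, 1e-9), by, sy)
        rp = raps(h, overdispersion=False, loss="plain")
        iv = ivw(wald_ratios(h), model="fixed")
        assert rp.beta == pytest.approx(iv.beta, abs=1e-6)
        assert rp.se == pytest.approx(iv.se, rel=1e-3)

    def test_unbiased_under_balanced_pleiotropy(self, make_hset):
        est = []
        for r in range(80):
            h, _ = make_hset(
                7000 + r, k_snp=30, beta_true=0.05, pleiotropy_mode="balanced",
                pleiotropy_sd=0.005,
            )
            est.append(raps(h, overdispersion=True).beta)
        est = np.array(est)
        assert abs(est.mean() - 0.05) < 2 * est.std(ddof=1) / np.sqrt(len(est))

    def test_overdispersion_zero_without_overdispersion(self, make_hset):
        taus = []
        for r in range(40):
            h, _ = make_hset(8000 + r, k_snp=50, beta_true=0.05)
            taus.append(raps(h, overdispersion=True).tau2)
        assert np.median(taus) == 0.0
        assert np.mean(taus) < 1e-5

    def test_huber_close_to_plain_on_clean_data(self, make_hset):
        h, _ = make_hset(42, k_snp=20, beta_true=0.05)
        plain = raps(h, loss="plain")
        hub = raps(h, loss="huber")
        assert hub.beta == pytest.approx(plain.beta, abs=3 * plain.se)


class TestScaleEquivariance:
    @pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
    def test_exposure_rescaling_divides_beta(self, make_hset, c):
        """Multiplying (beta_x, se_x) by c divides every estimate by c."""
        h, _ = make_hset(99, k_snp=12, beta_true=0.05)
        inst = h.instruments
        h2 = hset(inst["beta_x"] * c, inst["se_x"] * c,
                  inst["beta_y"], inst["se_y"])
        h1 = hset(inst["beta_x"], inst["se_x"], inst["beta_y"], inst["se_y"])
        for fn in (
            lambda g: ivw(wald_ratios(g), model="fixed").beta,
            lambda g: egger(g).estimate.beta,
            lambda g: weighted_median(wald_ratios(g), n_boot=100, seed=5).beta,
            lambda g: max_likelihood(g).beta,
            lambda g: raps(g).beta,
        ):
            assert fn(h2) == pytest.approx(fn(h1) / c, rel=1e-5)
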