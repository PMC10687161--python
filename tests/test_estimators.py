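import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from cismr.estimators import (
    EstimationError,
    ivw,
    mode_estimate,
    mr_egger,
    ratio_estimates,
    wald_ratio,
    weighted_median,
)
from conftest import make_pairs, random_pairs

THREE = make_pairs([0.2, 0.4, 0.3], [0.1, 0.18, 0.16], [0.05, 0.05, 0.05])


def ivw_oracle(pairs):
    """Weighted least squares through the origin, fit by statsmodels."""
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
    return float(fit.params[0])


def weighted_median_oracle(pairs):
    """Spec formula by explicit loop: interpolate at cumulative midpoint 0.5."""
    est = ratio_estimates(pairs)
    est = sorted(est, key=lambda e: e.ratio)
    total = sum(e.weight for e in est)
    s = []
    run = 0.0
    for e in est:
        w = e.weight / total
        s.append(run + w / 2.0)
        run += w
    if s[0] >= 0.5:
        return est[0].ratio
    for j in range(1, len(est)):
        if s[j] >= 0.5:
            frac = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return est[j - 1].ratio + frac * (est[j].ratio - est[j - 1].ratio)
    return est[-1].ratio


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (-1.0, 0.5, 0.1, -0.5, 0.1), (0.2, 0.1, 0.05, 0.5, 0.25)],
    )
    def test_closed_form(self, bx, by, sy, beta, se):
        res = wald_ratio(make_pairs([bx], [by], [sy])[0])
        assert res.beta == pytest.approx(beta)
        assert res.se == pytest.approx(se)
        assert res.n_snps == 1

    def test_zero_exposure_beta_is_degenerate(self):
        with pytest.raises(EstimationError, match="degenerate"):
            wald_ratio(make_pairs([0.0], [0.1], [0.05])[0])


class TestIvw:
    def test_worked_example(self):
        res = ivw(THREE)
        assert res.beta == pytest.approx(56.0 / 116.0, abs=1e-10)

    def test_duplicated_instrument_equals_wald(self):
        pairs = make_pairs([0.2] * 5, [0.1] * 5, [0.05] * 5)
        assert ivw(pairs).beta == pytest.approx(wald_ratio(pairs[0]).beta, abs=1e-12)

    def test_null_outcome_gives_zero(self):
        assert ivw(make_pairs([0.2, 0.3], [0.0, 0.0], [0.05, 0.05])).beta == 0.0

    def test_minimum_instruments(self):
        with pytest.raises(EstimationError):
            ivw(make_pairs([0.2], [0.1], [0.05]))

    def test_or_ci_convention(self):
        res = ivw(THREE)
        assert res.or_ == pytest.approx(np.exp(res.beta))
        assert res.ci_low == pytest.approx(np.exp(res.beta - 1.959964 * res.se))
        assert res.ci_low < res.or_ < res.ci_high

    def test_matches_wls_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            pairs = random_pairs(rng, int(rng.integers(2, 12)), het=0.02)
            assert ivw(pairs).beta == pytest.approx(ivw_oracle(pairs), abs=1e-10)


class TestMrEgger:
    def test_exact_line_through_origin(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.05] * 3)
        res = mr_egger(pairs)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.02 + 0.5 * bx, [0.05] * 4)
        res = mr_egger(pairs)
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.02, abs=1e-12)

    def test_directional_pleiotropy_recovered(self, rng):
        bx = rng.uniform(0.1, 0.5, 20)
        sy = np.full(20, 0.01)
        by = 0.03 + 0.4 * bx + rng.normal(0, 0.01, 20)
        res = mr_egger(make_pairs(bx, by, sy))
        assert abs(res.egger_intercept - 0.03) < 2 * res.egger_intercept_se

    def test_matches_wls_oracle(self, rng):
        for _ in range(200):
            pairs = random_pairs(rng, int(rng.integers(3, 15)), het=0.05)
            bx = np.abs([p.beta_exposure for p in pairs])
            by = [np.sign(p.beta_exposure) * p.beta_outcome for p in pairs]
            w = [1 / p.se_outcome**2 for p in pairs]
            fit = sm.WLS(by, sm.add_constant(bx), weights=w).fit()
            res = mr_egger(pairs)
            assert res.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_minimum_instruments(self):
        with pytest.raises(EstimationError):
            mr_egger(make_pairs([0.2, 0.3], [0.1, 0.15], [0.05, 0.05]))

    def test_collinear_exposures_rejected(self):
        with pytest.raises(EstimationError, match="collinear"):
            mr_egger(make_pairs([0.2, 0.2, -0.2], [0.1, 0.1, -0.1], [0.05] * 3))


class TestWeightedMedian:
    def test_hand_interpolation_example(self):
        res = weighted_median(THREE, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.4825, abs=2e-4)
        assert res.beta == pytest.approx(weighted_median_oracle(THREE), abs=1e-12)

    def test_equal_weights_hits_middle_ratio(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1, 0.2, 0.9], [0.05] * 3)
        res = weighted_median(pairs, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.2, abs=1e-12)

    def test_identical_ratios_and_small_bootstrap_se(self):
        pairs = make_pairs([0.2, 0.3, 0.4], [0.1, 0.15, 0.2], [1e-4] * 3,
                           sx=[1e-6] * 3)
        res = weighted_median(pairs, n_boot=200, seed=2)
        assert res.beta == pytest.approx(0.5, abs=1e-9)
        assert res.se < 0.01

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(1000):
            pairs = random_pairs(rng, int(rng.integers(3, 12)), het=0.05)
            got = weighted_median(pairs, n_boot=2, seed=3).beta
            assert got == pytest.approx(weighted_median_oracle(pairs), abs=1e-6)

    def test_bootstrap_seed_reproducible(self):
        a = weighted_median(THREE, n_boot=100, seed=42)
        b = weighted_median(THREE, n_boot=100, seed=42)
        assert a.se == b.se


class TestModeEstimators:
    def test_mode_ignores_outlier(self):
        pairs = make_pairs([1.0] * 4, [0.5, 0.5, 0.5, 5.0], [0.05] * 4)
        res = mode_estimate(pairs, weighted=False, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.5, abs=0.15)

    def test_identical_ratios_returned_exactly(self):
        pairs = make_pairs([0.2, 0.4, 0.8], [0.06, 0.12, 0.24], [0.05] * 3)
        res = mode_estimate(pairs, weighted=False, n_boot=50, seed=1)
        assert res.beta == pytest.approx(0.3, abs=1e-12)

    def test_dominant_weight_pulls_weighted_mode(self):
        # one ratio carries ~99% of the inverse-variance weight
        pairs = make_pairs([1.0, 0.05, 0.05], [0.8, 0.01, 0.02], [0.05] * 3)
        res = mode_estimate(pairs, weighted=True, n_boot=50, seed=1)
        ratios = np.array([0.8, 0.2, 0.4])
        h = 0.9 * min(np.std(ratios, ddof=1), (np.percentile(ratios, 75) - np.percentile(ratios, 25)) / 1.349) * 3 ** (-0.2)
        assert abs(res.beta - 0.8) <= h + 1e-9

    def test_simple_vs_weighted_differ_under_skewed_weights(self):
        pairs = make_pairs([1.0, 0.05, 0.06, 0.05], [0.8, 0.01, 0.012, 0.011], [0.05] * 4)
        simple = mode_estimate(pairs, weighted=False, n_boot=10, seed=1).beta
        weighted = mode_estimate(pairs, weighted=True, n_boot=10, seed=1).beta
        assert weighted > simple


class TestOrientationInvariance:
    def test_negating_all_pairs_leaves_estimates_unchanged(self, rng):
        pairs = random_pairs(rng, 8, het=0.05)
        flipped = make_pairs(
            [-p.beta_exposure for p in pairs],
            [-p.beta_outcome for p in pairs],
            [p.se_outcome for p in pairs],
            [p.se_exposure for p in pairs],
        )
        assert ivw(pairs).beta == pytest.approx(ivw(flipped).beta, abs=1e-12)
        assert mr_egger(pairs).beta == pytest.approx(mr_egger(flipped).beta, abs=1e-12)
        assert weighted_median(pairs, 10, 5).beta == pytest.approx(
            weighted_median(flipped, 10, 5).beta, abs=1e-12
        )
        for weighted in (False, True):
            assert mode_estimate(pairs, weighted, n_boot=10, seed=5).beta == pytest.approx(
                mode_estimate(flipped, weighted, n_boot=10, seed=5).beta, abs=1e-12
            )

    def test_duplicated_instrument_consistency_across_methods(self):
        pairs = make_pairs([0.25] * 5, [0.1] * 5, [0.04] * 5)
        wald = wald_ratio(pairs[0]).beta
        assert ivw(pairs).beta == pytest.approx(wald, abs=1e-12)
        assert weighted_median(pairs, 10, 1).beta == pytest.approx(wald, abs=1e-12)
        for weighted in (False, True):
            assert mode_estimate(pairs, weighted, n_boot=10, seed=1).beta == pytest.approx(
                wald, abs=1e-12
            )


@given(st.integers(0, 2**31 - 1))
def test_ivw_matches_oracle_property(seed):
    rng = np.random.default_rng(seed)
    pairs = random_pairs(rng, int(rng.integers(2, 10)), het=0.03)
    assert ivw(pairs).beta == pytest.approx(ivw_oracle(pairs), abs=1e-10)
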