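import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrchain import (
    EmptyInputError,
    HarmonizedPairs,
    InsufficientInstrumentsError,
    beta_to_or,
    egger,
    ivw,
    mode_estimate,
    wald_ratios,
    weighted_median,
)

from conftest import make_pairs


class TestWaldRatios:
    def test_arithmetic(self):
        pairs = make_pairs([0.1], [0.02], [0.005])
        df = wald_ratios(pairs)
        assert df.ratio.iloc[0] == pytest.approx(0.2)
        assert df.se_ratio.iloc[0] == pytest.approx(0.05)
        assert df.weight.iloc[0] == pytest.approx(400.0)

    def test_sign_carried(self):
        pairs = make_pairs([-0.1], [0.02], [0.005])
        assert wald_ratios(pairs).ratio.iloc[0] == pytest.approx(-0.2)

    def test_zero_exposure_beta_dropped(self):
        pairs = make_pairs([0.0, 0.1], [0.02, 0.02], [0.005, 0.005])
        df = wald_ratios(pairs)
        assert len(df) == 1

    def test_all_dropped_raises(self):
        pairs = make_pairs([0.0], [0.02], [0.005])
        with pytest.raises(EmptyInputError):
            wald_ratios(pairs)


class TestIVW:
    def test_single_pair_equals_wald_ratio(self):
        pairs = make_pairs([0.1], [0.02], [0.005])
        est = ivw(pairs)
        assert est.beta_hat == pytest.approx(0.2)
        assert est.se_hat == pytest.approx(0.05)

    def test_homogeneous_ratios_fixed_equals_random(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.005, 0.01, 0.02])
        fx = ivw(pairs, "fixed")
        rd = ivw(pairs, "random")
        assert fx.beta_hat == pytest.approx(0.2)
        assert fx.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert rd.se_hat == pytest.approx(fx.se_hat)

    def test_three_pair_closed_form_oracle(self, three_pairs):
        """Weighted mean with hand-computed weights 400, 400, 351.5625."""
        w = np.array([400.0, 400.0, (0.15 / 0.008) ** 2])
        r = np.array([0.2, 0.25, 0.2])
        expected_beta = (w * r).sum() / w.sum()
        expected_se = 1 / np.sqrt(w.sum())
        est = ivw(three_pairs, "fixed")
        assert est.beta_hat == pytest.approx(expected_beta, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.2174, abs=5e-4)
        assert est.se_hat == pytest.approx(expected_se, abs=1e-12)

    def test_auto_switches_to_random_under_heterogeneity(self):
        # two tight clusters far apart -> huge Q
        pairs = make_pairs(
            [0.1] * 3 + [0.1] * 3,
            [0.02] * 3 + [0.08] * 3,
            [0.002] * 6,
        )
        est = ivw(pairs, "auto")
        assert est.extras["Q_pval"] < 0.05
        assert est.extras["model_used"] == "random"
        assert est.se_hat > ivw(pairs, "fixed").se_hat

    def test_random_variance_floored_at_fixed(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.005, 0.01, 0.02])
        assert ivw(pairs, "random").se_hat >= ivw(pairs, "fixed").se_hat

    def test_empty_raises(self):
        pairs = make_pairs([0.0], [0.02], [0.005])
        with pytest.raises(EmptyInputError):
            ivw(pairs)


def _wls_normal_equations(x, y, w):
    """Independent weighted-least-squares solution via the 2x2 normal equations."""
    s_w = w.sum()
    s_x = (w * x).sum()
    s_y = (w * y).sum()
    s_xx = (w * x * x).sum()
    s_xy = (w * x * y).sum()
    det = s_w * s_xx - s_x**2
    intercept = (s_xx * s_y - s_x * s_xy) / det
    slope = (s_w * s_xy - s_x * s_y) / det
    return intercept, slope


class TestEgger:
    def test_exact_proportional_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.2 * bx, [0.01] * 4)
        est = egger(pairs)
        assert est.beta_hat == pytest.approx(0.2, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        pairs = make_pairs(bx, 0.01 + 0.2 * bx, [0.01] * 4)
        est = egger(pairs)
        assert est.beta_hat == pytest.approx(0.2, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(0.01, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.05, 0.3, 5)
        by = 0.02 + 0.25 * bx + rng.normal(0, 0.01, 5)
        se_out = rng.uniform(0.005, 0.02, 5)
        pairs = make_pairs(bx, by, se_out)
        est = egger(pairs)
        intercept, slope = _wls_normal_equations(bx, by, 1 / se_out**2)
        assert est.beta_hat == pytest.approx(slope, abs=1e-10)
        assert est.extras["egger_intercept"] == pytest.approx(intercept, abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping the allele frame of a variant (negating both betas)
        does not change the Egger fit."""
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 6)
        by = 0.01 + 0.2 * bx + rng.normal(0, 0.005, 6)
        se = np.full(6, 0.01)
        est1 = egger(make_pairs(bx, by, se))
        flip = np.array([1, -1, 1, -1, 1, -1])
        est2 = egger(make_pairs(bx * flip, by * flip, se))
        assert est1.beta_hat == pytest.approx(est2.beta_hat, abs=1e-12)
        assert est1.extras["egger_intercept"] == pytest.approx(
            est2.extras["egger_intercept"], abs=1e-12
        )

    def test_requires_three_pairs(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pairs([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]))


class TestWeightedMedian:
    def test_plain_median_with_equal_weights(self):
        pairs = make_pairs([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0])
        est = weighted_median(pairs, n_boot=10, seed=0)
        assert est.beta_hat == pytest.approx(2.0)

    def test_interpolation_oracle(self):
        # ratios {0.1, 0.2, 0.3} with weights {1, 1, 2}:
        # p = (0.125, 0.375, 0.75) -> interpolate at 0.5 -> 0.2333...
        pairs = make_pairs(
            [1.0, 1.0, 1.0],
            [0.1, 0.2, 0.3],
            [1.0, 1.0, 1.0 / np.sqrt(2)],
        )
        est = weighted_median(pairs, n_boot=10, seed=0)
        assert est.beta_hat == pytest.approx(0.2 + 0.1 * (0.5 - 0.375) / 0.375, abs=1e-12)
        assert est.beta_hat == pytest.approx(0.2333, abs=1e-4)

    def test_bootstrap_se_deterministic_under_seed(self, three_pairs):
        a = weighted_median(three_pairs, n_boot=200, seed=11)
        b = weighted_median(three_pairs, n_boot=200, seed=11)
        assert a.se_hat == b.se_hat


class TestModeEstimate:
    def test_point_mass(self):
        pairs = make_pairs([0.1, 0.2, 0.4], [0.02, 0.04, 0.08], [0.005, 0.01, 0.02])
        for weighted in (False, True):
            est = mode_estimate(pairs, weighted=weighted, n_boot=10, seed=0)
            assert est.beta_hat == pytest.approx(0.2, abs=1e-9)

    def test_mode_lands_in_dominant_cluster(self):
        pairs = make_pairs(
            [1.0] * 4, [0.2, 0.21, 0.19, 1.0], [0.05] * 4
        )
        for weighted in (False, True):
            est = mode_estimate(pairs, weighted=weighted, n_boot=10, seed=0)
            assert 0.19 - 0.02 <= est.beta_hat <= 0.21 + 0.02

    def test_agrees_with_dense_grid_search(self):
        """The 512-point grid mode matches an independent dense-grid
        maximization of the same kernel density."""
        rng = np.random.default_rng(5)
        r = np.concatenate([rng.normal(0.2, 0.01, 8), [1.0, 1.2]])
        pairs = make_pairs(np.ones(10), r, np.full(10, 0.05))
        est = mode_estimate(pairs, weighted=False, n_boot=10, seed=0, grid_size=512)
        # independent: brute-force density maximization on a 20x finer grid
        from mrchain.estimators import _default_bandwidth

        h = _default_bandwidth(r)
        fine = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512 * 20)
        dens = np.exp(-0.5 * ((fine[:, None] - r[None, :]) / h) ** 2).sum(axis=1)
        assert est.beta_hat == pytest.approx(fine[np.argmax(dens)], abs=3 * h / 100)

    def test_reproducible_under_seed(self, three_pairs):
        a = mode_estimate(three_pairs, n_boot=50, seed=4)
        b = mode_estimate(three_pairs, n_boot=50, seed=4)
        assert a.se_hat == b.se_hat


class TestBetaToOr:
    @pytest.mark.parametrize(
        "beta,expected_or",
        [(-0.425, 0.654), (-0.154, 0.857), (0.0, 1.0)],
    )
    def test_reported_or_values(self, beta, expected_or):
        pairs = make_pairs([1.0], [beta], [0.1])
        or_, lo, hi = beta_to_or(ivw(pairs))
        assert round(or_, 3) == pytest.approx(expected_or)
        assert lo < or_ < hi


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_sign_equivariance_all_estimators(seed):
    """Negating every outcome beta negates each estimator's beta_hat."""
    rng = np.random.default_rng(seed)
    L = 8
    bx = rng.uniform(0.05, 0.3, L)
    by = 0.2 * bx + rng.normal(0, 0.01, L)
    se = rng.uniform(0.005, 0.02, L)
    plus = make_pairs(bx, by, se)
    minus = make_pairs(bx, -by, se)
    assert ivw(plus).beta_hat == pytest.approx(-ivw(minus).beta_hat, abs=1e-12)
    assert egger(plus).beta_hat == pytest.approx(-egger(minus).beta_hat, abs=1e-12)
    wm_p = weighted_median(plus, n_boot=5, seed=1).beta_hat
    wm_m = weighted_median(minus, n_boot=5, seed=1).beta_hat
    assert wm_p == pytest.approx(-wm_m, abs=1e-12)
    for weighted in (False, True):
        mo_p = mode_estimate(plus, weighted=weighted, n_boot=5, seed=1).beta_hat
        mo_m = mode_estimate(minus, weighted=weighted, n_boot=5, seed=1).beta_hat
        assert mo_p == pytest.approx(-mo_m, abs=1e-9)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10**6), k=st.floats(0.5, 3.0))
def test_exposure_scaling_inverts_ivw_and_egger_slope(seed, k):
    """Scaling every exposure beta by k scales IVW and the Egger slope by 1/k."""
    rng = np.random.default_rng(seed)
    L = 8
    bx = rng.uniform(0.05, 0.3, L)
    by = 0.01 + 0.2 * bx + rng.normal(0, 0.01, L)
    se = rng.uniform(0.005, 0.02, L)
    base_ivw = ivw(make_pairs(bx, by, se)).beta_hat
    base_egg = egger(make_pairs(bx, by, se)).beta_hat
    scaled_ivw = ivw(make_pairs(k * bx, by, se)).beta_hat
    scaled_egg = egger(make_pairs(k * bx, by, se)).beta_hat
    assert scaled_ivw == pytest.approx(base_ivw / k, rel=1e-9)
    assert scaled_egg == pytest.approx(base_egg / k, rel=1e-9)


def _simulate_ratio_panel(rng, L, theta, n_invalid=0, pleio=0.0):
    """Summary coefficients for L instruments, n_invalid of them carrying
    directional pleiotropy `pleio` on the outcome."""
    bx = rng.uniform(0.05, 0.15, L)
    se_x = np.full(L, 1e-3)
    se_y = np.full(L, 0.01)
    alpha = np.zeros(L)
    alpha[:n_invalid] = pleio
    by = theta * bx + alpha + rng.normal(0, se_y)
    return HarmonizedPairs(bx, se_x, by, se_y)


def test_weighted_median_beats_ivw_with_forty_percent_invalid():
    """With 40% of instruments carrying directional pleiotropy and 60%
    valid, the weighted median's absolute bias is below IVW's."""
    rng = np.random.default_rng(2024)
    theta = 0.2
    L, n_invalid = 20, 8
    n_rep = 500
    ivw_est = np.empty(n_rep)
    wm_est = np.empty(n_rep)
    for i in range(n_rep):
        pairs = _simulate_ratio_panel(rng, L, theta, n_invalid, pleio=0.05)
        ivw_est[i] = ivw(pairs).beta_hat
        wm_est[i] = weighted_median(pairs, n_boot=2, seed=i).beta_hat
    assert abs(wm_est.mean() - theta) < abs(ivw_est.mean() - theta)


def test_egger_intercept_recovers_mean_pleiotropy_under_inside():
    """With pleiotropy independent of instrument strength (InSIDE), the
    Egger intercept estimates the mean pleiotropic effect."""
    rng = np.random.default_rng(77)
    mu_alpha = 0.05
    n_rep = 200
    intercepts = np.empty(n_rep)
    for i in range(n_rep):
        L = 30
        bx = rng.uniform(0.05, 0.3, L)
        alpha = rng.normal(mu_alpha, 0.02, L)
        se_y = np.full(L, 0.01)
        by = 0.2 * bx + alpha + rng.normal(0, se_y)
        intercepts[i] = egger(HarmonizedPairs(bx, np.full(L, 1e-3), by, se_y)).extras[
            "egger_intercept"
        ]
    mc_se = intercepts.std(ddof=1) / np.sqrt(n_rep)
    assert abs(intercepts.mean() - mu_alpha) < 2 * mc_se + 1e-4
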