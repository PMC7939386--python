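"""Censored-exponential run-length inference."""

import numpy as np
import pytest
from scipy import optimize

from motorcycle import (
    CensoredExponentialMLE,
    RunRecord,
    bootstrap_ci,
    censored_mle,
    gen_run_table,
    kaplan_meier_mean,
    log_likelihood,
    truncated_cdf_mean,
)


def brute_force_mle(y, w, t=None):
    """Independent oracle: numeric maximization of the log-likelihood.

    A bounded scalar search localizes the maximizer; a Brent root of the
    score (the analytic derivative of the log-likelihood, written out
    independently of the estimator) then polishes it to machine precision
    — function values alone cannot resolve a flat maximum to 1e-8.
    """
    runs = (y, w) if t is None else (y, w, t)
    coarse = optimize.minimize_scalar(
        lambda lam: -log_likelihood(lam, runs),
        bounds=(1e-9, 1e6), method="bounded",
    ).x
    tt = y if t is None else t
    score = lambda lam: np.sum(w) / lam - np.sum(w * y + (1 - w) * tt)
    lam = optimize.brentq(score, coarse / 4, coarse * 4, xtol=1e-15,
                          rtol=1e-15)
    return 1.0 / lam


class TestLogLikelihood:
    def test_single_observation_maximized_at_its_rate(self):
        ll = lambda lam: log_likelihood(lam, ([1.0], [1]))
        assert ll(1.0) > ll(0.5)
        assert ll(1.0) > ll(2.0)

    def test_hand_example_score_zero_at_one_third(self, hand_table):
        y, w = hand_table
        # dL/dlam = sum w (1/lam - y) - sum (1-w) t = 2/lam - 6
        eps = 1e-6
        deriv = (log_likelihood(1 / 3 + eps, (y, w))
                 - log_likelihood(1 / 3 - eps, (y, w))) / (2 * eps)
        assert deriv == pytest.approx(0.0, abs=1e-4)

    def test_adding_censored_record_lowers_rate(self):
        base_lam = 1.0 / censored_mle(([1.0, 2.0], [1, 1])).theta_hat
        more_lam = 1.0 / censored_mle(([1.0, 2.0, 5.0], [1, 1, 0])).theta_hat
        assert more_lam < base_lam

    def test_invalid_lambda(self, hand_table):
        with pytest.raises(ValueError):
            log_likelihood(0.0, hand_table)


class TestCensoredMLE:
    def test_hand_example(self, hand_table):
        est = censored_mle(hand_table)
        assert est.theta_hat == pytest.approx(3.0)
        assert est.se == pytest.approx(2.53, abs=0.005)
        assert est.n_censored == 1

    def test_no_censoring_equals_naive_mean(self):
        rng = np.random.default_rng(0)
        y = rng.exponential(2.0, 100)
        est = censored_mle((y, np.ones(100, int)))
        assert est.theta_hat == pytest.approx(est.naive_mean, rel=1e-15)

    def test_half_censored_doubles_naive_mean(self):
        rng = np.random.default_rng(1)
        y = rng.exponential(5.6, 200)
        w = np.array([1, 0] * 100)
        est = censored_mle((y, w))
        assert est.theta_hat == pytest.approx(2.0 * est.naive_mean, rel=1e-15)

    def test_corrected_never_below_naive(self):
        rng = np.random.default_rng(2)
        for s in range(5):
            table = gen_run_table(3.0, 100, seed=s)
            est = censored_mle(table)
            assert est.theta_hat >= est.naive_mean
            if est.n_censored > 0:
                assert est.theta_hat > est.naive_mean

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_likelihood_maximum(self, seed):
        """Closed form agrees with numeric maximization to 1e-8."""
        table = gen_run_table(5.6, 200, seed=seed)
        y = table["run_length_um"].to_numpy()
        w = 1 - table["censored"].to_numpy()
        est = censored_mle(table)
        assert est.theta_hat == pytest.approx(brute_force_mle(y, w), rel=1e-8)

    def test_order_invariance(self):
        table = gen_run_table(5.6, 150, seed=9)
        shuffled = table.sample(frac=1.0, random_state=4)
        assert censored_mle(table).theta_hat == pytest.approx(
            censored_mle(shuffled).theta_hat, rel=1e-14
        )

    def test_all_censored_is_undefined(self):
        with pytest.raises(ValueError, match="censored"):
            censored_mle(([1.0, 2.0], [0, 0]))

    def test_accepts_run_records(self):
        records = [RunRecord(1.0, 1), RunRecord(2.0, 1), RunRecord(3.0, 0, 3.0)]
        assert censored_mle(records).theta_hat == pytest.approx(3.0)

    def test_run_record_invariants(self):
        with pytest.raises(ValueError):
            RunRecord(2.0, 0, 1.0)  # y > t
        with pytest.raises(ValueError):
            RunRecord(1.0, 0, 3.0)  # censored but y != t

    def test_sklearn_estimator_interface(self, hand_table):
        y, w = hand_table
        est = CensoredExponentialMLE().fit(y, w)
        assert est.theta_ == pytest.approx(3.0)
        assert est.get_params() == {"use_distances": True,
                                    "min_run_length": None}
        lo, hi = est.confidence_interval()
        assert lo < 3.0 < hi

    def test_detection_cutoff_left_truncation(self):
        rng = np.random.default_rng(3)
        y = rng.exponential(5.6, 4000)
        w = np.ones(4000, int)
        est = censored_mle((y, w), min_run_length=0.4)
        # memorylessness: excess over the cutoff is exponential with the
        # same mean
        assert est.theta_hat == pytest.approx(5.6, rel=0.05)

    def test_estimator_consistency(self):
        """Mean of theta_hat over replicates within 2% of truth."""
        estimates = [
            censored_mle(gen_run_table(5.6, 534, seed=s)).theta_hat
            for s in range(500)
        ]
        assert np.mean(estimates) == pytest.approx(5.6, rel=0.02)


class TestKaplanMeier:
    def test_no_censoring_equals_sample_mean(self):
        y = np.array([1.0, 2.0, 4.0, 5.0])
        assert kaplan_meier_mean((y, np.ones(4, int))) == pytest.approx(
            y.mean()
        )

    def test_hand_product_limit_value(self, hand_table):
        # survival 1 on [0,1), 2/3 on [1,2), 1/3 on [2,3): area = 2.0
        assert kaplan_meier_mean(hand_table) == pytest.approx(2.0)

    def test_close_to_mle_at_moderate_censoring(self):
        table = gen_run_table(5.6, 2000, seed=21)
        assert table["censored"].mean() < 0.45
        km = kaplan_meier_mean(table)
        mle = censored_mle(table).theta_hat
        assert abs(km - mle) / mle < 0.10

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier_mean(([1.0, 1.0], [0, 0]))


class TestBootstrap:
    def test_degenerate_data_degenerate_interval(self):
        y = np.full(20, 2.5)
        lo, hi = bootstrap_ci((y, np.ones(20, int)), n_boot=200, seed=0)
        assert lo == hi == pytest.approx(2.5)

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 400):
            table = gen_run_table(5.6, n, seed=77)
            lo, hi = bootstrap_ci(table, n_boot=1000, seed=1)
            widths.append(hi - lo)
        ratio = widths[0] / widths[1]
        assert ratio == pytest.approx(2.0, rel=0.4)  # ~ sqrt(400/100)

    def test_agrees_with_fisher_information_se(self):
        """Bootstrap SE within 25% of the asymptotic SE (n=534, ~36% cens)."""
        table = gen_run_table(5.6, 534, seed=101)
        est = censored_mle(table)
        rng = np.random.default_rng(5)
        y = table["run_length_um"].to_numpy()
        w = 1 - table["censored"].to_numpy()
        thetas = []
        for _ in range(600):
            idx = rng.integers(0, len(y), len(y))
            if w[idx].sum() == 0:
                continue
            thetas.append(y[idx].sum() / w[idx].sum())
        boot_se = np.std(thetas)
        assert boot_se == pytest.approx(est.se, rel=0.25)

    def test_minimum_replicates_enforced(self, hand_table):
        with pytest.raises(ValueError):
            bootstrap_ci(hand_table, n_boot=10)


class TestTruncatedCdfFit:
    def test_cutoff_zero_matches_sample_mean(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(3.6, 2000)
        assert truncated_cdf_mean(x, 0.0) == pytest.approx(x.mean(), rel=0.05)

    def test_recovers_mean_above_cutoff(self):
        """Memorylessness: the fit above 0.4 um still estimates theta."""
        rng = np.random.default_rng(7)
        x = rng.exponential(3.6, 534)
        assert truncated_cdf_mean(x, 0.4) == pytest.approx(3.6, rel=0.15)

    def test_shift_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(2.0, 500)
        base = truncated_cdf_mean(x, 0.3)
        shifted = truncated_cdf_mean(x + 1.0, 1.3)
        assert shifted == pytest.approx(base, rel=1e-6)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            truncated_cdf_mean([1.0] * 5, 0.0)
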