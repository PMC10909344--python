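"""Cormack-Jolly-Seber likelihood and fitting.

The likelihood implementation is checked against an independent
brute-force oracle that enumerates every post-first-capture fate
(survival horizon x detection pattern) of each animal.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from capturebias import (
    CaptureHistory,
    cjs_negative_log_likelihood,
    collapse_histories,
    fit_cjs,
)


def make_history(det, infected, bias=1.0):
    det = np.asarray(det, dtype=np.int8)
    n = det.shape[0]
    cov = pd.DataFrame(
        {
            "id": np.arange(n),
            "geno": np.zeros(n, dtype=np.int8),
            "infected": np.asarray(infected, dtype=bool),
            "generation": "parent",
        }
    )
    return CaptureHistory(individuals=cov, detections=det, bias_value=bias)


def oracle_history_prob(h, phi, p):
    """Exhaustive enumeration of one animal's fate after first capture.

    Sums over every survival horizon a (alive through bout a, gone
    after), multiplying detection/non-detection probabilities while
    alive.  Independent of the chi-recursion implementation.
    """
    h = list(h)
    T = len(h)
    f = h.index(1)
    last = max(t for t in range(T) if h[t])
    total = 0.0
    for a in range(last, T):
        surv = phi ** (a - f) * ((1 - phi) if a < T - 1 else 1.0)
        det = 1.0
        for t in range(f + 1, a + 1):
            det *= p if h[t] else (1 - p)
        total += surv * det
    return total


class TestCollapse:
    def test_identical_histories_form_one_class(self):
        det = [[1, 0, 1, 0, 1]] * 3
        stats = collapse_histories(make_history(det, [False] * 3))
        patterns, counts = stats.groups["uninfected"]
        assert len(patterns) == 1 and counts[0] == 3

    def test_never_detected_are_excluded(self):
        det = [[0, 0, 0], [1, 0, 0]]
        stats = collapse_histories(make_history(det, [False, False]))
        assert stats.n_histories == 1

    def test_class_counts_conserve_detected_individuals(self, rng):
        det = (rng.random((40, 4)) < 0.4).astype(np.int8)
        stats = collapse_histories(make_history(det, rng.random(40) < 0.5))
        assert stats.n_histories == int(det.any(axis=1).sum())

    def test_single_bout_rejected(self):
        with pytest.raises(ValueError):
            collapse_histories(make_history([[1]], [False]))


class TestLikelihood:
    def test_two_bout_closed_forms(self):
        # phi = p = 0.5: seen-again probability phi*p = 0.25,
        # never-seen-again chi = (1-phi) + phi(1-p) = 0.75
        stats_11 = collapse_histories(make_history([[1, 1]], [False]))
        stats_10 = collapse_histories(make_history([[1, 0]], [False]))
        params = np.zeros(3)
        assert cjs_negative_log_likelihood(params, stats_11) == pytest.approx(-np.log(0.25), abs=1e-12)
        assert cjs_negative_log_likelihood(params, stats_10) == pytest.approx(-np.log(0.75), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Likelihood equals the brute-force fate enumeration to 1e-10."""
        r = np.random.default_rng(seed)
        T = 4
        det = np.zeros((6, T), dtype=np.int8)
        while not (det.sum(axis=1) > 0).all():
            det = (r.random((6, T)) < 0.5).astype(np.int8)
        infected = r.random(6) < 0.5
        stats = collapse_histories(make_history(det, infected))
        params = r.normal(size=3)
        phi = expit(params[0])
        p_by_group = {True: expit(params[1]), False: expit(params[2])}
        expected = -sum(
            np.log(oracle_history_prob(det[i], phi, p_by_group[bool(infected[i])]))
            for i in range(6)
        )
        ours = cjs_negative_log_likelihood(params, stats)
        assert ours == pytest.approx(expected, abs=1e-10)


def simulate_histories(n, T, phi, p_inf, p_unf, prevalence, rng):
    """Generate detection data straight from the CJS process."""
    infected = rng.random(n) < prevalence
    p = np.where(infected, p_inf, p_unf)
    alive = np.ones(n, dtype=bool)
    det = np.zeros((n, T), dtype=np.int8)
    for t in range(T):
        det[:, t] = alive & (rng.random(n) < p)
        if t < T - 1:
            alive &= rng.random(n) < phi
    return make_history(det, infected)


class TestFit:
    def test_census_detection_drives_p_to_boundary(self):
        det = np.ones((50, 5), dtype=np.int8)
        fit = fit_cjs(make_history(det, [True, False] * 25))
        assert fit.p_infected > 0.99 and fit.p_uninfected > 0.99
        assert fit.phi_hat > 0.99

    def test_recovers_group_detection_probabilities(self, rng):
        h = simulate_histories(5000, 5, 1.0, 0.05, 0.10, 0.5, rng)
        fit = fit_cjs(h)
        assert fit.converged
        assert fit.p_infected == pytest.approx(0.05, abs=0.015)
        assert fit.p_uninfected == pytest.approx(0.10, abs=0.015)
        assert fit.delta_p == pytest.approx(fit.p_infected - fit.p_uninfected, abs=1e-12)
        assert fit.log_likelihood < 0

    def test_equal_rates_give_small_delta_p(self, rng):
        h = simulate_histories(5000, 5, 1.0, 0.2, 0.2, 0.5, rng)
        fit = fit_cjs(h)
        # binomial SE of a detection probability at n*T trials per group
        se = np.sqrt(0.2 * 0.8 / (2500 * 5))
        assert abs(fit.delta_p) < 4 * np.sqrt(2) * se

    def test_no_recaptures_flagged_non_estimable(self):
        det = np.eye(4, 5, dtype=np.int8)  # four animals, one detection each
        fit = fit_cjs(make_history(det, [True, False, True, False]))
        assert not fit.converged
        assert np.isnan(fit.delta_p)

    def test_final_bout_first_captures_carry_no_information(self):
        det = np.array([[1, 1, 0], [0, 0, 1]], dtype=np.int8)
        stats = collapse_histories(make_history(det, [False, False]))
        assert stats.n_histories == 2
        assert stats.n_histories_used == 1
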