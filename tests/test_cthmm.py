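"""Forward-backward correctness, transition-matrix algebra, and HMM fitting."""

import math

import numpy as np
import pytest

from nephrohmm import cthmm, synthetic
from nephrohmm.cthmm import (
    FitConfig,
    HMMParams,
    HMMPosteriors,
    Trajectory,
    classify_states,
    departure_probabilities,
    emission_logdensity,
    filtered_state_probabilities,
    fit_hmm,
    posterior_states,
    sequence_loglik,
    transition_matrix,
)
from nephrohmm.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)
from oracles import brute_force_posteriors, expm_transition, random_params, random_trajectory

PARAMS = HMMParams(
    q_HU=0.004, q_UH=0.0005, mu_H=123.8, sigma_H=10.7,
    delta_preg=15.8, mu_U=85.0, sigma_U=25.0, pi_U=0.1,
)


def _traj(times, egfr, pregnant=None, **kw):
    pregnant = pregnant if pregnant is not None else [False] * len(times)
    return Trajectory("p", np.asarray(times, float), np.asarray(egfr, float),
                      np.asarray(pregnant, bool), **kw)


# ---------------------------------------------------------------------------
# transition matrix
# ---------------------------------------------------------------------------


class TestTransitionMatrix:
    def test_zero_rates_identity(self):
        assert np.allclose(transition_matrix(0.0, 0.0, 12.0), np.eye(2))

    def test_closed_form_values(self):
        P = transition_matrix(0.2, 0.1, 1.0)
        expected = np.array([[0.82721, 0.17279], [0.08639, 0.91361]])
        assert np.allclose(P, expected, atol=1e-5)

    def test_matches_general_matrix_exponential(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, dt = rng.uniform(0, 0.5), rng.uniform(0, 0.5), rng.uniform(0, 50)
            assert np.allclose(transition_matrix(a, b, dt), expm_transition(a, b, dt), atol=1e-12)

    def test_long_run_symmetric_stationary(self):
        P = transition_matrix(0.5, 0.5, 1e4)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_rows_stochastic_and_chapman_kolmogorov(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.uniform(0, 1, 2)
            dt1, dt2 = rng.uniform(0, 30, 2)
            P1, P2 = transition_matrix(a, b, dt1), transition_matrix(a, b, dt2)
            assert np.all(P1 >= 0) and np.all(P1 <= 1)
            assert np.allclose(P1.sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(P1 @ P2, transition_matrix(a, b, dt1 + dt2), atol=1e-12)

    @pytest.mark.parametrize("a,b,dt", [(-0.1, 0.1, 1), (0.1, -0.1, 1), (0.1, 0.1, -1)])
    def test_invalid_inputs(self, a, b, dt):
        with pytest.raises(InvalidInputError):
            transition_matrix(a, b, dt)


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


class TestEmission:
    def test_mode_value(self):
        got = emission_logdensity(PARAMS.mu_H, "H", PARAMS, pregnant=False)
        assert got == pytest.approx(math.log(1.0 / (PARAMS.sigma_H * math.sqrt(2 * math.pi))))

    def test_pregnancy_shift_symmetry(self):
        at_mode = emission_logdensity(PARAMS.mu_H, "H", PARAMS, pregnant=False)
        shifted = emission_logdensity(PARAMS.mu_H + PARAMS.delta_preg, "H", PARAMS, pregnant=True)
        assert shifted == pytest.approx(at_mode)

    def test_unhealthy_value(self):
        # Normal(85, 25) log-density at 100 (z = 0.6)
        assert emission_logdensity(100.0, "U", PARAMS) == pytest.approx(-4.317, abs=1e-3)

    def test_unhealthy_ignores_pregnancy(self):
        assert emission_logdensity(90.0, "U", PARAMS, True) == emission_logdensity(
            90.0, "U", PARAMS, False
        )


# ---------------------------------------------------------------------------
# likelihood and posteriors
# ---------------------------------------------------------------------------


class TestLikelihood:
    def test_single_visit_degenerate_prior(self):
        p = HMMParams(0.01, 0.01, 123.8, 10.7, 0.0, 85.0, 25.0, pi_U=0.0)
        tr = _traj([0.0], [123.8])
        assert sequence_loglik(tr, p) == pytest.approx(
            math.log(1.0 / (10.7 * math.sqrt(2 * math.pi))), abs=1e-12
        )

    def test_identical_emissions_independent_of_rates(self):
        # when both states emit the same distribution the latent process is invisible
        p1 = HMMParams(0.3, 0.2, 100.0, 15.0, 0.0, 100.0 - 1e-12, 15.0, pi_U=0.4)
        p2 = HMMParams(0.01, 0.05, 100.0, 15.0, 0.0, 100.0 - 1e-12, 15.0, pi_U=0.4)
        tr = _traj([0, 6, 12, 20], [90, 105, 112, 95])
        from scipy.stats import norm

        direct = norm.logpdf(tr.egfr, 100.0, 15.0).sum()
        assert sequence_loglik(tr, p1) == pytest.approx(direct, abs=1e-9)
        assert sequence_loglik(tr, p2) == pytest.approx(direct, abs=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(100)
        for _ in range(25):
            tr, p = random_trajectory(rng), random_params(rng)
            ll, _, _ = brute_force_posteriors(tr, p)
            assert sequence_loglik(tr, p) == pytest.approx(ll, abs=1e-10)

    def test_time_origin_invariance(self):
        tr = _traj([3, 9, 21], [120, 60, 55])
        shifted = _traj([103, 109, 121], [120, 60, 55])
        assert sequence_loglik(tr, PARAMS) == pytest.approx(
            sequence_loglik(shifted, PARAMS), abs=1e-12
        )

    def test_no_underflow_long_sequence(self):
        rng = np.random.default_rng(0)
        T = 10_000
        tr = _traj(np.arange(T, dtype=float), rng.normal(100, 20, T))
        assert np.isfinite(sequence_loglik(tr, PARAMS))


class TestPosteriors:
    def test_unreachable_unhealthy(self):
        p = HMMParams(0.0, 0.1, 123.8, 10.7, 0.0, 85.0, 25.0, pi_U=0.0)
        post = posterior_states(_traj([0, 6, 12], [120, 90, 100]), p)
        assert np.allclose(post.gamma, 0.0)
        assert np.allclose(post.xi_HU, 0.0)

    def test_symmetric_identical_emissions(self):
        p = HMMParams(0.0, 0.0, 100.0, 15.0, 0.0, 100.0 - 1e-12, 15.0, pi_U=0.5)
        post = posterior_states(_traj([0, 6], [95, 105]), p)
        assert np.allclose(post.gamma, 0.5, atol=1e-9)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(200)
        for _ in range(25):
            tr, p = random_trajectory(rng), random_params(rng)
            _, gamma, xi = brute_force_posteriors(tr, p)
            post = posterior_states(tr, p)
            assert np.allclose(post.gamma, gamma, atol=1e-10)
            assert np.allclose(post.xi, xi, atol=1e-10)

    def test_single_visit_empty_xi(self):
        post = departure_probabilities(_traj([0.0], [120.0]), PARAMS)
        assert post.xi_HU.size == 0

    def test_normalisation_and_marginalisation(self):
        rng = np.random.default_rng(300)
        for _ in range(40):
            tr, p = random_trajectory(rng), random_params(rng)
            post = posterior_states(tr, p)
            assert np.all((post.gamma >= 0) & (post.gamma <= 1))
            for t in range(len(tr) - 1):
                assert post.xi[t].sum() == pytest.approx(1.0, abs=1e-12)
                # joint marginalises to the adjacent smoothed gammas
                assert post.xi[t].sum(axis=1)[1] == pytest.approx(post.gamma[t], abs=1e-9)
                assert post.xi[t].sum(axis=0)[1] == pytest.approx(post.gamma[t + 1], abs=1e-9)

    def test_smoothing_discounts_isolated_dip(self):
        # a single low value flanked by clearly healthy ones: smoothed posterior
        # at the dip stays moderate, and later visits pull it down
        tr = _traj([0, 6, 12, 18, 24], [125, 120, 95, 124, 122])
        post = posterior_states(tr, PARAMS)
        filt = filtered_state_probabilities(tr, PARAMS)
        assert post.gamma[2] < filt[2]  # future healthy data reduce the dip's posterior


class TestClassification:
    def _post(self, gamma, xi_hu):
        gamma = np.asarray(gamma, float)
        xi_hu = np.asarray(xi_hu, float)
        return HMMPosteriors("p", gamma, xi_hu, np.zeros((len(xi_hu), 2, 2)), 0.0)

    def test_label_threshold(self):
        cls = classify_states(self._post([0.4, 0.6], [0.2]))
        assert list(cls.labels) == ["healthy", "unhealthy"]

    def test_exact_half_is_healthy(self):
        # strict ">" at the 50% threshold
        cls = classify_states(self._post([0.5, 0.5 + 1e-12], [0.5]))
        assert list(cls.labels) == ["healthy", "unhealthy"]
        assert not cls.probable_departure[0]

    def test_departure_flags(self):
        cls = classify_states(self._post([0.1, 0.2, 0.9], [0.2, 0.8]))
        assert list(cls.probable_departure) == [False, True]

    def test_reversion_flags(self):
        cls = classify_states(self._post([0.9, 0.2, 0.9, 0.1], [0.1, 0.1, 0.1]))
        assert list(cls.reverted) == [False, True, False, True]

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, thr):
        with pytest.raises(InvalidInputError):
            classify_states(self._post([0.5], []), threshold=thr)


def test_smoothing_beats_filtering_on_simulated_data():
    cfg = synthetic.SyntheticConfig(seed=777, n_cohort1=150, n_cohort2=0,
                                    mu_U=60.0, sigma_U=12.0)
    sim = synthetic.simulate_cohort(cfg)
    p = HMMParams(cfg.q_HU, cfg.q_UH, cfg.mu_H, cfg.sigma_H, cfg.delta_preg,
                  cfg.mu_U, cfg.sigma_U, pi_U=0.14)
    truth = sim.truth.states
    truth = truth[truth.attended]
    acc_s = acc_f = n = 0
    for tr in cthmm.trajectories_from_table(sim.visits):
        g = truth[truth.participant_id == tr.participant_id].sort_values("visit")
        true_states = g["true_state"].to_numpy()
        smoothed = posterior_states(tr, p).gamma > 0.5
        filtered = filtered_state_probabilities(tr, p) > 0.5
        acc_s += np.sum(smoothed == (true_states == 1))
        acc_f += np.sum(filtered == (true_states == 1))
        n += len(tr)
    assert acc_s >= acc_f
    assert acc_s / n > 0.95  # well-separated emissions: near-perfect recovery


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFit:
    def test_insufficient_data(self):
        trajs = [_traj([0.0], [120.0]) for _ in range(50)]
        with pytest.raises(InsufficientDataError):
            fit_hmm(trajs, FitConfig(seed=1))

    def test_degenerate_data(self):
        trajs = [
            _traj(np.arange(5.0) * 6, np.full(5, 110.0)) for _ in range(25)
        ]
        with pytest.raises(DegenerateDataError):
            fit_hmm(trajs, FitConfig(seed=1))

    def test_holdout_visits_excluded_from_likelihood(self, small_cohort):
        trajs = cthmm.trajectories_from_table(small_cohort.visits)
        full = fit_hmm(trajs, FitConfig(seed=2, n_starts=1, holdout_visits={}))
        held = fit_hmm(trajs, FitConfig(seed=2, n_starts=1, holdout_visits={1: (9, 10)}))
        assert held.diagnostics.n_observations < full.diagnostics.n_observations

    def test_refit_self_consistency(self, small_fit):
        trajs, fit = small_fit
        refit = fit_hmm(trajs, FitConfig(seed=3, n_starts=1, init_params=fit.params))
        assert refit.diagnostics.loglik == pytest.approx(fit.diagnostics.loglik, abs=1e-6)

    def test_rate_recovery_null_exposures(self):
        # clean marginal-intensity recovery requires exposure effects at 1
        cfg = synthetic.SyntheticConfig(seed=12, n_cohort1=600, n_cohort2=0)
        for e in cfg.exposures.values():
            e.effect = 1.0
        sim = synthetic.simulate_cohort(cfg)
        fit = fit_hmm(cthmm.trajectories_from_table(sim.visits), FitConfig(seed=12))
        assert fit.params.q_HU == pytest.approx(cfg.q_HU, rel=0.30)
        assert fit.params.mu_H == pytest.approx(cfg.mu_H, abs=1.0)
        assert fit.params.sigma_H == pytest.approx(cfg.sigma_H, abs=1.0)

    def test_likelihood_invariant_to_participant_order(self, small_fit):
        trajs, fit = small_fit
        rev = fit_hmm(list(reversed(trajs)), FitConfig(seed=11, n_starts=3))
        assert rev.diagnostics.loglik == pytest.approx(fit.diagnostics.loglik, rel=1e-9)
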