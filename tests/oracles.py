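"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's forward-backward code path:
transition matrices come from a general matrix exponential, emission
densities from scipy.stats.norm, and posteriors from explicit enumeration
of all 2^T latent state paths.
"""

from __future__ import annotations

import numpy as np
from itertools import product

from scipy.linalg import expm
from scipy.stats import norm

from nephrohmm.cthmm import Trajectory, HMMParams


def expm_transition(q_HU: float, q_UH: float, dt: float) -> np.ndarray:
    Q = np.array([[-q_HU, q_HU], [q_UH, -q_UH]])
    return expm(Q * dt)


def brute_force_posteriors(traj: Trajectory, params: HMMParams):
    """(loglik, gamma, xi) by summation over every latent state path."""
    T = len(traj)
    mu_h = params.mu_H + params.delta_preg * traj.pregnant.astype(float)
    f = np.column_stack(
        [
            norm.pdf(traj.egfr, mu_h, params.sigma_H),
            norm.pdf(traj.egfr, params.mu_U, params.sigma_U),
        ]
    )
    pi = np.array([1.0 - params.pi_U, params.pi_U])
    mats = [expm_transition(params.q_HU, params.q_UH, dt) for dt in np.diff(traj.times)]

    total = 0.0
    gamma = np.zeros(T)
    xi = np.zeros((T - 1, 2, 2))
    for path in product((0, 1), repeat=T):
        p = pi[path[0]] * f[0, path[0]]
        for t in range(1, T):
            p *= mats[t - 1][path[t - 1], path[t]] * f[t, path[t]]
        total += p
        for t in range(T):
            if path[t] == 1:
                gamma[t] += p
        for t in range(1, T):
            xi[t - 1, path[t - 1], path[t]] += p
    return np.log(total), gamma / total, xi / total


def random_trajectory(rng: np.random.Generator, t_max: int = 6) -> Trajectory:
    T = int(rng.integers(1, t_max + 1))
    times = np.cumsum(rng.uniform(1.0, 15.0, T))
    return Trajectory(
        participant_id="r",
        times=times,
        egfr=rng.uniform(40.0, 150.0, T),
        pregnant=rng.random(T) < 0.2,
    )


def random_params(rng: np.random.Generator) -> HMMParams:
    mu_H = rng.uniform(100.0, 135.0)
    return HMMParams(
        q_HU=rng.uniform(0.001, 0.3),
        q_UH=rng.uniform(0.0, 0.2),
        mu_H=mu_H,
        sigma_H=rng.uniform(5.0, 20.0),
        delta_preg=rng.uniform(-5.0, 20.0),
        mu_U=mu_H - rng.uniform(15.0, 60.0),
        sigma_U=rng.uniform(10.0, 30.0),
        pi_U=rng.uniform(0.05, 0.9),
    )


def cox_partial_loglik(beta: float, times, events, x):
    """Breslow/exact partial log-likelihood for untied event times, single covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in times[events]:
        at_risk = times >= t
        i = np.flatnonzero(events & (times == t))
        assert len(i) == 1, "oracle assumes untied event times"
        ll += beta * x[i[0]] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll
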