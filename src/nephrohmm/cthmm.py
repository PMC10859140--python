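"""Continuous-time two-state hidden Markov model for eGFR trajectories.

The latent process is a two-state Markov jump process in continuous time:
state H ("healthy") and state U ("unhealthy"), with transition intensities
q_HU (H->U, per month) and q_UH (U->H, per month).  Observations are eGFR
values at irregular visit times; between visits the latent state evolves
according to the intensity matrix, so the transition matrix over a gap of
dt months is the matrix exponential of Q*dt, available in closed form for
two states.

Emissions are Gaussian: the healthy state emits N(mu_H + delta_preg*[pregnant],
sigma_H^2) — pregnancy raises filtration, so the healthy mean is shifted
upward for pregnant visits — and the unhealthy state emits a fixed (or
optionally estimated) N(mu_U, sigma_U^2) with mu_U < mu_H.

The model yields, per participant, smoothed posterior state probabilities
gamma_t = P(S_t = U | y_1..T) and per-interval joint "departure"
probabilities xi_t(H,U) = P(S_{t-1}=H, S_t=U | y_1..T): the probability of
having left the healthy eGFR distribution since the previous visit.
Parameters are estimated by pooled maximum likelihood across participants
with multi-start quasi-Newton optimisation on transformed parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import approx_fprime, minimize

from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "Trajectory",
    "HMMParams",
    "HMMPosteriors",
    "StateClassification",
    "FitConfig",
    "FitDiagnostics",
    "HMMFit",
    "transition_matrix",
    "emission_logdensity",
    "sequence_loglik",
    "posterior_states",
    "filtered_state_probabilities",
    "departure_probabilities",
    "classify_states",
    "fit_hmm",
    "trajectories_from_table",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

STATE_H, STATE_U = 0, 1


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Time-ordered eGFR sequence for one participant.

    Missed visits are simply absent; they show up only as longer gaps
    between consecutive observation times.
    """

    participant_id: object
    times: np.ndarray  # months since baseline, strictly increasing
    egfr: np.ndarray  # aligned eGFR values, no missing entries
    pregnant: np.ndarray  # aligned booleans
    visit_numbers: np.ndarray | None = None  # optional, for holdout rules
    cohort: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.egfr = np.asarray(self.egfr, dtype=float)
        self.pregnant = np.asarray(self.pregnant, dtype=bool)
        if self.visit_numbers is not None:
            self.visit_numbers = np.asarray(self.visit_numbers, dtype=int)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise InvalidInputError("trajectory needs at least one visit")
        if len(self.egfr) != len(self.times) or len(self.pregnant) != len(self.times):
            raise InvalidInputError("times, egfr and pregnant must be aligned")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("visit times must be strictly increasing")
        if not np.all(np.isfinite(self.egfr)):
            raise InvalidInputError("eGFR values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class HMMParams:
    """Parameters of the two-state continuous-time HMM.

    Rates are per month; emission parameters in mL/min/1.73 m^2.  The
    unhealthy emission is Gaussian with mean ``mu_U`` and SD ``sigma_U``;
    identifiability requires mu_U < mu_H.
    """

    q_HU: float
    q_UH: float
    mu_H: float
    sigma_H: float
    delta_preg: float
    mu_U: float
    sigma_U: float
    pi_U: float

    def __post_init__(self) -> None:
        if self.q_HU < 0 or self.q_UH < 0:
            raise InvalidInputError("transition intensities must be non-negative")
        if self.sigma_H <= 0 or self.sigma_U <= 0:
            raise InvalidInputError("emission SDs must be positive")
        if not 0.0 <= self.pi_U <= 1.0:
            raise InvalidInputError("pi_U must lie in [0, 1]")
        if not self.mu_U < self.mu_H:
            raise InvalidInputError("state ordering requires mu_U < mu_H")

    def to_dict(self) -> dict:
        return {
            "q_HU": self.q_HU,
            "q_UH": self.q_UH,
            "mu_H": self.mu_H,
            "sigma_H": self.sigma_H,
            "delta_preg": self.delta_preg,
            "mu_U": self.mu_U,
            "sigma_U": self.sigma_U,
            "pi_U": self.pi_U,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "HMMParams":
        return cls(**{k: float(d[k]) for k in (
            "q_HU", "q_UH", "mu_H", "sigma_H", "delta_preg", "mu_U", "sigma_U", "pi_U")})


@dataclass
class HMMPosteriors:
    """Smoothed posteriors for one trajectory.

    gamma[t] is P(unhealthy at visit t | full sequence); xi_HU[t-1] is the
    joint probability of (healthy at visit t-1, unhealthy at visit t) given
    the full sequence.  ``xi`` stores the full 2x2 joint for each interval
    (rows: state at t-1, columns: state at t).
    """

    participant_id: object
    gamma: np.ndarray  # (T,)
    xi_HU: np.ndarray  # (T-1,)
    xi: np.ndarray  # (T-1, 2, 2)
    loglik: float
    visit_numbers: np.ndarray | None = None


@dataclass
class StateClassification:
    """Thresholded labels derived from posteriors."""

    labels: np.ndarray  # (T,) "healthy"/"unhealthy"
    probable_departure: np.ndarray  # (T-1,) bool
    reverted: np.ndarray  # (T,) bool: healthy label after an earlier unhealthy label


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def transition_matrix(q_HU: float, q_UH: float, dt: float) -> np.ndarray:
    """2x2 transition probability matrix over a gap of ``dt`` months.

    Closed-form matrix exponential of the intensity matrix
    Q = [[-a, a], [b, -b]] with a = q_HU, b = q_UH:

        P_HH = (b + a e^{-s dt}) / s,   s = a + b

    and analogously for the other entries; the identity when s = 0.
    """
    if dt < 0:
        raise InvalidInputError(f"dt must be non-negative, got {dt}")
    if q_HU < 0 or q_UH < 0:
        raise InvalidInputError("intensities must be non-negative")
    a, b = float(q_HU), float(q_UH)
    s = a + b
    if s == 0.0:
        return np.eye(2)
    e = math.exp(-s * dt)
    p_hh = (b + a * e) / s
    p_uu = (a + b * e) / s
    return np.array([[p_hh, 1.0 - p_hh], [1.0 - p_uu, p_uu]])


def _norm_logpdf(y, mu, sigma):
    z = (np.asarray(y, float) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI


def emission_logdensity(
    y: float, state: int | str, params: HMMParams, pregnant: bool = False
) -> float:
    """Log emission density of an eGFR value under one latent state.

    The healthy mean is shifted by ``delta_preg`` for pregnant visits; the
    unhealthy emission ignores the pregnancy flag.
    """
    if isinstance(state, str):
        state = {"H": STATE_H, "healthy": STATE_H, "U": STATE_U, "unhealthy": STATE_U}[state]
    if state == STATE_H:
        mu = params.mu_H + (params.delta_preg if pregnant else 0.0)
        return float(_norm_logpdf(y, mu, params.sigma_H))
    return float(_norm_logpdf(y, params.mu_U, params.sigma_U))


def _emission_log_matrix(traj: Trajectory, params: HMMParams) -> np.ndarray:
    """(T, 2) matrix of log emission densities, columns (H, U)."""
    mu_h = params.mu_H + params.delta_preg * traj.pregnant.astype(float)
    return np.column_stack(
        [
            _norm_logpdf(traj.egfr, mu_h, params.sigma_H),
            _norm_logpdf(traj.egfr, params.mu_U, params.sigma_U),
        ]
    )


# ---------------------------------------------------------------------------
# forward-backward
# ---------------------------------------------------------------------------


def _forward_backward(traj: Trajectory, params: HMMParams):
    """Scaled forward-backward pass.

    Returns (alpha_hat, beta_hat, scalers c, per-step log offsets m,
    transition matrices, scaled emission densities f).  The per-step
    offsets keep the scaled densities in [0, 1] so the recursion cannot
    underflow even for extreme observations.
    """
    T = len(traj)
    logf = _emission_log_matrix(traj, params)
    m = logf.max(axis=1)
    f = np.exp(logf - m[:, None])
    pi = np.array([1.0 - params.pi_U, params.pi_U])
    dts = np.diff(traj.times)
    mats = [transition_matrix(params.q_HU, params.q_UH, dt) for dt in dts]

    alpha = np.empty((T, 2))
    c = np.empty(T)
    a = pi * f[0]
    c[0] = a.sum()
    if c[0] <= 0:  # pragma: no cover - degenerate prior/emission combination
        raise InvalidInputError("zero likelihood at first visit")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ mats[t - 1]) * f[t]
        c[t] = a.sum()
        if c[t] <= 0:  # pragma: no cover
            raise InvalidInputError(f"zero likelihood at visit index {t}")
        alpha[t] = a / c[t]

    beta = np.empty((T, 2))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = mats[t] @ (f[t + 1] * beta[t + 1]) / c[t + 1]
    return alpha, beta, c, m, mats, f


def sequence_loglik(traj: Trajectory, params: HMMParams) -> float:
    """Log-likelihood of one trajectory under the model.

    Computed with a per-step scaled forward recursion; depends on visit
    times only through their differences, so it is invariant to shifting
    the time origin.
    """
    T = len(traj)
    logf = _emission_log_matrix(traj, params)
    m = logf.max(axis=1)
    f = np.exp(logf - m[:, None])
    pi = np.array([1.0 - params.pi_U, params.pi_U])
    a = pi * f[0]
    ll = math.log(a.sum()) + m[0]
    a /= a.sum()
    for t in range(1, T):
        P = transition_matrix(params.q_HU, params.q_UH, traj.times[t] - traj.times[t - 1])
        a = (a @ P) * f[t]
        s = a.sum()
        ll += math.log(s) + m[t]
        a /= s
    return ll


def posterior_states(traj: Trajectory, params: HMMParams) -> HMMPosteriors:
    """Smoothed posteriors: per-visit gamma and per-interval joint xi.

    gamma_t conditions on the *whole* sequence (smoothing, not filtering):
    an isolated low eGFR surrounded by healthy values is discounted by the
    later evidence.  For a single-visit trajectory xi is empty.
    """
    T = len(traj)
    alpha, beta, c, m, mats, f = _forward_backward(traj, params)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.empty((T - 1, 2, 2))
    for t in range(1, T):
        j = alpha[t - 1][:, None] * mats[t - 1] * (f[t] * beta[t])[None, :] / c[t]
        xi[t - 1] = j / j.sum()
    loglik = float(np.log(c).sum() + m.sum())
    return HMMPosteriors(
        participant_id=traj.participant_id,
        gamma=gamma[:, STATE_U],
        xi_HU=xi[:, STATE_H, STATE_U] if T > 1 else np.empty(0),
        xi=xi,
        loglik=loglik,
        visit_numbers=traj.visit_numbers,
    )


def filtered_state_probabilities(traj: Trajectory, params: HMMParams) -> np.ndarray:
    """Forward-only (filtered) P(unhealthy at t | y_1..t), for comparison with smoothing."""
    alpha, *_ = _forward_backward(traj, params)
    return alpha[:, STATE_U].copy()


def departure_probabilities(traj: Trajectory, params: HMMParams) -> HMMPosteriors:
    """Per-interval joint probabilities of departing the healthy state.

    Alias of :func:`posterior_states`; the xi_HU field holds, for each
    inter-visit interval, P(healthy at previous visit AND unhealthy at this
    visit | full sequence).
    """
    return posterior_states(traj, params)


def classify_states(
    posteriors: HMMPosteriors, threshold: float = 0.5
) -> StateClassification:
    """Threshold posteriors into labels and probable-departure flags.

    A visit is labelled unhealthy iff gamma > threshold (strictly); an
    interval is a probable departure iff xi_HU > threshold (strictly).
    The reversion flag marks healthy-labelled visits preceded by an
    unhealthy-labelled visit.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidInputError(f"threshold must lie strictly in (0, 1), got {threshold}")
    unhealthy = posteriors.gamma > threshold
    labels = np.where(unhealthy, "unhealthy", "healthy")
    departures = posteriors.xi_HU > threshold
    seen_unhealthy = np.concatenate([[False], np.cumsum(unhealthy)[:-1] > 0])
    reverted = seen_unhealthy & ~unhealthy
    return StateClassification(labels=labels, probable_departure=departures, reverted=reverted)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Settings for maximum-likelihood estimation.

    min_measures : minimum number of eGFR measures for a participant to
        enter the likelihood (counted after removing held-out visits).
    holdout_visits : per-cohort visit numbers excluded from estimation
        (default: the final two visits of cohort 1); held-out visits stay
        available downstream for descriptive use.
    unhealthy_mu / unhealthy_sigma : fixed Gaussian spec for the unhealthy
        emission (eGFR units).
    estimate_unhealthy : also estimate (mu_U, sigma_U) under the ordering
        constraint mu_U < mu_H - 10.
    sex_stratified is honoured by the pipeline, which calls fit_hmm once
    per stratum.
    """

    min_measures: int = 4
    holdout_visits: Mapping[int, Sequence[int]] = field(default_factory=lambda: {1: (9, 10)})
    unhealthy_mu: float = 85.0
    unhealthy_sigma: float = 25.0
    estimate_unhealthy: bool = False
    estimate_delta_preg: bool | None = None  # None = auto (any pregnant visits)
    n_starts: int = 5
    seed: int = 20230131
    sex_stratified: bool = False
    min_trajectories: int = 20
    init_params: "HMMParams | None" = None  # warm start (replaces moment-based init)


@dataclass
class FitDiagnostics:
    loglik: float
    converged: bool
    n_starts: int
    n_trajectories: int
    n_observations: int
    grad_norm: float
    start_logliks: list[float]
    message: str


@dataclass
class HMMFit:
    params: HMMParams
    diagnostics: FitDiagnostics


class _Batch:
    """Padded array view of a trajectory list for vectorised likelihoods."""

    def __init__(self, trajs: Sequence[Trajectory]):
        n = len(trajs)
        tmax = max(len(t) for t in trajs)
        self.Y = np.zeros((n, tmax))
        self.preg = np.zeros((n, tmax))
        self.mask = np.zeros((n, tmax), dtype=bool)
        self.dt = np.zeros((n, max(tmax - 1, 1)))
        for i, tr in enumerate(trajs):
            T = len(tr)
            self.Y[i, :T] = tr.egfr
            self.preg[i, :T] = tr.pregnant
            self.mask[i, :T] = True
            if T > 1:
                self.dt[i, : T - 1] = np.diff(tr.times)
        self.n_obs = int(self.mask.sum())
        self.tmax = tmax


def _batch_negloglik(theta: np.ndarray, batch: _Batch, spec: dict) -> float:
    """Pooled negative log-likelihood on transformed parameters."""
    p = _unpack(theta, spec)
    a, b = p["q_HU"], p["q_UH"]
    s = a + b
    mu_h = p["mu_H"] + p["delta_preg"] * batch.preg
    logf_h = -0.5 * ((batch.Y - mu_h) / p["sigma_H"]) ** 2 - math.log(p["sigma_H"]) - _LOG_SQRT_2PI
    logf_u = -0.5 * ((batch.Y - p["mu_U"]) / p["sigma_U"]) ** 2 - math.log(p["sigma_U"]) - _LOG_SQRT_2PI
    m = np.maximum(logf_h, logf_u)
    f_h = np.exp(logf_h - m)
    f_u = np.exp(logf_u - m)

    al_h = (1.0 - p["pi_U"]) * f_h[:, 0]
    al_u = p["pi_U"] * f_u[:, 0]
    c = al_h + al_u
    ll = np.log(c) + m[:, 0]
    al_h /= c
    al_u /= c
    for t in range(1, batch.tmax):
        e = np.exp(-s * batch.dt[:, t - 1])
        p_hh = (b + a * e) / s
        p_uu = (a + b * e) / s
        prop_h = al_h * p_hh + al_u * (1.0 - p_uu)
        prop_u = al_h * (1.0 - p_hh) + al_u * p_uu
        an_h = prop_h * f_h[:, t]
        an_u = prop_u * f_u[:, t]
        cn = np.maximum(an_h + an_u, 1e-300)
        valid = batch.mask[:, t]
        al_h = np.where(valid, an_h / cn, al_h)
        al_u = np.where(valid, an_u / cn, al_u)
        ll = ll + np.where(valid, np.log(cn) + m[:, t], 0.0)
    return -float(ll.sum())


def _free_names(spec: dict) -> list[str]:
    names = ["log_q_HU", "log_q_UH", "mu_H", "log_sigma_H", "logit_pi_U"]
    if spec["estimate_delta"]:
        names.append("delta_preg")
    if spec["estimate_unhealthy"]:
        names += ["log_gap_U", "log_sigma_U"]
    return names


def _unpack(theta: np.ndarray, spec: dict) -> dict:
    names = spec["names"]
    v = dict(zip(names, theta))
    p = {
        "q_HU": math.exp(v["log_q_HU"]),
        "q_UH": math.exp(v["log_q_UH"]),
        "mu_H": v["mu_H"],
        "sigma_H": math.exp(v["log_sigma_H"]),
        "pi_U": 1.0 / (1.0 + math.exp(-v["logit_pi_U"])),
        "delta_preg": v.get("delta_preg", spec["delta_fixed"]),
    }
    if spec["estimate_unhealthy"]:
        # ordering constraint: mu_U = mu_H - 10 - exp(log_gap_U) < mu_H - 10
        p["mu_U"] = p["mu_H"] - 10.0 - math.exp(v["log_gap_U"])
        p["sigma_U"] = math.exp(v["log_sigma_U"])
    else:
        p["mu_U"] = spec["mu_U"]
        p["sigma_U"] = spec["sigma_U"]
    return p


def _apply_holdout(traj: Trajectory, holdout: Mapping[int, Sequence[int]]) -> Trajectory:
    if traj.cohort is None or traj.visit_numbers is None:
        return traj
    excluded = set(holdout.get(traj.cohort, ()))
    if not excluded:
        return traj
    keep = ~np.isin(traj.visit_numbers, list(excluded))
    if keep.all():
        return traj
    if not keep.any():
        return replace(traj, times=traj.times[:0], egfr=traj.egfr[:0],
                       pregnant=traj.pregnant[:0], visit_numbers=traj.visit_numbers[:0])
    return Trajectory(
        participant_id=traj.participant_id,
        times=traj.times[keep],
        egfr=traj.egfr[keep],
        pregnant=traj.pregnant[keep],
        visit_numbers=traj.visit_numbers[keep],
        cohort=traj.cohort,
    )


def fit_hmm(trajectories: Iterable[Trajectory], config: FitConfig | None = None) -> HMMFit:
    """Maximum-likelihood fit of the two-state continuous-time HMM.

    Participants enter the pooled likelihood if, after removing held-out
    visits, they have at least ``config.min_measures`` eGFR measures.
    Optimisation runs on transformed parameters (log rates, log sigma,
    logit pi) with ``n_starts`` seeded multi-starts around moment-based
    initial values; the best local optimum is returned.

    Raises
    ------
    InsufficientDataError
        Fewer than ``config.min_trajectories`` eligible participants.
    DegenerateDataError
        The pooled eGFR values carry no variance.
    """
    config = config or FitConfig()
    kept: list[Trajectory] = []
    for tr in trajectories:
        tr = _apply_holdout(tr, config.holdout_visits)
        if len(tr) >= config.min_measures:
            kept.append(tr)
    if len(kept) < config.min_trajectories:
        raise InsufficientDataError(
            f"only {len(kept)} trajectories with >= {config.min_measures} measures "
            f"(need {config.min_trajectories})"
        )
    pooled = np.concatenate([t.egfr for t in kept])
    if np.ptp(pooled) == 0.0:
        raise DegenerateDataError("all eGFR values identical; emission parameters unidentifiable")

    any_preg = any(t.pregnant.any() for t in kept)
    est_delta = config.estimate_delta_preg if config.estimate_delta_preg is not None else any_preg
    spec = {
        "estimate_delta": bool(est_delta),
        "estimate_unhealthy": bool(config.estimate_unhealthy),
        "delta_fixed": 0.0,
        "mu_U": config.unhealthy_mu,
        "sigma_U": config.unhealthy_sigma,
    }
    spec["names"] = _free_names(spec)

    # moment-based start: healthy component from the upper part of the pooled
    # histogram, baseline prevalence from values far below it
    upper = pooled[pooled >= np.quantile(pooled, 0.4)]
    mu0 = float(upper.mean())
    sigma0 = float(max(upper.std(ddof=1), 1.0))
    first = np.array([t.egfr[0] for t in kept])
    pi0 = float(np.clip(np.mean(first < mu0 - 2.5 * sigma0), 0.02, 0.5))
    if config.init_params is not None:
        ip = config.init_params
        pi_c = min(max(ip.pi_U, 1e-6), 1 - 1e-6)
        theta0 = {
            "log_q_HU": math.log(max(ip.q_HU, 1e-10)),
            "log_q_UH": math.log(max(ip.q_UH, 1e-10)),
            "mu_H": ip.mu_H,
            "log_sigma_H": math.log(ip.sigma_H),
            "logit_pi_U": math.log(pi_c / (1 - pi_c)),
        }
        if spec["estimate_delta"]:
            theta0["delta_preg"] = ip.delta_preg
        else:
            spec["delta_fixed"] = ip.delta_preg
        if spec["estimate_unhealthy"]:
            theta0["log_gap_U"] = math.log(max(ip.mu_H - 10.0 - ip.mu_U, 0.2))
            theta0["log_sigma_U"] = math.log(ip.sigma_U)
        mu0 = ip.mu_H  # keep bounds centred on the warm start
    else:
        theta0 = {
            "log_q_HU": math.log(0.005),
            "log_q_UH": math.log(0.002),
            "mu_H": mu0,
            "log_sigma_H": math.log(sigma0),
            "logit_pi_U": math.log(pi0 / (1 - pi0)),
        }
        if spec["estimate_delta"]:
            theta0["delta_preg"] = 10.0
        if spec["estimate_unhealthy"]:
            theta0["log_gap_U"] = math.log(max(mu0 - 10.0 - config.unhealthy_mu, 5.0))
            theta0["log_sigma_U"] = math.log(config.unhealthy_sigma)
    x0 = np.array([theta0[n] for n in spec["names"]])

    bounds_map = {
        "log_q_HU": (-12.0, 2.0),
        "log_q_UH": (-12.0, 2.0),
        "mu_H": (mu0 - 60.0, mu0 + 60.0),
        "log_sigma_H": (math.log(0.5), math.log(100.0)),
        "logit_pi_U": (-8.0, 8.0),
        "delta_preg": (-60.0, 60.0),
        "log_gap_U": (math.log(0.1), math.log(150.0)),
        "log_sigma_U": (math.log(0.5), math.log(100.0)),
    }
    bounds = [bounds_map[n] for n in spec["names"]]
    scales = np.array(
        [1.0 if n.startswith(("log", "logit")) else max(abs(x0[i]) * 0.05, 2.0)
         for i, n in enumerate(spec["names"])]
    )

    batch = _Batch(kept)
    rng = np.random.default_rng(config.seed)
    best = None
    start_lls: list[float] = []
    for k in range(max(config.n_starts, 1)):
        xk = x0 if k == 0 else x0 + rng.normal(scale=0.5, size=x0.shape) * scales
        xk = np.clip(xk, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _batch_negloglik, xk, args=(batch, spec), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        start_lls.append(-float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    p = _unpack(best.x, spec)
    params = HMMParams(**p)
    grad = approx_fprime(best.x, _batch_negloglik, 1e-6, batch, spec)
    diag = FitDiagnostics(
        loglik=-float(best.fun),
        converged=bool(best.success),
        n_starts=max(config.n_starts, 1),
        n_trajectories=len(kept),
        n_observations=batch.n_obs,
        grad_norm=float(np.linalg.norm(grad)),
        start_logliks=start_lls,
        message=str(best.message),
    )
    return HMMFit(params=params, diagnostics=diag)


# ---------------------------------------------------------------------------
# table helpers
# ---------------------------------------------------------------------------


def trajectories_from_table(visits: pd.DataFrame) -> list[Trajectory]:
    """Build one :class:`Trajectory` per participant from a validated visit table."""
    out = []
    for pid, grp in visits.groupby("participant_id", sort=True):
        grp = grp.sort_values("visit")
        out.append(
            Trajectory(
                participant_id=pid,
                times=grp["months"].to_numpy(float),
                egfr=grp["egfr"].to_numpy(float),
                pregnant=grp["pregnant"].to_numpy(bool),
                visit_numbers=grp["visit"].to_numpy(int),
                cohort=int(grp["cohort"].iloc[0]),
            )
        )
    return out


def posteriors_to_frame(posteriors: Sequence[HMMPosteriors], threshold: float = 0.5) -> pd.DataFrame:
    """Long table of per-visit posteriors (xi_HU refers to the interval ending at the visit)."""
    rows = []
    for post in posteriors:
        cls = classify_states(post, threshold)
        T = len(post.gamma)
        visits = post.visit_numbers if post.visit_numbers is not None else np.arange(1, T + 1)
        for t in range(T):
            rows.append(
                {
                    "participant_id": post.participant_id,
                    "visit": int(visits[t]),
                    "gamma": post.gamma[t],
                    "xi_HU": post.xi_HU[t - 1] if t > 0 else np.nan,
                    "label": cls.labels[t],
                    "probable_departure": bool(cls.probable_departure[t - 1]) if t > 0 else False,
                }
            )
    return pd.DataFrame(rows)
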