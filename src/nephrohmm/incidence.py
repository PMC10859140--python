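"""CKD event detection, Kaplan-Meier survival, incidence rates and Cox models.

CKD (stages 3-5) is operationalised as the first of two *consecutive
attended* visits with eGFR < 60 mL/min/1.73 m^2; the event time is the
month of the first of the pair.  Participants already below 60 at baseline
are prevalent cases and contribute no risk time to incidence analyses.

Kaplan-Meier estimation and the Cox proportional-hazards model (with
time-updated covariates in counting-process layout, Efron tie handling)
are delegated to lifelines; the exact-Poisson incidence-rate interval uses
chi-square quantiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter, KaplanMeierFitter
from scipy.stats import chi2

from .cthmm import Trajectory
from .exceptions import EstimationError, InvalidInputError

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "IncidenceRate",
    "FitResult",
    "detect_ckd_event",
    "km_estimate",
    "incidence_rate",
    "build_counting_process",
    "cox_fit",
    "CKD_EGFR_THRESHOLD",
]

#: eGFR threshold (mL/min/1.73 m^2) defining CKD stages 3-5
CKD_EGFR_THRESHOLD = 60.0


@dataclass
class SurvivalRecord:
    participant_id: object
    entry_time: float
    exit_time: float
    event: bool
    baseline_excluded: bool


@dataclass
class KMEstimate:
    """Kaplan-Meier step function with Greenwood variance.

    ``table`` has one row per distinct event time: at_risk, events,
    survival, greenwood_var, ci_low, ci_high.
    """

    table: pd.DataFrame
    n_subjects: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Right-continuous survival probability at time ``t``."""
        if self.table.empty:
            return 1.0
        tab = self.table[self.table["time"] <= t]
        return 1.0 if tab.empty else float(tab["survival"].iloc[-1])


@dataclass
class IncidenceRate:
    """Incidence rate per 100 person-years with exact Poisson 95% CI."""

    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    person_years: float


@dataclass
class FitResult:
    """Coefficient table shared by Cox and fractional-logit fits.

    ``table`` is indexed by term with columns: estimate (log scale), se,
    ratio (HR or OR), ci_low, ci_high (ratio scale), p.
    """

    table: pd.DataFrame
    converged: bool
    n_obs: int
    n_events: int | None
    n_clusters: int | None
    loglik: float | None
    method: str


def detect_ckd_event(traj: Trajectory, threshold: float = CKD_EGFR_THRESHOLD) -> SurvivalRecord:
    """Apply the two-consecutive-low-measures event rule to one trajectory.

    "Consecutive" means consecutive *attended* visits: a missed visit
    between two low measures does not break the pair.  Event time is the
    month of the first of the pair; otherwise the participant is censored
    at the last attended visit.  ``baseline_excluded`` marks prevalent
    cases (first measure already below threshold).
    """
    low = traj.egfr < threshold
    baseline_excluded = bool(low[0])
    event = False
    exit_time = float(traj.times[-1])
    for t in range(len(traj) - 1):
        if low[t] and low[t + 1]:
            event = True
            exit_time = float(traj.times[t])
            break
    return SurvivalRecord(
        participant_id=traj.participant_id,
        entry_time=float(traj.times[0]),
        exit_time=exit_time,
        event=event,
        baseline_excluded=baseline_excluded,
    )


def km_estimate(
    records: Iterable[SurvivalRecord], exclude_baseline_prevalent: bool = True
) -> KMEstimate:
    """Kaplan-Meier CKD-free survival from per-participant survival records."""
    recs = [r for r in records if not (exclude_baseline_prevalent and r.baseline_excluded)]
    recs = [r for r in recs if r.exit_time > r.entry_time]
    if not recs:
        raise InvalidInputError("no records with positive follow-up time")
    durations = np.array([r.exit_time - r.entry_time for r in recs])
    events = np.array([r.event for r in recs], dtype=bool)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    et = kmf.event_table  # index: event/censor times

    rows = []
    surv = 1.0
    gw_sum = 0.0  # running Greenwood sum d / (n (n - d))
    for t, r in et.iterrows():
        d, n = float(r["observed"]), float(r["at_risk"])
        if d == 0:
            continue
        surv *= 1.0 - d / n
        gw_sum += d / (n * (n - d)) if n > d else np.inf
        var = surv**2 * gw_sum
        se = math.sqrt(var) if np.isfinite(var) else np.inf
        rows.append(
            {
                "time": float(t),
                "at_risk": int(n),
                "events": int(d),
                "survival": surv,
                "greenwood_var": var,
                "ci_low": max(surv - 1.96 * se, 0.0),
                "ci_high": min(surv + 1.96 * se, 1.0),
            }
        )
    columns = ["time", "at_risk", "events", "survival", "greenwood_var", "ci_low", "ci_high"]
    return KMEstimate(
        table=pd.DataFrame(rows, columns=columns),
        n_subjects=len(recs),
        n_events=int(events.sum()),
    )


def incidence_rate(n_events: int, person_years: float) -> IncidenceRate:
    """Incidence rate per 100 person-years with an exact Poisson 95% CI.

    The interval uses chi-square quantiles of the Poisson count:
    lower = chi2(0.025; 2k)/2, upper = chi2(0.975; 2k+2)/2, scaled by the
    person-time denominator (lower bound 0 when no events).
    """
    if person_years <= 0:
        raise InvalidInputError("person-years must be positive")
    if n_events < 0:
        raise InvalidInputError("event count must be non-negative")
    k = int(n_events)
    rate = 100.0 * k / person_years
    low = 0.0 if k == 0 else 100.0 * chi2.ppf(0.025, 2 * k) / 2.0 / person_years
    high = 100.0 * chi2.ppf(0.975, 2 * k + 2) / 2.0 / person_years
    return IncidenceRate(rate=rate, ci_low=low, ci_high=high, n_events=k, person_years=person_years)


def build_counting_process(
    visits: pd.DataFrame,
    covariates: Mapping[str, str],
    sex_filter: str | None = "male",
    threshold: float = CKD_EGFR_THRESHOLD,
) -> pd.DataFrame:
    """Counting-process (start, stop] rows with time-updated covariates.

    ``covariates`` maps column name -> mode:

    - ``"baseline"``: the visit-1 value, constant over follow-up;
    - ``"time_updated"``: the value reported at the visit opening the
      interval, held constant across it;
    - ``"cumulative"``: cumulative exposure-years up to the interval start
      (exposure value x interval length in years, summed).

    Baseline-prevalent participants are excluded; follow-up stops at the
    CKD event time.
    """
    from .cthmm import trajectories_from_table

    if sex_filter is not None:
        visits = visits[visits["sex"] == sex_filter]
    rows = []
    for traj in trajectories_from_table(visits):
        rec = detect_ckd_event(traj, threshold)
        if rec.baseline_excluded:
            continue
        grp = visits[visits["participant_id"] == traj.participant_id].sort_values("visit")
        months = grp["months"].to_numpy(float)
        cum = {name: 0.0 for name, mode in covariates.items() if mode == "cumulative"}
        for i in range(1, len(grp)):
            start, stop = months[i - 1], months[i]
            if start >= rec.exit_time:
                break
            stop = min(stop, rec.exit_time)
            row = {
                "participant_id": traj.participant_id,
                "start": start,
                "stop": stop,
                "event": bool(rec.event and stop == rec.exit_time),
            }
            for name, mode in covariates.items():
                if mode == "baseline":
                    row[name] = grp[name].iloc[0]
                elif mode == "time_updated":
                    row[name] = grp[name].iloc[i - 1]
                elif mode == "cumulative":
                    row[name] = cum[name]
                else:
                    raise InvalidInputError(f"unknown covariate mode {mode!r} for {name!r}")
            rows.append(row)
            for name, mode in covariates.items():
                if mode == "cumulative":
                    cum[name] += float(grp[name].iloc[i - 1]) * (stop - start) / 12.0
            if rec.event and stop == rec.exit_time:
                break
    return pd.DataFrame(rows)


def cox_fit(
    rows: pd.DataFrame,
    covariate_names: Sequence[str],
    robust: bool = False,
) -> FitResult:
    """Cox proportional-hazards fit on counting-process rows (Efron ties).

    Raises :class:`EstimationError` when no events are present or a
    covariate is constant across the risk sets.
    """
    if rows.empty or int(rows["event"].sum()) < 2:
        raise EstimationError("Cox model inestimable: fewer than 2 events")
    for name in covariate_names:
        if rows[name].nunique() < 2:
            raise EstimationError(f"Cox model inestimable: covariate {name!r} is constant")
    df = rows[["participant_id", "start", "stop", "event", *covariate_names]].copy()
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(
        df,
        id_col="participant_id",
        start_col="start",
        stop_col="stop",
        event_col="event",
        robust=robust,
        show_progress=False,
    )
    summ = ctv.summary
    table = pd.DataFrame(
        {
            "estimate": summ["coef"],
            "se": summ["se(coef)"],
            "ratio": summ["exp(coef)"],
            "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
            "p": summ["p"],
        }
    )
    return FitResult(
        table=table,
        converged=True,
        n_obs=len(df),
        n_events=int(df["event"].sum()),
        n_clusters=int(df["participant_id"].nunique()),
        loglik=float(ctv.log_likelihood_),
        method="cox-time-varying (Efron)",
    )
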