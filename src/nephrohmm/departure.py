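"""Fractional-logit risk-factor model on departure probabilities.

The outcome for each participant-interval is the smoothed joint probability
xi of having left the healthy eGFR distribution since the previous visit —
a fraction in [0, 1], not a binary event.  Associations with time-updated
exposures are estimated with a fractional logit (quasi-binomial GLM with a
logistic mean), which solves the score equations

    sum_i x_i (y_i - mu_i) = 0,   mu_i = logistic(x_i' beta)

and is the standard quasi-likelihood estimator for fractional outcomes.
Standard errors are cluster-robust (sandwich) at the participant level,
since each participant contributes several intervals.

Per the study design, intervals whose *previous*-visit posterior
probability of the unhealthy state exceeds 50% are censored: the model
asks what precedes a departure from health, so it conditions on having
been healthy at the start of the interval.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.families import Binomial
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationError

from .cthmm import HMMPosteriors
from .exceptions import EstimationError, IntegrityError, InvalidInputError
from .incidence import FitResult

__all__ = [
    "build_departure_dataset",
    "fractional_logit_fit",
    "departure_risk_table",
    "BASE_COVARIATES",
]

#: adjustment set of the base model: age, sex, community, visit indicators,
#: follow-up duration (months at interval end)
BASE_COVARIATES = ("age_baseline", "sex", "community", "visit", "followup_months")


def build_departure_dataset(
    posteriors: Mapping[object, HMMPosteriors] | Sequence[HMMPosteriors],
    visits: pd.DataFrame,
    exposures: Sequence[str] = (),
    gamma_censor: float = 0.5,
) -> pd.DataFrame:
    """One row per participant-interval, ready for the fractional logit.

    Each row describes the interval ending at an attended visit: the
    outcome is xi_HU for that interval, covariates are taken from the
    interval-end visit (exposure questions refer to the period since the
    previous visit).  Rows whose previous-visit gamma exceeds
    ``gamma_censor`` (strictly) get ``included=False`` and should be
    dropped from modelling; single-visit participants contribute no rows.

    Raises :class:`IntegrityError` on participant/visit mismatches between
    the posterior set and the visit table.
    """
    if not isinstance(posteriors, Mapping):
        posteriors = {p.participant_id: p for p in posteriors}
    rows = []
    by_pid = dict(tuple(visits.groupby("participant_id", sort=False)))
    for pid, post in posteriors.items():
        if pid not in by_pid:
            raise IntegrityError(f"participant {pid!r} in posteriors but not in visit table")
        grp = by_pid[pid].sort_values("visit")
        T = len(post.gamma)
        vnums = (
            post.visit_numbers
            if post.visit_numbers is not None
            else grp["visit"].to_numpy(int)[:T]
        )
        sub = grp[grp["visit"].isin(vnums)]
        if len(sub) != T:
            raise IntegrityError(
                f"participant {pid!r}: posterior visits {list(vnums)} not all in visit table"
            )
        months = sub["months"].to_numpy(float)
        for t in range(1, T):
            row = {
                "participant_id": pid,
                "visit": int(vnums[t]),
                "outcome": float(post.xi_HU[t - 1]),
                "prev_gamma": float(post.gamma[t - 1]),
                "included": bool(post.gamma[t - 1] <= gamma_censor),
                "age_baseline": float(sub["age_baseline"].iloc[0]),
                "sex": sub["sex"].iloc[0],
                "community": sub["community"].iloc[t],
                "cohort": int(sub["cohort"].iloc[0]),
                "followup_months": months[t],
            }
            for e in exposures:
                row[e] = sub[e].iloc[t]
            rows.append(row)
    return pd.DataFrame(rows)


def _formula(exposure_terms: Sequence[str], base: Sequence[str]) -> str:
    parts = list(exposure_terms)
    for c in base:
        if c in ("sex", "community", "visit", "cohort"):
            parts.append(f"C({c})")
        else:
            parts.append(c)
    return "outcome ~ " + " + ".join(parts) if parts else "outcome ~ 1"


def _check_rank(model) -> None:
    X = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR on the design
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [model.exog_names[j] for j in piv[diag <= tol]] + [
            model.exog_names[j] for j in piv[len(diag):]
        ]
        raise EstimationError(f"design matrix rank deficient; aliased columns: {aliased}")


def fractional_logit_fit(
    data: pd.DataFrame,
    exposures: Sequence[str] = (),
    base_covariates: Sequence[str] | None = None,
    cluster: str | None = "participant_id",
    drop_excluded: bool = True,
) -> FitResult:
    """Quasi-binomial logistic fit of departure probabilities on covariates.

    ``exposures`` are entered jointly on top of the base covariates (pass a
    single name for the one-at-a-time analyses; several for multivariable
    adjustment).  Outcomes of exactly 0 or 1 are admitted — the
    quasi-likelihood is defined there.  Rows with a missing exposure value
    are dropped.  With ``cluster`` set, the covariance is the sandwich
    estimator clustered on that column; with ``cluster=None`` the
    heteroskedasticity-robust (HC0) sandwich is used.
    """
    base = BASE_COVARIATES if base_covariates is None else tuple(base_covariates)
    base = tuple(c for c in base if c in data.columns and data[c].nunique() > 1)
    df = data[data["included"]] if (drop_excluded and "included" in data.columns) else data
    cols = ["outcome", *base, *exposures] + ([cluster] if cluster else [])
    df = df.dropna(subset=[c for c in dict.fromkeys(cols)])
    if df["outcome"].nunique() < 2 and df["outcome"].iloc[0] in (0.0, 1.0):
        raise EstimationError("outcome constant at a boundary value; intercept diverges")
    if ((df["outcome"] < 0) | (df["outcome"] > 1)).any():
        raise InvalidInputError("outcomes must lie in [0, 1]")

    formula = _formula(list(exposures), base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DomainWarning)
        model = smf.glm(formula, data=df, family=Binomial())
        _check_rank(model)
        try:
            if cluster:
                res = model.fit(
                    cov_type="cluster", cov_kwds={"groups": df[cluster].to_numpy()}
                )
            else:
                res = model.fit(cov_type="HC0")
        except PerfectSeparationError as err:  # binary outcomes can separate
            raise EstimationError(f"fit did not converge: {err}") from err
    if not np.all(np.isfinite(res.params)):
        raise EstimationError("fit did not converge: non-finite coefficients")

    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ratio": np.exp(res.params),
            "ci_low": np.exp(res.params - 1.96 * res.bse),
            "ci_high": np.exp(res.params + 1.96 * res.bse),
            "p": res.pvalues,
        }
    )
    return FitResult(
        table=table,
        converged=bool(res.converged) if hasattr(res, "converged") else True,
        n_obs=int(res.nobs),
        n_events=None,
        n_clusters=int(df[cluster].nunique()) if cluster else None,
        loglik=None,  # quasi-likelihood: no proper log-likelihood
        method="fractional logit (quasi-binomial, cluster-robust)" if cluster
        else "fractional logit (quasi-binomial, HC0)",
    )


def departure_risk_table(
    data: pd.DataFrame,
    exposures: Sequence[str],
    base_covariates: Sequence[str] | None = None,
    cluster: str = "participant_id",
) -> pd.DataFrame:
    """One-at-a-time exposure screen, one output row per exposure.

    Mirrors the structure of a published risk-factor table: each exposure
    is fitted on top of the base adjustment set; the row reports OR, 95%
    CI, and the analysis size.  Inestimable exposures are reported with a
    note instead of aborting the screen.
    """
    rows = []
    for e in exposures:
        try:
            fit = fractional_logit_fit(data, [e], base_covariates, cluster)
            term = next(t for t in fit.table.index if t == e or t.startswith(f"C({e})"))
            r = fit.table.loc[term]
            rows.append(
                {
                    "exposure": e,
                    "OR": r["ratio"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "n_obs": fit.n_obs,
                    "n_clusters": fit.n_clusters,
                    "note": "",
                }
            )
        except (EstimationError, StopIteration) as err:
            rows.append(
                {
                    "exposure": e,
                    "OR": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": np.nan,
                    "n_obs": 0,
                    "n_clusters": 0,
                    "note": str(err),
                }
            )
    return pd.DataFrame(rows)
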