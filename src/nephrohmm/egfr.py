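"""CKD-EPI 2009 estimated glomerular filtration rate and visit-table I/O.

The 2009 CKD-EPI creatinine equation estimates GFR (mL/min/1.73 m^2) from
serum creatinine (mg/dL), age, sex and an optional race coefficient:

    eGFR = 141 * min(Scr/kappa, 1)^alpha * max(Scr/kappa, 1)^(-1.209)
           * 0.993^age * 1.018[female] * 1.159[black]

with kappa = 0.7 (female) / 0.9 (male) and alpha = -0.329 (female) /
-0.411 (male).  The module also provides the numerical inverse (creatinine
for a target eGFR, used by the cohort simulator) and a validating reader
for the long-format visit table consumed by the rest of the pipeline.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import IntegrityError, InvalidInputError, NoSolutionError, SchemaError

__all__ = [
    "egfr_ckdepi",
    "invert_ckdepi",
    "read_visit_table",
    "write_visit_table",
    "SchemaConfig",
    "ValidationReport",
    "REQUIRED_COLUMNS",
    "UMOL_PER_MGDL",
]

_KAPPA = {"female": 0.7, "male": 0.9}
_ALPHA = {"female": -0.329, "male": -0.411}

#: conversion factor from µmol/L to mg/dL for creatinine
UMOL_PER_MGDL = 88.4

#: columns every visit table must provide (exposures come on top, per config)
REQUIRED_COLUMNS = (
    "participant_id",
    "cohort",
    "community",
    "visit",
    "months",
    "sex",
    "age_baseline",
    "pregnant",
)


def _norm_sex(sex: str) -> str:
    s = str(sex).strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    raise InvalidInputError(f"unrecognised sex value: {sex!r}")


def egfr_ckdepi(scr: float, age: float, sex: str, black: bool = False) -> float:
    """Estimated GFR (mL/min/1.73 m^2) from the 2009 CKD-EPI creatinine equation.

    Parameters
    ----------
    scr : float
        Serum creatinine in mg/dL (must be positive).
    age : float
        Age in years (must be positive).
    sex : {"male", "female"}
    black : bool, optional
        Apply the 1.159 race coefficient.  Defaults to False, matching
        usage in Central American cohorts where the term is not applied.
    """
    sex = _norm_sex(sex)
    scr = float(scr)
    age = float(age)
    if not scr > 0:
        raise InvalidInputError(f"serum creatinine must be positive, got {scr}")
    if not age > 0:
        raise InvalidInputError(f"age must be positive, got {age}")
    kappa = _KAPPA[sex]
    alpha = _ALPHA[sex]
    ratio = scr / kappa
    g = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
    if sex == "female":
        g *= 1.018
    if black:
        g *= 1.159
    return g


def invert_ckdepi(
    egfr: float,
    age: float,
    sex: str,
    black: bool = False,
    scr_bounds: tuple[float, float] = (1e-4, 60.0),
) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``egfr``.

    The equation is strictly decreasing in creatinine, so the inverse is
    found by bracketed root-finding.  Raises :class:`NoSolutionError` when
    the target lies outside the range attainable on ``scr_bounds``.
    """
    if not egfr > 0:
        raise InvalidInputError(f"eGFR must be positive, got {egfr}")
    lo, hi = scr_bounds
    g_hi = egfr_ckdepi(lo, age, sex, black)  # eGFR decreasing in scr
    g_lo = egfr_ckdepi(hi, age, sex, black)
    if egfr > g_hi or egfr < g_lo:
        raise NoSolutionError(
            f"eGFR {egfr} not attainable for scr in [{lo}, {hi}] "
            f"(range [{g_lo:.3g}, {g_hi:.3g}])"
        )
    return float(brentq(lambda s: egfr_ckdepi(s, age, sex, black) - egfr, lo, hi, xtol=1e-12))


@dataclass
class SchemaConfig:
    """How to interpret a visit-table CSV.

    exposure_columns : names of time-updated exposure columns to carry through.
    creatinine_unit : "mg/dL" (default) or "umol/L" (converted on read).
    black_column : optional column with a per-row race-coefficient override.
    """

    exposure_columns: Sequence[str] = ()
    creatinine_unit: str = "mg/dL"
    black_column: str | None = None


@dataclass
class ValidationReport:
    """Line-oriented log of rows dropped or repaired while reading a table."""

    dropped: list[str] = field(default_factory=list)
    repaired: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.dropped and not self.repaired

    def lines(self) -> list[str]:
        return [f"DROPPED: {m}" for m in self.dropped] + [
            f"REPAIRED: {m}" for m in self.repaired
        ]


def read_visit_table(
    source, schema: SchemaConfig | None = None
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a long-format visit table.

    ``source`` is a path or text stream of a comma-separated, UTF-8 table
    with "." decimals and empty cells for missing values.  Rows carrying
    creatinine but no eGFR get eGFR filled in via :func:`egfr_ckdepi`; rows
    with neither are dropped (logged in the report).

    Returns the validated table (sorted by participant and visit) and a
    :class:`ValidationReport`.

    Raises
    ------
    SchemaError
        A required column is absent.
    IntegrityError
        Duplicate (participant_id, visit) pairs, or months not strictly
        increasing with visit number within a participant.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(source)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if "scr_mgdl" not in df.columns and "egfr" not in df.columns:
        raise SchemaError("table must contain at least one of 'scr_mgdl', 'egfr'")
    for col in ("scr_mgdl", "egfr"):
        if col not in df.columns:
            df[col] = np.nan
    for col in schema.exposure_columns:
        if col not in df.columns:
            raise SchemaError(f"missing declared exposure column: {col!r}")

    report = ValidationReport()
    df = df.copy()
    df["sex"] = df["sex"].map(_norm_sex)
    df["pregnant"] = df["pregnant"].astype(bool)

    if schema.creatinine_unit.lower() in ("umol/l", "umol", "µmol/l"):
        df["scr_mgdl"] = df["scr_mgdl"] / UMOL_PER_MGDL
    elif schema.creatinine_unit.lower() not in ("mg/dl", "mgdl"):
        raise InvalidInputError(f"unknown creatinine unit {schema.creatinine_unit!r}")

    dup = df.duplicated(subset=["participant_id", "visit"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "visit"]].drop_duplicates()
        listing = ", ".join(f"({r.participant_id}, {r.visit})" for r in pairs.itertuples())
        raise IntegrityError(f"duplicate (participant_id, visit) pairs: {listing}")

    df = df.sort_values(["participant_id", "visit"], kind="mergesort").reset_index(drop=True)
    for pid, grp in df.groupby("participant_id", sort=False):
        m = grp["months"].to_numpy(float)
        if len(m) > 1 and not np.all(np.diff(m) > 0):
            raise IntegrityError(
                f"months_since_baseline not strictly increasing for participant {pid}"
            )

    # males flagged pregnant: repair to False
    bad_preg = (df["sex"] == "male") & df["pregnant"]
    if bad_preg.any():
        for r in df.loc[bad_preg].itertuples():
            report.repaired.append(
                f"participant {r.participant_id} visit {r.visit}: pregnant=True for male reset to False"
            )
        df.loc[bad_preg, "pregnant"] = False

    # rows with neither measurement are useless: drop
    no_measure = df["scr_mgdl"].isna() & df["egfr"].isna()
    if no_measure.any():
        for r in df.loc[no_measure].itertuples():
            report.dropped.append(
                f"participant {r.participant_id} visit {r.visit}: no creatinine or eGFR"
            )
        df = df.loc[~no_measure].reset_index(drop=True)

    # fill eGFR from creatinine where absent
    needs = df["egfr"].isna() & df["scr_mgdl"].notna()
    if needs.any():
        black = (
            df[schema.black_column].fillna(False).astype(bool)
            if schema.black_column and schema.black_column in df.columns
            else pd.Series(False, index=df.index)
        )
        age_now = df["age_baseline"] + df["months"] / 12.0
        df.loc[needs, "egfr"] = [
            egfr_ckdepi(s, a, x, b)
            for s, a, x, b in zip(
                df.loc[needs, "scr_mgdl"], age_now[needs], df.loc[needs, "sex"], black[needs]
            )
        ]
        for r in df.loc[needs].itertuples():
            report.repaired.append(
                f"participant {r.participant_id} visit {r.visit}: eGFR filled from creatinine"
            )
    return df, report


def write_visit_table(df: pd.DataFrame, dest) -> None:
    """Write a visit table with fixed 6-significant-digit float formatting."""
    out = df.to_csv(index=False, float_format="%.6g")
    if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__"):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            fh.write(out)
    elif isinstance(dest, io.TextIOBase) or hasattr(dest, "write"):
        dest.write(out)
    else:  # pragma: no cover
        raise InvalidInputError(f"cannot write to {dest!r}")
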