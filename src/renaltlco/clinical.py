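"""Renal-function targets from longitudinal serum creatinine.

eGFR is computed with the Japanese-cohort equation

    eGFR (mL/min/1.73 m^2) = 194 * Cr^(-1.094) * age^(-0.287)   [* 0.739 if female]

and the per-subject regression targets — eGFR at the imaging date and the
annual eGFR slope — come from an ordinary least-squares line fitted to the
eGFR values of all observations against time in fractional years.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

__all__ = [
    "SubjectRecord",
    "RenalFunctionTarget",
    "compute_egfr",
    "invert_egfr",
    "fit_trajectory",
]

DAYS_PER_YEAR = 365.25


@dataclass
class SubjectRecord:
    """Demographics plus dated serum-creatinine observations (mg/dL)."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years at imaging
    imaging_date: date
    observations: list[tuple[date, float]]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        self.observations = sorted(self.observations)
        if any(c <= 0 for _, c in self.observations):
            raise ValueError("creatinine values must be positive")


@dataclass
class RenalFunctionTarget:
    """eGFR evaluated at the imaging date and its annual slope.

    ``fit_r2`` is the coefficient of determination of the trajectory line;
    it is only defined (non-None) when the fit used >= 3 observations.
    """

    egfr_at_imaging: float
    egfr_slope: float
    fit_r2: float | None = None


def compute_egfr(creatinine: float, age: float, sex: str) -> float:
    """Estimated glomerular filtration rate, mL/min/1.73 m^2."""
    if creatinine <= 0 or age <= 0:
        raise ValueError("creatinine and age must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    egfr = 194.0 * creatinine ** (-1.094) * age ** (-0.287)
    if sex == "female":
        egfr *= 0.739
    return egfr


def invert_egfr(egfr: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) that yields ``egfr`` for this age/sex.

    Exact algebraic inverse of :func:`compute_egfr`; used by the phantom
    cohort generator to plant creatinine series with a known eGFR.
    """
    if egfr <= 0 or age <= 0:
        raise ValueError("egfr and age must be positive")
    scale = 194.0 * age ** (-0.287) * (0.739 if sex == "female" else 1.0)
    return float((egfr / scale) ** (-1.0 / 1.094))


def fit_trajectory(record: SubjectRecord) -> RenalFunctionTarget:
    """OLS line of eGFR versus time, evaluated at the imaging date.

    Time is measured in fractional years (365.25 days/year) since the first
    observation, so the slope is in mL/min/1.73 m^2 per year, signed as
    fitted (decline is negative).
    """
    obs = record.observations
    if len(obs) < 2:
        raise ValueError(
            f"subject {record.subject_id}: >= 2 creatinine observations required"
        )
    t0 = obs[0][0]
    t = np.array([(d - t0).days / DAYS_PER_YEAR for d, _ in obs])
    if np.ptp(t) == 0:
        raise ValueError(f"subject {record.subject_id}: all observations on one date")
    y = np.array([compute_egfr(c, record.age, record.sex) for _, c in obs])
    slope, intercept = np.polyfit(t, y, 1)
    t_img = (record.imaging_date - t0).days / DAYS_PER_YEAR
    r2 = None
    if len(obs) >= 3:
        resid = y - (slope * t + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else float(1.0 - np.sum(resid**2) / ss_tot)
    return RenalFunctionTarget(
        egfr_at_imaging=float(slope * t_img + intercept),
        egfr_slope=float(slope),
        fit_r2=r2,
    )
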