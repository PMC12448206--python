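"""Population intake trajectories and biomonitoring-trend simulation.

Population-average PFAS intake is modelled as a piecewise log-linear
function of calendar time: zero before 1950, rising log-linearly from a
small anchor (default 1% of the 1990 level) to a 1990 peak, then falling
log-linearly to 1998 and again to 2017, constant afterwards.  The knots
reflect production history: growing use to 1990, phase-downs beginning in
the 1990s, restricted use after 1998.  The level is continuous at the
knots; the slope is not ("discontinuous breaks").  A coarser step variant
(instantaneous level drops at the break years) is available behind the
``mode`` flag.

A survey respondent of age ``a`` in survey year ``s`` is simulated as a
constant-physiology 70 kg adult exposed to ``intake(t) * BW`` from
``max(birth year, 1950)`` to the survey date; the model output is central
serum in ug/L (ppb).  Comparisons are restricted to ages 21-79 because
the model has no developmental compartment (younger ages are biased by
gestational/breastfeeding exposure) and exact ages above 79 are not
reported in the surveys.

At survey-scale intakes (ng/kg/day) the filtrate concentration is orders
of magnitude below the resorption affinity, so the kinetics are linear
and each life course has an exact piecewise-exponential solution (the
default fast path, with an automatic saturation check falling back to the
full ODE).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .dosimetry import HOURS_PER_YEAR, clearance
from .model import DoseSchedule, OralRate, simulate
from .params import ChemicalParams, PhysioParams, derive_rates

__all__ = [
    "IntakeTrajectory",
    "intake_at",
    "simulate_lifecourse",
    "predict_survey",
    "ExposureTrajectoryFitter",
    "fit_exposure",
    "read_biomonitoring",
    "write_biomonitoring",
    "AGE_RANGE",
]

log = logging.getLogger("pfastk")

AGE_RANGE = (21, 79)
BIOMON_COLUMNS = ("survey_year", "age", "mean_serum_ppb")


@dataclass(frozen=True)
class IntakeTrajectory:
    """Piecewise log-linear population intake, ng/kg BW/day.

    ``L1990``, ``L1998``, ``L2017`` are the intake levels at the knot
    years; intake starts in ``anchor_year`` (1950) at
    ``anchor_fraction * L1990`` and is extrapolated as constant after
    2017.
    """

    L1990: float
    L1998: float
    L2017: float
    anchor_year: float = 1950.0
    anchor_fraction: float = 0.01
    mode: str = "continuous"      # "continuous" | "step"

    def __post_init__(self):
        for nm in ("L1990", "L1998", "L2017"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        if not 0 < self.anchor_fraction <= 1:
            raise ValueError("anchor_fraction must be in (0, 1]")
        if self.mode not in ("continuous", "step"):
            raise ValueError("mode must be 'continuous' or 'step'")

    @property
    def knot_years(self):
        return (self.anchor_year, 1990.0, 1998.0, 2017.0)

    def knot_levels(self):
        return (self.anchor_fraction * self.L1990, self.L1990,
                self.L1998, self.L2017)

    def scaled(self, c: float) -> "IntakeTrajectory":
        return IntakeTrajectory(c * self.L1990, c * self.L1998, c * self.L2017,
                                self.anchor_year, self.anchor_fraction, self.mode)


def intake_at(t, traj: IntakeTrajectory):
    """Intake (ng/kg/day) at calendar time ``t`` (fractional years)."""
    t = np.asarray(t, float)
    ky = np.asarray(traj.knot_years)
    kl = np.asarray(traj.knot_levels())
    if traj.mode == "continuous":
        out = np.exp(np.interp(t, ky, np.log(kl)))
    else:
        # step variant: log-linear rise to 1990, then flat segments with
        # instantaneous drops at the break years
        out = np.exp(np.interp(t, ky[:2], np.log(kl[:2])))
        out = np.where(t >= 1990.0, traj.L1998, out)
        out = np.where(t >= 1998.0, traj.L2017, out)
    out = np.where(t < traj.anchor_year, 0.0, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# life-course simulation


def _linear_system(physio, chem):
    """(A, CL) of the linearized 3-state (Agut, Aprim, Adeep) system."""
    r = derive_rates(physio, chem)
    CL = r.Qfil**2 * chem.Free / (r.Qfil + r.Tm / chem.Kt)  # L/h
    A = np.array([
        [-chem.ka, 0.0, 0.0],
        [chem.bioAv * chem.ka, -chem.k12 - CL / r.Vc, chem.k21],
        [0.0, chem.k12, -chem.k21],
    ])
    return A, r


def _intake_rate_mg_per_h(level_ng_per_kg_day, BW):
    return level_ng_per_kg_day * BW * 1e-6 / 24.0


def _lifecourse_linear(start_year, end_year, traj, physio, chem):
    """Exact solution of the linear system under piecewise-exponential intake.

    Returns (Aprim at end, peak central concentration along the way).
    """
    A, r = _linear_system(physio, chem)
    b = np.array([1.0, 0.0, 0.0])
    years = [start_year] + [k for k in traj.knot_years
                            if start_year < k < end_year] + [end_year]
    y = np.zeros(3)
    peak_cp = 0.0
    for y0_yr, y1_yr in zip(years[:-1], years[1:]):
        dt = (y1_yr - y0_yr) * HOURS_PER_YEAR
        if dt <= 0:
            continue
        u0 = _intake_rate_mg_per_h(float(intake_at(y0_yr, traj)), physio.BW)
        u1 = _intake_rate_mg_per_h(float(intake_at(y1_yr - 1e-9, traj)), physio.BW)
        E = sla.expm(A * dt)
        if u0 <= 0.0:
            y = E @ y
        else:
            g = math.log(u1 / u0) / dt if u1 > 0 else 0.0
            M = g * np.eye(3) - A
            try:
                w = np.linalg.solve(M, b) * u0
            except np.linalg.LinAlgError:
                w = np.linalg.solve((g + 1e-12) * np.eye(3) - A, b) * u0
            y = E @ (y - w) + w * math.exp(g * dt)
        peak_cp = max(peak_cp, y[1] / r.Vc)
    return y[1], peak_cp


def simulate_lifecourse(birth_year: float, traj: IntakeTrajectory,
                        physio: PhysioParams, chem: ChemicalParams,
                        survey_date: float, method: str = "auto") -> float:
    """Serum concentration (ug/L, ppb) at the survey date.

    ``method="linear"`` uses the exact piecewise-exponential solution of
    the linearized (sub-saturating) system; ``"ode"`` integrates the full
    nonlinear model; ``"auto"`` (default) uses the linear path and falls
    back to the ODE if the implied filtrate concentration approaches the
    resorption affinity (peak Cfil > 1% of Kt).
    """
    if survey_date <= birth_year:
        raise ValueError("survey_date must be after birth_year")
    if traj.mode != "continuous" and method in ("auto", "linear"):
        method = "ode"  # step trajectories only via the ODE path
    start = max(float(birth_year), traj.anchor_year)
    if survey_date <= start:
        return 0.0
    r = derive_rates(physio, chem)
    if method in ("auto", "linear"):
        aprim, peak_cp = _lifecourse_linear(start, survey_date, traj,
                                            physio, chem)
        if method == "linear":
            return 1000.0 * aprim / r.Vc
        peak_cfil = r.Qfil * chem.Free * peak_cp / (r.Qfil + r.Tm / chem.Kt)
        if peak_cfil <= 0.01 * chem.Kt:
            return 1000.0 * aprim / r.Vc
        log.info("life-course intake approaches resorption saturation; "
                 "switching to the full ODE")
    elif method != "ode":
        raise ValueError(f"unknown method {method!r}")
    # full nonlinear path, hours since `start`
    horizon = (survey_date - start) * HOURS_PER_YEAR
    ky = [start] + [k for k in traj.knot_years if start < k < survey_date] \
        + [survey_date]
    times_h = [(k - start) * HOURS_PER_YEAR for k in ky]
    rates = [max(_intake_rate_mg_per_h(float(intake_at(k, traj)), physio.BW),
                 1e-300) for k in ky]
    sch = DoseSchedule(oral_rate=OralRate(tuple(times_h), tuple(rates)))
    res = simulate(sch, physio, chem, [horizon], method="stiff",
                   rtol=1e-8, atol=1e-12)
    return 1000.0 * float(res.serum[0])


def predict_survey(traj: IntakeTrajectory, physio: PhysioParams,
                   chem: ChemicalParams, survey_years, ages,
                   method: str = "auto") -> pd.DataFrame:
    """Predicted mean serum (ppb) for every (survey year x age) cell."""
    rows = []
    for s in survey_years:
        for a in ages:
            ppb = simulate_lifecourse(s - a, traj, physio, chem, s,
                                      method=method)
            rows.append({"survey_year": float(s), "age": float(a),
                         "mean_serum_ppb": ppb})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting intake levels to biomonitoring means


class ExposureTrajectoryFitter(BaseEstimator):
    """Least-squares fit of (L1990, L1998, L2017) to survey serum means.

    Scikit-learn style: ``fit`` takes a biomonitoring table (columns
    survey_year, age, mean_serum_ppb), minimizes the sum of squared log10
    errors between predicted and observed means over the three intake
    levels (log10 scale), and exposes ``trajectory_`` and ``msle_``.
    """

    def __init__(self, physio: PhysioParams, chem: ChemicalParams,
                 anchor_fraction: float = 0.01, method: str = "auto",
                 log10_halfwidth: float = 4.0):
        self.physio = physio
        self.chem = chem
        self.anchor_fraction = anchor_fraction
        self.method = method
        self.log10_halfwidth = log10_halfwidth

    def _traj(self, x):
        return IntakeTrajectory(*10.0**np.asarray(x),
                                anchor_fraction=self.anchor_fraction)

    def fit(self, X: pd.DataFrame, y=None):
        records = X
        for c in BIOMON_COLUMNS:
            if c not in records.columns:
                raise ValueError(f"biomonitoring table missing column {c!r}")
        bad_age = ~records["age"].between(*AGE_RANGE)
        if bad_age.any():
            raise ValueError(f"ages outside {AGE_RANGE}: "
                             f"{sorted(records['age'][bad_age].unique())}")
        records = records[records["mean_serum_ppb"] > 0]
        if len(records) < 3:
            raise ValueError("need at least 3 informative cells")
        if records["survey_year"].nunique() < 2:
            log.warning("single survey year: intake levels are likely "
                        "non-identifiable")
        obs_log = np.log10(records["mean_serum_ppb"].to_numpy(float))
        years = records["survey_year"].to_numpy(float)
        ages = records["age"].to_numpy(float)

        # crude steady-state inversion of the overall mean seeds the levels
        CL = clearance(self.physio, self.chem)       # mL/kg/day
        mean_ppb = float(records["mean_serum_ppb"].mean())
        guess = max(CL * mean_ppb / self.chem.bioAv, 1e-6)  # ng/kg/day
        x0 = np.log10([guess * 3.0, guess, guess / 3.0])

        def resid(x):
            traj = self._traj(x)
            pred = np.array([
                simulate_lifecourse(s - a, traj, self.physio, self.chem, s,
                                    method=self.method)
                for s, a in zip(years, ages)])
            with np.errstate(divide="ignore"):
                rr = np.log10(pred) - obs_log
            return np.where(np.isfinite(rr), rr, 1e3)

        sol = least_squares(resid, x0, bounds=(x0 - self.log10_halfwidth,
                                               x0 + self.log10_halfwidth),
                            xtol=1e-12, ftol=1e-14, gtol=1e-14)
        self.trajectory_ = self._traj(sol.x)
        r = sol.fun
        self.msle_ = float(np.mean(r * r))
        self.n_cells_ = len(records)
        self.converged_ = bool(sol.status > 0)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "trajectory_"):
            raise RuntimeError("call fit() before predict()")
        return np.array([
            simulate_lifecourse(r.survey_year - r.age, self.trajectory_,
                                self.physio, self.chem, r.survey_year,
                                method=self.method)
            for r in X.itertuples()])


def fit_exposure(records: pd.DataFrame, physio: PhysioParams,
                 chem: ChemicalParams, **kw):
    """Functional wrapper: returns (IntakeTrajectory, achieved MSLE)."""
    f = ExposureTrajectoryFitter(physio, chem, **kw).fit(records)
    return f.trajectory_, f.msle_


# ---------------------------------------------------------------------------
# I/O


def read_biomonitoring(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BIOMON_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"biomonitoring table missing columns: {missing}")
    return df


def write_biomonitoring(df: pd.DataFrame, path):
    df.to_csv(path, index=False)
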