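"""Steady-state dosimetry, clearance, half-life, and human scaling.

At steady state under a constant daily oral dose the model collapses to
closed-form algebra.  The absorbed intake rate is ``R = bioAv*dose*BW/24``
(mg/h).  All of it must ultimately leave in urine, so the filtrate
concentration is ``Cfil = R/Qfil``; the filtrate balance then yields the
central (serum) concentration

    Css = [Cfil + (Tm/Qfil) * Cfil/(Kt + Cfil)] / Free .

Reverse dosimetry (the human-equivalent dose of a serum point of
departure) inverts that relation: given ``Css``, the filtrate balance is a
quadratic in ``Cfil`` with exactly one positive root, and the administered
dose follows as ``dose = 24*Qfil*Cfil/(bioAv*BW)``.  The "administered"
(pre-bioavailability) convention is used throughout for doses.

Primate-to-human scaling replaces the animal physiology by a 70 kg adult
with cardiac output 12.5 L/h/kg^0.74, keeps the animal's chemical-specific
constants, and recalibrates the maximum resorption rate ``Tmc`` so the
model's serum half-life matches the half-life reported in human exposure
studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import DoseSchedule, simulate
from .params import ChemicalParams, PhysioParams, derive_rates

__all__ = [
    "HumanScalingSpec",
    "PODRecord",
    "steady_state_serum",
    "pod_hed",
    "clearance",
    "half_life",
    "calibrate_Tm",
    "scale_to_human",
    "HOURS_PER_YEAR",
]

HOURS_PER_YEAR = 24.0 * 365.25

DEFAULT_HUMAN_PHYSIO = PhysioParams(BW=70.0, QCC=12.5, QfilC=0.15, VfilC=4.0e-4)


@dataclass(frozen=True)
class HumanScalingSpec:
    """Target of the primate-to-human scaling step.

    ``target_half_life`` is the human serum half-life in years;
    ``parameters_held`` lists the chemical parameters carried over
    unchanged from the animal fit (everything except ``Tmc``).
    """

    target_half_life: float
    human_physio: PhysioParams = DEFAULT_HUMAN_PHYSIO
    parameters_held: tuple = ("bioAv", "VCC", "Kt", "Free", "k12", "k21", "ka")
    half_life_method: str = "terminal-slope"

    def __post_init__(self):
        if not self.target_half_life > 0:
            raise ValueError("target_half_life must be > 0")


@dataclass(frozen=True)
class PODRecord:
    """A serum point of departure and (once computed) its human dose."""

    endpoint: str
    pod_serum: float           # mg/L
    pod_hed: float | None = None  # mg/kg/day

    def __post_init__(self):
        if not self.pod_serum > 0:
            raise ValueError("pod_serum must be > 0")


def _ss_cfil_from_dose(dose, physio, chem):
    r = derive_rates(physio, chem)
    R = chem.bioAv * dose * physio.BW / 24.0  # absorbed rate, mg/h
    return R / r.Qfil, r


def steady_state_serum(dose: float, physio: PhysioParams,
                       chem: ChemicalParams) -> float:
    """Steady-state serum concentration (mg/L) under a constant oral dose.

    ``dose`` is the administered dose in mg/kg/day.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    Cfil, r = _ss_cfil_from_dose(dose, physio, chem)
    return (Cfil + (r.Tm / r.Qfil) * Cfil / (chem.Kt + Cfil)) / chem.Free


def pod_hed(pod_serum: float, physio: PhysioParams,
            chem: ChemicalParams) -> float:
    """Human-equivalent administered dose (mg/kg/day) of a serum POD (mg/L).

    Exact inverse of :func:`steady_state_serum`: solves the filtrate
    balance ``Free*Css = Cfil + (Tm/Qfil)*Cfil/(Kt+Cfil)`` — a quadratic in
    ``Cfil`` with a single positive root — then converts the urinary
    elimination rate back to an administered oral dose.
    """
    if pod_serum < 0:
        raise ValueError("pod_serum must be >= 0")
    if pod_serum == 0:
        return 0.0
    r = derive_rates(physio, chem)
    S = chem.Free * pod_serum
    b = chem.Kt + r.Tm / r.Qfil - S
    sq = math.sqrt(b * b + 4.0 * S * chem.Kt)
    # conjugate form for b >= 0 avoids cancellation at sub-saturating PODs
    Cfil = 2.0 * S * chem.Kt / (b + sq) if b >= 0.0 else 0.5 * (sq - b)
    if not Cfil > 0:
        raise RuntimeError("no positive filtrate root; invalid parameters")
    return 24.0 * r.Qfil * Cfil / (chem.bioAv * physio.BW)


def clearance(physio: PhysioParams, chem: ChemicalParams,
              dose: float | str = "linear-limit") -> float:
    """Whole-body clearance referenced to serum, in mL/kg/day.

    With ``dose="linear-limit"`` (or 0) returns the sub-saturating limit
    ``Qfil^2*Free/(Qfil + Tm/Kt)`` converted to mL/kg/day.  With a numeric
    dose (mg/kg/day) returns the absorbed-dose clearance
    ``bioAv*dose/Css`` at that dose; clearance rises with dose toward the
    ceiling ``Qfil*Free`` as resorption saturates.
    """
    r = derive_rates(physio, chem)
    if isinstance(dose, str):
        if dose != "linear-limit":
            raise ValueError(f"unknown clearance mode {dose!r}")
        dose = 0.0
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0.0:
        CL = r.Qfil**2 * chem.Free / (r.Qfil + r.Tm / chem.Kt)  # L/h
        return CL * 24.0 * 1000.0 / physio.BW
    Css = steady_state_serum(dose, physio, chem)
    return chem.bioAv * dose / Css * 1000.0


def _linearized_matrix(physio, chem):
    """Jacobian of the (Aprim, Adeep, Cfil) system in the Cfil << Kt regime."""
    r = derive_rates(physio, chem)
    TmKt = r.Tm / chem.Kt
    return np.array([
        [-chem.k12 - r.Qfil * chem.Free / r.Vc, chem.k21, TmKt],
        [chem.k12, -chem.k21, 0.0],
        [r.Qfil * chem.Free / (r.Vc * r.Vfil), 0.0, -(r.Qfil + TmKt) / r.Vfil],
    ])


def half_life(physio: PhysioParams, chem: ChemicalParams,
              method: str = "terminal-slope", bolus_mg_per_kg: float = 1e-6,
              rsq_warn: float = 0.999) -> float:
    """Serum elimination half-life, in years.

    Methods
    -------
    ``"terminal-slope"`` (default)
        Simulate washout after a sub-saturating IV bolus (default 1e-6
        mg/kg) and regress log10 serum on time over the final decade of
        the simulation; warns if the tail is not log-linear (R^2 below
        ``rsq_warn``).  This mirrors how half-lives are estimated from
        human exposure-study serum series.
    ``"eigenvalue"``
        ln 2 over the smallest-magnitude eigenvalue of the linearized
        (Cfil << Kt) system; cross-check for the default.
    ``"one-compartment"``
        ln 2 * Vc / CL with the linear-limit clearance, i.e. ignoring the
        deep compartment's contribution to the distribution volume.
    """
    r = derive_rates(physio, chem)
    if method == "eigenvalue":
        lam = np.linalg.eigvals(_linearized_matrix(physio, chem))
        rate = float(np.min(np.abs(np.real(lam))))  # slowest decay envelope
        return math.log(2.0) / rate / HOURS_PER_YEAR
    if method == "one-compartment":
        CL = r.Qfil**2 * chem.Free / (r.Qfil + r.Tm / chem.Kt)  # L/h
        return math.log(2.0) * r.Vc / CL / HOURS_PER_YEAR
    if method != "terminal-slope":
        raise ValueError(f"unknown half-life method {method!r}")
    # horizon from the eigenvalue estimate, then regress the final decade
    t_half_guess = half_life(physio, chem, method="eigenvalue") * HOURS_PER_YEAR
    t_end = 12.0 * t_half_guess
    times = np.linspace(t_end / 10.0, t_end, 40)
    sch = DoseSchedule.iv_bolus(bolus_mg_per_kg)
    res = simulate(sch, physio, chem, times, method="qss",
                   rtol=1e-8, atol=0.0)
    logc = np.log10(res.serum)
    slope, intercept = np.polyfit(times, logc, 1)
    fitted = slope * times + intercept
    ss_res = np.sum((logc - fitted) ** 2)
    ss_tot = np.sum((logc - logc.mean()) ** 2)
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if rsq < rsq_warn:
        warnings.warn(f"washout tail is not log-linear (R^2 = {rsq:.5f})")
    rate = -slope * math.log(10.0)
    if rate <= 0:
        raise RuntimeError("non-decaying washout; cannot estimate half-life")
    return math.log(2.0) / rate / HOURS_PER_YEAR


def calibrate_Tm(physio: PhysioParams, chem: ChemicalParams,
                 target_half_life: float, method: str = "terminal-slope",
                 rel_tol: float = 1e-5) -> float:
    """Find the ``Tmc`` (mg/h/kg) giving a target serum half-life (years).

    The half-life is strictly increasing in ``Tmc`` (stronger resorption
    means slower net elimination), so the root is found by Brent's method
    on log10(Tmc).  A target below the ``Tmc = 0`` floor is infeasible and
    raises ``ValueError``.
    """
    if not target_half_life > 0:
        raise ValueError("target_half_life must be > 0")
    floor = half_life(physio, chem.replace(Tmc=0.0), method=method)
    if target_half_life <= floor * (1.0 + 1e-9):
        raise ValueError(
            f"target half-life {target_half_life} y is at or below the "
            f"no-resorption floor {floor:.4g} y; not achievable by Tmc")

    def f(log10_tmc):
        return half_life(physio, chem.replace(Tmc=10.0**log10_tmc),
                         method=method) - target_half_life

    lo, hi = -6.0, 0.0
    while f(hi) < 0:
        lo = hi
        hi += 1.0
        if hi > 8:
            raise ValueError("target half-life unreachable within Tmc bounds")
    while f(lo) > 0:
        lo -= 1.0
        if lo < -30:
            break
    x = brentq(f, lo, hi, xtol=1e-7, rtol=1e-12)
    tmc = 10.0**x
    achieved = half_life(physio, chem.replace(Tmc=tmc), method=method)
    if abs(achieved - target_half_life) > rel_tol * target_half_life:
        raise RuntimeError(
            f"Tmc calibration did not converge: achieved {achieved} y "
            f"vs target {target_half_life} y")
    return tmc


def scale_to_human(animal_chem: ChemicalParams,
                   spec: HumanScalingSpec) -> ChemicalParams:
    """Scale an animal-fitted parameter set to humans.

    All chemical-specific constants are carried over unchanged; only the
    maximum resorption rate coefficient ``Tmc`` is recalibrated so the
    human-physiology model matches ``spec.target_half_life``.  (For a
    chemical whose animal bioavailability was experiment-specific — PFOA —
    pass the animal refit obtained under the human bioavailability, e.g.
    the packaged ``pfoa_monkey_highbioav`` set.)
    """
    tmc = calibrate_Tm(spec.human_physio, animal_chem,
                       spec.target_half_life, method=spec.half_life_method)
    return animal_chem.replace(Tmc=tmc)
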