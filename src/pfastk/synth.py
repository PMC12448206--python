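"""Synthetic study generators with known ground truth.

The primate PK data behind the published parameter fits are proprietary,
and population biomonitoring means require survey microdata; every other
module is therefore exercised against synthetic stand-ins generated here.
The default primate design is shaped like the cynomolgus-monkey studies
this class of model is calibrated on — three repeated-dose oral groups
(daily dosing for 26 weeks, sampled through dosing and a washout year)
plus one IV-bolus group, six animals each, sparse sampling — without
asserting any unpublished study's specifics.  Residual error is
multiplicative lognormal: ``obs = pred * 10^eps`` with
``eps ~ N(0, residual_sd)``, i.i.d., the convention matching log-scale
fitting of serum PK data.

All generators are pure functions of (truth, design, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import PKDataset
from .exposure import IntakeTrajectory, predict_survey
from .model import DoseSchedule, simulate
from .params import ChemicalParams, PhysioParams

__all__ = [
    "GroupDesign",
    "StudyDesign",
    "PanelDesign",
    "default_study_design",
    "gen_primate_study",
    "gen_biomonitoring",
    "write_truth",
    "read_truth",
]


def _weeks(*w):
    return tuple(168.0 * x for x in w)


@dataclass(frozen=True)
class GroupDesign:
    """One dose group: route, dose, regimen and sampling times."""

    name: str
    route: str                  # "oral" | "iv"
    dose_mg_per_kg: float
    regimen: str = "single"     # "single" | "daily"
    duration_weeks: float = 0.0
    obs_times_h: tuple = ()

    def schedule(self) -> DoseSchedule:
        if self.regimen == "single":
            if self.route == "iv":
                return DoseSchedule.iv_bolus(self.dose_mg_per_kg)
            return DoseSchedule.oral_bolus(self.dose_mg_per_kg)
        if self.regimen == "daily":
            n_days = int(round(self.duration_weeks * 7))
            if self.route != "oral":
                raise ValueError("daily regimen is oral-only")
            return DoseSchedule.daily_oral(self.dose_mg_per_kg, n_days)
        raise ValueError(f"unknown regimen {self.regimen!r}")


@dataclass(frozen=True)
class StudyDesign:
    """A multi-group primate study design."""

    groups: tuple
    n_subjects: int = 6
    residual_sd: float = 0.1    # log10 units
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


def default_study_design(residual_sd: float = 0.1, seed: int = 0) -> StudyDesign:
    """Three daily-oral dose groups (26 weeks + washout year) and one IV bolus.

    The oral doses (0.03, 0.15, 0.75 mg/kg/day) bracket the saturation of
    renal resorption — the low dose sits in the linear regime, the middle
    dose near the transition, the high dose saturates it — which is what
    makes the resorption affinity identifiable; sampling continues through
    a washout year because the decay back through the transition carries
    most of the information on ``Kt``.
    """
    oral_obs = _weeks(2, 4, 8, 13, 18, 22, 26, 27, 28, 30, 33, 37, 42, 47, 52)
    iv_obs = (1.0, 24.0, 72.0, 168.0, 336.0, 672.0, 1176.0, 1680.0, 2184.0)
    groups = (
        GroupDesign("oral_low", "oral", 0.03, "daily", 26.0, oral_obs),
        GroupDesign("oral_mid", "oral", 0.15, "daily", 26.0, oral_obs),
        GroupDesign("oral_high", "oral", 0.75, "daily", 26.0, oral_obs),
        GroupDesign("iv", "iv", 2.0, "single", 0.0, iv_obs),
    )
    return StudyDesign(groups=groups, residual_sd=residual_sd, seed=seed)


def gen_primate_study(physio: PhysioParams, chem: ChemicalParams,
                      design: StudyDesign | None = None,
                      method: str = "qss") -> PKDataset:
    """Simulate a primate study and add lognormal residual noise.

    With ``residual_sd=0`` the observations equal the noise-free model
    predictions exactly.  Ground truth (parameters, design, seed) is
    embedded in the dataset's ``meta``.
    """
    design = design or default_study_design()
    rng = np.random.default_rng(design.seed)
    rows = []
    schedules, bws = {}, {}
    for grp in design.groups:
        times = np.asarray(grp.obs_times_h, float)
        res = simulate(grp.schedule(), physio, chem, times, method=method)
        schedules[grp.name] = grp.schedule()
        bws[grp.name] = physio.BW
        for s in range(design.n_subjects):
            eps = rng.standard_normal(len(times)) * design.residual_sd
            conc = res.serum * 10.0**eps
            for t, c in zip(times, conc):
                rows.append({"subject": f"{grp.name}_{s + 1}",
                             "group": grp.name, "route": grp.route,
                             "time_h": t, "conc_ug_per_mL": c})
    obs = pd.DataFrame(rows)
    meta = {
        "truth_chem": {k: getattr(chem, k) for k in
                       ("bioAv", "VCC", "Tmc", "Kt", "Free", "k12", "k21", "ka")},
        "truth_physio": {"BW": physio.BW, "QCC": physio.QCC,
                         "QfilC": physio.QfilC, "VfilC": physio.VfilC},
        "residual_sd": design.residual_sd,
        "seed": design.seed,
    }
    return PKDataset(obs, schedules, bws, meta)


@dataclass(frozen=True)
class PanelDesign:
    """Biomonitoring panel layout: survey years x ages, log10 noise.

    The default grid mirrors the survey structure the panel emulates: one
    mean per single year of age, 21-79, in each of three survey cycles.
    """

    survey_years: tuple = (1999.5, 2003.5, 2017.5)
    ages: tuple = tuple(range(21, 80))
    noise_sd: float = 0.05      # log10 units
    seed: int = 0

    def __post_init__(self):
        for a in self.ages:
            if not 21 <= a <= 79:
                raise ValueError("ages must lie in [21, 79]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_biomonitoring(truth_traj: IntakeTrajectory, physio: PhysioParams,
                      chem: ChemicalParams,
                      design: PanelDesign | None = None) -> pd.DataFrame:
    """Simulate survey-mean serum by (survey year x age) plus noise.

    Columns match the biomonitoring CSV schema: survey_year, age,
    mean_serum_ppb, se_ppb.  With ``noise_sd=0`` the means equal the
    life-course model predictions exactly.
    """
    design = design or PanelDesign()
    rng = np.random.default_rng(design.seed)
    table = predict_survey(truth_traj, physio, chem,
                           design.survey_years, design.ages)
    eps = rng.standard_normal(len(table)) * design.noise_sd
    out = table.copy()
    out["mean_serum_ppb"] = out["mean_serum_ppb"] * 10.0**eps
    # a summary-table SE consistent with the multiplicative noise scale
    out["se_ppb"] = out["mean_serum_ppb"] * design.noise_sd * np.log(10.0)
    return out


def write_truth(path, physio: PhysioParams, chem: ChemicalParams,
                extra: dict | None = None):
    """Sidecar JSON with the generating parameters of a synthetic file."""
    d = {"physiological": {"BW": physio.BW, "QCC": physio.QCC,
                           "QfilC": physio.QfilC, "VfilC": physio.VfilC},
         "chemical": {k: getattr(chem, k) for k in
                      ("bioAv", "VCC", "Tmc", "Kt", "Free", "k12", "k21", "ka")}}
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def read_truth(path):
    d = json.loads(Path(path).read_text())
    return (PhysioParams(**d["physiological"]),
            ChemicalParams(**d["chemical"]), d)
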