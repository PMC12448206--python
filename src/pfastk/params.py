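"""Parameter containers and body-weight scaling for the three-compartment model.

Physiological parameters are species-level (body weight, cardiac output,
filtration fraction, filtrate volume); chemical parameters are the eight
compound-specific constants (bioavailability, central volume coefficient,
saturable-resorption maximum and affinity, free fraction in serum, and the
three first-order exchange/absorption rates).  Coefficients are expressed
per kg body weight and converted to whole-body rates/volumes by
:func:`derive_rates`.

Units convention: amounts in mg, volumes in L, flows in L/h, concentrations
in mg/L (equivalent to ug/mL).  ppb (ug/L) appears only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "PhysioParams",
    "ChemicalParams",
    "DerivedRates",
    "derive_rates",
    "load_params",
    "save_params",
    "load_fixture",
    "list_fixtures",
    "CHEMICAL_FIELDS",
]

CHEMICAL_FIELDS = ("bioAv", "VCC", "Tmc", "Kt", "Free", "k12", "k21", "ka")


def _require_positive(obj, fields):
    for f in fields:
        v = getattr(obj, f)
        if not (v > 0):
            raise ValueError(f"{type(obj).__name__}.{f} must be > 0, got {v!r}")


@dataclass(frozen=True)
class PhysioParams:
    """Species physiology.

    Parameters
    ----------
    BW : float
        Body weight, kg.
    QCC : float
        Cardiac output coefficient, L/h per kg^0.74.
    QfilC : float
        Fraction of cardiac output directed to the renal filtrate, in (0, 1).
    VfilC : float
        Filtrate compartment volume coefficient, L/kg, in (0, 1).
    """

    BW: float
    QCC: float
    QfilC: float = 0.15
    VfilC: float = 4.0e-4

    def __post_init__(self):
        _require_positive(self, ("BW", "QCC", "QfilC", "VfilC"))
        if not self.QfilC < 1:
            raise ValueError(f"QfilC must be in (0,1), got {self.QfilC}")
        if not self.VfilC < 1:
            raise ValueError(f"VfilC must be in (0,1), got {self.VfilC}")


@dataclass(frozen=True)
class ChemicalParams:
    """The eight chemical-specific constants.

    Parameters
    ----------
    bioAv : float
        Oral bioavailability fraction, in (0, 1].
    VCC : float
        Central volume of distribution coefficient, L/kg.
    Tmc : float
        Maximum saturable-resorption rate coefficient, mg/h/kg.
    Kt : float
        Resorption affinity (Michaelis constant in the filtrate), mg/L.
    Free : float
        Free (unbound) fraction of compound in serum, in (0, 1].
    k12 : float
        Central-to-deep first-order rate, 1/h.
    k21 : float
        Deep-to-central first-order rate, 1/h.
    ka : float
        Gut-to-central absorption rate, 1/h.
    """

    bioAv: float
    VCC: float
    Tmc: float
    Kt: float
    Free: float
    k12: float
    k21: float
    ka: float

    def __post_init__(self):
        # Tmc=0 (no resorption) and k12=0 (no deep exchange) are meaningful
        # degenerate limits and are permitted; everything else is positive.
        _require_positive(self, ("bioAv", "VCC", "Kt", "Free", "k21", "ka"))
        if self.Tmc < 0 or self.k12 < 0:
            raise ValueError("Tmc and k12 must be >= 0")
        if self.bioAv > 1:
            raise ValueError(f"bioAv must be <= 1, got {self.bioAv}")
        if self.Free > 1:
            raise ValueError(f"Free must be <= 1, got {self.Free}")

    def replace(self, **kw) -> "ChemicalParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DerivedRates:
    """Whole-body rates and volumes obtained by body-weight scaling.

    QC = QCC * BW^0.74 (L/h); Qfil = QfilC * QC (L/h); Vc = VCC * BW (L);
    Vfil = VfilC * BW (L); Tm = Tmc * BW (mg/h).
    """

    QC: float
    Qfil: float
    Vc: float
    Vfil: float
    Tm: float


def derive_rates(physio: PhysioParams, chem: ChemicalParams) -> DerivedRates:
    """Scale per-kg coefficients to whole-body rates and volumes.

    Cardiac output scales allometrically with BW^0.74; volumes and the
    maximum resorption rate scale linearly with body weight.
    """
    QC = physio.QCC * physio.BW**0.74
    Qfil = physio.QfilC * QC
    return DerivedRates(
        QC=QC,
        Qfil=Qfil,
        Vc=chem.VCC * physio.BW,
        Vfil=physio.VfilC * physio.BW,
        Tm=chem.Tmc * physio.BW,
    )


# ---------------------------------------------------------------------------
# structured-config I/O


def _to_dict(physio: PhysioParams, chem: ChemicalParams, meta: dict | None = None) -> dict:
    d = {
        "physiological": dataclasses.asdict(physio),
        "chemical": dataclasses.asdict(chem),
    }
    if meta:
        d["meta"] = dict(meta)
    return d


def save_params(path, physio: PhysioParams, chem: ChemicalParams, meta: dict | None = None):
    """Write a parameter set as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = _to_dict(physio, chem, meta)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def _from_dict(d: dict) -> tuple[PhysioParams, ChemicalParams, dict]:
    try:
        physio = PhysioParams(**d["physiological"])
        chem = ChemicalParams(**d["chemical"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed parameter config: {exc}") from exc
    return physio, chem, d.get("meta", {})


def load_params(path) -> tuple[PhysioParams, ChemicalParams, dict]:
    """Read a parameter set written by :func:`save_params`.

    Returns ``(physio, chem, meta)``; ``meta`` carries non-model annotations
    such as the chemical name or the reference human half-life.
    """
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_dict(d)


_FIXTURES = (
    "pfos_monkey",
    "pfoa_monkey",
    "pfoa_monkey_highbioav",
    "pfhxs_monkey",
    "pfos_human",
    "pfoa_human",
    "pfhxs_human",
)


def list_fixtures() -> tuple[str, ...]:
    return _FIXTURES


def load_fixture(name: str) -> tuple[PhysioParams, ChemicalParams, dict]:
    """Load one of the packaged chemical/species parameter sets.

    Available names: ``pfos_monkey``, ``pfoa_monkey``, ``pfoa_monkey_highbioav``
    (the PFOA animal refit under 90% bioavailability used for human scaling),
    ``pfhxs_monkey``, ``pfos_human``, ``pfoa_human``, ``pfhxs_human``.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")
    ref = resources.files("pfastk.data").joinpath(f"{name}.yaml")
    return _from_dict(yaml.safe_load(ref.read_text()))
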