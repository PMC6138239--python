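"""Renal-function calculators: eGFR and Cockcroft-Gault creatinine clearance.

Serum creatinine is expected in μmol/L throughout (the SI convention used in
New Zealand laboratories); weights in kg, heights in cm, ages in years.

The eGFR equation is the CKD-EPI-style creatinine equation

    eGFR = 141 · min(Cr/a, 1)^b · max(Cr/a, 1)^(-1.209) · 0.993^age · c · k

with sex-specific constants ``a`` (the creatinine knot, μmol/L), ``b`` (the
below-knot exponent) and ``c`` (the female multiplier), and ``k = 1.159`` for
patients carrying the ethnicity adjustment (Māori or Samoan ancestry in the
source cohort), 1 otherwise.

Creatinine clearance uses the Cockcroft-Gault equation in its μmol/L form,

    CrCl (mL/min) = (140 − age) · weight · F_sex / Cr,

with F_sex = 1.23 (male) / 1.04 (female), and a BMI-dependent choice of the
weight entering the formula: total body weight below BMI 18.5, ideal body
weight (Devine) for BMI 18.5-22.9, and adjusted body weight
IBW + 0.4·(TBW − IBW) at BMI ≥ 23.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

__all__ = [
    "PatientCovariates",
    "RenalResult",
    "egfr",
    "ideal_body_weight",
    "weight_for_crcl",
    "crcl_cockcroft_gault",
    "renal_profile",
    "convert_clearance",
    "read_covariates_csv",
]

Sex = Literal["male", "female"]

# eGFR sex-specific constants: creatinine knot a (μmol/L), exponent b,
# multiplier c.
_EGFR_CONSTANTS = {
    "male": (79.6, -0.411, 1.0),
    "female": (61.9, -0.329, 1.018),
}
_ETHNICITY_FACTOR = 1.159
_AGE_FACTOR = 0.993

# Cockcroft-Gault sex factors for creatinine in μmol/L
# (≈ 1/(0.815 μmol-per-mg conversion) folded into the classic 72-denominator form).
_CG_FACTOR = {"male": 1.23, "female": 1.04}

# Devine ideal body weight: base (kg) at 152.4 cm + 0.906 kg per cm above.
_IBW_BASE = {"male": 50.0, "female": 45.5}
_IBW_SLOPE_PER_CM = 0.906
_IBW_REF_HEIGHT_CM = 152.4


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics and serum creatinine for one patient.

    Units: age years, weight kg (total body weight), height cm,
    serum_creatinine μmol/L.
    """

    patient_id: str
    age: float
    sex: Sex
    weight: float
    height: float
    serum_creatinine: float
    ethnicity_adjustment: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}; expected 'male' or 'female'")
        for name in ("age", "weight", "height", "serum_creatinine"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v!r}")

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m²."""
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class RenalResult:
    """Bundle of renal-function quantities for one patient."""

    egfr: float  # mL/min/1.73 m²
    crcl: float  # mL/min
    bmi: float  # kg/m²
    weight_used: float  # kg
    weight_rule: Literal["TBW", "IBW", "ABW"]


def egfr(cov: PatientCovariates) -> float:
    """Estimated glomerular filtration rate, mL/min/1.73 m²."""
    a, b, c = _EGFR_CONSTANTS[cov.sex]
    ratio = cov.serum_creatinine / a
    k = _ETHNICITY_FACTOR if cov.ethnicity_adjustment else 1.0
    return (
        141.0
        * min(ratio, 1.0) ** b
        * max(ratio, 1.0) ** -1.209
        * _AGE_FACTOR**cov.age
        * c
        * k
    )


def ideal_body_weight(cov: PatientCovariates) -> float:
    """Devine ideal body weight (kg), floored at the sex-specific base."""
    base = _IBW_BASE[cov.sex]
    excess_cm = max(cov.height - _IBW_REF_HEIGHT_CM, 0.0)
    return base + _IBW_SLOPE_PER_CM * excess_cm


def weight_for_crcl(cov: PatientCovariates) -> tuple[float, str]:
    """Weight (kg) entering Cockcroft-Gault and the rule that selected it.

    TBW below BMI 18.5, IBW for BMI 18.5-22.9, adjusted body weight
    IBW + 0.4·(TBW − IBW) at BMI ≥ 23.  BMI is compared unrounded.
    """
    bmi = cov.bmi
    if bmi < 18.5:
        return cov.weight, "TBW"
    ibw = ideal_body_weight(cov)
    if bmi < 23.0:
        return ibw, "IBW"
    return ibw + 0.4 * (cov.weight - ibw), "ABW"


def crcl_cockcroft_gault(cov: PatientCovariates) -> float:
    """Creatinine clearance (mL/min) by the modified Cockcroft-Gault equation."""
    if cov.age >= 140:
        raise ValueError(f"age {cov.age} gives a non-positive Cockcroft-Gault numerator")
    weight_used, _ = weight_for_crcl(cov)
    return (140.0 - cov.age) * weight_used * _CG_FACTOR[cov.sex] / cov.serum_creatinine


def renal_profile(cov: PatientCovariates) -> RenalResult:
    """All renal-function quantities for one patient."""
    weight_used, rule = weight_for_crcl(cov)
    return RenalResult(
        egfr=egfr(cov),
        crcl=crcl_cockcroft_gault(cov),
        bmi=cov.bmi,
        weight_used=weight_used,
        weight_rule=rule,
    )


_CLEARANCE_FACTORS = {("L/h", "mL/min"): 1000.0 / 60.0}


def convert_clearance(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a clearance between L/h and mL/min (exact factor 1000/60)."""
    if from_unit == to_unit and from_unit in ("L/h", "mL/min"):
        return value
    if (from_unit, to_unit) in _CLEARANCE_FACTORS:
        return value * _CLEARANCE_FACTORS[(from_unit, to_unit)]
    if (to_unit, from_unit) in _CLEARANCE_FACTORS:
        return value / _CLEARANCE_FACTORS[(to_unit, from_unit)]
    raise ValueError(f"cannot convert clearance from {from_unit!r} to {to_unit!r}")


_DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "age": "age",
    "sex": "sex",
    "weight": "weight",
    "height": "height",
    "serum_creatinine": "serum_creatinine",
    "ethnicity_adjustment": "ethnicity_adjustment",
}


def read_covariates_csv(
    path, columns: dict[str, str] | None = None
) -> list[PatientCovariates]:
    """Read one patient per row from CSV.

    ``columns`` maps field names to CSV column names for files with
    nonstandard headers.  Units are fixed: years, kg, cm, μmol/L.
    """
    mapping = dict(_DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in mapping.values() if c not in df.columns and c != mapping["ethnicity_adjustment"]]
    if missing:
        raise ValueError(f"covariate file {path} is missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        eth_col = mapping["ethnicity_adjustment"]
        out.append(
            PatientCovariates(
                patient_id=str(row[mapping["patient_id"]]),
                age=float(row[mapping["age"]]),
                sex=str(row[mapping["sex"]]).lower(),
                weight=float(row[mapping["weight"]]),
                height=float(row[mapping["height"]]),
                serum_creatinine=float(row[mapping["serum_creatinine"]]),
                ethnicity_adjustment=bool(row[eth_col]) if eth_col in df.columns else False,
            )
        )
    return out
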