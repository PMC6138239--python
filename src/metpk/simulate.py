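"""Synthetic dose-escalation trial generator.

Emulates a three-cohort single-then-repeat-dose design in severe chronic
kidney disease: cohorts of 6 patients on 250/500/1000 mg once daily, a rich
first-dose profile (0, 2, 4, 6, 8, 24 h), and fasting pre-dose troughs at
weekly-ish visits over four weeks.  Patient heterogeneity enters through
correlated random effects on apparent clearance and absorption rate
(truncated bivariate normal on the natural scale, mirroring the fitting
assumption), and an additive Gaussian residual on each concentration.

Two mechanisms make the trough data interesting for the downstream
classifier, both switched on by default and fully parameterized:

* model breakdown — patients with creatinine clearance below a threshold
  accumulate drug beyond what the one-compartment model predicts; their
  troughs are multiplied by a patient-level factor drawn log-uniformly.
  This is a deliberately phenomenological device: it gives the trough
  classifier a planted signal with a known answer, not a kinetic theory.
* suspected protocol violations — with small probability a trough visit is
  drawn near the individual steady-state peak instead (as if the dose was
  taken before the blood draw); these are marked in the truth log.

Concentrations below the assay limit of quantification are reported at the
LOQ and flagged, never silently dropped.  All randomness flows from one
integer seed; the same seed gives byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pk
from .renal import PatientCovariates, weight_for_crcl

__all__ = [
    "TrialDesign",
    "PopulationTruth",
    "SyntheticTrial",
    "generate_covariates",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
    "load_config",
]

ML_MIN_PER_L_H = 1000.0 / 60.0


@dataclass(frozen=True)
class TrialDesign:
    """Sampling design of the trial."""

    n_per_cohort: int = 6
    doses: tuple[float, ...] = (250.0, 500.0, 1000.0)
    single_dose_sampling: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 24.0)
    trough_days: tuple[float, ...] = (1.0, 7.0, 14.0, 21.0, 25.0, 28.0)
    tau: float = 24.0
    loq: float = 0.02  # mg/L

    def __post_init__(self) -> None:
        times = np.asarray(self.single_dose_sampling)
        if np.any(times < 0) or np.any(np.diff(times) <= 0):
            raise ValueError("single_dose_sampling must be non-negative and strictly increasing")
        if not self.loq > 0:
            raise ValueError("loq must be positive")


@dataclass(frozen=True)
class PopulationTruth:
    """Generating parameters.

    Defaults are the population estimates for once-daily immediate-release
    metformin in CKD stage 4: K = 0.119 h⁻¹, ka = 0.65 h⁻¹, Cl/F = 29.6 L/h,
    between-patient SDs 11.56 L/h and 0.395 h⁻¹ with correlation 0.785,
    residual SD 0.095 mg/L, and baseline creatinine clearance uniform on
    18-49 mL/min.  Breakdown below 32 mL/min multiplies troughs by a
    log-uniform factor on [1.5, 4].
    """

    K: float = 0.119
    ka: float = 0.65
    cl_over_f: float = 29.6
    sd_cl: float = 11.56
    sd_ka: float = 0.395
    re_correlation: float = 0.785
    residual_sd: float = 0.095
    crcl_range_ml_min: tuple[float, float] = (18.0, 49.0)
    clearance_from_crcl: bool = False  # if True, individual Cl/F = ratio·CrCl
    cl_to_crcl_ratio: float = 17.4
    breakdown_threshold_ml_min: float = 32.0
    breakdown_factor_range: tuple[float, float] = (1.5, 4.0)
    breakdown_enabled: bool = True
    violation_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_cl < 0 or self.sd_ka < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if not -1 <= self.re_correlation <= 1:
            raise ValueError("re_correlation must lie in [-1, 1]")
        if not 0 <= self.violation_rate <= 1:
            raise ValueError("violation_rate must lie in [0, 1]")


@dataclass
class SyntheticTrial:
    """Generated fixture: analysis-facing tables plus a truth sidecar."""

    covariates: pd.DataFrame
    concentrations: pd.DataFrame  # single-dose profiles
    troughs: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _draw_random_effects(rng, n, sd_cl, sd_ka, rho, mean_cl, mean_ka, max_redraws=1000):
    """Correlated (ΔCl, Δka) pairs, redrawn until individual parameters are positive."""
    cov = np.array(
        [[sd_cl**2, rho * sd_cl * sd_ka], [rho * sd_cl * sd_ka, sd_ka**2]]
    )
    out = np.empty((n, 2))
    for i in range(n):
        for attempt in range(max_redraws):
            b = rng.multivariate_normal([0.0, 0.0], cov)
            if mean_cl + b[0] > 0 and mean_ka + b[1] > 0:
                out[i] = b
                break
        else:
            raise RuntimeError(
                f"could not draw positive individual parameters after {max_redraws} tries "
                f"(mean_cl={mean_cl}, sd_cl={sd_cl}, mean_ka={mean_ka}, sd_ka={sd_ka})"
            )
    return out


def _iqr_to_sd(iqr: float) -> float:
    # normal IQR = 2 * 0.6745 * sd
    return iqr / 1.349


def generate_covariates(
    n: int,
    seed: int,
    age_median: float = 66.0,
    age_iqr: float = 6.54,
    bmi_median: float = 38.0,
    bmi_iqr: float = 9.87,
    crcl_range_ml_min: tuple[float, float] = (18.0, 49.0),
    female_fraction: float = 4 / 18,
    ethnicity_fraction: float = 0.2,
) -> pd.DataFrame:
    """Draw a demographic table matching the study cohort's summaries.

    Ages are normal (median 66 y, IQR 6.54 y); BMI is log-normal
    (median 38 kg/m², IQR 9.87 kg/m²) truncated at 23 — everyone in the
    observed regime where the adjusted-body-weight rule applies.  Heights
    are sex-specific normals, weights back-solved from BMI, and serum
    creatinine back-solved so the Cockcroft-Gault clearance lands uniformly
    in ``crcl_range_ml_min``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mu_bmi = np.log(bmi_median)
    # lognormal IQR = median*(e^{q σ} − e^{−q σ}) with q = 0.6745
    q = 0.6745
    # solve for sigma: 2 median sinh(q σ) = IQR
    sigma_bmi = np.arcsinh(bmi_iqr / (2 * bmi_median)) / q
    for i in range(n):
        sex = "female" if rng.random() < female_fraction else "male"
        age = float(np.clip(rng.normal(age_median, _iqr_to_sd(age_iqr)), 30, 75))
        for _ in range(1000):
            bmi = float(np.exp(rng.normal(mu_bmi, sigma_bmi)))
            if bmi >= 23.0:
                break
        height = float(rng.normal(175.0, 7.0) if sex == "male" else rng.normal(161.0, 6.0))
        weight = bmi * (height / 100.0) ** 2
        crcl_target = float(rng.uniform(*crcl_range_ml_min))
        # invert Cockcroft-Gault for serum creatinine given the target CrCl
        probe = PatientCovariates(
            patient_id=f"P{i + 1:02d}", age=age, sex=sex, weight=weight,
            height=height, serum_creatinine=100.0,
            ethnicity_adjustment=bool(rng.random() < ethnicity_fraction),
        )
        w_used, _ = weight_for_crcl(probe)
        f_sex = 1.23 if sex == "male" else 1.04
        creat = (140.0 - age) * w_used * f_sex / crcl_target
        rows.append(
            {
                "patient_id": f"P{i + 1:02d}",
                "age": age,
                "sex": sex,
                "weight": weight,
                "height": height,
                "serum_creatinine": creat,
                "ethnicity_adjustment": probe.ethnicity_adjustment,
                "bmi": bmi,
                "crcl_ml_min": crcl_target,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    design: TrialDesign | None = None,
    truth: PopulationTruth | None = None,
    seed: int = 0,
) -> SyntheticTrial:
    """Generate one full synthetic trial.

    Returns covariates, single-dose concentration records, trough records,
    and a truth log (individual parameters, breakdown factors, violation
    visits) that never enters the analysis-facing tables.
    """
    design = design or TrialDesign()
    truth = truth or PopulationTruth()
    rng = np.random.default_rng(seed)

    n_total = design.n_per_cohort * len(design.doses)
    cov = generate_covariates(
        n_total, seed=int(rng.integers(2**31 - 1)),
        crcl_range_ml_min=truth.crcl_range_ml_min,
    )
    doses = np.repeat(design.doses, design.n_per_cohort)
    cov = cov.assign(dose=doses)

    mean_cl = truth.cl_to_crcl_ratio if truth.clearance_from_crcl else truth.cl_over_f
    re = _draw_random_effects(
        rng, n_total, truth.sd_cl, truth.sd_ka, truth.re_correlation,
        mean_cl, truth.ka,
    )

    conc_rows, trough_rows, truth_patients = [], [], []
    for idx, row in cov.reset_index(drop=True).iterrows():
        pid = row["patient_id"]
        dose = float(row["dose"])
        crcl_lh = row["crcl_ml_min"] / ML_MIN_PER_L_H
        if truth.clearance_from_crcl:
            cl_i = (truth.cl_to_crcl_ratio + re[idx, 0]) * crcl_lh
        else:
            cl_i = truth.cl_over_f + re[idx, 0]
        ka_i = truth.ka + re[idx, 1]
        p_i = pk.PKParameters(K=truth.K, ka=ka_i, cl_over_f=cl_i, dose=dose, tau=design.tau)

        # first-dose profile
        for t in design.single_dose_sampling:
            c_true = pk.concentration_single_dose(p_i, t)
            c_obs = max(c_true + rng.normal(0.0, truth.residual_sd), 0.0) if t > 0 else 0.0
            below = 0 < c_obs < design.loq
            conc_rows.append(
                {
                    "patient_id": pid,
                    "dose": dose,
                    "time": float(t),
                    "concentration": design.loq if below else c_obs,
                    "below_loq": bool(below),
                    "crcl_baseline": crcl_lh,
                }
            )

        # trough visits
        ss = pk.steady_state(p_i)
        breakdown = (
            truth.breakdown_enabled
            and row["crcl_ml_min"] < truth.breakdown_threshold_ml_min
        )
        factor = (
            float(np.exp(rng.uniform(*np.log(truth.breakdown_factor_range))))
            if breakdown
            else 1.0
        )
        violation_visits = []
        for visit, day in enumerate(design.trough_days, start=1):
            if rng.random() < truth.violation_rate:
                c_true = ss.c_max_ss
                violation_visits.append(visit)
            else:
                c_true = ss.c_min_ss * factor
            c_obs = max(c_true + rng.normal(0.0, truth.residual_sd), 0.0)
            below = c_obs < design.loq
            trough_rows.append(
                {
                    "patient_id": pid,
                    "visit": visit,
                    "day_post_first_dose": float(day),
                    "dose": dose,
                    "concentration": design.loq if below else c_obs,
                    "below_loq": bool(below),
                }
            )
        truth_patients.append(
            {
                "patient_id": pid,
                "dose": dose,
                "cl_over_f_i": cl_i,
                "ka_i": ka_i,
                "crcl_ml_min": float(row["crcl_ml_min"]),
                "breakdown": bool(breakdown),
                "breakdown_factor": factor,
                "violation_visits": violation_visits,
            }
        )

    truth_log = {
        "seed": seed,
        "design": asdict(design),
        "truth": asdict(truth),
        "patients": truth_patients,
    }
    return SyntheticTrial(
        covariates=cov,
        concentrations=pd.DataFrame(conc_rows),
        troughs=pd.DataFrame(trough_rows),
        truth=truth_log,
    )


def write_fixture(trial: SyntheticTrial, directory) -> dict[str, Path]:
    """Write the trial as CSVs plus a JSON truth sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "covariates": directory / "covariates.csv",
        "concentrations": directory / "concentrations.csv",
        "troughs": directory / "troughs.csv",
        "truth": directory / "truth.json",
    }
    trial.covariates.to_csv(paths["covariates"], index=False)
    trial.concentrations.to_csv(paths["concentrations"], index=False)
    trial.troughs.to_csv(paths["troughs"], index=False)
    paths["truth"].write_text(json.dumps(trial.truth, indent=1, default=float))
    return paths


_REQUIRED = {
    "concentrations": ["patient_id", "dose", "time", "concentration", "below_loq"],
    "troughs": ["patient_id", "visit", "day_post_first_dose", "dose", "concentration"],
    "covariates": ["patient_id", "age", "sex", "weight", "height", "serum_creatinine"],
}


def read_fixture(directory) -> SyntheticTrial:
    """Read a fixture back; raises with the file and missing columns on mismatch."""
    directory = Path(directory)
    frames = {}
    for name in ("covariates", "concentrations", "troughs"):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"fixture file missing: {path}")
        df = pd.read_csv(path)
        missing = [c for c in _REQUIRED[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        frames[name] = df
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticTrial(
        covariates=frames["covariates"],
        concentrations=frames["concentrations"],
        troughs=frames["troughs"],
        truth=truth,
    )


def load_config(path) -> tuple[TrialDesign, PopulationTruth, int]:
    """Load design/truth/seed from a YAML config; the seed is mandatory."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if "seed" not in cfg:
        raise ValueError(f"config {path} must set an explicit seed")
    design_kw = cfg.get("design", {})
    for key in ("doses", "single_dose_sampling", "trough_days"):
        if key in design_kw:
            design_kw[key] = tuple(design_kw[key])
    truth_kw = cfg.get("truth", {})
    for key in ("crcl_range_ml_min", "breakdown_factor_range"):
        if key in truth_kw:
            truth_kw[key] = tuple(truth_kw[key])
    return TrialDesign(**design_kw), PopulationTruth(**truth_kw), int(cfg["seed"])
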