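"""Trough-concentration diagnostics against model-implied steady-state bands.

Under once-daily dosing, the fitted single-dose population model implies
steady-state trough, average and peak concentrations, each with a 95%
confidence interval for the *mean* response (delta method).  Observed
pre-dose troughs are compared against those bands:

* a patient whose troughs sit above the trough band more than once is
  labeled Group 1 — evidence the one-compartment model under-predicts
  accumulation for them (in the source cohort this tracks creatinine
  clearance below ~32 mL/min);
* a visit whose trough lands inside the *peak* band, while the patient's
  other visits sit inside the trough band, is flagged as a suspected
  protocol violation (dose likely taken before the blood draw).  Flags are
  labels only; no observation is ever removed.

Because the bands are confidence intervals for the mean — not prediction
intervals — individual observations legitimately fall outside them; the
classification rule is about *consistent* exceedance, not single outliers.

The module also provides the supporting inference: an exact/asymptotic
Wilcoxon rank-sum comparison with a Hodges-Lehmann shift estimate, a
log-trough linear mixed model with backward elimination, and the
dose-by-renal-function table of predicted steady-state peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from . import pk
from .nlme import PopPKFit, delta_method
from .renal import convert_clearance

__all__ = [
    "TroughRecord",
    "Band",
    "SteadyStateBands",
    "TroughClassification",
    "steady_state_bands",
    "classify_patients",
    "flag_violations",
    "wilcoxon_rank_sum",
    "WilcoxonResult",
    "log_trough_lmm",
    "dose_recommendation_table",
]


@dataclass(frozen=True)
class TroughRecord:
    """One pre-dose trough observation."""

    patient_id: str
    visit: int
    day_post_first_dose: float
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class Band:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("band lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        """Closed-interval membership."""
        return self.lower <= x <= self.upper


@dataclass
class SteadyStateBands:
    """Per-dose 95% CI bands for mean c_min,ss / c_avg,ss / c_max,ss (mg/L)."""

    c_min: dict[float, Band] = field(default_factory=dict)
    c_avg: dict[float, Band] = field(default_factory=dict)
    c_max: dict[float, Band] = field(default_factory=dict)

    def for_dose(self, dose: float) -> tuple[Band, Band, Band]:
        try:
            return self.c_min[dose], self.c_avg[dose], self.c_max[dose]
        except KeyError:
            raise KeyError(f"no steady-state bands available for dose {dose} mg") from None


def steady_state_bands(
    fit: PopPKFit,
    doses=(250, 500, 1000),
    tau: float = 24.0,
    crcl: float | None = None,
    level: float = 0.95,
) -> SteadyStateBands:
    """Delta-method CI bands for the mean steady-state concentrations."""
    bands = SteadyStateBands()
    for d in doses:
        for attr, name in (("c_min", "c_min_ss"), ("c_avg", "c_avg_ss"), ("c_max", "c_max_ss")):
            de = delta_method(fit, name, dose=d, tau=tau, crcl=crcl, level=level)
            getattr(bands, attr)[float(d)] = Band(de.ci_lower, de.ci_upper)
    return bands


@dataclass
class TroughClassification:
    patient_id: str
    group: str  # "group1" | "group2"
    n_above_cmin_upper: int
    suspected_violation_visits: list[int]


def _trough_frame(troughs) -> pd.DataFrame:
    if isinstance(troughs, pd.DataFrame):
        return troughs
    return pd.DataFrame(
        {
            "patient_id": [t.patient_id for t in troughs],
            "visit": [t.visit for t in troughs],
            "day_post_first_dose": [t.day_post_first_dose for t in troughs],
            "concentration": [t.concentration for t in troughs],
        }
    )


def classify_patients(
    troughs: pd.DataFrame,
    bands: SteadyStateBands,
    dose_by_patient: dict[str, float] | None = None,
) -> list[TroughClassification]:
    """Group 1 iff strictly more than one trough exceeds the c_min,ss CI upper limit.

    Exceedance is a strict inequality: a value exactly on the boundary counts
    as inside the band (conservative toward Group 2).  ``troughs`` needs a
    ``dose`` column or an explicit patient→dose mapping.
    """
    df = _trough_frame(troughs)
    out = []
    flags = flag_violations(df, bands, dose_by_patient)
    for pid, g in df.groupby("patient_id", sort=True):
        dose = _dose_for(pid, g, dose_by_patient)
        band_min, _, _ = bands.for_dose(dose)
        n_above = int((g["concentration"] > band_min.upper).sum())
        out.append(
            TroughClassification(
                patient_id=str(pid),
                group="group1" if n_above > 1 else "group2",
                n_above_cmin_upper=n_above,
                suspected_violation_visits=flags.get(str(pid), []),
            )
        )
    return out


def _dose_for(pid, group_df, dose_by_patient):
    if dose_by_patient is not None:
        try:
            return float(dose_by_patient[str(pid)])
        except KeyError:
            raise KeyError(f"no dose mapping for patient {pid!r}") from None
    if "dose" not in group_df.columns:
        raise KeyError(f"troughs lack a 'dose' column and no mapping given (patient {pid!r})")
    return float(group_df["dose"].iloc[0])


def flag_violations(
    troughs: pd.DataFrame,
    bands: SteadyStateBands,
    dose_by_patient: dict[str, float] | None = None,
) -> dict[str, list[int]]:
    """Visits suspected of a pre-draw dose, per patient.

    The pattern: one or two of the patient's troughs lie inside the
    c_max,ss CI while every other trough lies inside the c_min,ss CI.
    Band membership is closed-interval.  Flags label visits; the data are
    never modified or removed.
    """
    df = _trough_frame(troughs)
    flags: dict[str, list[int]] = {}
    for pid, g in df.groupby("patient_id", sort=True):
        dose = _dose_for(pid, g, dose_by_patient)
        band_min, _, band_max = bands.for_dose(dose)
        in_max = g["concentration"].apply(band_max.contains)
        in_min = g["concentration"].apply(band_min.contains)
        n_peak = int(in_max.sum())
        if 1 <= n_peak <= 2 and bool(in_min[~in_max].all()):
            flags[str(pid)] = [int(v) for v in g.loc[in_max, "visit"]]
    return flags


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum / Mann-Whitney with Hodges-Lehmann shift estimate


@dataclass
class WilcoxonResult:
    W: float  # Mann-Whitney count of (x_i > y_j) pairs, ties ½
    p_two_sided: float
    hl_estimate: float
    hl_ci: tuple[float, float]
    method: str


def _u_distribution(n: int, m: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U for sample sizes n, m."""
    # recurrence: c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def table(a: int, b: int) -> tuple:
        if a == 0 or b == 0:
            return (1.0,) + (0.0,) * (a * b)
        prev_a = table(a - 1, b)
        prev_b = table(a, b - 1)
        out = []
        for u in range(a * b + 1):
            v = 0.0
            if u - b >= 0 and u - b < len(prev_a):
                v += prev_a[u - b]
            if u < len(prev_b):
                v += prev_b[u]
            out.append(v)
        return tuple(out)

    return np.array(table(n, m))


def wilcoxon_rank_sum(x, y, ci_level: float = 0.95) -> WilcoxonResult:
    """Two-sample rank-sum test with Hodges-Lehmann shift estimate.

    W counts pairs (x_i, y_j) with x_i > y_j (ties contribute ½).  The
    two-sided p-value is exact (full permutation distribution) when
    n_x·n_y ≤ 400 and there are no cross-sample ties, and a tie-corrected
    normal approximation otherwise.  The Hodges-Lehmann estimate is the
    median of the n_x·n_y pairwise differences with an exact
    order-statistic confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    diffs = np.subtract.outer(x, y).ravel()
    W = float(np.sum(diffs > 0) + 0.5 * np.sum(diffs == 0))
    has_ties = np.any(diffs == 0) or len(np.unique(np.concatenate([x, y]))) < n + m

    if n * m <= 400 and not has_ties:
        counts = _u_distribution(n, m)
        total = counts.sum()
        u = int(round(W))
        # two-sided: double the smaller tail, capped at 1
        lower = counts[: u + 1].sum() / total
        upper = counts[u:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal_tie_corrected"

    diffs_sorted = np.sort(diffs)
    hl = float(np.median(diffs_sorted))
    # order-statistic CI: find k with P(U <= k-1) <= alpha/2 from exact dist
    alpha = 1.0 - ci_level
    counts = _u_distribution(n, m) if n * m <= 2500 else None
    if counts is not None:
        cdf = np.cumsum(counts) / counts.sum()
        k = int(np.searchsorted(cdf, alpha / 2.0))  # largest k with cdf[k-1] <= α/2
    else:
        mu = n * m / 2.0
        sd = math.sqrt(n * m * (n + m + 1) / 12.0)
        k = int(math.floor(mu + stats.norm.ppf(alpha / 2.0) * sd))
    k = max(0, min(k, n * m - 1))
    lo = diffs_sorted[k]
    hi = diffs_sorted[n * m - 1 - k]
    return WilcoxonResult(W=W, p_two_sided=p, hl_estimate=hl, hl_ci=(float(lo), float(hi)), method=method)


# ---------------------------------------------------------------------------
# exploratory log-trough mixed model


def log_trough_lmm(
    troughs: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    start_with_interactions: bool = True,
) -> pd.DataFrame:
    """Linear mixed model for log trough concentration with backward elimination.

    Fixed effects start from dose, crcl and bmi with all two-way
    interactions; a patient random intercept absorbs the repeated measures.
    Non-significant terms (Wald, ``alpha``) are removed one per step,
    largest p first, interactions before main effects; a main effect is
    kept while any surviving interaction contains it.  Returns the
    coefficient table of the final model with 95% CIs and exponentiated
    effects.
    """
    df = troughs.merge(covariates, on="patient_id", how="inner", suffixes=("", "_cov"))
    if (df["concentration"] <= 0).any():
        raise ValueError("log model requires strictly positive trough concentrations")
    df = df.assign(log_conc=np.log(df["concentration"]))
    for col in ("dose", "crcl", "bmi"):
        if col not in df.columns:
            raise ValueError(f"covariates must provide a {col!r} column")

    mains = ["dose", "crcl", "bmi"]
    inters = ["dose:crcl", "dose:bmi", "crcl:bmi"] if start_with_interactions else []
    terms = mains + inters

    def fit(terms):
        formula = "log_conc ~ " + (" + ".join(terms) if terms else "1")
        model = smf.mixedlm(formula, df, groups=df["patient_id"])
        # near a zero random-intercept variance some optimizers hit singular
        # working matrices; fall through a chain of methods
        last_err = None
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                return model.fit(reml=True, method=method, maxiter=2000)
            except np.linalg.LinAlgError as err:  # pragma: no cover - data dependent
                last_err = err
        raise RuntimeError(f"mixed model failed to fit: {last_err}")

    while True:
        result = fit(terms)
        pvals = result.pvalues
        # candidates: interactions always droppable; mains only if in no interaction
        droppable = [t for t in terms if ":" in t] or [
            t for t in terms if all(t not in i.split(":") for i in terms if ":" in i)
        ]
        cand = [(t, pvals.get(t, np.nan)) for t in droppable if t in pvals.index]
        cand = [(t, p) for t, p in cand if np.isfinite(p) and p > alpha]
        if not cand:
            break
        worst = max(cand, key=lambda tp: tp[1])[0]
        terms = [t for t in terms if t != worst]
        if not terms:
            result = fit(terms)
            break

    conf = result.conf_int()
    rows = []
    for name in result.fe_params.index:
        beta = float(result.fe_params[name])
        rows.append(
            {
                "term": name,
                "estimate": beta,
                "se": float(result.bse_fe[name]),
                "ci_lower": float(conf.loc[name, 0]),
                "ci_upper": float(conf.loc[name, 1]),
                "p_value": float(result.pvalues[name]),
                "exp_estimate": math.exp(beta),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# renal dose individualization


def dose_recommendation_table(
    fit: PopPKFit,
    crcl_grid_ml_min=(30, 35, 40, 45, 50),
    doses=(250, 500, 1000),
    tau: float = 24.0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted steady-state peak concentration by dose and creatinine clearance.

    Requires the crcl_scaled fit (clearance = ratio · CrCl).  CrCl values are
    given in mL/min and converted internally; each cell carries a
    delta-method CI for the mean response.
    """
    if fit.model_variant != "crcl_scaled":
        raise ValueError("dose_recommendation_table needs a crcl_scaled fit")
    rows = []
    for crcl_ml_min in crcl_grid_ml_min:
        if crcl_ml_min <= 0:
            raise ValueError("CrCl must be positive")
        crcl_lh = convert_clearance(float(crcl_ml_min), "mL/min", "L/h")
        for d in doses:
            de = delta_method(fit, "c_max_ss", dose=float(d), tau=tau, crcl=crcl_lh, level=level)
            rows.append(
                {
                    "crcl_ml_min": float(crcl_ml_min),
                    "dose": float(d),
                    "c_max_ss": de.point,
                    "ci_lower": de.ci_lower,
                    "ci_upper": de.ci_upper,
                }
            )
    return pd.DataFrame(rows)
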