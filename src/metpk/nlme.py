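"""Nonlinear mixed-effects estimation for the one-compartment oral model.

The population model for patient i, observation j is

    y_ij = f(t_ij; K, ka + b_ka_i, cl_i) + ε_ij,      ε_ij ~ N(0, σ²)

where f is the Bateman curve, and patient-level random intercepts act
additively on the natural scale of clearance and absorption:

    plain variant:        cl_i = Cl/F + b_cl_i
    crcl_scaled variant:  cl_i = ((Cl/F)′ + b_cl_i) · CrCl_i

with (b_cl_i, b_ka_i) ~ N(0, Ψ), Ψ an unstructured 2×2 covariance.

The marginal likelihood integrates the random effects out with a Laplace
approximation: for each patient the mode of the penalized least-squares
problem is found by damped Gauss-Newton (analytic Jacobians), and the
integral is replaced by the Gaussian volume at that mode.  The seven
population parameters (K, ka, clearance parameter, two random-effect SDs,
their correlation, residual SD) are estimated on transformed scales
(log for positive quantities, atanh for the correlation) by quasi-Newton
maximization; the covariance of the fixed effects comes from the observed
information (numerical Hessian at the optimum).

Derived quantities (t_max, C_max, AUC, half-lives, steady-state
concentrations, ...) get standard errors and Wald confidence intervals by
the delta method applied to that covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import pk

__all__ = [
    "ConcentrationRecord",
    "PopPKFit",
    "DerivedEstimate",
    "records_to_frame",
    "initial_estimates",
    "fit_poppk",
    "information_criteria",
    "compare_models",
    "compute_blups",
    "delta_method",
    "derived_table",
    "TRANSFORMS",
]

LOG2 = math.log(2.0)


@dataclass(frozen=True)
class ConcentrationRecord:
    """One observed concentration: (patient, dose mg, time h postdose, mg/L)."""

    patient_id: str
    dose: float
    time: float
    concentration: float
    crcl_baseline: float | None = None  # L/h; required for the crcl_scaled variant

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be non-negative")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


def records_to_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "dose": [r.dose for r in records],
            "time": [r.time for r in records],
            "concentration": [r.concentration for r in records],
            "crcl_baseline": [r.crcl_baseline for r in records],
        }
    )


@dataclass
class DerivedEstimate:
    """A derived quantity with delta-method SE and Wald CI (native units)."""

    name: str
    point: float
    se: float
    ci_lower: float
    ci_upper: float


@dataclass
class PopPKFit:
    """Result of a population-PK fit.

    ``fixed_effects`` holds (K, ka, clearance_parameter) on the natural scale;
    the clearance parameter is Cl/F (L/h) for the plain variant and the
    dimensionless (Cl/F)/CrCl ratio for the crcl_scaled variant.
    """

    model_variant: Literal["plain", "crcl_scaled"]
    fixed_effects: dict[str, float]
    fixed_cov: np.ndarray  # 3×3, natural scale, order (K, ka, clearance)
    random_effect_sd: tuple[float, float]  # (sd_cl, sd_ka)
    random_effect_correlation: float
    residual_sd: float
    blups: pd.DataFrame  # per-patient individual parameters
    log_likelihood: float
    n_parameters: int
    n_observations: int
    n_patients: int
    aic: float
    bic: float
    converged: bool
    theta_internal: np.ndarray = field(repr=False, default=None)

    @property
    def clearance_name(self) -> str:
        return "cl_over_f" if self.model_variant == "plain" else "cl_over_f_ratio"


# ---------------------------------------------------------------------------
# model function and analytic Jacobian w.r.t. the random effects


def _patient_arrays(df: pd.DataFrame, variant: str):
    """Group the long-format data into per-patient arrays."""
    patients = []
    for pid, g in df.groupby("patient_id", sort=True):
        dose = g["dose"].to_numpy(float)
        if np.ptp(dose) > 0:
            raise ValueError(f"patient {pid!r} has more than one dose level")
        crcl = None
        if variant == "crcl_scaled":
            vals = g["crcl_baseline"].to_numpy(float)
            if np.any(~np.isfinite(vals)):
                raise ValueError(
                    f"patient {pid!r} lacks crcl_baseline required by the crcl_scaled variant"
                )
            crcl = float(vals[0])
        patients.append(
            {
                "id": str(pid),
                "dose": float(dose[0]),
                "t": g["time"].to_numpy(float),
                "y": g["concentration"].to_numpy(float),
                "crcl": crcl,
            }
        )
    return patients


# ---------------------------------------------------------------------------
# inner problem: per-patient random-effect modes, vectorized across patients
# (damped Gauss-Newton on the penalized least-squares objective)


def _pack_patients(patients):
    """Stack the per-patient data into padded (P, n_max) arrays."""
    P = len(patients)
    n_max = max(len(p["y"]) for p in patients)
    T = np.zeros((P, n_max))
    Y = np.zeros((P, n_max))
    W = np.zeros((P, n_max))
    dose = np.zeros(P)
    mult = np.ones(P)
    for i, p in enumerate(patients):
        n = len(p["y"])
        T[i, :n] = p["t"]
        Y[i, :n] = p["y"]
        W[i, :n] = 1.0
        dose[i] = p["dose"]
        if p["crcl"] is not None:
            mult[i] = p["crcl"]
    return {"T": T, "Y": Y, "W": W, "dose": dose, "mult": mult,
            "n_obs": W.sum(axis=1), "ids": [p["id"] for p in patients]}


def _vec_model_jac(packed, K, ka_i, cl_i):
    """Bateman curve and (df/dcl_param, df/dka) rows for all patients at once.

    ka_i, cl_i are per-patient vectors (P,); returns (P, n_max) arrays.
    A tiny nudge keeps ka_i away from K so the closed form stays conditioned;
    the fit objective is unaffected at this magnitude.
    """
    T = packed["T"]
    d = ka_i - K
    d = np.where(np.abs(d) < 1e-7, np.where(d >= 0, 1e-7, -1e-7), d)
    ka = K + d
    eK = np.exp(-K * T)
    ea = np.exp(-ka[:, None] * T)
    A = (packed["dose"] * K / cl_i)[:, None]
    u = (ka / d)[:, None]
    f = A * u * (eK - ea)
    dka = A * ((-K / d**2)[:, None] * (eK - ea) + u * T * ea)
    return f, dka


def _inner_objective(packed, B, K, ka0, clpar0, psi_inv, sigma2):
    """Objective, residuals and Jacobian stack for candidate modes B (P, 2)."""
    clp = clpar0 + B[:, 0]
    kai = ka0 + B[:, 1]
    valid = (clp > 0) & (kai > 0)
    clp_s = np.where(valid, clp, 1.0)
    kai_s = np.where(valid, kai, ka0)
    f, dka = _vec_model_jac(packed, K, kai_s, clp_s * packed["mult"])
    R = (packed["Y"] - f) * packed["W"]
    # df/db_cl = df/d(cl_i)·mult = -f/clp  (the crcl multiplier cancels)
    Jcl = -f / clp_s[:, None] * packed["W"]
    Jka = dka * packed["W"]
    rss = np.einsum("pn,pn->p", R, R)
    pen = np.einsum("pi,ij,pj->p", B, psi_inv, B)
    obj = np.where(valid, 0.5 * rss / sigma2 + 0.5 * pen, np.inf)
    return obj, R, Jcl, Jka, rss


def _solve2(H, g):
    """Batched 2x2 solve of H x = g (overflow during line search is benign:
    the resulting huge step is rejected by backtracking)."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] * H[:, 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        x0 = (H[:, 1, 1] * g[:, 0] - H[:, 0, 1] * g[:, 1]) / det
        x1 = (H[:, 0, 0] * g[:, 1] - H[:, 1, 0] * g[:, 0]) / det
        out = np.stack([x0, x1], axis=1)
    return np.nan_to_num(out, nan=0.0, posinf=1e150, neginf=-1e150)


def _inner_modes(packed, K, ka0, clpar0, psi_inv, sigma2, B0,
                 max_iter=50, grad_tol=1e-9):
    """Penalized least-squares modes for every patient.

    Minimizes ||y_i - f_i(b)||²/(2σ²) + bᵀΨ⁻¹b/2 over b = (b_cl, b_ka) for
    each patient by Gauss-Newton with per-patient step halving, keeping the
    individual clearance parameter and absorption rate positive.
    Returns (B_hat, rss, H = JᵀJ/σ² + Ψ⁻¹ per patient, logdet H).
    """
    B = np.array(B0, dtype=float)
    obj, R, Jcl, Jka, rss = _inner_objective(packed, B, K, ka0, clpar0, psi_inv, sigma2)
    bad = ~np.isfinite(obj)
    if bad.any():
        B[bad] = 0.0
        obj, R, Jcl, Jka, rss = _inner_objective(packed, B, K, ka0, clpar0, psi_inv, sigma2)

    def hess_grad(B, R, Jcl, Jka):
        H = np.empty((len(B), 2, 2))
        H[:, 0, 0] = np.einsum("pn,pn->p", Jcl, Jcl) / sigma2 + psi_inv[0, 0]
        H[:, 0, 1] = H[:, 1, 0] = (
            np.einsum("pn,pn->p", Jcl, Jka) / sigma2 + psi_inv[0, 1]
        )
        H[:, 1, 1] = np.einsum("pn,pn->p", Jka, Jka) / sigma2 + psi_inv[1, 1]
        g = np.stack(
            [
                -np.einsum("pn,pn->p", Jcl, R) / sigma2,
                -np.einsum("pn,pn->p", Jka, R) / sigma2,
            ],
            axis=1,
        ) + B @ psi_inv
        return H, g

    # patients whose objective can no longer be improved (stalled at float
    # precision) are frozen for the rest of this call; the decision depends
    # only on (parameters, B0), so the likelihood stays a deterministic
    # function of its inputs
    stalled = np.zeros(len(B), dtype=bool)
    for _ in range(max_iter):
        H, g = hess_grad(B, R, Jcl, Jka)
        active = (~stalled) & (
            np.linalg.norm(g, axis=1) >= grad_tol * (1.0 + np.abs(obj))
        )
        if not active.any():
            break
        step = _solve2(H, -g)
        step[~active] = 0.0
        scale = np.maximum(np.abs(B), 1.0)
        if np.all(np.abs(step) < 1e-12 * scale):
            break
        lam = np.ones(len(B))
        improved = ~active  # inactive patients count as done
        B_new = B.copy()
        for _ in range(20):
            trial = B + lam[:, None] * step
            obj_t, R_t, Jcl_t, Jka_t, rss_t = _inner_objective(
                packed, trial, K, ka0, clpar0, psi_inv, sigma2
            )
            good = active & ~improved & (obj_t < obj)
            if good.any():
                B_new[good] = trial[good]
                improved |= good
            if improved.all():
                break
            lam = np.where(improved, lam, lam * 0.5)
        stalled |= active & ~improved
        if not (improved & active).any():
            break
        B = B_new
        obj, R, Jcl, Jka, rss = _inner_objective(packed, B, K, ka0, clpar0, psi_inv, sigma2)

    H, _ = hess_grad(B, R, Jcl, Jka)
    det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
    logdet = np.log(np.maximum(det, 1e-300))
    return B, rss, H, logdet


def _unpack(x):
    K = math.exp(x[0])
    ka = math.exp(x[1])
    clpar = math.exp(x[2])
    sd_cl = math.exp(x[3])
    sd_ka = math.exp(x[4])
    rho = math.tanh(x[5])
    sigma = math.exp(x[6])
    return K, ka, clpar, sd_cl, sd_ka, rho, sigma


def _psi(sd_cl, sd_ka, rho):
    return np.array(
        [
            [sd_cl**2, rho * sd_cl * sd_ka],
            [rho * sd_cl * sd_ka, sd_ka**2],
        ]
    )


def _laplace_loglik(x, packed, warm):
    """Laplace-approximate marginal log-likelihood at internal parameters x.

    ``warm`` carries the previous random-effect modes (P, 2) across calls so
    each evaluation starts its inner Gauss-Newton near the solution.
    """
    K, ka, clpar, sd_cl, sd_ka, rho, sigma = _unpack(x)
    psi = _psi(sd_cl, sd_ka, rho)
    det_psi = psi[0, 0] * psi[1, 1] - psi[0, 1] ** 2
    if det_psi <= 0:
        return -np.inf
    psi_inv = np.linalg.inv(psi)
    logdet_psi = math.log(det_psi)
    sigma2 = sigma**2
    B0 = warm.get("B", np.zeros((len(packed["ids"]), 2)))
    B, rss, H, logdet_H = _inner_modes(packed, K, ka, clpar, psi_inv, sigma2, B0)
    warm["B"] = B
    det_H = np.exp(logdet_H)
    if np.any(det_H <= 0) or np.any(~np.isfinite(logdet_H)):
        return -np.inf
    pen = np.einsum("pi,ij,pj->p", B, psi_inv, B)
    ll = np.sum(
        -0.5 * packed["n_obs"] * math.log(2 * math.pi * sigma2)
        - 0.5 * rss / sigma2
        - 0.5 * pen
        - 0.5 * logdet_psi
        - 0.5 * logdet_H
    )
    return float(ll)


# ---------------------------------------------------------------------------
# deterministic initial values


def initial_estimates(df: pd.DataFrame, variant: str = "plain") -> dict[str, float]:
    """Starting values from dose-normalized pooled data.

    The terminal slope of the pooled log dose-normalized concentrations at
    t ≥ 8 h gives K; the method of residuals (back-extrapolated terminal
    line minus early observations) gives ka; clearance comes from
    dose / AUC with a trapezoidal AUC extrapolated by the terminal slope.
    A pooled nonlinear least-squares polish makes the values stable.
    """
    d = df[(df["time"] > 0) & (df["concentration"] > 0)]
    t = d["time"].to_numpy(float)
    ynorm = d["concentration"].to_numpy(float) / d["dose"].to_numpy(float)

    term = t >= 8
    if term.sum() >= 2 and np.ptp(t[term]) > 0:
        slope, intercept = np.polyfit(t[term], np.log(ynorm[term]), 1)
        K0 = max(-slope, 1e-3)
    else:
        K0, intercept = 0.1, math.log(max(ynorm.mean(), 1e-9))
    early = t < 8
    resid = np.exp(intercept + (-K0) * t[early]) - ynorm[early]
    ok = resid > 0
    if ok.sum() >= 2 and np.ptp(t[early][ok]) > 0:
        slope_a, _ = np.polyfit(t[early][ok], np.log(resid[ok]), 1)
        ka0 = max(-slope_a, K0 * 1.5)
    else:
        ka0 = K0 * 5.0

    # trapezoidal AUC per patient, extrapolated with the terminal slope
    cls = []
    for pid, g in df[df["concentration"] > 0].groupby("patient_id"):
        g = g.sort_values("time")
        tt, yy = g["time"].to_numpy(float), g["concentration"].to_numpy(float)
        if len(tt) < 3:
            continue
        auc = np.trapezoid(yy, tt) + yy[-1] / K0
        cls.append(float(g["dose"].iloc[0]) / auc)
    cl0 = float(np.median(cls)) if cls else 30.0

    # pooled NLS polish on (log K, log ka, log Cl)
    dd = df[(df["time"] > 0)]
    tt = dd["time"].to_numpy(float)
    yy = dd["concentration"].to_numpy(float)
    doses = dd["dose"].to_numpy(float)

    def resid_fn(logp):
        Kp, kap, clp = np.exp(logp)
        return pk.bateman(tt, 1.0, Kp, kap, clp) * doses - yy

    sol = optimize.least_squares(
        resid_fn,
        np.log([K0, ka0, cl0]),
        method="lm",
        max_nfev=2000,
    )
    K0, ka0, cl0 = np.exp(sol.x)
    sigma0 = max(float(np.std(sol.fun)), 1e-3)

    if variant == "crcl_scaled":
        crcl = df.groupby("patient_id")["crcl_baseline"].first().to_numpy(float)
        cl0 = cl0 / float(np.mean(crcl))

    return {
        "K": float(K0),
        "ka": float(ka0),
        "clearance": float(cl0),
        "sd_cl": 0.3 * float(cl0),
        "sd_ka": 0.5 * float(ka0),
        "corr": 0.0,
        "sigma": sigma0,
    }


# ---------------------------------------------------------------------------
# the fit


def fit_poppk(
    data: pd.DataFrame | Sequence[ConcentrationRecord],
    variant: Literal["plain", "crcl_scaled"] = "plain",
    include_baseline_zeros: bool = False,
    init: dict[str, float] | None = None,
    maxiter: int = 400,
) -> PopPKFit:
    """Fit the population model by maximum (Laplace) marginal likelihood.

    ``data`` is long-format with columns patient_id, dose, time,
    concentration, and crcl_baseline (L/h, needed for variant='crcl_scaled');
    rows flagged ``below_loq`` are excluded.  Pre-dose zero-concentration
    records carry no information under the additive-error model (the model
    predicts exactly zero there) and are dropped unless
    ``include_baseline_zeros`` is set.

    Deterministic given the data, initial values and tolerances.  Raises
    RuntimeError on non-convergence or a singular information matrix.
    """
    if not isinstance(data, pd.DataFrame):
        data = records_to_frame(data)
    df = data.copy()
    if "below_loq" in df.columns:
        df = df[~df["below_loq"].astype(bool)]
    if not include_baseline_zeros:
        df = df[~((df["time"] == 0) & (df["concentration"] == 0))]
    if df["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    if (df.groupby("patient_id").size() < 3).any():
        raise ValueError("need at least 3 observations per patient")
    if "crcl_baseline" not in df.columns:
        df["crcl_baseline"] = np.nan

    patients = _patient_arrays(df, variant)
    packed = _pack_patients(patients)
    n_obs = len(df)

    ini = init or initial_estimates(df, variant)
    x0 = np.array(
        [
            math.log(ini["K"]),
            math.log(ini["ka"]),
            math.log(ini["clearance"]),
            math.log(max(ini["sd_cl"], 1e-6)),
            math.log(max(ini["sd_ka"], 1e-6)),
            math.atanh(np.clip(ini.get("corr", 0.0), -0.99, 0.99)),
            math.log(ini["sigma"]),
        ]
    )

    warm: dict[str, np.ndarray] = {}
    ll0 = _laplace_loglik(x0, packed, warm)
    if not np.isfinite(ll0):
        raise RuntimeError("initial values give a degenerate likelihood")

    def neg_ll(x):
        v = _laplace_loglik(x, packed, warm)
        return -v if np.isfinite(v) else 1e12

    bounds = [(-12, 8)] * 3 + [(-14, 8), (-14, 8), (-4, 4), (-12, 4)]
    res = optimize.minimize(
        neg_ll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    # Derivative-free polish: finite-difference gradients are noisy along the
    # flat ka/clearance ridge, so a short Nelder-Mead refinement recovers the
    # last fraction of a percent of the optimum.  Nelder-Mead is unbounded,
    # so the objective clips to the box (variance parameters may legitimately
    # sit on a bound, e.g. sigma on noise-free data).
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def neg_ll_boxed(x):
        return neg_ll(np.clip(x, lo, hi))

    polish = optimize.minimize(
        neg_ll_boxed, res.x, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
    )
    if polish.fun <= res.fun:
        x_hat = np.clip(polish.x, lo, hi)
        ll_hat = -polish.fun
    else:
        x_hat = res.x
        ll_hat = -res.fun
    if not np.isfinite(ll_hat) or ll_hat < ll0 - 1e-6:
        raise RuntimeError(
            f"optimizer failed to improve the marginal likelihood (status: {res.message})"
        )

    K, ka, clpar, sd_cl, sd_ka, rho, sigma = _unpack(x_hat)

    # observed information for the fixed effects (numerical Hessian on the
    # internal scale, then chain rule to the natural scale)
    hess = _numerical_hessian(neg_ll, x_hat)
    fixed_cov = _fixed_effects_cov(hess, x_hat)

    blups = _blups_frame(packed, x_hat, variant, warm)

    p = 7  # 3 fixed effects + 2 SDs + correlation + residual SD
    aic = -2 * ll_hat + 2 * p
    bic = -2 * ll_hat + p * math.log(n_obs)
    clearance_name = "cl_over_f" if variant == "plain" else "cl_over_f_ratio"
    return PopPKFit(
        model_variant=variant,
        fixed_effects={"K": K, "ka": ka, clearance_name: clpar},
        fixed_cov=fixed_cov,
        random_effect_sd=(sd_cl, sd_ka),
        random_effect_correlation=rho,
        residual_sd=sigma,
        blups=blups,
        log_likelihood=ll_hat,
        n_parameters=p,
        n_observations=n_obs,
        n_patients=len(patients),
        aic=aic,
        bic=bic,
        converged=bool(res.success or ll_hat >= ll0),
        theta_internal=x_hat,
    )


def _numerical_hessian(fun, x, rel_step=1e-4):
    n = len(x)
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.zeros((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            if i == j:
                H[i, i] = (fun(x + ei) - 2 * f0 + fun(x - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


_PARAM_NAMES = ["K", "ka", "clearance", "sd_cl", "sd_ka", "corr", "sigma"]


def _fixed_effects_cov(hess, x_hat):
    diag = np.diag(hess)
    tol = 1e-10 * max(diag.max(), 1.0)
    flat = diag <= tol
    if flat[:3].any():
        worst = _PARAM_NAMES[int(np.argmin(diag[:3]))]
        raise RuntimeError(
            f"singular information matrix: no curvature in parameter {worst!r}"
        )
    # variance components pinned at a boundary (e.g. SDs collapsing to zero
    # on noise-free data) contribute no curvature; treat them as fixed and
    # invert the information over the remaining parameters
    keep = np.flatnonzero(~flat)
    sub = hess[np.ix_(keep, keep)]
    eigvals = np.linalg.eigvalsh(sub)
    if eigvals.min() <= 0:
        worst = _PARAM_NAMES[int(keep[int(np.argmin(eigvals))])]
        raise RuntimeError(
            f"singular information matrix: non-positive curvature near parameter {worst!r}"
        )
    cov_sub = np.linalg.inv(sub)
    cov_internal = np.zeros_like(hess)
    cov_internal[np.ix_(keep, keep)] = cov_sub
    # natural fixed effects are exp of the first three internal coordinates
    scale = np.exp(x_hat[:3])
    return cov_internal[:3, :3] * np.outer(scale, scale)


def _blups_frame(packed, x_hat, variant, warm):
    K, ka, clpar, sd_cl, sd_ka, rho, sigma = _unpack(x_hat)
    psi_inv = np.linalg.inv(_psi(sd_cl, sd_ka, rho))
    B0 = warm.get("B", np.zeros((len(packed["ids"]), 2)))
    B, _, _, _ = _inner_modes(packed, K, ka, clpar, psi_inv, sigma**2, B0)
    col = "cl_over_f_i" if variant == "plain" else "cl_over_f_ratio_i"
    return pd.DataFrame(
        {
            "patient_id": packed["ids"],
            "b_cl": B[:, 0],
            "b_ka": B[:, 1],
            col: clpar + B[:, 0],
            "ka_i": ka + B[:, 1],
        }
    )


def compute_blups(fit: PopPKFit, data: pd.DataFrame | Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Per-patient empirical Bayes modes at the fitted population parameters."""
    if not isinstance(data, pd.DataFrame):
        data = records_to_frame(data)
    df = data.copy()
    if "below_loq" in df.columns:
        df = df[~df["below_loq"].astype(bool)]
    df = df[~((df["time"] == 0) & (df["concentration"] == 0))]
    if "crcl_baseline" not in df.columns:
        df["crcl_baseline"] = np.nan
    packed = _pack_patients(_patient_arrays(df, fit.model_variant))
    return _blups_frame(packed, fit.theta_internal, fit.model_variant, {})


def information_criteria(fit: PopPKFit) -> tuple[float, float]:
    """(AIC, BIC) = (−2ℓ + 2p, −2ℓ + p·ln n)."""
    return fit.aic, fit.bic


def compare_models(fit_a: PopPKFit, fit_b: PopPKFit) -> dict:
    """Smaller-is-better AIC/BIC comparison of two fits."""
    return {
        "aic": (fit_a.aic, fit_b.aic),
        "bic": (fit_a.bic, fit_b.bic),
        "aic_winner": fit_a.model_variant if fit_a.aic < fit_b.aic else fit_b.model_variant,
        "bic_winner": fit_a.model_variant if fit_a.bic < fit_b.bic else fit_b.model_variant,
    }


# ---------------------------------------------------------------------------
# delta method


def _params_from_fixed(fit: PopPKFit, theta, dose, tau, crcl=None):
    K, ka, clpar = theta
    if fit.model_variant == "plain":
        cl = clpar
    else:
        if crcl is None:
            raise ValueError("crcl (L/h) required for crcl_scaled transforms")
        cl = clpar * crcl
    return pk.PKParameters(K=K, ka=ka, cl_over_f=cl, dose=dose, tau=tau)


def _make_transforms() -> dict[str, Callable]:
    t = {
        "t_max": lambda p: pk.t_max_single(p),
        "c_max": lambda p: pk.c_max_single(p),
        "auc_inf": lambda p: pk.auc_inf(p),
        "t_half_elim": lambda p: pk.half_lives(p)[0],
        "t_half_abs": lambda p: pk.half_lives(p)[1],
        "v_over_f": lambda p: p.cl_over_f / p.K,
        "c_min_ss": lambda p: pk.steady_state(p).c_min_ss,
        "c_avg_ss": lambda p: pk.steady_state(p).c_avg_ss,
        "c_max_ss": lambda p: pk.steady_state(p).c_max_ss,
        "t_max_ss": lambda p: pk.steady_state(p).t_max_ss,
    }
    return t


TRANSFORMS = _make_transforms()


def delta_method(
    fit: PopPKFit,
    transform: str | Callable[[np.ndarray], float],
    dose: float = 0.0,
    tau: float = 24.0,
    crcl: float | None = None,
    level: float = 0.95,
) -> DerivedEstimate:
    """Delta-method SE and Wald CI for a function of the fixed effects.

    ``transform`` is either a registered name (see ``TRANSFORMS``; dose, tau
    and — for the crcl_scaled variant — crcl in L/h are forwarded) or a
    callable taking the natural-scale fixed-effect vector
    (K, ka, clearance parameter).
    """
    theta = np.array(
        [fit.fixed_effects["K"], fit.fixed_effects["ka"], fit.fixed_effects[fit.clearance_name]]
    )
    if isinstance(transform, str):
        name = transform
        fn_pk = TRANSFORMS[transform]

        def fn(th):
            return fn_pk(_params_from_fixed(fit, th, dose, tau, crcl))

    else:
        name = getattr(transform, "__name__", "transform")
        fn = transform

    point = float(fn(theta))
    grad = np.zeros(3)
    for i in range(3):
        h = 1e-6 * max(abs(theta[i]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grad[i] = (fn(tp) - fn(tm)) / (2 * h)
    if not np.all(np.isfinite(grad)):
        raise RuntimeError(f"non-finite gradient in delta-method transform {name!r}")
    se = float(np.sqrt(grad @ fit.fixed_cov @ grad))
    z = stats.norm.ppf(0.5 + level / 2)
    return DerivedEstimate(
        name=name, point=point, se=se, ci_lower=point - z * se, ci_upper=point + z * se
    )


def derived_table(
    fit: PopPKFit,
    doses: Sequence[float] = (250, 500, 1000),
    tau: float = 24.0,
    crcl: float | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Fixed-effect estimates plus delta-method CIs for the derived quantities.

    Mirrors the usual report layout: rate constants, half-lives, clearance,
    V/F, t_max, then dose-specific C_max and AUC rows.
    """
    rows = []
    z = stats.norm.ppf(0.5 + level / 2)
    theta_names = ["K", "ka", fit.clearance_name]
    for i, nm in enumerate(theta_names):
        est = fit.fixed_effects[nm]
        se = math.sqrt(fit.fixed_cov[i, i])
        rows.append({"parameter": nm, "dose": None, "estimate": est,
                     "ci_lower": est - z * se, "ci_upper": est + z * se})
    for nm in ("t_half_elim", "t_half_abs", "t_max"):
        de = delta_method(fit, nm, tau=tau, crcl=crcl, level=level)
        rows.append({"parameter": nm, "dose": None, "estimate": de.point,
                     "ci_lower": de.ci_lower, "ci_upper": de.ci_upper})
    if fit.model_variant == "plain":
        de = delta_method(fit, "v_over_f", tau=tau, level=level)
        rows.append({"parameter": "v_over_f", "dose": None, "estimate": de.point,
                     "ci_lower": de.ci_lower, "ci_upper": de.ci_upper})
    for d in doses:
        for nm in ("c_max", "auc_inf"):
            de = delta_method(fit, nm, dose=d, tau=tau, crcl=crcl, level=level)
            rows.append({"parameter": nm, "dose": d, "estimate": de.point,
                         "ci_lower": de.ci_lower, "ci_upper": de.ci_upper})
    return pd.DataFrame(rows)
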