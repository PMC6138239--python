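"""Closed-form one-compartment oral-absorption pharmacokinetics.

Single-dose concentrations follow the Bateman equation

    c(t) = D·K·ka / [(Cl/F)·(ka − K)] · (exp(−K·t) − exp(−ka·t)),

with dose D (mg), absorption and elimination rate constants ka and K (1/h),
and apparent oral clearance Cl/F (L/h).  With ka > K this prefactor sign
gives non-negative concentrations; the degenerate ka = K case is handled by
its analytic limit c(t) = D·K²·t·exp(−K·t)/(Cl/F) so optimizers can cross
the boundary.

Steady state under repeated dosing every τ hours replaces each exponential
exp(−k·t) by its geometric accumulation exp(−k·t)/(1 − exp(−k·τ)); the
module provides troughs, averages, peaks, the steady-state time-to-peak, and
an explicit n-dose superposition sum used as an independent cross-check.

Clearance may alternatively be specified as a dimensionless ratio to the
patient's creatinine clearance ((Cl/F)/CrCl), the form used for renal dose
individualization: effective clearance = ratio · CrCl (CrCl in L/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PKParameters",
    "CrClScaledPKParameters",
    "DerivedPK",
    "SteadyStatePK",
    "concentration_single_dose",
    "concentration_crcl",
    "t_max_single",
    "c_max_single",
    "auc_inf",
    "half_lives",
    "time_to_steady_state",
    "derived_parameters",
    "steady_state",
    "superposition_oracle",
]

# |ka - K| below which the Bateman closed form switches to its series
# expansion around ka = K (second order in (ka-K)·t, so the two branches
# agree to ~1e-8 relative at the boundary).
_RATE_EQ_TOL = 1e-6


@dataclass(frozen=True)
class PKParameters:
    """Fixed-effect parameters of the one-compartment oral model.

    K and ka in 1/h, cl_over_f in L/h, dose in mg, dosing interval tau in h.
    """

    K: float
    ka: float
    cl_over_f: float
    dose: float = 0.0
    tau: float = 24.0

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.ka > 0 and self.cl_over_f > 0):
            raise ValueError("K, ka and cl_over_f must all be positive")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.tau > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class CrClScaledPKParameters:
    """Parameters with clearance expressed as a ratio to creatinine clearance.

    cl_over_f_ratio is dimensionless; crcl is in L/h; effective apparent
    clearance is cl_over_f_ratio · crcl.
    """

    K: float
    ka: float
    cl_over_f_ratio: float
    crcl: float
    dose: float = 0.0
    tau: float = 24.0

    def __post_init__(self) -> None:
        if not (self.K > 0 and self.ka > 0 and self.cl_over_f_ratio > 0 and self.crcl > 0):
            raise ValueError("K, ka, cl_over_f_ratio and crcl must all be positive")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    def to_plain(self) -> PKParameters:
        return PKParameters(
            K=self.K,
            ka=self.ka,
            cl_over_f=self.cl_over_f_ratio * self.crcl,
            dose=self.dose,
            tau=self.tau,
        )


@dataclass(frozen=True)
class DerivedPK:
    """Derived single-dose quantities (t in h, c in mg/L, AUC in mg·h/L, V in L)."""

    t_max: float
    c_max: float
    auc_inf: float
    t_half_elim: float
    t_half_abs: float
    v_over_f: float


@dataclass(frozen=True)
class SteadyStatePK:
    """Steady-state concentrations (mg/L) and time of peak (h) under τ-dosing."""

    c_min_ss: float
    c_avg_ss: float
    c_max_ss: float
    t_max_ss: float


def _as_plain(p: PKParameters | CrClScaledPKParameters) -> PKParameters:
    return p.to_plain() if isinstance(p, CrClScaledPKParameters) else p


def bateman(
    t, dose: float, K: float, ka: float, cl_over_f: float
):
    """Single-dose concentration at time(s) ``t`` (h) for raw parameter values.

    Vectorized over ``t``; used directly by the fitting machinery, which works
    on unchecked floats.  Handles the ka = K limit.
    """
    t = np.asarray(t, dtype=float)
    d = ka - K
    if abs(d) < _RATE_EQ_TOL:
        # (e^(-Kt) - e^(-ka t))/(ka-K) = t·e^(-Kt)·(1 - dt/2 + (dt)²/6 - ...)
        dt = d * t
        out = (
            dose * K * ka / cl_over_f
            * t * np.exp(-K * t)
            * (1.0 - dt / 2.0 + dt**2 / 6.0)
        )
    else:
        pref = dose * K * ka / (cl_over_f * (ka - K))
        out = pref * (np.exp(-K * t) - np.exp(-ka * t))
    return out if out.ndim else float(out)


def concentration_single_dose(p: PKParameters | CrClScaledPKParameters, t):
    """Concentration (mg/L) at time ``t`` hours after a single oral dose."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    p = _as_plain(p)
    return bateman(t, p.dose, p.K, p.ka, p.cl_over_f)


def concentration_crcl(p: CrClScaledPKParameters, t):
    """Single-dose concentration for the CrCl-scaled clearance model."""
    return concentration_single_dose(p, t)


def t_max_single(p: PKParameters | CrClScaledPKParameters) -> float:
    """Time to maximum concentration after a single dose, h."""
    p = _as_plain(p)
    d = p.ka - p.K
    if abs(d) < _RATE_EQ_TOL:
        # ln(ka/K)/(ka-K) expanded around ka = K
        return 1.0 / p.K - d / (2.0 * p.K**2) + d**2 / (3.0 * p.K**3)
    return math.log(p.ka / p.K) / d


def c_max_single(p: PKParameters | CrClScaledPKParameters) -> float:
    """Maximum single-dose concentration, mg/L."""
    p = _as_plain(p)
    return float(bateman(t_max_single(p), p.dose, p.K, p.ka, p.cl_over_f))


def auc_inf(p: PKParameters | CrClScaledPKParameters) -> float:
    """Area under the single-dose curve over [0, ∞) = dose / (Cl/F), mg·h/L."""
    p = _as_plain(p)
    return p.dose / p.cl_over_f


def half_lives(p: PKParameters | CrClScaledPKParameters) -> tuple[float, float]:
    """(elimination half-life, absorption half-life) in hours."""
    p = _as_plain(p)
    return math.log(2.0) / p.K, math.log(2.0) / p.ka


def time_to_steady_state(
    p: PKParameters | CrClScaledPKParameters, n_half_lives: float = 5
) -> float:
    """Approximate time to steady state, h.

    The conventional rule of ``n_half_lives`` elimination half-lives
    (default 5, i.e. ~97% of the asymptote).
    """
    p = _as_plain(p)
    return n_half_lives * math.log(2.0) / p.K


def derived_parameters(p: PKParameters | CrClScaledPKParameters) -> DerivedPK:
    """All derived single-dose PK quantities."""
    p = _as_plain(p)
    th_k, th_ka = half_lives(p)
    return DerivedPK(
        t_max=t_max_single(p),
        c_max=c_max_single(p),
        auc_inf=auc_inf(p),
        t_half_elim=th_k,
        t_half_abs=th_ka,
        v_over_f=p.cl_over_f / p.K,
    )


# the steady-state forms keep a zeroth-order ka=K limit, switched much closer
# to the boundary (the O(|ka-K|) error there is below 1e-7 relative)
_SS_EQ_TOL = 1e-9


def _accumulated(t: float, dose, K, ka, cl_over_f, tau) -> float:
    # steady-state profile: each exponential picks up its 1/(1-e^{-k tau}) factor
    if abs(ka - K) < _SS_EQ_TOL:
        # limit of the accumulation-factor form as ka -> K
        eK = math.exp(-K * tau)
        aK = 1.0 - eK
        term = (t * math.exp(-K * t) / aK
                + tau * eK * math.exp(-K * t) / aK**2)
        return dose * K * K / cl_over_f * term
    pref = dose * K * ka / (cl_over_f * (ka - K))
    return pref * (
        math.exp(-K * t) / (1.0 - math.exp(-K * tau))
        - math.exp(-ka * t) / (1.0 - math.exp(-ka * tau))
    )


def steady_state(p: PKParameters | CrClScaledPKParameters) -> SteadyStatePK:
    """Steady-state trough, average and peak concentrations for τ-interval dosing.

    c_min,ss is the accumulated profile at t = τ (immediately before the next
    dose); c_avg,ss = D/[(Cl/F)·τ]; c_max,ss is the accumulated profile at

        t_max,ss = ln[ka(1 − e^(−Kτ)) / (K(1 − e^(−kaτ)))] / (ka − K).
    """
    p = _as_plain(p)
    K, ka, cl, D, tau = p.K, p.ka, p.cl_over_f, p.dose, p.tau
    if abs(ka - K) < _SS_EQ_TOL:
        # stationary point of the ka=K limit profile
        eK = math.exp(-K * tau)
        t_max_ss = 1.0 / K - tau * eK / (1.0 - eK)
    else:
        t_max_ss = math.log(
            ka * (1.0 - math.exp(-K * tau)) / (K * (1.0 - math.exp(-ka * tau)))
        ) / (ka - K)
    return SteadyStatePK(
        c_min_ss=_accumulated(tau, D, K, ka, cl, tau),
        c_avg_ss=D / (cl * tau),
        c_max_ss=_accumulated(t_max_ss, D, K, ka, cl, tau),
        t_max_ss=t_max_ss,
    )


def superposition_oracle(
    p: PKParameters | CrClScaledPKParameters,
    n_doses: int,
    t_within_interval: float,
) -> float:
    """Concentration after ``n_doses`` repeated doses by explicit summation.

    Sums the single-dose curve shifted by each past dose:
    Σ_{j=0}^{n−1} c_single(t + j·τ).  Converges to the steady-state profile
    geometrically; serves as an independent check of the closed forms.
    """
    if n_doses < 1:
        raise ValueError("n_doses must be at least 1")
    if not 0 <= t_within_interval < _as_plain(p).tau:
        raise ValueError("t_within_interval must lie in [0, tau)")
    p = _as_plain(p)
    times = t_within_interval + p.tau * np.arange(n_doses)
    return float(np.sum(bateman(times, p.dose, p.K, p.ka, p.cl_over_f)))


def with_dose(p: PKParameters, dose: float) -> PKParameters:
    """Copy of ``p`` at a different dose."""
    return replace(p, dose=dose)
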