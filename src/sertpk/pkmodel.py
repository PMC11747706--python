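"""Closed-form one-compartment oral kinetics.

Structural model: first-order absorption into a single disposition
compartment with first-order elimination.  All parameters are *apparent*
(CL/F, V/F): bioavailability is not separable from sparse oral trough
data, so no standalone F appears anywhere.

Unit convention: doses in mg, volumes in L, times in h.  Amount/volume is
therefore mg/L internally; concentrations are reported in ng/mL via
1 mg/L = 1000 ng/mL.  This conversion happens exactly once, at the return
boundary of the public functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructuralParams",
    "Regimen",
    "conc_single_dose",
    "conc_steady_state",
    "trough_at_steady_state",
]

#: 1 mg/L expressed in ng/mL (reporting boundary only).
NG_PER_ML_PER_MG_PER_L = 1000.0

#: relative half-width of the ka ~= ke degeneracy window; inside it the
#: analytic ka -> ke limit form is used instead of the generic formula.
KA_KE_SWITCH_RTOL = 1e-8


def _require_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class StructuralParams:
    """Individual structural parameters of the one-compartment model.

    Attributes
    ----------
    cl : float
        Apparent oral clearance CL/F (L/h), > 0.
    v : float
        Apparent volume of distribution V/F (L), > 0.
    ka : float
        First-order absorption rate constant (1/h), > 0.
    """

    cl: float
    v: float
    ka: float

    def __post_init__(self) -> None:
        _require_finite(cl=self.cl, v=self.v, ka=self.ka)
        if self.cl <= 0 or self.v <= 0 or self.ka <= 0:
            raise ValueError(
                f"cl, v, ka must all be > 0; got cl={self.cl}, v={self.v}, ka={self.ka}"
            )

    @property
    def ke(self) -> float:
        """Elimination rate constant CL/V (1/h); always derived."""
        return self.cl / self.v


@dataclass(frozen=True)
class Regimen:
    """Repeated oral dosing scheme: ``dose_mg`` every ``tau_h`` hours."""

    dose_mg: float
    tau_h: float = 24.0

    def __post_init__(self) -> None:
        _require_finite(dose_mg=self.dose_mg, tau_h=self.tau_h)
        if self.dose_mg < 0:
            raise ValueError(f"dose_mg must be >= 0, got {self.dose_mg}")
        if self.tau_h <= 0:
            raise ValueError(f"tau_h must be > 0, got {self.tau_h}")

    @property
    def n_doses_per_day(self) -> float:
        return 24.0 / self.tau_h


def _single_dose_mg_per_l(cl, v, ka, dose, t):
    """Single-dose concentration in mg/L; array-safe in every argument."""
    cl, v, ka, dose, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, v, ka, dose, t))
    )
    ke = cl / v
    degenerate = np.abs(ka - ke) <= KA_KE_SWITCH_RTOL * ke
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = (
            dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        )
    # ka -> ke limit: C = D*ka*t*exp(-ka*t)/V
    limit = dose * ka * t * np.exp(-ka * t) / v
    return np.where(degenerate, limit, generic)


def _steady_state_mg_per_l(cl, v, ka, dose, tau, t):
    """Steady-state multiple-dose concentration in mg/L (superposition sum).

    Valid for any t >= 0: the profile is tau-periodic, so t is wrapped
    into [0, tau) first (t = tau maps to t = 0; the pre-dose trough is
    continuous across the dosing instant).
    """
    cl, v, ka, dose, tau, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (cl, v, ka, dose, tau, t))
    )
    t = np.mod(t, tau)
    ke = cl / v
    degenerate = np.abs(ka - ke) <= KA_KE_SWITCH_RTOL * ke
    ea, ee = np.exp(-ka * tau), np.exp(-ke * tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        generic = (
            dose
            * ka
            / (v * (ka - ke))
            * (np.exp(-ke * t) / (1.0 - ee) - np.exp(-ka * t) / (1.0 - ea))
        )
        # ka -> ke limit of the superposed series:
        #   C = (D*ka/V) * e^{-ka t} * [ t/(1-a) + tau*a/(1-a)^2 ],  a = e^{-ka tau}
        limit = (
            dose
            * ka
            / v
            * np.exp(-ka * t)
            * (t / (1.0 - ea) + tau * ea / (1.0 - ea) ** 2)
        )
    return np.where(degenerate, limit, generic)


def conc_single_dose(p: StructuralParams, dose_mg, t_h):
    """Concentration (ng/mL) at time ``t_h`` after a single oral dose.

    Vectorized over ``t_h`` (and ``dose_mg``).  Raises on negative times
    or non-finite inputs.
    """
    dose_mg = np.asarray(dose_mg, dtype=float)
    t_h = np.asarray(t_h, dtype=float)
    _require_finite(dose_mg=dose_mg, t_h=t_h)
    if np.any(dose_mg < 0):
        raise ValueError("dose_mg must be >= 0")
    if np.any(t_h < 0):
        raise ValueError("t_h must be >= 0")
    c = _single_dose_mg_per_l(p.cl, p.v, p.ka, dose_mg, t_h)
    return c[()] * NG_PER_ML_PER_MG_PER_L


def conc_steady_state(p: StructuralParams, r: Regimen, t_in_interval_h):
    """Steady-state concentration (ng/mL) at ``t_in_interval_h`` post-dose.

    Steady state is analytic (infinitely many prior doses every
    ``r.tau_h``); the profile is periodic so times beyond one interval are
    wrapped.
    """
    t = np.asarray(t_in_interval_h, dtype=float)
    _require_finite(t_in_interval_h=t)
    if np.any(t < 0):
        raise ValueError("t_in_interval_h must be >= 0")
    c = _steady_state_mg_per_l(p.cl, p.v, p.ka, r.dose_mg, r.tau_h, t)
    return c[()] * NG_PER_ML_PER_MG_PER_L


def trough_at_steady_state(p: StructuralParams, r: Regimen):
    """Pre-dose (trough) concentration at steady state, ng/mL.

    Defined as the steady-state concentration at t = tau, i.e.
    immediately before the next dose — the quantity therapeutic drug
    monitoring measures.
    """
    return conc_steady_state(p, r, r.tau_h)
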