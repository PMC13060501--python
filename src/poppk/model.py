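"""Structural and statistical model primitives.

One-compartment disposition after an IV bolus with first-order elimination,

    C(t) = (Dose / V) * exp(-(CL / V) * t),

lognormal between-animal variability ``P_i = P_pop * exp(eta_i)``, a power
dose-clearance covariate ``CL_i = CL_pop * (Dose_i / Dose_ref)**beta``
and additive/proportional/combined residual-error models with
SD(y | f) = a + b * f.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import numpy as np

from .params import DOSE_TO_UG, PopulationParameters

__all__ = [
    "individual_parameter",
    "individual_clearance",
    "predict_concentration",
    "observation_sd",
    "observation_variance",
    "auc_inf_analytic",
]


def individual_parameter(p_pop, eta):
    """Individual parameter value ``p_pop * exp(eta)``.

    The lognormal between-animal model: ``eta`` is the subject's deviation
    on the log scale, N(0, omega^2) in the population.
    """
    p_pop = np.asarray(p_pop, dtype=float)
    if np.any(p_pop <= 0):
        raise ValueError("p_pop must be strictly positive")
    out = p_pop * np.exp(np.asarray(eta, dtype=float))
    return out if out.ndim else float(out)


def individual_clearance(params: PopulationParameters, dose, eta_cl=0.0):
    """Clearance of an animal given its dose, mL/h/kg.

    ``cl_pop * (dose / dose_median)**beta * exp(eta_cl)``: equals ``cl_pop``
    at the reference dose for a typical animal; with beta < 0 clearance
    declines as the dose increases.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise ValueError("dose must be strictly positive (mg/kg)")
    typical = params.cl_pop * (dose / params.dose_median) ** params.beta
    out = typical * np.exp(np.asarray(eta_cl, dtype=float))
    return out if out.ndim else float(out)


def predict_concentration(dose, cl, v, t):
    """Plasma concentration (ug/mL) of the IV-bolus one-compartment model.

    Parameters
    ----------
    dose : mg/kg
    cl : mL/h/kg
    v : mL/kg
    t : h (scalar or array, >= 0)
    """
    dose = np.asarray(dose, dtype=float)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(dose <= 0) or np.any(cl <= 0) or np.any(v <= 0):
        raise ValueError("dose, cl and v must be strictly positive")
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (dose * DOSE_TO_UG / v) * np.exp(-(cl / v) * t)
    return out if out.ndim else float(out)


def observation_sd(f, params: PopulationParameters):
    """Residual SD at model prediction ``f``: ``a + b * f`` (ug/mL)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("model prediction f must be non-negative")
    out = params.error_a + params.error_b * f
    return out if out.ndim else float(out)


def observation_variance(f, params: PopulationParameters):
    """Residual variance ``(a + b * f)**2`` in (ug/mL)^2.

    Reduces to ``(b*f)**2`` for the proportional model (a = 0) and to
    ``a**2`` for the additive model (b = 0).
    """
    sd = observation_sd(f, params)
    out = np.asarray(sd, dtype=float) ** 2
    return out if out.ndim else float(out)


def auc_inf_analytic(dose, cl):
    """Closed-form AUC_0-inf = Dose / CL for the IV-bolus model, ug*h/mL.

    Under the power covariate model the dose-normalised AUC is proportional
    to dose**(-beta), so a negative exponent makes exposure superlinear.
    """
    dose = np.asarray(dose, dtype=float)
    cl = np.asarray(cl, dtype=float)
    if np.any(dose <= 0) or np.any(cl <= 0):
        raise ValueError("dose and cl must be strictly positive")
    out = dose * DOSE_TO_UG / cl
    return out if out.ndim else float(out)
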