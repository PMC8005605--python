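"""Structural and covariate PK model.

One-compartment disposition with zero-order intravenous infusion input and
first-order elimination.  The covariate model follows the final infant-ARC
cefathiamidine model:

    CL = theta1 * (WT / 10.25)^0.75 * (AGE / 1.25)^theta3   [L/h]
    V  = theta2 * (WT / 10.25)                              [L]

with fixed allometric exponents (0.75 on CL, 1 on V), reference covariates
equal to the cohort medians (10.25 kg, 1.25 y), exponential between-subject
variability theta_i = theta * exp(eta) with eta ~ N(0, omega^2), and an
exponential residual error handled exactly as additive Gaussian noise on
the natural-log concentration scale: log y = log f + eps, eps ~ N(0, sigma^2).

Additional screened covariate relations (power on a normalized continuous
covariate; proportional shift for sex) are carried as
:class:`CovariateEffect` entries so the covariate-selection machinery can
grow and prune models without touching the final-model fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .dataset_io import DoseEvent

__all__ = [
    "CovariateEffect",
    "PopulationModel",
    "IndividualParams",
    "Regimen",
    "typical_params",
    "individual_params",
    "concentration",
    "steady_state_concentration",
    "steady_state_interval",
]


@dataclass(frozen=True)
class CovariateEffect:
    """One screened covariate-parameter relation.

    form="power": multiplies the parameter by (covariate/reference)^coefficient.
    form="proportional": multiplies by (1 + coefficient * covariate), intended
    for the 0/1 sex indicator.
    """

    covariate: str  # "weight" | "age" | "egfr" | "sex"
    parameter: str  # "cl" | "v"
    form: str  # "power" | "proportional"
    reference: float = 1.0
    coefficient: float = 0.0

    def factor(self, value):
        value = np.asarray(value, float)
        if self.form == "power":
            return (value / self.reference) ** self.coefficient
        if self.form == "proportional":
            return 1.0 + self.coefficient * value
        raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def label(self) -> str:
        return f"{self.covariate}_{self.parameter}"


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, random-effect variances and residual variance.

    theta3 is the age-power exponent on CL (the final model's F_age);
    ``None`` means the age effect is absent (base model).  Any other
    covariate relations under evaluation live in ``extra_effects``.
    """

    theta1: float  # typical CL at reference covariates, L/h
    theta2: float  # typical V at reference covariates, L
    theta3: float | None = None  # age-power exponent on CL
    ref_weight: float = 10.25  # kg (cohort median)
    ref_age: float = 1.25  # years (cohort median)
    allo_cl: float = 0.75  # fixed allometric exponent on CL
    allo_v: float = 1.0  # fixed allometric exponent on V
    allometric: bool = True  # weight scaling applied at all?
    extra_effects: tuple[CovariateEffect, ...] = ()
    omega2_cl: float = 0.0  # IIV variance of eta_CL (log scale)
    omega2_v: float = 0.0  # IIV variance of eta_V (log scale)
    sigma2: float = 0.04  # residual variance (log scale for exponential)
    error_model: str = "exponential"  # "exponential" | "additive" | "combined"
    sigma2_add: float = 0.0  # additive component, (mg/L)^2, for combined

    def __post_init__(self):
        if self.theta1 <= 0 or self.theta2 <= 0:
            raise ValueError("theta1 and theta2 must be positive")
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("omega2 entries must be >= 0")
        # zero residual variance is allowed for noiseless simulation;
        # estimation requires a positive variance and guards separately
        if self.sigma2 < 0 or self.sigma2_add < 0:
            raise ValueError("residual variances must be >= 0")
        if self.error_model not in ("exponential", "additive", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        object.__setattr__(self, "extra_effects", tuple(self.extra_effects))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "theta1": float(self.theta1),
            "theta2": float(self.theta2),
            "theta3": None if self.theta3 is None else float(self.theta3),
            "ref_weight": float(self.ref_weight),
            "ref_age": float(self.ref_age),
            "allo_cl": float(self.allo_cl),
            "allo_v": float(self.allo_v),
            "allometric": bool(self.allometric),
            "omega2_cl": float(self.omega2_cl),
            "omega2_v": float(self.omega2_v),
            "sigma2": float(self.sigma2),
            "error_model": self.error_model,
            "sigma2_add": float(self.sigma2_add),
        }
        if self.extra_effects:
            d["extra_effects"] = [
                {
                    "covariate": e.covariate,
                    "parameter": e.parameter,
                    "form": e.form,
                    "reference": float(e.reference),
                    "coefficient": float(e.coefficient),
                }
                for e in self.extra_effects
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        d = dict(d)
        effects = tuple(
            CovariateEffect(**e) for e in d.pop("extra_effects", []) or []
        )
        return cls(extra_effects=effects, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def infant_arc_reference(cls) -> "PopulationModel":
        """Published final estimates for cefathiamidine in ARC infants."""
        return cls(
            theta1=2.20,
            theta2=3.36,
            theta3=0.662,
            omega2_cl=0.256**2,
            omega2_v=0.224**2,
            sigma2=0.226**2,
        )


@dataclass(frozen=True)
class IndividualParams:
    """Disposition parameters of one (real or virtual) subject."""

    cl: float  # L/h
    v: float  # L

    def __post_init__(self):
        if np.any(np.asarray(self.cl) <= 0) or np.any(np.asarray(self.v) <= 0):
            raise ValueError("cl and v must be positive")

    @property
    def ke(self):
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class Regimen:
    """Repeated intermittent-infusion regimen, dosed per kg."""

    daily_dose: float  # mg/kg/day
    interval: float  # h
    infusion_duration: float = 0.5  # h

    def __post_init__(self):
        if self.daily_dose <= 0:
            raise ValueError("daily_dose must be positive")
        if self.interval <= 0 or 24.0 % self.interval != 0:
            raise ValueError("interval must divide 24 h")
        if not 0 < self.infusion_duration < self.interval:
            raise ValueError("infusion duration must lie inside the interval")

    def dose_amount(self, weight: float) -> float:
        """Per-administration dose in mg for a subject of given weight."""
        return self.daily_dose * weight * self.interval / 24.0

    @property
    def label(self) -> str:
        return f"{self.daily_dose:g} mg/kg/day q{self.interval:g}h"


def typical_params(weight, age, model: PopulationModel, covariates=None):
    """Population-typical CL and V at the given covariates.

    ``covariates`` optionally supplies extra columns (egfr, sex, ...) for
    screened :class:`CovariateEffect` relations; keys are covariate names.
    """
    weight = np.asarray(weight, float)
    age = np.asarray(age, float)
    if np.any(weight <= 0) or np.any(age <= 0):
        raise ValueError("weight and age must be positive")
    cl = model.theta1 * np.ones_like(weight)
    v = model.theta2 * np.ones_like(weight)
    if model.allometric:
        cl = cl * (weight / model.ref_weight) ** model.allo_cl
        v = v * (weight / model.ref_weight) ** model.allo_v
    if model.theta3 is not None:
        cl = cl * (age / model.ref_age) ** model.theta3
    values = {"weight": weight, "age": age}
    if covariates:
        values.update({k: np.asarray(vv, float) for k, vv in covariates.items()})
    for eff in model.extra_effects:
        if eff.covariate not in values:
            raise ValueError(f"covariate {eff.covariate!r} not supplied")
        f = eff.factor(values[eff.covariate])
        if eff.parameter == "cl":
            cl = cl * f
        elif eff.parameter == "v":
            v = v * f
        else:
            raise ValueError(f"unknown parameter {eff.parameter!r}")
    if weight.ndim == 0:
        return IndividualParams(float(cl), float(v))
    return IndividualParams(cl, v)


def individual_params(typical: IndividualParams, eta_cl, eta_v) -> IndividualParams:
    """Apply exponential random effects: theta_i = theta * exp(eta)."""
    return IndividualParams(typical.cl * np.exp(eta_cl), typical.v * np.exp(eta_v))


def concentration(t, doses: Sequence[DoseEvent], params: IndividualParams):
    """Total plasma concentration (mg/L) at time(s) ``t`` after dose history.

    Superposition of analytic zero-order-infusion / first-order-elimination
    solutions: a dose with rate R0 = amount/duration contributes

        (R0/CL) * (1 - exp(-ke*min(s, D))) * exp(-ke*max(0, s - D))

    at elapsed time s = t - dose time (zero for s <= 0).
    """
    t = np.asarray(t, float)
    ke = params.ke
    out = np.zeros(np.broadcast_shapes(t.shape, np.shape(ke)), float)
    for d in doses:
        s = t - d.time
        s_inf = np.clip(np.minimum(s, d.duration), 0.0, None)
        s_dec = np.clip(s - d.duration, 0.0, None)
        out = out + (d.rate / params.cl) * (-np.expm1(-ke * s_inf)) * np.exp(
            -ke * s_dec
        )
    return float(out) if out.ndim == 0 else out


def steady_state_concentration(t, rate, duration, interval, cl, ke):
    """Steady-state concentration at time ``t`` within one dosing interval.

    Analytic geometric-series accumulation of the single-dose solution for
    an infusion of zero-order rate ``rate`` (mg/h) over ``duration`` h
    repeated every ``interval`` h.  ``t`` in [0, interval], t=0 at infusion
    start (so t=0 and t=interval are the trough).  All arguments broadcast.
    """
    t = np.asarray(t, float)
    rate, cl, ke = np.asarray(rate, float), np.asarray(cl, float), np.asarray(ke, float)
    acc = 1.0 / (-np.expm1(-ke * interval))  # 1/(1 - e^{-ke*tau})
    pulse = -np.expm1(-ke * duration)  # 1 - e^{-ke*D}
    during = (rate / cl) * (
        -np.expm1(-ke * t) + pulse * np.exp(-ke * (interval - duration + t)) * acc
    )
    after = (rate / cl) * pulse * np.exp(-ke * (t - duration)) * acc
    out = np.where(t <= duration, during, after)
    return float(out) if out.ndim == 0 else out


def steady_state_interval(
    regimen: Regimen,
    weight: float,
    params: IndividualParams,
    resolution: float = 0.005,
):
    """Steady-state profile over one dosing interval on a uniform grid.

    Returns ``(times, concentrations)`` with spacing <= ``resolution`` h.
    The trapezoid AUC of the returned grid over 24 h matches daily dose/CL
    (mass balance) to within the grid discretization error.
    """
    if resolution > 0.01:
        raise ValueError("resolution must be <= 0.01 h")
    amount = regimen.dose_amount(weight)
    rate = amount / regimen.infusion_duration
    n = int(math.ceil(regimen.interval / resolution)) + 1
    times = np.linspace(0.0, regimen.interval, n)
    conc = steady_state_concentration(
        times, rate, regimen.infusion_duration, regimen.interval, params.cl, params.ke
    )
    return times, conc
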