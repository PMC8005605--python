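"""FOCE-I nonlinear mixed-effects estimation and fit diagnostics.

The marginal likelihood of each subject's concentrations is approximated
by the Laplacian/FOCE method: the per-subject random-effect vector
eta = (eta_CL, eta_V) is set to the mode of its conditional posterior and
the Gauss-Newton curvature of the joint -2 log density is used for the
integration correction.  With the exponential residual model handled as
additive Gaussian noise on log concentration, the eta-eps interaction term
is exact; additive and combined error forms are supported on the natural
scale with the variance evaluated at the conditional mode (FOCE-I).

The objective function value (OFV) reported everywhere is
-2 log(marginal likelihood) minus N_obs * log(2*pi), the customary
additive-constant convention, so likelihood-ratio differences (dOFV) are
unchanged.

All per-subject computations are vectorized across the population (the
inner Newton iterations run for every subject simultaneously), which keeps
replicate fits for calibration studies affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .dataset_io import PKDataset
from .pk_model import CovariateEffect, IndividualParams, PopulationModel

__all__ = [
    "CompiledDataset",
    "FitResult",
    "CovariateSelectionSpec",
    "ofv_foce",
    "fit",
    "stepwise_select",
    "empirical_bayes",
    "shrinkage",
    "cwres",
]

_BIG = 1e12  # objective value returned for infeasible parameter vectors
_OMEGA_FLOOR = 1e-14  # variance floor standing in for an exact zero


# ---------------------------------------------------------------------------
# dataset compilation
# ---------------------------------------------------------------------------


class CompiledDataset:
    """Flat array view of a :class:`PKDataset` for vectorized likelihoods.

    Observations below the LLOQ are excluded with a warning (the study
    reported none; censored-likelihood handling is out of scope).
    """

    def __init__(self, dataset: PKDataset):
        self.n_subjects = len(dataset)
        self.subject_ids = [s.record.subject_id for s in dataset]
        self.weight = np.array([s.record.weight for s in dataset])
        self.age = np.array([s.record.age for s in dataset])
        self.sex = np.array([float(s.record.sex) for s in dataset])
        self.egfr = np.array(
            [s.record.egfr if s.record.egfr is not None else np.nan for s in dataset]
        )

        obs_subj, obs_time, dv = [], [], []
        n_lloq = 0
        for i, subj in enumerate(dataset):
            for o in subj.observations:
                if o.below_lloq:
                    n_lloq += 1
                    continue
                obs_subj.append(i)
                obs_time.append(o.time)
                dv.append(o.concentration)
        if n_lloq:
            warnings.warn(
                f"excluded {n_lloq} observation(s) below the LLOQ from the "
                "likelihood",
                stacklevel=2,
            )
        self.obs_subj = np.asarray(obs_subj, int)
        self.obs_time = np.asarray(obs_time, float)
        self.dv = np.asarray(dv, float)
        self.log_dv = np.log(self.dv)
        self.n_obs = len(self.dv)
        self.n_obs_per_subject = np.bincount(self.obs_subj, minlength=self.n_subjects)

        pair_obs, pair_subj, sinf, sdec, rate = [], [], [], [], []
        starts = []
        for j, (i, t) in enumerate(zip(self.obs_subj, self.obs_time)):
            doses = dataset.subjects[i].doses
            if not doses or max(t - d.time for d in doses) <= 0:
                raise ValueError(
                    f"subject {self.subject_ids[i]}: observation at t={t} has "
                    "no preceding dose"
                )
            starts.append(len(pair_obs))
            for d in doses:
                s = t - d.time
                pair_obs.append(j)
                pair_subj.append(i)
                sinf.append(max(min(s, d.duration), 0.0))
                sdec.append(max(s - d.duration, 0.0))
                rate.append(d.rate)
        self.pair_subj = np.asarray(pair_subj, int)
        self.pair_sinf = np.asarray(sinf, float)
        self.pair_sdec = np.asarray(sdec, float)
        self.pair_rate = np.asarray(rate, float)
        self.pair_starts = np.asarray(starts, int)

    # -- vectorized kinetics ------------------------------------------------

    def conc(self, cl, v):
        """Concentrations at every observation; cl/v shape (..., n_subjects)."""
        ke = cl / v
        kep = ke[..., self.pair_subj]
        clp = cl[..., self.pair_subj]
        contrib = (
            (self.pair_rate / clp)
            * (-np.expm1(-kep * self.pair_sinf))
            * np.exp(-kep * self.pair_sdec)
        )
        return np.add.reduceat(contrib, self.pair_starts, axis=-1)

    def conc_and_grad(self, cl, v):
        """Concentration plus dC/d(eta_cl), dC/d(eta_v) at every observation.

        Uses the exact derivatives of the infusion solution under the
        exponential random-effect parameterization cl*e^eta, v*e^eta.
        """
        ke = cl / v
        kep = ke[..., self.pair_subj]
        clp = cl[..., self.pair_subj]
        a, b = self.pair_sinf, self.pair_sdec
        ea = np.exp(-kep * a)
        dec = np.exp(-kep * b)
        pulse = -np.expm1(-kep * a)  # 1 - e^{-ke a}
        base = (self.pair_rate / clp) * pulse * dec
        dke = (self.pair_rate / clp) * dec * (a * ea - b * pulse)
        # eta_cl moves cl and ke together; eta_v moves ke opposite
        g_cl = -base + kep * dke
        g_v = -kep * dke
        starts = self.pair_starts
        C = np.add.reduceat(base, starts, axis=-1)
        G1 = np.add.reduceat(g_cl, starts, axis=-1)
        G2 = np.add.reduceat(g_v, starts, axis=-1)
        return C, G1, G2


def compile_dataset(dataset: PKDataset) -> CompiledDataset:
    return CompiledDataset(dataset)


def _typical_arrays(comp: CompiledDataset, model: PopulationModel):
    """Typical CL and V per subject; None on infeasible covariate factors."""
    cl = np.full(comp.n_subjects, model.theta1)
    v = np.full(comp.n_subjects, model.theta2)
    if model.allometric:
        cl = cl * (comp.weight / model.ref_weight) ** model.allo_cl
        v = v * (comp.weight / model.ref_weight) ** model.allo_v
    if model.theta3 is not None:
        cl = cl * (comp.age / model.ref_age) ** model.theta3
    values = {
        "weight": comp.weight,
        "age": comp.age,
        "egfr": comp.egfr,
        "sex": comp.sex,
    }
    for eff in model.extra_effects:
        f = eff.factor(values[eff.covariate])
        if eff.parameter == "cl":
            cl = cl * f
        else:
            v = v * f
    if not (np.all(np.isfinite(cl)) and np.all(np.isfinite(v))):
        return None
    if np.any(cl <= 0) or np.any(v <= 0):
        return None
    return cl, v


# ---------------------------------------------------------------------------
# inner (conditional-mode) problem
# ---------------------------------------------------------------------------


def _obj_parts(comp, model, tv_cl, tv_v, inv_om, eta):
    """Per-subject penalized -2 log density (up to constants): data part
    plus the eta prior quadratic.  Returns (q, residuals)."""
    cl = tv_cl * np.exp(eta[:, 0])
    v = tv_v * np.exp(eta[:, 1])
    C = comp.conc(cl, v)
    pen = inv_om[0] * eta[:, 0] ** 2 + inv_om[1] * eta[:, 1] ** 2
    if model.error_model == "exponential":
        r = comp.log_dv - np.log(np.maximum(C, 1e-300))
        data = np.bincount(comp.obs_subj, r * r, minlength=comp.n_subjects)
        return data / model.sigma2 + pen, r
    r = comp.dv - C
    g = _natural_variance(model, C)
    data = np.bincount(
        comp.obs_subj, r * r / g + np.log(g), minlength=comp.n_subjects
    )
    return data + pen, r


def _natural_variance(model, f):
    if model.error_model == "additive":
        return np.full_like(f, model.sigma2_add)
    return model.sigma2_add + model.sigma2 * f * f  # combined


def _inner_solve(
    comp,
    model,
    tv_cl,
    tv_v,
    inv_om,
    eta0,
    grad_tol: float = 1e-8,
    max_iter: int = 100,
):
    """Vectorized per-subject Newton search for the conditional mode.

    Returns (eta_hat, q_hat, converged_mask).  Subjects whose gradient
    stays above 1e-5 after the iteration budget are flagged.
    """
    S = comp.n_subjects
    eta = np.array(eta0, float).reshape(S, 2).copy()
    q, _ = _obj_parts(comp, model, tv_cl, tv_v, inv_om, eta)
    if not np.all(np.isfinite(q)):
        eta[:] = 0.0
        q, _ = _obj_parts(comp, model, tv_cl, tv_v, inv_om, eta)
    gmax = np.full(S, np.inf)
    decrement = np.full(S, np.inf)
    damp = np.zeros(S)  # Levenberg damping for near-singular curvature
    frozen = np.zeros(S, bool)  # numerically stationary subjects
    for _ in range(max_iter):
        g1, g2, H11, H12, H22 = _inner_derivs(comp, model, tv_cl, tv_v, inv_om, eta)
        gmax = np.maximum(np.abs(g1), np.abs(g2))
        A11, A22 = H11 + damp, H22 + damp
        det = A11 * A22 - H12 * H12
        det = np.where(det > 1e-300, det, 1e-300)
        step = np.stack(
            [-(A22 * g1 - H12 * g2) / det, -(A11 * g2 - H12 * g1) / det], axis=1
        )
        # Newton decrement: bounds the remaining objective improvement, so
        # subjects with a negligible decrement are done even if their
        # gradient is above tolerance (slow linear-convergence tail).  The
        # threshold sits far below the final acceptance so that the OFV is
        # resolved finely enough for finite-difference curvature on top.
        decrement = -(g1 * step[:, 0] + g2 * step[:, 1])
        done = (gmax <= grad_tol) | (decrement <= 1e-11 * (1.0 + np.abs(q)))
        active = ~done & ~frozen
        if not active.any():
            break
        step[~active] = 0.0
        lam = np.ones(S)
        trial = eta + step
        qt, _ = _obj_parts(comp, model, tv_cl, tv_v, inv_om, trial)
        for _bt in range(12):
            worse = active & ~(qt <= q + 1e-12)
            if not worse.any():
                break
            lam[worse] *= 0.5
            trial = eta + lam[:, None] * step
            qt, _ = _obj_parts(comp, model, tv_cl, tv_v, inv_om, trial)
        improved = active & (qt < q)
        eta[improved] = trial[improved]
        q[improved] = qt[improved]
        # stalled subjects: escalate damping (turns the step towards steepest
        # descent when the Gauss-Newton curvature is nearly singular); once
        # fully damped a subject is numerically stationary and is frozen,
        # while the others keep iterating
        stalled = active & ~improved
        if stalled.any():
            scale = np.maximum(H11 + H22, 1.0)
            damp[stalled] = np.where(
                damp[stalled] > 0, damp[stalled] * 10.0, 1e-8 * scale[stalled]
            )
            frozen |= stalled & (damp > 1e10 * scale)
        damp[improved] *= 0.1
    else:
        g1, g2, *_ = _inner_derivs(comp, model, tv_cl, tv_v, inv_om, eta)
        gmax = np.maximum(np.abs(g1), np.abs(g2))
    # gradients scale with the data precision (1/sigma2 for near-noiseless
    # data), so accept a small gradient, a Newton decrement that bounds the
    # remaining objective improvement by a negligible amount, or a frozen
    # (numerically stationary) state
    converged = (
        (gmax <= 1e-5)
        | (decrement <= 1e-7 * (1.0 + np.abs(q)))
        | frozen
    )
    return eta, q, converged


def _inner_derivs(comp, model, tv_cl, tv_v, inv_om, eta):
    """Gradient and Gauss-Newton Hessian of the per-subject inner objective.

    The Gauss-Newton curvature is always positive definite; subjects where
    it underestimates the true curvature converge linearly and are caught
    by the Newton-decrement acceptance in the solver, so the residual
    second-derivative term is not needed here.
    """
    S = comp.n_subjects
    cl = tv_cl * np.exp(eta[:, 0])
    v = tv_v * np.exp(eta[:, 1])
    C, G1, G2 = comp.conc_and_grad(cl, v)
    if model.error_model == "exponential":
        Cs = np.maximum(C, 1e-300)
        J1, J2 = G1 / Cs, G2 / Cs
        r = comp.log_dv - np.log(Cs)
        w = 1.0 / model.sigma2
        rw = r * w
        extra1 = extra2 = 0.0
    else:
        J1, J2 = G1, G2
        r = comp.dv - C
        g = _natural_variance(model, C)
        w = 1.0 / g
        rw = r * w
        # d/d eta of log g + r^2/g through g(eta) (combined model only)
        dg_dC = 2.0 * model.sigma2 * C
        coef = (w - rw * rw) * dg_dC
        extra1 = np.bincount(comp.obs_subj, coef * J1, minlength=S)
        extra2 = np.bincount(comp.obs_subj, coef * J2, minlength=S)
    g1 = -2.0 * np.bincount(comp.obs_subj, J1 * rw, minlength=S) + extra1
    g2 = -2.0 * np.bincount(comp.obs_subj, J2 * rw, minlength=S) + extra2
    g1 = g1 + 2.0 * inv_om[0] * eta[:, 0]
    g2 = g2 + 2.0 * inv_om[1] * eta[:, 1]
    H11 = 2.0 * np.bincount(comp.obs_subj, J1 * J1 * w, minlength=S) + 2 * inv_om[0]
    H12 = 2.0 * np.bincount(comp.obs_subj, J1 * J2 * w, minlength=S)
    H22 = 2.0 * np.bincount(comp.obs_subj, J2 * J2 * w, minlength=S) + 2 * inv_om[1]
    return g1, g2, H11, H12, H22


def _ofv_from_mode(comp, model, tv_cl, tv_v, eta):
    """Assemble the FOCE-I OFV given the conditional modes.

    The integration correction log det(I + Omega * J' W J) uses the
    Gauss-Newton (expected) curvature of the per-subject data term, the
    classic FOCE-I form.  The exact Hessian (with the residual-curvature
    term) is deliberately NOT used here: its determinant can be driven
    towards zero by the outer optimizer on sparse subjects, creating a
    spurious unbounded minimum, whereas the Gauss-Newton determinant is
    always >= 1 and keeps the outer problem smooth and bounded.
    """
    S = comp.n_subjects
    cl = tv_cl * np.exp(eta[:, 0])
    v = tv_v * np.exp(eta[:, 1])
    om1, om2 = model.omega2_cl, model.omega2_v
    C, G1, G2 = comp.conc_and_grad(cl, v)
    if model.error_model == "exponential":
        Cs = np.maximum(C, 1e-300)
        J1, J2 = G1 / Cs, G2 / Cs
        r = comp.log_dv - np.log(Cs)
        w = np.full_like(r, 1.0 / model.sigma2)
        data = np.bincount(comp.obs_subj, r * r * w, minlength=S)
        data = data + comp.n_obs_per_subject * np.log(model.sigma2)
    else:
        J1, J2 = G1, G2
        r = comp.dv - C
        g = _natural_variance(model, C)
        w = 1.0 / g
        data = np.bincount(comp.obs_subj, r * r * w + np.log(g), minlength=S)
    M11 = np.bincount(comp.obs_subj, J1 * J1 * w, minlength=S)
    M12 = np.bincount(comp.obs_subj, J1 * J2 * w, minlength=S)
    M22 = np.bincount(comp.obs_subj, J2 * J2 * w, minlength=S)
    det = (1.0 + om1 * M11) * (1.0 + om2 * M22) - om1 * om2 * M12 * M12
    if np.any(det <= 0):
        return None
    pen = np.zeros(S)
    if om1 > 0:
        pen += eta[:, 0] ** 2 / om1
    if om2 > 0:
        pen += eta[:, 1] ** 2 / om2
    return float(np.sum(data + pen + np.log(det)))


def _check_estimable(model: PopulationModel) -> None:
    if model.error_model == "exponential" and model.sigma2 <= 0:
        raise ValueError("exponential error model needs sigma2 > 0 for estimation")
    if model.error_model == "additive" and model.sigma2_add <= 0:
        raise ValueError("additive error model needs sigma2_add > 0 for estimation")
    if model.error_model == "combined" and model.sigma2 <= 0 and model.sigma2_add <= 0:
        raise ValueError("combined error model needs a positive variance component")


def _inv_om(model):
    return (
        1.0 / max(model.omega2_cl, _OMEGA_FLOOR),
        1.0 / max(model.omega2_v, _OMEGA_FLOOR),
    )


def ofv_foce(
    dataset: PKDataset | CompiledDataset,
    model: PopulationModel,
    eta0: np.ndarray | None = None,
    return_etas: bool = False,
):
    """FOCE-I objective function value of ``model`` on ``dataset``.

    Deterministic given inputs.  Raises ``RuntimeError`` listing the
    affected subjects when the inner optimization fails to converge.
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    _check_estimable(model)
    tv = _typical_arrays(comp, model)
    if tv is None:
        raise ValueError("covariate model produces non-positive typical values")
    tv_cl, tv_v = tv
    inv_om = _inv_om(model)
    if eta0 is None:
        eta0 = np.zeros((comp.n_subjects, 2))
    eta, _, converged = _inner_solve(comp, model, tv_cl, tv_v, inv_om, eta0)
    if not converged.all():
        bad = [comp.subject_ids[i] for i in np.nonzero(~converged)[0]]
        raise RuntimeError(f"inner optimization did not converge for subjects {bad}")
    ofv = _ofv_from_mode(comp, model, tv_cl, tv_v, eta)
    if ofv is None or not np.isfinite(ofv):
        raise RuntimeError("OFV is not finite at the conditional modes")
    if return_etas:
        return ofv, eta
    return ofv


# ---------------------------------------------------------------------------
# free-parameter packing
# ---------------------------------------------------------------------------

_LOG_PARAMS = ("theta1", "theta2", "omega2_cl", "omega2_v", "sigma2", "sigma2_add")


def _param_layout(model: PopulationModel, fix: Sequence[str]):
    names = ["theta1", "theta2"]
    if model.theta3 is not None:
        names.append("theta3")
    names += [f"beta_{e.label}" for e in model.extra_effects]
    names += ["omega2_cl", "omega2_v"]
    if model.error_model in ("exponential", "combined"):
        names.append("sigma2")
    if model.error_model in ("additive", "combined"):
        names.append("sigma2_add")
    return [n for n in names if n not in set(fix)]


def _get_param(model: PopulationModel, name: str) -> float:
    if name.startswith("beta_"):
        label = name[5:]
        for e in model.extra_effects:
            if e.label == label:
                return e.coefficient
        raise KeyError(name)
    return getattr(model, name)


def _set_params(model: PopulationModel, updates: dict) -> PopulationModel:
    effects = list(model.extra_effects)
    fields = {}
    for name, value in updates.items():
        if name.startswith("beta_"):
            label = name[5:]
            for k, e in enumerate(effects):
                if e.label == label:
                    effects[k] = replace(e, coefficient=value)
                    break
            else:
                raise KeyError(name)
        else:
            fields[name] = value
    return replace(model, extra_effects=tuple(effects), **fields)


def _pack(model: PopulationModel, names: Sequence[str]) -> np.ndarray:
    x = []
    for n in names:
        v = _get_param(model, n)
        if n in _LOG_PARAMS:
            if v <= 0:
                raise ValueError(f"parameter {n} must be positive to be estimated")
            x.append(np.log(v))
        else:
            x.append(v)
    return np.asarray(x, float)


def _unpack(x: np.ndarray, model: PopulationModel, names: Sequence[str]):
    updates = {}
    for n, xv in zip(names, x):
        if n in _LOG_PARAMS:
            updates[n] = float(np.exp(np.clip(xv, -34.0, 6.0)))
        else:
            updates[n] = float(xv)
    return _set_params(model, updates)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Maximum-likelihood estimates and diagnostics of one FOCE-I fit."""

    model: PopulationModel
    ofv: float
    param_names: list[str]
    x: np.ndarray  # internal (log-transformed) estimates
    covariance: np.ndarray | None  # internal scale; None if Hessian not PD
    rse: dict | None  # % per parameter (natural scale)
    ebes: np.ndarray  # (n_subjects, 2) conditional modes
    individual: IndividualParams  # per-subject CL, V at the modes
    eta_shrinkage: dict  # % per random effect
    eps_shrinkage: float | None  # %
    cwres: np.ndarray  # per retained observation, compiled order
    subject_ids: list[str]
    n_obs: int
    messages: list[str] = field(default_factory=list)

    @property
    def estimates(self) -> PopulationModel:
        return self.model

    def se(self) -> dict | None:
        """Standard errors on the natural parameter scale."""
        if self.covariance is None:
            return None
        out = {}
        for k, n in enumerate(self.param_names):
            s = float(np.sqrt(self.covariance[k, k]))
            if n in _LOG_PARAMS:
                out[n] = s * _get_param(self.model, n)
            else:
                out[n] = s
        return out


def _make_objective(comp, model, names):
    cache = {"eta": np.zeros((comp.n_subjects, 2))}

    def objective(x):
        try:
            m = _unpack(x, model, names)
        except (ValueError, OverflowError):
            return _BIG
        if m.omega2_cl > 25 or m.omega2_v > 25 or m.sigma2 > 25:
            return _BIG
        tv = _typical_arrays(comp, m)
        if tv is None:
            return _BIG
        inv_om = _inv_om(m)
        eta, _, converged = _inner_solve(comp, m, tv[0], tv[1], inv_om, cache["eta"])
        if not converged.all():
            # retry cold before declaring failure at this point
            eta, _, converged = _inner_solve(
                comp, m, tv[0], tv[1], inv_om, np.zeros_like(eta)
            )
            if not converged.all():
                return _BIG
        ofv = _ofv_from_mode(comp, m, tv[0], tv[1], eta)
        if ofv is None or not np.isfinite(ofv):
            return _BIG
        cache["eta"] = eta
        return ofv

    return objective, cache


def _fd_hessian(fun, x, rel_step=1e-3):
    """Central finite-difference Hessian.

    The step is set well above the objective's numerical noise floor (the
    inner mode search resolves the OFV to ~1e-8), so curvature estimates
    stay stable in low-curvature directions.
    """
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            fa = fun(x + ei + ej)
            fb = fun(x + ei - ej)
            fc = fun(x - ei + ej)
            fd = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fa - fb - fc + fd) / (4 * h[i] * h[j])
    return H


def fit(
    dataset: PKDataset | CompiledDataset,
    model: PopulationModel,
    fix: Sequence[str] = (),
    fast: bool = False,
    compute_uncertainty: bool = True,
) -> FitResult:
    """Estimate the free parameters of ``model`` by minimizing the FOCE OFV.

    ``model`` supplies both the structure and the initial values; ``fix``
    names parameters held at their initial value (e.g. ``("omega2_v",)``).
    ``fast=True`` relaxes outer tolerances and skips the quasi-Newton
    polish and the covariance step — intended for covariate screening.
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    if comp.n_subjects < 2:
        raise ValueError("at least 2 subjects are required for a population fit")
    _check_estimable(model)
    names = _param_layout(model, fix)
    x0 = _pack(model, names)
    objective, cache = _make_objective(comp, model, names)
    messages: list[str] = []

    if fast:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 2e-3, "fatol": 2e-3, "maxfev": 2500},
        )
        x_hat = res.x
    else:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-5, "maxfev": 5000},
        )
        x_hat = res.x
        polish = optimize.minimize(
            objective,
            x_hat,
            method="L-BFGS-B",
            options={"ftol": 1e-10, "gtol": 1e-6, "eps": 1e-6, "maxiter": 300},
        )
        if np.isfinite(polish.fun) and polish.fun <= res.fun:
            x_hat = polish.x
    ofv_hat = objective(x_hat)
    if ofv_hat >= _BIG:
        raise RuntimeError("fit failed: objective not finite at the optimum")

    fitted = _unpack(x_hat, model, names)

    covariance = None
    rse = None
    if compute_uncertainty and not fast:
        H = _fd_hessian(objective, x_hat)
        try:
            eigvals = np.linalg.eigvalsh(H)
            if np.all(eigvals > 0):
                covariance = 2.0 * np.linalg.inv(H)
                rse = {}
                for k, n in enumerate(names):
                    sd_int = float(np.sqrt(covariance[k, k]))
                    val = _get_param(fitted, n)
                    if n in _LOG_PARAMS:
                        rse[n] = 100.0 * sd_int
                    else:
                        rse[n] = 100.0 * sd_int / abs(val) if val != 0 else np.inf
            else:
                messages.append(
                    "Hessian not positive definite; covariance unavailable"
                )
        except np.linalg.LinAlgError:
            messages.append("Hessian inversion failed; covariance unavailable")

    ebes, indiv = empirical_bayes(comp, fitted)
    shr = shrinkage(comp, fitted, ebes=ebes)
    cw = cwres(comp, fitted, ebes=ebes)
    return FitResult(
        model=fitted,
        ofv=float(ofv_hat),
        param_names=list(names),
        x=np.asarray(x_hat, float),
        covariance=covariance,
        rse=rse,
        ebes=ebes,
        individual=indiv,
        eta_shrinkage={"eta_cl": shr["eta_cl"], "eta_v": shr["eta_v"]},
        eps_shrinkage=shr["eps"],
        cwres=cw,
        subject_ids=list(comp.subject_ids),
        n_obs=comp.n_obs,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# empirical Bayes, shrinkage, CWRES
# ---------------------------------------------------------------------------


def empirical_bayes(dataset, model: PopulationModel):
    """Conditional posterior modes (EBEs) and individual parameters.

    Subjects without observations get eta = 0 (the prior mode); subjects
    whose inner search fails are flagged with a warning and fall back to 0.
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    tv = _typical_arrays(comp, model)
    if tv is None:
        raise ValueError("covariate model produces non-positive typical values")
    inv_om = _inv_om(model)
    eta, _, converged = _inner_solve(
        comp, model, tv[0], tv[1], inv_om, np.zeros((comp.n_subjects, 2))
    )
    if not converged.all():
        bad = [comp.subject_ids[i] for i in np.nonzero(~converged)[0]]
        warnings.warn(
            f"EBE search did not converge for subjects {bad}; eta=0 used",
            stacklevel=2,
        )
        eta[~converged] = 0.0
    indiv = IndividualParams(tv[0] * np.exp(eta[:, 0]), tv[1] * np.exp(eta[:, 1]))
    return eta, indiv


def shrinkage(dataset, model: PopulationModel, ebes: np.ndarray | None = None) -> dict:
    """Eta- and epsilon-shrinkage in percent.

    eta-shrinkage = 100 * (1 - SD(eta_hat)/omega); undefined (None) when
    the corresponding omega is zero.  eps-shrinkage = 100 * (1 - SD(IWRES))
    with IWRES computed on the residual-model scale.
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    if comp.n_subjects < 2:
        raise ValueError("shrinkage requires >= 2 subjects")
    if ebes is None:
        ebes, _ = empirical_bayes(comp, model)
    out = {}
    for k, (key, om2) in enumerate(
        (("eta_cl", model.omega2_cl), ("eta_v", model.omega2_v))
    ):
        if om2 <= 0:
            out[key] = None
        else:
            out[key] = 100.0 * (1.0 - np.std(ebes[:, k], ddof=1) / np.sqrt(om2))
    tv = _typical_arrays(comp, model)
    cl = tv[0] * np.exp(ebes[:, 0])
    v = tv[1] * np.exp(ebes[:, 1])
    if comp.n_obs >= 2:
        C = comp.conc(cl, v)
        if model.error_model == "exponential":
            iwres = (comp.log_dv - np.log(C)) / np.sqrt(model.sigma2)
        else:
            iwres = (comp.dv - C) / np.sqrt(_natural_variance(model, C))
        out["eps"] = 100.0 * (1.0 - np.std(iwres, ddof=1))
    else:
        out["eps"] = None
    return out


def cwres(dataset, model: PopulationModel, ebes: np.ndarray | None = None):
    """Conditional weighted residuals (FOCE linearization about the EBEs).

    Per subject the observation vector is linearized about eta_hat:
    marginal mean  m = f(eta_hat) - J eta_hat,  covariance
    V = J Omega J' + residual variance;  CWRES = chol(V)^-1 (y - m).
    Observations in subjects with a singular V are flagged (NaN) after a
    jittered retry.
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    if ebes is None:
        ebes, _ = empirical_bayes(comp, model)
    tv = _typical_arrays(comp, model)
    cl = tv[0] * np.exp(ebes[:, 0])
    v = tv[1] * np.exp(ebes[:, 1])
    C, G1, G2 = comp.conc_and_grad(cl, v)
    if model.error_model == "exponential":
        y = comp.log_dv
        pred = np.log(C)
        J1, J2 = G1 / C, G2 / C
        res_var = np.full(comp.n_obs, model.sigma2)
    else:
        y = comp.dv
        pred = C
        J1, J2 = G1, G2
        res_var = _natural_variance(model, C)
    Om = np.diag([model.omega2_cl, model.omega2_v])
    out = np.full(comp.n_obs, np.nan)
    for i in range(comp.n_subjects):
        idx = np.nonzero(comp.obs_subj == i)[0]
        if len(idx) == 0:
            continue
        J = np.column_stack([J1[idx], J2[idx]])
        V = J @ Om @ J.T + np.diag(res_var[idx])
        resid = y[idx] - (pred[idx] - J @ ebes[i])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            V = V + np.eye(len(idx)) * (1e-10 * max(np.trace(V), 1.0))
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                warnings.warn(
                    f"singular conditional covariance for subject "
                    f"{comp.subject_ids[i]}; CWRES flagged NaN",
                    stacklevel=2,
                )
                continue
        out[idx] = linalg.solve_triangular(L, resid, lower=True)
    return out


# ---------------------------------------------------------------------------
# stepwise covariate selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSelectionSpec:
    """Candidate covariate-parameter relations and LRT thresholds.

    Defaults screen age, eGFR (power on the normalized covariate) and sex
    (proportional shift) on both CL and V; weight enters the base model
    through the fixed allometric exponents and is not re-screened.
    Thresholds are chi-square(1) critical values: forward p<0.05 (3.84),
    backward p<0.01 (6.635).
    """

    base_model: PopulationModel
    candidates: tuple[tuple[str, str, str], ...] = (
        ("age", "cl", "power"),
        ("age", "v", "power"),
        ("egfr", "cl", "power"),
        ("egfr", "v", "power"),
        ("sex", "cl", "proportional"),
        ("sex", "v", "proportional"),
    )
    forward_threshold: float = 3.84
    backward_threshold: float = 6.635
    fast: bool = True

    def __post_init__(self):
        if self.forward_threshold <= 0 or self.backward_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.forward_threshold >= self.backward_threshold:
            raise ValueError("forward threshold must be below backward threshold")


def _candidate_effect(comp, cov, par, form):
    if form == "power":
        values = getattr(comp, cov if cov != "weight" else "weight")
        ref = float(np.nanmedian(values))
        if not np.isfinite(ref) or ref <= 0:
            raise ValueError(f"covariate {cov} has no usable reference value")
        return CovariateEffect(cov, par, "power", reference=ref, coefficient=0.0)
    return CovariateEffect(cov, par, "proportional", reference=1.0, coefficient=0.0)


def stepwise_select(
    dataset: PKDataset | CompiledDataset,
    spec: CovariateSelectionSpec,
    refit_final: bool = True,
):
    """Forward-inclusion / backward-deletion covariate search.

    Forward: repeatedly add the candidate with the largest OFV drop,
    provided the drop strictly exceeds ``forward_threshold``.  Backward:
    from the full model, delete any covariate whose removal raises the OFV
    by at most ``backward_threshold`` (smallest rise first).  Candidate
    fits that fail are skipped with a warning.  Returns
    (final FitResult, trace DataFrame).
    """
    comp = dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    current = fit(comp, spec.base_model, fast=spec.fast, compute_uncertainty=False)
    trace: list[dict] = []
    pool = list(spec.candidates)
    step = 0

    while pool:
        step += 1
        best = None
        for cand in pool:
            cov, par, form = cand
            try:
                eff = _candidate_effect(comp, cov, par, form)
                m = replace(
                    current.model,
                    extra_effects=current.model.extra_effects + (eff,),
                )
                cand_fit = fit(comp, m, fast=spec.fast, compute_uncertainty=False)
            except Exception as exc:  # noqa: BLE001 - candidate must not abort search
                warnings.warn(
                    f"candidate {cov} on {par} failed ({exc}); skipped",
                    stacklevel=2,
                )
                trace.append(
                    {
                        "phase": "forward",
                        "step": step,
                        "candidate": f"{cov}_{par}",
                        "ofv": np.nan,
                        "delta_ofv": np.nan,
                        "decision": "failed",
                    }
                )
                continue
            delta = current.ofv - cand_fit.ofv
            trace.append(
                {
                    "phase": "forward",
                    "step": step,
                    "candidate": f"{cov}_{par}",
                    "ofv": cand_fit.ofv,
                    "delta_ofv": delta,
                    "decision": "tested",
                }
            )
            if delta > spec.forward_threshold and (best is None or delta > best[0]):
                best = (delta, cand, cand_fit)
        if best is None:
            break
        delta, cand, cand_fit = best
        pool.remove(cand)
        current = cand_fit
        trace.append(
            {
                "phase": "forward",
                "step": step,
                "candidate": f"{cand[0]}_{cand[1]}",
                "ofv": cand_fit.ofv,
                "delta_ofv": delta,
                "decision": "added",
            }
        )

    # backward deletion on the added covariates
    step = 0
    while current.model.extra_effects:
        step += 1
        rises = []
        for eff in current.model.extra_effects:
            reduced_effects = tuple(
                e for e in current.model.extra_effects if e is not eff
            )
            try:
                m = replace(current.model, extra_effects=reduced_effects)
                red_fit = fit(comp, m, fast=spec.fast, compute_uncertainty=False)
            except Exception as exc:  # noqa: BLE001
                warnings.warn(
                    f"backward fit without {eff.label} failed ({exc}); retained",
                    stacklevel=2,
                )
                continue
            rise = red_fit.ofv - current.ofv
            rises.append((rise, eff, red_fit))
            trace.append(
                {
                    "phase": "backward",
                    "step": step,
                    "candidate": eff.label,
                    "ofv": red_fit.ofv,
                    "delta_ofv": rise,
                    "decision": "tested",
                }
            )
        removable = [t for t in rises if t[0] <= spec.backward_threshold]
        if not removable:
            for rise, eff, _ in rises:
                trace.append(
                    {
                        "phase": "backward",
                        "step": step,
                        "candidate": eff.label,
                        "ofv": current.ofv,
                        "delta_ofv": rise,
                        "decision": "retained",
                    }
                )
            break
        rise, eff, red_fit = min(removable, key=lambda t: t[0])
        current = red_fit
        trace.append(
            {
                "phase": "backward",
                "step": step,
                "candidate": eff.label,
                "ofv": red_fit.ofv,
                "delta_ofv": rise,
                "decision": "removed",
            }
        )

    final_model = _fold_age_effect(current.model)
    if refit_final:
        final = fit(comp, final_model, fast=False, compute_uncertainty=True)
    else:
        final = replace(current, model=final_model)
    return final, pd.DataFrame(trace)


def _fold_age_effect(model: PopulationModel) -> PopulationModel:
    """Promote a selected age-power effect on CL to the theta3 slot."""
    for eff in model.extra_effects:
        if eff.covariate == "age" and eff.parameter == "cl" and eff.form == "power":
            rest = tuple(e for e in model.extra_effects if e is not eff)
            return replace(
                model,
                theta3=eff.coefficient,
                ref_age=eff.reference,
                extra_effects=rest,
            )
    return model
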