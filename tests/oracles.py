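"""Independent oracles used by the test suite.

These deliberately avoid the vectorized likelihood engine: they are built
on the closed-form single-dose solution (itself checked against hand
calculations) plus brute-force numerics — adaptive Gauss-Hermite
quadrature for the marginal likelihood, dense-grid searches for fT>MIC,
and many-dose superposition for the steady-state profile.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize

from popkarc.dataset_io import DoseEvent
from popkarc.pk_model import (
    IndividualParams,
    PopulationModel,
    Regimen,
    concentration,
    typical_params,
)


def marginal_ofv_quadrature(dataset, model: PopulationModel, n_nodes: int = 64):
    """-2 log marginal likelihood (minus N log 2pi) by adaptive 2-D
    Gauss-Hermite quadrature, subject by subject."""
    x, w = hermgauss(n_nodes)
    X1, X2 = np.meshgrid(x, x, indexing="ij")
    W = np.outer(w, w).ravel()
    pts = np.stack([X1.ravel(), X2.ravel()], axis=1)
    total = 0.0
    n_total = 0
    omega = np.diag([model.omega2_cl, model.omega2_v])
    omega_inv = np.linalg.inv(omega)
    log_det_omega = float(np.log(np.linalg.det(omega)))
    for subj in dataset:
        obs = [o for o in subj.observations if not o.below_lloq]
        n = len(obs)
        n_total += n
        times = np.array([o.time for o in obs])
        log_y = np.log([o.concentration for o in obs])
        tv = typical_params(subj.record.weight, subj.record.age, model)
        doses = list(subj.doses)

        def neg_log_joint(eta):
            p = IndividualParams(tv.cl * np.exp(eta[0]), tv.v * np.exp(eta[1]))
            r = log_y - np.log(concentration(times, doses, p))
            return 0.5 * (
                r @ r / model.sigma2
                + eta @ omega_inv @ eta
                + n * np.log(model.sigma2)
                + log_det_omega
            )

        mode = optimize.minimize(neg_log_joint, np.zeros(2), method="BFGS").x
        h = 1e-4
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h
                ej[j] = h
                H[i, j] = (
                    neg_log_joint(mode + ei + ej)
                    - neg_log_joint(mode + ei - ej)
                    - neg_log_joint(mode - ei + ej)
                    + neg_log_joint(mode - ei - ej)
                ) / (4 * h * h)
        L = np.linalg.cholesky(np.linalg.inv(H))
        etas = mode + (np.sqrt(2) * pts) @ L.T
        g_vals = np.array([neg_log_joint(e) for e in etas])
        integral = float(
            np.sum(W * np.exp(-g_vals + (pts**2).sum(axis=1)))
            * 2.0
            * abs(np.linalg.det(L))
        )
        total += -2.0 * np.log(integral) + n * np.log(2 * np.pi) + 2 * np.log(2 * np.pi)
    return total - n_total * np.log(2 * np.pi)


def steady_state_by_superposition(
    regimen: Regimen, weight: float, params: IndividualParams, times, n_doses: int = 60
):
    """Steady-state profile by brute-force superposition of many repeated
    doses, evaluated at ``times`` within one interval after the last dose."""
    amount = regimen.dose_amount(weight)
    doses = [
        DoseEvent(k * regimen.interval, amount, regimen.infusion_duration)
        for k in range(n_doses)
    ]
    t_abs = (n_doses - 1) * regimen.interval + np.asarray(times, float)
    return concentration(t_abs, doses, params)


def ft_above_mic_grid(
    regimen: Regimen,
    weight: float,
    params: IndividualParams,
    mic: float,
    unbound_fraction: float = 0.77,
    resolution: float = 0.001,
):
    """fT>MIC by dense-grid evaluation of the superposed profile."""
    n = int(round(regimen.interval / resolution))
    times = (np.arange(n) + 0.5) * resolution  # midpoint rule
    conc = steady_state_by_superposition(regimen, weight, params, times)
    return float(np.mean(unbound_fraction * conc > mic))
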