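"""Slow, independent reference computations for verification.

These implementations deliberately avoid the closed-form/linearized
production code paths: concentrations come from numerically integrating
the one-compartment differential equation, AUCs from adaptive
quadrature, and the marginal likelihood from adaptive Gauss-Hermite
quadrature over the random effects.  They exist to cross-check the fast
analytic kinetics and the FOCE-I approximation, not for production use.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.integrate import quad, solve_ivp
from numpy.polynomial.hermite import hermgauss

from .data import Dataset
from .model import ModelSpec
from .pk import DoseEvent, PKParams

__all__ = ["conc_ode", "auc_quad", "marginal_ofv_agq"]


def _infusion_rate(doses: list[DoseEvent], t: float) -> float:
    return sum(d.rate for d in doses if d.start_time < t <= d.start_time + d.duration)


def conc_ode(params: PKParams, doses: list[DoseEvent], times, rtol=1e-10) -> np.ndarray:
    """Concentration by numeric integration of dA/dt = R(t) - ke*A.

    Integrates piecewise between infusion on/off switch points so the
    discontinuous input rate never crosses a solver step.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    switch = sorted({0.0}
                    | {d.start_time for d in doses}
                    | {d.start_time + d.duration for d in doses}
                    | set(times))
    ke = params.ke
    amounts = {}
    a = 0.0
    for t0, t1 in zip(switch[:-1], switch[1:]):
        amounts[t0] = a
        if t1 <= t0:
            continue
        tm = 0.5 * (t0 + t1)
        rate = _infusion_rate(doses, tm)
        sol = solve_ivp(
            lambda t, y: [rate - ke * y[0]], (t0, t1), [a],
            rtol=rtol, atol=1e-12, dense_output=False,
        )
        a = float(sol.y[0, -1])
    amounts[switch[-1]] = a
    return np.array([amounts[t] / params.v for t in times])


def auc_quad(params: PKParams, doses: list[DoseEvent], t1: float, t2: float) -> float:
    """AUC by adaptive quadrature of the concentration curve."""
    from .pk import concentration

    pts = sorted({d.start_time for d in doses}
                 | {d.start_time + d.duration for d in doses})
    pts = [p for p in pts if t1 < p < t2]
    val, _ = quad(lambda t: concentration(params, doses, t), t1, t2,
                  points=pts or None, limit=50 + 10 * len(pts), epsabs=1e-12,
                  epsrel=1e-10)
    return val


# ---------------------------------------------------------------------------
# exact (quadrature) marginal likelihood

def _conc_batch(cl, v, doses, times):
    """Textbook one-compartment infusion solution, batched over (cl, v).

    Written with explicit during/post-infusion branches, independently of
    the production kernel.  cl, v: (Q,); times: (m,) -> (Q, m).
    """
    cl = np.asarray(cl, dtype=float)[:, None]
    v = np.asarray(v, dtype=float)[:, None]
    ke = cl / v
    t = np.asarray(times, dtype=float)[None, :]
    c = np.zeros((cl.shape[0], t.shape[1]))
    for d in doses:
        tau = t - d.start_time
        rate_cl = d.rate / cl
        during = (tau > 0) & (tau <= d.duration)
        after = tau > d.duration
        tau_c = np.clip(tau, 0.0, None)
        c_during = rate_cl * (1.0 - np.exp(-ke * tau_c))
        c_after = (
            rate_cl
            * (1.0 - np.exp(-ke * d.duration))
            * np.exp(-ke * np.clip(tau_c - d.duration, 0.0, None))
        )
        c = c + np.where(during, c_during, 0.0) + np.where(after, c_after, 0.0)
    return c


def _subject_loglik_factory(model: ModelSpec, subj_row, doses, t_obs, y):
    """Batched log p(y | eta) for one subject: eta (Q, k) -> (Q,)."""
    from .pk import typical_params

    eta_names = model.eta_names
    p = typical_params(model.theta, model.effects, subj_row)

    def loglik(eta):
        eta = np.atleast_2d(eta)
        cl = np.full(eta.shape[0], p.cl)
        v = np.full(eta.shape[0], p.v)
        for d, name in enumerate(eta_names):
            if model.bsv == "exponential":
                if name == "cl":
                    cl = cl * np.exp(eta[:, d])
                else:
                    v = v * np.exp(eta[:, d])
            else:
                if name == "cl":
                    cl = cl + eta[:, d]
                else:
                    v = v + eta[:, d]
        out = np.full(eta.shape[0], -np.inf)
        ok = (cl > 0) & (v > 0)
        if ok.any():
            f = _conc_batch(cl[ok], v[ok], doses, t_obs)
            sd = model.residual.sd(f)
            out[ok] = -0.5 * np.sum(
                np.log(2 * np.pi * sd**2) + (y[None, :] - f) ** 2 / sd**2, axis=1
            )
        return out

    return loglik


def marginal_ofv_agq(data, model: ModelSpec, n_nodes: int = 32) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Per subject the integrand is centered at the conditional mode and
    scaled by the local curvature; with ``n_nodes`` points per random
    effect dimension the result is accurate far beyond the FOCE
    approximation and serves as its oracle on small problems.
    """
    arrays = data.arrays() if isinstance(data, Dataset) else data
    eta_names = model.eta_names
    k = len(eta_names)
    om2 = np.array([model.omega2[p] for p in eta_names])
    total = 0.0
    x1, w1 = hermgauss(n_nodes)
    if k == 2:
        X = np.array(np.meshgrid(x1, x1)).reshape(2, -1).T
        W = np.outer(w1, w1).ravel()
    elif k == 1:
        X = x1[:, None]
        W = w1
    else:
        X = np.zeros((1, 0))
        W = np.array([1.0])

    for i in range(arrays.n_subjects):
        msk = arrays.obs_mask[i]
        t_obs = arrays.t_obs[i][msk]
        y = arrays.y[i][msk]
        dmask = arrays.dose_mask[i]
        doses = [
            DoseEvent(s, r * du, du)
            for s, r, du in zip(
                arrays.dose_start[i][dmask],
                arrays.dose_rate[i][dmask],
                arrays.dose_dur[i][dmask],
            )
        ]
        loglik = _subject_loglik_factory(
            model, arrays.covariates.iloc[i].to_dict(), doses, t_obs, y
        )
        if k == 0:
            total += -2.0 * float(loglik(np.zeros((1, 0)))[0])
            continue

        def h(eta):  # log joint density, batched (Q, k) -> (Q,)
            eta = np.atleast_2d(eta)
            prior = -0.5 * np.sum(
                np.log(2 * np.pi * om2)[None, :] + eta**2 / om2[None, :], axis=1
            )
            return loglik(eta) + prior

        res = optimize.minimize(lambda e: -float(h(e[None, :])[0]),
                                np.zeros(k), method="BFGS")
        mode = res.x
        # curvature at the mode by central differences
        hstep = 1e-4
        A = np.zeros((k, k))
        hs = lambda e: float(h(e[None, :])[0])
        for a in range(k):
            for b in range(a, k):
                ea = np.zeros(k); ea[a] = hstep
                eb = np.zeros(k); eb[b] = hstep
                if a == b:
                    A[a, a] = -(hs(mode + ea) - 2 * hs(mode) + hs(mode - ea)) / hstep**2
                else:
                    A[a, b] = A[b, a] = -(
                        hs(mode + ea + eb) - hs(mode + ea - eb)
                        - hs(mode - ea + eb) + hs(mode - ea - eb)
                    ) / (4 * hstep**2)
        # guard: fall back to the prior curvature if not PD
        try:
            L = np.linalg.cholesky(np.linalg.inv(A))
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(np.diag(om2))
        log_jac = float(np.log(np.abs(np.linalg.det(np.sqrt(2.0) * L))))
        nodes = mode[None, :] + np.sqrt(2.0) * (X @ L.T)
        vals = h(nodes)
        log_terms = vals + np.sum(X**2, axis=1) + np.log(W) + log_jac
        mx = log_terms.max()
        total += -2.0 * (mx + np.log(np.exp(log_terms - mx).sum()))
    return float(total)
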