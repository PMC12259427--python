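"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's sparse concentration data is
approximated NONMEM-style: the subject's random-effect vector eta is set
to its conditional mode (inner optimization), the model prediction is
linearized about that mode, and the resulting Gaussian marginal gives
the subject's contribution to the objective function value

    OFV_i = n_i log(2 pi) + log|C_i| + r_i' C_i^{-1} r_i,

with C_i = G_i Omega G_i' + Sigma_i, G_i the Jacobian of the prediction
in eta at the mode, Sigma_i the residual variance evaluated at the
*individual* prediction (the "interaction"), and
r_i = y_i - f_i(eta_hat) + G_i eta_hat.

The inner problem is solved by a damped Gauss-Newton iteration,
vectorized across subjects; Jacobians come from complex-step
differentiation of the closed-form kinetics and are exact to machine
precision.  Variance parameters are estimated on the log scale; an
exact zero variance is handled by dropping that eta dimension.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .data import Dataset, SubjectArrays
from .model import ModelSpec, ResidualModel
from .pk import conc_kernel

__all__ = ["FitResult", "foce_ofv", "fit", "compute_cwres"]

_LOG2PI = float(np.log(2.0 * np.pi))
_CSTEP = 1e-100  # complex-step size; no subtractive cancellation


# ---------------------------------------------------------------------------
# model evaluation on padded subject arrays

def _typical_vectors(model: ModelSpec, cov_df):
    """Covariate-adjusted typical CL and V per subject, shape (n,)."""
    n = len(cov_df)
    log_cl = np.full(n, np.log(model.theta["cl"]))
    log_v = np.full(n, np.log(model.theta["v"]))
    for eff in model.effects:
        if eff.covariate not in cov_df.columns:
            raise KeyError(f"covariate {eff.covariate!r} missing from dataset")
        x = cov_df[eff.covariate].to_numpy(dtype=float)
        z = x if eff.form == "exponential" else np.log(x / eff.reference)
        if eff.parameter == "cl":
            log_cl = log_cl + eff.coefficient * z
        else:
            log_v = log_v + eff.coefficient * z
    return np.exp(log_cl), np.exp(log_v)


class _Prepared:
    """Arrays + model bound together for repeated likelihood evaluation."""

    def __init__(self, arrays: SubjectArrays, model: ModelSpec):
        self.a = arrays
        self.model = model
        self.base_cl, self.base_v = _typical_vectors(model, arrays.covariates)
        self.eta_names = model.eta_names
        self.k = len(self.eta_names)
        self.om2 = np.array([model.omega2[p] for p in self.eta_names])
        self.n = arrays.n_subjects
        self.mask = arrays.obs_mask
        self.n_obs_i = self.mask.sum(axis=1)

    def _cl_v(self, eta, idx=None):
        """Individual CL, V given eta (n, k); dtype follows eta."""
        base_cl = self.base_cl if idx is None else self.base_cl[idx]
        base_v = self.base_v if idx is None else self.base_v[idx]
        cl = base_cl.astype(eta.dtype)
        v = base_v.astype(eta.dtype)
        for d, p in enumerate(self.eta_names):
            if self.model.bsv == "exponential":
                if p == "cl":
                    cl = cl * np.exp(eta[:, d])
                else:
                    v = v * np.exp(eta[:, d])
            else:
                if p == "cl":
                    cl = cl + eta[:, d]
                else:
                    v = v + eta[:, d]
        return cl[:, None], v[:, None]

    def predict(self, eta, idx=None):
        """Model prediction f at the given eta, optionally row-subset."""
        cl, v = self._cl_v(eta.astype(float), idx)
        if np.any(cl.real <= 0) or np.any(v.real <= 0):
            raise FloatingPointError("non-positive individual CL or V")
        a = self.a
        sl = slice(None) if idx is None else idx
        return conc_kernel(cl, v, a.dose_start[sl], a.dose_rate[sl],
                           a.dose_dur[sl], a.dose_mask[sl], a.t_obs[sl]).real

    def predict_with_jac(self, eta, idx=None):
        """f and G = df/deta by complex step, optionally row-subset."""
        a = self.a
        sl = slice(None) if idx is None else idx
        t_obs = a.t_obs[sl]
        G = np.zeros(t_obs.shape + (self.k,))
        if self.k == 0:
            return self.predict(eta, idx), G
        f = None
        for d in range(self.k):
            eta_c = eta.astype(complex)
            eta_c[:, d] = eta_c[:, d] + 1j * _CSTEP
            cl, v = self._cl_v(eta_c, idx)
            fc = conc_kernel(cl, v, a.dose_start[sl], a.dose_rate[sl],
                             a.dose_dur[sl], a.dose_mask[sl], t_obs)
            G[:, :, d] = fc.imag / _CSTEP
            if f is None:
                f = fc.real
        return f, G

    # -- inner (conditional-mode) objective --------------------------------
    def _data_terms(self, f, idx=None):
        """Per-observation residual variance and residuals."""
        sl = slice(None) if idx is None else idx
        mask = self.mask[sl]
        var, dvar = self.model.residual.var_and_dvar(f)
        var = np.where(mask, var, 1.0)
        if np.any(var <= 0):
            raise FloatingPointError("non-positive residual variance")
        res = np.where(mask, self.a.y[sl] - f, 0.0)
        return var, dvar, res, mask

    def q_obj(self, eta, idx=None):
        """-2 log joint density (up to constants) per subject."""
        f = self.predict(eta, idx)
        var, _, res, mask = self._data_terms(f, idx)
        l = np.where(mask, np.log(var) + res**2 / var, 0.0).sum(axis=1)
        if self.k:
            l = l + (eta**2 / self.om2).sum(axis=1)
        return l

    def inner_mode(self, eta0=None, tol=1e-7, max_iter=60):
        """Conditional mode of eta per subject (damped Gauss-Newton).

        Each iteration works only on the not-yet-converged subjects; a
        subject is done when its gradient is below ``tol`` or its
        proposed step is numerically nil.
        """
        if self.k == 0:
            return np.zeros((self.n, 0))
        eta = np.zeros((self.n, self.k)) if eta0 is None else eta0.copy()
        try:
            q = self.q_obj(eta)
        except FloatingPointError:
            eta = np.zeros((self.n, self.k))
            q = self.q_obj(eta)
        idx = np.arange(self.n)
        for _ in range(max_iter):
            if len(idx) == 0:
                break
            e = eta[idx]
            f, G = self.predict_with_jac(e, idx)
            var, dvar, res, mask = self._data_terms(f, idx)
            dvar = np.where(mask, dvar, 0.0)
            dl_df = dvar / var * (1.0 - res**2 / var) - 2.0 * res / var
            grad = np.einsum("nm,nmk->nk", np.where(mask, dl_df, 0.0), G)
            grad = grad + 2.0 * e / self.om2
            gmax = np.abs(grad).max(axis=1)
            live = gmax > tol * (1.0 + np.abs(q[idx]))
            idx = idx[live]
            if len(idx) == 0:
                break
            w = np.where(mask[live], 2.0 / var[live], 0.0)
            Gl = G[live]
            H = np.einsum("nmk,nm,nml->nkl", Gl, w, Gl)
            H = H + 2.0 * np.eye(self.k) / self.om2
            step = -np.linalg.solve(H, grad[live][..., None])[..., 0]
            tiny = np.abs(step).max(axis=1) < 1e-10 * (1.0 + np.abs(eta[idx]).max(axis=1))
            idx = idx[~tiny]
            step = step[~tiny]
            if len(idx) == 0:
                break
            # backtracking line search on the shrinking active set
            rem = idx
            for _bt in range(10):
                trial = eta[rem] + step
                try:
                    q_t = self.q_obj(trial, rem)
                except FloatingPointError:
                    q_t = np.full(len(rem), np.inf)
                ok = q_t < q[rem] - 1e-12
                eta[rem[ok]] = trial[ok]
                q[rem[ok]] = q_t[ok]
                rem = rem[~ok]
                step = step[~ok] * 0.5
                if len(rem) == 0:
                    break
            # subjects whose line search failed entirely are left in place;
            # drop them from further iterations (flat to double precision)
            idx = np.setdiff1d(idx, rem, assume_unique=True)
        return eta

    # -- FOCE-I marginal ----------------------------------------------------
    def foce_terms(self, eta_hat):
        """Per-subject OFV contributions at the conditional modes."""
        f, G = self.predict_with_jac(eta_hat)
        var, _, res, _ = self._data_terms(f)
        Gm = np.where(self.mask[:, :, None], G, 0.0)
        base = self.n_obs_i * _LOG2PI + np.where(
            self.mask, np.log(var), 0.0
        ).sum(axis=1)
        if self.k == 0:
            return base + (res**2 / var).sum(axis=1)
        r = res + np.einsum("nmk,nk->nm", Gm, eta_hat)
        r = np.where(self.mask, r, 0.0)
        GtSiG = np.einsum("nmk,nm,nml->nkl", Gm, 1.0 / var, Gm)
        A = np.eye(self.k) + GtSiG * self.om2[None, None, :]
        sign, logdetA = np.linalg.slogdet(A)
        if np.any(sign <= 0):
            raise FloatingPointError("indefinite marginal covariance")
        M = np.diag(1.0 / self.om2) + GtSiG
        u = np.einsum("nmk,nm->nk", Gm, r / var)
        quad = (r**2 / var).sum(axis=1) - np.einsum(
            "nk,nk->n", u, np.linalg.solve(M, u[..., None])[..., 0]
        )
        return base + logdetA + quad


def _as_arrays(data) -> SubjectArrays:
    return data.arrays() if isinstance(data, Dataset) else data


def foce_ofv(data, model: ModelSpec, eta0=None):
    """FOCE-I objective function value and empirical Bayes estimates.

    Returns a dict with ``ofv`` (float), ``ofv_i`` (per-subject terms),
    ``ebe`` (n, k) conditional modes and ``eta_names``.
    """
    arrays = _as_arrays(data)
    prep = _Prepared(arrays, model)
    if (prep.n_obs_i == 0).any():
        raise ValueError("every subject needs at least one observation")
    eta_hat = prep.inner_mode(eta0)
    terms = prep.foce_terms(eta_hat)
    return {
        "ofv": float(terms.sum()),
        "ofv_i": terms,
        "ebe": eta_hat,
        "eta_names": prep.eta_names,
    }


# ---------------------------------------------------------------------------
# outer estimation

@dataclass
class FitResult:
    """Converged (or best-effort) population estimates."""

    model: ModelSpec
    ofv: float
    estimates: dict
    se: dict | None
    rse: dict | None
    ebe: np.ndarray
    eta_names: tuple
    convergence: str
    n_iter: int
    n_eval: int
    warnings: list = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.convergence == "converged"


def _param_layout(model: ModelSpec, fixed=()):
    """(name, transform) pairs for the free parameters of a model."""
    layout = [("tv_cl", "log"), ("tv_v", "log")]
    for eff in model.effects:
        layout.append((f"beta_{eff.key}", "id"))
    for p in model.eta_names:
        layout.append((f"omega2_{p}", "log"))
    for comp in model.residual.free_components():
        layout.append((comp, "id" if comp == "gamma" else "log"))
    return [(n, tr) for n, tr in layout if n not in fixed]


def _get_param(model: ModelSpec, name: str) -> float:
    if name == "tv_cl":
        return model.theta["cl"]
    if name == "tv_v":
        return model.theta["v"]
    if name.startswith("beta_"):
        key = name[len("beta_"):]
        return next(e.coefficient for e in model.effects if e.key == key)
    if name.startswith("omega2_"):
        return model.omega2[name[len("omega2_"):]]
    return getattr(model.residual, name)


def _set_params(model: ModelSpec, values: dict) -> ModelSpec:
    theta = dict(model.theta)
    omega2 = dict(model.omega2)
    res_kw = {}
    effects = list(model.effects)
    for name, val in values.items():
        if name == "tv_cl":
            theta["cl"] = val
        elif name == "tv_v":
            theta["v"] = val
        elif name.startswith("beta_"):
            key = name[len("beta_"):]
            effects = [
                replace(e, coefficient=val) if e.key == key else e for e in effects
            ]
        elif name.startswith("omega2_"):
            omega2[name[len("omega2_"):]] = val
        else:
            res_kw[name] = val
    residual = replace(model.residual, **res_kw) if res_kw else model.residual
    return replace(
        model, theta=theta, omega2=omega2, effects=tuple(effects), residual=residual
    )


def fit(data, model: ModelSpec, fixed=(), outer_tol=1e-6, max_iter=400,
        compute_se: bool = True) -> FitResult:
    """Maximum-likelihood fit of a population model by FOCE-I.

    ``model`` supplies the structure and the initial values; ``fixed``
    names parameters to hold at their initial values.  Positive
    parameters (typical values, variances, residual sds) are optimized
    on the log scale.  The result is deterministic given the dataset,
    the initial values and the tolerances.
    """
    arrays = _as_arrays(data)
    layout = _param_layout(model, fixed)
    names = [n for n, _ in layout]
    warn: list[str] = []

    n_var_free = sum(1 for n in names if n.startswith(("omega2_", "sigma")))
    max_obs = int(arrays.obs_mask.sum(axis=1).max())
    if max_obs <= 1 and n_var_free >= 2:
        warn.append(
            "identifiability: one observation per subject cannot separate "
            f"{n_var_free} variance components"
        )

    def pack(m: ModelSpec):
        x = []
        for name, tr in layout:
            v = _get_param(m, name)
            x.append(np.log(v) if tr == "log" else v)
        return np.array(x)

    def unpack(x) -> ModelSpec:
        vals = {}
        for (name, tr), xi in zip(layout, x):
            vals[name] = float(np.exp(xi)) if tr == "log" else float(xi)
        return _set_params(model, vals)

    state = {"eta": None, "n_eval": 0}

    def objective(x) -> float:
        state["n_eval"] += 1
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > 50):
            return 1e10
        try:
            m = unpack(x)
            prep = _Prepared(arrays, m)
            eta0 = state["eta"]
            if eta0 is not None and eta0.shape != (prep.n, prep.k):
                eta0 = None
            eta_hat = prep.inner_mode(eta0)
            state["eta"] = eta_hat
            ofv = float(prep.foce_terms(eta_hat).sum())
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            return 1e10
        return ofv if np.isfinite(ofv) else 1e10

    if not layout:
        # everything held fixed: evaluate the model as given
        prep = _Prepared(arrays, model)
        ebe = prep.inner_mode()
        return FitResult(
            model=model, ofv=float(prep.foce_terms(ebe).sum()), estimates={},
            se=None, rse=None, ebe=ebe, eta_names=prep.eta_names,
            convergence="converged", n_iter=0, n_eval=1, warnings=warn,
        )

    x0 = pack(model)
    with np.errstate(over="raise", invalid="raise", divide="raise", under="ignore"):
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": outer_tol * 1e-2,
                     "gtol": 1e-4, "eps": 1e-6},
        )
        # polish with a simplex pass if the quasi-Newton run looks unhappy
        if not res.success or not np.isfinite(res.fun):
            res2 = optimize.minimize(
                objective, res.x if np.isfinite(res.fun) else x0,
                method="Nelder-Mead",
                options={"maxiter": max_iter * 4, "fatol": outer_tol,
                         "xatol": 1e-6},
            )
            if res2.fun <= res.fun:
                res = res2

    fitted = unpack(res.x)
    prep = _Prepared(arrays, fitted)
    ebe = prep.inner_mode(state["eta"])
    ofv = float(prep.foce_terms(ebe).sum())
    estimates = {n: _get_param(fitted, n) for n in names}

    for p in fitted.eta_names:
        if fitted.omega2[p] < 1e-6:
            warn.append(f"boundary: omega2_{p} collapsed to ~0")
    for comp in fitted.residual.free_components():
        if comp != "gamma" and getattr(fitted.residual, comp) < 1e-6:
            warn.append(f"boundary: {comp} collapsed to ~0")

    se = rse = None
    if compute_se and (res.success or np.isfinite(ofv)):
        se, rse, hess_warn = _standard_errors(objective, pack(fitted), layout, estimates)
        warn.extend(hess_warn)

    return FitResult(
        model=fitted,
        ofv=ofv,
        estimates=estimates,
        se=se,
        rse=rse,
        ebe=ebe,
        eta_names=prep.eta_names,
        convergence="converged" if res.success else f"failed: {res.message}",
        n_iter=int(getattr(res, "nit", 0)),
        n_eval=state["n_eval"],
        warnings=warn,
    )


def _standard_errors(objective, x_opt, layout, estimates):
    """SEs from the observed information: cov = 2 H^{-1} of the OFV.

    The Hessian is taken on the transformed (packed) scale by central
    differences and mapped back by the delta method.
    """
    p = len(x_opt)
    h = 1e-3
    H = np.zeros((p, p))
    f0 = objective(x_opt)
    warn = []
    try:
        for i in range(p):
            for j in range(i, p):
                ei = np.zeros(p); ei[i] = h
                ej = np.zeros(p); ej[j] = h
                if i == j:
                    H[i, i] = (objective(x_opt + ei) - 2 * f0 + objective(x_opt - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        objective(x_opt + ei + ej) - objective(x_opt + ei - ej)
                        - objective(x_opt - ei + ej) + objective(x_opt - ei - ej)
                    ) / (4 * h**2)
        cov_t = 2.0 * np.linalg.inv(H)
        if np.any(np.diag(cov_t) <= 0):
            raise np.linalg.LinAlgError("non-PD information matrix")
    except np.linalg.LinAlgError:
        return None, None, ["standard errors unavailable (singular information)"]
    se, rse = {}, {}
    for idx, (name, tr) in enumerate(layout):
        sd_t = float(np.sqrt(cov_t[idx, idx]))
        est = estimates[name]
        # log-scale parameters: SE on natural scale by the delta method
        sd_nat = sd_t * abs(est) if tr == "log" else sd_t
        se[name] = sd_nat
        rse[name] = 100.0 * sd_nat / abs(est) if est != 0 else np.inf
    return se, rse, warn


# ---------------------------------------------------------------------------
# residual diagnostics

def compute_cwres(data, fit_result: FitResult):
    """PRED, IPRED and conditional weighted residuals per observation.

    CWRES decorrelates the FOCE-linearized residual by the model-implied
    observation covariance: ``cwres_i = L_i^{-1} r_i`` with
    ``C_i = L_i L_i'``.  With no between-subject variability this reduces
    to the standardized residual (y - f) / sd.
    """
    import pandas as pd
    from scipy.linalg import cholesky, solve_triangular

    arrays = _as_arrays(data)
    model = fit_result.model
    prep = _Prepared(arrays, model)
    eta_hat = prep.inner_mode(
        fit_result.ebe if fit_result.ebe.shape == (prep.n, prep.k) else None
    )
    f, G = prep.predict_with_jac(eta_hat)
    var, _, res, _ = prep._data_terms(f)
    pred = prep.predict(np.zeros_like(eta_hat))
    rows = []
    Om = np.diag(prep.om2) if prep.k else np.zeros((0, 0))
    for i in range(prep.n):
        msk = prep.mask[i]
        mi = int(msk.sum())
        Gi = G[i][msk]
        Ci = Gi @ Om @ Gi.T + np.diag(var[i][msk])
        ri = res[i][msk] + Gi @ eta_hat[i]
        try:
            L = cholesky(Ci, lower=True)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular observation covariance for subject {arrays.ids[i]}"
            )
        cw = solve_triangular(L, ri, lower=True)
        t = arrays.t_obs[i][msk]
        yv = arrays.y[i][msk]
        for j in range(mi):
            rows.append({
                "ID": arrays.ids[i], "TIME": t[j], "DV": yv[j],
                "PRED": pred[i][msk][j], "IPRED": f[i][msk][j], "CWRES": cw[j],
            })
    return pd.DataFrame(rows)
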