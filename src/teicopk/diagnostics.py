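"""Model evaluation: goodness-of-fit tables, nonparametric bootstrap,
and the prediction-corrected visual predictive check (pc-VPC).

All diagnostics are pure functions of (dataset, model/fit, seed): a
rerun with the same inputs reproduces the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .estimate import FitResult, _Prepared, compute_cwres, fit
from .model import ModelSpec

__all__ = ["gof", "bootstrap", "BootstrapResult", "pc_vpc", "VPCResult"]


def gof(data, fit_result: FitResult) -> pd.DataFrame:
    """Observation-level goodness-of-fit table.

    One row per observation with DV, population prediction (PRED, all
    random effects at zero), individual prediction (IPRED, at the
    empirical Bayes estimates), CWRES and time — the material of the
    classic four-panel diagnostic plot.
    """
    return compute_cwres(data, fit_result)


@dataclass
class BootstrapResult:
    """Percentile bootstrap summary of parameter uncertainty."""

    table: pd.DataFrame  # index: parameter; estimate, median, ci_lo, ci_hi
    n_resamples: int
    n_converged: int

    def covers(self, name: str, value: float) -> bool:
        row = self.table.loc[name]
        return bool(row["ci_lo"] <= value <= row["ci_hi"])


def bootstrap(data, model: ModelSpec, n_resamples: int = 1000, seed=None,
              index_sampler=None, **fit_kw) -> BootstrapResult:
    """Nonparametric bootstrap: subjects resampled with replacement.

    Each resampled cohort (original size) is refit from the initial
    values in ``model``; non-converged resamples are dropped and
    counted.  Percentile 95% CIs (2.5th/97.5th) are taken across the
    converged fits.  ``index_sampler(i, rng, n) -> indices`` can replace
    the default uniform resampler (testing hook).
    """
    arrays = data.arrays() if isinstance(data, Dataset) else data
    rng = np.random.default_rng(seed)
    n = arrays.n_subjects
    fit_kw.setdefault("compute_se", False)

    point = fit(arrays, model, **fit_kw)
    names = list(point.estimates)
    draws = []
    n_converged = 0
    for i in range(n_resamples):
        idx = (index_sampler(i, rng, n) if index_sampler is not None
               else rng.integers(0, n, size=n))
        res = arrays.subset(np.asarray(idx))
        try:
            # resample fits start from the point estimates
            f = fit(res, point.model, **fit_kw)
        except Exception:
            continue
        if not np.isfinite(f.ofv):
            continue
        n_converged += 1
        draws.append([f.estimates[k] for k in names])
    if n_converged < 0.5 * n_resamples:
        raise RuntimeError(
            f"bootstrap failed: only {n_converged}/{n_resamples} resamples converged"
        )
    mat = np.array(draws)
    table = pd.DataFrame(
        {
            "estimate": [point.estimates[k] for k in names],
            "median": np.median(mat, axis=0),
            "ci_lo": np.percentile(mat, 2.5, axis=0),
            "ci_hi": np.percentile(mat, 97.5, axis=0),
        },
        index=names,
    )
    return BootstrapResult(table=table, n_resamples=n_resamples,
                           n_converged=n_converged)


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary per time bin."""

    bins: pd.DataFrame   # bin_lo, bin_hi, n_obs, obs_p*, sim_p*_lo/hi
    percentiles: tuple
    n_replicates: int

    def observed_inside_band(self, percentile: int) -> np.ndarray:
        p = percentile
        b = self.bins
        return ((b[f"obs_p{p}"] >= b[f"sim_p{p}_lo"])
                & (b[f"obs_p{p}"] <= b[f"sim_p{p}_hi"])).to_numpy()


def pc_vpc(data, model: ModelSpec, n_replicates: int = 1000, bins: int = 4,
           percentiles=(10, 50, 90), seed=None) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observations and simulations are scaled by bin-median population
    prediction (pcY = y * median(PRED in bin) / PRED), which removes
    covariate- and dose-driven trends; each replicate re-simulates every
    observation under the model at the original design.  The band for
    each percentile is its 90% CI (5th-95th) across replicates.
    """
    arrays = data.arrays() if isinstance(data, Dataset) else data
    rng = np.random.default_rng(seed)
    prep = _Prepared(arrays, model)
    mask = arrays.obs_mask
    t = arrays.t_obs[mask]
    y = arrays.y[mask]
    pred = prep.predict(np.zeros((prep.n, prep.k)))[mask]

    # bins by time quantiles; merge any empty/duplicate edges
    edges = np.unique(np.quantile(t, np.linspace(0, 1, bins + 1)))
    if len(edges) < 2:
        edges = np.array([t.min() - 0.5, t.max() + 0.5])
    bin_idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)

    med_pred = np.array([
        np.median(pred[bin_idx == b]) if np.any(bin_idx == b) else np.nan
        for b in range(len(edges) - 1)
    ])
    with np.errstate(divide="ignore", invalid="ignore"):
        pc_obs = y * med_pred[bin_idx] / np.where(pred > 0, pred, np.nan)

    obs_pct = {
        p: np.array([
            np.percentile(pc_obs[bin_idx == b], p)
            for b in range(len(edges) - 1)
        ])
        for p in percentiles
    }

    sim_pct = {p: np.zeros((n_replicates, len(edges) - 1)) for p in percentiles}
    for r in range(n_replicates):
        eta = np.zeros((prep.n, prep.k))
        for d in range(prep.k):
            eta[:, d] = rng.normal(0.0, np.sqrt(prep.om2[d]), size=prep.n)
        f = prep.predict(eta)
        sd = model.residual.sd(f)
        sim = np.clip(f + sd * rng.standard_normal(f.shape), 0.0, None)[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            pc_sim = sim * med_pred[bin_idx] / np.where(pred > 0, pred, np.nan)
        for p in percentiles:
            for b in range(len(edges) - 1):
                sel = bin_idx == b
                sim_pct[p][r, b] = np.percentile(pc_sim[sel], p)

    rows = {
        "bin_lo": edges[:-1], "bin_hi": edges[1:],
        "n_obs": np.bincount(bin_idx, minlength=len(edges) - 1),
    }
    for p in percentiles:
        rows[f"obs_p{p}"] = obs_pct[p]
        rows[f"sim_p{p}_lo"] = np.percentile(sim_pct[p], 5, axis=0)
        rows[f"sim_p{p}_med"] = np.percentile(sim_pct[p], 50, axis=0)
        rows[f"sim_p{p}_hi"] = np.percentile(sim_pct[p], 95, axis=0)
    return VPCResult(bins=pd.DataFrame(rows), percentiles=tuple(percentiles),
                     n_replicates=n_replicates)
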