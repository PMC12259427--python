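"""One-compartment IV-infusion kinetics with linear elimination.

Closed-form concentration and interval-AUC under superposition of
constant-rate infusions, plus dosing-regimen expansion.  All time is in
hours, zero-based at the first dose; concentrations in mg/L, amounts in
mg, clearance in L/h, volume in L.

Conventions
-----------
* Evaluation at a dose start time *excludes* that dose (pre-dose / trough
  convention), so ``concentration(p, doses, t)`` at a scheduled dose time
  is the trough preceding that dose.
* AUC over an interval is the exact analytic integral of the superposed
  solution, piecewise across infusion boundaries; no quadrature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseEvent",
    "Regimen",
    "PKParams",
    "expand_regimen",
    "parse_regimen",
    "concentration",
    "auc",
    "typical_params",
]


@dataclass(frozen=True)
class DoseEvent:
    """A single constant-rate IV infusion."""

    start_time: float  # h since first dose
    amount: float      # mg
    duration: float = 1.0  # h

    def __post_init__(self):
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.duration <= 0:
            raise ValueError(f"infusion duration must be > 0, got {self.duration}")
        if self.start_time < 0:
            raise ValueError(f"dose start time must be >= 0, got {self.start_time}")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """Loading/maintenance dose pattern expandable to timed infusions.

    Loading doses are given at 0, loading_interval, ...; the first
    maintenance dose follows one *maintenance* interval after the last
    loading dose, then repeats up to and including the horizon.
    """

    loading_dose: float
    loading_interval: float
    n_loading: int
    maintenance_dose: float
    maintenance_interval: float
    infusion_duration: float = 1.0
    horizon: float = 168.0

    def __post_init__(self):
        if self.n_loading < 0:
            raise ValueError("n_loading must be >= 0")
        if self.loading_interval <= 0 or self.maintenance_interval <= 0:
            raise ValueError("dose intervals must be > 0")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be > 0")
        last = (self.n_loading - 1) * self.loading_interval if self.n_loading else 0.0
        if self.horizon < last:
            raise ValueError("horizon must reach the last loading dose")

    def label(self) -> str:
        if self.n_loading:
            return (
                f"{self.loading_dose:g}x{self.n_loading}@q{self.loading_interval:g}h"
                f"+{self.maintenance_dose:g}@q{self.maintenance_interval:g}h"
            )
        return f"{self.maintenance_dose:g}@q{self.maintenance_interval:g}h"

    @property
    def total_dose(self) -> float:
        return sum(d.amount for d in expand_regimen(self))


@dataclass(frozen=True)
class PKParams:
    """Individual disposition parameters."""

    cl: float  # L/h
    v: float   # L

    def __post_init__(self):
        if self.cl <= 0 or self.v <= 0:
            raise ValueError(f"CL and V must be > 0 (got CL={self.cl}, V={self.v})")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


def expand_regimen(regimen: Regimen) -> list[DoseEvent]:
    """Expand a loading + maintenance pattern into timed infusion events.

    Loading doses at ``0, L, ..., (n_loading-1)*L``; maintenance doses
    start one maintenance interval after the last loading dose (or at 0
    when there is no loading phase) and repeat while ``t <= horizon``.
    """
    events: list[DoseEvent] = []
    t = 0.0
    for i in range(regimen.n_loading):
        t = i * regimen.loading_interval
        events.append(DoseEvent(t, regimen.loading_dose, regimen.infusion_duration))
    if regimen.n_loading:
        t = (regimen.n_loading - 1) * regimen.loading_interval + regimen.maintenance_interval
    else:
        t = 0.0
    while t <= regimen.horizon + 1e-9:
        events.append(DoseEvent(t, regimen.maintenance_dose, regimen.infusion_duration))
        t += regimen.maintenance_interval
    return events


_REGIMEN_RE = re.compile(
    r"^\s*(?:(?P<ld>[\d.]+)x(?P<n>\d+)@q(?P<li>[\d.]+)h\+)?"
    r"(?P<md>[\d.]+)@q(?P<mi>[\d.]+)h"
    r"(?:/(?P<dur>[\d.]+)h)?(?:/(?P<hor>[\d.]+)h)?\s*$"
)


def parse_regimen(text: str) -> Regimen:
    """Parse the compact regimen grammar.

    ``"600x3@q12h+400@q24h/1h/168h"`` reads as 600 mg q12h for 3 loading
    doses, then 400 mg q24h maintenance, 1-h infusions, 168-h horizon.
    The loading part, infusion duration and horizon are optional
    (defaults: no loading, 1 h, 168 h).
    """
    m = _REGIMEN_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse regimen {text!r}")
    g = m.groupdict()
    return Regimen(
        loading_dose=float(g["ld"]) if g["ld"] else float(g["md"]),
        loading_interval=float(g["li"]) if g["li"] else 12.0,
        n_loading=int(g["n"]) if g["n"] else 0,
        maintenance_dose=float(g["md"]),
        maintenance_interval=float(g["mi"]),
        infusion_duration=float(g["dur"]) if g["dur"] else 1.0,
        horizon=float(g["hor"]) if g["hor"] else 168.0,
    )


# ---------------------------------------------------------------------------
# Vectorized kernels.  cl, v: (n, 1); dose arrays: (n, d); t: (n, m).
# cl and v may be complex (complex-step differentiation); times and dose
# schedules are always real.

def conc_kernel(cl, v, dose_start, dose_rate, dose_dur, dose_mask, t):
    """Superposed one-compartment infusion concentration, broadcast form.

    A dose contributes only strictly after its start time (pre-dose
    convention).  The during/post-infusion branches are unified through
    the elapsed-infusion time ``te = min(tau, duration)``:
    ``C = (R/CL) (1 - exp(-ke te)) exp(-ke (tau - te))``.
    """
    ke = (cl / v)[..., None]                      # (n, 1, 1)
    tau = t[:, :, None] - dose_start[:, None, :]  # (n, m, d)
    active = (tau > 0) & dose_mask[:, None, :]
    tau_s = np.maximum(tau, 0.0)                  # keep the exp argument bounded
    dur = dose_dur[:, None, :]
    te = np.minimum(tau_s, dur)
    c = (dose_rate[:, None, :] / cl[..., None]) * (1.0 - np.exp(-ke * te)) * np.exp(
        -ke * (tau_s - te)
    )
    return np.where(active, c, 0.0).sum(axis=2)


def auc_kernel(cl, v, dose_start, dose_rate, dose_dur, dose_mask, t1, t2):
    """Exact integral of the superposed solution over [t1, t2].

    Each dose's contribution splits at its infusion end; both pieces have
    elementary antiderivatives.
    """
    ke = cl / v
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    out = np.zeros(
        np.broadcast_shapes(cl.shape, t1.shape, t2.shape), dtype=np.result_type(cl, t1)
    )
    for j in range(dose_start.shape[1]):
        s = dose_start[:, j : j + 1]
        dur = dose_dur[:, j : j + 1]
        scale = dose_rate[:, j : j + 1] / cl
        a = np.clip(t1 - s, 0.0, None)
        b = np.clip(t2 - s, 0.0, None)
        a1 = np.minimum(a, dur)
        b1 = np.minimum(b, dur)
        part1 = scale * ((b1 - a1) + (np.exp(-ke * b1) - np.exp(-ke * a1)) / ke)
        a2 = np.maximum(a, dur)
        b2 = np.maximum(b, dur)
        part2 = (
            scale
            * (1.0 - np.exp(-ke * dur))
            * (np.exp(-ke * (a2 - dur)) - np.exp(-ke * (b2 - dur)))
            / ke
        )
        out = out + np.where(dose_mask[:, j : j + 1] & (b > a), part1 + part2, 0.0)
    return out


def _dose_arrays(doses: list[DoseEvent]):
    if not doses:
        z = np.zeros((1, 0))
        return z, z, z, np.zeros((1, 0), dtype=bool)
    start = np.array([[d.start_time for d in doses]])
    rate = np.array([[d.rate for d in doses]])
    dur = np.array([[d.duration for d in doses]])
    return start, rate, dur, np.ones_like(start, dtype=bool)


def concentration(params: PKParams, doses: list[DoseEvent], t) -> float | np.ndarray:
    """Plasma concentration at time(s) ``t`` (mg/L).

    A dose starting exactly at ``t`` is excluded, so the value at a
    scheduled dose time is the preceding trough.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    start, rate, dur, mask = _dose_arrays(doses)
    cl = np.array([[params.cl]])
    v = np.array([[params.v]])
    out = conc_kernel(cl, v, start, rate, dur, mask, t_arr[None, :])[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def auc(params: PKParams, doses: list[DoseEvent], t1: float, t2: float) -> float:
    """Analytic AUC (mg·h/L) of the superposed profile over [t1, t2].

    ``t2 = inf`` is supported: by mass balance the total AUC of each dose
    is amount/CL, so AUC(t1, inf) = sum(amount)/CL − AUC(0, t1).
    """
    if t1 < 0 or t2 <= t1:
        raise ValueError(f"need 0 <= t1 < t2, got [{t1}, {t2}]")
    if not doses:
        return 0.0
    if np.isinf(t2):
        total = sum(d.amount for d in doses) / params.cl
        return total - (auc(params, doses, 0.0, t1) if t1 > 0 else 0.0)
    start, rate, dur, mask = _dose_arrays(doses)
    cl = np.array([[params.cl]])
    v = np.array([[params.v]])
    return float(auc_kernel(cl, v, start, rate, dur, mask, t1, t2)[0, 0])


def typical_params(theta: dict, effects, cov: dict) -> PKParams:
    """Covariate-adjusted typical CL and V for one covariate profile.

    ``theta`` maps ``{"cl": tvCL, "v": tvV}``; each effect multiplies its
    target parameter by ``exp(coef * x)`` (categorical, x in {0,1}) or
    ``(x / reference) ** coef`` (continuous, median-normalized power).
    """
    vals = {"cl": float(theta["cl"]), "v": float(theta["v"])}
    for eff in effects:
        if eff.covariate not in cov:
            raise KeyError(f"covariate {eff.covariate!r} missing from profile")
        vals[eff.parameter] *= eff.multiplier(cov[eff.covariate])
    return PKParams(cl=vals["cl"], v=vals["v"])
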