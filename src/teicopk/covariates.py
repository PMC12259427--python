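"""Stepwise covariate model building on the likelihood-ratio scale.

Forward inclusion adds, one at a time, the candidate effect with the
largest drop in objective function value among those dropping it by
more than 3.84 (chi-square, 1 df, p < 0.05); backward elimination then
removes any retained effect whose removal raises the OFV by 6.63 or
less (p < 0.01 to stay).  Every candidate carries exactly one
coefficient, so 1 df is hard-wired.

Continuous candidates use the median-normalized power form with the
reference median computed once from the base dataset; categorical
candidates (0/1) use the exponential form.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import Dataset
from .estimate import FitResult, fit
from .model import CovariateEffect, ModelSpec

__all__ = [
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
    "default_candidates",
    "evaluate_candidate",
    "stepwise_search",
    "SearchStep",
    "SearchResult",
]

FORWARD_THRESHOLD = 3.84   # chi2(1) 5% point: required OFV *drop* to enter
BACKWARD_THRESHOLD = 6.63  # chi2(1) 1% point: required OFV *rise* to stay

_CATEGORICAL = {"sex", "crrt", "ecmo"}
_INIT_COEF = {"power": 0.1, "exponential": 0.01}


@dataclass(frozen=True)
class SearchStep:
    phase: str        # "forward" | "backward"
    candidate: str    # effect key, e.g. "crrt_v"
    delta_ofv: float  # improvement offered (forward) or cost of removal (backward)
    threshold: float
    decision: str     # "added" | "rejected" | "removed" | "kept" | "failed"


@dataclass
class SearchResult:
    final: ModelSpec
    final_fit: FitResult
    trace: list = field(default_factory=list)

    def trace_records(self) -> list:
        return [vars(s) for s in self.trace]


def default_candidates(dataset, parameters=("cl", "v"),
                       covariates=("sex", "crrt", "age", "weight", "albumin", "scr")):
    """Candidate effects for each (covariate, parameter) pairing.

    Continuous covariates are referenced to their dataset median, taken
    over subjects (not rows).
    """
    arrays = dataset.arrays() if isinstance(dataset, Dataset) else dataset
    cov = arrays.covariates
    out = []
    for name in covariates:
        for p in parameters:
            if name in _CATEGORICAL:
                out.append(CovariateEffect(p, name, "exponential", _INIT_COEF["exponential"]))
            else:
                med = float(np.median(cov[name].to_numpy(dtype=float)))
                out.append(CovariateEffect(p, name, "power", _INIT_COEF["power"], med))
    return out


def _with_init_coef(effect: CovariateEffect) -> CovariateEffect:
    if effect.coefficient != 0.0:
        return effect
    return replace(effect, coefficient=_INIT_COEF[effect.form])


def evaluate_candidate(data, base: ModelSpec, candidate: CovariateEffect,
                       base_fit: FitResult | None = None, **fit_kw):
    """OFV improvement offered by one additional covariate effect.

    Both models are fit from the same initial values (those stored in
    ``base``); returns ``OFV(base) - OFV(base + candidate)``, positive
    when the candidate improves the fit, together with the candidate's
    fit.  Raises if the candidate duplicates an effect already present.
    """
    if any(e.key == candidate.key for e in base.effects):
        raise ValueError(f"candidate {candidate.key} already in the base model")
    fit_kw.setdefault("compute_se", False)
    if base_fit is None:
        base_fit = fit(data, base, **fit_kw)
    cand_model = base.with_effect(_with_init_coef(candidate))
    cand_fit = fit(data, cand_model, **fit_kw)
    return base_fit.ofv - cand_fit.ofv, cand_fit


def stepwise_search(data, base: ModelSpec, candidates,
                    forward_threshold: float = FORWARD_THRESHOLD,
                    backward_threshold: float = BACKWARD_THRESHOLD,
                    fitter=None, **fit_kw) -> SearchResult:
    """Forward-inclusion / backward-elimination covariate search.

    ``fitter(data, model) -> FitResult`` may be injected (mainly for
    testing); by default the FOCE-I ``fit`` is used without standard
    errors.  Ties in the forward phase break alphabetically by covariate
    name, then by target parameter.
    """
    if fitter is None:
        fit_kw.setdefault("compute_se", False)
        fitter = lambda d, m: fit(d, m, **fit_kw)

    arrays = data.arrays() if isinstance(data, Dataset) else data
    trace: list[SearchStep] = []
    current_fit = fitter(arrays, base)
    # carry converged estimates forward as the next phase's initial values
    current = current_fit.model
    remaining = [_with_init_coef(c) for c in candidates]

    # forward inclusion
    while remaining:
        results = []
        for cand in remaining:
            if any(e.key == cand.key for e in current.effects):
                continue
            try:
                cand_fit = fitter(arrays, current.with_effect(cand))
            except Exception:
                trace.append(SearchStep("forward", cand.key, np.nan,
                                        forward_threshold, "failed"))
                continue
            d = current_fit.ofv - cand_fit.ofv
            results.append((cand, d, cand_fit))
        if not results:
            break
        # deterministic tie-break: largest drop, then covariate, parameter
        results.sort(key=lambda r: (-r[1], r[0].covariate, r[0].parameter))
        best, best_d, best_fit = results[0]
        for cand, d, _ in results:
            if cand.key != best.key:
                trace.append(SearchStep("forward", cand.key, d,
                                        forward_threshold, "rejected"))
        if best_d > forward_threshold:
            trace.append(SearchStep("forward", best.key, best_d,
                                    forward_threshold, "added"))
            current = best_fit.model
            current_fit = best_fit
            remaining = [c for c in remaining if c.key != best.key]
        else:
            trace.append(SearchStep("forward", best.key, best_d,
                                    forward_threshold, "rejected"))
            break

    # backward elimination, least significant effect first
    retained = [e for e in current.effects if e.key not in {x.key for x in base.effects}]
    while retained:
        costs = []
        for eff in retained:
            try:
                red_fit = fitter(arrays, current.without_effect(eff.key))
            except Exception:
                trace.append(SearchStep("backward", eff.key, np.nan,
                                        backward_threshold, "failed"))
                continue
            costs.append((eff, red_fit.ofv - current_fit.ofv, red_fit))
        if not costs:
            break
        costs.sort(key=lambda r: (r[1], r[0].covariate, r[0].parameter))
        worst, cost, red_fit = costs[0]
        if cost > backward_threshold:
            for eff, c, _ in costs:
                trace.append(SearchStep("backward", eff.key, c,
                                        backward_threshold, "kept"))
            break
        trace.append(SearchStep("backward", worst.key, cost,
                                backward_threshold, "removed"))
        current = red_fit.model
        current_fit = red_fit
        retained = [e for e in retained if e.key != worst.key]

    return SearchResult(final=current, final_fit=current_fit, trace=trace)
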