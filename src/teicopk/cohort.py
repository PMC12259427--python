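"""Synthetic study cohorts emulating the sepsis TDM study design.

The real patient data are not deposited, so this module generates
virtual cohorts with the study's covariate structure (86 septic adults,
40.70% female, 23.26% on CRRT, 4.65% on ECMO; log-normal continuous
covariates matched to the published median/IQR) and simulates sparse
therapeutic-drug-monitoring observations under a given population model.

Default dosing is the study regimen: 400 mg q12h for three loading doses
then 400 mg q24h maintenance, all as 1-h infusions.  The default
sampling design is one steady-state trough per subject, drawn on a
uniformly chosen maintenance day (days 4–7 after the first dose) and
placed immediately pre-dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset
from .model import ModelSpec
from .pk import DoseEvent, Regimen, conc_kernel, expand_regimen

__all__ = [
    "CovariateProfile",
    "CohortConfig",
    "Observation",
    "Subject",
    "generate_cohort",
    "simulate_observations",
    "DEFAULT_REGIMEN",
    "RICH_TIMES",
]

# z-score of the 75th percentile: IQR of a log-normal spans 2*z075 sigmas in log
_Z075 = 0.674489750196082

DEFAULT_REGIMEN = Regimen(
    loading_dose=400.0, loading_interval=12.0, n_loading=3,
    maintenance_dose=400.0, maintenance_interval=24.0,
    infusion_duration=1.0, horizon=192.0,
)

#: Rich sampling grid used for estimation work: end of first infusion,
#: distribution phase, and pre-dose troughs across the first week.
RICH_TIMES = (1.0, 2.0, 6.0, 12.0, 24.0, 48.0, 96.0, 168.0)


@dataclass(frozen=True)
class CovariateProfile:
    sex: int        # 0 male, 1 female
    crrt: int       # 0/1
    ecmo: int       # 0/1
    age: float      # years
    weight: float   # kg
    height: float   # cm
    albumin: float  # g/L
    scr: float      # umol/L

    def __post_init__(self):
        if self.age < 18:
            raise ValueError("adult cohort: age must be >= 18")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        for flag in (self.sex, self.crrt, self.ecmo):
            if flag not in (0, 1):
                raise ValueError("sex/crrt/ecmo flags must be 0 or 1")

    def as_dict(self) -> dict:
        return {
            "sex": self.sex, "crrt": self.crrt, "ecmo": self.ecmo,
            "age": self.age, "weight": self.weight, "height": self.height,
            "albumin": self.albumin, "scr": self.scr,
        }


@dataclass(frozen=True)
class Observation:
    time: float           # h since first dose
    concentration: float  # mg/L
    is_below_loq: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class Subject:
    id: int
    covariates: CovariateProfile
    dose_events: list = field(default_factory=list)
    observations: list = field(default_factory=list)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design; defaults reproduce the published study table."""

    n_subjects: int = 86
    fraction_female: float = 0.4070
    fraction_crrt: float = 0.2326
    fraction_ecmo: float = 0.0465
    # continuous covariates: name -> (median, q25, q75)
    continuous: dict = field(default_factory=lambda: {
        "age": (62.00, 53.00, 71.25),       # years
        "weight": (62.00, 51.88, 70.00),    # kg
        "height": (165.00, 156.30, 172.00), # cm
        "albumin": (31.60, 29.48, 36.90),   # g/L
        "scr": (109.00, 74.00, 184.80),     # umol/L
    })
    sampling_design: str = "trough"  # or "rich"
    tdm_day_range: tuple = (4, 7)    # inclusive days post first dose
    regimen: Regimen = DEFAULT_REGIMEN
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("fraction_female", "fraction_crrt", "fraction_ecmo"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {f}")
        if self.sampling_design not in ("trough", "rich"):
            raise ValueError(f"unknown sampling design {self.sampling_design!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _lognormal_from_median_iqr(rng, n, median, q25, q75, lower=None):
    """Log-normal samples with the given median and IQR; optional lower
    truncation by resampling (used to keep ages >= 18)."""
    mu = math.log(median)
    sigma = (math.log(q75) - math.log(q25)) / (2.0 * _Z075)
    x = rng.lognormal(mu, sigma, size=n)
    if lower is not None:
        bad = x < lower
        while bad.any():
            x[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
            bad = x < lower
    return x


def generate_cohort(config: CohortConfig, rng=None) -> list[Subject]:
    """Generate a virtual cohort: covariates and dosing, no observations.

    Categorical strata are allocated exactly — ``round(n * fraction)``
    subjects per stratum (half rounds to the larger stratum) — and the
    assignment of subjects to strata is randomized.  Continuous
    covariates are drawn log-normally matched to the configured
    median/IQR.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sex = np.zeros(n, dtype=int)
    sex[: _round_half_up(n * config.fraction_female)] = 1
    rng.shuffle(sex)
    crrt = np.zeros(n, dtype=int)
    crrt[: _round_half_up(n * config.fraction_crrt)] = 1
    rng.shuffle(crrt)
    ecmo = np.zeros(n, dtype=int)
    ecmo[: _round_half_up(n * config.fraction_ecmo)] = 1
    rng.shuffle(ecmo)

    cont = {
        name: _lognormal_from_median_iqr(
            rng, n, *summ, lower=18.0 if name == "age" else None
        )
        for name, summ in config.continuous.items()
    }
    doses = expand_regimen(config.regimen)
    subjects = []
    for i in range(n):
        prof = CovariateProfile(
            sex=int(sex[i]), crrt=int(crrt[i]), ecmo=int(ecmo[i]),
            age=float(cont["age"][i]), weight=float(cont["weight"][i]),
            height=float(cont["height"][i]), albumin=float(cont["albumin"][i]),
            scr=float(cont["scr"][i]),
        )
        subjects.append(Subject(id=i + 1, covariates=prof, dose_events=list(doses)))
    return subjects


def simulate_observations(
    cohort: list[Subject],
    model: ModelSpec,
    design: str = "trough",
    tdm_day_range: tuple = (4, 7),
    rich_times=RICH_TIMES,
    seed=None,
    rng=None,
) -> Dataset:
    """Simulate TDM observations for a cohort under a population model.

    Per subject, random effects are drawn from the BSV distribution,
    concentrations are evaluated with the closed-form kinetics, and
    residual noise is added per the residual model (negative draws
    truncated at 0).  The ``"trough"`` design places one observation
    immediately pre-dose on a uniformly drawn maintenance day inside
    ``tdm_day_range``; ``"rich"`` uses the fixed ``rich_times`` grid.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(cohort)
    eta = {p: np.zeros(n) for p in ("cl", "v")}
    for p in ("cl", "v"):
        w2 = model.omega2.get(p, 0.0)
        if w2 > 0:
            eta[p] = rng.normal(0.0, math.sqrt(w2), size=n)

    if design == "trough":
        lo, hi = tdm_day_range
        days = rng.integers(lo, hi + 1, size=n)
        times = [[24.0 * float(day)] for day in days]
    elif design == "rich":
        times = [list(rich_times)] * n
    else:
        raise ValueError(f"unknown sampling design {design!r}")

    out = []
    for i, subj in enumerate(cohort):
        params = model.individual_params(
            subj.covariates.as_dict(), {"cl": eta["cl"][i], "v": eta["v"][i]}
        )
        t = np.asarray(times[i], dtype=float)
        from .pk import concentration

        f = np.atleast_1d(concentration(params, subj.dose_events, t))
        sd = model.residual.sd(f)
        y = np.clip(f + sd * rng.standard_normal(f.shape), 0.0, None)
        obs = [Observation(float(tt), float(yy)) for tt, yy in zip(t, y)]
        out.append(Subject(subj.id, subj.covariates, list(subj.dose_events), obs))
    return Dataset.from_subjects(out)
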