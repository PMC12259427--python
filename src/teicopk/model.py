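"""Population PK model specification.

A ``ModelSpec`` bundles the structural one-compartment IV model's fixed
effects (typical CL and V), multiplicative covariate effects, diagonal
between-subject variance components, and the residual-error model.  It
doubles as the container for initial values before fitting and for
estimates afterwards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = ["CovariateEffect", "ResidualModel", "ModelSpec", "final_model"]

PARAMETERS = ("cl", "v")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on a disposition parameter.

    Categorical covariates (coded 0/1) enter exponentially,
    ``P' = P * exp(coef * x)``; continuous covariates enter as a
    median-normalized power, ``P' = P * (x / reference) ** coef``.
    """

    parameter: str   # "cl" or "v"
    covariate: str   # column name, e.g. "crrt", "sex", "weight"
    form: str        # "exponential" (categorical) or "power" (continuous)
    coefficient: float = 0.0
    reference: float | None = None  # median of the covariate (power form only)

    def __post_init__(self):
        if self.parameter not in PARAMETERS:
            raise ValueError(f"unknown target parameter {self.parameter!r}")
        if self.form not in ("exponential", "power"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and (self.reference is None or self.reference <= 0):
            raise ValueError("power-form effects need a positive reference (median)")

    @property
    def key(self) -> str:
        return f"{self.covariate}_{self.parameter}"

    def design_value(self, x: float) -> float:
        """Linearized design value z such that the multiplier is exp(coef*z)."""
        if self.form == "exponential":
            return float(x)
        return float(np.log(x / self.reference))

    def multiplier(self, x: float) -> float:
        return float(np.exp(self.coefficient * self.design_value(x)))


@dataclass(frozen=True)
class ResidualModel:
    """Residual unexplained variability: sd of an observation given its
    model prediction f.

    additive      sd = sigma_add
    proportional  sd = sigma_prop * |f|
    mixed         sd = sqrt(sigma_add^2 + (sigma_prop * f)^2)
    power         sd = sigma_add * |f| ** gamma
    """

    form: str = "additive"
    sigma_add: float = 0.23
    sigma_prop: float = 0.0
    gamma: float = 1.0

    def __post_init__(self):
        if self.form not in ("additive", "proportional", "mixed", "power"):
            raise ValueError(f"unknown residual form {self.form!r}")
        active = {
            "additive": [self.sigma_add],
            "proportional": [self.sigma_prop],
            "mixed": [self.sigma_add, self.sigma_prop],
            "power": [self.sigma_add],
        }[self.form]
        if not any(s > 0 for s in active):
            raise ValueError("at least one residual sd component must be > 0")

    def sd(self, f):
        f = np.asarray(f, dtype=float)
        if self.form == "additive":
            return np.full_like(f, self.sigma_add)
        if self.form == "proportional":
            return self.sigma_prop * np.abs(f)
        if self.form == "mixed":
            return np.sqrt(self.sigma_add**2 + (self.sigma_prop * f) ** 2)
        return self.sigma_add * np.abs(f) ** self.gamma

    def var_and_dvar(self, f):
        """Residual variance and its derivative w.r.t. the prediction."""
        f = np.asarray(f, dtype=float)
        if self.form == "additive":
            v = np.full_like(f, self.sigma_add**2)
            return v, np.zeros_like(f)
        if self.form == "proportional":
            return (self.sigma_prop * f) ** 2, 2.0 * self.sigma_prop**2 * f
        if self.form == "mixed":
            return self.sigma_add**2 + (self.sigma_prop * f) ** 2, (
                2.0 * self.sigma_prop**2 * f
            )
        v = self.sigma_add**2 * np.abs(f) ** (2.0 * self.gamma)
        with np.errstate(divide="ignore", invalid="ignore"):
            dv = np.where(f != 0, 2.0 * self.gamma * v / f, 0.0)
        return v, dv

    def free_components(self) -> list[str]:
        return {
            "additive": ["sigma_add"],
            "proportional": ["sigma_prop"],
            "mixed": ["sigma_add", "sigma_prop"],
            "power": ["sigma_add", "gamma"],
        }[self.form]


@dataclass(frozen=True)
class ModelSpec:
    """Full population model: structure, fixed effects, BSV, residual."""

    theta: dict = field(default_factory=lambda: {"cl": 1.0, "v": 100.0})
    effects: tuple = ()
    omega2: dict = field(default_factory=lambda: {"cl": 0.1, "v": 0.1})
    bsv: str = "exponential"  # or "additive"
    residual: ResidualModel = field(default_factory=ResidualModel)

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        for p in PARAMETERS:
            if self.theta.get(p, 0) <= 0:
                raise ValueError(f"typical {p} must be > 0")
            if self.omega2.get(p, 0.0) < 0:
                raise ValueError(f"omega2[{p!r}] must be >= 0")
        if self.bsv not in ("exponential", "additive"):
            raise ValueError(f"unknown BSV form {self.bsv!r}")
        keys = [e.key for e in self.effects]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate covariate effect")

    # -- convenience -------------------------------------------------------
    @property
    def eta_names(self) -> tuple:
        """Parameters carrying a nonzero BSV variance, in canonical order."""
        return tuple(p for p in PARAMETERS if self.omega2.get(p, 0.0) > 0)

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        if any(e.key == effect.key for e in self.effects):
            raise ValueError(f"effect {effect.key} already in model")
        return replace(self, effects=self.effects + (effect,))

    def without_effect(self, key: str) -> "ModelSpec":
        kept = tuple(e for e in self.effects if e.key != key)
        if len(kept) == len(self.effects):
            raise ValueError(f"effect {key} not in model")
        return replace(self, effects=kept)

    def individual_params(self, cov: dict, eta: dict | None = None):
        """Covariate-adjusted CL, V for one subject, optionally with eta."""
        from .pk import typical_params

        p = typical_params(self.theta, self.effects, cov)
        if not eta:
            return p
        cl, v = p.cl, p.v
        if self.bsv == "exponential":
            cl *= np.exp(eta.get("cl", 0.0))
            v *= np.exp(eta.get("v", 0.0))
        else:
            cl += eta.get("cl", 0.0)
            v += eta.get("v", 0.0)
        from .pk import PKParams

        return PKParams(cl=cl, v=v)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta": dict(self.theta),
            "effects": [dataclasses.asdict(e) for e in self.effects],
            "omega2": dict(self.omega2),
            "bsv": self.bsv,
            "residual": dataclasses.asdict(self.residual),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            theta=dict(d.get("theta", {"cl": 1.0, "v": 100.0})),
            effects=tuple(CovariateEffect(**e) for e in d.get("effects", [])),
            omega2=dict(d.get("omega2", {"cl": 0.0, "v": 0.0})),
            bsv=d.get("bsv", "exponential"),
            residual=ResidualModel(**d.get("residual", {})),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def final_model() -> ModelSpec:
    """The published teicoplanin sepsis model.

    Typical CL 0.98 L/h (no covariates); typical V 108.69 L scaled by
    exp(−0.71) under CRRT and exp(−1.07) for females; log-normal BSV with
    ω²_CL = 0.31 and ω²_V = 0.09; additive residual sd 0.23 mg/L.
    """
    return ModelSpec(
        theta={"cl": 0.98, "v": 108.69},
        effects=(
            CovariateEffect("v", "crrt", "exponential", -0.71),
            CovariateEffect("v", "sex", "exponential", -1.07),
        ),
        omega2={"cl": 0.31, "v": 0.09},
        bsv="exponential",
        residual=ResidualModel(form="additive", sigma_add=0.23),
    )
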