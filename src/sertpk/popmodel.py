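"""Population parameter model for sertraline in pediatric MDD.

Typical-value model with allometric weight scaling and a binary
zopiclone co-medication effect on clearance, exponential inter-individual
variability (IIV) on clearance, and a combined proportional + additive
residual-error model:

    CL/F_i = cl_pop * (WT_i/70)^0.75 * (1 + theta_zop * ZOP_i) * exp(eta_i)
    V/F_i  = v_pop  * (WT_i/70)
    Ka_i   = ka_fixed
    B_ij   = C_ij * (1 + eps1_ij) + eps2_ij

The published final model has cl_pop = 74 L/h, v_pop = 874 L,
ka_fixed = 0.5 /h, theta_zop = -0.547, omega_cl = 0.391,
sigma_prop = 0.159, sigma_add = 9.803 ng/mL.

``interpretation_mode`` records whether the variability magnitudes are
standard deviations (``"sd"``, the default — see docs/methods.md) or
variances (``"variance"``); every fitted or simulated artifact carries
the mode it used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import yaml

from .pkmodel import StructuralParams

__all__ = [
    "FixedEffects",
    "RandomEffects",
    "ResidualModel",
    "CovariateEffect",
    "Subject",
    "PopulationModel",
    "typical_params",
    "individual_params",
    "sample_eta",
    "apply_residual",
    "FINAL_MODEL",
]

Mode = Literal["sd", "variance"]


def _as_sd(value: float, mode: Mode) -> float:
    if mode == "sd":
        return float(value)
    if mode == "variance":
        return float(np.sqrt(value))
    raise ValueError(f"interpretation_mode must be 'sd' or 'variance', got {mode!r}")


@dataclass(frozen=True)
class FixedEffects:
    """Typical values and fixed covariate structure.

    ``theta_zop`` is the signed fractional change in clearance under
    zopiclone co-administration (clearance ratio with/without equals
    1 + theta_zop); ``wt_ref`` the allometric reference weight (kg);
    ``exp_cl``/``exp_v`` the allometric exponents on clearance/volume.
    """

    cl_pop: float = 74.0
    v_pop: float = 874.0
    ka_fixed: float = 0.5
    theta_zop: float = -0.547
    wt_ref: float = 70.0
    exp_cl: float = 0.75
    exp_v: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v_pop", "ka_fixed", "wt_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 1.0 + self.theta_zop > 0:
            raise ValueError(
                f"1 + theta_zop must stay > 0 (clearance positivity), got theta_zop={self.theta_zop}"
            )


@dataclass(frozen=True)
class RandomEffects:
    """Inter-individual variability on clearance (log scale)."""

    omega_cl: float = 0.391
    interpretation_mode: Mode = "sd"

    def __post_init__(self) -> None:
        if self.omega_cl < 0:
            raise ValueError(f"omega_cl must be >= 0, got {self.omega_cl}")
        _as_sd(self.omega_cl, self.interpretation_mode)  # validates mode

    @property
    def omega_sd(self) -> float:
        """omega as a log-scale standard deviation, whatever the mode."""
        return _as_sd(self.omega_cl, self.interpretation_mode)


@dataclass(frozen=True)
class ResidualModel:
    """Combined proportional + additive residual error."""

    sigma_prop: float = 0.159
    sigma_add: float = 9.803
    interpretation_mode: Mode = "sd"

    def __post_init__(self) -> None:
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("sigma_prop and sigma_add must be >= 0")
        _as_sd(self.sigma_prop, self.interpretation_mode)

    @property
    def prop_sd(self) -> float:
        return _as_sd(self.sigma_prop, self.interpretation_mode)

    @property
    def add_sd(self) -> float:
        return _as_sd(self.sigma_add, self.interpretation_mode)

    def variance(self, c_pred):
        """Var(B | C) = C^2 * sigma_prop^2 + sigma_add^2 (ng/mL)^2."""
        c = np.asarray(c_pred, dtype=float)
        return (c * self.prop_sd) ** 2 + self.add_sd**2


@dataclass(frozen=True)
class CovariateEffect:
    """A generic covariate sub-model on one structural parameter.

    kind='power-continuous':   P_i = TV(P) * (Cov_i / reference)^theta
    kind='linear-categorical': P_i = TV(P) * (1 + theta * Cov_i), Cov binary
    """

    name: str
    kind: Literal["power-continuous", "linear-categorical"]
    target_parameter: Literal["cl", "v"] = "cl"
    theta: float = 0.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "power-continuous":
            if self.reference is None or not self.reference > 0:
                raise ValueError(
                    f"power-continuous effect {self.name!r} needs reference > 0"
                )
        elif self.kind != "linear-categorical":
            raise ValueError(f"unknown covariate effect kind {self.kind!r}")

    def factor(self, cov_value):
        cov = np.asarray(cov_value, dtype=float)
        if self.kind == "power-continuous":
            return (cov / self.reference) ** self.theta
        return 1.0 + self.theta * cov


@dataclass(frozen=True)
class Subject:
    """One individual: id, weight, zopiclone flag, extra covariates."""

    id: int | str
    weight_kg: float
    zop: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")
        if self.zop not in (0, 1):
            raise ValueError(f"zop must be 0 or 1, got {self.zop!r}")

    def covariate(self, name: str) -> float:
        if name == "WT":
            return self.weight_kg
        if name == "ZOP":
            return float(self.zop)
        return float(self.extra[name])


@dataclass(frozen=True)
class PopulationModel:
    """Complete population model: fixed, random, residual and covariates.

    ``extra_effects`` carries covariate effects beyond the built-in
    allometric weight and zopiclone terms (used by the stepwise covariate
    search); each multiplies the targeted structural parameter.
    """

    fe: FixedEffects = field(default_factory=FixedEffects)
    re: RandomEffects = field(default_factory=RandomEffects)
    rm: ResidualModel = field(default_factory=ResidualModel)
    extra_effects: tuple[CovariateEffect, ...] = ()

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        return replace(self, extra_effects=self.extra_effects + (effect,))

    def without_effect(self, name: str) -> "PopulationModel":
        kept = tuple(e for e in self.extra_effects if e.name != name)
        return replace(self, extra_effects=kept)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "fixed_effects": {
                "cl_pop": self.fe.cl_pop,
                "v_pop": self.fe.v_pop,
                "ka_fixed": self.fe.ka_fixed,
                "theta_zop": self.fe.theta_zop,
                "wt_ref": self.fe.wt_ref,
                "exp_cl": self.fe.exp_cl,
                "exp_v": self.fe.exp_v,
            },
            "random_effects": {
                "omega_cl": self.re.omega_cl,
                "interpretation_mode": self.re.interpretation_mode,
            },
            "residual_model": {
                "sigma_prop": self.rm.sigma_prop,
                "sigma_add": self.rm.sigma_add,
                "interpretation_mode": self.rm.interpretation_mode,
            },
            "covariate_effects": [
                {
                    "name": e.name,
                    "kind": e.kind,
                    "target_parameter": e.target_parameter,
                    "theta": e.theta,
                    "reference": e.reference,
                }
                for e in self.extra_effects
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        fe = FixedEffects(**d.get("fixed_effects", {}))
        re_ = RandomEffects(**d.get("random_effects", {}))
        rm = ResidualModel(**d.get("residual_model", {}))
        effects = tuple(
            CovariateEffect(**e) for e in d.get("covariate_effects", [])
        )
        return cls(fe=fe, re=re_, rm=rm, extra_effects=effects)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PopulationModel":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(data)


#: The published final model (Table-3 values, sd interpretation).
FINAL_MODEL = PopulationModel()


def typical_params(
    fe: FixedEffects,
    s: Subject,
    extra_effects: Sequence[CovariateEffect] = (),
) -> StructuralParams:
    """Typical (eta = 0) structural parameters for one subject."""
    cl = (
        fe.cl_pop
        * (s.weight_kg / fe.wt_ref) ** fe.exp_cl
        * (1.0 + fe.theta_zop * s.zop)
    )
    v = fe.v_pop * (s.weight_kg / fe.wt_ref) ** fe.exp_v
    for eff in extra_effects:
        f = float(eff.factor(s.covariate(eff.name)))
        if eff.target_parameter == "cl":
            cl *= f
        else:
            v *= f
    return StructuralParams(cl=cl, v=v, ka=fe.ka_fixed)


def individual_params(
    fe: FixedEffects,
    re: RandomEffects,
    s: Subject,
    eta: float,
    extra_effects: Sequence[CovariateEffect] = (),
) -> StructuralParams:
    """Individual parameters: clearance scaled by exp(eta); v, ka unchanged."""
    if not np.isfinite(eta):
        raise ValueError(f"eta must be finite, got {eta!r}")
    tp = typical_params(fe, s, extra_effects)
    return StructuralParams(cl=tp.cl * float(np.exp(eta)), v=tp.v, ka=tp.ka)


def sample_eta(re: RandomEffects, n: int, seed=None) -> np.ndarray:
    """Draw n IIV deviates eta ~ N(0, omega^2); reproducible under seed.

    ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(0.0, re.omega_sd, size=int(n))


def apply_residual(rm: ResidualModel, c_pred, rng, truncate: bool = False):
    """Observed-scale concentration B = C(1 + eps1) + eps2.

    eps1, eps2 are independent zero-mean Gaussians with the model's
    proportional/additive scales.  ``truncate`` clips negative realized
    observations to 0 (reporting convention); the default keeps them, as
    the error model states.
    """
    c = np.asarray(c_pred, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_pred must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps1 = rng.normal(0.0, rm.prop_sd, size=c.shape)
    eps2 = rng.normal(0.0, rm.add_sd, size=c.shape)
    b = c * (1.0 + eps1) + eps2
    if truncate:
        b = np.maximum(b, 0.0)
    return b[()]
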