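"""Synthetic pediatric cohorts and sparse trough TDM datasets.

The study's raw therapeutic-drug-monitoring database is not public, so
this module generates virtual cohorts with its demographic structure
(n = 111; weight 56.58 +/- 15.01 kg, range 35-117; 3/111 on zopiclone)
and simulates sparse steady-state trough observations from any
:class:`~sertpk.popmodel.PopulationModel`.

Weights follow a truncated log-normal moment-matched to the reported
mean/SD inside the reported range — log-normal respects positivity and
the right skew implied by median 52.5 < mean 56.58.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import DatasetDialect, TdmDataset
from .pkmodel import Regimen, trough_at_steady_state
from .popmodel import PopulationModel, Subject, individual_params

__all__ = ["CohortSpec", "Individual", "generate_cohort", "simulate_tdm",
           "truncated_lognormal_moments"]

#: first TDM visit (h after treatment start); far beyond 10 half-lives of
#: the typical patient, so the analytic steady state applies.
FIRST_VISIT_H = 14 * 24.0
#: spacing between repeat TDM visits (h).
VISIT_SPACING_H = 7 * 24.0


@dataclass(frozen=True)
class Individual:
    subject: Subject
    regimen: Regimen
    dose_per_kg_day: float


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition defaults for the virtual cohort.

    weight_dist = (mean, sd, min, max) in kg of the truncated log-normal;
    zop_prevalence the Bernoulli probability of the zopiclone flag;
    dose_range_mg_kg_day the uniform range of assigned maintenance doses;
    troughs_per_subject an int or (lo, hi) inclusive range of per-subject
    steady-state trough observations on weekly visits.
    """

    n_subjects: int = 111
    weight_dist: tuple[float, float, float, float] = (56.58, 15.01, 35.0, 117.0)
    zop_prevalence: float = 3.0 / 111.0
    dose_range_mg_kg_day: tuple[float, float] = (0.5, 5.0)
    bid_fraction: float = 0.5
    troughs_per_subject: int | tuple[int, int] = (1, 3)
    truncate_negative_obs: bool = False
    seed: int | None = None
    extra_covariates: dict = field(default_factory=dict)
    # extra_covariates: name -> (mean, sd, min, max) for carried (unmodeled)
    # continuous columns, or a float in (0,1) for a binary prevalence.

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.zop_prevalence <= 1.0:
            raise ValueError("zop_prevalence must be in [0, 1]")
        mean, sd, lo, hi = self.weight_dist
        if not lo < hi:
            raise ValueError("weight min must be < max")
        if not lo < mean < hi:
            raise ValueError(
                f"weight mean {mean} outside truncation range ({lo}, {hi})"
            )
        if sd <= 0:
            raise ValueError("weight sd must be > 0")

    def trough_counts(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if isinstance(self.troughs_per_subject, int):
            return np.full(n, self.troughs_per_subject)
        lo, hi = self.troughs_per_subject
        return rng.integers(lo, hi + 1, size=n)


def truncated_lognormal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and sd of a log-normal(mu, sigma) truncated to [lo, hi].

    Closed form via normal CDFs: E[X^k | lo<X<hi] =
    exp(k mu + k^2 sigma^2 / 2) * [Phi(b - k sigma) - Phi(a - k sigma)]
    / [Phi(b) - Phi(a)], with a,b the standardized log bounds.
    """
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = stats.norm.cdf(b) - stats.norm.cdf(a)

    def raw(k):
        return (
            np.exp(k * mu + 0.5 * k**2 * sigma**2)
            * (stats.norm.cdf(b - k * sigma) - stats.norm.cdf(a - k * sigma))
            / z
        )

    m1 = raw(1)
    m2 = raw(2)
    return m1, float(np.sqrt(max(m2 - m1**2, 0.0)))


@lru_cache(maxsize=32)
def _solve_weight_params(mean, sd, lo, hi):
    """(mu, sigma) of the parent log-normal matching truncated moments."""

    def resid(x):
        m, s = truncated_lognormal_moments(x[0], np.exp(x[1]), lo, hi)
        return [m - mean, s - sd]

    x0 = [np.log(mean) - 0.5 * np.log1p((sd / mean) ** 2),
          np.log(np.sqrt(np.log1p((sd / mean) ** 2)))]
    sol = optimize.root(resid, x0, method="hybr")
    if not sol.success:
        raise RuntimeError(f"weight-distribution moment match failed: {sol.message}")
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _sample_truncated_lognormal(rng, n, mean, sd, lo, hi):
    mu, sigma = _solve_weight_params(mean, sd, lo, hi)
    plo = stats.norm.cdf((np.log(lo) - mu) / sigma)
    phi = stats.norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(plo, phi, size=n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate_cohort(spec: CohortSpec, rng=None) -> list[Individual]:
    """Draw a virtual cohort: subjects with covariates and regimens."""
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    n = spec.n_subjects
    mean, sd, lo, hi = spec.weight_dist
    weights = _sample_truncated_lognormal(rng, n, mean, sd, lo, hi)
    zop = (rng.uniform(size=n) < spec.zop_prevalence).astype(int)
    dose_kg = rng.uniform(*spec.dose_range_mg_kg_day, size=n)
    bid = rng.uniform(size=n) < spec.bid_fraction
    extras = {}
    for name, spec_val in spec.extra_covariates.items():
        if isinstance(spec_val, tuple):
            m, s, clo, chi = spec_val
            extras[name] = np.clip(rng.normal(m, s, size=n), clo, chi)
        else:
            extras[name] = (rng.uniform(size=n) < float(spec_val)).astype(int)
    cohort = []
    for i in range(n):
        tau = 12.0 if bid[i] else 24.0
        subject = Subject(
            id=i + 1,
            weight_kg=float(weights[i]),
            zop=int(zop[i]),
            extra={k: float(v[i]) for k, v in extras.items()},
        )
        regimen = Regimen(
            dose_mg=float(dose_kg[i] * weights[i] * tau / 24.0), tau_h=tau
        )
        cohort.append(Individual(subject, regimen, float(dose_kg[i])))
    return cohort


def simulate_tdm(
    cohort: list[Individual],
    model: PopulationModel,
    spec: CohortSpec,
    rng=None,
) -> TdmDataset:
    """Forward-simulate sparse steady-state troughs for a cohort.

    Each subject gets one eta draw (IIV on clearance) and per-visit
    residual error on the observed trough.  True etas are retained on the
    returned dataset for recovery testing.
    """
    if rng is None or not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(spec.seed if rng is None else rng)
    d = DatasetDialect()
    n = len(cohort)
    etas = rng.normal(0.0, model.re.omega_sd, size=n)
    n_troughs = spec.trough_counts(rng, n)
    rows = []
    for i, ind in enumerate(cohort):
        s, r = ind.subject, ind.regimen
        p = individual_params(model.fe, model.re, s, etas[i], model.extra_effects)
        c_true = float(trough_at_steady_state(p, r))
        base = {
            d.id_col: s.id,
            d.wt_col: s.weight_kg,
            d.zop_col: s.zop,
            **s.extra,
        }
        for visit in range(int(n_troughs[i])):
            t0 = FIRST_VISIT_H + visit * VISIT_SPACING_H
            rows.append(
                {**base, d.time_col: t0, d.amt_col: r.dose_mg, d.ss_col: 1,
                 d.ii_col: r.tau_h, d.dv_col: np.nan, d.mdv_col: 1}
            )
            eps1 = rng.normal(0.0, model.rm.prop_sd)
            eps2 = rng.normal(0.0, model.rm.add_sd)
            obs = c_true * (1.0 + eps1) + eps2
            if spec.truncate_negative_obs:
                obs = max(obs, 0.0)
            rows.append(
                {**base, d.time_col: t0 + r.tau_h, d.amt_col: np.nan,
                 d.ss_col: 0, d.ii_col: np.nan, d.dv_col: obs, d.mdv_col: 0}
            )
    events = pd.DataFrame(rows)
    ordered = list(d.mandatory) + [c for c in events.columns if c not in d.mandatory]
    events = events[ordered]
    true_etas = pd.Series(etas, index=[ind.subject.id for ind in cohort], name="eta")
    return TdmDataset(events, dialect=d, true_etas=true_etas)
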