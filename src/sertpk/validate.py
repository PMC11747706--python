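"""Model qualification: bootstrap, visual predictive check, diagnostics.

Bootstrap resamples *subjects* (with all their rows) with replacement to
the original subject count and refits each replicate; bias per parameter
is (bootstrap median - estimate)/estimate x 100%.  The VPC re-simulates
the original design (same subjects, regimens, sampling times) many times
and compares observed percentiles with the simulated percentile bands.
Percentiles use linear interpolation of order statistics (type-7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TdmDataset
from .estimate import FitSpec, FitResult, _Design, _Inner, fit
from .popmodel import PopulationModel

__all__ = ["BootstrapResult", "VpcResult", "bootstrap", "vpc", "gof",
           "simulate_replicate"]

BOOT_FAILURE_FLAG_FRACTION = 0.2


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap summary plus replicate bookkeeping."""

    table: pd.DataFrame  # parameter, estimate, median, ci_lo, ci_hi, bias_pct
    n_requested: int
    n_success: int
    replicates: pd.DataFrame

    @property
    def n_failed(self) -> int:
        return self.n_requested - self.n_success

    @property
    def unreliable(self) -> bool:
        return self.n_failed > BOOT_FAILURE_FLAG_FRACTION * self.n_requested

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def bias_pct(median: float, estimate: float) -> float:
    """(median - estimate)/estimate x 100."""
    return (median - estimate) / estimate * 100.0


def bootstrap(
    dataset: TdmDataset,
    model: PopulationModel,
    spec: FitSpec = FitSpec(compute_se=False),
    n_boot: int = 1000,
    seed=None,
    original_fit: FitResult | None = None,
) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the fit.

    ``model`` provides starting values; the point estimate is refit on the
    original data (or taken from ``original_fit``).  Replicate fits warm-
    start at the point estimates.  Failed replicates are excluded and
    counted; >20% failures flags the result unreliable.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = FitSpec(free=spec.free, approx=spec.approx, maxiter=spec.maxiter,
                   ftol=spec.ftol, compute_se=False)
    if original_fit is None:
        original_fit = fit(dataset, model, spec)
    ids = dataset.subject_ids
    rows = []
    for b in range(n_boot):
        draw = [ids[k] for k in rng.integers(0, len(ids), size=len(ids))]
        try:
            replicate = dataset.subset_subjects(draw, relabel=True)
            res = fit(replicate, original_fit.model, spec)
            if not np.isfinite(res.ofv):
                raise RuntimeError("non-finite OFV")
            rows.append({"replicate": b, "success": True, **res.estimates})
        except Exception as exc:
            rows.append({"replicate": b, "success": False, "error": str(exc)})
    reps = pd.DataFrame(rows)
    ok = reps[reps["success"]]
    table_rows = []
    for name, est in original_fit.estimates.items():
        vals = ok[name].to_numpy(dtype=float)
        med = float(np.percentile(vals, 50)) if len(vals) else np.nan
        lo = float(np.percentile(vals, 2.5)) if len(vals) else np.nan
        hi = float(np.percentile(vals, 97.5)) if len(vals) else np.nan
        table_rows.append(
            dict(parameter=name, estimate=est, median=med,
                 ci_lo=lo, ci_hi=hi, bias_pct=bias_pct(med, est))
        )
    return BootstrapResult(
        table=pd.DataFrame(table_rows),
        n_requested=n_boot,
        n_success=int(ok.shape[0]),
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# VPC
# ---------------------------------------------------------------------------

def simulate_replicate(
    dataset: TdmDataset, model: PopulationModel, rng
) -> np.ndarray:
    """Simulated DV vector sharing the dataset's design (one replicate).

    Only etas and residuals are re-drawn; subjects, regimens, covariates
    and sampling times are those of the original dataset.
    """
    design = _Design(dataset)
    inner = _Inner(model, design, check_residual=False)
    etas = rng.normal(0.0, model.re.omega_sd, size=design.n_subjects)
    c = inner.conc(etas[design.subj_idx])
    eps1 = rng.normal(0.0, model.rm.prop_sd, size=design.n_obs)
    eps2 = rng.normal(0.0, model.rm.add_sd, size=design.n_obs)
    return c * (1.0 + eps1) + eps2


@dataclass
class VpcResult:
    """Observed vs simulated percentile bands per bin."""

    bins: pd.DataFrame   # bin, lo, hi, n_obs
    observed: pd.DataFrame  # bin, p2.5, p50, p97.5
    simulated: pd.DataFrame  # bin, percentile, band_lo, band_mid, band_hi
    n_replicates: int
    binning: str

    def to_csv(self, path) -> None:
        sim_wide = self.simulated.pivot(
            index="bin", columns="percentile",
            values=["band_lo", "band_mid", "band_hi"],
        )
        sim_wide.columns = [f"{a}_p{b:g}" for a, b in sim_wide.columns]
        merged = (
            self.bins.merge(self.observed, on="bin")
            .merge(sim_wide.reset_index(), on="bin")
        )
        merged.to_csv(path, index=False)


_PCTS = (2.5, 50.0, 97.5)


def vpc(
    dataset: TdmDataset,
    model: PopulationModel,
    n_replicates: int = 200,
    seed=None,
    bins: int = 6,
    binning: str = "pred",
) -> VpcResult:
    """Visual-predictive-check quantities (rendering is separate).

    Bins observations by population-prediction quantiles (default) or by
    time; within each bin computes observed 2.5/50/97.5 percentiles and,
    across simulated replicates, the 2.5/50/97.5 envelope of each
    simulated percentile.  Empty bins are reported with NaN rows, never
    dropped silently.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = _Design(dataset)
    inner = _Inner(model, design, check_residual=False)
    pred = inner.conc(np.zeros(design.n_obs))
    axis = pred if binning == "pred" else design.dt
    edges = np.unique(np.percentile(axis, np.linspace(0, 100, bins + 1)))
    idx = np.clip(np.searchsorted(edges, axis, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1

    obs_rows, bin_rows = [], []
    for b in range(n_bins):
        mask = idx == b
        bin_rows.append(dict(bin=b, lo=edges[b], hi=edges[b + 1],
                             n_obs=int(mask.sum())))
        if mask.sum():
            pc = np.percentile(design.y[mask], _PCTS)
        else:
            pc = [np.nan] * 3
        obs_rows.append(dict(bin=b, p2_5=pc[0], p50=pc[1], p97_5=pc[2]))

    sim_pct = np.full((n_replicates, n_bins, len(_PCTS)), np.nan)
    for r in range(n_replicates):
        y_sim = simulate_replicate(dataset, model, rng)
        for b in range(n_bins):
            mask = idx == b
            if mask.sum():
                sim_pct[r, b] = np.percentile(y_sim[mask], _PCTS)
    sim_rows = []
    for b in range(n_bins):
        for k, pct in enumerate(_PCTS):
            band = sim_pct[:, b, k]
            sim_rows.append(
                dict(bin=b, percentile=pct,
                     band_lo=float(np.nanpercentile(band, 2.5)),
                     band_mid=float(np.nanpercentile(band, 50)),
                     band_hi=float(np.nanpercentile(band, 97.5)))
            )
    return VpcResult(
        bins=pd.DataFrame(bin_rows),
        observed=pd.DataFrame(obs_rows),
        simulated=pd.DataFrame(sim_rows),
        n_replicates=n_replicates,
        binning=binning,
    )


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

def gof(dataset: TdmDataset, model: PopulationModel, fit_result: FitResult) -> pd.DataFrame:
    """Per-observation diagnostics: PRED, IPRED, iWRES, WRES, time.

    iWRES = (DV - IPRED)/sd(IPRED) with sd from the residual model at the
    individual prediction.  WRES uses the population prediction and a
    first-order variance (eta linearization plus residual).  Rows whose
    predicted sd is zero are flagged.
    """
    design = _Design(dataset)
    inner = _Inner(model, design, check_residual=False)
    etas = fit_result.etas.reindex(design.subject_ids).to_numpy(dtype=float)
    eta_obs = etas[design.subj_idx]
    ipred = inner.conc(eta_obs)
    pred = inner.conc(np.zeros(design.n_obs))
    sd_i = np.sqrt(model.rm.variance(ipred))
    delta = 1e-4
    g = (inner.conc(np.full(design.n_obs, delta)) - inner.conc(np.full(design.n_obs, -delta))) / (2 * delta)
    var_pop = g**2 * model.re.omega_sd**2 + model.rm.variance(pred)
    flagged = sd_i <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        iwres = np.where(flagged, np.nan, (design.y - ipred) / sd_i)
        wres = (design.y - pred) / np.sqrt(var_pop)
    return pd.DataFrame(
        {
            "id": [design.subject_ids[i] for i in design.subj_idx],
            "time": design.dt,
            "dv": design.y,
            "pred": pred,
            "ipred": ipred,
            "iwres": iwres,
            "wres": wres,
            "zero_sd_flag": flagged,
        }
    )
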