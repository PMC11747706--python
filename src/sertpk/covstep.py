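"""Stepwise covariate model building and the Ka sensitivity sweep.

Forward phase: each round fits every remaining candidate on top of the
current model and greedily adds the one with the largest objective
function drop, provided the drop exceeds ``add_threshold`` (default
3.84, chi-square(1) at p=0.05).  Backward phase: effects whose removal
raises the OFV by no more than ``remove_threshold`` (default 6.63,
p=0.01) are deleted, iterating to stability.  Ties resolve by larger
OFV drop, then candidate-list order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TdmDataset
from .estimate import FitSpec, FitResult, fit
from .popmodel import CovariateEffect, PopulationModel

__all__ = ["CovariateCandidate", "StepwiseTrace", "forward_backward", "ka_sweep"]

ADD_THRESHOLD = 3.84
REMOVE_THRESHOLD = 6.63


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate to test: column name, target parameter, functional form."""

    name: str
    target_parameter: str = "cl"
    kind: str = "power-continuous"  # or "linear-categorical"

    def effect(self, dataset: TdmDataset) -> CovariateEffect:
        reference = None
        if self.kind == "power-continuous":
            reference = dataset.covariate_median(self.name)
        return CovariateEffect(
            name=self.name,
            kind=self.kind,
            target_parameter=self.target_parameter,
            theta=0.0,
            reference=reference,
        )


@dataclass
class StepwiseTrace:
    """Ordered record of every tried model; decisions replayable."""

    records: pd.DataFrame

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = []
        for _, r in self.records.iterrows():
            lines.append(
                f"[{r['phase']}/round {r['round']}] {r['action']} {r['candidate']}: "
                f"OFV {r['ofv']:.3f} (dOFV {r['delta_ofv']:+.3f}) -> {r['decision']}"
            )
        return "\n".join(lines)


def _fit_quiet(dataset, model, spec):
    try:
        return fit(dataset, model, spec)
    except Exception as exc:  # candidate fit failure is data, not fatal
        return exc


def forward_backward(
    dataset: TdmDataset,
    base_model: PopulationModel,
    candidates: list[CovariateCandidate],
    add_threshold: float = ADD_THRESHOLD,
    remove_threshold: float = REMOVE_THRESHOLD,
    base_spec: FitSpec = FitSpec(
        free=("cl_pop", "v_pop", "omega_cl", "sigma_prop", "sigma_add"),
        compute_se=False,
    ),
):
    """Greedy forward selection then backward elimination.

    Returns ``(final FitResult, StepwiseTrace)``.  A candidate whose fit
    fails is skipped with a trace annotation, never silently.
    """
    if add_threshold <= 0 or remove_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    records = []
    current = fit(dataset, base_model, base_spec)
    current_free = tuple(base_spec.free)
    remaining = list(candidates)
    included: list[CovariateCandidate] = []
    round_no = 0

    while True:
        round_no += 1
        best = None
        for cand in remaining:
            model_c = current.model.with_effect(cand.effect(dataset))
            spec_c = FitSpec(
                free=current_free + (f"beta:{cand.name}",),
                approx=base_spec.approx,
                compute_se=False,
            )
            res = _fit_quiet(dataset, model_c, spec_c)
            if isinstance(res, Exception):
                records.append(
                    dict(phase="forward", round=round_no, candidate=cand.name,
                         action="try-add", ofv=np.nan, delta_ofv=np.nan,
                         decision=f"skipped: {res}")
                )
                continue
            d_ofv = current.ofv - res.ofv
            qualifies = d_ofv > add_threshold
            records.append(
                dict(phase="forward", round=round_no, candidate=cand.name,
                     action="try-add", ofv=res.ofv, delta_ofv=-d_ofv,
                     decision="qualifies" if qualifies else "rejected")
            )
            if qualifies and (best is None or d_ofv > best[0]):
                best = (d_ofv, cand, res)
        if best is None:
            break
        _, cand, res = best
        records.append(
            dict(phase="forward", round=round_no, candidate=cand.name,
                 action="add", ofv=res.ofv, delta_ofv=res.ofv - current.ofv,
                 decision="included")
        )
        current = res
        current_free = current_free + (f"beta:{cand.name}",)
        included.append(cand)
        remaining = [c for c in remaining if c.name != cand.name]

    # backward elimination
    changed = True
    while changed and included:
        round_no += 1
        changed = False
        for cand in list(included):
            model_r = current.model.without_effect(cand.name)
            free_r = tuple(f for f in current_free if f != f"beta:{cand.name}")
            res = _fit_quiet(dataset, model_r, FitSpec(
                free=free_r, approx=base_spec.approx, compute_se=False))
            if isinstance(res, Exception):
                records.append(
                    dict(phase="backward", round=round_no, candidate=cand.name,
                         action="try-remove", ofv=np.nan, delta_ofv=np.nan,
                         decision=f"skipped: {res}")
                )
                continue
            rise = res.ofv - current.ofv
            keep = rise > remove_threshold
            records.append(
                dict(phase="backward", round=round_no, candidate=cand.name,
                     action="try-remove", ofv=res.ofv, delta_ofv=rise,
                     decision="kept" if keep else "removed")
            )
            if not keep:
                current = res
                current_free = free_r
                included.remove(cand)
                changed = True
                break

    trace = StepwiseTrace(pd.DataFrame(records, columns=[
        "phase", "round", "candidate", "action", "ofv", "delta_ofv", "decision"
    ]))
    return current, trace


def ka_sweep(
    dataset: TdmDataset,
    model: PopulationModel,
    ka_values=(0.01, 0.4, 0.5, 0.6, 1.0, 2.0),
    spec: FitSpec = FitSpec(
        free=("cl_pop", "v_pop", "omega_cl", "sigma_prop", "sigma_add"),
        compute_se=False,
    ),
) -> pd.DataFrame:
    """Re-fit the model with Ka fixed at each candidate value.

    Returns a (ka, ofv, converged) table; per-value failures are recorded
    as non-finite OFV and the sweep continues.
    """
    import dataclasses as _dc

    rows = []
    for ka in ka_values:
        if ka <= 0:
            raise ValueError("ka values must be positive")
        m = PopulationModel(
            fe=_dc.replace(model.fe, ka_fixed=float(ka)),
            re=model.re, rm=model.rm, extra_effects=model.extra_effects,
        )
        res = _fit_quiet(dataset, m, spec)
        if isinstance(res, Exception):
            rows.append(dict(ka=ka, ofv=np.nan, converged=False, message=str(res)))
        else:
            rows.append(dict(ka=ka, ofv=res.ofv, converged=res.converged,
                             message=res.message))
    return pd.DataFrame(rows)
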