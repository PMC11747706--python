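"""Long-format TDM event dataset (NONMEM-style records).

One row per event.  Dose rows carry AMT (mg), SS=1 and II (h) — every
regimen here is a steady-state maintenance schedule, matching sparse
trough-only therapeutic drug monitoring.  Observation rows carry DV
(ng/mL) with MDV=0.  WT/ZOP (and any extra covariate columns) are
repeated on every row of a subject, the usual flat-file convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DatasetDialect", "TdmDataset", "ValidationError"]


@dataclass(frozen=True)
class DatasetDialect:
    """Column-name conventions for the CSV encoding."""

    id_col: str = "ID"
    time_col: str = "TIME"
    amt_col: str = "AMT"
    ss_col: str = "SS"
    ii_col: str = "II"
    dv_col: str = "DV"
    mdv_col: str = "MDV"
    wt_col: str = "WT"
    zop_col: str = "ZOP"

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (
            self.id_col,
            self.time_col,
            self.amt_col,
            self.ss_col,
            self.ii_col,
            self.dv_col,
            self.mdv_col,
            self.wt_col,
            self.zop_col,
        )


DEFAULT_DIALECT = DatasetDialect()


class ValidationError(ValueError):
    """Dataset contract violation; ``problems`` lists row-level messages."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid dataset:\n" + "\n".join(self.problems))


@dataclass
class TdmDataset:
    """Validated event table plus an optional hidden true-eta side table.

    ``events`` columns follow :class:`DatasetDialect`; extra columns are
    carried untouched (candidate covariates for the stepwise search).
    ``true_etas`` (subject id -> simulated eta) is kept only for
    recovery testing of synthetic data and is never serialized with the
    events.
    """

    events: pd.DataFrame
    dialect: DatasetDialect = field(default_factory=DatasetDialect)
    true_etas: pd.Series | None = None

    def __post_init__(self) -> None:
        problems = self._collect_problems()
        if problems:
            raise ValidationError(problems)
        self.events = self.events.reset_index(drop=True)

    # -- validation ------------------------------------------------------
    def _collect_problems(self) -> list[str]:
        d = self.dialect
        ev = self.events
        problems: list[str] = []
        missing = [c for c in d.mandatory if c not in ev.columns]
        if missing:
            return [f"missing mandatory columns: {missing}"]
        for col in d.mandatory:
            numeric = pd.to_numeric(ev[col], errors="coerce")
            allow_na = col in (d.amt_col, d.ii_col, d.dv_col)
            bad = ev.index[numeric.isna() & ~(ev[col].isna() if allow_na else False)]
            if len(bad):
                problems.append(
                    f"column {col}: non-numeric values at rows {list(bad[:5])}"
                )
        if problems:
            return problems
        mdv = ev[d.mdv_col].to_numpy()
        dv = ev[d.dv_col].to_numpy(dtype=float, na_value=np.nan)
        amt = ev[d.amt_col].to_numpy(dtype=float, na_value=np.nan)
        for i in ev.index[(mdv == 1) & np.isfinite(dv)]:
            problems.append(f"row {i}: DV present on an MDV=1 row")
        for i in ev.index[(mdv == 0) & ~np.isfinite(dv)]:
            problems.append(f"row {i}: observation row (MDV=0) without DV")
        for i in ev.index[(mdv == 0) & np.isfinite(amt) & (amt > 0)]:
            problems.append(f"row {i}: AMT on an observation row")
        if np.any(ev[d.time_col].to_numpy(dtype=float) < 0):
            problems.append("negative times present")
        for sid, grp in ev.groupby(d.id_col, sort=False):
            t = grp[d.time_col].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                problems.append(f"subject {sid}: times not non-decreasing")
            g_mdv = grp[d.mdv_col].to_numpy()
            g_amt = grp[d.amt_col].to_numpy(dtype=float, na_value=np.nan)
            is_dose = (g_mdv == 1) & np.isfinite(g_amt)
            obs_pos = np.flatnonzero(g_mdv == 0)
            for j in obs_pos:
                if not np.any(is_dose[: j + 1]):
                    problems.append(
                        f"subject {sid}: observation at t={t[j]} with no preceding dose"
                    )
                    break
        return problems

    # -- convenience -----------------------------------------------------
    @property
    def subject_ids(self) -> list:
        return list(self.events[self.dialect.id_col].drop_duplicates())

    @property
    def n_subjects(self) -> int:
        return self.events[self.dialect.id_col].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.events[self.dialect.mdv_col] == 0).sum())

    def observations(self) -> pd.DataFrame:
        return self.events[self.events[self.dialect.mdv_col] == 0]

    def extra_columns(self) -> list[str]:
        return [c for c in self.events.columns if c not in self.dialect.mandatory]

    def covariate_median(self, name: str) -> float:
        """Per-subject (not per-row) median of a covariate column."""
        d = self.dialect
        col = d.wt_col if name == "WT" else name
        per_subject = self.events.groupby(d.id_col, sort=False)[col].first()
        return float(per_subject.median())

    def subset_subjects(self, ids, relabel: bool = True) -> "TdmDataset":
        """Rows of the listed subjects, in the listed order (repeats allowed).

        With ``relabel`` (bootstrap resampling) each entry of ``ids``
        becomes a fresh subject id so repeated draws stay distinct.
        """
        d = self.dialect
        groups = dict(tuple(self.events.groupby(d.id_col, sort=False)))
        frames = []
        for new_id, sid in enumerate(ids, start=1):
            g = groups[sid].copy()
            if relabel:
                g[d.id_col] = new_id
            frames.append(g)
        return TdmDataset(pd.concat(frames, ignore_index=True), dialect=d)

    def equals(self, other: "TdmDataset") -> bool:
        a = self.events.reset_index(drop=True)
        b = other.events.reset_index(drop=True)
        return a.equals(b)
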