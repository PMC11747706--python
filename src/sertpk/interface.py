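"""Dataset I/O, pipeline orchestration and the run manifest.

The on-disk dataset is a plain CSV in the NONMEM-style dialect of
:class:`~sertpk.data.DatasetDialect` (ID, TIME, AMT, SS, II, DV, MDV,
WT, ZOP + extra covariate columns; empty cells for non-applicable
fields).  ``run_pipeline`` drives simulate -> fit -> covstep ->
bootstrap/VPC/GOF -> PTA/recommend from one config mapping and writes
every artifact plus a manifest (seeds, stages, interpretation mode,
design flags) into an output directory.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covstep as covstep_mod
from . import dosing as dosing_mod
from . import validate as validate_mod
from .cohort import CohortSpec, generate_cohort, simulate_tdm
from .data import DEFAULT_DIALECT, DatasetDialect, TdmDataset, ValidationError
from .estimate import FitSpec, fit
from .popmodel import PopulationModel

__all__ = ["read_dataset", "write_dataset", "run_pipeline", "load_config"]


def write_dataset(dataset: TdmDataset, path) -> None:
    """Write the event table as CSV (round-trips through read_dataset)."""
    dataset.events.to_csv(path, index=False)


def read_dataset(path, dialect: DatasetDialect = DEFAULT_DIALECT) -> TdmDataset:
    """Read and validate a NONMEM-style CSV.

    All contract violations (missing columns, stray DV on dose rows,
    out-of-order times, observations before any dose) are collected and
    raised together as :class:`ValidationError` with row numbers; no
    partial dataset is ever returned.
    """
    events = pd.read_csv(path)
    return TdmDataset(events, dialect=dialect)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _default_stages():
    return ["simulate", "fit", "bootstrap", "vpc", "gof", "pta", "recommend"]


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; return the manifest dict.

    Config keys (all optional, with study defaults):
      model: PopulationModel mapping (see PopulationModel.to_dict)
      cohort: CohortSpec fields          seed: master seed
      fit: {free: [...], approx: ...}    stages: subset of
      bootstrap: {n_boot: int}           [simulate, fit, covstep,
      vpc: {n_replicates, bins}           bootstrap, vpc, gof, pta,
      covstep: {candidates: [...]}        recommend]
      pta: {scenarios: [{zop, tau_h, n_virtual, ...}], bands: [[lo, hi], ...]}
      dataset: path of an existing CSV (alternative to simulate)

    A stage failure halts downstream stages but preserves what was
    already written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", _default_stages())
    seed = int(config.get("seed", 0))
    model = PopulationModel.from_dict(config["model"]) if "model" in config else PopulationModel()
    manifest: dict = {
        "seed": seed,
        "stages": list(stages),
        "interpretation_mode": model.re.interpretation_mode,
        "completed": [],
        "timings_s": {},
        "outputs": {},
        "failed": None,
    }

    def _finish(stage, t0, **outputs):
        manifest["completed"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        manifest["outputs"].update(outputs)
        _write_manifest(manifest, outdir)

    dataset = None
    fit_result = None
    try:
        if "simulate" in stages:
            t0 = time.perf_counter()
            spec = CohortSpec(**{**config.get("cohort", {}), "seed": seed})
            cohort = generate_cohort(spec)
            dataset = simulate_tdm(cohort, model, spec)
            path = outdir / "dataset.csv"
            write_dataset(dataset, path)
            manifest["cohort_spec"] = {
                "n_subjects": spec.n_subjects,
                "weight_dist": list(spec.weight_dist),
                "zop_prevalence": spec.zop_prevalence,
                "troughs_per_subject": list(np.atleast_1d(spec.troughs_per_subject).tolist()),
            }
            _finish("simulate", t0, dataset=str(path))
        elif "dataset" in config:
            dataset = read_dataset(config["dataset"])
            manifest["outputs"]["dataset"] = str(config["dataset"])

        if "fit" in stages:
            if dataset is None:
                raise RuntimeError("fit stage needs a dataset (simulate stage or dataset path)")
            t0 = time.perf_counter()
            fit_kw = config.get("fit", {})
            spec = FitSpec(
                free=tuple(fit_kw.get("free", FitSpec().free)),
                approx=fit_kw.get("approx", "foce"),
            )
            fit_result = fit(dataset, model, spec)
            fit_result.to_json(outdir / "fit.json")
            fit_result.report_table().to_csv(outdir / "fit_table.csv", index=False)
            _finish("fit", t0, fit=str(outdir / "fit.json"),
                    fit_table=str(outdir / "fit_table.csv"))

        if "covstep" in stages:
            if dataset is None:
                raise RuntimeError("covstep stage needs a dataset")
            t0 = time.perf_counter()
            cands = [
                covstep_mod.CovariateCandidate(**c)
                for c in config.get("covstep", {}).get("candidates", [])
            ]
            final, trace = covstep_mod.forward_backward(dataset, model, cands)
            trace.to_csv(outdir / "covstep_trace.csv")
            (outdir / "covstep_trace.txt").write_text(trace.to_text() + "\n")
            fit_result = final
            _finish("covstep", t0, covstep_trace=str(outdir / "covstep_trace.csv"))

        base_for_validation = fit_result.model if fit_result is not None else model

        if "bootstrap" in stages:
            if dataset is None:
                raise RuntimeError("bootstrap stage needs a dataset")
            t0 = time.perf_counter()
            n_boot = int(config.get("bootstrap", {}).get("n_boot", 200))
            boot = validate_mod.bootstrap(
                dataset, base_for_validation, n_boot=n_boot, seed=seed,
                original_fit=fit_result,
            )
            boot.to_csv(outdir / "bootstrap.csv")
            manifest["bootstrap"] = {
                "n_requested": boot.n_requested,
                "n_success": boot.n_success,
                "unreliable": boot.unreliable,
            }
            _finish("bootstrap", t0, bootstrap=str(outdir / "bootstrap.csv"))

        if "vpc" in stages:
            if dataset is None:
                raise RuntimeError("vpc stage needs a dataset")
            t0 = time.perf_counter()
            vpc_kw = config.get("vpc", {})
            result = validate_mod.vpc(
                dataset, base_for_validation,
                n_replicates=int(vpc_kw.get("n_replicates", 200)),
                bins=int(vpc_kw.get("bins", 6)),
                seed=seed,
            )
            result.to_csv(outdir / "vpc.csv")
            _finish("vpc", t0, vpc=str(outdir / "vpc.csv"))

        if "gof" in stages:
            if dataset is None or fit_result is None:
                raise RuntimeError("gof stage needs a dataset and a fit")
            t0 = time.perf_counter()
            table = validate_mod.gof(dataset, base_for_validation, fit_result)
            table.to_csv(outdir / "gof.csv", index=False)
            _finish("gof", t0, gof=str(outdir / "gof.csv"))

        if "pta" in stages:
            t0 = time.perf_counter()
            pta_cfg = config.get("pta", {})
            scenarios = pta_cfg.get(
                "scenarios",
                [{"zop": z, "tau_h": t} for z in (0, 1) for t in (24.0, 12.0)],
            )
            bands = [tuple(b) for b in pta_cfg.get("bands", [(30.0, 80.0)])]
            all_pta, all_rec = [], []
            for sc_kw in scenarios:
                scenario = dosing_mod.SimulationScenario(**{**sc_kw, "seed": seed})
                table = dosing_mod.pta_grid(base_for_validation, scenario)
                all_pta.append(table.records)
                if "recommend" in stages:
                    rec = dosing_mod.recommend(table, bands)
                    rec.table.insert(0, "scenario", scenario.label)
                    all_rec.append(rec.table)
            pd.concat(all_pta, ignore_index=True).to_csv(outdir / "pta.csv", index=False)
            outputs = {"pta": str(outdir / "pta.csv")}
            if all_rec:
                pd.concat(all_rec, ignore_index=True).to_csv(
                    outdir / "recommendations.csv", index=False
                )
                outputs["recommendations"] = str(outdir / "recommendations.csv")
                manifest["completed"].append("recommend")
            _finish("pta", t0, **outputs)
    except Exception as exc:
        manifest["failed"] = {"stage": _next_stage(manifest, stages), "error": str(exc)}
        _write_manifest(manifest, outdir)
        raise
    _write_manifest(manifest, outdir)
    return manifest


def _next_stage(manifest, stages):
    done = set(manifest["completed"])
    for s in stages:
        if s not in done:
            return s
    return None


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
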