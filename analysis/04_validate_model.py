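#!/usr/bin/env python
"""Step 4 — qualify the fitted model: bootstrap, VPC, goodness of fit.

Runs a 200-replicate subject-level bootstrap (median, 2.5-97.5th
percentiles, bias %), the visual-predictive-check bands (300 simulated
replicates, 6 prediction bins), and the per-observation diagnostics
(PRED/IPRED/iWRES).  Writes results/bootstrap.csv, results/vpc.csv,
results/gof.csv and figures under results/figures/.
"""

from pathlib import Path

import sertpk as sp
from sertpk.estimate import FitSpec, fit
from sertpk.interface import read_dataset
from sertpk.plots import plot_gof, plot_vpc
from sertpk.validate import bootstrap, gof, vpc

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    dataset = read_dataset(RESULTS / "dataset.csv")
    figures = RESULTS / "figures"
    figures.mkdir(exist_ok=True)

    print("fitting point estimates ...")
    point = fit(dataset, sp.FINAL_MODEL, FitSpec(compute_se=False))

    print("bootstrap (200 replicates) ...")
    boot = bootstrap(dataset, sp.FINAL_MODEL, n_boot=200, seed=SEED,
                     original_fit=point)
    boot.to_csv(RESULTS / "bootstrap.csv")
    print(boot.table.round(4).to_string(index=False))
    print(f"replicates: {boot.n_success}/{boot.n_requested} converged"
          + ("  [UNRELIABLE]" if boot.unreliable else ""))

    print("\nvisual predictive check (300 replicates) ...")
    bands = vpc(dataset, point.model, n_replicates=300, seed=SEED, bins=6)
    bands.to_csv(RESULTS / "vpc.csv")
    plot_vpc(bands, figures / "vpc.png")
    inside = 0
    med = bands.simulated[bands.simulated["percentile"] == 50.0].set_index("bin")
    for _, row in bands.observed.iterrows():
        if med.loc[row["bin"], "band_lo"] <= row["p50"] <= med.loc[row["bin"], "band_hi"]:
            inside += 1
    print(f"observed medians inside simulated 95% bands: {inside}/{len(bands.observed)} bins")

    print("\ngoodness of fit ...")
    table = gof(dataset, point.model, point)
    table.to_csv(RESULTS / "gof.csv", index=False)
    plot_gof(table, figures / "gof.png")
    print(f"iWRES mean {table['iwres'].mean():+.3f}, sd {table['iwres'].std():.3f} "
          f"over {len(table)} observations")


if __name__ == "__main__":
    main()
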