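"""Optional rendering of diagnostics and simulation outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .dosing import PtaTable
from .validate import VpcResult


def plot_vpc(result: VpcResult, path) -> None:
    """Observed percentiles over the simulated 95% envelopes, per bin."""
    fig, ax = plt.subplots(figsize=(6, 4))
    centers = 0.5 * (result.bins["lo"] + result.bins["hi"])
    for pct, color in ((2.5, "tab:blue"), (50.0, "tab:red"), (97.5, "tab:blue")):
        band = result.simulated[result.simulated["percentile"] == pct]
        ax.fill_between(centers, band["band_lo"], band["band_hi"],
                        alpha=0.25, color=color, lw=0)
    obs = result.observed
    ax.plot(centers, obs["p50"], "o-", color="tab:red", label="observed median")
    ax.plot(centers, obs["p2_5"], "o--", color="tab:blue", label="observed 2.5/97.5%")
    ax.plot(centers, obs["p97_5"], "o--", color="tab:blue")
    ax.set_xlabel("population prediction (ng/mL)")
    ax.set_ylabel("concentration (ng/mL)")
    ax.set_title("Visual predictive check")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gof(table: pd.DataFrame, path) -> None:
    """Observation-vs-prediction and residual panels."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    lim = max(table["dv"].max(), table["pred"].max()) * 1.05
    for ax, col, label in (
        (axes[0, 0], "pred", "population prediction"),
        (axes[0, 1], "ipred", "individual prediction"),
    ):
        ax.plot(table[col], table["dv"], ".", alpha=0.5)
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{label} (ng/mL)")
        ax.set_ylabel("observation (ng/mL)")
    axes[1, 0].plot(table["ipred"], table["iwres"].abs(), ".", alpha=0.5)
    axes[1, 0].set_xlabel("individual prediction (ng/mL)")
    axes[1, 0].set_ylabel("|iWRES|")
    axes[1, 1].plot(table["time"], table["wres"], ".", alpha=0.5)
    axes[1, 1].axhline(0, color="k", lw=1, ls="--")
    axes[1, 1].set_xlabel("time after dose (h)")
    axes[1, 1].set_ylabel("weighted residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pta_curves(table: PtaTable, path) -> None:
    """Attainment probability vs weight, one line per dose."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for dose, grp in table.records.groupby("dose"):
        grp = grp.sort_values("weight")
        ax.plot(grp["weight"], 100 * grp["pta"], "o-", label=f"{dose:g} mg/kg/day")
    ax.set_xlabel("body weight (kg)")
    ax.set_ylabel("probability in 10-150 ng/mL (%)")
    ax.set_ylim(0, 102)
    ax.set_title(table.scenario.label)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
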