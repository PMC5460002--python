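"""Optional figure export: persistence curves, GRT ensemble CDFs and
recharge CDF comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_persistence_curves(curves: pd.DataFrame, path) -> None:
    """Fraction of springs still active versus timescale, per mode."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, sub in curves.groupby("mode"):
        ax.semilogx(sub["timescale_y"], 100 * sub["fraction_active"],
                    marker="o", ms=3, label=mode)
    ax.set_xlabel("timescale of climate change (y)")
    ax.set_ylabel("springs still active (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_grt_ensemble(ensemble, path, n_show: int = 200) -> None:
    """Monte Carlo GRT CDFs (black) with the point-estimate CDF in red."""
    grid = ensemble.cdf_grid()
    cdfs = ensemble.cdfs(grid)
    fig, ax = plt.subplots(figsize=(6, 4))
    for row in cdfs[:n_show]:
        ax.semilogx(grid, row, color="k", alpha=0.05, lw=0.5)
    ax.semilogx(grid, np.median(cdfs, axis=0), color="r", lw=1.5)
    ax.set_xlabel("groundwater response time (y)")
    ax.set_ylabel("cumulative frequency")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_recharge_cdfs(cdfs: pd.DataFrame, path) -> None:
    """All-spring, active-spring and regional recharge CDFs."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(cdfs["recharge_mm_per_y"], cdfs["cdf_all_springs"],
            label="all springs")
    ax.plot(cdfs["recharge_mm_per_y"], cdfs["cdf_active_springs"],
            label="active springs")
    ax.plot(cdfs["recharge_mm_per_y"], cdfs["cdf_regional"], ls="--",
            label="regional recharge")
    ax.set_xlabel("average catchment recharge (mm/y)")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
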