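"""Minimal plotting helpers for sweeps and eigenvalue clouds."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers save to file
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_sweep", "plot_eigen_cloud"]


def plot_sweep(sweep, path=None, ax=None):
    """Lambda, -N*min, -<N*> and the mean-field prediction against P."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    s = sweep.summary
    ax.plot(s["P"], s["Lambda_mean"], "k-", label=r"$\Lambda$")
    ax.plot(s["P"], -s["Nmin_mean"], "b-", label=r"$-N^*_{min}$")
    ax.plot(s["P"], -s["Nmean_mean"], "g-", label=r"$-\langle N^*\rangle$")
    ax.plot(s["P"], -s["mean_field"], "mo", mfc="none", ms=4, label="mean field")
    ax.set_xlabel("proportion of mutualistic pairs $P$")
    ax.set_ylabel("rate / density")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_eigen_cloud(cloud_df, path=None, ax=None):
    """Scatter one community's spectrum in the complex plane."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    bulk = cloud_df[~cloud_df["is_outlier"]]
    outl = cloud_df[cloud_df["is_outlier"]]
    ax.plot(bulk["re"], bulk["im"], "r.", ms=4)
    ax.plot(outl["re"], outl["im"], "k*", ms=10)
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(r"Re $\lambda$")
    ax.set_ylabel(r"Im $\lambda$")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
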