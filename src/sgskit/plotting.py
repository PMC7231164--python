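"""Diagnostic plots: sweep curves, survival surfaces, interaction fits."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_sweep(sweep_table, path, trait: str = "") -> None:
    """R² versus nominal SGS threshold, annotated with locus counts."""
    t = sweep_table.dropna(subset=["r2"])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(t["threshold"], 100 * t["r2"], "o-", color="tab:blue")
    for _, row in t.iterrows():
        ax.annotate(int(row["n_loci"]), (row["threshold"], 100 * row["r2"]),
                    textcoords="offset points", xytext=(0, 6),
                    fontsize=7, color="firebrick", ha="center")
    ax.set_xscale("log")
    ax.set_xlabel("nominal SGS P-value threshold")
    ax.set_ylabel("variance explained (%)")
    if trait:
        ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_surface(surface, path, coords_pre=None, coords_post=None) -> None:
    """Filled contours of the survival surface, optionally with samples."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    lim = np.abs(surface.z).max() or 1.0
    cs = ax.contourf(surface.x, surface.y, surface.z.T, levels=21,
                     cmap="RdBu_r", vmin=-lim, vmax=lim)
    fig.colorbar(cs, ax=ax, label="survival score (z)")
    if coords_pre is not None:
        ax.plot(*np.asarray(coords_pre).T, "o", ms=3, mfc="none", c="firebrick")
    if coords_post is not None:
        ax.plot(*np.asarray(coords_post).T, "^", ms=3, mfc="none", c="black")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if surface.habitat:
        ax.set_title(surface.habitat)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_interaction(y, x, group, fit, path, ylab="trait", xlab="polygenic score") -> None:
    """Scatter with per-group fitted regression lines."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    group = np.asarray(list(group), dtype=object)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for g, color in zip(fit.slopes, ("tab:green", "tab:blue", "tab:red")):
        m = group == g
        ax.plot(x[m], y[m], "o", ms=3, alpha=0.5, color=color, label=str(g))
        xs = np.linspace(np.nanmin(x[m]), np.nanmax(x[m]), 10)
        ax.plot(xs, fit.intercepts[g] + fit.slopes[g] * xs, "-", color=color)
    ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.set_title(f"interaction P = {fit.interaction_p:.2g}, R² = {fit.r_squared:.3f}",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
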