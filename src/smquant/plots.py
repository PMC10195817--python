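"""Minimal plotting helpers for CLI outputs and examples."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from smquant.cluster import ClusterResult, RipleyCurve
from smquant.io import LocalizationTable
from smquant.tracking import DIFFUSE_D_MIN, STATIC_D_MAX, DiffusionFit


def plot_cluster_map(locs: LocalizationTable, result: ClusterResult, path):
    """Scatter of localizations coloured by cluster id (noise in grey)."""
    fig, ax = plt.subplots(figsize=(5, 5))
    noise = result.labels < 0
    ax.scatter(locs.xy[noise, 0], locs.xy[noise, 1], s=2, c="0.8", label="noise")
    ax.scatter(locs.xy[~noise, 0], locs.xy[~noise, 1], s=2,
               c=result.labels[~noise] % 20, cmap="tab20")
    ax.set_xlabel("x (nm)")
    ax.set_ylabel("y (nm)")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ripley(curve: RipleyCurve, path):
    fig, ax = plt.subplots()
    ax.plot(curve.radii, curve.l_minus_r)
    ax.axhline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("L(r) − r (nm)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_d_histogram(fits: list[DiffusionFit], path):
    """Log-scale D histogram with the static/slow/diffuse thresholds drawn."""
    d = np.array([f.D for f in fits if not f.failed and f.D > 0])
    fig, ax = plt.subplots()
    ax.hist(np.log10(d), bins=40, color="steelblue")
    for thr in (STATIC_D_MAX, DIFFUSE_D_MIN):
        ax.axvline(np.log10(thr), color="k", ls=":")
    ax.set_xlabel("log10 D (µm²/s)")
    ax.set_ylabel("tracks")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_titration(curve, fit, path):
    from smquant.binding import eq1_bound

    fig, ax = plt.subplots()
    ax.semilogx(curve.titrant_total, curve.signal, "o", label="data")
    xx = np.geomspace(curve.titrant_total[0], curve.titrant_total[-1], 200)
    bound = eq1_bound(xx, curve.fixed_partner, fit.kd)
    yy = fit.f_free + (fit.f_bound - fit.f_free) * bound / curve.fixed_partner
    if fit.a is not None:
        yy = yy + fit.a + (fit.b or 0.0) * xx
    ax.semilogx(xx, yy, "-", label=f"fit KD={fit.kd:.3g} µM")
    ax.set_xlabel("titrant (µM)")
    ax.set_ylabel("signal")
    ax.legend()
    fig.savefig(path, dpi=150)
    plt.close(fig)
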