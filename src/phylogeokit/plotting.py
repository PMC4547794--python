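"""Minimal plotting helpers for curves and randomization histograms."""

from __future__ import annotations

from typing import Sequence

from .curves import CumulativeCurve
from .montecarlo import MCResult

__all__ = ["plot_curves", "plot_mc_histogram"]


def _axes():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_curves(curves: Sequence[CumulativeCurve], path: str) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in curves:
        xs = c.step_points()
        ax.step(xs, c.cdf(xs), where="post", label=c.label)
    ax.set_xlabel("pairwise differences")
    ax.set_ylabel("cumulative fraction of pairs")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_mc_histogram(result: MCResult, path: str) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(6, 4))
    classes = sorted(result.histogram)
    counts = [result.histogram[c] for c in classes]
    ax.bar(classes, counts, width=0.8, color="steelblue",
           label="randomized L")
    ax.axvline(result.observed_L, color="crimson", label="observed L")
    ax.set_xlabel("dispersal length L")
    ax.set_ylabel("replicates")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
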