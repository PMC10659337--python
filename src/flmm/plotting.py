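"""Coefficient-function plots: estimate, pointwise and joint bands, significance bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import inference

__all__ = ["plot_coefficient"]


def plot_coefficient(band, out=None, ax=None, title=None):
    """One panel per coefficient: estimate curve, dark pointwise band, light
    joint band, zero line, alignment-event marker at t = 0 and bars marking
    intervals where the joint band excludes zero.

    ``out`` may be any path matplotlib can write (png, pdf, svg).
    Returns the matplotlib figure.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
    else:
        fig = ax.figure
    t = band.time
    ax.fill_between(
        t, band.joint_bounds[:, 0], band.joint_bounds[:, 1],
        color="0.85", label=f"joint {band.joint_level:.0%} CI",
    )
    ax.fill_between(
        t, band.pw_bounds[:, 0], band.pw_bounds[:, 1],
        color="0.6", alpha=0.6, label=f"pointwise {band.pw_level:.0%} CI",
    )
    ax.plot(t, band.estimate, color="C0", lw=1.8, label="estimate")
    ax.axhline(0.0, color="k", lw=0.8)
    if t.min() <= 0.0 <= t.max():
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ivals = inference.significant_intervals(band, "joint")
    y0 = ax.get_ylim()[0]
    for a, b in ivals:
        ax.plot([a, b], [y0, y0], color="C3", lw=4, solid_capstyle="butt")
    ax.set_xlabel("time from alignment event (s)")
    ax.set_ylabel(rf"$\hat\beta$ ({band.name})")
    ax.set_title(title or band.name)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
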