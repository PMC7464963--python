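"""Figure builders for the pipeline reports."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # noqa: E402 — headless rendering
import matplotlib.pyplot as plt
import numpy as np

from .kinetics import KineticsFit
from .microbiota import CorePrevalenceResult

__all__ = ["plot_kinetics", "plot_scores", "plot_prevalence_heatmap"]

_GROUP_COLORS = {"A": "tab:blue", "B": "tab:orange", "C": "tab:green"}


def plot_kinetics(fits: Sequence[KineticsFit], ax=None):
    """Per-group sqrt-mean points (+- SD), fitted curves and 95% bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for f in fits:
        c = _GROUP_COLORS.get(f.group)
        ax.errorbar(
            f.days, f.sqrt_means, yerr=f.sqrt_sds, fmt="o", color=c, label=f.group
        )
        ax.plot(f.day_grid, f.curve, color=c)
        if f.has_band():
            ax.fill_between(f.day_grid, f.band_lower, f.band_upper, color=c, alpha=0.2)
    ax.set_xlabel("day")
    ax.set_ylabel("sqrt(normalized signal) [A.U.]")
    ax.set_title(fits[0].metabolite)
    ax.legend(title="group")
    return ax.figure


def plot_scores(scores: np.ndarray, y, ax=None, title: str = ""):
    """First two latent-variable scores coloured by group."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    y = np.asarray(y)
    for g in np.unique(y):
        sel = y == g
        ax.scatter(scores[sel, 0], scores[sel, 1], s=12, label=str(g),
                   color=_GROUP_COLORS.get(str(g)))
    ax.set_xlabel("LV1")
    ax.set_ylabel("LV2")
    ax.set_title(title)
    ax.legend(title="group")
    return ax.figure


def plot_prevalence_heatmap(result: CorePrevalenceResult, ax=None):
    """Core-taxon prevalence (%) across (ecosystem, group, time) strata."""
    prev = result.prevalence
    if result.ecology_groups:
        order = sorted(prev.index, key=lambda t: (result.ecology_groups.get(t, ""), t))
        prev = prev.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.3 * prev.shape[1]), max(4, 0.3 * prev.shape[0])))
    im = ax.imshow(prev.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(prev.shape[1]))
    ax.set_xticklabels(
        [f"{e[:2]}-{g}-d{int(t)}" for e, g, t in prev.columns], rotation=90, fontsize=6
    )
    labels = [
        f"{t} [{result.ecology_groups.get(t, '')}]" if result.ecology_groups else t
        for t in prev.index
    ]
    ax.set_yticks(range(prev.shape[0]))
    ax.set_yticklabels(labels, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="prevalence (%)")
    return ax.figure
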