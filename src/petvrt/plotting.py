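"""Plots: VRT-vs-SBR curves, overestimation curves, radial profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .vrt import ProfileSeries

__all__ = ["plot_vrt_curves", "plot_overestimation", "plot_profiles"]


def plot_vrt_curves(vrt_table: pd.DataFrame):
    """Relative VRT against SBR, one line per sphere, one panel per variant."""
    variants = list(dict.fromkeys(vrt_table["variant"]))
    fig, axes = plt.subplots(1, len(variants), figsize=(5 * len(variants), 4), sharey=True, squeeze=False)
    for ax, variant in zip(axes[0], variants):
        sub = vrt_table[vrt_table["variant"] == variant]
        for diameter, grp in sub.groupby("diameter_mm"):
            grp = grp.sort_values("sbr")
            ax.plot(grp["sbr"], grp["vrt_percent"], marker="o", label=f"{diameter:g} mm")
        ax.set_xlabel("SBR")
        ax.set_title(variant)
        ax.grid(alpha=0.3)
    axes[0][0].set_ylabel("VRT [%]")
    axes[0][-1].legend(title="diameter", fontsize=8)
    fig.tight_layout()
    return fig


def plot_overestimation(over_table: pd.DataFrame):
    """Volume overestimation from cross-applied thresholds against SBR."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for diameter, grp in over_table.groupby("diameter_mm"):
        grp = grp.sort_values("sbr")
        ax.plot(grp["sbr"], grp["overestimation_percent"], marker="o", label=f"{diameter:g} mm")
    ax.set_xlabel("SBR")
    ax.set_ylabel("volume overestimation [%]")
    ax.grid(alpha=0.3)
    ax.legend(title="diameter", fontsize=8)
    fig.tight_layout()
    return fig


def plot_profiles(profiles: dict[str, ProfileSeries]):
    """Mirrored radial intensity profiles with VRT and reference levels."""
    n = len(profiles)
    fig, axes = plt.subplots(1, n, figsize=(4.5 * n, 3.5), sharey=True, squeeze=False)
    for ax, (label, series) in zip(axes[0], profiles.items()):
        ax.plot(series.points[:, 0], series.points[:, 1], ".", ms=2, alpha=0.4)
        ax.axhline(series.reference_level, color="0.6", lw=6, alpha=0.4, label="true concentration")
        if series.vrt_level is not None:
            ax.axhline(series.vrt_level, color="tab:red", lw=1.2, label="VRT threshold")
        ax.set_xlabel("radial distance [mm]")
        ax.set_title(label, fontsize=9)
        ax.legend(fontsize=7)
    axes[0][0].set_ylabel("intensity")
    fig.tight_layout()
    return fig
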