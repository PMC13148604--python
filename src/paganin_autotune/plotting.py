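"""Diagnostic PNG panels for spectral curves, merit curves and frames."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .imaging_core import Image2D
from .metrics import histogram_stats, line_profile
from .spectral import SpectralCurves

__all__ = ["plot_spectral_curves", "plot_merit_curve", "plot_frame_panel"]


def plot_spectral_curves(curves: SpectralCurves, path, title: str = "") -> None:
    """FRC, consistency bound and (rescaled) NPS against normalized radius."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curves.r, curves.frc, label="FRC c(r)")
    ax.plot(curves.r, curves.bound, "--", label="bound B(r)")
    nps = curves.nps
    if np.nanmax(nps) > 0:
        ax.plot(curves.r, nps / np.nanmax(nps), ":", label="NPS W(r) (rescaled)")
    ax.set_xlabel("normalized radius r")
    ax.set_ylim(-1.05, 1.05)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_merit_curve(l_values, values, path, ylabel: str,
                     l_selected: float | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(l_values, values)
    if l_selected is not None:
        ax.axvline(l_selected, color="r", ls="--",
                   label=f"selected l = {l_selected:.3g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("filter parameter l")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_frame_panel(img: Image2D, path, title: str = "") -> None:
    """Frame with histogram inset and central line profile beneath."""
    fig, (ax_img, ax_prof) = plt.subplots(
        2, 1, figsize=(5, 6), gridspec_kw={"height_ratios": [4, 1]})
    shown = np.where(img.mask, img.values, np.nan)
    ax_img.imshow(shown, cmap="gray")
    ax_img.set_axis_off()
    if title:
        ax_img.set_title(title)
    inset = ax_img.inset_axes([0.02, 0.02, 0.3, 0.25])
    stats = histogram_stats(img)
    centers = 0.5 * (stats["edges"][:-1] + stats["edges"][1:])
    inset.fill_between(centers, stats["counts"], color="w", alpha=0.8)
    inset.set_xticks([]), inset.set_yticks([])
    prof, pmask = line_profile(img, img.shape[0] // 2)
    ax_prof.plot(np.where(pmask, prof, np.nan), lw=0.8)
    ax_prof.set_xlabel("column (central row profile)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
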