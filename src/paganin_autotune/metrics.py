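"""Quality diagnostics: blockwise local-contrast maps, line profiles, histograms.

The local-contrast map is a blockwise coefficient of variation (population
standard deviation over mean) — a texture/contrast indicator that is invariant
under global positive rescaling and decoupled from edge sharpness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .imaging_core import Image2D

__all__ = [
    "ContrastMap",
    "local_contrast_map",
    "line_profile",
    "histogram_stats",
]


@dataclass
class ContrastMap:
    """Coarse-grid coefficient-of-variation map with its block size (pixels).

    Blocks whose mean is non-positive, or boundary blocks smaller than
    ``block_size``, are masked rather than partially computed.
    """

    values: np.ndarray
    block_size: int
    mask: np.ndarray


def local_contrast_map(img: Image2D, block: int) -> ContrastMap:
    """Per-block CV = population std / mean over valid pixels."""
    if block < 2:
        raise ValueError("block must be >= 2")
    ny, nx = img.shape
    if block > min(ny, nx):
        raise ValueError(f"block {block} larger than image {img.shape}")
    by, bx = ny // block, nx // block
    values = np.full((by, bx), np.nan)
    mask = np.zeros((by, bx), dtype=bool)
    for i in range(by):
        for j in range(bx):
            tile = img.values[i * block:(i + 1) * block,
                              j * block:(j + 1) * block]
            tmask = img.mask[i * block:(i + 1) * block,
                             j * block:(j + 1) * block]
            vals = tile[tmask]
            if vals.size == 0:
                continue
            mean = vals.mean()
            if mean <= 0:
                continue
            values[i, j] = vals.std() / mean  # population std
            mask[i, j] = True
    return ContrastMap(values, block, mask)


def line_profile(img: Image2D, row: int) -> tuple[np.ndarray, np.ndarray]:
    """Values and validity mask along one row of the frame."""
    if not 0 <= row < img.shape[0]:
        raise ValueError(f"row {row} out of range for {img.shape[0]} rows")
    return img.values[row].copy(), img.mask[row].copy()


def _smooth_counts(counts: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(counts.astype(float), kernel, mode="same")


def histogram_stats(img: Image2D, n_bins: int = 64) -> dict:
    """Histogram of valid pixels plus a two-mode separation score.

    The score is the distance between the two largest local maxima of a
    lightly smoothed histogram, divided by the pooled within-mode width
    (robust scale — scaled median absolute deviation — of the pixels assigned
    to the nearer mode, so edge-transition pixels do not swamp the width).
    It is a qualitative separability indicator; with fewer than two modes it
    is reported as None.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = img.valid_values()
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = _smooth_counts(counts)
    # two most salient interior maxima of the smoothed histogram; ranking by
    # prominence keeps sub-peaks of one broad lump from shadowing a genuine
    # second mode
    idx, props = signal.find_peaks(smooth, prominence=0)
    order = np.argsort(props["prominences"])[::-1]
    peaks = [int(idx[k]) for k in order]
    out = {"counts": counts, "edges": edges, "separation": None,
           "modes": None}
    if len(peaks) < 2:
        return out
    i1, i2 = sorted(peaks[:2])
    m1, m2 = centers[i1], centers[i2]
    assign = np.abs(vals[:, None] - np.array([m1, m2])[None, :]).argmin(axis=1)
    spreads = []
    for k, m in enumerate((m1, m2)):
        grp = vals[assign == k]
        if grp.size:
            spreads.append(1.4826 * np.median(np.abs(grp - m)))
    pooled = float(np.sqrt(np.mean(np.square(spreads)))) if spreads else 0.0
    out["modes"] = (float(m1), float(m2))
    if pooled > 0:
        out["separation"] = float(abs(m2 - m1) / pooled)
    return out
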