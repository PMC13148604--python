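"""Synthetic projection frames for exercising the selectors end to end.

The forward model is the exact inverse of the Paganin low-pass filter under
the linearized homogeneous-object transport-of-intensity description: a
projected-thickness map T gives a contact image exp(-mu T), whose spectrum is
multiplied by (1 + l_true ||q||^2) to produce the edge-enhanced free-space
frame f_clean.  Filtering f_clean at l = l_true therefore recovers -mu T
exactly — the module's central round-trip oracle.  Counting statistics are
emulated with independent Poisson sample and flat-field frames.

Feature edges are softened by a Gaussian blur (detector/source blur scale);
perfectly sharp edges would produce unphysically large phase-contrast fringes
under the inverse filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .imaging_core import FilterParams, Image2D, transfer_grid

__all__ = [
    "Feature",
    "PhantomSpec",
    "PhantomDataset",
    "generate_thickness",
    "forward_project",
    "add_counting_noise",
    "make_dataset",
    "default_spec",
    "two_material_spec",
]

FeatureKind = Literal["disc", "rod", "annulus"]


@dataclass(frozen=True)
class Feature:
    """A thickness feature: disc(radius), rod(length, width) or
    annulus(outer, inner radius), centered at ``center`` (row, col) in pixels,
    contributing ``thickness`` (working length units) where present."""

    kind: FeatureKind
    center: tuple[float, float]
    size: tuple[float, ...]
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("feature thickness must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic dataset; every output is a pure
    function of this spec (hash-stable fixtures).

    Defaults model a small two-material synchrotron projection: unit pixel
    size (so l is in squared pixels), attenuation mu*T of order 0.5 at the
    thickest feature, moderate phase-contrast strength l_true = 100, and 1e4
    expected photons per pixel in the flat field.
    """

    shape: tuple[int, int] = (128, 128)
    pixel_size: float = 1.0
    features: tuple[Feature, ...] = ()
    mu: float = 0.5
    l_true: float = 100.0
    photons: float = 1e4
    seed: int = 0
    edge_sigma: float = 6.0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.photons <= 0:
            raise ValueError("photons must be > 0")
        if self.l_true < 0:
            raise ValueError("l_true must be >= 0")


@dataclass
class PhantomDataset:
    """Generated frames: ground-truth thickness, clean normalized frame, and
    the Poisson sample/flat pair."""

    thickness: Image2D
    f_clean: Image2D
    I: Image2D
    I0: Image2D
    spec: PhantomSpec


def generate_thickness(spec: PhantomSpec) -> Image2D:
    """Superpose the spec's features into a projected-thickness map."""
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    T = np.zeros(spec.shape)
    for feat in spec.features:
        cy, cx = feat.center
        if not (0 <= cy < ny and 0 <= cx < nx):
            raise ValueError(f"feature center {feat.center} outside the frame")
        dy, dx = yy - cy, xx - cx
        if feat.kind == "disc":
            (radius,) = feat.size
            inside = dy**2 + dx**2 <= radius**2
        elif feat.kind == "rod":
            length, width = feat.size
            inside = (np.abs(dx) <= length / 2) & (np.abs(dy) <= width / 2)
        elif feat.kind == "annulus":
            outer, inner = feat.size
            rsq = dy**2 + dx**2
            inside = (rsq <= outer**2) & (rsq >= inner**2)
        else:
            raise ValueError(f"unknown feature kind {feat.kind!r}")
        T += np.where(inside, feat.thickness, 0.0)
    if spec.edge_sigma > 0 and spec.features:
        T = ndimage.gaussian_filter(T, spec.edge_sigma, mode="wrap")
    return Image2D(T, spec.pixel_size)


def forward_project(thickness: Image2D, mu: float, l_true: float,
                    pixel_size: float | None = None) -> Image2D:
    """Edge-enhanced normalized frame from a thickness map.

    f_clean = F^-1[ F[exp(-mu T)] * (1 + l_true ||q||^2) ], the exact inverse
    of the Paganin low-pass stage; the spatial mean is preserved (the extra
    factor is 1 at DC).  l_true = 0 gives the contact image exp(-mu T).
    """
    if pixel_size is None:
        pixel_size = thickness.pixel_size
    contact = np.exp(-mu * thickness.values)
    H = transfer_grid(contact.shape, pixel_size, FilterParams(l_true))
    out = np.fft.ifft2(np.fft.fft2(contact) / H).real
    return Image2D(out, pixel_size)


def add_counting_noise(f_clean: Image2D, photons: float, seed: int,
                       noiseless: bool = False) -> tuple[Image2D, Image2D]:
    """Poisson sample/flat pair: I ~ Poi(photons * f_clean), I0 ~ Poi(photons).

    The two frames use independent substreams derived from ``seed``.  With
    ``noiseless=True`` the expectations are returned directly, so
    I / I0 = f_clean exactly.  Negative clean intensities (extreme fringe
    undershoot) are clamped to zero expected counts.
    """
    if photons <= 0:
        raise ValueError("photons must be > 0")
    lam = photons * np.clip(f_clean.values, 0.0, None)
    if noiseless:
        return (Image2D(lam, f_clean.pixel_size),
                Image2D(np.full(f_clean.shape, photons), f_clean.pixel_size))
    ss_I, ss_I0 = np.random.SeedSequence(seed).spawn(2)
    I = np.random.default_rng(ss_I).poisson(lam).astype(float)
    I0 = np.random.default_rng(ss_I0).poisson(
        np.full(f_clean.shape, float(photons))).astype(float)
    return (Image2D(I, f_clean.pixel_size), Image2D(I0, f_clean.pixel_size))


def make_dataset(spec: PhantomSpec) -> PhantomDataset:
    """Generate the full dataset described by ``spec`` (deterministic)."""
    T = generate_thickness(spec)
    f_clean = forward_project(T, spec.mu, spec.l_true, spec.pixel_size)
    I, I0 = add_counting_noise(f_clean, spec.photons, spec.seed,
                               noiseless=spec.noiseless)
    return PhantomDataset(T, f_clean, I, I0, spec)


def default_spec(seed: int = 0, shape: tuple[int, int] = (128, 128),
                 **overrides) -> PhantomSpec:
    """The standard two-material test phantom: a thick disc, a thin rod and an
    annulus, scaled to the frame size."""
    ny, nx = shape
    s = min(ny, nx)
    features = (
        Feature("disc", (0.38 * ny, 0.36 * nx), (0.18 * s,), 1.0),
        Feature("rod", (0.70 * ny, 0.55 * nx), (0.55 * s, 0.08 * s), 0.45),
        Feature("annulus", (0.36 * ny, 0.72 * nx), (0.14 * s, 0.07 * s), 0.7),
    )
    spec = PhantomSpec(shape=shape, features=features, seed=seed)
    return replace(spec, **overrides) if overrides else spec


def two_material_spec(seed: int = 0, shape: tuple[int, int] = (64, 64),
                      photons: float = 2e3, **overrides) -> PhantomSpec:
    """A single-disc, two-material phantom for histogram-separability work.

    Phase-contrast strength and edge blur are kept mild (l_true = 5,
    3-px blur) so the background intensity distribution stays unimodal and
    the two-mode separation score is meaningful."""
    ny, nx = shape
    features = (Feature("disc", (ny / 2, nx / 2), (0.28 * min(shape),), 1.0),)
    spec = PhantomSpec(shape=shape, features=features, l_true=5.0,
                       edge_sigma=3.0, photons=photons, seed=seed)
    return replace(spec, **overrides) if overrides else spec
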