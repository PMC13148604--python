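"""Flat-field normalization and the single-distance Paganin phase-retrieval filter.

The Paganin filter maps a flat-field-corrected propagation-based phase-contrast
frame ``f = I / I0`` to

    p_l = ln( F^-1 [ F[f] / (1 + l * ||q||^2) ] ),

where ``q`` is the spatial-frequency coordinate and the regularization
parameter ``l`` has units of squared length.  Under the homogeneous-object
transport-of-intensity model, ``-p_l / mu`` approximates the projected
thickness of the sample, with ``mu`` the linear attenuation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Image2D",
    "FilterParams",
    "ExperimentGeometry",
    "normalize_flat",
    "paganin_transfer",
    "transfer_grid",
    "apply_lowpass",
    "apply_paganin",
    "l_to_delta_beta",
    "delta_beta_to_l",
]

FreqConvention = Literal["angular", "cyclic"]


@dataclass
class Image2D:
    """A real-valued 2D frame with pixel-size metadata and a validity mask.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Pixel intensities (arbitrary units).  Entries outside the mask may be
        NaN; entries inside the mask must be finite.
    pixel_size : float
        Physical side length of one pixel (working length units, > 0).
    mask : ndarray of bool, same shape, optional
        True marks valid pixels.  Defaults to all-valid.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"Image2D expects a 2D array, got shape {self.values.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values on masked-in pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def area(self) -> float:
        """Total physical area of the frame."""
        return self.values.size * self.pixel_size**2

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def filled(self, fill: float | None = None) -> np.ndarray:
        """Values with masked-out pixels replaced (default: mean of valid pixels)."""
        if self.mask.all():
            return self.values
        if not self.mask.any():
            raise ValueError("image has no valid pixels")
        if fill is None:
            fill = float(self.values[self.mask].mean())
        out = self.values.copy()
        out[~self.mask] = fill
        return out


@dataclass(frozen=True)
class FilterParams:
    """Paganin-filter parameter.

    ``l`` carries units of squared length; ``freq_convention`` fixes whether
    the frequency norm in ``1 + l * ||q||^2`` is angular (includes the 2*pi
    factor) or cyclic (plain FFT cycle frequency).
    """

    l: float
    freq_convention: FreqConvention = "angular"

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError(f"filter parameter l must be >= 0, got {self.l}")
        if self.freq_convention not in ("angular", "cyclic"):
            raise ValueError(f"unknown frequency convention {self.freq_convention!r}")


@dataclass(frozen=True)
class ExperimentGeometry:
    """Propagation geometry: distance z (m), wavelength (m), attenuation mu (1/m)."""

    z: float
    wavelength: float
    mu: float

    def __post_init__(self) -> None:
        for name in ("z", "wavelength", "mu"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def normalize_flat(I: Image2D, I0: Image2D) -> Image2D:
    """Flat-field correction ``f = I / I0``.

    Pixels where either frame is non-positive (dead detector pixels, zero
    counts) are masked out rather than clipped, so downstream statistics stay
    unbiased.
    """
    if I.shape != I0.shape:
        raise ValueError(f"shape mismatch: {I.shape} vs {I0.shape}")
    if I.pixel_size != I0.pixel_size:
        raise ValueError("pixel_size mismatch between sample and flat frames")
    valid = I.mask & I0.mask & (I.values > 0) & (I0.values > 0)
    if not valid.any():
        raise ValueError("flat-field normalization produced a fully masked frame")
    out = np.full(I.shape, np.nan)
    out[valid] = I.values[valid] / I0.values[valid]
    return Image2D(out, I.pixel_size, valid)


def paganin_transfer(q_norm_sq, l: float):
    """Fourier transfer function ``1 / (1 + l * ||q||^2)`` of the Paganin kernel.

    Accepts scalars or arrays of squared frequency norms; always in (0, 1],
    equal to 1 at DC and for ``l = 0``, and non-increasing in both arguments.
    """
    q_norm_sq = np.asarray(q_norm_sq, dtype=float)
    if np.any(q_norm_sq < 0):
        raise ValueError("squared frequency norm must be >= 0")
    if l < 0:
        raise ValueError("filter parameter l must be >= 0")
    out = 1.0 / (1.0 + l * q_norm_sq)
    return out if out.ndim else float(out)


def _q_squared(shape: tuple[int, int], pixel_size: float,
               convention: FreqConvention = "angular") -> np.ndarray:
    """Squared frequency-norm grid ``||q||^2`` on the FFT sample layout."""
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    scale = 2.0 * np.pi if convention == "angular" else 1.0
    return (scale * fy[:, None]) ** 2 + (scale * fx[None, :]) ** 2


def transfer_grid(shape: tuple[int, int], pixel_size: float,
                  params: FilterParams) -> np.ndarray:
    """Per-sample transfer function of the filter on the FFT grid."""
    return paganin_transfer(_q_squared(shape, pixel_size, params.freq_convention), params.l)


def apply_lowpass(f: Image2D, params: FilterParams, pad: bool = False) -> Image2D:
    """The Fourier low-pass stage of the Paganin filter, without the logarithm.

    The DC gain is exactly 1, so the spatial mean of the output equals the mean
    of the input.  Boundary handling is periodic (circular convolution), which
    matches the discrete Fourier definition of the filter; ``pad=True``
    symmetrically extends the frame by half its extent before filtering to
    soften wrap-around at strong smoothing.

    Masked-out pixels are filled with the valid-pixel mean before the FFT and
    stay masked-out in the result.
    """
    work = f.filled()
    if pad:
        py, px = f.shape[0] // 2, f.shape[1] // 2
        work = np.pad(work, ((py, py), (px, px)), mode="symmetric")
    H = transfer_grid(work.shape, f.pixel_size, params)
    filt = np.fft.ifft2(np.fft.fft2(work) * H).real
    if pad:
        filt = filt[py:py + f.shape[0], px:px + f.shape[1]]
    out = filt.copy()
    out[~f.mask] = np.nan
    return Image2D(out, f.pixel_size, f.mask.copy())


def apply_paganin(f: Image2D, params: FilterParams, pad: bool = False) -> Image2D:
    """Paganin filter with logarithm: ``p_l = ln(lowpass(f))``.

    Pixels where the filtered intensity is non-positive cannot support the
    logarithm and are masked out (no epsilon clipping).  The projected
    thickness is ``-p_l / mu``.
    """
    low = apply_lowpass(f, params, pad=pad)
    valid = low.mask & (np.nan_to_num(low.values, nan=-1.0) > 0)
    out = np.full(f.shape, np.nan)
    out[valid] = np.log(low.values[valid])
    return Image2D(out, f.pixel_size, valid)


def l_to_delta_beta(l: float, geom: ExperimentGeometry) -> float:
    """Convert the filter parameter ``l = z * delta * lambda / (4 pi beta)``
    to the refractive-index ratio ``delta / beta``."""
    if l <= 0:
        raise ValueError("l must be > 0 for conversion to delta/beta")
    return 4.0 * np.pi * l / (geom.z * geom.wavelength)


def delta_beta_to_l(delta_beta: float, geom: ExperimentGeometry) -> float:
    """Inverse of :func:`l_to_delta_beta` (exact algebraic round trip)."""
    if delta_beta <= 0:
        raise ValueError("delta/beta must be > 0")
    return delta_beta * geom.z * geom.wavelength / (4.0 * np.pi)
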