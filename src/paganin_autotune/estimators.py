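"""Scikit-learn-style estimators wrapping the filter and the selectors.

``PaganinFilter`` is a stateless transformer; the selector estimators tune
the filter parameter on a frame in ``fit`` (exposing the fitted value as
``l_`` and the full :class:`~paganin_autotune.selection.SelectionResult` as
``result_``) and apply the tuned filter in ``transform``.  All estimators
accept either an :class:`~paganin_autotune.imaging_core.Image2D` or a plain
2D array (treated as fully valid with the estimator's ``pixel_size``), and
support ``get_params`` / ``set_params`` / ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import selection
from .imaging_core import FilterParams, Image2D, apply_paganin
from .selection import LogGrid

__all__ = [
    "PaganinFilter",
    "NPSSelector",
    "StdCurveSelector",
    "CorrCurveSelector",
    "ThicknessSelector",
]


def _as_image(X, pixel_size: float) -> Image2D:
    if isinstance(X, Image2D):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2D frame, got shape {X.shape}")
    mask = np.isfinite(X)
    return Image2D(X, pixel_size, mask)


class PaganinFilter(TransformerMixin, BaseEstimator):
    """Apply the Paganin filter at a fixed parameter ``l``.

    ``transform`` returns the filtered log-frame as an array with NaN at
    masked-out pixels (non-positive filtered intensities).
    """

    def __init__(self, l: float = 0.0, pixel_size: float = 1.0,
                 freq_convention: str = "angular", pad: bool = False):
        self.l = l
        self.pixel_size = pixel_size
        self.freq_convention = freq_convention
        self.pad = pad

    def fit(self, X, y=None):
        _as_image(X, self.pixel_size)  # validation only; the filter is stateless
        self.n_features_in_ = np.asarray(
            X.values if isinstance(X, Image2D) else X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        img = _as_image(X, self.pixel_size)
        params = FilterParams(self.l, self.freq_convention)  # type: ignore[arg-type]
        p = apply_paganin(img, params, pad=self.pad)
        out = p.values.copy()
        out[~p.mask] = np.nan
        return out


class _BaseSelector(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing; subclasses implement ``_select``."""

    def __init__(self, pixel_size: float = 1.0, pad: bool = False):
        self.pixel_size = pixel_size
        self.pad = pad

    def _select(self, img: Image2D) -> selection.SelectionResult:
        raise NotImplementedError

    def fit(self, X, y=None):
        img = _as_image(X, self.pixel_size)
        self.result_ = self._select(img)
        self.l_ = self.result_.l_selected
        self.n_features_in_ = img.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "l_"):
            raise RuntimeError("selector is not fitted; call fit first")
        return PaganinFilter(self.l_, self.pixel_size,
                             pad=self.pad).transform(X)


class NPSSelector(_BaseSelector):
    """Fit the smallest ``l`` whose high-frequency noise fraction phi is <= eps.

    Fitted attributes: ``l_``, ``phi_`` (phi at the selection), ``interval_``
    (the fuzzy near-optimal interval when ``delta_r`` > 0) and ``result_``.
    """

    def __init__(self, eps: float = selection.DEFAULT_EPS,
                 r_hat: float = selection.DEFAULT_R_HAT,
                 delta_r: float = 0.0,
                 bounds: tuple[float, float] = selection.DEFAULT_BOUNDS,
                 tol: float = selection.BISECT_TOL,
                 n_rings: int | None = None, scheme: str = "rows",
                 pixel_size: float = 1.0, pad: bool = False):
        super().__init__(pixel_size, pad)
        self.eps = eps
        self.r_hat = r_hat
        self.delta_r = delta_r
        self.bounds = bounds
        self.tol = tol
        self.n_rings = n_rings
        self.scheme = scheme

    def _select(self, img: Image2D) -> selection.SelectionResult:
        res = selection.select_l_nps(
            img, eps=self.eps, r_hat=self.r_hat, bounds=self.bounds,
            tol=self.tol, n_rings=self.n_rings, scheme=self.scheme,  # type: ignore[arg-type]
            pad=self.pad)
        if self.delta_r > 0:
            res.interval = selection.fuzzy_interval(
                img, eps=self.eps, r_hat=self.r_hat, delta_r=self.delta_r,
                bounds=self.bounds, tol=self.tol, n_rings=self.n_rings,
                scheme=self.scheme, pad=self.pad, check_monotone=False)  # type: ignore[arg-type]
            self.interval_ = res.interval
        self.phi_ = res.diagnostics["phi_at_selected"]
        return res


class StdCurveSelector(_BaseSelector):
    """Fit ``l`` at the maximum of the consecutive-difference std curve f(l)."""

    def __init__(self, grid: LogGrid | None = None,
                 upper: float | None = None, refine: bool = False,
                 eps: float = selection.DEFAULT_EPS,
                 r_hat: float = selection.DEFAULT_R_HAT,
                 pixel_size: float = 1.0, pad: bool = False):
        super().__init__(pixel_size, pad)
        self.grid = grid
        self.upper = upper
        self.refine = refine
        self.eps = eps
        self.r_hat = r_hat

    def _select(self, img: Image2D) -> selection.SelectionResult:
        res = selection.select_l_std(img, self.grid, self.upper,
                                     refine=self.refine, pad=self.pad,
                                     eps=self.eps, r_hat=self.r_hat)
        self.curve_ = res.diagnostics["curve"]
        return res


class CorrCurveSelector(_BaseSelector):
    """Fit ``l`` at the minimum of the consecutive-frame correlation g(l)."""

    def __init__(self, grid: LogGrid | None = None, refine: bool = False,
                 pixel_size: float = 1.0, pad: bool = False):
        super().__init__(pixel_size, pad)
        self.grid = grid
        self.refine = refine

    def _select(self, img: Image2D) -> selection.SelectionResult:
        res = selection.select_l_corr(img, self.grid, refine=self.refine,
                                      pad=self.pad)
        self.curve_ = res.diagnostics["curve"]
        return res


class ThicknessSelector(_BaseSelector):
    """Fit the smallest ``l`` giving a non-positive filtered profile
    (non-negative recovered projected thickness) along one line."""

    def __init__(self, line: int | None = None,
                 bounds: tuple[float, float] = selection.DEFAULT_BOUNDS,
                 tol: float = selection.BISECT_TOL, slack: float = 0.0,
                 pixel_size: float = 1.0, pad: bool = False):
        super().__init__(pixel_size, pad)
        self.line = line
        self.bounds = bounds
        self.tol = tol
        self.slack = slack

    def _select(self, img: Image2D) -> selection.SelectionResult:
        return selection.select_l_thickness(img, self.line, self.bounds,
                                            self.tol, slack=self.slack,
                                            pad=self.pad)
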