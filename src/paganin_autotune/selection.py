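"""Data-driven selection of the Paganin-filter parameter.

Four complementary selectors are provided:

* ``select_l_nps`` — the noise-power-spectrum criterion: the smallest ``l``
  whose filtered frame leaves at most a fraction ``eps`` of split-difference
  noise power above the normalized cutoff radius ``r_hat``; found by bisection
  thanks to the monotone decay of phi(l).
* ``select_l_std`` — argmax of the standard deviation f(l) of differences of
  consecutively filtered frames over a log-spaced grid (noise-suppression
  elbow).
* ``select_l_corr`` — argmin of the correlation g(l) between consecutively
  filtered frames (g tends to 1 at both extremes and dips in between).
* ``select_l_thickness`` — the smallest ``l`` making the filtered log-frame
  non-positive along a line profile, i.e. a non-negative recovered projected
  thickness; the physically motivated (and much larger) choice.

All selectors are deterministic given their inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .imaging_core import FilterParams, Image2D, apply_paganin
from .spectral import (SplitScheme, compute_curves, default_n_rings,
                       make_ring_partition, phi_highfreq, split_image)

__all__ = [
    "LogGrid",
    "SelectionResult",
    "phi_of_l",
    "select_l_nps",
    "fuzzy_interval",
    "curve_f_std",
    "select_l_std",
    "curve_g_corr",
    "select_l_corr",
    "select_l_thickness",
]

DEFAULT_BOUNDS = (0.0, 1e8)
DEFAULT_EPS = 0.01
DEFAULT_R_HAT = 0.5
# Relative bisection tolerance on l and iteration cap.
BISECT_TOL = 1e-3
BISECT_MAX_ITER = 60
# Positive floor, relative to the upper bracket, below which "smallest l" is
# indistinguishable from 0 for the log-scale bisection.
_FLOOR_REL = 1e-14


@dataclass(frozen=True)
class LogGrid:
    """Logarithmically spaced grid of filter parameters.

    The span [l_min, l_max] is divided into ``n_subintervals`` equal
    subintervals in log space, each sampled with the same number of points —
    a mesh dense enough to resolve the peak/valley structure of the merit
    curves across many orders of magnitude.
    """

    l_values: np.ndarray
    n_subintervals: int
    bounds: tuple[float, float]

    @property
    def n_points(self) -> int:
        return len(self.l_values)

    def __post_init__(self) -> None:
        lv = np.asarray(self.l_values, dtype=float)
        object.__setattr__(self, "l_values", lv)
        if lv.ndim != 1 or len(lv) < 2:
            raise ValueError("grid needs at least 2 points")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if lv[0] < 0:
            raise ValueError("grid values must be non-negative")

    @classmethod
    def make(cls, l_min: float = 1e-2, l_max: float = 1e8,
             n_points: int = 128, n_subintervals: int = 8) -> "LogGrid":
        if not 0 < l_min < l_max:
            raise ValueError("require 0 < l_min < l_max")
        if n_points % n_subintervals:
            raise ValueError("n_points must be a multiple of n_subintervals")
        # equal log subintervals sampled with a common density: a uniform
        # geometric mesh whose every (n_points/n_subintervals)-th point sits
        # on a subinterval edge; uniform log spacing keeps the consecutive
        # finite-difference step of the merit curves consistent
        values = np.geomspace(l_min, l_max, n_points)
        values[-1] = l_max
        return cls(values, n_subintervals, (l_min, l_max))


@dataclass
class SelectionResult:
    """Outcome of a parameter-selection run with its diagnostics."""

    l_selected: float
    criterion: str  # {"nps", "std", "corr", "thickness"}
    epsilon: float | None = None
    r_hat: float | None = None
    interval: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, np.ndarray):
                return [None if (isinstance(v, float) and np.isnan(v)) else v
                        for v in x.tolist()]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            return x

        return {
            "l_selected": float(self.l_selected),
            "criterion": self.criterion,
            "epsilon": self.epsilon,
            "r_hat": self.r_hat,
            "interval": list(self.interval) if self.interval else None,
            "diagnostics": _clean(self.diagnostics),
        }


def phi_of_l(f: Image2D, l: float, *, r_hat: float = DEFAULT_R_HAT,
             n_rings: int | None = None, scheme: SplitScheme = "rows",
             pad: bool = False) -> float:
    """High-frequency noise fraction phi(l) of the filtered frame.

    Pipeline: Paganin filter at ``l`` -> split into half-images -> difference
    -> ring-averaged NPS -> normalized mass above ``r_hat``.
    """
    p = apply_paganin(f, FilterParams(l), pad=pad)
    u, v = split_image(p, scheme)
    if n_rings is None:
        n_rings = default_n_rings(u.shape)
    part = make_ring_partition(u.shape, u.pixel_size, n_rings)
    curves = compute_curves(u, v, part)
    return phi_highfreq(curves, r_hat)


def _bisect_smallest_feasible(value: Callable[[float], float], eps: float,
                              bounds: tuple[float, float], tol: float,
                              log: list | None = None) -> float:
    """Smallest l in ``bounds`` with value(l) <= eps, assuming monotone decay.

    Bisection runs on a log scale (with a positive floor when the lower bound
    is 0) until the bracket's relative width falls below ``tol``; the feasible
    upper end of the final bracket is returned.
    """
    l_min, l_max = bounds

    def rec(l: float) -> float:
        v = value(l)
        if log is not None:
            log.append((float(l), float(v)))
        return v

    if rec(l_min) <= eps:
        return l_min
    if rec(l_max) > eps:
        raise ValueError(
            f"criterion unreachable: value({l_max:g}) > {eps:g}; "
            "enlarge the search interval")
    lo = max(l_min, l_max * _FLOOR_REL)
    if l_min < lo and rec(lo) <= eps:
        # answer hides below the log floor; resolve linearly on [l_min, lo]
        a, b = l_min, lo
        for _ in range(BISECT_MAX_ITER):
            mid = 0.5 * (a + b)
            if rec(mid) <= eps:
                b = mid
            else:
                a = mid
            if b - a <= tol * max(b, 1e-300):
                break
        return b
    a, b = np.log(lo), np.log(l_max)  # value(e^a) > eps >= value(e^b)
    for _ in range(BISECT_MAX_ITER):
        mid = 0.5 * (a + b)
        if rec(float(np.exp(mid))) <= eps:
            b = mid
        else:
            a = mid
        if b - a <= np.log1p(tol):
            break
    return float(np.exp(b))


def _check_monotone(value: Callable[[float], float], bounds: tuple[float, float],
                    n_probe: int = 9, rel_tol: float = 1e-6,
                    ) -> tuple[bool, np.ndarray, np.ndarray]:
    lo = max(bounds[0], bounds[1] * _FLOOR_REL)
    ls = np.geomspace(lo, bounds[1], n_probe)
    vals = np.array([value(l) for l in ls])
    increases = np.diff(vals)
    ok = bool(np.all(increases <= rel_tol * max(vals.max(), 1e-300)))
    return ok, ls, vals


def select_l_nps(f: Image2D, eps: float = DEFAULT_EPS,
                 r_hat: float = DEFAULT_R_HAT,
                 bounds: tuple[float, float] = DEFAULT_BOUNDS,
                 tol: float = BISECT_TOL, *,
                 n_rings: int | None = None, scheme: SplitScheme = "rows",
                 pad: bool = False, check_monotone: bool = True,
                 ) -> SelectionResult:
    """NPS criterion: smallest l with phi(l) <= eps, by bisection.

    phi decays monotonically with l (stronger low-pass filtration leaves less
    high-frequency noise); this is verified on a coarse probe grid and, if
    violated, the selector warns and falls back to a dense-grid scan.
    """
    if not 0.0 < eps < 1.0:
        raise ValueError("eps must lie in (0, 1)")
    value = lambda l: phi_of_l(f, l, r_hat=r_hat, n_rings=n_rings,
                               scheme=scheme, pad=pad)
    iterations: list = []
    diagnostics: dict = {"eps": eps, "r_hat": r_hat, "bounds": list(bounds)}

    monotone = True
    if check_monotone:
        monotone, probe_l, probe_phi = _check_monotone(value, bounds)
        diagnostics["probe_l"] = probe_l
        diagnostics["probe_phi"] = probe_phi
    if not monotone:
        warnings.warn("phi(l) is not monotone on the probe grid; "
                      "falling back to a dense-grid scan")
        grid = LogGrid.make(max(bounds[0], bounds[1] * _FLOOR_REL), bounds[1],
                            512, 8)
        phis = np.array([value(l) for l in grid.l_values])
        feasible = np.nonzero(phis <= eps)[0]
        if len(feasible) == 0:
            raise ValueError("criterion unreachable on the dense grid")
        l_sel = float(grid.l_values[feasible[0]])
        diagnostics["scan_l"] = grid.l_values
        diagnostics["scan_phi"] = phis
    else:
        l_sel = _bisect_smallest_feasible(value, eps, bounds, tol,
                                          log=iterations)
        diagnostics["iterations"] = iterations
    diagnostics["phi_at_selected"] = value(l_sel)
    return SelectionResult(l_sel, "nps", epsilon=eps, r_hat=r_hat,
                           diagnostics=diagnostics)


def fuzzy_interval(f: Image2D, eps: float = DEFAULT_EPS,
                   r_hat: float = DEFAULT_R_HAT, delta_r: float = 0.1,
                   bounds: tuple[float, float] = DEFAULT_BOUNDS,
                   **kwargs) -> tuple[float, float]:
    """Interval of near-optimal parameters [l_{r_hat+delta_r}, l_{r_hat}].

    Raising the cutoff radius relaxes the criterion, so the selection at
    ``r_hat + delta_r`` bounds the selection at ``r_hat`` from below.
    """
    if delta_r < 0 or r_hat + delta_r >= 1.0:
        raise ValueError("require 0 <= delta_r and r_hat + delta_r < 1")
    l_high = select_l_nps(f, eps, r_hat, bounds, **kwargs).l_selected
    if delta_r == 0.0:
        return (l_high, l_high)
    l_low = select_l_nps(f, eps, r_hat + delta_r, bounds, **kwargs).l_selected
    return (min(l_low, l_high), l_high)


def _joint_valid(p1: Image2D, p2: Image2D) -> np.ndarray:
    joint = p1.mask & p2.mask
    if not joint.any():
        raise ValueError("no jointly valid pixels between consecutive filtered frames")
    return joint


def curve_f_std(f: Image2D, grid: LogGrid, *, pad: bool = False) -> np.ndarray:
    """Noise-suppression merit f_i = std(p_{l_i} - p_{l_{i+1}}).

    The step between consecutive frames is the local grid spacing.  The curve
    has length ``n_points - 1`` and is indexed by the left grid point.
    Constants are fixed points of the filter, so a constant frame gives f = 0.
    """
    if grid.n_points < 3:
        raise ValueError("grid needs at least 3 points")
    out = np.empty(grid.n_points - 1)
    p_prev = apply_paganin(f, FilterParams(grid.l_values[0]), pad=pad)
    for i in range(1, grid.n_points):
        p_next = apply_paganin(f, FilterParams(grid.l_values[i]), pad=pad)
        joint = _joint_valid(p_prev, p_next)
        diff = p_prev.values[joint] - p_next.values[joint]
        out[i - 1] = float(np.std(diff))
        p_prev = p_next
    return out


def curve_g_corr(f: Image2D, grid: LogGrid, *, pad: bool = False) -> np.ndarray:
    """Consecutive-frame correlation merit g_i = corr(p_{l_i}, p_{l_{i+1}}).

    Pearson form (mean-centered inner product), insensitive to additive
    offsets.  Two jointly constant frames are perfectly correlated (g = 1); a
    single zero-variance frame against a varying one is undefined and raises.
    """
    if grid.n_points < 3:
        raise ValueError("grid needs at least 3 points")
    out = np.empty(grid.n_points - 1)
    p_prev = apply_paganin(f, FilterParams(grid.l_values[0]), pad=pad)
    for i in range(1, grid.n_points):
        p_next = apply_paganin(f, FilterParams(grid.l_values[i]), pad=pad)
        joint = _joint_valid(p_prev, p_next)
        a = p_prev.values[joint] - p_prev.values[joint].mean()
        b = p_next.values[joint] - p_next.values[joint].mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        scale = max(np.abs(p_prev.values[joint]).max(),
                    np.abs(p_next.values[joint]).max(), 1.0)
        tiny = 1e-12 * scale * np.sqrt(joint.sum())
        if na <= tiny and nb <= tiny:
            out[i - 1] = 1.0  # identical constants: trivially correlated
        elif na <= tiny or nb <= tiny:
            raise ValueError("zero-variance frame: correlation undefined")
        else:
            out[i - 1] = float(a @ b / (na * nb))
        p_prev = p_next
    return out


def _argbest(values: np.ndarray, mode: str) -> int:
    """Index of the extremum; ties broken toward the smallest l."""
    if mode == "max":
        return int(np.argmax(values))
    return int(np.argmin(values))


def _select_from_curve(grid: LogGrid, values: np.ndarray, mode: str,
                       upper: float | None, criterion: str,
                       refine: bool) -> SelectionResult:
    ls = grid.l_values[:len(values)]
    sel = np.ones(len(values), dtype=bool)
    if upper is not None:
        sel &= (ls > 0) & (ls <= upper)
        if not sel.any():
            raise ValueError("no grid points inside (0, upper]")
    idx_local = _argbest(values[sel], mode)
    idx = np.nonzero(sel)[0][idx_local]
    l_sel = float(ls[idx])
    if idx_local in (0, sel.sum() - 1):
        warnings.warn(f"{criterion}: extremum at a grid boundary; "
                      "the extremum may not be bracketed")
    elif refine:
        # 3-point quadratic fit in log(l) around the grid extremum
        x = np.log(ls[idx - 1:idx + 2])
        y = values[idx - 1:idx + 2]
        a, b, _ = np.polyfit(x, y, 2)
        if a != 0:
            x_star = -b / (2 * a)
            if x[0] <= x_star <= x[2]:
                l_sel = float(np.exp(x_star))
    return SelectionResult(
        l_sel, criterion,
        diagnostics={"grid_l": ls, "curve": values,
                     "grid_index": int(idx), "upper": upper})


def select_l_std(f: Image2D, grid: LogGrid | None = None,
                 upper: float | None = None, *, refine: bool = False,
                 pad: bool = False, eps: float = DEFAULT_EPS,
                 r_hat: float = DEFAULT_R_HAT) -> SelectionResult:
    """Maximize the noise-suppression merit f(l) over the grid.

    The search is restricted to (0, upper]; when ``upper`` is omitted it is
    taken from the NPS criterion, which brackets the maximum from above.
    """
    if grid is None:
        grid = LogGrid.make()
    if upper is None:
        upper = select_l_nps(f, eps=eps, r_hat=r_hat,
                             bounds=(0.0, grid.bounds[1]), pad=pad).l_selected
    values = curve_f_std(f, grid, pad=pad)
    return _select_from_curve(grid, values, "max", upper, "std", refine)


def select_l_corr(f: Image2D, grid: LogGrid | None = None, *,
                  refine: bool = False, pad: bool = False) -> SelectionResult:
    """Minimize the consecutive-frame correlation g(l) over the grid."""
    if grid is None:
        grid = LogGrid.make()
    values = curve_g_corr(f, grid, pad=pad)
    return _select_from_curve(grid, values, "min", None, "corr", refine)


def select_l_thickness(f: Image2D, line: int | None = None,
                       bounds: tuple[float, float] = DEFAULT_BOUNDS,
                       tol: float = BISECT_TOL, *, slack: float = 0.0,
                       atol: float = 1e-10, pad: bool = False,
                       ) -> SelectionResult:
    """Thickness-recovery criterion: smallest l with p_l <= slack on a line.

    Non-positive p_l means non-negative recovered thickness -p_l / mu; edge
    overshoot from residual phase contrast keeps the profile positive until
    the filter is strong enough.  ``atol`` absorbs FFT round-off when
    comparing against the slack level (default 0).
    """
    ny = f.shape[0]
    if line is None:
        line = ny // 2
    if not 0 <= line < ny:
        raise ValueError(f"line {line} outside frame of {ny} rows")

    def value(l: float) -> float:
        p = apply_paganin(f, FilterParams(l), pad=pad)
        row_mask = p.mask[line]
        if not row_mask.any():
            return np.inf  # fully invalid profile: infeasible
        return float(p.values[line][row_mask].max())

    iterations: list = []
    l_sel = _bisect_smallest_feasible(value, slack + atol, bounds, tol,
                                      log=iterations)
    return SelectionResult(
        l_sel, "thickness",
        diagnostics={"line": line, "slack": slack, "bounds": list(bounds),
                     "iterations": iterations,
                     "profile_max_at_selected": value(l_sel)})
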