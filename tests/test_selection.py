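"""Parameter selectors: grids, merit curves, bisection, fuzzy interval."""

import numpy as np
import pytest

from paganin_autotune import (FilterParams, Image2D, LogGrid, apply_paganin,
                              curve_f_std, curve_g_corr, fuzzy_interval,
                              phi_of_l, select_l_corr, select_l_nps,
                              select_l_std, select_l_thickness)
from paganin_autotune.phantom import (default_spec, forward_project,
                                      generate_thickness)
from paganin_autotune.selection import _select_from_curve
from conftest import normalized_phantom


class TestLogGrid:
    def test_default_grid_layout(self):
        grid = LogGrid.make()
        assert grid.n_points == 128
        assert grid.n_subintervals == 8
        assert grid.l_values[0] == pytest.approx(1e-2)
        assert grid.l_values[-1] == pytest.approx(1e8)
        assert np.all(np.diff(grid.l_values) > 0)

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            LogGrid.make(1.0, 0.5)
        with pytest.raises(ValueError):
            LogGrid(np.array([1.0, 0.5, 2.0]), 1, (0.5, 2.0))


class TestMeritCurves:
    def test_constant_frame_gives_zero_f(self):
        f = Image2D(np.full((16, 16), 2.0))
        grid = LogGrid.make(1.0, 100.0, 8, 2)
        np.testing.assert_allclose(curve_f_std(f, grid), 0.0, atol=1e-14)

    def test_f_matches_two_filter_subtract_oracle(self, rng):
        f = Image2D(rng.uniform(0.5, 1.5, (8, 8)))
        grid = LogGrid(np.array([1.0, 5.0, 25.0]), 1, (1.0, 25.0))
        got = curve_f_std(f, grid)
        for i in range(2):
            p1 = apply_paganin(f, FilterParams(grid.l_values[i]))
            p2 = apply_paganin(f, FilterParams(grid.l_values[i + 1]))
            expected = np.std(p1.values - p2.values)
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_constant_frame_gives_unit_g(self):
        f = Image2D(np.full((16, 16), 2.0))
        grid = LogGrid.make(1.0, 100.0, 8, 2)
        np.testing.assert_allclose(curve_g_corr(f, grid), 1.0)

    def test_g_bounded_by_one(self, noisy_frame):
        grid = LogGrid.make(1e-1, 1e4, 16, 4)
        g = curve_g_corr(noisy_frame, grid)
        assert np.all(g <= 1.0 + 1e-12)

    def test_f_nonnegative(self, noisy_frame):
        grid = LogGrid.make(1e-1, 1e4, 16, 4)
        assert np.all(curve_f_std(noisy_frame, grid) >= 0)


class TestCurveSelection:
    def test_interior_peak_location_returned(self):
        grid = LogGrid.make(1.0, 1e4, 16, 4)
        values = -np.abs(np.arange(15) - 7.0)  # single interior peak at index 7
        res = _select_from_curve(grid, values, "max", None, "std", False)
        assert res.l_selected == grid.l_values[7]

    def test_upper_restriction_honored(self):
        grid = LogGrid.make(1.0, 1e4, 16, 4)
        values = np.arange(15.0)  # unrestricted argmax at the end
        upper = grid.l_values[5]
        with pytest.warns(UserWarning, match="boundary"):
            res = _select_from_curve(grid, values, "max", upper, "std", False)
        assert res.l_selected <= upper
        assert res.l_selected == grid.l_values[5]

    def test_ties_break_toward_smaller_l(self):
        grid = LogGrid.make(1.0, 1e4, 16, 4)
        values = np.zeros(15)
        with pytest.warns(UserWarning, match="boundary"):
            res = _select_from_curve(grid, values, "max", None, "std", False)
        assert res.l_selected == grid.l_values[0]


class TestSelectNPS:
    def test_nearly_noiseless_frame_returns_lower_bound(self):
        spec = default_spec(0, shape=(64, 64), noiseless=True,
                            l_true=0.0, edge_sigma=10.0)
        from paganin_autotune import make_dataset, normalize_flat
        ds = make_dataset(spec)
        f = normalize_flat(ds.I, ds.I0)
        res = select_l_nps(f, eps=0.05, check_monotone=False)
        assert res.l_selected == 0.0

    def test_bisection_matches_dense_scan(self, noisy_frame):
        res = select_l_nps(noisy_frame, check_monotone=False)
        ls = np.geomspace(1e-4, 1e8, 256)
        phis = np.array([phi_of_l(noisy_frame, l) for l in ls])
        feasible = np.nonzero(phis <= 0.01)[0]
        first = feasible[0]
        assert first > 0, "scan should bracket the transition"
        assert ls[first - 1] * (1 - 2e-3) <= res.l_selected <= ls[first] * (1 + 2e-3)

    def test_deterministic_to_the_bit(self, noisy_frame):
        a = select_l_nps(noisy_frame, check_monotone=False)
        b = select_l_nps(noisy_frame, check_monotone=False)
        assert a.l_selected == b.l_selected

    def test_unreachable_eps_raises(self, noisy_frame):
        with pytest.raises(ValueError, match="unreachable"):
            select_l_nps(noisy_frame, eps=1e-6, bounds=(0.0, 1e-9),
                         check_monotone=False)

    def test_phi_constraint_satisfied_at_selection(self, noisy_frame):
        res = select_l_nps(noisy_frame, check_monotone=False)
        assert res.diagnostics["phi_at_selected"] <= 0.01


class TestFuzzyInterval:
    def test_zero_span_degenerates(self, noisy_frame):
        lo, hi = fuzzy_interval(noisy_frame, delta_r=0.0, check_monotone=False)
        assert lo == hi

    def test_interval_ordered_on_seeded_phantoms(self):
        # raising the cutoff relaxes the criterion: l(r+dr) <= l(r)
        for seed in range(3):
            f = normalized_phantom(seed)
            lo, hi = fuzzy_interval(f, r_hat=0.5, delta_r=0.1,
                                    check_monotone=False)
            assert lo <= hi


class TestSelectStdCorr:
    def test_grid_extrema_match_exhaustive_scan(self, noisy_frame):
        grid = LogGrid.make(1e-2, 1e6, 32, 8)
        res_std = select_l_std(noisy_frame, grid, upper=None,
                               eps=0.01, r_hat=0.5)
        res_corr = select_l_corr(noisy_frame, grid)
        f_curve = curve_f_std(noisy_frame, grid)
        g_curve = curve_g_corr(noisy_frame, grid)
        upper = res_std.diagnostics["upper"]
        sel = grid.l_values[:-1] <= upper
        assert res_std.l_selected == grid.l_values[:-1][sel][np.argmax(f_curve[sel])]
        assert res_corr.l_selected == grid.l_values[np.argmin(g_curve)]

    def test_std_selection_below_nps_selection(self, noisy_frame):
        res_nps = select_l_nps(noisy_frame, check_monotone=False)
        grid = LogGrid.make(1e-2, 1e6, 32, 8)
        res_std = select_l_std(noisy_frame, grid, upper=res_nps.l_selected)
        assert res_std.l_selected <= res_nps.l_selected


class TestSelectThickness:
    def _clean_frame(self, l_true, seed=0):
        spec = default_spec(seed, shape=(64, 64), l_true=l_true, edge_sigma=0.0)
        T = generate_thickness(spec)
        return Image2D(forward_project(T, spec.mu, l_true).values), T, spec.mu

    def test_already_nonpositive_profile_returns_zero(self):
        f, _, _ = self._clean_frame(0.0)  # contact image: f <= 1, p <= 0
        res = select_l_thickness(f)
        assert res.l_selected == 0.0

    def test_recovers_generating_parameter(self):
        f, T, mu = self._clean_frame(100.0)
        res = select_l_thickness(f)
        assert res.l_selected == pytest.approx(100.0, rel=0.01)
        # overshoot persists below l_true and vanishes at l_true
        p_under = apply_paganin(f, FilterParams(90.0))
        assert p_under.values[32][p_under.mask[32]].max() > 1e-6
        p_at = apply_paganin(f, FilterParams(100.0))
        np.testing.assert_array_less(p_at.values[32][p_at.mask[32]],
                                     np.full(p_at.mask[32].sum(), 1e-8))

    def test_invariant_to_starting_bracket(self):
        f, _, _ = self._clean_frame(100.0)
        a = select_l_thickness(f, bounds=(0.0, 1e8)).l_selected
        b = select_l_thickness(f, bounds=(0.0, 1e6)).l_selected
        assert a == pytest.approx(b, rel=5e-3)

    def test_line_out_of_range_rejected(self):
        f, _, _ = self._clean_frame(10.0)
        with pytest.raises(ValueError, match="line"):
            select_l_thickness(f, line=999)
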