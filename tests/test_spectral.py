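"""Split images, ring partitions, FRC, NPS, bound, phi and consistency."""

import numpy as np
import pytest

from paganin_autotune import (FilterParams, Image2D, apply_paganin,
                              check_consistency, frc_curve,
                              lower_bound_curve, make_ring_partition,
                              nps_curve, phi_highfreq, split_image)
from paganin_autotune.spectral import (SpectralCurves, band_mass,
                                       compute_curves, default_bound)


class TestSplitImage:
    def test_rows_scheme_keeps_even_and_odd_rows(self):
        f = Image2D(np.repeat(np.arange(4.0)[:, None], 4, axis=1))
        u, v = split_image(f, "rows")
        np.testing.assert_array_equal(u.values[:, 0], [0, 2])
        np.testing.assert_array_equal(v.values[:, 0], [1, 3])

    @pytest.mark.parametrize("scheme", ["rows", "cols", "checkerboard"])
    def test_constant_frame_gives_identical_halves(self, scheme):
        u, v = split_image(Image2D(np.full((6, 6), 2.5)), scheme)
        np.testing.assert_array_equal(u.values, v.values)

    @pytest.mark.parametrize("scheme", ["rows", "cols", "checkerboard"])
    def test_halves_are_complementary(self, scheme, rng):
        f = Image2D(rng.normal(size=(8, 10)))
        u, v = split_image(f, scheme)
        assert u.shape == v.shape
        pooled = np.sort(np.concatenate([u.values.ravel(), v.values.ravel()]))
        np.testing.assert_array_equal(pooled, np.sort(f.values.ravel()))

    def test_odd_extent_instructs_crop(self):
        with pytest.raises(ValueError, match="crop"):
            split_image(Image2D(np.ones((5, 4))), "rows")

    @pytest.mark.parametrize("scheme", ["rows", "checkerboard"])
    def test_halves_preserve_gaussian_variance(self, scheme):
        # split halves of iid noise keep the source variance (5 SE band)
        n = 32 * 32 // 2
        se = np.sqrt(2.0 / (n - 1))
        for seed in range(100):
            f = Image2D(np.random.default_rng(seed).normal(size=(32, 32)))
            for half in split_image(f, scheme):
                assert abs(half.values.var(ddof=1) - 1.0) < 5 * se


class TestRingPartition:
    def test_partition_covers_grid_minus_dc_and_corners(self):
        part = make_ring_partition((8, 8), 1.0, 4)
        counted = (part.assignment >= 0).sum()
        fy = np.fft.fftfreq(8)
        rho = np.hypot(fy[:, None], fy[None, :])
        inside = (rho > 0) & (rho <= np.abs(fy).max())
        assert counted == inside.sum()
        assert part.ring_counts.sum() == counted  # disjoint rings

    def test_square_grid_symmetries(self):
        part = make_ring_partition((16, 16), 1.0, 8)
        a = part.assignment
        np.testing.assert_array_equal(a, a.T)  # fy <-> fx swap
        # frequency negation k -> -k maps the grid onto itself
        neg = a[(-np.arange(16)) % 16][:, (-np.arange(16)) % 16]
        np.testing.assert_array_equal(a, neg)

    def test_matches_per_sample_binning_loop(self):
        part = make_ring_partition((16, 16), 2.0, 8)
        fy = np.fft.fftfreq(16, d=2.0)
        rho_max = np.abs(fy).max()
        for i in range(16):
            for j in range(16):
                r = np.hypot(fy[i], fy[j]) / rho_max
                if r == 0 or r > 1:
                    expected = -1
                else:
                    expected = min(int(np.ceil(r * 8)) - 1, 7)
                assert part.assignment[i, j] == expected

    def test_too_many_rings_rejected(self):
        with pytest.raises(ValueError):
            make_ring_partition((8, 8), 1.0, 64)


class TestFRC:
    def test_self_correlation_is_one(self, rng):
        u = Image2D(rng.normal(size=(16, 16)))
        part = make_ring_partition(u.shape, 1.0, 8)
        np.testing.assert_allclose(frc_curve(u, u, part), 1.0, atol=1e-12)

    def test_anti_correlation_is_minus_one(self, rng):
        u = Image2D(rng.normal(size=(16, 16)))
        v = Image2D(-u.values)
        part = make_ring_partition(u.shape, 1.0, 8)
        np.testing.assert_allclose(frc_curve(u, v, part), -1.0, atol=1e-12)

    def test_matches_explicit_ring_sum_oracle(self, rng):
        u = Image2D(rng.normal(size=(8, 8)))
        v = Image2D(rng.normal(size=(8, 8)))
        part = make_ring_partition((8, 8), 1.0, 4)
        got = frc_curve(u, v, part)
        Fu, Fv = np.fft.fft2(u.values), np.fft.fft2(v.values)
        for k in range(4):
            cross = nu = nv = 0.0
            for i in range(8):
                for j in range(8):
                    if part.assignment[i, j] == k:
                        cross += (Fu[i, j] * np.conj(Fv[i, j])).real
                        nu += abs(Fu[i, j]) ** 2
                        nv += abs(Fv[i, j]) ** 2
            assert got[k] == pytest.approx(cross / np.sqrt(nu * nv), abs=1e-12)

    def test_bounded_by_cauchy_schwarz(self, rng):
        for _ in range(10):
            u = Image2D(rng.normal(size=(16, 16)))
            v = Image2D(rng.normal(size=(16, 16)))
            part = make_ring_partition((16, 16), 1.0, 8)
            c = frc_curve(u, v, part)
            assert np.all(np.abs(c) <= 1 + 1e-12)


class TestNPS:
    def test_zero_noise_gives_zero_power(self):
        part = make_ring_partition((16, 16), 1.0, 8)
        w = nps_curve(Image2D(np.zeros((16, 16))), part)
        np.testing.assert_array_equal(w, 0.0)

    def test_parseval_identity(self, rng):
        n = Image2D(rng.normal(size=(32, 32)), pixel_size=0.5)
        part = make_ring_partition(n.shape, 0.5, 16)
        w = nps_curve(n, part)
        ring_power = (part.ring_counts * w).sum() / n.area
        Fhat = np.fft.fft2(n.values) / n.values.size
        out_of_band = (np.abs(Fhat) ** 2)[part.assignment < 0].sum()
        total = np.mean(n.values ** 2)
        assert ring_power + out_of_band == pytest.approx(total, rel=1e-10)


class TestLowerBound:
    @pytest.mark.parametrize("m, M, expected", [
        (0.7, 0.7, 1.0),   # all magnitudes equal
        (0.0, 1.3, 0.0),   # a vanishing coefficient
        (1.0, 2.0, 0.8),
    ])
    def test_default_bound_form(self, m, M, expected):
        assert default_bound(m, M) == pytest.approx(expected)

    def test_curve_in_unit_interval_and_pluggable(self, rng):
        u = Image2D(rng.normal(size=(16, 16)))
        v = Image2D(rng.normal(size=(16, 16)))
        part = make_ring_partition((16, 16), 1.0, 8)
        b = lower_bound_curve(u, v, part)
        assert np.all((b >= 0) & (b <= 1))
        b_const = lower_bound_curve(u, v, part, bound_fn=lambda m, M: 0.25)
        np.testing.assert_array_equal(b_const, 0.25)


class TestPhiHighfreq:
    def _curves(self, nps, counts):
        n = len(nps)
        r = (np.arange(n) + 0.5) / n
        return SpectralCurves(r, np.ones(n), np.asarray(nps, float),
                              np.zeros(n), np.asarray(counts))

    def test_zero_above_cutoff(self):
        curves = self._curves([1, 1, 0, 0], [4, 8, 12, 16])
        assert phi_highfreq(curves, 0.5) == 0.0

    def test_flat_spectrum_gives_mass_fraction(self):
        counts = np.array([4, 8, 12, 16])
        curves = self._curves([2.0] * 4, counts)
        assert phi_highfreq(curves, 0.5) == pytest.approx(
            counts[2:].sum() / counts.sum())

    def test_matches_two_pass_summation_oracle(self, rng):
        noise = Image2D(rng.normal(size=(32, 32)))
        part = make_ring_partition(noise.shape, 1.0, 16)
        w = nps_curve(noise, part)
        curves = self._curves(w, part.ring_counts)
        got = phi_highfreq(curves, 0.5)
        hi = total = 0.0
        for k in range(16):
            mass = part.ring_counts[k] * w[k]
            total += mass
            if (k + 0.5) / 16 > 0.5:
                hi += mass
        assert got == pytest.approx(hi / total, abs=1e-12)

    def test_zero_total_power_returns_zero(self):
        curves = self._curves([0.0] * 4, [1, 2, 3, 4])
        assert phi_highfreq(curves, 0.5) == 0.0


class TestConsistency:
    def test_identical_halves_fully_consistent(self, rng):
        u = Image2D(rng.normal(size=(16, 16)))
        part = make_ring_partition(u.shape, 1.0, 8)
        curves = compute_curves(u, u, part)
        ok, frac = check_consistency(curves)
        assert frac == 1.0 and ok.all()

    def test_forced_violation_flagged(self, rng):
        u = Image2D(rng.normal(size=(16, 16)))
        v = Image2D(rng.normal(size=(16, 16)))
        part = make_ring_partition(u.shape, 1.0, 8)
        curves = compute_curves(u, v, part)
        curves.bound = np.ones_like(curves.bound)  # impossible bound
        ok, frac = check_consistency(curves)
        assert frac < 1.0


def test_high_band_mass_and_phi_decrease_with_filtering(noisy_frame):
    """Stronger low-pass filtering leaves less high-frequency noise mass."""
    masses, phis = [], []
    part = None
    for l in np.geomspace(1e-1, 1e5, 8):
        p = apply_paganin(noisy_frame, FilterParams(l))
        u, v = split_image(p)
        if part is None:
            part = make_ring_partition(u.shape, u.pixel_size, 16)
        curves = compute_curves(u, v, part)
        masses.append(band_mass(curves.nps, curves.ring_counts)[curves.r > 0.5].sum())
        phis.append(phi_highfreq(curves, 0.5))
    masses, phis = np.array(masses), np.array(phis)
    assert np.all(np.diff(masses) <= 1e-9 * masses[0])
    assert np.all(np.diff(phis) <= 1e-9)
    assert np.all((phis >= 0) & (phis <= 1))
    assert phis[-1] < 1e-3  # phi collapses under strong filtering
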