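"""Axial circular statistics: doubling, PI, Rayleigh test, ellipse fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0, i1

from conftest import circular_axial_diff_deg
from ecshear.orientation import (EmptySampleError, angular_histogram, axial_summary,
                                 circular_mean_resultant, double_angles,
                                 fit_region_ellipse, rayleigh_test)
from ecshear.synth import sample_axial_angles


class TestDoubling:
    def test_worked_values(self):
        assert double_angles([45.0])[0] == 90.0
        assert double_angles([179.5])[0] == 359.0

    def test_axial_identification(self):
        # 190 deg is the same axis as 10 deg
        assert double_angles([10.0])[0] == double_angles([190.0])[0]


class TestMeanResultant:
    def test_constant_sample(self):
        mean, r = circular_mean_resultant([73.0] * 5)
        assert r == pytest.approx(1.0)
        assert mean == pytest.approx(73.0)

    def test_antipodal_cancellation(self):
        _, r = circular_mean_resultant([0.0, 180.0])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_two_one_split(self):
        mean, r = circular_mean_resultant([0.0, 0.0, 180.0])
        assert r == pytest.approx(1.0 / 3.0)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(EmptySampleError):
            circular_mean_resultant([])


class TestAxialSummary:
    def test_constant(self):
        s = axial_summary([45.0, 45.0, 45.0])
        assert s.polarity_index == pytest.approx(1.0)
        assert s.mean_direction_deg == pytest.approx(45.0)

    def test_perpendicular_pair_cancels(self):
        s = axial_summary([0.0, 90.0])
        assert s.polarity_index == pytest.approx(0.0, abs=1e-12)

    def test_two_one_split(self):
        s = axial_summary([0.0, 0.0, 90.0])
        assert s.polarity_index == pytest.approx(1.0 / 3.0)
        assert s.mean_direction_deg == pytest.approx(0.0, abs=1e-9)

    @given(st.lists(st.floats(0, 179.999), min_size=2, max_size=30),
           st.floats(-360, 360))
    @settings(max_examples=50, deadline=None)
    def test_rotation_equivariance(self, angles, delta):
        base = axial_summary(angles)
        rotated = axial_summary((np.asarray(angles) + delta) % 180.0)
        assert rotated.polarity_index == pytest.approx(base.polarity_index, abs=1e-9)
        if base.polarity_index > 1e-6:
            d = circular_axial_diff_deg(rotated.mean_direction_deg,
                                        (base.mean_direction_deg + delta) % 180.0)
            assert d < 1e-6

    def test_pi_bounds(self, rng):
        for _ in range(20):
            s = axial_summary(rng.uniform(0, 180, size=rng.integers(1, 40)))
            assert 0.0 <= s.polarity_index <= 1.0

    def test_null_calibration(self, rng):
        # uniform axial samples: E[PI] is O(1/sqrt(N))
        n, reps = 1000, 500
        theta = rng.uniform(0, 2 * np.pi, size=(reps, n))
        r = np.hypot(np.cos(theta).mean(axis=1), np.sin(theta).mean(axis=1))
        assert r.mean() < 0.05

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_parameter_recovery_vs_bessel_ratio(self, kappa):
        n = 100_000
        angles = sample_axial_angles(n, mean_deg=30.0, kappa=kappa, seed=int(kappa * 10))
        pi = axial_summary(angles).polarity_index
        rho = float(i1(kappa) / i0(kappa))
        alpha2 = float((i0(kappa) - 2 * i1(kappa) / kappa) / i0(kappa))  # I2/I0
        se = np.sqrt(max(1.0 + alpha2 - 2 * rho ** 2, 0.0) / (2 * n))
        assert abs(pi - rho) <= 2 * se + np.sqrt(np.pi / (4 * n))


class TestRayleigh:
    def test_uniformly_spaced_angles_not_rejected(self):
        p = rayleigh_test(np.linspace(0, 360, 36, endpoint=False))
        assert p > 0.9

    def test_concentrated_sample_rejected(self):
        angles = double_angles(sample_axial_angles(100, 0.0, 2.0, seed=3))
        assert rayleigh_test(angles) < 1e-6

    def test_matches_permutation_oracle(self, rng):
        # moderate concentration, N = 20, against a Monte-Carlo null
        n = 20
        obs = np.degrees(rng.vonmises(0.0, 1.0, size=n))
        _, r_obs = circular_mean_resultant(obs)
        sims = rng.uniform(0, 2 * np.pi, size=(100_000, n))
        r_null = np.hypot(np.cos(sims).mean(axis=1), np.sin(sims).mean(axis=1))
        p_mc = np.mean(r_null >= r_obs)
        p_formula = rayleigh_test(obs)
        assert p_formula == pytest.approx(p_mc, rel=0.10, abs=2e-3)


class TestEllipseFit:
    def test_axis_aligned_rectangle(self):
        mask = np.zeros((30, 40), bool)
        mask[10:20, 5:25] = True  # 20 wide (cols) x 10 tall
        shape = fit_region_ellipse(mask)
        assert shape.orientation_deg == pytest.approx(0.0, abs=1e-9)
        shape_t = fit_region_ellipse(mask.T)
        assert shape_t.orientation_deg == pytest.approx(90.0, abs=1e-9)
        assert shape.major_axis_length > shape.minor_axis_length

    @pytest.mark.parametrize("angle", [15.0, 30.0, 75.0, 120.0])
    def test_render_and_refit_rotated_ellipse(self, angle):
        rr, cc = np.meshgrid(np.arange(80), np.arange(80), indexing="ij")
        dx, dy = cc - 40.0, -(rr - 40.0)
        a = np.radians(angle)
        u = dx * np.cos(a) + dy * np.sin(a)
        v = -dx * np.sin(a) + dy * np.cos(a)
        mask = (u / 25.0) ** 2 + (v / 10.0) ** 2 <= 1.0
        shape = fit_region_ellipse(mask)
        assert circular_axial_diff_deg(shape.orientation_deg, angle) < 1.0
        assert shape.major_axis_length == pytest.approx(50.0, rel=0.03)

    def test_translation_invariance(self):
        mask = np.zeros((60, 60), bool)
        mask[5:15, 5:30] = True
        shifted = np.roll(np.roll(mask, 20, axis=0), 15, axis=1)
        s1, s2 = fit_region_ellipse(mask), fit_region_ellipse(shifted)
        assert s1.orientation_deg == pytest.approx(s2.orientation_deg)
        assert s1.major_axis_length == pytest.approx(s2.major_axis_length)

    def test_degenerate_objects_flagged(self):
        single = np.zeros((5, 5), bool)
        single[2, 2] = True
        assert not fit_region_ellipse(single).orientation_defined
        rr, cc = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15 ** 2
        assert not fit_region_ellipse(disk).orientation_defined


class TestHistogram:
    def test_counts_conserved(self, rng):
        angles = rng.uniform(0, 180, size=12)
        _, counts = angular_histogram(angles, n_bins=9, axial=True)
        assert counts.sum() == 12

    def test_empty_sample_all_zero(self):
        _, counts = angular_histogram([], n_bins=8, axial=False)
        assert counts.sum() == 0

    def test_uniform_grid_fills_evenly(self):
        angles = np.linspace(-180, 180, 360, endpoint=False) + 0.5
        edges, counts = angular_histogram(angles, n_bins=36, axial=False)
        assert np.all(counts == 10)
        assert edges[0] == -180.0 and edges[-1] == 180.0

    def test_axial_range(self):
        edges, counts = angular_histogram([0.0, 90.0, 179.9, 180.0], n_bins=4, axial=True)
        assert edges[0] == 0.0 and edges[-1] == 180.0
        assert counts.sum() == 4
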