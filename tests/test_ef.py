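"""Ellipsoid factor: axis formula, medial seeding, inscribed-ellipsoid fits, EF maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trabgeo import (
    EllipsoidFit,
    VoxelImage,
    compute_ef_map,
    ef_from_axes,
    fit_max_ellipsoid,
    make_cylinder,
    make_lattice,
    make_plate,
    make_sphere,
    medial_seeds,
)
from trabgeo.ef import ellipsoid_factor


class TestEfFromAxes:
    def test_sphere_is_zero(self):
        assert ef_from_axes(1, 1, 1) == 0.0

    def test_prolate_rod(self):
        assert ef_from_axes(5, 5, 50) == pytest.approx(0.9)

    def test_oblate_plate(self):
        assert ef_from_axes(5, 50, 50) == pytest.approx(-0.9)

    @given(st.floats(0.05, 1.0), st.floats(0.5, 100.0))
    def test_q_class_is_zero(self, q, c):
        assert ef_from_axes(q * q * c, q * c, c) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            ef_from_axes(3, 2, 1)
        with pytest.raises(ValueError):
            ef_from_axes(0, 1, 2)

    @given(
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
        st.floats(0.1, 10.0),
    )
    def test_bounded_in_unit_interval(self, a, b, c):
        lo, mid, hi = sorted([a, b, c])
        assert -1.0 <= ef_from_axes(lo, mid, hi) <= 1.0


class TestEllipsoidFit:
    def test_axes_sorted_and_orientation_proper(self):
        fit = EllipsoidFit(
            center=[0, 0, 0],
            semi_axes=(5.0, 1.0, 3.0),
            orientation=np.eye(3),
        )
        assert fit.semi_axes == (1.0, 3.0, 5.0)
        assert np.linalg.det(fit.orientation) == pytest.approx(1.0)
        # axis directions permuted with the radii: the 5-axis was x
        assert abs(fit.orientation[0, 2]) == pytest.approx(1.0)

    def test_contains(self):
        fit = EllipsoidFit(center=[0, 0, 0], semi_axes=(1, 2, 3), orientation=np.eye(3))
        inside = fit.contains(np.array([[0.5, 0, 0], [0, 0, 2.9], [0, 2.1, 0]]))
        np.testing.assert_array_equal(inside, [True, True, False])


class TestMedialSeeds:
    def test_ball_seeds_at_center(self):
        img = make_sphere(15, (41, 41, 41))
        seeds = medial_seeds(img)
        assert np.abs(seeds - 20.0).max() <= 2.0

    def test_cylinder_seeds_on_axis(self):
        img = make_cylinder(5, (100, 40, 40), axis=0)
        seeds = medial_seeds(img, max_seeds=200)
        perp = np.sqrt((seeds[:, 1] - 19.5) ** 2 + (seeds[:, 2] - 19.5) ** 2)
        assert perp.max() <= 1.5

    def test_max_seeds_subsample_deterministic(self):
        img = make_cylinder(5, (100, 40, 40), axis=0)
        a = medial_seeds(img, max_seeds=10, seed=4)
        b = medial_seeds(img, max_seeds=10, seed=4)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 10

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            medial_seeds(VoxelImage(np.zeros((8, 8, 8), np.uint8)))


class TestFitMaxEllipsoid:
    def test_ball_recovered(self):
        img = make_sphere(20, (60, 60, 60))
        fit = fit_max_ellipsoid(img, [29.0, 29.0, 29.0], rng=1)
        assert all(abs(ax - 20.0) <= 1.0 for ax in fit.semi_axes)
        assert abs(fit.ef) <= 0.1

    def test_cylinder_prolate(self):
        img = make_cylinder(5, (100, 40, 40), axis=0)
        fit = fit_max_ellipsoid(img, [50.0, 19.0, 19.0], rng=1)
        a, b, c = fit.semi_axes
        assert abs(a - 5.0) <= 1.0 and abs(b - 5.0) <= 1.0
        assert fit.ef == pytest.approx(0.9, abs=0.1)

    def test_slab_oblate(self):
        img = make_plate(10, (40, 120, 120), normal_axis=0)
        fit = fit_max_ellipsoid(img, [20.0, 60.0, 60.0], rng=1)
        assert abs(fit.semi_axes[0] - 5.0) <= 1.0
        assert fit.ef <= -0.5

    def test_deterministic_for_seed(self):
        img = make_sphere(10, (30, 30, 30))
        f1 = fit_max_ellipsoid(img, [14.0, 14.0, 14.0], rng=7)
        f2 = fit_max_ellipsoid(img, [14.0, 14.0, 14.0], rng=7)
        assert f1.semi_axes == f2.semi_axes
        np.testing.assert_array_equal(f1.center, f2.center)

    def test_background_seed_rejected(self):
        img = make_sphere(10, (30, 30, 30))
        with pytest.raises(ValueError, match="foreground"):
            fit_max_ellipsoid(img, [0.0, 0.0, 0.0], rng=1)


class TestEfMap:
    def test_single_ball_fit_covers_ball_phantom(self):
        img = make_sphere(20, (60, 60, 60))
        fit = EllipsoidFit(center=[29.5, 29.5, 29.5], semi_axes=(20.0, 20.0, 20.0),
                           orientation=np.eye(3))
        ef_map = compute_ef_map(img, [fit])
        assert ef_map.coverage > 0.9
        assert ef_map.mean_ef == pytest.approx(fit.ef, abs=0.1)

    def test_largest_volume_wins(self):
        img = make_sphere(10, (40, 40, 40))
        small = EllipsoidFit(center=[19.5] * 3, semi_axes=(5, 5, 5), orientation=np.eye(3))
        big_prolate = EllipsoidFit(center=[19.5] * 3, semi_axes=(6, 6, 9), orientation=np.eye(3))
        ef_map = compute_ef_map(img, [small, big_prolate])
        # voxels inside both take the larger (prolate) ellipsoid's EF
        inner = ef_map.values[19, 19, 19]
        assert inner == pytest.approx(big_prolate.ef)

    def test_values_within_unit_interval(self, lattice_mixed):
        ef_map, fits = ellipsoid_factor(lattice_mixed, max_seeds=30, rng_seed=2)
        vals = ef_map.values[np.isfinite(ef_map.values)]
        assert vals.min() >= -1.0 and vals.max() <= 1.0
        assert all(-1.0 <= f.ef <= 1.0 for f in fits)

    def test_no_fits_rejected(self):
        img = make_sphere(5, (16, 16, 16))
        with pytest.raises(ValueError):
            compute_ef_map(img, [])


class TestMeanEfDirections:
    def test_rod_lattice_positive_plate_lattice_negative(self):
        rods = make_lattice(rod_radius=6, plate_thickness=0, cell_spacing=24, dims=(72, 72, 72))
        plates = make_lattice(rod_radius=0, plate_thickness=8, cell_spacing=24, dims=(72, 72, 72))
        ef_rods, _ = ellipsoid_factor(rods, max_seeds=60, rng_seed=1)
        ef_plates, _ = ellipsoid_factor(plates, max_seeds=60, rng_seed=1)
        assert ef_rods.mean_ef > 0.3
        assert ef_plates.mean_ef < -0.3

    def test_invariant_to_translation_and_right_angle_rotation(self, lattice_mixed):
        base, _ = ellipsoid_factor(lattice_mixed, max_seeds=150, rng_seed=5)
        rot = VoxelImage(np.rot90(lattice_mixed.data, axes=(0, 2)).copy(), 1.0)
        rotated, _ = ellipsoid_factor(rot, max_seeds=150, rng_seed=5)
        shifted_data = np.zeros((78, 72, 72), np.uint8)
        shifted_data[4:76] = lattice_mixed.data
        shifted, _ = ellipsoid_factor(VoxelImage(shifted_data, 1.0), max_seeds=150, rng_seed=5)
        assert abs(base.mean_ef - rotated.mean_ef) <= 0.05
        assert abs(base.mean_ef - shifted.mean_ef) <= 0.05
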