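"""Structure model index: dilation, per-triangle decomposition, classification."""

import numpy as np
import pytest
import trimesh

from trabgeo import (
    TriangleMesh,
    classify_and_color,
    compute_smi,
    dilate_mesh,
    export_colored_mesh,
    make_cylinder,
    make_lattice,
    make_sphere,
    marching_cubes,
    mesh_area,
    triangle_deltas,
)
from trabgeo.smi import CONCAVE, CONVEX, FLAT
from .conftest import VALIDATION_MESH


def icosphere(radius=10.0, subdivisions=3):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(s.vertices), np.asarray(s.faces))


def torus_mesh(R=1.5, rho=1.0, n_t=160, n_p=240):
    """Parametric torus with near-square elements and exact wrap topology."""
    th = np.arange(n_t) * 2 * np.pi / n_t
    ph = np.arange(n_p) * 2 * np.pi / n_p
    T, P = np.meshgrid(th, ph, indexing="ij")
    x = (R + rho * np.cos(T)) * np.cos(P)
    y = (R + rho * np.cos(T)) * np.sin(P)
    z = rho * np.sin(T)
    V = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    ii, jj = np.meshgrid(np.arange(n_t), np.arange(n_p), indexing="ij")
    idx = lambda i, j: (i % n_t) * n_p + (j % n_p)
    a, b, c, d = (idx(ii, jj).ravel(), idx(ii + 1, jj).ravel(),
                  idx(ii + 1, jj + 1).ravel(), idx(ii, jj + 1).ravel())
    F = np.concatenate([np.column_stack([a, b, c]), np.column_stack([a, c, d])])
    mesh = TriangleMesh(V, F)
    from trabgeo.meshing import _signed_volume
    return mesh if _signed_volume(mesh) > 0 else mesh.flipped()


class TestDilateMesh:
    def test_flat_sheet_translates_without_area_change(self, plate8):
        mesh = marching_cubes(plate8, boundary="open", **VALIDATION_MESH)
        dilated = dilate_mesh(mesh, 0.5)
        np.testing.assert_allclose(dilated.face_areas(), mesh.face_areas(), rtol=1e-12)

    def test_sphere_offset_area_ratio(self):
        mesh = icosphere(radius=10.0)
        r = 0.5
        dilated = dilate_mesh(mesh, r)
        R_eff = np.sqrt(mesh_area(mesh) / (4 * np.pi))
        expected = ((R_eff + r) / R_eff) ** 2
        assert mesh_area(dilated) / mesh_area(mesh) == pytest.approx(expected, rel=0.005)

    def test_nonpositive_r_rejected(self):
        mesh = icosphere()
        with pytest.raises(ValueError):
            dilate_mesh(mesh, 0.0)


class TestTriangleDeltas:
    def test_identical_meshes_zero_delta(self):
        mesh = icosphere()
        d = triangle_deltas(mesh, mesh)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_convex_body_all_positive(self):
        mesh = icosphere()
        d = triangle_deltas(mesh, dilate_mesh(mesh, 0.01))
        assert (d.delta > 0).all()

    def test_sum_of_deltas_equals_total_area_change(self):
        mesh = torus_mesh()
        dil = dilate_mesh(mesh, 1e-3)
        d = triangle_deltas(mesh, dil)
        assert d.delta.sum() == pytest.approx(mesh_area(dil) - mesh_area(mesh), rel=1e-9)

    def test_face_list_mismatch_rejected(self):
        a, b = icosphere(subdivisions=1), icosphere(subdivisions=2)
        with pytest.raises(ValueError):
            triangle_deltas(a, b)

    def test_torus_concave_fraction_matches_analytic_integral(self):
        """Negative mean curvature covers the inner-tube band cos(theta) < -R/(2 rho);
        the area-weighted fraction follows from a 1-D integral over the tube angle."""
        R, rho = 1.5, 1.0
        mesh = torus_mesh(R, rho)
        d = triangle_deltas(mesh, dilate_mesh(mesh, 1e-4))
        A = d.original_area
        measured = A[d.delta < 0].sum() / A.sum()
        th = np.linspace(0, 2 * np.pi, 400001)
        w = R + rho * np.cos(th)
        analytic = np.trapezoid(w * (np.cos(th) < -R / (2 * rho)), th) / np.trapezoid(w, th)
        assert measured == pytest.approx(analytic, rel=0.02)


class TestComputeSMI:
    def test_partition_identity_on_every_phantom(self, sphere20, cylinder10, lattice_mixed, pseudo_small):
        for img, kwargs in [
            (sphere20, dict(**VALIDATION_MESH)),
            (cylinder10, dict(boundary="open", **VALIDATION_MESH)),
            (lattice_mixed, {}),
            (pseudo_small, {}),
        ]:
            res = compute_smi(img, **kwargs)
            assert res.smi_plus + res.smi_minus == pytest.approx(res.smi, rel=1e-9)
            assert res.smi_plus >= 0 >= res.smi_minus
            assert 0 <= res.cf <= 1

    def test_convex_body_purity_sphere(self, sphere40):
        """A sufficiently smoothed convex surface has essentially no shrinking triangles."""
        res = compute_smi(sphere40, resample_factor=3, smoothing=0.5, smoothing_iterations=3)
        assert abs(res.smi_minus) < 0.01
        assert res.cf < 0.01

    def test_cf_zero_iff_no_negative_component(self, plate8):
        res = compute_smi(plate8, boundary="open", **VALIDATION_MESH)
        assert res.cf == 0.0
        assert res.smi_minus == 0.0

    def test_r_robustness(self, sphere40, cylinder10):
        for img, kw in [(sphere40, {}), (cylinder10, dict(boundary="open"))]:
            a = compute_smi(img, r=0.005, **VALIDATION_MESH, **kw).smi
            b = compute_smi(img, r=0.0025, **VALIDATION_MESH, **kw).smi
            assert abs(a - b) < 0.01

    def test_resolution_convergence(self):
        errs = []
        for radius, dims in [(10, (28, 28, 28)), (20, (52, 52, 52)), (40, (100, 100, 100))]:
            res = compute_smi(make_sphere(radius, dims))  # default protocol
            errs.append(abs(res.smi - 4.0))
        assert errs[0] > errs[1] > errs[2]

    def test_scale_invariance(self):
        a = compute_smi(make_sphere(20, (52, 52, 52), spacing=1.0), **VALIDATION_MESH).smi
        b = compute_smi(make_sphere(20, (52, 52, 52), spacing=7.66), **VALIDATION_MESH).smi
        assert a == pytest.approx(b, abs=1e-6)

    def test_lattice_junctions_raise_cf_rods_alone_do_not(self):
        mixed = make_lattice(rod_radius=5, plate_thickness=6, cell_spacing=24, dims=(72, 72, 72))
        rods = make_lattice(rod_radius=5, plate_thickness=0, cell_spacing=24, dims=(72, 72, 72))
        cf_mixed = compute_smi(mixed, **VALIDATION_MESH).cf
        cf_rods = compute_smi(rods, boundary="open", **VALIDATION_MESH).cf
        assert cf_mixed > 0.1
        assert cf_rods < 0.05

    def test_non_binary_input_rejected(self):
        import trabgeo

        img = trabgeo.VoxelImage(np.full((8, 8, 8), 100, np.uint8))
        with pytest.raises(ValueError, match="binary"):
            compute_smi(img)

    def test_mesh_volume_mode_close_to_voxel_mode(self, sphere40):
        a = compute_smi(sphere40, resample_factor=1, smoothing=0.0, volume_mode="voxel").smi
        b = compute_smi(sphere40, resample_factor=1, smoothing=0.0, volume_mode="mesh").smi
        assert a == pytest.approx(b, rel=0.02)


class TestClassifyAndColor:
    def test_convex_sphere_all_yellow(self):
        mesh = icosphere()
        d = triangle_deltas(mesh, dilate_mesh(mesh, 0.01))
        classes, colors = classify_and_color(d, r=0.01)
        assert (classes == CONVEX).all()
        assert (colors[:, 2] < 255).all()  # yellow = blue channel pulled down

    def test_open_plate_all_white(self, plate8):
        mesh = marching_cubes(plate8, boundary="open", **VALIDATION_MESH)
        d = triangle_deltas(mesh, dilate_mesh(mesh, 0.005))
        classes, colors = classify_and_color(d, r=0.005)
        assert (classes == FLAT).all()
        np.testing.assert_array_equal(colors, 255)

    def test_classes_match_sign_oracle_on_lattice(self, lattice_mixed):
        _, mesh, deltas = compute_smi(lattice_mixed, **VALIDATION_MESH, return_mesh=True)
        eps = 1e-6
        classes, _ = classify_and_color(deltas, r=0.005, epsilon_flat=eps)
        rel = deltas.delta / (0.005 * deltas.original_area)
        assert ((classes == CONCAVE) == (rel < -eps)).all()
        assert ((classes == CONVEX) == (rel > eps)).all()
        assert (classes == CONCAVE).sum() > 0  # junctions exist
        assert (classes == CONVEX).sum() > 0  # rod shafts exist


class TestColoredExport:
    def test_roundtrip_face_colors(self, tmp_path):
        mesh = icosphere(subdivisions=1)
        d = triangle_deltas(mesh, dilate_mesh(mesh, 0.01))
        _, colors = classify_and_color(d, r=0.01)
        path = tmp_path / "colored.ply"
        export_colored_mesh(mesh, colors, str(path))
        back = trimesh.load(str(path), process=False)
        np.testing.assert_array_equal(np.asarray(back.visual.face_colors[:, :3]), colors)

    def test_ascii_and_binary_identical(self, tmp_path):
        mesh = icosphere(subdivisions=1)
        d = triangle_deltas(mesh, dilate_mesh(mesh, 0.01))
        _, colors = classify_and_color(d, r=0.01)
        p_bin, p_asc = tmp_path / "b.ply", tmp_path / "a.ply"
        export_colored_mesh(mesh, colors, str(p_bin), encoding="binary")
        export_colored_mesh(mesh, colors, str(p_asc), encoding="ascii")
        mb = trimesh.load(str(p_bin), process=False)
        ma = trimesh.load(str(p_asc), process=False)
        np.testing.assert_array_equal(
            np.asarray(mb.visual.face_colors)[:, :3], np.asarray(ma.visual.face_colors)[:, :3]
        )
        np.testing.assert_allclose(np.asarray(mb.vertices), np.asarray(ma.vertices), atol=1e-6)

    def test_empty_mesh_rejected(self, tmp_path):
        mesh = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            export_colored_mesh(mesh, np.zeros((0, 3), np.uint8), str(tmp_path / "x.ply"))
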