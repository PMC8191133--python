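"""Mesh construction, Laplace-Beltrami discretization and geodesics."""

import numpy as np
import pytest

from hydrapattern.geometry import (MeshError, _cotangent_laplacian,
                                   build_spheroid_mesh, export_mesh,
                                   geodesic_separation, write_vtk)


class TestSpheroidConstruction:
    def test_icosahedron_base(self):
        mesh = build_spheroid_mesh(0, 0.0)
        assert mesh.n_vertices == 12
        assert mesh.n_faces == 20
        # closed genus-0 surface: V - E + F = 2
        edges = 3 * mesh.n_faces // 2
        assert mesh.n_vertices - edges + mesh.n_faces == 2

    def test_displacement_stretch_extents(self):
        mesh = build_spheroid_mesh(2, 4.0)
        assert abs(np.abs(mesh.vertices[:, 2]).max() - 5.0) < 1e-9
        r = np.hypot(mesh.vertices[:, 0], mesh.vertices[:, 1])
        assert abs(r.max() - 1.0) < 1e-9

    def test_icosphere_counts(self):
        mesh = build_spheroid_mesh(4, 4.0)
        assert mesh.n_vertices == 2562
        assert mesh.n_faces == 5120

    def test_sphere_coords_unit_norm(self, sphere_l3):
        norms = np.linalg.norm(sphere_l3.sphere_coords, axis=1)
        assert np.abs(norms - 1.0).max() < 1e-12

    def test_vertex_areas_positive_and_consistent(self, spheroid_l2):
        areas = spheroid_l2.vertex_areas
        assert np.all(areas > 0)
        # lumped areas must total the surface triangle area
        v, f = spheroid_l2.vertices, spheroid_l2.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        total = 0.5 * np.linalg.norm(cross, axis=1).sum()
        assert abs(areas.sum() - total) / total < 1e-9

    def test_negative_stretch_rejected(self):
        with pytest.raises(ValueError):
            build_spheroid_mesh(1, -1.0)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            build_spheroid_mesh(-1, 1.0)

    @pytest.mark.parametrize("stretch", [0.1, 1.0, 4.0, 10.0])
    def test_deformation_preserves_manifoldness(self, stretch):
        # construction itself validates edge sharing and Euler characteristic
        mesh = build_spheroid_mesh(1, stretch)
        assert np.all(mesh.vertex_areas > 0)

    def test_degenerate_triangle_reported_with_index(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        faces = np.array([[0, 1, 2], [0, 1, 3]])  # face 0 is collinear
        with pytest.raises(MeshError, match=r"\[0\]"):
            _cotangent_laplacian(verts, faces)


class TestLaplaceBeltrami:
    def test_annihilates_constants(self, spheroid_l2):
        ones = np.ones(spheroid_l2.n_vertices)
        assert np.abs(spheroid_l2.lb_operator @ ones).max() < 1e-10

    def test_zero_row_sums(self, sphere_l3):
        rs = np.asarray(sphere_l3.lb_operator.sum(axis=1)).ravel()
        assert np.abs(rs).max() < 1e-10

    def test_weak_form_symmetric_negative_semidefinite(self, sphere_l2):
        lap = sphere_l2.lb_weak.toarray()
        assert np.abs(lap - lap.T).max() < 1e-12
        eigvals = np.linalg.eigvalsh(lap)
        assert eigvals.max() < 1e-10

    @pytest.mark.parametrize("degree,expected", [(1, -2.0), (2, -6.0)])
    def test_spherical_harmonic_eigenfunctions(self, sphere_l4, degree,
                                               expected):
        s = sphere_l4.sphere_coords
        f = s[:, 2] if degree == 1 else s[:, 0] * s[:, 1]
        lf = sphere_l4.lb_operator @ f
        err = np.linalg.norm(lf - expected * f) / np.linalg.norm(expected * f)
        assert err < 0.05

    def test_eigenvalue_error_decreases_with_refinement(self, sphere_l2,
                                                        sphere_l3, sphere_l4):
        def residual_error(mesh, degree):
            s = mesh.sphere_coords
            f = s[:, 2] if degree == 1 else s[:, 0] * s[:, 1]
            exact = -degree * (degree + 1)
            lf = mesh.lb_operator @ f
            return np.linalg.norm(lf - exact * f) / np.linalg.norm(exact * f)

        for degree in (1, 2):
            errs = [residual_error(m, degree)
                    for m in (sphere_l2, sphere_l3, sphere_l4)]
            assert errs[0] > errs[1] > errs[2]

    def test_diffusion_conserves_mass(self, sphere_l2, params):
        # pure diffusion: zero all productions, make decay negligible
        from hydrapattern.simulator import _ImexStepper
        p = params.replace(**{f"b{i}": 0.0 for i in range(1, 10)},
                           s_wntant=0.0, s_tentant=0.0, s_sd=0.0,
                           s_bcatant=0.0, wnt3_oe_const=0.0,
                           **{f"d{i}": 1e-14 for i in range(1, 10)})
        rng = np.random.default_rng(0)
        values = rng.uniform(0.5, 1.5, (9, sphere_l2.n_vertices))
        m = sphere_l2.vertex_areas
        mass0 = values @ m
        stepper = _ImexStepper(sphere_l2, p, dt=0.1)
        for _ in range(1000):
            values = stepper.step(values)
        drift = np.abs(values @ m - mass0) / mass0
        assert drift.max() < 1e-8


class TestGeodesics:
    def test_identity(self, sphere_l2):
        assert geodesic_separation(sphere_l2, 7, 7) == 0.0

    def test_symmetry_and_euclidean_lower_bound(self, sphere_l2, rng):
        for _ in range(20):
            a, b = rng.integers(0, sphere_l2.n_vertices, 2)
            d_ab = geodesic_separation(sphere_l2, int(a), int(b))
            d_ba = geodesic_separation(sphere_l2, int(b), int(a))
            assert d_ab == pytest.approx(d_ba, rel=1e-12)
            euclid = np.linalg.norm(sphere_l2.vertices[a]
                                    - sphere_l2.vertices[b])
            assert d_ab >= euclid - 1e-12

    def test_antipodal_distance_near_pi(self, sphere_l4):
        top = int(np.argmax(sphere_l4.sphere_coords[:, 2]))
        bottom = int(np.argmin(sphere_l4.sphere_coords[:, 2]))
        d = geodesic_separation(sphere_l4, top, bottom)
        assert abs(d - np.pi) / np.pi < 0.05

    def test_triangle_inequality(self, sphere_l2, rng):
        dists = sphere_l2.geodesic_distances(
            np.arange(sphere_l2.n_vertices))
        n = sphere_l2.n_vertices
        triples = rng.integers(0, n, (100, 3))
        for a, b, c in triples:
            assert dists[a, c] <= dists[a, b] + dists[b, c] + 1e-12

    def test_invalid_index_rejected(self, sphere_l2):
        with pytest.raises(IndexError):
            geodesic_separation(sphere_l2, 0, sphere_l2.n_vertices)


class TestExport:
    def test_vtk_roundtrip(self, sphere_l2, tmp_path):
        from hydrapattern.cli import _read_vtk_point_data
        field = sphere_l2.sphere_coords[:, 2] + 1.5
        path = tmp_path / "state.vtk"
        write_vtk(path, sphere_l2, {"wnt3": field})
        back = _read_vtk_point_data(path)
        assert np.allclose(back["wnt3"], field, atol=1e-9)

    @pytest.mark.parametrize("ext", ["off", "ply"])
    def test_mesh_export_formats(self, sphere_l2, tmp_path, ext):
        import trimesh
        path = tmp_path / f"mesh.{ext}"
        export_mesh(path, sphere_l2)
        loaded = trimesh.load(str(path), process=False)
        assert len(loaded.vertices) == sphere_l2.n_vertices
        assert len(loaded.faces) == sphere_l2.n_faces

    def test_vtk_rejects_wrong_length(self, sphere_l2, tmp_path):
        with pytest.raises(ValueError):
            write_vtk(tmp_path / "bad.vtk", sphere_l2,
                      {"f": np.zeros(3)})
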