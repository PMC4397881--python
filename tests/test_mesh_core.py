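"""Geometry kernel: I/O, rigid transforms, contact queries, resolution."""

import numpy as np
import pytest
import trimesh

from hipsim.mesh_core import (
    RigidTransform,
    TriangleMesh,
    ValidationError,
    exhaustive_min_distance,
    load_mesh,
    query_contact,
    resolve_translation,
    save_mesh,
    transform_mesh,
    validate_mesh,
)

from conftest import make_sphere, random_rigid_transform


class TestMeshIO:
    @pytest.mark.parametrize("ext", ["stl", "ply", "obj"])
    def test_save_load_roundtrip(self, tmp_path, ext):
        mesh = make_sphere(5.0, subdivisions=1)
        path = tmp_path / f"m.{ext}"
        save_mesh(mesh, path)
        back = load_mesh(path)
        assert len(back.faces) == len(mesh.faces)
        assert back.volume == pytest.approx(mesh.volume, rel=1e-6)

    def test_unit_cube_volume_and_unit_scaling(self, tmp_path):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        path = tmp_path / "cube.stl"
        cube.export(path)
        m1 = load_mesh(path, units=1.0)
        m10 = load_mesh(path, units=10.0)
        assert len(m1.faces) == 12
        assert m1.volume == pytest.approx(1.0)
        assert m10.volume == pytest.approx(1000.0)  # cubic scaling

    def test_icosphere_volume_near_closed_form(self):
        mesh = make_sphere(25.0, subdivisions=3)
        assert mesh.volume == pytest.approx(4 / 3 * np.pi * 25**3, rel=0.02)

    def test_degenerate_faces_dropped_and_counted(self, tmp_path):
        box = trimesh.creation.box()
        v = np.vstack([box.vertices, box.vertices[0]])
        f = np.vstack([box.faces, [[0, 1, 8]]])  # vertex 8 == vertex 0
        trimesh.Trimesh(v, f, process=False).export(tmp_path / "d.stl")
        mesh = load_mesh(tmp_path / "d.stl")
        assert len(mesh.faces) == 12
        assert validate_mesh(mesh).watertight

    def test_missing_file_raises(self):
        with pytest.raises(FileNotFoundError):
            load_mesh("/nonexistent/mesh.stl")

    def test_empty_mesh_rejected(self):
        with pytest.raises(ValidationError):
            TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), int))


class TestRigidTransform:
    def test_identity_and_group_axioms(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            T = random_rigid_transform(rng)
            S = random_rigid_transform(rng)
            I = T @ T.inverse()
            assert np.abs(I.rotation - np.eye(3)).max() < 1e-9
            assert np.abs(I.translation).max() < 1e-9
            p = rng.normal(size=(5, 3))
            assert np.allclose((T @ S).apply(p), T.apply(S.apply(p)), atol=1e-9)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 1.01, np.zeros(3))
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_transform_mesh_identity_and_inverse_roundtrip(self):
        mesh = make_sphere(3.0, subdivisions=2)
        same = transform_mesh(mesh, RigidTransform.identity())
        assert np.array_equal(same.vertices, mesh.vertices)
        rng = np.random.default_rng(4)
        T = random_rigid_transform(rng)
        back = transform_mesh(transform_mesh(mesh, T), T.inverse())
        assert np.abs(back.vertices - mesh.vertices).max() < 1e-9

    def test_rotation_about_z_keeps_cube_aabb(self):
        cube = trimesh.creation.box(extents=(2, 2, 2))
        mesh = TriangleMesh(cube.vertices, cube.faces)
        rot = transform_mesh(mesh, RigidTransform.from_axis_angle([0, 0, 1], 90.0))
        assert np.allclose(rot.bounds, mesh.bounds, atol=1e-12)

    def test_volume_invariant_under_rigid_transform(self):
        mesh = make_sphere(7.0, subdivisions=2)
        rng = np.random.default_rng(5)
        for _ in range(5):
            T = random_rigid_transform(rng)
            assert transform_mesh(mesh, T).volume == pytest.approx(
                mesh.volume, rel=1e-6
            )


class TestContactQuery:
    def test_separated_spheres_gap(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (3.0, 0, 0))
        res = query_contact(a, b)
        assert not res.colliding
        assert res.min_distance == pytest.approx(1.0, abs=0.02)

    def test_overlapping_spheres_penetration_estimate(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (1.5, 0, 0))
        res = query_contact(a, b)
        assert res.colliding
        assert res.min_distance == pytest.approx(-0.5, abs=0.05)

    def test_self_overlap_collides(self):
        a = make_sphere(1.0)
        res = query_contact(a, a.copy())
        assert res.colliding and res.min_distance <= 0

    def test_full_containment_detected(self):
        outer = make_sphere(5.0)
        inner = make_sphere(1.0, subdivisions=1)
        res = query_contact(outer, inner)
        assert res.colliding
        assert res.min_distance == pytest.approx(-4.0, abs=0.05)

    def test_collision_boolean_symmetric(self):
        rng = np.random.default_rng(6)
        for _ in range(25):
            a = make_sphere(rng.uniform(0.5, 2.0), rng.normal(scale=2.0, size=3),
                            subdivisions=1)
            b = make_sphere(rng.uniform(0.5, 2.0), rng.normal(scale=2.0, size=3),
                            subdivisions=1)
            assert query_contact(a, b).colliding == query_contact(b, a).colliding

    def test_min_distance_matches_bruteforce_on_small_meshes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = make_sphere(rng.uniform(0.5, 1.5), rng.normal(scale=4.0, size=3),
                            subdivisions=1)  # 80 faces
            b = make_sphere(rng.uniform(0.5, 1.5), rng.normal(scale=4.0, size=3),
                            subdivisions=1)
            res = query_contact(a, b)
            if not res.colliding:
                assert res.min_distance == pytest.approx(
                    exhaustive_min_distance(a, b), abs=1e-9
                )

    def test_witness_pairs_present_within_tolerance(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (2.05, 0, 0))
        res = query_contact(a, b, tolerance=0.1)
        assert not res.colliding
        assert len(res.witness_pairs) > 0

    def test_negative_tolerance_rejected(self):
        a = make_sphere(1.0)
        with pytest.raises(ValidationError):
            query_contact(a, a, tolerance=-1.0)


class TestResolveTranslation:
    def test_overlap_resolved_along_center_line(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (1.6, 0, 0))  # 0.4 mm overlap
        t = resolve_translation(a, b, max_norm=3.0, tolerance=0.1)
        assert t is not None
        assert np.linalg.norm(t) >= 0.4 + 0.1 - 0.05
        # separation must act along the center line (+x), up to mesh grain
        assert t[0] > 0.9 * np.linalg.norm(t)
        moved = transform_mesh(b, RigidTransform.from_translation(t))
        assert not query_contact(a, moved).colliding

    def test_insufficient_cap_unresolvable(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (1.6, 0, 0))
        assert resolve_translation(a, b, max_norm=0.1, tolerance=0.1) is None

    def test_clear_input_returns_zero(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (3.0, 0, 0))
        assert np.allclose(resolve_translation(a, b, 3.0, 0.1), 0.0)

    def test_cap_respected_and_monotone(self):
        a = make_sphere(1.0)
        b = make_sphere(1.0, (1.3, 0, 0))  # 0.7 mm overlap
        for cap in (1.0, 2.0, 4.0):
            t = resolve_translation(a, b, max_norm=cap, tolerance=0.1)
            assert t is not None, f"resolvable at cap 1 must stay resolvable at {cap}"
            assert np.linalg.norm(t) <= cap + 1e-9

    def test_invalid_cap_rejected(self):
        a = make_sphere(1.0)
        with pytest.raises(ValidationError):
            resolve_translation(a, a, max_norm=0.0)
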