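"""Phantom generation, analytic oracle, synthetic CT pipeline."""

import numpy as np
import pytest

from hipsim import (
    CamSpec,
    PhantomSpec,
    add_cam,
    analytic_rom,
    brute_force_rom,
    generate_phantom,
    material_volume,
    segment_volume,
    voxelize_ct,
)
from hipsim.hip_phantom import CTVolumeSpec, OracleUnavailable, soft_envelope
from hipsim.mesh_core import ValidationError, contains_points, query_contact
from hipsim.rom_engine import MotionDefinition, standard_motions

from conftest import make_sphere

CAP_VOLUME = np.pi * 3.5 * (3 * 5.0**2 + 3.5**2) / 6  # h=3.5, a=5


class TestSpec:
    def test_defaults_valid_and_neutral_margin_positive(self):
        spec = PhantomSpec(cam=CamSpec())
        assert spec.neutral_margin() > 0
        assert np.isclose(np.linalg.norm(spec.cup_pole), 1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            PhantomSpec(neck_radius=30.0)  # neck wider than head
        with pytest.raises(ValidationError):
            PhantomSpec(clearance=0.0)
        with pytest.raises(ValidationError):
            PhantomSpec(cup_coverage=95.0)
        with pytest.raises(ValidationError):
            # rim + neck cone exceed the neutral offset: collides at rest
            PhantomSpec(cup_coverage=85.0, neutral_offset=100.0)

    def test_left_side_mirrors_pole(self):
        r = PhantomSpec(side="right")
        l = PhantomSpec(side="left")
        assert np.allclose(r.cup_pole * [1, 1, -1], l.cup_pole)


class TestGeneration:
    def test_meshes_watertight_and_neutral_clearance(self, native_phantom_small):
        ph = native_phantom_small
        assert ph.femur.is_watertight and ph.pelvis.is_watertight
        res = query_contact(ph.pelvis, ph.femur)
        assert not res.colliding
        assert res.min_distance == pytest.approx(ph.spec.clearance, abs=0.1)

    def test_landmarks_support_frames(self, native_phantom_small):
        from hipsim.anatomy_frames import femur_frame, pelvis_frame

        ph = native_phantom_small
        pf = pelvis_frame(ph.landmarks)
        ff = femur_frame(ph.landmarks, ph.hip_center)
        assert np.allclose(pf.z, ph.pelvis_frame.z, atol=1e-9)
        assert np.allclose(ff.y, ph.femur_frame.y, atol=1e-9)

    def test_pelvic_fiducials_stated_spacing_apart(self, native_phantom_small):
        fid = native_phantom_small.landmarks.fiducials
        assert np.linalg.norm(fid[1] - fid[0]) == pytest.approx(30.0)

    def test_mesh_resolution_convergence(self):
        """Doubling tessellation moves an endpoint by < 0.2 degrees."""
        from hipsim import SimulationConfig, simulate_standard_set

        cfg = SimulationConfig(max_translation=0.0)
        motion = standard_motions(cfg)[5]
        angles = []
        for res in (3, 4):
            ph = generate_phantom(PhantomSpec(), mesh_resolution=res)
            eps = simulate_standard_set(
                ph.femur, ph.pelvis, ph.pelvis_frame, ph.femur_frame,
                ph.hip_center, ph.side, cfg, motions=[motion],
            )
            angles.append(eps[motion.label].angle)
        assert abs(angles[1] - angles[0]) < 0.2


class TestCam:
    def test_zero_height_is_identity(self, native_phantom_small):
        ph = native_phantom_small
        out = add_cam(ph.femur_nocam, CamSpec(height=0.0), ph.hip_center, ph.spec)
        assert np.array_equal(out.vertices, ph.femur_nocam.vertices)

    def test_added_volume_matches_spherical_cap(self, cam_phantom_default):
        ph = cam_phantom_default
        added = ph.femur.volume - ph.femur_nocam.volume
        assert added == pytest.approx(CAP_VOLUME, rel=0.10)

    def test_two_adjacent_cams_add_volumes(self, cam_phantom_default):
        ph = cam_phantom_default
        spec = ph.spec
        one = add_cam(ph.femur_nocam, CamSpec(clock_hour=11.5), ph.hip_center, spec)
        two = add_cam(one, CamSpec(clock_hour=1.5), ph.hip_center, spec)
        added = two.volume - ph.femur_nocam.volume
        assert added == pytest.approx(2 * CAP_VOLUME, rel=0.15)

    def test_mesh_stays_watertight(self, cam_phantom_small):
        assert cam_phantom_small.femur.is_watertight

    def test_screw_mode_adds_two_studs(self, native_phantom_small):
        ph = native_phantom_small
        out = add_cam(
            ph.femur_nocam, CamSpec(profile="screws"), ph.hip_center, ph.spec
        )
        assert len(out.faces) > len(ph.femur_nocam.faces)
        assert out.volume > ph.femur_nocam.volume


class TestAnalyticOracle:
    def test_point_neck_limit(self):
        """As the neck radius shrinks, the in-plane endpoint approaches
        neutral_offset - cup_coverage."""
        spec = PhantomSpec(neck_radius=0.05, cup_pole=np.array([0.5, 0.86, 0.0]))
        m = MotionDefinition("max_flexion", "flexion", {}, 0.0, 150.0)
        r = analytic_rom(spec, m)
        assert r.angle == pytest.approx(
            spec.neutral_offset - spec.cup_coverage, abs=0.2
        )

    def test_in_plane_closed_form(self):
        """A cup pole in the sagittal sweep plane reproduces the textbook
        formula a0 - coverage - asin(r_n / R_cup) for flexion."""
        spec = PhantomSpec(cup_pole=np.array([0.5, 0.866, 0.0]))
        m = MotionDefinition("max_flexion", "flexion", {}, 0.0, 150.0)
        expect = (
            spec.neutral_offset
            - spec.cup_coverage
            - np.degrees(np.arcsin(spec.neck_radius / spec.cup_radius))
        )
        assert analytic_rom(spec, m).angle == pytest.approx(expect, abs=1e-9)

    def test_cam_below_clearance_is_invisible(self):
        base = PhantomSpec()
        sub = PhantomSpec(cam=CamSpec(height=1.5))  # below the 2 mm clearance
        for m in standard_motions():
            assert analytic_rom(sub, m).angle == analytic_rom(base, m).angle

    def test_matches_brute_force_sampler(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            kw = dict(
                cup_coverage=rng.uniform(54, 66),
                neutral_offset=rng.uniform(168, 176),
                neck_radius=rng.uniform(10, 12.5),
                clearance=rng.uniform(1.5, 2.5),
            )
            cam = CamSpec(clock_hour=rng.uniform(11, 14) % 12,
                          polar_deg=rng.uniform(38, 52),
                          height=rng.uniform(2.5, 5))
            for spec in (PhantomSpec(**kw), PhantomSpec(**kw, cam=cam)):
                for m in standard_motions():
                    try:
                        a = analytic_rom(spec, m)
                    except OracleUnavailable:
                        continue
                    b = brute_force_rom(spec, m)
                    assert a.angle == pytest.approx(b.angle, abs=0.02), m.label

    def test_blocked_fixed_pose_unavailable(self):
        spec = PhantomSpec()
        m = MotionDefinition("ir_120", "internal_rotation", {"flexion": 120.0})
        with pytest.raises(OracleUnavailable):
            analytic_rom(spec, m)

    def test_cam_monotone_in_height(self):
        angles = []
        m = standard_motions()[4]  # internal rotation at 60 flexion
        for h in (0.0, 2.5, 3.5, 5.0):
            spec = PhantomSpec(cam=CamSpec(height=h) if h else None)
            angles.append(analytic_rom(spec, m).angle)
        assert all(a >= b - 1e-12 for a, b in zip(angles, angles[1:]))


class TestSyntheticCT:
    # coarse grid keeps unit tests quick; the scan-protocol spacing is
    # exercised by the acceptance suite
    COARSE = (0.53, 0.53, 1.0)

    def test_sphere_volume_conserved(self):
        sph = make_sphere(15.0, subdivisions=3)
        ct = voxelize_ct([(sph, "bone")], CTVolumeSpec(spacing=self.COARSE))
        vol = material_volume(ct, 1.9)
        assert vol == pytest.approx(4 / 3 * np.pi * 15**3, rel=0.02)

    def test_empty_scene_is_air(self):
        far = make_sphere(5.0, center=(500.0, 0, 0), subdivisions=1)
        spec = CTVolumeSpec(
            spacing=self.COARSE, extent=np.array([[-20.0, -20, -20], [20, 20, 20.0]])
        )
        ct = voxelize_ct([(far, "bone")], spec)
        assert ct.data.max() == 0.0

    def test_nylon_cam_distinguishable_from_bone(self, cam_phantom_small):
        ph = cam_phantom_small
        ext = np.array([[-40.0, -40, -40], [40, 40, 40.0]])
        ct = voxelize_ct(
            [(ph.femur, "nylon"), (ph.femur_nocam, "bone"), (ph.pelvis, "bone")],
            CTVolumeSpec(spacing=self.COARSE, extent=ext),
        )
        nylon_vox = ((ct.data > 1.05) & (ct.data < 1.3)).sum()
        bone_vox = (ct.data > 1.8).sum()
        assert nylon_vox > 50  # the cam mantle shows at nylon density
        assert bone_vox > 10000
        # intensity ordering follows the density model
        assert ct.data.max() == pytest.approx(1.9, abs=0.01)

    def test_open_mesh_rejected(self):
        sph = make_sphere(5.0, subdivisions=1)
        open_mesh = type(sph)(sph.vertices, sph.faces[:-5], "open")
        with pytest.raises(ValidationError):
            voxelize_ct([(open_mesh, "bone")], CTVolumeSpec(spacing=self.COARSE))

    def test_bad_material_rejected(self):
        sph = make_sphere(5.0, subdivisions=1)
        with pytest.raises(ValidationError):
            voxelize_ct([(sph, "adamantium")], CTVolumeSpec(spacing=self.COARSE))

    def test_intensity_ordering_enforced(self):
        with pytest.raises(ValidationError):
            CTVolumeSpec(nylon=2.5)

    def test_segmentation_roundtrip_two_components(self, native_phantom_small):
        ph = native_phantom_small
        ext = np.array([[-45.0, -45, -45], [45, 42, 45.0]])
        ct = voxelize_ct(
            [(ph.femur, "bone"), (ph.pelvis, "bone"), (soft_envelope(), "soft_tissue")],
            CTVolumeSpec(spacing=self.COARSE, extent=ext),
        )
        segs = segment_volume(ct, 1.45, iso_edge=0.6)
        assert len(segs) == 2
        assert all(s.is_watertight for s in segs)
        # the head component encloses the hip center region
        fem = next(
            s for s in segs
            if contains_points(s, np.array([[0.0, -20, 0], [0.0, 0, -20]])).any()
        )
        from hipsim._voxel import rasterize_occupancy

        dims = np.ceil((ext[1] - ext[0]) / 0.4).astype(int)
        occ = rasterize_occupancy(ph.femur.triangles, ext[0], (0.4,) * 3, dims)
        ref = occ.sum() * 0.4**3
        assert fem.volume == pytest.approx(ref, rel=0.05)

    def test_threshold_above_bone_errors(self, native_phantom_small):
        ph = native_phantom_small
        ext = np.array([[-30.0, -30, -30], [30, 30, 30.0]])
        ct = voxelize_ct(
            [(ph.femur, "bone")], CTVolumeSpec(spacing=self.COARSE, extent=ext)
        )
        with pytest.raises(ValidationError):
            segment_volume(ct, 2.5)

    def test_save_volume_formats(self, tmp_path):
        import SimpleITK as sitk

        from hipsim import save_volume

        sph = make_sphere(5.0, subdivisions=1)
        spec = CTVolumeSpec(
            spacing=(1.0, 1.0, 1.0), extent=np.array([[-8.0, -8, -8], [8, 8, 8.0]])
        )
        ct = voxelize_ct([(sph, "bone")], spec)
        for name in ("vol.nii.gz", "vol.mha"):
            save_volume(ct, tmp_path / name)
            img = sitk.ReadImage(str(tmp_path / name))
            assert img.GetSpacing() == (1.0, 1.0, 1.0)
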