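"""Parametric synthetic hip: meshes, landmarks, analytic ROM oracle and a
synthetic CT pipeline (voxelization + threshold/marching-cubes
segmentation).

The phantom emulates the experimental setup the simulation method was
validated on: a spherical femoral head articulating in a spherical
acetabular cup with uniform clearance, a cylindrical neck, an artificial
cam bump at the anterosuperior head-neck region (default geometry
matching a nylon screw head: 10 mm diameter, 3.5 mm proud), K-wire-style
registration fiducials, and a CT protocol of 1.0 mm slices with
0.265 mm in-plane pixels.  Because head and cup are concentric spheres,
every standard motion has a closed-form impingement angle, which is the
engine's validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh as _trimesh
from scipy import ndimage
from skimage import measure

from ._voxel import block_average, rasterize_occupancy
from .anatomy_frames import AnatomicalFrame, HipCenter, LandmarkSet
from .mesh_core import TriangleMesh, ValidationError
from .rom_engine import MotionDefinition, component_sign

__all__ = [
    "CamSpec",
    "PhantomSpec",
    "Phantom",
    "OracleResult",
    "OracleUnavailable",
    "generate_phantom",
    "add_cam",
    "analytic_rom",
    "brute_force_rom",
    "CTVolumeSpec",
    "CTVolume",
    "voxelize_ct",
    "segment_volume",
    "save_volume",
    "material_volume",
]


class OracleUnavailable(RuntimeError):
    """The requested motion lies outside the oracle's validity domain."""


@dataclass(frozen=True)
class CamSpec:
    """Artificial cam bump: spherical-cap profile, proud of the head.

    Defaults match the screws used to induce the deformity: 10 mm
    diameter (cap_radius 5 mm footprint) and 3.5 mm proud, placed in the
    anterosuperior 11-2 o'clock band.
    """

    clock_hour: float = 1.5
    cap_radius: float = 5.0  # a, mm
    height: float = 3.5  # h, mm
    polar_deg: float = 45.0  # cam center's angle from the neck axis
    profile: str = "spherical-cap"  # or "screws"

    @property
    def profile_radius(self) -> float:
        """Radius of the sphere whose cap has this height and footprint."""
        return (self.cap_radius**2 + self.height**2) / (2.0 * self.height)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the synthetic hip (mm / degrees)."""

    head_radius: float = 25.0  # r_h
    clearance: float = 2.0  # c; cup inner radius = r_h + c
    cup_coverage: float = 60.0  # rim polar angle from the cup pole
    cup_pole: np.ndarray | None = None  # unit vector, pelvis frame
    neck_radius: float = 11.0  # r_n
    neck_length: float = 50.0
    neutral_offset: float = 172.0  # angle(neck axis, cup pole) at neutral
    cam: CamSpec | None = None
    side: str = "right"
    shaft_radius: float = 16.0
    shaft_length: float = 70.0
    cup_thickness: float = 4.0
    fiducial_spacing: float = 30.0  # the paired pelvic K-wires

    def __post_init__(self):
        if self.cup_pole is None:
            # typical acetabular orientation: anterosuperior, facing the
            # head from medial; mirrored in z for a left hip
            sigma = 1.0 if self.side == "right" else -1.0
            p = np.array([0.35, 0.75, -0.56 * sigma])
            object.__setattr__(self, "cup_pole", p / np.linalg.norm(p))
        else:
            p = np.asarray(self.cup_pole, dtype=float).reshape(3)
            object.__setattr__(self, "cup_pole", p / np.linalg.norm(p))
        self.validate()

    def validate(self) -> None:
        if not (self.head_radius > self.neck_radius > 0):
            raise ValidationError("require head_radius > neck_radius > 0")
        if not self.clearance > 0:
            raise ValidationError("clearance must be > 0")
        if not 0 < self.cup_coverage < 90:
            raise ValidationError("cup_coverage must be in (0, 90) degrees")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        if self.neutral_margin() <= 0:
            raise ValidationError(
                "neutral pose not collision-free: "
                "cup_coverage + asin(r_n/R_cup) must be < neutral_offset"
            )

    @property
    def cup_radius(self) -> float:
        return self.head_radius + self.clearance

    def neutral_margin(self) -> float:
        """Angular margin (deg) between the neck and the rim at neutral."""
        tau = self.cup_coverage + np.degrees(
            np.arcsin(self.neck_radius / self.cup_radius)
        )
        return self.neutral_offset - tau

    # -- derived unit vectors (world frame == pelvis ISB frame) -------------

    @property
    def neck_axis(self) -> np.ndarray:
        """Unit vector from head center along the neck, at neutral pose."""
        p = self.cup_pole
        inferior = np.array([0.0, -1.0, 0.0])
        w = inferior - (inferior @ p) * p
        w /= np.linalg.norm(w)
        a0 = np.radians(self.neutral_offset)
        return np.cos(a0) * p + np.sin(a0) * w

    def clock_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """(12 o'clock, quadrature) directions of the head-neck clock face.

        12 points superior; the quadrature direction is oriented so hour 3
        is anterior on a right hip (mirrored for the left).
        """
        n = self.neck_axis
        sup = np.array([0.0, 1.0, 0.0])
        e12 = sup - (sup @ n) * n
        nrm = np.linalg.norm(e12)
        if nrm < 1e-9:
            raise ValidationError("neck axis parallel to superior: clock undefined")
        e12 /= nrm
        q = np.cross(n, e12)
        q /= np.linalg.norm(q)
        sigma = 1.0 if self.side == "right" else -1.0
        if (q @ np.array([1.0, 0.0, 0.0])) * sigma < 0:
            q = -q
        return e12, q

    @property
    def cam_direction(self) -> np.ndarray:
        """Unit direction from the head center to the cam-bump apex."""
        if self.cam is None:
            raise ValidationError("spec has no cam")
        e12, q = self.clock_basis()
        ang = np.radians(self.cam.clock_hour * 30.0)
        d = np.cos(ang) * e12 + np.sin(ang) * q
        psi = np.radians(self.cam.polar_deg)
        return np.cos(psi) * self.neck_axis + np.sin(psi) * d


@dataclass
class Phantom:
    """Generated phantom: meshes, landmarks, frames and analytic handles."""

    spec: PhantomSpec
    femur: TriangleMesh
    femur_nocam: TriangleMesh
    pelvis: TriangleMesh
    landmarks: LandmarkSet
    hip_center: HipCenter
    pelvis_frame: AnatomicalFrame
    femur_frame: AnatomicalFrame

    @property
    def side(self) -> str:
        return self.spec.side


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------


def _orthobasis(p: np.ndarray):
    ref = np.array([0.0, 0.0, 1.0]) if abs(p[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(p, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(p, e1)
    return e1, e2


def _revolve(profile: np.ndarray, axis: np.ndarray, center, n_az: int) -> _trimesh.Trimesh:
    """Closed surface of revolution of an (axial, radial) profile curve.

    The profile must start and end on the axis (radial == 0).
    """
    e1, e2 = _orthobasis(axis)
    phis = np.linspace(0.0, 2.0 * np.pi, n_az, endpoint=False)
    ring_ids = []
    verts = []
    for s, rho in profile:
        if rho <= 1e-12:
            verts.append(center + s * axis)
            ring_ids.append(("pole", len(verts) - 1))
        else:
            base = len(verts)
            for ph in phis:
                verts.append(center + s * axis + rho * (np.cos(ph) * e1 + np.sin(ph) * e2))
            ring_ids.append(("ring", base))
    faces = []
    for (ka, ia), (kb, ib) in zip(ring_ids[:-1], ring_ids[1:]):
        if ka == "pole" and kb == "ring":
            for j in range(n_az):
                faces.append([ia, ib + j, ib + (j + 1) % n_az])
        elif ka == "ring" and kb == "pole":
            for j in range(n_az):
                faces.append([ia + j, ib, ia + (j + 1) % n_az])
        elif ka == "ring" and kb == "ring":
            for j in range(n_az):
                j2 = (j + 1) % n_az
                faces.append([ia + j, ib + j, ib + j2])
                faces.append([ia + j, ib + j2, ia + j2])
    tm = _trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)
    if tm.volume < 0:
        tm.invert()
    return tm


def _cup_shell(spec: PhantomSpec, n_polar: int, n_az: int) -> _trimesh.Trimesh:
    """Spherical-shell cup: inner cap, rim annulus, outer cap."""
    r_in = spec.cup_radius
    r_out = r_in + spec.cup_thickness
    tc = np.radians(spec.cup_coverage)
    prof = []
    for th in np.linspace(0.0, tc, n_polar + 1):
        prof.append((r_in * np.cos(th), r_in * np.sin(th)))
    prof.append((r_out * np.cos(tc), r_out * np.sin(tc)))
    for th in np.linspace(tc, 0.0, n_polar + 1)[1:]:
        prof.append((r_out * np.cos(th), r_out * np.sin(th)))
    return _revolve(np.array(prof), spec.cup_pole, np.zeros(3), n_az)


def _cylinder(p0, p1, radius, sections) -> _trimesh.Trimesh:
    tm = _trimesh.creation.cylinder(
        radius=radius, segment=np.vstack([p0, p1]), sections=sections
    )
    if tm.volume < 0:  # pragma: no cover - trimesh returns outward winding
        tm.invert()
    return tm


def _bead(center, radius=6.0, subdivisions=1) -> _trimesh.Trimesh:
    b = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    b.apply_translation(center)
    return b


def generate_phantom(spec: PhantomSpec | None = None, mesh_resolution: int = 4) -> Phantom:
    """Build the phantom's femur and pelvis meshes plus landmarks.

    ``mesh_resolution`` is the icosphere subdivision level of the femoral
    head; the cup and cylinder tessellations scale with it.  The world
    frame coincides with the ISB pelvis frame and the hip center is at
    the origin, by construction.
    """
    spec = spec or PhantomSpec()
    sigma = 1.0 if spec.side == "right" else -1.0
    n_az = 32 * 2 ** (mesh_resolution - 2)  # 128 at the default level
    n_polar = max(12, n_az // 8)

    # the cam's super-clearance boundary needs finer sampling than the
    # bare head: one extra subdivision level keeps its contact angles
    # within the engine's discretization budget
    head_sub = mesh_resolution + (2 if spec.cam is not None else 0)
    head = _trimesh.creation.icosphere(subdivisions=head_sub, radius=spec.head_radius)
    n0 = spec.neck_axis
    s0 = np.sqrt(spec.head_radius**2 - spec.neck_radius**2)
    neck = _cylinder(n0 * s0, n0 * spec.neck_length, spec.neck_radius, n_az)
    shaft = _cylinder(
        n0 * spec.neck_length,
        n0 * spec.neck_length + np.array([0.0, -spec.shaft_length, 0.0]),
        spec.shaft_radius,
        max(n_az // 2, 24),
    )
    # landmark beads: epicondylar pair and greater trochanter
    # (motion-tracker-style marker spheres, disjoint from the bone solids)
    epi_y = -400.0
    epi_med = np.array([0.0, epi_y, -45.0 * sigma])
    epi_lat = np.array([0.0, epi_y, 45.0 * sigma])
    troch = n0 * spec.neck_length + np.array([0.0, 5.0, 28.0 * sigma])
    femur_nocam_tm = _trimesh.util.concatenate(
        [head, neck, shaft, _bead(epi_med), _bead(epi_lat), _bead(troch, 4.0)]
    )
    femur_nocam = TriangleMesh(
        femur_nocam_tm.vertices, femur_nocam_tm.faces, "femur"
    )

    pelvis_tm = _cup_shell(spec, n_polar, n_az)
    asis_mid = np.array([20.0, 90.0, -90.0 * sigma])
    asis_l = asis_mid + np.array([0.0, 0.0, -128.0])
    asis_r = asis_mid + np.array([0.0, 0.0, 128.0])
    psis = np.array([-110.0, 90.0, -90.0 * sigma])
    pelvis_tm = _trimesh.util.concatenate(
        [pelvis_tm, _bead(asis_l), _bead(asis_r), _bead(psis)]
    )
    pelvis = TriangleMesh(pelvis_tm.vertices, pelvis_tm.faces, "pelvis")

    hip_center = HipCenter(np.zeros(3), spec.head_radius, 0.0)
    if spec.cam is not None and spec.cam.height > 0:
        femur = add_cam(femur_nocam, spec.cam, hip_center, spec)
    else:
        femur = femur_nocam

    # paired pelvic K-wires (stated spacing apart) plus femoral wires
    wire = spec.fiducial_spacing
    fiducials = np.array(
        [asis_r, asis_r + np.array([0.0, wire, 0.0]), troch, epi_med, epi_lat]
    )
    landmarks = LandmarkSet(
        side=spec.side,
        landmarks={
            "ASIS_left": asis_l,
            "ASIS_right": asis_r,
            "PSIS_mid": psis,
            "epicondyle_medial": epi_med,
            "epicondyle_lateral": epi_lat,
            "greater_trochanter": troch,
        },
        fiducials=fiducials,
    )
    pelvis_frame = AnatomicalFrame(
        asis_mid, np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    )
    femur_frame = AnatomicalFrame(
        np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])
    )
    return Phantom(
        spec, femur, femur_nocam, pelvis, landmarks, hip_center,
        pelvis_frame, femur_frame,
    )


def add_cam(
    femur: TriangleMesh,
    cam: CamSpec,
    hip_center: HipCenter,
    spec: PhantomSpec,
) -> TriangleMesh:
    """Raise the cam bump on the femoral head surface.

    Head-sphere vertices within the cap footprint are displaced radially
    with the spherical-cap height profile (max ``cam.height`` at the cam
    center, zero at ``cam.cap_radius``), which keeps the mesh watertight.
    The ``screws`` profile instead adds two discrete cylindrical studs in
    the 11-2 o'clock band, mimicking the physical screw heads.
    """
    if cam.height <= 0:
        return femur.copy()
    spec = replace(spec, cam=cam)
    c_dir = spec.cam_direction
    center = hip_center.center
    r_h = spec.head_radius

    if cam.profile == "screws":
        parts = [femur.trimesh]
        e12, q = spec.clock_basis()
        for hour in (cam.clock_hour - 1.0, cam.clock_hour + 1.0):
            ang = np.radians(hour * 30.0)
            d = np.cos(ang) * e12 + np.sin(ang) * q
            psi = np.radians(cam.polar_deg)
            u = np.cos(psi) * spec.neck_axis + np.sin(psi) * d
            stud = _cylinder(
                center + u * (r_h - 1.0),
                center + u * (r_h + cam.height),
                cam.cap_radius,
                48,
            )
            parts.append(stud)
        tm = _trimesh.util.concatenate(parts)
        return TriangleMesh(tm.vertices, tm.faces, femur.name)

    v = femur.vertices.copy()
    rel = v - center
    r = np.linalg.norm(rel, axis=1)
    on_head = np.abs(r - r_h) < 1e-6
    with np.errstate(invalid="ignore"):
        cosang = np.clip((rel @ c_dir) / np.where(r > 0, r, 1.0), -1.0, 1.0)
    # geodesic arc length from the cam apex along the head surface
    s = r_h * np.arccos(cosang)
    R_c = cam.profile_radius
    lift = np.sqrt(np.maximum(R_c**2 - s**2, 0.0)) - (R_c - cam.height)
    lift = np.where((cosang > 0) & (s < cam.cap_radius) & on_head, np.maximum(lift, 0.0), 0.0)
    v += (rel / np.where(r[:, None] > 0, r[:, None], 1.0)) * lift[:, None]
    return TriangleMesh(v, femur.faces.copy(), femur.name)


# ---------------------------------------------------------------------------
# analytic ROM oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleResult:
    angle: float  # degrees
    status: str  # "impinged" | "bound_reached"
    mechanism: str  # "neck" | "cam" | "none"


def _first_crossing(p, v, w, cos_tau, bound_rad):
    """Smallest positive sweep angle at which angle(p, R(w, phi) v) == tau.

    Uses the Rodrigues closed form  cos psi(phi) = A cos phi + B sin phi + C.
    Returns None when no crossing occurs within the bound.
    """
    A = p @ v - (p @ w) * (w @ v)
    B = p @ np.cross(w, v)
    C = (p @ w) * (w @ v)
    Rm = np.hypot(A, B)
    if Rm < 1e-15:
        return None
    k = (cos_tau - C) / Rm
    if abs(k) > 1.0:
        return None
    delta = np.arctan2(B, A)
    base = np.arccos(np.clip(k, -1.0, 1.0))
    cands = []
    for sgn in (+1.0, -1.0):
        for n in (-1, 0, 1):
            phi = delta + sgn * base + 2.0 * np.pi * n
            if 1e-12 < phi <= bound_rad + 1e-12:
                cands.append(phi)
    return min(cands) if cands else None


def _sweep_setup(spec: PhantomSpec, motion: MotionDefinition):
    """Fixed-pose rotation and effective sweep axis for a phantom motion."""
    order = ("flexion", "abduction", "internal_rotation")
    axes = {
        "flexion": np.array([0.0, 0.0, 1.0]),
        "abduction": np.array([1.0, 0.0, 0.0]),
    }
    R = np.eye(3)
    for comp in order:
        if comp == motion.swept:
            continue
        ang = np.radians(component_sign(comp, spec.side) * motion.fixed.get(comp, 0.0))
        if ang == 0.0:
            continue
        axis = axes[comp] if comp in axes else R @ np.array([0.0, 1.0, 0.0])
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = (np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K) @ R
    sgn = component_sign(motion.swept, spec.side)
    if motion.swept in axes:
        w = sgn * axes[motion.swept]
    else:
        w = sgn * (R @ np.array([0.0, 1.0, 0.0]))
    return R, w


def _cam_super_clearance_halfwidth(spec: PhantomSpec) -> float | None:
    """Angular half-width (rad) of the cam region prouder than the
    clearance; None when the cam passes under the rim entirely."""
    # touching counts as contact (min_distance <= 0 is colliding), so a
    # bump exactly as proud as the clearance grazes the cup: only a
    # strictly lower bump passes under the rim
    cam = spec.cam
    if cam is None or cam.height < spec.clearance:
        return None
    R_c = cam.profile_radius
    s_c = np.sqrt(max(R_c**2 - (R_c - cam.height + spec.clearance) ** 2, 0.0))
    return float(s_c / spec.head_radius)  # geodesic arc -> angle


def analytic_rom(spec: PhantomSpec, motion: MotionDefinition) -> OracleResult:
    """Closed-form impingement angle of a single-axis sweep.

    Valid for the concentric head/cup phantom under uncorrected motion
    (zero translation cap): contact happens either when the neck axis
    comes within ``cup_coverage + asin(r_n / R_cup)`` of the cup pole
    (neck-on-rim) or when the cam's super-clearance region reaches the
    rim circle (cam-on-rim).
    """
    if motion.start != 0.0:
        raise OracleUnavailable("oracle defined for sweeps starting at neutral")
    p = spec.cup_pole
    R_fix, w = _sweep_setup(spec, motion)
    bound_rad = np.radians(motion.bound)

    tau_neck = np.radians(spec.cup_coverage) + np.arcsin(
        spec.neck_radius / spec.cup_radius
    )
    v_neck = R_fix @ spec.neck_axis
    if np.arccos(np.clip(p @ v_neck, -1, 1)) <= tau_neck:
        raise OracleUnavailable("fixed components already impinge the neck")
    best = None
    mech = "none"
    phi_n = _first_crossing(p, v_neck, w, np.cos(tau_neck), bound_rad)
    if phi_n is not None:
        best, mech = phi_n, "neck"

    gamma = _cam_super_clearance_halfwidth(spec)
    if gamma is not None:
        tau_cam = np.radians(spec.cup_coverage) + gamma
        v_cam = R_fix @ spec.cam_direction
        if np.arccos(np.clip(p @ v_cam, -1, 1)) <= tau_cam:
            raise OracleUnavailable("fixed components already impinge the cam")
        phi_c = _first_crossing(p, v_cam, w, np.cos(tau_cam), bound_rad)
        if phi_c is not None and (best is None or phi_c < best):
            best, mech = phi_c, "cam"

    if best is None:
        return OracleResult(motion.bound, "bound_reached", "none")
    return OracleResult(float(np.degrees(best)), "impinged", mech)


def brute_force_rom(
    spec: PhantomSpec, motion: MotionDefinition, step: float = 0.01
) -> OracleResult:
    """Dense-sampling geometric oracle (independent of the closed form).

    The neck mechanism is checked by marching the sweep in ``step``-degree
    increments against the analytic rim/cylinder condition.  The cam
    mechanism samples the displacement field itself on a dense spherical
    grid (no super-clearance disc geometry involved) and finds, per
    sample point prouder than the clearance, the sweep angle at which it
    enters the covered cup region; the earliest such entry is the cam
    contact angle.
    """
    p = spec.cup_pole
    R_fix, w = _sweep_setup(spec, motion)
    tau_neck = np.radians(spec.cup_coverage) + np.arcsin(
        spec.neck_radius / spec.cup_radius
    )
    v_neck = R_fix @ spec.neck_axis

    K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])

    def neck_psi(phi_rad: float) -> float:
        R = np.eye(3) + np.sin(phi_rad) * K + (1 - np.cos(phi_rad)) * (K @ K)
        return float(np.arccos(np.clip(p @ (R @ v_neck), -1, 1)))

    if neck_psi(0.0) < tau_neck:
        raise OracleUnavailable("start pose already collides")
    n = int(np.floor(motion.bound / step))
    neck_phi = None
    for k in range(1, n + 1):
        if neck_psi(np.radians(k * step)) < tau_neck:
            neck_phi = (k - 1) * step
            break

    cam_phi = None
    if spec.cam is not None and spec.cam.height > 0:
        cam = spec.cam
        c_dir = R_fix @ spec.cam_direction
        e1, e2 = _orthobasis(c_dir)
        th_max = cam.cap_radius / spec.head_radius
        R_c = cam.profile_radius

        def lift_of(th):
            s = spec.head_radius * th  # geodesic arc length
            return np.sqrt(np.maximum(R_c**2 - s**2, 0.0)) - (R_c - cam.height)

        cos_tau = np.cos(np.radians(spec.cup_coverage))
        pw = p @ w
        pxw = np.cross(p, w)

        def first_entry(ths, azs):
            """Earliest sweep angle (rad) at which any sampled cam point
            prouder than the clearance enters the covered region."""
            TH, AZ = np.meshgrid(ths, azs, indexing="ij")
            pts = (
                np.cos(TH)[..., None] * c_dir
                + (np.sin(TH) * np.cos(AZ))[..., None] * e1
                + (np.sin(TH) * np.sin(AZ))[..., None] * e2
            ).reshape(-1, 3)
            A = pts @ p - pw * (pts @ w)
            B = pts @ pxw
            C = pw * (pts @ w)
            Rm = np.hypot(A, B)
            with np.errstate(invalid="ignore", divide="ignore"):
                kk = (cos_tau - C) / Rm
            ok = (Rm > 1e-15) & (np.abs(kk) <= 1.0)
            if not ok.any():
                return np.inf, None
            delta = np.arctan2(B[ok], A[ok])
            base = np.arccos(np.clip(kk[ok], -1.0, 1.0))
            cand = np.stack(
                [delta + sgn * base + 2 * np.pi * cyc
                 for sgn in (1.0, -1.0) for cyc in (-1, 0, 1)]
            )
            cand = np.where(cand > 1e-9, cand, np.inf)
            per_pt = cand.min(axis=0)
            j = int(np.argmin(per_pt))
            az = AZ.reshape(-1)[np.nonzero(ok.reshape(-1))[0][j]]
            return float(per_pt[j]), float(az)

        if lift_of(0.0) >= spec.clearance:
            # boundary polar angle where the bump stops out-prouding the
            # clearance, by bisection of the sampled profile
            lo, hi = 0.0, th_max
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if lift_of(mid) >= spec.clearance:
                    lo = mid
                else:
                    hi = mid
            th_b = lo
            ths = np.unique(np.concatenate([
                np.linspace(0.0, th_b, 60),
                th_b - np.geomspace(1e-9, max(th_b / 30, 1e-8), 24),
            ]))
            ths = ths[ths >= 0]
            azs = np.linspace(0.0, 2 * np.pi, 1440, endpoint=False)
            best, az0 = first_entry(ths, azs)
            if az0 is not None:
                daz = 2 * np.pi / 1440
                azs2 = az0 + np.linspace(-daz, daz, 801)
                best2, _az = first_entry(ths, azs2)
                best = min(best, best2)
            if np.isfinite(best) and best <= np.radians(motion.bound):
                cam_phi = np.degrees(best)

    options = [x for x in (neck_phi, cam_phi) if x is not None]
    if not options:
        return OracleResult(motion.bound, "bound_reached", "none")
    best = min(options)
    mech = "neck" if best == neck_phi else "cam"
    return OracleResult(best, "impinged", mech)


def soft_envelope(radius: float = 75.0, center=(0.0, -10.0, 0.0)) -> TriangleMesh:
    """Soft-tissue background sphere for the synthetic CT.

    Embedding the bones in soft-tissue density (rather than air) puts the
    partial-volume mid-point of the bone boundary at the usual bone
    segmentation thresholds, as in a real scan.
    """
    tm = _trimesh.creation.icosphere(subdivisions=3, radius=radius)
    tm.apply_translation(np.asarray(center, dtype=float))
    return TriangleMesh(tm.vertices, tm.faces, "soft_tissue")


# ---------------------------------------------------------------------------
# synthetic CT: voxelization and segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTVolumeSpec:
    """Voxel grid and intensity model of the synthetic CT.

    Intensities are relative densities (bone 1.9 vs nylon 1.15 g/cm3),
    not calibrated Hounsfield units; ``hu_slope``/``hu_intercept`` give an
    optional linear density-to-HU map, off by default.
    """

    spacing: tuple = (0.265, 0.265, 1.0)
    air: float = 0.0
    soft_tissue: float = 1.0
    nylon: float = 1.15
    bone: float = 1.9
    extent: np.ndarray | None = None  # (2, 3) world bounds, mm
    supersample: int = 2
    hu_slope: float | None = None
    hu_intercept: float = 0.0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be positive")
        if not (self.bone > self.nylon > self.soft_tissue > self.air):
            raise ValidationError(
                "intensity model must order bone > nylon > soft tissue > air"
            )


@dataclass
class CTVolume:
    """Image volume with world geometry (x, y, z array order, mm)."""

    data: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray


def voxelize_ct(
    labeled_meshes: list[tuple[TriangleMesh, str]],
    spec: CTVolumeSpec | None = None,
) -> CTVolume:
    """Voxelize closed meshes into a CT-like intensity volume.

    Each voxel takes the intensity of the densest enclosing mesh (so a
    bone mesh nested inside a nylon cam shell keeps bone intensity and
    the cam mantle keeps nylon).  Anti-aliasing by ``supersample``-fold
    subdivision and block averaging yields partial-volume values at
    boundaries, which the segmentation stage exploits for sub-voxel
    surface recovery.
    """
    spec = spec or CTVolumeSpec()
    intensities = {
        "air": spec.air,
        "soft_tissue": spec.soft_tissue,
        "nylon": spec.nylon,
        "bone": spec.bone,
    }
    for mesh, mat in labeled_meshes:
        if mat not in intensities:
            raise ValidationError(f"unknown material {mat!r}")
        if not mesh.is_watertight:
            raise ValidationError(f"mesh {mesh.name!r} is not closed; cannot voxelize")

    spacing = np.asarray(spec.spacing, dtype=float)
    if spec.extent is None:
        lo = np.min([m.bounds[0] for m, _ in labeled_meshes], axis=0) - 3.0
        hi = np.max([m.bounds[1] for m, _ in labeled_meshes], axis=0) + 3.0
    else:
        lo, hi = np.asarray(spec.extent, dtype=float)
    dims = np.ceil((hi - lo) / spacing).astype(int)
    # irrational sub-voxel jitter: no voxel-center ray hits an edge exactly
    origin = lo + spacing * np.array([np.sqrt(2.0), np.sqrt(3.0), np.sqrt(5.0)]) * 1e-3

    f = int(spec.supersample)
    sdims = dims * f
    sspacing = spacing / f
    ranked = sorted(intensities.items(), key=lambda kv: kv[1])
    rank = {mat: i for i, (mat, _v) in enumerate(ranked)}
    lut = np.array([v for _m, v in ranked], dtype=np.float32)

    label = np.zeros(tuple(sdims), np.uint8)
    for mesh, mat in labeled_meshes:
        occ = rasterize_occupancy(mesh.triangles, origin, sspacing, sdims)
        np.maximum(label, occ.astype(np.uint8) * rank[mat], out=label)
    data = block_average(lut[label], f)
    if spec.hu_slope is not None:
        data = data * spec.hu_slope + spec.hu_intercept
    return CTVolume(data, origin, spacing)


def material_volume(ct: CTVolume, intensity: float) -> float:
    """Volume (mm^3) of a single material from its partial-volume field."""
    vox = float(np.prod(ct.spacing))
    return float(ct.data.sum()) * vox / intensity


def segment_volume(
    ct: CTVolume,
    bone_threshold: float = 1.5,
    nylon_band: tuple | None = None,
    iso_edge: float = 0.5,
    min_volume: float = 500.0,
) -> list[TriangleMesh]:
    """Threshold + marching-cubes segmentation into closed surface models.

    Bone is everything at or above ``bone_threshold``.  Passing a
    ``nylon_band`` (lo, hi) additionally includes voxels inside that
    intensity window, which reproduces the paired bone models with and
    without the artificial (nylon-density) cam from one scan.

    The intensity volume is resampled to an isotropic ``iso_edge`` grid
    (linear interpolation of the partial-volume field preserves sub-voxel
    surface position), converted to a signed indicator field, split into
    connected components and iso-surfaced per component.  Components
    below ``min_volume`` mm^3 (marker beads, specks) are discarded.
    Returns watertight meshes sorted by volume, largest first.
    """
    zoom = ct.spacing / iso_edge
    # cubic interpolation keeps the blurred partial-volume ramp sharp
    # enough for sub-voxel surface recovery at the rim edge
    vol = ndimage.zoom(ct.data.astype(np.float32), zoom, order=3)
    spacing = ct.spacing / zoom  # actual achieved spacing after rounding
    field = vol - bone_threshold
    if nylon_band is not None:
        lo, hi = nylon_band
        if not lo < hi:
            raise ValidationError("nylon_band must be (lo, hi) with lo < hi")
        band_field = np.minimum(vol - lo, hi - vol)
        # partial-volume averaging coats *every* bone surface with a thin
        # nylon-density skin; a one-voxel morphological opening keeps only
        # the thick nylon core (the cam mantle) while the signed field
        # preserves its sub-voxel boundary
        core = ndimage.binary_opening(
            band_field >= 0.0, structure=np.ones((3, 3, 3), bool)
        )
        keep = ndimage.binary_dilation(core, np.ones((3, 3, 3), bool), iterations=2)
        field = np.maximum(field, np.where(keep, band_field, -1.0))
    binary = field >= 0.0
    if not binary.any():
        raise ValidationError(f"empty segmentation at threshold {bone_threshold}")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), int))
    slices = ndimage.find_objects(labels)
    meshes = []
    vox = float(np.prod(spacing))
    for comp in range(1, n + 1):
        mask = labels == comp
        if mask.sum() * vox < min_volume:
            continue
        sl = slices[comp - 1]
        pad = tuple(slice(max(s.start - 2, 0), min(s.stop + 2, d))
                    for s, d in zip(sl, field.shape))
        sub = np.where(
            (labels[pad] == comp) | (labels[pad] == 0), field[pad], -1.0
        )
        sub = np.pad(sub, 1, constant_values=-1.0)
        verts, faces, _norm, _val = measure.marching_cubes(
            sub, level=0.0, spacing=tuple(spacing)
        )
        off = ct.origin + spacing * (np.array([p.start for p in pad]) - 1)
        tm = _trimesh.Trimesh(vertices=verts + off, faces=faces, process=True)
        tm.update_faces(tm.nondegenerate_faces())
        tm.remove_unreferenced_vertices()
        tm.fix_normals()
        if tm.volume < 0:
            tm.invert()
        meshes.append(TriangleMesh(tm.vertices, tm.faces, f"component_{comp}"))
    if not meshes:
        raise ValidationError("segmentation produced no component above min_volume")
    meshes.sort(key=lambda m: -abs(m.trimesh.volume))
    return meshes


def save_volume(ct: CTVolume, path) -> None:
    """Write NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) with geometry."""
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(ct.data.T))
    img.SetSpacing(tuple(float(s) for s in ct.spacing))
    img.SetOrigin(tuple(float(o) for o in ct.origin))
    sitk.WriteImage(img, str(path))
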