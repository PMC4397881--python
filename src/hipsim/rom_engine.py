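"""Pose parameterization and motion sweeps.

A joint pose is flexion / abduction / internal rotation (degrees) about
the ISB axes: flexion about the pelvic Z axis, abduction about the
pelvic X axis, internal rotation about the femoral long (Y) axis,
composed in that fixed order with the axial rotation intrinsic (about
the already-reoriented femoral axis).  All rotations pivot at the hip
center; a corrective translation of the femoral head of at most
``max_translation`` (3 mm by default) may be applied when a reorientation
collides, and the sweep halts — registering the impingement angle — when
no translation within the cap restores clearance.

Angle signs follow the clinical motion names for the given side: positive
flexion carries the thigh anteriorly, positive abduction laterally,
positive internal rotation turns the anterior thigh medially, for both
left and right hips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .anatomy_frames import AnatomicalFrame, HipCenter
from .mesh_core import (
    ContactQueryResult,
    PosedCollider,
    RigidTransform,
    TriangleMesh,
    ValidationError,
    resolve_translation,
)

__all__ = [
    "JointPose",
    "MotionDefinition",
    "ROMEndpoint",
    "SimulationConfig",
    "PoseStatus",
    "pose_to_transform",
    "check_pose",
    "find_endpoint",
    "simulate_standard_set",
    "standard_motions",
    "STANDARD_MOTIONS",
    "component_sign",
]

COMPONENTS = ("flexion", "abduction", "internal_rotation")

#: canonical labels of the six-motion examination set
STANDARD_MOTIONS = (
    "max_flexion",
    "max_abduction",
    "max_ir_0",
    "max_ir_30",
    "max_ir_60",
    "max_ir_90",
)


@dataclass(frozen=True)
class JointPose:
    """Hip pose in degrees plus the corrective head translation (mm)."""

    flexion: float = 0.0
    abduction: float = 0.0
    internal_rotation: float = 0.0
    correction: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(
            self, "correction", np.asarray(self.correction, dtype=float).reshape(3)
        )

    def component(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class MotionDefinition:
    """One clinically defined motion: sweep one component, fix the others."""

    label: str
    swept: str
    fixed: dict = field(default_factory=dict)
    start: float = 0.0
    bound: float = 90.0

    def __post_init__(self):
        if self.swept not in COMPONENTS:
            raise ValidationError(f"unknown motion component {self.swept!r}")
        for k, v in self.fixed.items():
            if k not in COMPONENTS or k == self.swept:
                raise ValidationError(f"invalid fixed component {k!r}")
            if not -30.0 <= v <= 120.0:
                raise ValidationError(f"fixed {k}={v} outside [-30, 120] degrees")
        if not self.bound > self.start:
            raise ValidationError("sweep bound must exceed start")

    def pose_at(self, angle: float) -> JointPose:
        kw = {c: 0.0 for c in COMPONENTS}
        kw.update(self.fixed)
        kw[self.swept] = angle
        return JointPose(**kw)


class PoseStatus(Enum):
    FREE = "free"
    RESOLVED = "resolved"
    IMPINGED = "impinged"


@dataclass(frozen=True)
class ROMEndpoint:
    """Registered end point of one simulated motion."""

    motion: MotionDefinition
    angle: float
    status: str  # "impinged" | "bound_reached"
    contact: ContactQueryResult | None = None
    correction_at_endpoint: np.ndarray = field(default_factory=lambda: np.zeros(3))
    start_blocked: bool = False


@dataclass(frozen=True)
class SimulationConfig:
    """Tunable simulation parameters (mm / degrees)."""

    max_translation: float = 3.0
    contact_tolerance: float = 0.1
    angle_resolution: float = 0.1
    coarse_step: float = 2.0
    rotation_order: tuple = COMPONENTS
    flexion_bound: float = 150.0
    abduction_bound: float = 90.0
    internal_rotation_bound: float = 90.0

    def __post_init__(self):
        if self.contact_tolerance < 0 or self.max_translation < 0:
            raise ValidationError("tolerances must be non-negative")
        if not 0 < self.angle_resolution <= self.coarse_step:
            raise ValidationError("require 0 < angle_resolution <= coarse_step")
        if tuple(sorted(self.rotation_order)) != tuple(sorted(COMPONENTS)):
            raise ValidationError("rotation_order must permute the three components")

    def bound(self, component: str) -> float:
        return {
            "flexion": self.flexion_bound,
            "abduction": self.abduction_bound,
            "internal_rotation": self.internal_rotation_bound,
        }[component]


def standard_motions(config: SimulationConfig | None = None) -> list[MotionDefinition]:
    """The six-motion set: max flexion, max abduction, max internal
    rotation at 0/30/60/90 degrees of flexion."""
    cfg = config or SimulationConfig()
    out = [
        MotionDefinition("max_flexion", "flexion", {}, 0.0, cfg.bound("flexion")),
        MotionDefinition("max_abduction", "abduction", {}, 0.0, cfg.bound("abduction")),
    ]
    for flex in (0.0, 30.0, 60.0, 90.0):
        out.append(
            MotionDefinition(
                f"max_ir_{int(flex)}",
                "internal_rotation",
                {"flexion": flex} if flex else {},
                0.0,
                cfg.bound("internal_rotation"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pose -> rigid transform
# ---------------------------------------------------------------------------


def component_sign(component: str, side: str) -> float:
    """Sign mapping clinical positive angles onto right-handed rotations
    about the ISB axes (pelvis Z points toward the subject's right)."""
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    if component == "flexion":
        return 1.0
    if component == "abduction":
        return -1.0 if side == "right" else 1.0
    if component == "internal_rotation":
        return 1.0 if side == "right" else -1.0
    raise ValidationError(f"unknown component {component!r}")


def pose_to_transform(
    pose: JointPose,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    hip_center: HipCenter,
    side: str = "right",
    rotation_order: tuple = COMPONENTS,
) -> RigidTransform:
    """World transform moving the neutral femur into the given pose.

    Rotations compose in ``rotation_order`` (default flexion about pelvis
    Z, then abduction about pelvis X, then intrinsic axial rotation about
    the reoriented femoral Y), all pivoting at the hip center; the
    corrective translation is added last.
    """
    center = hip_center.center
    R = np.eye(3)
    for comp in rotation_order:
        ang = component_sign(comp, side) * pose.component(comp)
        if comp == "flexion":
            axis = pelvis_frame.z
        elif comp == "abduction":
            axis = pelvis_frame.x
        else:  # intrinsic: current femoral long axis
            axis = R @ femur_frame.y
        R = RigidTransform.from_axis_angle(axis, ang).rotation @ R
    T = RigidTransform(R, center - R @ center)
    return RigidTransform(T.rotation, T.translation + pose.correction)


# ---------------------------------------------------------------------------
# pose checking and end-point search
# ---------------------------------------------------------------------------


@dataclass
class _SimContext:
    """Bundles the meshes, frames and reusable collider of one hip."""

    femur: TriangleMesh
    pelvis: TriangleMesh
    pelvis_frame: AnatomicalFrame
    femur_frame: AnatomicalFrame
    hip_center: HipCenter
    side: str
    config: SimulationConfig
    collider: PosedCollider = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.collider is None:
            self.collider = PosedCollider(self.pelvis, self.femur)

    def set_pose(self, pose: JointPose) -> RigidTransform:
        T = pose_to_transform(
            pose, self.pelvis_frame, self.femur_frame, self.hip_center,
            self.side, self.config.rotation_order,
        )
        self.collider.set_pose(T)
        return T


def check_pose(pose: JointPose, ctx: _SimContext):
    """Classify a pose: free, resolved (with its correction), or impinged."""
    cfg = ctx.config
    ctx.set_pose(pose)
    if not ctx.collider.colliding(tolerance=cfg.contact_tolerance):
        return PoseStatus.FREE, np.zeros(3)
    if cfg.max_translation <= 0:
        return PoseStatus.IMPINGED, None
    t = resolve_translation(
        ctx.pelvis, ctx.femur, cfg.max_translation, cfg.contact_tolerance,
        collider=ctx.collider,
    )
    if t is None:
        return PoseStatus.IMPINGED, None
    return PoseStatus.RESOLVED, t


def find_endpoint(motion: MotionDefinition, ctx: _SimContext) -> ROMEndpoint:
    """Largest collision-free (or translation-resolved) angle of a motion.

    Coarse sweep at ``coarse_step`` followed by bisection on the
    ``angle_resolution`` grid, so the returned angle is the largest
    checked grid angle that is free/resolved while one resolution step
    further impinges (unless the bound is reached).
    """
    cfg = ctx.config
    res = cfg.angle_resolution
    n_total = int(round((motion.bound - motion.start) / res))
    coarse = max(int(round(cfg.coarse_step / res)), 1)

    status0, corr0 = check_pose(motion.pose_at(motion.start), ctx)
    if status0 is PoseStatus.IMPINGED:
        contact = _contact_at(motion.start, motion, ctx)
        return ROMEndpoint(motion, motion.start, "impinged", contact,
                           np.zeros(3), start_blocked=True)

    lo, lo_corr = 0, corr0  # grid index of last good angle
    hi = None  # grid index of first impinged angle
    k = coarse
    while k <= n_total:
        ang = motion.start + k * res
        status, corr = check_pose(motion.pose_at(ang), ctx)
        if status is PoseStatus.IMPINGED:
            hi = k
            break
        lo, lo_corr = k, corr
        k += coarse
    if hi is None:
        if lo < n_total:  # bound not on the coarse grid
            status, corr = check_pose(motion.pose_at(motion.bound), ctx)
            if status is PoseStatus.IMPINGED:
                hi = n_total
            else:
                lo, lo_corr = n_total, corr
        if hi is None:
            return ROMEndpoint(motion, motion.bound, "bound_reached", None,
                               lo_corr if lo_corr is not None else np.zeros(3))
    while hi - lo > 1:
        mid = (hi + lo) // 2
        status, corr = check_pose(motion.pose_at(motion.start + mid * res), ctx)
        if status is PoseStatus.IMPINGED:
            hi = mid
        else:
            lo, lo_corr = mid, corr
    angle = motion.start + lo * res
    contact = _contact_at(motion.start + hi * res, motion, ctx)
    return ROMEndpoint(motion, angle, "impinged", contact,
                       lo_corr if lo_corr is not None else np.zeros(3))


def _contact_at(angle: float, motion: MotionDefinition, ctx: _SimContext):
    """Full contact query (with witness pairs) at the first impinged pose."""
    ctx.set_pose(motion.pose_at(angle))
    pc = ctx.collider
    tol = ctx.config.contact_tolerance
    d, bi, bj, nc, nx, _ov = pc.raw_query((0.0, 0.0, 0.0), tol, 1e12)
    pairs = (
        np.stack([pc._pi[:nc], pc._pj[:nc]], axis=1)
        if nc else np.empty((0, 2), np.int64)
    )
    xpairs = (
        np.stack([pc._xi[:nx], pc._xj[:nx]], axis=1)
        if nx else np.empty((0, 2), np.int64)
    )
    if nx > 0:
        depth, _g = pc._penetration(np.zeros(3), int(pc._xi[0]))
        d = -depth
    # witness pairs are (pelvis face, femur face) in collider order; report
    # them femur-first to match the femur/pelvis argument convention
    return ContactQueryResult(
        colliding=nx > 0,
        min_distance=float(d),
        witness_pairs=pairs[:, ::-1].copy(),
        pair_distances=pc._pd[:nc].copy(),
        crossing_pairs=xpairs[:, ::-1].copy(),
    )


def make_context(
    femur: TriangleMesh,
    pelvis: TriangleMesh,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    hip_center: HipCenter,
    side: str = "right",
    config: SimulationConfig | None = None,
) -> _SimContext:
    return _SimContext(
        femur, pelvis, pelvis_frame, femur_frame, hip_center, side,
        config or SimulationConfig(),
    )


def simulate_standard_set(
    femur: TriangleMesh,
    pelvis: TriangleMesh,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    hip_center: HipCenter,
    side: str = "right",
    config: SimulationConfig | None = None,
    motions: list[MotionDefinition] | None = None,
) -> dict[str, ROMEndpoint]:
    """Endpoints of the six standard motions (deterministic)."""
    cfg = config or SimulationConfig()
    ctx = make_context(femur, pelvis, pelvis_frame, femur_frame, hip_center, side, cfg)
    out = {}
    for motion in motions if motions is not None else standard_motions(cfg):
        out[motion.label] = find_endpoint(motion, ctx)
    return out
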