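"""Anatomical coordinate systems, hip-center fitting and fiducial
registration.

Frames follow the International Society of Biomechanics conventions for
the pelvis (Z toward the subject's right along the inter-ASIS line, X
anterior, Y superior) and femur (Y along the shaft toward the hip
center).  The ``side`` flag controls the left/right axis signs so that
both hips produce right-handed frames with Z toward the subject's right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .mesh_core import RigidTransform, TriangleMesh, ValidationError

__all__ = [
    "LandmarkSet",
    "AnatomicalFrame",
    "HipCenter",
    "pelvis_frame",
    "femur_frame",
    "fit_hip_center",
    "register_point_sets",
    "load_landmarks",
    "save_landmarks",
]

PELVIS_LANDMARKS = ("ASIS_left", "ASIS_right", "PSIS_mid")
FEMUR_LANDMARKS = ("epicondyle_medial", "epicondyle_lateral")


@dataclass
class LandmarkSet:
    """Named anatomical points plus ordered registration fiducials (mm)."""

    side: str
    landmarks: dict = field(default_factory=dict)
    fiducials: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")
        self.landmarks = {
            k: np.asarray(v, dtype=float).reshape(3)
            for k, v in self.landmarks.items()
        }
        self.fiducials = np.asarray(self.fiducials, dtype=float).reshape(-1, 3)
        pts = list(self.landmarks.values())
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if np.allclose(pts[i], pts[j]):
                    names = list(self.landmarks)
                    raise ValidationError(
                        f"landmarks {names[i]} and {names[j]} coincide"
                    )

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.landmarks]
        if missing:
            raise ValidationError(f"missing landmarks: {missing}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.landmarks[name]

    def transformed(self, T: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            self.side,
            {k: T.apply(v) for k, v in self.landmarks.items()},
            T.apply(self.fiducials) if len(self.fiducials) else self.fiducials,
        )


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus right-handed orthonormal axes (unit vectors, world mm)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x", "y", "z"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        M = np.stack([self.x, self.y, self.z])
        if np.abs(M @ M.T - np.eye(3)).max() > 1e-9:
            raise ValidationError("frame axes not orthonormal")
        if np.linalg.norm(np.cross(self.x, self.y) - self.z) > 1e-9:
            raise ValidationError("frame axes not right-handed (x cross y != z)")

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes: maps frame coords to world coords."""
        return np.stack([self.x, self.y, self.z], axis=1)

    def as_transform(self) -> RigidTransform:
        return RigidTransform(self.rotation, self.origin)

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation

    def transformed(self, T: RigidTransform) -> "AnatomicalFrame":
        R = T.rotation
        return AnatomicalFrame(T.apply(self.origin), R @ self.x, R @ self.y, R @ self.z)


@dataclass(frozen=True)
class HipCenter:
    """Hip rotation center from the femoral-head sphere fit (mm)."""

    center: np.ndarray
    head_radius: float
    fit_rms: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.head_radius > 0:
            raise ValidationError("head_radius must be > 0")
        if self.fit_rms < 0:
            raise ValidationError("fit_rms must be >= 0")


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError(f"degenerate frame: {what} has zero length")
    return v / n


def _orthonormalize(x, y, z, origin) -> AnatomicalFrame:
    # tighten to the 1e-9 budget via one Gram-Schmidt pass
    z = z / np.linalg.norm(z)
    x = x - (x @ z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return AnatomicalFrame(origin, x, y, z)


def pelvis_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """ISB pelvic frame from bilateral ASIS and a posterior midline point.

    Z runs from the left to the right ASIS, X points anteriorly within the
    plane of the two ASIS and the posterior point, Y = Z x X is superior.
    Origin is the ASIS midpoint.
    """
    landmarks.require(PELVIS_LANDMARKS)
    asis_l = landmarks["ASIS_left"]
    asis_r = landmarks["ASIS_right"]
    psis = landmarks["PSIS_mid"]
    origin = 0.5 * (asis_l + asis_r)
    z = _unit(asis_r - asis_l, "inter-ASIS line")
    anterior = origin - psis
    x = anterior - (anterior @ z) * z
    if np.linalg.norm(x) < 1e-9 * max(np.linalg.norm(anterior), 1.0):
        raise ValidationError("degenerate frame: PSIS_mid lies on the ASIS line")
    x = _unit(x, "anterior axis")
    y = np.cross(z, x)
    return _orthonormalize(x, y, z, origin)


def femur_frame(landmarks: LandmarkSet, hip_center: HipCenter) -> AnatomicalFrame:
    """ISB femoral frame: Y along the shaft axis (epicondyle midpoint to hip
    center), Z toward the subject's right in the epicondylar plane.

    Internal/external rotation is the axial rotation about this Y axis.
    """
    landmarks.require(FEMUR_LANDMARKS)
    med = landmarks["epicondyle_medial"]
    lat = landmarks["epicondyle_lateral"]
    if np.allclose(med, lat):
        raise ValidationError("epicondyles coincide")
    origin = hip_center.center
    y = _unit(origin - 0.5 * (med + lat), "femoral long axis")
    across = lat - med if landmarks.side == "right" else med - lat
    z = across - (across @ y) * y
    if np.linalg.norm(z) < 1e-9 * np.linalg.norm(across):
        raise ValidationError("degenerate frame: epicondylar line parallel to shaft")
    z = _unit(z, "epicondylar axis")
    x = np.cross(y, z)
    return _orthonormalize(x, np.cross(z, x), z, origin)


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------


def _sphere_fit(points: np.ndarray):
    """Algebraic least-squares sphere fit (exact on noiseless data)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = (points**2).sum(axis=1)
    sol, _res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise ValidationError("sphere fit degenerate: points (nearly) coplanar")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValidationError("sphere fit produced non-positive radius")
    return center, float(np.sqrt(r2))


def fit_hip_center(
    head_surface, cup_surface: TriangleMesh | None = None
) -> HipCenter:
    """Hip rotation center from the femoral head surface.

    A least-squares sphere is fitted to the head sample; when an
    acetabular surface is supplied the center is refined so the
    head-to-cup clearance is as uniform as possible over the covered
    directions (the equidistant criterion), starting from the sphere-fit
    center.
    """
    if isinstance(head_surface, TriangleMesh):
        pts = head_surface.vertices
    else:
        pts = np.asarray(head_surface, dtype=float).reshape(-1, 3)
    if len(pts) < 10:
        raise ValidationError("need at least 10 head-surface points")
    center, radius = _sphere_fit(pts)

    if cup_surface is not None:
        q = cup_surface.vertices
        # inner-shell sample: cup points within ~half a radius of the head
        d = np.linalg.norm(q - center, axis=1)
        sel = q[d < radius * 1.5]
        if len(sel) >= 10:
            def residuals(x):
                g = np.linalg.norm(sel - x, axis=1)
                return g - g.mean()

            out = least_squares(residuals, center, method="lm")
            center = out.x
        r_dir = np.linalg.norm(pts - center, axis=1)
        radius = float(r_dir.mean())

    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return HipCenter(center, radius, rms)


# ---------------------------------------------------------------------------
# fiducial registration
# ---------------------------------------------------------------------------


def register_point_sets(source: np.ndarray, target: np.ndarray):
    """Least-squares rigid registration (no scaling) of ordered point sets.

    Returns ``(RigidTransform, fre)`` where FRE is the root-mean-square
    fiducial registration error of the mapped source against the target.
    """
    src = np.asarray(source, dtype=float).reshape(-1, 3)
    tgt = np.asarray(target, dtype=float).reshape(-1, 3)
    if len(src) != len(tgt):
        raise ValidationError("source/target correspondence count mismatch")
    if len(src) < 3:
        raise ValidationError("need at least 3 correspondences")
    sc = src.mean(axis=0)
    tc = tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    u, s, vt = np.linalg.svd(H)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValidationError("registration degenerate: points (nearly) collinear")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(vt.T @ u.T))
    R = vt.T @ D @ u.T
    t = tc - R @ sc
    T = RigidTransform(R, t)
    fre = float(np.sqrt(np.mean(np.sum((T.apply(src) - tgt) ** 2, axis=1))))
    return T, fre


# ---------------------------------------------------------------------------
# landmark JSON I/O
# ---------------------------------------------------------------------------


def load_landmarks(path) -> LandmarkSet:
    """Read the landmark JSON schema: side, named landmarks, fiducials."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        return LandmarkSet(
            side=data["side"],
            landmarks=data.get("landmarks", {}),
            fiducials=np.asarray(data.get("fiducials", []), dtype=float).reshape(-1, 3),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed landmark file {path}: {exc}") from exc


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    data = {
        "side": landmarks.side,
        "landmarks": {k: list(map(float, v)) for k, v in landmarks.landmarks.items()},
        "fiducials": [list(map(float, p)) for p in landmarks.fiducials],
    }
    Path(path).write_text(json.dumps(data, indent=2))
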