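"""Geometry kernel: mesh I/O, rigid transforms, contact queries and the
bounded penetration-resolving translation.

All lengths are millimetres, all angles degrees at API boundaries.  Meshes
are treated as immutable: every operation returns a new
:class:`TriangleMesh` and caches (AABB tree, trimesh view) are built
lazily per instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from ._kernels import (
    _brute_min_distance,
    _pair_query,
    _points_query,
    _refit,
    _winding_numbers,
    build_bvh,
)

log = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "TriangleMesh",
    "RigidTransform",
    "ContactQueryResult",
    "load_mesh",
    "save_mesh",
    "validate_mesh",
    "transform_mesh",
    "query_contact",
    "resolve_translation",
    "exhaustive_min_distance",
    "contains_points",
    "PosedCollider",
]


class ValidationError(ValueError):
    """Input violates a documented precondition."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R @ x + t (millimetres)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("transform contains non-finite values")
        err = np.abs(R @ R.T - np.eye(3)).max()
        if err > 1e-9:
            raise ValidationError(f"rotation not orthonormal (error {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation has determinant -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=None) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` through ``center``."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValidationError("rotation axis must be nonzero")
        axis = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        R = np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
        # renormalize to keep the 1e-9 orthonormality budget over compositions
        u, _s, vt = np.linalg.svd(R)
        R = u @ vt
        if center is None:
            t = np.zeros(3)
        else:
            c = np.asarray(center, dtype=float)
            t = c - R @ c
        return cls(R, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        """Composition: (self @ other)(x) == self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def matrix4(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M


# ---------------------------------------------------------------------------
# triangle meshes
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangulated bone surface in millimetres."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValidationError("faces must be (m, 3)")
        if len(f) == 0 or len(v) == 0:
            raise ValidationError("mesh is empty")
        if not np.all(np.isfinite(v)):
            raise ValidationError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise ValidationError("face index out of range")
        self.vertices = v
        self.faces = f

    # -- lazy derived data ---------------------------------------------------

    @property
    def trimesh(self) -> _trimesh.Trimesh:
        if "tm" not in self._cache:
            self._cache["tm"] = _trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._cache["tm"]

    @property
    def triangles(self) -> np.ndarray:
        if "tris" not in self._cache:
            self._cache["tris"] = np.ascontiguousarray(
                self.vertices[self.faces]
            )
        return self._cache["tris"]

    @property
    def bvh(self) -> dict:
        if "bvh" not in self._cache:
            self._cache["bvh"] = build_bvh(self.triangles)
        return self._cache["bvh"]

    @property
    def vertex_neighbors(self) -> list:
        if "vadj" not in self._cache:
            adj = [[] for _ in range(len(self.vertices))]
            for a, b, c in self.faces:
                adj[a].extend((b, c))
                adj[b].extend((a, c))
                adj[c].extend((a, b))
            self._cache["vadj"] = [np.unique(x) for x in adj]
        return self._cache["vadj"]

    @property
    def is_watertight(self) -> bool:
        return bool(self.trimesh.is_watertight)

    @property
    def volume(self) -> float:
        return float(self.trimesh.volume)

    @property
    def face_areas(self) -> np.ndarray:
        return self.trimesh.area_faces

    @property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.trimesh.vertex_normals)

    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self, name: str | None = None) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), name or self.name
        )

    def surface_distance(self, points: np.ndarray):
        """Unsigned distance, closest point and face index per query point."""
        pts = np.ascontiguousarray(np.atleast_2d(points).astype(np.float64))
        b = self.bvh
        return _points_query(
            pts, b["nmin"], b["nmax"], b["left"], b["right"], b["start"],
            b["count"], b["order"], b["tris"],
        )


def contains_points(mesh: TriangleMesh, points: np.ndarray) -> np.ndarray:
    """Inside test by generalized winding number (requires a closed mesh)."""
    pts = np.ascontiguousarray(np.atleast_2d(points).astype(np.float64))
    w = _winding_numbers(pts, mesh.triangles)
    return w > 0.5


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

_SUPPORTED = {".stl", ".ply", ".obj"}


def load_mesh(path, units: float = 1.0, name: str | None = None) -> TriangleMesh:
    """Load an STL/PLY/OBJ surface and scale coordinates by ``units`` to mm.

    Degenerate (zero-area) faces are dropped here, once, and reported in a
    structured log record — never silently mid-pipeline.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValidationError(f"unsupported mesh format: {path.suffix}")
    try:
        tm = _trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - corrupt file paths vary
        raise IOError(f"unreadable mesh file {path}: {exc}") from exc
    if tm.faces.shape[0] == 0:
        raise ValidationError(f"{path} contains no faces")
    tm.merge_vertices()  # STL stores triangle soup; restore shared topology
    n_before = len(tm.faces)
    keep = tm.nondegenerate_faces()
    tm.update_faces(keep)
    tm.remove_unreferenced_vertices()
    n_dropped = n_before - len(tm.faces)
    if len(tm.faces) == 0:
        raise ValidationError(f"{path}: no faces left after dropping degenerates")
    mesh = TriangleMesh(
        np.asarray(tm.vertices, dtype=float) * float(units),
        np.asarray(tm.faces),
        name or path.stem,
    )
    log.info(
        "loaded mesh",
        extra={
            "mesh_path": str(path),
            "n_faces": len(mesh.faces),
            "faces_dropped": int(n_dropped),
            "watertight": mesh.is_watertight,
        },
    )
    return mesh


def save_mesh(mesh: TriangleMesh, path) -> None:
    """Write STL (binary), PLY or OBJ by file extension."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise ValidationError(f"unsupported mesh format: {path.suffix}")
    mesh.trimesh.export(str(path))


@dataclass(frozen=True)
class MeshValidation:
    watertight: bool
    winding_consistent: bool
    volume: float
    n_degenerate: int

    @property
    def ok(self) -> bool:
        return self.watertight and self.winding_consistent and self.volume > 0


def validate_mesh(mesh: TriangleMesh) -> MeshValidation:
    tm = mesh.trimesh
    areas = tm.area_faces
    return MeshValidation(
        watertight=bool(tm.is_watertight),
        winding_consistent=bool(tm.is_winding_consistent),
        volume=float(tm.volume) if tm.is_watertight else float("nan"),
        n_degenerate=int((areas <= 0).sum()),
    )


def transform_mesh(mesh: TriangleMesh, T: RigidTransform) -> TriangleMesh:
    """Apply a rigid transform; topology unchanged, volume preserved."""
    return TriangleMesh(T.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


# ---------------------------------------------------------------------------
# contact queries
# ---------------------------------------------------------------------------


@dataclass
class ContactQueryResult:
    """Outcome of a surface-to-surface contact query.

    ``min_distance`` is the minimal surface separation when the meshes are
    disjoint, and the *negative* of a penetration-depth estimate (maximum
    depth of penetrating vertices, see methods note) when they collide.
    """

    colliding: bool
    min_distance: float
    witness_pairs: np.ndarray  # (k, 2) face index pairs within tolerance
    pair_distances: np.ndarray  # (k,)
    crossing_pairs: np.ndarray  # (c, 2) interpenetrating face pairs
    witness_point_a: np.ndarray | None = None
    witness_point_b: np.ndarray | None = None
    deepest_point: np.ndarray | None = None
    deepest_target: np.ndarray | None = None


class PosedCollider:
    """Re-usable contact query between a fixed and a re-posable mesh.

    The moving mesh's tree topology is built once; each pose only rotates
    the triangle array and refits the node boxes, and pure translations
    are folded into the traversal, so per-pose cost stays low across a
    sweep.
    """

    _PAIR_CAP = 262144

    def __init__(self, fixed: TriangleMesh, moving: TriangleMesh):
        self.fixed = fixed
        self.moving = moving
        self._fb = fixed.bvh
        base = moving.bvh
        # private copy: refit mutates the boxes
        self._mb = {
            "nmin": base["nmin"].copy(),
            "nmax": base["nmax"].copy(),
            "left": base["left"],
            "right": base["right"],
            "start": base["start"],
            "count": base["count"],
            "order": base["order"],
            "tris": base["tris"].copy(),
        }
        self._base_tris = moving.triangles
        self._pose = RigidTransform.identity()
        self._pi = np.empty(self._PAIR_CAP, np.int64)
        self._pj = np.empty(self._PAIR_CAP, np.int64)
        self._pd = np.empty(self._PAIR_CAP, np.float64)
        self._xi = np.empty(self._PAIR_CAP, np.int64)
        self._xj = np.empty(self._PAIR_CAP, np.int64)

    def set_pose(self, T: RigidTransform) -> None:
        """Rotate/translate the moving mesh and refit its tree."""
        self._pose = T
        tris = self._mb["tris"]
        np.einsum("ij,nvj->nvi", T.rotation, self._base_tris, out=tris)
        tris += T.translation
        _refit(
            self._mb["nmin"], self._mb["nmax"], self._mb["left"],
            self._mb["right"], self._mb["start"], self._mb["count"],
            self._mb["order"], tris,
        )

    @property
    def posed_triangles(self) -> np.ndarray:
        return self._mb["tris"]

    def raw_query(self, offset=(0.0, 0.0, 0.0), tolerance: float = 0.1,
                  distance_cap: float = 1e12):
        fb, mb = self._fb, self._mb
        return _pair_query(
            fb["nmin"], fb["nmax"], fb["left"], fb["right"], fb["start"],
            fb["count"], fb["order"], fb["tris"],
            mb["nmin"], mb["nmax"], mb["left"], mb["right"], mb["start"],
            mb["count"], mb["order"], mb["tris"],
            np.asarray(offset, dtype=np.float64), float(tolerance),
            float(distance_cap), self._pi, self._pj, self._pd,
            self._xi, self._xj,
        )

    def colliding(self, offset=(0.0, 0.0, 0.0), tolerance: float = 0.1) -> bool:
        _d, _i, _j, _nc, nx, _ov = self.raw_query(offset, tolerance, 2.0 * tolerance + 0.5)
        return nx > 0

    def signed_clearance(self, offset=(0.0, 0.0, 0.0), tolerance: float = 0.1,
                         distance_cap: float = 2.0):
        """min surface distance (capped), negative penetration if colliding.

        Returns (value, gradient_direction) where the direction is the unit
        vector along which translating the *moving* mesh increases the
        active clearance/depth (a subgradient of the min-clearance
        objective).
        """
        d, bi, bj, _nc, nx, _ov = self.raw_query(offset, tolerance, distance_cap)
        off = np.asarray(offset, dtype=np.float64)
        if nx > 0:
            depth, grad = self._penetration(off, int(self._xi[0]))
            return -depth, grad
        if bi < 0:  # nothing below the cap
            return d, None
        # recompute the witness pair closest points for the gradient
        from ._kernels import _tri_tri_closest

        ta = self._fb["tris"][bi]
        tb = self._mb["tris"][bj] + off
        _dd, p1x, p1y, p1z, p2x, p2y, p2z = _tri_tri_closest(
            ta[0, 0], ta[0, 1], ta[0, 2], ta[1, 0], ta[1, 1], ta[1, 2],
            ta[2, 0], ta[2, 1], ta[2, 2],
            tb[0, 0], tb[0, 1], tb[0, 2], tb[1, 0], tb[1, 1], tb[1, 2],
            tb[2, 0], tb[2, 1], tb[2, 2],
        )
        g = np.array([p2x - p1x, p2y - p1y, p2z - p1z])
        n = np.linalg.norm(g)
        return d, (g / n if n > 0 else None)

    # -- penetration depth estimate ------------------------------------------

    def _penetration(self, off: np.ndarray, seed_moving_face: int):
        """Max depth of penetrating vertices (both directions).

        Flood-fills the penetrating vertex region outward from the crossing
        faces; cheap and adequate for the shallow bone-on-bone overlaps the
        simulation produces (documented as an estimate, not exact depth).
        """
        nx = int(self.raw_query(off, 0.0, 0.05)[4])
        mov_faces = np.unique(self._xj[:nx]) if nx > 0 else np.array([seed_moving_face])
        fix_faces = np.unique(self._xi[:nx]) if nx > 0 else np.array([], dtype=np.int64)

        best_depth = 0.0
        best_point = None
        best_target = None
        sign = 1.0

        # moving vertices inside the fixed mesh
        mv = self._pose.apply(self.moving.vertices) + off
        d1, p1, g1 = self._flood_depth(
            self.moving, mv, mov_faces, self.fixed.triangles, self._fb,
        )
        if d1 > best_depth:
            best_depth, best_point, best_target = d1, p1, g1
        # fixed vertices inside the moving mesh: equivalent to querying the
        # fixed vertices shifted by -off against the already-refit posed tree
        if len(fix_faces):
            d2, p2, g2 = self._flood_depth(
                self.fixed, self.fixed.vertices - off, fix_faces,
                self._mb["tris"], self._mb,
            )
            if d2 > best_depth:
                best_depth, best_point, best_target = d2, g2, p2
                sign = -1.0
        if best_point is None or best_target is None:
            return 0.0, None
        g = np.asarray(best_target) - np.asarray(best_point)
        g *= sign
        n = np.linalg.norm(g)
        return best_depth, (g / n if n > 0 else None)

    @staticmethod
    def _flood_depth(mesh: TriangleMesh, verts: np.ndarray,
                     seed_faces: np.ndarray, other_tris: np.ndarray,
                     other_bvh: dict):
        adj = mesh.vertex_neighbors
        seeds = np.unique(mesh.faces[seed_faces].ravel())
        visited = set()
        inside_pts = []
        frontier = list(seeds)
        while frontier:
            batch = np.array([v for v in frontier if v not in visited], dtype=np.int64)
            frontier = []
            if len(batch) == 0:
                break
            visited.update(batch.tolist())
            w = _winding_numbers(np.ascontiguousarray(verts[batch]), other_tris)
            ins = batch[w > 0.5]
            for v in ins:
                inside_pts.append(verts[v])
                for nb in adj[v]:
                    if nb not in visited:
                        frontier.append(int(nb))
            if len(visited) > 4000:  # deep overlap: estimate is enough
                break
        if not inside_pts:
            return 0.0, None, None
        pts = np.ascontiguousarray(np.array(inside_pts))
        b = other_bvh
        dist, closest, _f = _points_query(
            pts, b["nmin"], b["nmax"], b["left"], b["right"], b["start"],
            b["count"], b["order"], b["tris"],
        )
        k = int(np.argmax(dist))
        return float(dist[k]), pts[k], closest[k]


def query_contact(
    meshA: TriangleMesh,
    meshB: TriangleMesh,
    tolerance: float = 0.1,
    require_closed: bool = True,
) -> ContactQueryResult:
    """Collision / clearance query between two meshes.

    ``colliding`` is true iff any triangle pair intersects or one closed
    mesh contains the other; ``min_distance`` is the exact minimal
    surface-to-surface distance when disjoint and the negative of the
    penetration-depth estimate when colliding.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    pc = PosedCollider(meshA, meshB)
    d, bi, bj, nc, nx, ov = pc.raw_query((0.0, 0.0, 0.0), tolerance, 1e12)
    if ov:
        log.warning("contact query overflowed its pair buffers; results truncated")
    pairs = np.stack([pc._pi[:nc], pc._pj[:nc]], axis=1) if nc else np.empty((0, 2), np.int64)
    dists = pc._pd[:nc].copy()
    xpairs = np.stack([pc._xi[:nx], pc._xj[:nx]], axis=1) if nx else np.empty((0, 2), np.int64)

    colliding = nx > 0
    if not colliding:
        # containment: only meaningful against a closed mesh
        a_closed = meshA.is_watertight
        b_closed = meshB.is_watertight
        if not a_closed and not b_closed:
            if require_closed:
                raise ValidationError(
                    "containment test requires at least one watertight mesh"
                )
        else:
            if a_closed and contains_points(meshA, meshB.vertices[:1])[0]:
                colliding = True
            elif b_closed and contains_points(meshB, meshA.vertices[:1])[0]:
                colliding = True
            if colliding:
                # fully nested: depth = max distance of contained vertices
                inner, outer = (
                    (meshB, meshA)
                    if a_closed and contains_points(meshA, meshB.vertices[:1])[0]
                    else (meshA, meshB)
                )
                dist, _c, _f = outer.surface_distance(inner.vertices)
                return ContactQueryResult(
                    True, -float(dist.max()), pairs, dists, xpairs,
                )
    if colliding:
        depth, _grad = pc._penetration(np.zeros(3), int(pc._xi[0]) if nx else 0)
        return ContactQueryResult(True, -float(depth), pairs, dists, xpairs)
    return ContactQueryResult(False, float(d), pairs, dists, xpairs)


def exhaustive_min_distance(meshA: TriangleMesh, meshB: TriangleMesh) -> float:
    """Brute-force all-pairs surface distance (small-mesh oracle)."""
    return float(_brute_min_distance(meshA.triangles, meshB.triangles))


# ---------------------------------------------------------------------------
# bounded penetration-resolving translation
# ---------------------------------------------------------------------------

_AXIS_DIRS = np.array(
    [
        [1.0, 0, 0], [-1.0, 0, 0],
        [0, 1.0, 0], [0, -1.0, 0],
        [0, 0, 1.0], [0, 0, -1.0],
    ]
)


def resolve_translation(
    fixed: TriangleMesh,
    moving: TriangleMesh,
    max_norm: float = 3.0,
    tolerance: float = 0.1,
    collider: PosedCollider | None = None,
):
    """Find a translation of ``moving`` (|t| <= max_norm) that clears contact.

    The objective operationalizes the equidistant criterion: maximize the
    minimal surface clearance over the translation ball, by deterministic
    multi-start line searches (penetration-extraction direction plus the six
    axis directions) followed by a subgradient polish.

    Returns the translation vector, ``zeros`` for an already-clear input,
    or ``None`` when no translation within the cap reaches a clearance of
    ``tolerance`` (the "unresolvable" outcome that halts a simulated
    motion).
    """
    if max_norm <= 0:
        raise ValidationError("max_norm must be > 0")
    pc = collider if collider is not None else PosedCollider(fixed, moving)
    cap = max(4.0 * tolerance, 1.0)

    f0, g0 = pc.signed_clearance((0.0, 0.0, 0.0), tolerance, cap)
    was_colliding = f0 < 0
    if not was_colliding and f0 >= tolerance:
        return np.zeros(3)
    # a translation can raise the minimal clearance by at most its norm
    if f0 + max_norm < tolerance:
        return None if was_colliding else np.zeros(3)

    def f(t):
        v, g = pc.signed_clearance(t, tolerance, cap)
        return v, g

    best_t = np.zeros(3)
    best_f = f0
    # stage 1: line search along the extraction/witness direction; stop
    # once the clearance starts falling again (pushing further only
    # drives the head into the far side of the socket)
    steps = np.linspace(max_norm / 8.0, max_norm, 8)
    if g0 is not None:
        worse = 0
        last = f0
        for s in steps:
            v, _g = f(s * np.asarray(g0))
            if v > best_f:
                best_f = v
                best_t = s * np.asarray(g0)
            worse = worse + 1 if v < last else 0
            last = v
            if v >= cap or worse >= 2:
                break
    # fallback: probe the axis directions at half the cap
    if best_f < tolerance:
        for u in _AXIS_DIRS:
            v, _g = f(0.5 * max_norm * u)
            if v > best_f:
                best_f = v
                best_t = 0.5 * max_norm * u
    # stage 2: golden-section refinement along the winning ray
    nrm = np.linalg.norm(best_t)
    if nrm > 0 and best_f < cap:
        u = best_t / nrm
        lo, hi = max(nrm - max_norm / 8.0, 0.0), min(nrm + max_norm / 8.0, max_norm)
        phi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c1 = b - phi * (b - a)
        c2 = a + phi * (b - a)
        f1, _ = f(c1 * u)
        f2, _ = f(c2 * u)
        for _ in range(6):
            if f1 < f2:
                a, c1, f1 = c1, c2, f2
                c2 = a + phi * (b - a)
                f2, _ = f(c2 * u)
            else:
                b, c2, f2 = c2, c1, f1
                c1 = b - phi * (b - a)
                f1, _ = f(c1 * u)
        s = c1 if f1 >= f2 else c2
        v = f1 if f1 >= f2 else f2
        if v > best_f:
            best_f, best_t = v, s * u
    # stage 3: subgradient polish
    t = best_t.copy()
    step = 0.25 * max_norm
    for _ in range(10):
        v, g = f(t)
        if v > best_f:
            best_f, best_t = v, t.copy()
        if g is None or best_f >= cap:
            break
        t2 = t + step * g
        n2 = np.linalg.norm(t2)
        if n2 > max_norm:
            t2 *= max_norm / n2
        t = t2
        step *= 0.6

    if was_colliding and best_f < tolerance:
        return None
    if not was_colliding and best_f <= f0:
        return np.zeros(3)
    return best_t
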