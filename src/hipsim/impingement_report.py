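"""Impingement localization and virtual resection planning.

At a blocked pose the impinging area is the set of femur/pelvis face
pairs within the contact tolerance (0.1 mm by default).  Zones are
expressed on the radiological head-neck clock face (12 superior,
3 anterior on a right hip, mirrored on the left) and aggregated over a
motion set; the resection estimator then carves the femoral surface
along inward vertex normals — mimicking arthroscopic burring normal to
the bone — until the target motions clear, reporting the removed volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .anatomy_frames import AnatomicalFrame
from .mesh_core import (
    TriangleMesh,
    ValidationError,
    contains_points,
    query_contact,
)
from .rom_engine import (
    MotionDefinition,
    PoseStatus,
    ROMEndpoint,
    SimulationConfig,
    _SimContext,
    check_pose,
    find_endpoint,
    make_context,
)

__all__ = [
    "ContactZone",
    "ImpingementMap",
    "ResectionEstimate",
    "contact_zone",
    "clock_position",
    "aggregate_map",
    "resection_estimate",
    "write_zone_report",
    "write_depth_map_ply",
]


@dataclass
class ContactZone:
    """Face pairs within tolerance at a queried pose."""

    femur_faces: np.ndarray
    pelvis_faces: np.ndarray
    centroid: np.ndarray | None  # area-weighted, on the femur (world mm)
    area: float  # summed femur face area, mm^2
    clock_hour: float | None = None

    @property
    def empty(self) -> bool:
        return len(self.femur_faces) == 0


def contact_zone(
    femur_posed: TriangleMesh,
    pelvis: TriangleMesh,
    tolerance: float = 0.1,
) -> ContactZone:
    """All face pairs whose surface distance is within ``tolerance``.

    An empty zone (clearance everywhere above tolerance) is a valid
    result, not an error.
    """
    res = query_contact(femur_posed, pelvis, tolerance, require_closed=False)
    pairs = res.witness_pairs
    if res.crossing_pairs.size:
        pairs = np.vstack([pairs, res.crossing_pairs]) if pairs.size else res.crossing_pairs
    if pairs.size == 0:
        return ContactZone(
            np.empty(0, np.int64), np.empty(0, np.int64), None, 0.0
        )
    ff = np.unique(pairs[:, 0])
    pf = np.unique(pairs[:, 1])
    areas = femur_posed.face_areas[ff]
    cents = femur_posed.face_centroids[ff]
    area = float(areas.sum())
    centroid = (cents * areas[:, None]).sum(axis=0) / area if area > 0 else cents.mean(axis=0)
    return ContactZone(ff, pf, centroid, area)


def clock_position(
    point: np.ndarray,
    femur_frame: AnatomicalFrame,
    side: str,
    axis: np.ndarray | None = None,
) -> float:
    """Clock hour of a point about the femoral neck axis.

    12 o'clock is superior and 3 o'clock anterior for a right hip (9
    o'clock anterior on a left hip).  ``axis`` is the neck axis pointing
    from the head center down the neck; it defaults to the femoral long
    axis, which is only meaningful for shaft-level points.  Returns a
    value in (0, 12], with exactly 12.0 at the superior anchor.
    """
    if side not in ("left", "right"):
        raise ValidationError("side must be 'left' or 'right'")
    n = np.asarray(axis if axis is not None else femur_frame.y, dtype=float)
    n = n / np.linalg.norm(n)
    sup = femur_frame.y
    ant = femur_frame.x
    e12 = sup - (sup @ n) * n
    if np.linalg.norm(e12) < 1e-9:
        raise ValidationError("clock undefined: axis parallel to the superior axis")
    e12 /= np.linalg.norm(e12)
    a_proj = ant - (ant @ n) * n
    if np.linalg.norm(a_proj) < 1e-9:
        raise ValidationError("clock undefined: axis parallel to the anterior axis")
    a_proj /= np.linalg.norm(a_proj)
    # rotation sense: from 12 toward 3 passes the anterior direction on a
    # right hip; mirrored on the left
    sense = np.sign(np.cross(e12, a_proj) @ n) * (1.0 if side == "right" else -1.0)
    u = np.asarray(point, dtype=float) - femur_frame.origin
    u_perp = u - (u @ n) * n
    if np.linalg.norm(u_perp) < 1e-9:
        raise ValidationError("clock undefined: point lies on the axis")
    u_perp /= np.linalg.norm(u_perp)
    phi = np.degrees(np.arctan2(sense * (np.cross(e12, u_perp) @ n), e12 @ u_perp))
    hour = (phi / 30.0) % 12.0
    return 12.0 if hour == 0.0 else float(hour)


@dataclass
class ImpingementMap:
    """Union of contact zones over a motion set, on the femur's faces."""

    flags: np.ndarray  # (n_faces,) bool
    depth: np.ndarray  # (n_faces,) max penetration depth over poses, mm
    zones: dict = field(default_factory=dict)  # motion label -> ContactZone
    endpoints: dict = field(default_factory=dict)  # motion label -> ROMEndpoint

    @property
    def faces(self) -> np.ndarray:
        return np.nonzero(self.flags)[0]


def aggregate_map(
    motions: list[MotionDefinition],
    femur: TriangleMesh,
    pelvis: TriangleMesh,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    hip_center,
    side: str = "right",
    config: SimulationConfig | None = None,
    neck_axis: np.ndarray | None = None,
) -> ImpingementMap:
    """Impinging femur faces and depths over all blocked motions.

    Each impinged motion contributes the contact zone at its first
    blocked pose (one resolution step beyond the registered endpoint);
    per-face depth is the maximum penetration depth seen at any of those
    poses.
    """
    cfg = config or SimulationConfig()
    ctx = make_context(femur, pelvis, pelvis_frame, femur_frame, hip_center, side, cfg)
    flags = np.zeros(len(femur.faces), bool)
    depth = np.zeros(len(femur.faces))
    zones = {}
    endpoints = {}
    for motion in motions:
        ep = find_endpoint(motion, ctx)
        endpoints[motion.label] = ep
        if ep.status != "impinged":
            continue
        blocked = ep.angle if ep.start_blocked else ep.angle + cfg.angle_resolution
        T = ctx.set_pose(motion.pose_at(blocked))
        posed = TriangleMesh(T.apply(femur.vertices), femur.faces, femur.name)
        zone = contact_zone(posed, pelvis, cfg.contact_tolerance)
        if not zone.empty and zone.centroid is not None:
            local = T.inverse().apply(zone.centroid)
            try:
                zone.clock_hour = clock_position(local, femur_frame, side, neck_axis)
            except ValidationError:
                zone.clock_hour = None
        zones[motion.label] = zone
        if zone.empty:
            continue
        flags[zone.femur_faces] = True
        # per-face depth: how far the zone faces' vertices sit inside the
        # pelvis at this pose
        vids = np.unique(femur.faces[zone.femur_faces].ravel())
        pts = posed.vertices[vids]
        dist, _c, _f = pelvis.surface_distance(pts)
        inside = contains_points(pelvis, pts)
        vdepth = np.where(inside, dist, 0.0)
        vmap = dict(zip(vids.tolist(), vdepth.tolist()))
        for f in zone.femur_faces:
            d = max(vmap.get(int(v), 0.0) for v in femur.faces[f])
            depth[f] = max(depth[f], d)
    return ImpingementMap(flags, depth, zones, endpoints)


# ---------------------------------------------------------------------------
# virtual resection
# ---------------------------------------------------------------------------


@dataclass
class ResectionEstimate:
    """Per-vertex resection plan and its removed volume."""

    depth_map: np.ndarray  # (n_vertices,) carve depth along inward normal, mm
    resected_volume: float  # mm^3
    achieved: bool
    iterations: int
    resected_femur: TriangleMesh
    endpoints_after: dict = field(default_factory=dict)
    diagnostics: str = ""


def _carve(femur: TriangleMesh, depth_map: np.ndarray) -> TriangleMesh:
    v = femur.vertices - femur.vertex_normals * depth_map[:, None]
    return TriangleMesh(v, femur.faces, femur.name)


def _voxel_volume_difference(a: TriangleMesh, b: TriangleMesh, pitch: float = 0.25) -> float:
    """Voxel-count fallback when carving breaks watertightness."""
    from ._voxel import rasterize_occupancy

    lo = np.minimum(a.bounds[0], b.bounds[0]) - 2 * pitch
    hi = np.maximum(a.bounds[1], b.bounds[1]) + 2 * pitch
    dims = np.ceil((hi - lo) / pitch).astype(int)
    va = rasterize_occupancy(a.triangles, lo, (pitch,) * 3, dims).sum()
    vb = rasterize_occupancy(b.triangles, lo, (pitch,) * 3, dims).sum()
    return float(va - vb) * pitch**3


def resection_estimate(
    femur: TriangleMesh,
    pelvis: TriangleMesh,
    pelvis_frame: AnatomicalFrame,
    femur_frame: AnatomicalFrame,
    hip_center,
    targets: dict[str, tuple[MotionDefinition, float]],
    side: str = "right",
    config: SimulationConfig | None = None,
    max_iterations: int = 20,
    margin: float | None = None,
) -> ResectionEstimate:
    """Carve the femur until every target motion reaches its target angle.

    ``targets`` maps motion labels to (motion, target angle).  Each
    iteration re-simulates the targets on the carved femur; wherever a
    motion still blocks short of its target, the femoral vertices within
    the clearance deficit are carved along their inward normals, at the
    blocked angle and at 2-degree stations up to the target.  ``margin``
    is the clearance the carved surface must reach: by default the
    articular clearance of the uninvolved joint (median femur-to-pelvis
    gap at the neutral pose, floored at the contact tolerance), i.e. the
    prominence is burred back to the equidistant joint space rather than
    merely un-snagged; pass ``margin=config.contact_tolerance`` for the
    minimal carve.  Converges in a few iterations for cam-type
    prominences; ``achieved=False`` with diagnostics if the budget runs
    out.
    """
    cfg = config or SimulationConfig()
    tol = cfg.contact_tolerance
    if margin is None:
        d0, _c, _f = pelvis.surface_distance(femur.vertices)
        near0 = d0[d0 < 8.0]
        margin = float(np.median(near0)) if len(near0) else tol
    margin = max(float(margin), tol)
    depth_map = np.zeros(len(femur.vertices))
    normals = femur.vertex_normals
    work = femur
    achieved = False
    iters = 0
    endpoints_after: dict[str, ROMEndpoint] = {}

    for iters in range(1, max_iterations + 1):
        ctx = make_context(work, pelvis, pelvis_frame, femur_frame, hip_center, side, cfg)
        all_clear = True
        endpoints_after = {}
        # largest clearance deficit seen by each vertex over all blocked
        # stations this round; applied once so deficits never compound
        max_deficit = np.zeros(len(depth_map))
        for label, (motion, target) in targets.items():
            ep = find_endpoint(motion, ctx)
            endpoints_after[label] = ep
            if ep.status == "bound_reached" or ep.angle >= target - 1e-9:
                continue
            all_clear = False
            first_block = ep.angle + (0 if ep.start_blocked else cfg.angle_resolution)
            stations = np.unique(
                np.concatenate([[first_block], np.arange(first_block, target, 2.0), [target]])
            )
            for ang in stations:
                T = ctx.set_pose(motion.pose_at(ang))
                _d, _bi, _bj, _nc, nx, _ov = ctx.collider.raw_query(
                    (0.0, 0.0, 0.0), tol, 2.0 * tol + 0.5
                )
                if nx == 0:  # this station does not collide: nothing to carve
                    continue
                # flood outward from the colliding femur faces while the
                # clearance deficit persists: covers the whole prominence
                # but stops where the joint space returns to normal, so
                # native contacts (e.g. the neck at its natural endpoint)
                # are never burred
                posed_v = T.apply(work.vertices)
                seeds = np.unique(work.faces[ctx.collider._xj[:nx]].ravel())
                adj = femur.vertex_neighbors  # same topology as `work`
                visited: set[int] = set()
                frontier = list(seeds)
                while frontier:
                    batch = np.array(
                        [v for v in frontier if v not in visited], dtype=np.int64
                    )
                    frontier = []
                    if len(batch) == 0:
                        break
                    visited.update(batch.tolist())
                    pts = posed_v[batch]
                    dist, _cp, _cf = pelvis.surface_distance(pts)
                    cand = dist < margin + 0.5
                    inside = np.zeros(len(batch), bool)
                    if cand.any():
                        inside[cand] = contains_points(pelvis, pts[cand])
                    deficit = np.where(inside, dist + margin, margin - dist)
                    grow = deficit > 0.1 * margin
                    np.maximum.at(
                        max_deficit, batch[grow], np.maximum(deficit[grow], 0.0)
                    )
                    for v in batch[grow]:
                        for nb in adj[v]:
                            if int(nb) not in visited:
                                frontier.append(int(nb))
                    if len(visited) > 30000:
                        break
        if all_clear:
            achieved = True
            break
        depth_map = depth_map + max_deficit
        work = _carve(femur, depth_map)

    if femur.is_watertight and work.is_watertight:
        volume = float(femur.volume - work.volume)
    else:
        volume = _voxel_volume_difference(femur, work)
    diag = "" if achieved else (
        f"targets not reached after {iters} iterations: "
        + ", ".join(
            f"{k}={endpoints_after[k].angle:.1f}<{t:.1f}"
            for k, (_m, t) in targets.items()
            if endpoints_after.get(k) and endpoints_after[k].status == "impinged"
            and endpoints_after[k].angle < t
        )
    )
    return ResectionEstimate(
        depth_map, volume, achieved, iters, work, endpoints_after, diag
    )


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------


def write_zone_report(imap: ImpingementMap, path) -> None:
    """CSV: motion, endpoint angle, status, clock hour, zone area."""
    import pandas as pd

    rows = []
    for label, ep in imap.endpoints.items():
        zone = imap.zones.get(label)
        rows.append(
            {
                "motion": label,
                "endpoint_deg": round(ep.angle, 1),
                "status": ep.status,
                "clock_hour": (
                    round(zone.clock_hour, 2)
                    if zone is not None and zone.clock_hour is not None
                    else ""
                ),
                "zone_area_mm2": round(zone.area, 2) if zone is not None else 0.0,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_depth_map_ply(mesh: TriangleMesh, depth_map: np.ndarray, path) -> None:
    """ASCII PLY with the per-vertex resection depth as a quality scalar."""
    v = mesh.vertices
    f = mesh.faces
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(v)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {len(f)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for p, q in zip(v, depth_map):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {q:.6f}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def write_resection_summary(est: ResectionEstimate, path) -> None:
    data = {
        "resected_volume_mm3": est.resected_volume,
        "max_depth_mm": float(est.depth_map.max(initial=0.0)),
        "resected_area_mm2": float(
            est.resected_femur.face_areas[
                np.unique(
                    np.nonzero(est.depth_map[est.resected_femur.faces] > 0)[0]
                )
            ].sum()
        ) if (est.depth_map > 0).any() else 0.0,
        "achieved": bool(est.achieved),
        "iterations": int(est.iterations),
        "diagnostics": est.diagnostics,
    }
    Path(path).write_text(json.dumps(data, indent=2))
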