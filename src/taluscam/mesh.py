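"""The PTS measurement protocol on triangle meshes.

Given a talus mesh with two marked regions — the lateral tibial facet (LTF)
and the flexor fibularis groove (FFG) — the protocol is:

1. fit a cylinder to the LTF by least squares (the cylinder axis models the
   talocrural joint axis, its radius the cam's base circle),
2. place a landmark at the saddle point of the FFG (or at the point of
   maximal convex curvature when the groove is convex),
3. record the signed distance from the landmark to the cylinder surface
   ("groove to cylinder"; negative inside the cylinder),
4. form AxisToGroove = Radius + GrooveToCylinder and the dimensionless
   PTS index = AxisToGroove / Radius.

A PTS index of 1 means the groove landmark lies on the curvature traced by
the facet; > 1 means the shelf protrudes beyond the base circle (a cam
rise); < 1 means the groove sits inside it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import trimesh
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = [
    "FacetSelection",
    "CylinderFit",
    "PTSMeasurement",
    "read_mesh",
    "write_mesh",
    "read_regions",
    "write_regions",
    "select_region",
    "fit_cylinder",
    "signed_distance_to_cylinder",
    "vertex_principal_curvatures",
    "locate_ffg_landmark",
    "measure_specimen",
]

_FORMATS = ("ply", "obj", "stl")


def read_mesh(path: str, fmt: Optional[str] = None) -> trimesh.Trimesh:
    """Load a triangle mesh; merge duplicate vertices, drop degenerate faces.

    STL stores each face's vertices independently, so merging typically
    reduces the vertex count there. Counts before/after cleaning are logged.
    """
    if fmt is not None and fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format: {fmt}")
    mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    raw_v, raw_f = len(mesh.vertices), len(mesh.faces)
    if raw_f == 0:
        raise ValueError(f"mesh has no faces: {path}")
    mesh.merge_vertices()
    mesh.update_faces(mesh.nondegenerate_faces())
    log.info(
        "loaded %s: %d->%d vertices, %d->%d faces",
        path, raw_v, len(mesh.vertices), raw_f, len(mesh.faces),
    )
    if len(mesh.faces) == 0:
        raise ValueError(f"mesh empty after cleaning: {path}")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str) -> None:
    mesh.export(str(path))


def write_regions(regions: Dict[str, Sequence[int]], path: str) -> None:
    """Write a region sidecar: JSON mapping label -> vertex-id list."""
    with open(path, "w") as fh:
        json.dump({k: [int(i) for i in v] for k, v in regions.items()}, fh)


def read_regions(path: str) -> Dict[str, np.ndarray]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: np.asarray(v, dtype=np.int64) for k, v in raw.items()}


@dataclasses.dataclass(frozen=True)
class FacetSelection:
    """A labelled vertex-index region of a mesh (e.g. "LTF", "FFG")."""

    mesh: trimesh.Trimesh
    vertex_ids: np.ndarray
    label: str = ""

    @property
    def points(self) -> np.ndarray:
        return self.mesh.vertices[self.vertex_ids]


def select_region(
    mesh: trimesh.Trimesh,
    spec: Union[str, Sequence[int]],
    regions: Optional[Dict[str, Sequence[int]]] = None,
    label: str = "",
    min_size: int = 6,
) -> FacetSelection:
    """Resolve a region from an explicit id list or a sidecar label."""
    if isinstance(spec, str):
        if regions is None or spec not in regions:
            raise KeyError(f"unknown region label: {spec!r}")
        ids = np.asarray(regions[spec], dtype=np.int64)
        label = label or spec
    else:
        ids = np.asarray(list(spec), dtype=np.int64)
    if len(ids) < min_size:
        raise ValueError(
            f"region needs >= {min_size} vertices, got {len(ids)}"
        )
    if ids.min() < 0 or ids.max() >= len(mesh.vertices):
        raise IndexError("region vertex ids out of range")
    return FacetSelection(mesh=mesh, vertex_ids=ids, label=label)


@dataclasses.dataclass(frozen=True)
class CylinderFit:
    """Best-fit cylinder: the talocrural-axis model.

    The fit minimises sum((d_i - r)^2) over axis point, axis direction and
    radius, where d_i is the orthogonal distance of point i to the axis —
    unconstrained by the surface ("do not contact").
    """

    axis_point: np.ndarray
    axis_direction: np.ndarray
    radius: float
    rms_residual: float
    n_points: int


def _axis_distances(P: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    rel = P - c
    return np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)


def _dir_from_angles(theta: float, phi: float) -> np.ndarray:
    return np.array(
        [
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ]
    )


def _cyl_residuals(params: np.ndarray, P: np.ndarray) -> np.ndarray:
    cx, cy, cz, theta, phi, r = params
    d = _dir_from_angles(theta, phi)
    return _axis_distances(P, np.array([cx, cy, cz]), d) - r


def _init_from_direction(P: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Given a candidate axis direction, estimate centre and radius from an
    algebraic (Kasa) circle fit of the points projected onto the normal
    plane."""
    d = d / np.linalg.norm(d)
    # orthonormal basis of the normal plane
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rel = P - P.mean(axis=0)
    u, v = rel @ e1, rel @ e2
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u**2 + v**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    uc, vc, c0 = sol
    r = math.sqrt(max(c0 + uc**2 + vc**2, 1e-12))
    centre = P.mean(axis=0) + uc * e1 + vc * e2
    theta = math.acos(np.clip(d[2], -1.0, 1.0))
    phi = math.atan2(d[1], d[0])
    return np.array([*centre, theta, phi, r])


def fit_cylinder(
    selection: FacetSelection,
    max_restarts: int = 10,
    seed: int = 0,
) -> CylinderFit:
    """Least-squares cylinder through a facet selection.

    Initialisation tries the three principal axes of the selected points
    (for a partial cylindrical arc the true axis is close to one of them),
    refines with Levenberg-Marquardt-style least squares, and falls back on
    random-direction restarts; partial arcs (< 180 deg) make the objective
    locally multimodal, so the best of all converged starts is returned.
    """
    P = np.asarray(selection.points, dtype=float)
    if len(P) < 6:
        raise ValueError("need >= 6 points for a cylinder fit")
    rel = P - P.mean(axis=0)
    cov = rel.T @ rel / len(P)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[-1], 1.0):
        raise ValueError("degenerate geometry: points are collinear")
    # coplanar points admit no unique cylinder
    if evals[0] < 1e-10 * max(evals[-1], 1.0):
        raise ValueError("degenerate geometry: points are coplanar")
    rng = np.random.default_rng(seed)
    starts = [evecs[:, i] for i in range(3)]
    starts += [rng.standard_normal(3) for _ in range(max_restarts)]
    best = None
    for k, d0 in enumerate(starts):
        try:
            x0 = _init_from_direction(P, d0)
            res = least_squares(
                _cyl_residuals, x0, args=(P,), xtol=1e-14, ftol=1e-14,
                gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # noqa: BLE001 - a failed start is just skipped
            continue
        if best is None or res.cost < best.cost - 1e-16:
            best = res
        # principal-axis starts done and already converged tightly: stop
        if k >= 2 and best is not None and best.cost < 1e-18 * len(P):
            break
    if best is None:
        raise RuntimeError("cylinder fit did not converge from any start")
    cx, cy, cz, theta, phi, r = best.x
    d = _dir_from_angles(theta, phi)
    c = np.array([cx, cy, cz])
    # canonical axis point: closest to the centroid
    c = c + ((P.mean(axis=0) - c) @ d) * d
    resid = _axis_distances(P, c, d) - abs(r)
    return CylinderFit(
        axis_point=c,
        axis_direction=d,
        radius=abs(float(r)),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        n_points=len(P),
    )


def signed_distance_to_cylinder(point: np.ndarray, cyl: CylinderFit) -> float:
    """(distance of point to axis) - radius; negative inside the cylinder."""
    p = np.asarray(point, dtype=float)
    d = _axis_distances(p[None, :], cyl.axis_point, cyl.axis_direction)[0]
    return float(d - cyl.radius)


def _mean_edge_length(mesh: trimesh.Trimesh) -> float:
    return float(mesh.edges_unique_length.mean())


def vertex_principal_curvatures(
    mesh: trimesh.Trimesh,
    vertex_ids: Iterable[int],
    neighborhood: Optional[float] = None,
) -> Dict[int, Tuple[float, float]]:
    """Principal curvatures (k1 >= k2) at vertices by local quadric fitting.

    For each vertex, neighbours within ``neighborhood`` (default 3x mean
    edge length) are expressed in a local frame with the vertex normal as
    z; a full quadric h(u, v) with linear terms is fitted and the shape
    operator evaluated at the origin via the first/second fundamental
    forms. Sign convention: positive curvature bends toward the outward
    normal (convex).
    """
    if neighborhood is None:
        neighborhood = 3.0 * _mean_edge_length(mesh)
    V = mesh.vertices
    normals = mesh.vertex_normals
    from scipy.spatial import cKDTree

    tree = cKDTree(V)
    out: Dict[int, Tuple[float, float]] = {}
    for vid in vertex_ids:
        vid = int(vid)
        idx = tree.query_ball_point(V[vid], neighborhood)
        if len(idx) < 6:
            continue
        n = normals[vid]
        a = np.array([1.0, 0.0, 0.0])
        if abs(n @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(n, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        rel = V[idx] - V[vid]
        u, v, h = rel @ e1, rel @ e2, rel @ n
        A = np.column_stack(
            [u, v, 0.5 * u**2, u * v, 0.5 * v**2]
        )
        try:
            coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        except np.linalg.LinAlgError:
            continue
        hu, hv, huu, huv, hvv = coef
        w = math.sqrt(1.0 + hu**2 + hv**2)
        E = 1 + hu**2
        F = hu * hv
        G = 1 + hv**2
        L, M, N = huu / w, huv / w, hvv / w
        I1 = np.array([[E, F], [F, G]])
        II = np.array([[L, M], [M, N]])
        shape = np.linalg.solve(I1, II)
        k = np.linalg.eigvals(shape).real
        k1, k2 = max(k), min(k)
        out[vid] = (float(k1), float(k2))
    return out


class NoSaddleError(ValueError):
    """Raised when a groove region contains no saddle-shaped vertex.

    Signals the convex case (as in the one Avahi specimen whose groove is
    convex mediolaterally); the caller may retry with mode="convex_max".
    """


def locate_ffg_landmark(
    mesh: trimesh.Trimesh,
    groove_region: FacetSelection,
    mode: str = "saddle",
    neighborhood: Optional[float] = None,
) -> np.ndarray:
    """Place the flexor-fibularis-groove landmark.

    saddle mode: among vertices with principal curvatures of opposite sign
    (k1 > 0 > k2), return the one maximising |k1 * k2| — the most
    saddle-like point. convex_max mode: among vertices whose curvatures
    share a sign, return the one with the largest mean-curvature magnitude.
    """
    if mode not in ("saddle", "convex_max"):
        raise ValueError(f"unknown landmark mode: {mode}")
    curv = vertex_principal_curvatures(
        mesh, groove_region.vertex_ids, neighborhood=neighborhood
    )
    if not curv:
        raise ValueError("groove region too small for curvature estimation")
    if mode == "saddle":
        cands = {
            vid: k for vid, k in curv.items() if k[0] > 0 > k[1]
        }
        if not cands:
            raise NoSaddleError(
                "no saddle-shaped vertex in groove region; groove may be "
                "convex — retry with mode='convex_max'"
            )
        best = max(cands, key=lambda vid: abs(cands[vid][0] * cands[vid][1]))
    else:
        cands = {
            vid: k
            for vid, k in curv.items()
            if k[0] * k[1] >= 0
        }
        if not cands:
            raise ValueError("no same-sign-curvature vertex in groove region")
        best = max(
            cands, key=lambda vid: abs(cands[vid][0] + cands[vid][1]) / 2
        )
    return np.asarray(mesh.vertices[int(best)], dtype=float)


@dataclasses.dataclass(frozen=True)
class PTSMeasurement:
    """One specimen's cam measurements.

    The identity AxisToGroove = Radius + GrooveToCylinder holds exactly;
    PTSIndex = AxisToGroove / Radius. The natural log of the index is
    stored alongside (NaN when the index is non-positive); default
    analyses use the raw index.
    """

    specimen_id: str
    taxon: str
    radius: float
    groove_to_cylinder: float
    axis_to_groove: float
    pts_index: float
    ln_pts_index: float

    @classmethod
    def from_components(
        cls, specimen_id: str, taxon: str, radius: float,
        groove_to_cylinder: float,
    ) -> "PTSMeasurement":
        axis_to_groove = radius + groove_to_cylinder
        pts = axis_to_groove / radius
        return cls(
            specimen_id=specimen_id,
            taxon=taxon,
            radius=float(radius),
            groove_to_cylinder=float(groove_to_cylinder),
            axis_to_groove=float(axis_to_groove),
            pts_index=float(pts),
            ln_pts_index=float(np.log(pts)) if pts > 0 else float("nan"),
        )


def measure_specimen(
    mesh: trimesh.Trimesh,
    ltf: FacetSelection,
    ffg: FacetSelection,
    specimen_id: str = "",
    taxon: str = "",
    mode: str = "saddle",
    landmark_id: Optional[int] = None,
    scale: float = 1.0,
) -> PTSMeasurement:
    """Full protocol: cylinder on the LTF, landmark in the FFG, PTS index.

    ``landmark_id`` overrides curvature-based detection with a
    user-supplied vertex (the manual-placement workflow). ``scale``
    rescales the mesh units to millimetres at measurement time.
    """
    if scale != 1.0:
        mesh = mesh.copy()
        mesh.apply_scale(scale)
        ltf = FacetSelection(mesh, ltf.vertex_ids, ltf.label)
        ffg = FacetSelection(mesh, ffg.vertex_ids, ffg.label)
    cyl = fit_cylinder(ltf)
    if landmark_id is not None:
        landmark = np.asarray(mesh.vertices[int(landmark_id)], dtype=float)
        used_mode = "manual"
    else:
        landmark = locate_ffg_landmark(mesh, ffg, mode=mode)
        used_mode = mode
    g2c = signed_distance_to_cylinder(landmark, cyl)
    log.info(
        "specimen %s: radius=%.4f rms=%.2e landmark_mode=%s g2c=%.4f",
        specimen_id, cyl.radius, cyl.rms_residual, used_mode, g2c,
    )
    return PTSMeasurement.from_components(
        specimen_id, taxon, cyl.radius, g2c
    )
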