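"""Talus-as-cam kinematics: tendon path length versus flexion angle.

The talus is modelled as a 2-D cam in the sagittal plane: a base circle of
the talocrural radius plus a raised-cosine lobe (the posterior trochlear
shelf, PTS) whose height over the base circle is ``(PTS index - 1) x
radius``. The flexor fibularis tendon is the follower: a taut string from
a fixed proximal origin, around the cam body, to an insertion point that
rotates rigidly with the cam (the foot). Rotating the cam (dorsi-/
plantarflexion) changes the shortest obstacle-avoiding path length; the
excursion (max - min path length over the flexion range) is the cam
effect.

The cam *body* is the base circle together with any protruding lobe:
``r(phi) = R + max(0, rise) * bump(phi)``. A groove sunk inside the base
circle (negative rise, PTS index < 1) leaves the convex body unchanged —
the taut tendon rides the base circle and cannot be pushed by a recess —
so such profiles produce no cam effect, by construction. Absolute path
lengths depend on the (configurable) tendon geometry defaults; only
ordinal comparisons (more rise, more excursion) carry anatomical meaning.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CamProfile",
    "PathLengthCurve",
    "profile_from_index",
    "tendon_path_length",
    "cam_excursion",
]

# tendon geometry defaults, in units of the base radius: the muscle origin
# sits proximally up the limb axis, the insertion distally on the foot,
# both offset posteriorly so the tendon wraps the posterior side of the
# talus where the PTS lies
_ORIGIN_FACTOR = (-0.6, 10.0)
_INSERTION_FACTOR = (-0.6, -3.0)
_RISE_CENTER = np.deg2rad(140.0)
_RISE_WIDTH = np.deg2rad(70.0)


@dataclasses.dataclass(frozen=True)
class CamProfile:
    """Cam cross-section plus follower endpoints.

    base_radius     : base-circle radius, mm (the talocrural radius).
    rise_height     : signed lobe height, mm; rise/base + 1 = PTS index.
    rise_center     : angular position of the lobe (rad, posterior).
    rise_width      : full angular width of the raised-cosine lobe (rad).
    origin_point    : fixed proximal end of the tendon, world frame (mm).
    insertion_point : distal end in the cam frame; rotates with the cam.
    """

    base_radius: float
    rise_height: float
    rise_center: float = _RISE_CENTER
    rise_width: float = _RISE_WIDTH
    origin_point: Tuple[float, float] = (0.0, 0.0)
    insertion_point: Tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.base_radius + self.rise_height <= 0:
            raise ValueError("base_radius + rise_height must be > 0")
        if not (0 < self.rise_width < np.pi):
            raise ValueError("rise_width must be in (0, pi)")

    def radii(self, phi: np.ndarray) -> np.ndarray:
        """Body radius at cam-frame angle phi (lobe only if protruding)."""
        delta = np.angle(np.exp(1j * (phi - self.rise_center)))
        bump = np.where(
            np.abs(delta) <= self.rise_width / 2,
            0.5 * (1 + np.cos(2 * np.pi * delta / self.rise_width)),
            0.0,
        )
        return self.base_radius + max(0.0, self.rise_height) * bump


def profile_from_index(
    pts_index: float,
    base_radius: float,
    rise_center: float = _RISE_CENTER,
    rise_width: float = _RISE_WIDTH,
    origin_point: Optional[Tuple[float, float]] = None,
    insertion_point: Optional[Tuple[float, float]] = None,
) -> CamProfile:
    """Build a cam profile from a measured PTS index.

    rise_height = (pts_index - 1) * base_radius; tendon endpoints default
    to the documented geometry (origin 10 radii proximal, insertion 3
    radii distal, both 0.6 radii posterior).
    """
    if pts_index <= 0:
        raise ValueError("pts_index must be > 0")
    R = float(base_radius)
    if origin_point is None:
        origin_point = (_ORIGIN_FACTOR[0] * R, _ORIGIN_FACTOR[1] * R)
    if insertion_point is None:
        insertion_point = (_INSERTION_FACTOR[0] * R, _INSERTION_FACTOR[1] * R)
    prof = CamProfile(
        base_radius=R,
        rise_height=(pts_index - 1.0) * R,
        rise_center=rise_center,
        rise_width=rise_width,
        origin_point=tuple(origin_point),
        insertion_point=tuple(insertion_point),
    )
    prof.validate()
    return prof


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _chain_length(pts: np.ndarray, i: int, j: int) -> float:
    """Length of the hull boundary chain from vertex i to vertex j (CCW)."""
    n = len(pts)
    total = 0.0
    k = i
    while k != j:
        nxt = (k + 1) % n
        total += float(np.linalg.norm(pts[nxt] - pts[k]))
        k = nxt
    return total


def tendon_path_length(
    profile: CamProfile,
    theta: float,
    n_segments: int = 4096,
    rotate_insertion: bool = False,
) -> float:
    """Taut-string length from origin to insertion around the rotated cam.

    The cam cross-section is discretised into ``n_segments`` boundary
    points and rotated by ``theta`` (positive = dorsiflexion, counter-
    clockwise). By default both tendon endpoints stay fixed in the world
    frame, so the computed length change is the *cam-attributable*
    excursion: a featureless circular cam is rotation-invariant and gives
    exactly zero excursion, and any change comes from the rise sweeping
    through the wrap region. ``rotate_insertion=True`` instead rotates the
    insertion rigidly with the cam (the foot), which adds the ordinary
    moment-arm excursion every ankle tendon has (about base_radius x
    theta) on top of the cam effect. The shortest path avoiding the
    convex body is the straight segment when unblocked, else the shorter
    boundary chain of the convex hull of the endpoints and the cam
    outline.
    """
    profile.validate()
    if n_segments < 64:
        raise ValueError("n_segments too small for a faithful outline")
    phi = np.linspace(0.0, 2 * np.pi, n_segments, endpoint=False)
    r = profile.radii(phi)
    world_angle = phi + theta
    outline = np.column_stack(
        [r * np.cos(world_angle), r * np.sin(world_angle)]
    )
    A = np.asarray(profile.origin_point, dtype=float)
    B = np.asarray(profile.insertion_point, dtype=float)
    if rotate_insertion:
        B = _rot(theta) @ B

    body = Polygon(outline)
    for name, p in (("origin", A), ("insertion", B)):
        if body.contains(Point(p)):
            raise ValueError(f"{name} point lies inside the cam body")

    hull_obstacle = outline[ConvexHull(outline).vertices]
    obstacle_poly = Polygon(hull_obstacle)
    seg = LineString([A, B])
    blocked = seg.intersection(obstacle_poly).length > 1e-12
    if not blocked:
        return float(np.linalg.norm(B - A))

    pts = np.vstack([hull_obstacle, A[None, :], B[None, :]])
    hull = ConvexHull(pts)
    verts = hull.vertices  # CCW order
    ia = np.where(verts == len(pts) - 2)[0]
    ib = np.where(verts == len(pts) - 1)[0]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(
            "endpoint swallowed by the cam hull; tendon geometry invalid"
        )
    ring = pts[verts]
    i, j = int(ia[0]), int(ib[0])
    return min(_chain_length(ring, i, j), _chain_length(ring, j, i))


@dataclasses.dataclass(frozen=True)
class PathLengthCurve:
    """Tendon path length sampled over a flexion range.

    angles in radians (negative = plantarflexion, positive =
    dorsiflexion); lengths in mm.
    """

    angles: np.ndarray
    lengths: np.ndarray

    @property
    def excursion(self) -> float:
        """Total cam effect: max - min path length over the range."""
        return float(self.lengths.max() - self.lengths.min())

    @property
    def argmax_angle(self) -> float:
        """Flexion angle at which the path length peaks."""
        return float(self.angles[int(np.argmax(self.lengths))])


def cam_excursion(
    profile: CamProfile,
    theta_min: float = -np.pi / 3,
    theta_max: float = np.pi / 3,
    n: int = 61,
    n_segments: int = 4096,
) -> PathLengthCurve:
    """Sample tendon path length on a uniform flexion grid."""
    if theta_min >= theta_max:
        raise ValueError("theta_min must be < theta_max")
    angles = np.linspace(theta_min, theta_max, n)
    lengths = np.array(
        [tendon_path_length(profile, th, n_segments=n_segments)
         for th in angles]
    )
    return PathLengthCurve(angles=angles, lengths=lengths)
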