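"""Reachable-workspace quantification on the shoulder-centered sphere.

Hand trajectories are normalized to the shoulder: per frame the
shoulder-to-hand vector is divided by arm length and projected radially
onto the unit sphere.  The covered region's outer boundary is located by
a 2-D alpha shape in a stereographic chart, smoothed with a closed
centripetal Catmull-Rom spline, and the enclosed spherical surface is
split by the horizontal (through-shoulder) and sagittal (inner/outer)
planes into four quadrants whose areas are reported as relative surface
area, RSA = area / (4*pi).

Quadrant convention: Q1 inner-above, Q2 inner-below, Q3 outer-above,
Q4 outer-below, where "inner" is the side of the sagittal plane toward
the body midline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import LineString

__all__ = [
    "WorkspaceEnvelope", "to_shoulder_sphere", "boundary_alpha_shape",
    "smooth_boundary", "quadrant_areas", "compute_envelope",
]

log = logging.getLogger(__name__)


@dataclass
class WorkspaceEnvelope:
    """Boundary curve on the unit sphere + quadrant relative areas."""

    boundary: np.ndarray          # (n, 3) closed (first != last) unit points
    quadrant_rsa: np.ndarray      # (4,) Q1..Q4
    total_rsa: float

    def __post_init__(self):
        self.boundary = np.asarray(self.boundary, float)
        self.quadrant_rsa = np.asarray(self.quadrant_rsa, float)


def to_shoulder_sphere(hand_traj: np.ndarray, shoulder_traj: np.ndarray,
                       arm_length: float,
                       min_extension: float = 0.2) -> np.ndarray:
    """Shoulder-centered, arm-length-normalized unit-sphere directions.

    Frames where the hand sits closer to the shoulder than
    ``min_extension`` times the arm length are dropped as non-extended.
    """
    hand = np.asarray(hand_traj, float).reshape(-1, 3)
    sho = np.asarray(shoulder_traj, float).reshape(-1, 3)
    if hand.shape[0] == 0:
        raise ValueError("empty trajectory")
    if hand.shape != sho.shape:
        raise ValueError("hand and shoulder trajectories differ in length")
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    rel = (hand - sho) / arm_length
    r = np.linalg.norm(rel, axis=1)
    keep = r >= min_extension
    if not keep.any():
        log.warning("all frames non-extended; empty spherical trajectory")
        return np.empty((0, 3))
    return rel[keep] / r[keep, None]


def _chart_rotation(points: np.ndarray) -> np.ndarray:
    """Rotation taking the point centroid direction to +z."""
    c = np.asarray(points, float).mean(axis=0)
    nc = np.linalg.norm(c)
    if nc < 1e-9:
        return np.eye(3)
    c = c / nc
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(c, z)
    s = np.linalg.norm(v)
    d = float(np.dot(c, z))
    if s < 1e-12:
        return np.eye(3) if d > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - d) / s**2)


def _to_chart(points: np.ndarray, rot: np.ndarray) -> np.ndarray:
    """Stereographic chart from the antipode of the chart center.

    Conformal everywhere except the antipode itself, which for a
    shoulder workspace sits behind the back where no data lives.
    """
    p = np.asarray(points, float) @ rot.T
    denom = 1.0 + np.clip(p[:, 2], -1 + 1e-9, None)
    return p[:, :2] / denom[:, None]


def _from_chart(chart: np.ndarray, rot: np.ndarray) -> np.ndarray:
    x, y = chart[:, 0], chart[:, 1]
    r2 = x**2 + y**2
    p = np.column_stack([2 * x, 2 * y, 1 - r2]) / (1 + r2)[:, None]
    return p @ rot


def boundary_alpha_shape(points: np.ndarray,
                         alpha: Optional[float] = None) -> np.ndarray:
    """Closed outer boundary of a unit-sphere point set (alpha shape).

    Works in a stereographic chart centered on the data centroid:
    triangles of the chart Delaunay triangulation with circumradius
    above 1/alpha are discarded and the outer boundary of the surviving
    union is returned.  ``alpha`` defaults to the inverse of
    max(2.5 x median nearest-neighbor distance, 0.25 x chart extent).
    Boundary vertices are input points.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    rot = _chart_rotation(pts)
    chart = _to_chart(pts, rot)
    # degenerate (collinear) charts have a rank-deficient spread
    spread = chart - chart.mean(axis=0)
    if np.linalg.svd(spread, compute_uv=False)[-1] < 1e-9:
        raise ValueError("points are collinear in the chart")
    if pts.shape[0] == 3:
        return pts.copy()
    if alpha is None:
        from scipy.spatial import cKDTree
        d, _ = cKDTree(chart).query(chart, k=2)
        nn = np.median(d[:, 1])
        # bridge gaps between sweep passes: the radius also scales with
        # the chart extent so the outer envelope is captured
        extent = np.linalg.norm(chart - chart.mean(axis=0), axis=1).max()
        alpha = 1.0 / max(2.5 * nn, 0.25 * extent, 1e-9)
    tri = Delaunay(chart)
    keep = []
    for simplex in tri.simplices:
        a, b, c = chart[simplex]
        r = _circumradius(a, b, c)
        if r <= 1.0 / alpha:
            keep.append(simplex)
    if not keep:
        raise ValueError("alpha too large: no triangles survive")
    # union of surviving triangles; the largest component's exterior ring
    # is the outer boundary, a simple cycle through input points
    from shapely.geometry import MultiPolygon, Polygon
    from shapely.ops import unary_union
    union = unary_union([Polygon(chart[s]) for s in keep])
    if isinstance(union, MultiPolygon):
        union = max(union.geoms, key=lambda g: g.area)
    ring = np.asarray(union.exterior.coords)[:-1]
    index = {tuple(np.round(c, 12)): i for i, c in enumerate(chart)}
    idx = [index.get(tuple(np.round(c, 12))) for c in ring]
    if any(i is None for i in idx):
        # fall back to chart coordinates if a union vertex was synthesized
        return _from_chart(ring, rot)
    return pts[idx]


def _circumradius(a, b, c) -> float:
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                  np.linalg.norm(a - b))
    area2 = abs((b[0] - a[0]) * (c[1] - a[1])
                - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 < 1e-15:
        return np.inf
    return la * lb * lc / (2.0 * area2)


def smooth_boundary(boundary: np.ndarray,
                    samples_per_edge: int = 8) -> np.ndarray:
    """Closed centripetal Catmull-Rom through the boundary vertices.

    The dense curve passes through every original vertex and is
    re-projected onto the unit sphere.  Fewer than 4 vertices fall back
    to the unchanged polyline.
    """
    b = np.asarray(boundary, float).reshape(-1, 3)
    n = b.shape[0]
    if n < 4:
        log.warning("fewer than 4 boundary vertices; skipping smoothing")
        return b.copy()
    out = []
    for i in range(n):
        p0, p1, p2, p3 = b[(i - 1) % n], b[i], b[(i + 1) % n], b[(i + 2) % n]
        out.append(p1)
        for j in range(1, samples_per_edge):
            t = j / samples_per_edge
            out.append(_catmull_rom(p0, p1, p2, p3, t))
    curve = np.asarray(out)
    norms = np.linalg.norm(curve, axis=1)
    return curve / norms[:, None]


def _catmull_rom(p0, p1, p2, p3, t: float, alpha: float = 0.5) -> np.ndarray:
    """Centripetal Catmull-Rom point between p1 and p2 at fraction t."""
    def tj(ti, pa, pb):
        return ti + np.linalg.norm(pb - pa) ** alpha
    t0 = 0.0
    t1 = tj(t0, p0, p1)
    t2 = tj(t1, p1, p2)
    t3 = tj(t2, p2, p3)
    if t1 == t0 or t2 == t1 or t3 == t2:   # repeated control points
        return (1 - t) * p1 + t * p2
    u = t1 + t * (t2 - t1)
    a1 = (t1 - u) / (t1 - t0) * p0 + (u - t0) / (t1 - t0) * p1
    a2 = (t2 - u) / (t2 - t1) * p1 + (u - t1) / (t2 - t1) * p2
    a3 = (t3 - u) / (t3 - t2) * p2 + (u - t2) / (t3 - t2) * p3
    b1 = (t2 - u) / (t2 - t0) * a1 + (u - t0) / (t2 - t0) * a2
    b2 = (t3 - u) / (t3 - t1) * a2 + (u - t1) / (t3 - t1) * a3
    return (t2 - u) / (t2 - t1) * b1 + (u - t1) / (t2 - t1) * b2


def _spherical_triangle_area(a, b, c) -> float:
    """l'Huilier's formula for a geodesic triangle on the unit sphere."""
    def side(u, v):
        return 2.0 * math.asin(min(1.0, 0.5 * np.linalg.norm(u - v)))
    sa, sb, sc = side(b, c), side(a, c), side(a, b)
    s = 0.5 * (sa + sb + sc)
    inner = (math.tan(s / 2) * math.tan((s - sa) / 2)
             * math.tan((s - sb) / 2) * math.tan((s - sc) / 2))
    return 4.0 * math.atan(math.sqrt(max(inner, 0.0)))


def quadrant_areas(region: np.ndarray,
                   inner_axis: np.ndarray = np.array([-1.0, 0.0, 0.0]),
                   vertical_axis: np.ndarray = np.array([0.0, 1.0, 0.0]),
                   subdivisions: int = 2) -> WorkspaceEnvelope:
    """Quadrant relative surface areas of a closed spherical region.

    The region bounded by the closed curve is triangulated as a fan from
    its spherical centroid, each triangle subdivided for resolution, and
    each micro-triangle's l'Huilier area assigned to a quadrant by the
    sign of its centroid against the horizontal and sagittal planes.
    The four quadrant areas therefore sum to the total area exactly.
    RSA normalizes by the full sphere, 4*pi.
    """
    curve = np.asarray(region, float).reshape(-1, 3)
    if curve.shape[0] == 0:
        return WorkspaceEnvelope(boundary=curve,
                                 quadrant_rsa=np.zeros(4), total_rsa=0.0)
    if curve.shape[0] < 3:
        raise ValueError("closed region needs at least 3 vertices")
    chart = _to_chart(curve, _chart_rotation(curve))
    ring = LineString(np.vstack([chart, chart[:1]]))
    if not ring.is_simple:
        # tolerate hairline spline loops; reject gross self-intersection
        from shapely.geometry import Polygon
        poly = Polygon(chart)
        shoelace = 0.5 * abs(
            np.dot(chart[:, 0], np.roll(chart[:, 1], -1))
            - np.dot(chart[:, 1], np.roll(chart[:, 0], -1)))
        cleaned = poly.buffer(0)
        if (shoelace <= 0
                or abs(cleaned.area - shoelace) > 0.01 * shoelace):
            raise ValueError("boundary curve is self-intersecting")
    center = curve.mean(axis=0)
    nc = np.linalg.norm(center)
    if nc < 1e-6:
        # near-great-circle boundary: fan from the best-fit plane normal
        _, _, vt = np.linalg.svd(curve - curve.mean(axis=0))
        center = vt[-1]
    else:
        center = center / nc
    areas = np.zeros(4)
    n = curve.shape[0]
    for i in range(n):
        tri = (center, curve[i], curve[(i + 1) % n])
        for (a, b, c) in _subdivide(tri, subdivisions):
            area = _spherical_triangle_area(a, b, c)
            mid = a + b + c
            mid = mid / np.linalg.norm(mid)
            above = float(np.dot(mid, vertical_axis)) >= 0.0
            inner = float(np.dot(mid, inner_axis)) >= 0.0
            q = (0 if (inner and above) else
                 1 if (inner and not above) else
                 2 if above else 3)
            areas[q] += area
    rsa = areas / (4.0 * math.pi)
    return WorkspaceEnvelope(boundary=curve, quadrant_rsa=rsa,
                             total_rsa=float(rsa.sum()))


def _subdivide(tri, levels: int):
    tris = [tuple(np.asarray(p, float) for p in tri)]
    for _ in range(levels):
        nxt = []
        for a, b, c in tris:
            ab, bc, ca = (a + b), (b + c), (c + a)
            ab, bc, ca = (v / np.linalg.norm(v) for v in (ab, bc, ca))
            nxt += [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        tris = nxt
    return tris


def compute_envelope(hand_traj: np.ndarray, shoulder_traj: np.ndarray,
                     arm_length: float, side: str = "right",
                     alpha: Optional[float] = None,
                     samples_per_edge: int = 8) -> WorkspaceEnvelope:
    """Full workspace analysis: normalize, bound, smooth, quantify.

    ``side`` fixes the sagittal inner direction: the inner half-space of
    the right shoulder points toward -x (the body midline), mirrored for
    the left.
    """
    pts = to_shoulder_sphere(hand_traj, shoulder_traj, arm_length)
    if pts.shape[0] == 0:
        return WorkspaceEnvelope(boundary=np.empty((0, 3)),
                                 quadrant_rsa=np.zeros(4), total_rsa=0.0)
    boundary = boundary_alpha_shape(pts, alpha=alpha)
    smooth = smooth_boundary(boundary, samples_per_edge=samples_per_edge)
    inner = np.array([-1.0, 0.0, 0.0]) if side == "right" \
        else np.array([1.0, 0.0, 0.0])
    return quadrant_areas(smooth, inner_axis=inner)
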