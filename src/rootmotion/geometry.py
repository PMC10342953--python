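"""Geometric primitives for aortic-root cross-section analysis.

The measurement plane for root motion sits at the sinuses of Valsalva,
perpendicular to the aortic centerline at the level of the coronary ostia.
Everything downstream (areas, centroids, displacement decomposition) is
planar polygon math in that plane's orthonormal frame, so this module owns:

* plane construction from a centerline and two ostium landmarks,
* mesh-plane intersection stitched into a closed lumen contour,
* polygon area / centroid in the plane,
* least-squares plane fitting to warped (systolic) contour points.

All coordinates are millimetres; the math is frame-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TriSurfaceMesh",
    "AnalysisPlane",
    "PlanarContour",
    "Centerline",
    "GeometryError",
    "plane_at_ostia",
    "slice_mesh",
    "contour_area",
    "contour_centroid",
    "fit_plane",
]

_DEGENERATE_TRI_AREA = 1e-12  # mm^2
_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """Raised when geometric preconditions are violated."""


@dataclass(frozen=True)
class TriSurfaceMesh:
    """Triangulated aortic wall surface in the diastolic configuration.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    """

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 4:
            raise GeometryError("mesh needs an (n>=4, 3) vertex array")
        if not np.isfinite(v).all():
            raise GeometryError("mesh vertices contain non-finite coordinates")
        if t.ndim != 2 or t.shape[1] != 3 or t.shape[0] < 1:
            raise GeometryError("mesh needs an (m>=1, 3) triangle index array")
        if t.min() < 0 or t.max() >= len(v):
            raise GeometryError("triangle index out of range")
        e1 = v[t[:, 1]] - v[t[:, 0]]
        e2 = v[t[:, 2]] - v[t[:, 0]]
        areas = 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)
        if (areas <= _DEGENERATE_TRI_AREA).any():
            bad = int(np.argmin(areas))
            raise GeometryError(f"degenerate triangle {bad} (area <= 1e-12 mm^2)")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class AnalysisPlane:
    """Measurement plane: origin plus right-handed orthonormal frame (u, v, n).

    ``n = u x v`` by construction; ``n`` points from the root toward the
    arch (direction of increasing centerline parameter).
    """

    origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        u = np.asarray(self.u, dtype=float).reshape(3)
        v = np.asarray(self.v, dtype=float).reshape(3)
        n = np.asarray(self.n, dtype=float).reshape(3)
        for name, vec in (("u", u), ("v", v), ("n", n)):
            if abs(np.linalg.norm(vec) - 1.0) > _UNIT_TOL:
                raise GeometryError(f"plane basis vector {name} is not unit length")
        for a, b, pair in ((u, v, "u.v"), (u, n, "u.n"), (v, n, "v.n")):
            if abs(float(a @ b)) > _UNIT_TOL:
                raise GeometryError(f"plane basis not orthogonal ({pair} != 0)")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "n", n)

    @classmethod
    def from_normal(cls, origin, n, reference_u=None) -> "AnalysisPlane":
        """Build a plane from origin + normal with a deterministic in-plane basis.

        ``u`` is the normalized cross product of ``n`` with the global axis
        least parallel to ``n`` (smallest |component|), ``v = n x u``; this
        fixes the frame bit-for-bit without any arbitrary SVD sign.
        """
        n = np.asarray(n, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError("zero normal vector")
        n = n / norm
        if reference_u is None:
            k = np.zeros(3)
            k[int(np.argmin(np.abs(n)))] = 1.0
        else:
            k = np.asarray(reference_u, dtype=float).reshape(3)
        u = np.cross(n, k)
        un = np.linalg.norm(u)
        if un < 1e-12:
            raise GeometryError("reference axis parallel to normal")
        u = u / un
        v = np.cross(n, u)
        # re-derive n = u x v exactly so the invariant holds to the last bit
        return cls(origin=origin, u=u, v=v, n=np.cross(u, v))

    def project_uv(self, points: np.ndarray) -> np.ndarray:
        """In-plane (u, v) coordinates of 3D ``points`` relative to origin."""
        d = np.atleast_2d(points) - self.origin
        return np.column_stack([d @ self.u, d @ self.v])

    def lift(self, uv: np.ndarray) -> np.ndarray:
        """Map (u, v) coordinates back to 3D points on the plane."""
        uv = np.atleast_2d(uv)
        return self.origin + np.outer(uv[:, 0], self.u) + np.outer(uv[:, 1], self.v)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.n


@dataclass(frozen=True)
class Centerline:
    """Ordered samples along the aortic lumen axis, root first."""

    points: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
            raise GeometryError("centerline needs >=2 ordered 3D samples")
        if not np.isfinite(p).all():
            raise GeometryError("centerline contains non-finite coordinates")
        if (np.linalg.norm(np.diff(p, axis=0), axis=1) == 0).any():
            raise GeometryError("centerline has coincident consecutive samples")
        object.__setattr__(self, "points", p)

    def resample(self, spacing: float = 0.5) -> "Centerline":
        """Equal arc-length resampling (default 0.5 mm) for stable tangents."""
        p = self.points
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(int(np.ceil(total / spacing)) + 1, 2)
        si = np.linspace(0.0, total, n)
        out = np.column_stack([np.interp(si, s, p[:, k]) for k in range(3)])
        return Centerline(out)

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class PlanarContour:
    """Closed lumen contour lying in an analysis plane.

    ``points`` are ordered counterclockwise when viewed down the plane
    normal (positive shoelace area in the (u, v) frame).  For contours cut
    exactly from a mesh the planarity tolerance is tight (1e-6 mm); warped
    systolic point sets are only approximately planar and use a relaxed
    tolerance (default 0.5 mm).

    ``edge_vertices``/``edge_weights`` record, for contours produced by
    :func:`slice_mesh`, which mesh edge each point lies on and the linear
    parameter along it — needed to interpolate vertex fields to the contour.
    """

    points: np.ndarray
    plane: AnalysisPlane
    planarity_tol: float = 1e-6
    edge_vertices: np.ndarray | None = field(default=None, compare=False)
    edge_weights: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
            raise GeometryError("contour needs >=3 ordered 3D points")
        if (np.linalg.norm(np.diff(np.vstack([p, p[:1]]), axis=0), axis=1) < 1e-12).any():
            raise GeometryError("contour has consecutive duplicate points")
        dist = np.abs(self.plane.signed_distance(p))
        if dist.max() > self.planarity_tol:
            raise GeometryError(
                f"contour departs plane by {dist.max():.3g} mm "
                f"(tolerance {self.planarity_tol:g} mm)"
            )
        object.__setattr__(self, "points", p)

    def uv(self) -> np.ndarray:
        return self.plane.project_uv(self.points)


def plane_at_ostia(
    centerline: Centerline,
    left_ostium,
    right_ostium,
    resample_spacing: float = 0.5,
) -> AnalysisPlane:
    """Place the analysis plane at the coronary-ostia level.

    Each ostium is projected onto the (resampled) centerline; the plane
    origin is the centerline point at the mean of the two arc-length
    parameters, and the normal is the centerline tangent there (central
    finite difference), oriented root-to-arch by the sample order.
    """
    cl = centerline.resample(resample_spacing) if resample_spacing else centerline
    p = cl.points
    s = cl.arc_lengths()
    total = s[-1]

    def project(point, name):
        point = np.asarray(point, dtype=float).reshape(3)
        # closest point over all segments
        a, b = p[:-1], p[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        t_raw = np.einsum("ij,ij->i", point - a, ab) / denom
        t = np.clip(t_raw, 0.0, 1.0)
        foot = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", point - foot, point - foot)
        i = int(np.argmin(d2))
        # clamped to an end of the polyline -> outside the sampled span
        if (i == 0 and t_raw[i] < 0.0) or (i == len(a) - 1 and t_raw[i] > 1.0):
            raise GeometryError(
                f"landmark '{name}' projects outside the centerline span"
            )
        return s[i] + t[i] * np.sqrt(denom[i])

    arc_l = project(left_ostium, "left_coronary_ostium")
    arc_r = project(right_ostium, "right_coronary_ostium")
    arc0 = 0.5 * (arc_l + arc_r)

    origin = np.column_stack([np.interp(arc0, s, p[:, k]) for k in range(3)])[0]
    # central finite-difference tangent at arc0
    h = max(resample_spacing or 0.5, 1e-6)
    sa, sb = max(arc0 - h, 0.0), min(arc0 + h, total)
    pa = np.array([np.interp(sa, s, p[:, k]) for k in range(3)])
    pb = np.array([np.interp(sb, s, p[:, k]) for k in range(3)])
    tangent = pb - pa
    norm = np.linalg.norm(tangent)
    if norm < 1e-12:
        raise GeometryError("centerline tangent undefined (coincident samples)")
    return AnalysisPlane.from_normal(origin, tangent / norm)


def _stitch_loops(segments: list[tuple]) -> list[list[int]]:
    """Stitch edge-keyed intersection segments into closed loops.

    ``segments`` holds (key_a, key_b) pairs of hashable endpoint keys; two
    triangles sharing a mesh edge produce identical keys, so stitching is
    exact.  Returns loops as lists of endpoint keys (closed, first!=last).
    """
    # adjacency: key -> list of (segment index, other key)
    adj: dict = {}
    for i, (a, b) in enumerate(segments):
        adj.setdefault(a, []).append((i, b))
        adj.setdefault(b, []).append((i, a))
    used = [False] * len(segments)
    loops = []
    for start_i, (a0, b0) in enumerate(segments):
        if used[start_i]:
            continue
        used[start_i] = True
        loop = [a0, b0]
        current = b0
        while True:
            nxt = None
            for j, other in adj.get(current, ()):
                if not used[j]:
                    nxt = (j, other)
                    break
            if nxt is None:
                break
            used[nxt[0]] = True
            current = nxt[1]
            if current == loop[0]:
                break
            loop.append(current)
        if current != loop[0]:
            raise GeometryError(
                "open intersection polyline: slice could not be stitched into "
                f"a closed loop (loop of {len(loop)} points left open)"
            )
        loops.append(loop)
    return loops


def slice_mesh(mesh: TriSurfaceMesh, plane: AnalysisPlane) -> PlanarContour:
    """Intersect the mesh with the plane and return the closed lumen contour.

    Triangle-plane crossings are collected as segments keyed by the mesh
    edge they lie on, stitched into closed loops, and — if the plane also
    cuts other structures — the loop whose centroid is nearest the plane
    origin is returned (the origin is inside the root lumen by
    construction).  Points are ordered counterclockwise viewed down ``n``.
    """
    v = mesh.vertices
    tri = mesh.triangles
    d = (v - plane.origin) @ plane.n
    # vertices exactly on the plane get an infinitesimal positive push so
    # every crossing lies strictly on an edge and edge keys stay consistent
    eps = 1e-12 * max(1.0, float(np.abs(d).max()))
    d = np.where(d == 0.0, eps, d)

    sign = d > 0
    s0, s1, s2 = sign[tri[:, 0]], sign[tri[:, 1]], sign[tri[:, 2]]
    crossing = ~((s0 & s1 & s2) | (~s0 & ~s1 & ~s2))
    if not crossing.any():
        raise GeometryError("plane does not intersect the mesh")

    point_on_edge: dict[tuple[int, int], int] = {}
    pts: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    weights: list[float] = []

    def edge_point(i, j) -> tuple[int, int]:
        key = (i, j) if i < j else (j, i)
        if key not in point_on_edge:
            a, b = key
            t = d[a] / (d[a] - d[b])  # d[a], d[b] have opposite signs
            point_on_edge[key] = len(pts)
            pts.append(v[a] + t * (v[b] - v[a]))
            edges.append(key)
            weights.append(float(t))
        return key

    segments = []
    for t0, t1, t2 in tri[crossing]:
        ids = [t0, t1, t2]
        cross_edges = []
        for k in range(3):
            i, j = ids[k], ids[(k + 1) % 3]
            if sign[i] != sign[j]:
                cross_edges.append(edge_point(i, j))
        if len(cross_edges) == 2:
            segments.append((cross_edges[0], cross_edges[1]))

    loops = _stitch_loops(segments)
    pts_arr = np.array(pts)
    key_index = {k: i for i, k in enumerate(edges)}

    def loop_points(loop):
        return pts_arr[[key_index[k] for k in loop]]

    if len(loops) > 1:
        cents = [loop_points(lp).mean(axis=0) for lp in loops]
        dists = [np.linalg.norm(c - plane.origin) for c in cents]
        loop = loops[int(np.argmin(dists))]
    else:
        loop = loops[0]

    idx = [key_index[k] for k in loop]
    points = pts_arr[idx]
    ev = np.array([edges[i] for i in idx], dtype=np.int64)
    ew = np.array([weights[i] for i in idx], dtype=float)

    # drop near-duplicate consecutive points (plane through a vertex yields
    # two coincident edge points)
    closed = np.vstack([points, points[:1]])
    keep = np.linalg.norm(np.diff(closed, axis=0), axis=1) > 1e-9
    points, ev, ew = points[keep], ev[keep], ew[keep]
    if len(points) < 3:
        raise GeometryError("intersection degenerated to fewer than 3 points")

    # enforce CCW orientation viewed down n
    uv = plane.project_uv(points)
    if _shoelace(uv) < 0:
        points, ev, ew = points[::-1], ev[::-1], ew[::-1]

    return PlanarContour(
        points=points, plane=plane, planarity_tol=1e-6,
        edge_vertices=ev, edge_weights=ew,
    )


def _shoelace(uv: np.ndarray) -> float:
    x, y = uv[:, 0], uv[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def contour_area(contour: PlanarContour) -> float:
    """Enclosed planar area (mm^2) by the shoelace formula in (u, v)."""
    uv = contour.uv()
    if len(uv) < 3:
        raise GeometryError("area needs >=3 contour points")
    return abs(_shoelace(uv))


def contour_centroid(contour: PlanarContour) -> np.ndarray:
    """Area-weighted polygon centroid, lifted back to 3D."""
    uv = contour.uv()
    a = _shoelace(uv)
    if a == 0:
        raise GeometryError("centroid undefined for zero-area contour")
    x, y = uv[:, 0], uv[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return contour.plane.lift([[cx, cy]])[0]


def fit_plane(points, reference_normal=None) -> AnalysisPlane:
    """Fit a plane to 3D points: mean-point origin, Newell-method normal.

    The Newell normal of an ordered (approximately planar) polygon is
    robust to noise and respects winding order; when ``reference_normal``
    is given the returned normal is flipped, if needed, so that
    ``n . reference_normal > 0`` (keeps diastolic/systolic normals
    consistently oriented).
    """
    p = np.asarray(points, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 3:
        raise GeometryError("plane fit needs >=3 points")
    origin = p.mean(axis=0)
    q = p - origin
    nxt = np.roll(q, -1, axis=0)
    n = np.array([
        np.sum((q[:, 1] - nxt[:, 1]) * (q[:, 2] + nxt[:, 2])),
        np.sum((q[:, 2] - nxt[:, 2]) * (q[:, 0] + nxt[:, 0])),
        np.sum((q[:, 0] - nxt[:, 0]) * (q[:, 1] + nxt[:, 1])),
    ])
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("points are collinear or coincident; plane undefined")
    n = n / norm
    if reference_normal is not None:
        ref = np.asarray(reference_normal, dtype=float).reshape(3)
        if float(n @ ref) < 0:
            n = -n
    return AnalysisPlane.from_normal(origin, n)
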