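"""Aortic root motion metrics from a mesh + diastole-to-systole displacement field.

Given the diastolic surface, the per-vertex displacement field produced by
deformable registration of the systolic phase onto the diastolic one, the
centerline, and the coronary-ostia landmarks, this module computes the
per-subject metric record:

* total / axial / in-plane displacement of the root at the sinus plane,
  and the relative (total-normalized) axial and in-plane components,
* axial tilt — angle between diastolic and systolic plane normals,
* aortic rotation — twist about the root axis, from centroid-to-reference
  vectors projected onto the diastolic plane,
* diastolic/systolic lumen areas, area ratio and distensibility
  (area ratio - 1) / pulse pressure, reported in 1e-3 / mmHg,
* LV/Ao angle between aortic- and mitral-annulus normals.

Axial displacement and rotation are reported as magnitudes (the convention
of cohort tables); signed values are retained on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    AnalysisPlane,
    Centerline,
    GeometryError,
    PlanarContour,
    TriSurfaceMesh,
    contour_area,
    contour_centroid,
    fit_plane,
    plane_at_ostia,
    slice_mesh,
)

__all__ = [
    "VertexDisplacementField",
    "RootMotionMetrics",
    "LvAoAngle",
    "MetricsError",
    "mean_plane_displacement",
    "decompose_displacement",
    "axial_tilt",
    "aortic_rotation",
    "distensibility",
    "lv_ao_angle",
    "compute_root_metrics",
]

_UNIT_TOL = 1e-9
SYSTOLIC_PLANARITY_TOL = 0.5  # mm; warped contours are only ~planar


class MetricsError(ValueError):
    """Raised when metric preconditions are violated."""


@dataclass(frozen=True)
class VertexDisplacementField:
    """One diastole-to-systole 3-vector (mm) per mesh vertex."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MetricsError("displacement field must be an (n, 3) array")
        if not np.isfinite(v).all():
            raise MetricsError("displacement field contains non-finite values")
        object.__setattr__(self, "vectors", v)

    def check_mesh(self, mesh: TriSurfaceMesh) -> None:
        if len(self.vectors) != mesh.n_vertices:
            raise MetricsError(
                f"field has {len(self.vectors)} vectors but mesh has "
                f"{mesh.n_vertices} vertices"
            )


class Decomposition(NamedTuple):
    total: float
    axial: float           # magnitude
    inplane: float
    rel_axial: float       # nan when total == 0
    rel_inplane: float
    axial_signed: float    # sign vs. root->arch normal


@dataclass(frozen=True)
class RootMotionMetrics:
    """Complete per-subject aortic root motion record."""

    total_disp: float            # mm
    axial_disp: float            # mm, magnitude
    inplane_disp: float          # mm
    rel_axial: float             # unitless, nan if total == 0
    rel_inplane: float
    axial_tilt_deg: float
    rotation_deg: float          # magnitude
    area_dia: float              # mm^2
    area_sys: float
    area_ratio: float
    distensibility: float        # 1e-3 / mmHg
    pulse_pressure: float        # mmHg
    axial_disp_signed: float = math.nan
    rotation_deg_signed: float = math.nan

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LvAoAngle:
    """Angle between the lines perpendicular to the aortic and mitral annuli."""

    phi_deg: float

    def __post_init__(self):
        if not (0.0 < self.phi_deg <= 180.0):
            raise MetricsError("LV/Ao angle must lie in (0, 180] degrees")


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between vectors via atan2(|a x b|, a.b) — safe at collinearity."""
    cross = np.linalg.norm(np.cross(a, b))
    dot = float(np.dot(a, b))
    return math.degrees(math.atan2(cross, dot))


def _require_unit(vec, name: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float).reshape(3)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise MetricsError(f"{name} must be a unit vector")
    return v


def interpolate_contour_field(
    contour: PlanarContour, field: VertexDisplacementField
) -> np.ndarray:
    """Displacement at each contour point by linear interpolation on its edge."""
    if contour.edge_vertices is None or contour.edge_weights is None:
        raise MetricsError("contour carries no mesh-edge interpolation data")
    d = field.vectors
    i, j = contour.edge_vertices[:, 0], contour.edge_vertices[:, 1]
    t = contour.edge_weights[:, None]
    return (1.0 - t) * d[i] + t * d[j]


def resample_closed_polyline(
    points: np.ndarray, values: np.ndarray, n_samples: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-arc-length resampling of a closed polyline and attached values.

    Removes mesh-density bias before averaging: contour points from a slice
    cluster where triangles are small.
    """
    closed = np.vstack([points, points[:1]])
    vals = np.vstack([values, values[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.arange(n_samples) * total / n_samples
    pts = np.column_stack([np.interp(si, s, closed[:, k]) for k in range(3)])
    out_vals = np.column_stack(
        [np.interp(si, s, vals[:, k]) for k in range(values.shape[1])]
    )
    return pts, out_vals


def mean_plane_displacement(
    mesh: TriSurfaceMesh,
    field: VertexDisplacementField,
    plane: AnalysisPlane,
    n_samples: int = 256,
) -> np.ndarray:
    """Mean 3D displacement of the lumen contour at the analysis plane.

    The displacement field is interpolated onto the slice contour, the
    contour is resampled at ``n_samples`` equal arc-length steps, and the
    arithmetic mean vector is returned.
    """
    field.check_mesh(mesh)
    contour = slice_mesh(mesh, plane)
    disp = interpolate_contour_field(contour, field)
    _, vals = resample_closed_polyline(contour.points, disp, n_samples)
    return vals.mean(axis=0)


def decompose_displacement(total_vec, n_dia) -> Decomposition:
    """Split a displacement into axial (along ``n_dia``) and in-plane parts.

    Relative components satisfy rel_axial^2 + rel_inplane^2 = 1 whenever the
    total is nonzero; a zero displacement leaves them undefined (NaN).
    """
    n = _require_unit(n_dia, "n_dia")
    vec = np.asarray(total_vec, dtype=float).reshape(3)
    total = float(np.linalg.norm(vec))
    axial_signed = float(vec @ n)
    axial = abs(axial_signed)
    inplane = float(np.linalg.norm(vec - axial_signed * n))
    if total > 0:
        rel_ax, rel_in = axial / total, inplane / total
    else:
        rel_ax = rel_in = math.nan
    return Decomposition(total, axial, inplane, rel_ax, rel_in, axial_signed)


def axial_tilt(n_dia, n_sys) -> float:
    """Angle (degrees) between diastolic and systolic plane normals.

    The systolic normal is flipped, if needed, so the two normals agree in
    orientation; the tilt is the acute deviation.
    """
    a = _require_unit(n_dia, "n_dia")
    b = _require_unit(n_sys, "n_sys")
    if float(a @ b) < 0:
        b = -b
    return _angle_deg(a, b)


def aortic_rotation(
    centroid_dia,
    centroid_sys,
    ref_dia,
    ref_sys,
    plane_dia: AnalysisPlane,
    signed: bool = False,
) -> float:
    """Twist of the root about its axis, in degrees.

    Each phase's centroid-to-reference vector is projected onto the
    diastolic plane; the returned angle is between the projections
    (unsigned by default; ``signed=True`` gives the right-handed angle
    about the diastolic normal).
    """
    n = plane_dia.n
    v1 = np.asarray(ref_dia, float) - np.asarray(centroid_dia, float)
    v2 = np.asarray(ref_sys, float) - np.asarray(centroid_sys, float)
    v1 = v1 - (v1 @ n) * n
    v2 = v2 - (v2 @ n) * n
    if np.linalg.norm(v1) < 1e-9 or np.linalg.norm(v2) < 1e-9:
        raise MetricsError(
            "reference vector nearly parallel to the plane normal; "
            "in-plane projection vanished"
        )
    x1, y1 = float(v1 @ plane_dia.u), float(v1 @ plane_dia.v)
    x2, y2 = float(v2 @ plane_dia.u), float(v2 @ plane_dia.v)
    ang = math.degrees(math.atan2(x1 * y2 - y1 * x2, x1 * x2 + y1 * y2))
    return ang if signed else abs(ang)


def distensibility(area_dia: float, area_sys: float, pulse_pressure: float):
    """Area ratio and distensibility D = (Asys/Adia - 1) / PP.

    Returns ``(area_ratio, distensibility)`` with distensibility scaled to
    the conventional 1e-3 / mmHg units.
    """
    if area_dia <= 0:
        raise MetricsError("diastolic area must be positive")
    if pulse_pressure <= 0:
        raise MetricsError("pulse pressure must be positive")
    ratio = area_sys / area_dia
    return ratio, (ratio - 1.0) / pulse_pressure * 1e3


def lv_ao_angle(
    aortic_annulus_pts, mitral_annulus_pts, lv_apex_hint, aorta_hint
) -> LvAoAngle:
    """LV/Ao angle from the two annulus point sets.

    Planes are fitted to each annulus; the aortic normal is oriented toward
    the aorta, the mitral normal toward the LV apex, and phi is the angle
    between those oriented normals (equivalently 180 deg minus the angle to
    the base-oriented mitral normal).  A coaxial outflow tract gives
    phi -> 180 deg and clinical hearts fall near 120-140 deg.
    """
    ao = fit_plane(aortic_annulus_pts)
    mi = fit_plane(mitral_annulus_pts)
    n_ao = ao.n if float(ao.n @ (np.asarray(aorta_hint, float) - ao.origin)) >= 0 else -ao.n
    n_mi = mi.n if float(mi.n @ (np.asarray(lv_apex_hint, float) - mi.origin)) >= 0 else -mi.n
    return LvAoAngle(phi_deg=_angle_deg(n_ao, n_mi))


def displacement_at_point(
    mesh: TriSurfaceMesh,
    field: VertexDisplacementField,
    point,
    k: int = 3,
) -> np.ndarray:
    """Inverse-distance interpolation of the field at an off-vertex point.

    Used for the systolic position of landmark points (e.g. the left
    coronary ostium, the rotation reference).
    """
    field.check_mesh(mesh)
    point = np.asarray(point, dtype=float).reshape(3)
    tree = cKDTree(mesh.vertices)
    dist, idx = tree.query(point, k=min(k, mesh.n_vertices))
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    if dist[0] < 1e-12:
        return field.vectors[idx[0]].copy()
    w = 1.0 / dist
    return (w[:, None] * field.vectors[idx]).sum(axis=0) / w.sum()


def compute_root_metrics(
    mesh: TriSurfaceMesh,
    field: VertexDisplacementField,
    centerline: Centerline,
    landmarks: dict,
    pulse_pressure: float,
    n_samples: int = 256,
    systolic_planarity_tol: float = SYSTOLIC_PLANARITY_TOL,
) -> RootMotionMetrics:
    """Run the full metric pipeline for one subject.

    ``landmarks`` must contain ``left_coronary_ostium`` and
    ``right_coronary_ostium`` (3-vectors, mm).  Stages: diastolic plane at
    the ostia level -> diastolic slice -> warp contour by the interpolated
    field -> fitted systolic plane -> areas/centroids -> mean displacement
    decomposition -> tilt, rotation, distensibility.
    """
    field.check_mesh(mesh)
    try:
        left = np.asarray(landmarks["left_coronary_ostium"], float).reshape(3)
        right = np.asarray(landmarks["right_coronary_ostium"], float).reshape(3)
    except KeyError as e:
        raise MetricsError(f"landmarks missing required entry {e}") from e

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (GeometryError, MetricsError) as e:
            raise MetricsError(f"stage '{name}': {e}") from e

    plane_dia = stage("plane_at_ostia", plane_at_ostia, centerline, left, right)
    contour_dia = stage("slice_diastolic", slice_mesh, mesh, plane_dia)
    disp_on_contour = stage(
        "interpolate_field", interpolate_contour_field, contour_dia, field
    )
    warped_pts = contour_dia.points + disp_on_contour

    plane_sys = stage("fit_systolic_plane", fit_plane, warped_pts, plane_dia.n)
    contour_sys = stage(
        "systolic_contour",
        PlanarContour,
        points=warped_pts,
        plane=plane_sys,
        planarity_tol=systolic_planarity_tol,
    )

    area_dia = stage("area_diastolic", contour_area, contour_dia)
    area_sys = stage("area_systolic", contour_area, contour_sys)
    centroid_dia = stage("centroid_diastolic", contour_centroid, contour_dia)
    centroid_sys = stage("centroid_systolic", contour_centroid, contour_sys)

    _, vals = resample_closed_polyline(contour_dia.points, disp_on_contour, n_samples)
    mean_disp = vals.mean(axis=0)
    dec = stage("decompose", decompose_displacement, mean_disp, plane_dia.n)

    tilt = stage("axial_tilt", axial_tilt, plane_dia.n, plane_sys.n)

    ref_dia = left
    ref_sys = ref_dia + stage(
        "reference_displacement", displacement_at_point, mesh, field, ref_dia
    )
    rot_signed = stage(
        "aortic_rotation",
        aortic_rotation,
        centroid_dia, centroid_sys, ref_dia, ref_sys, plane_dia,
        signed=True,
    )

    ratio, dist = stage(
        "distensibility", distensibility, area_dia, area_sys, pulse_pressure
    )

    return RootMotionMetrics(
        total_disp=dec.total,
        axial_disp=dec.axial,
        inplane_disp=dec.inplane,
        rel_axial=dec.rel_axial,
        rel_inplane=dec.rel_inplane,
        axial_tilt_deg=tilt,
        rotation_deg=abs(rot_signed),
        area_dia=area_dia,
        area_sys=area_sys,
        area_ratio=ratio,
        distensibility=dist,
        pulse_pressure=float(pulse_pressure),
        axial_disp_signed=dec.axial_signed,
        rotation_deg_signed=rot_signed,
    )
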