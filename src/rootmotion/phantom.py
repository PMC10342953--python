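"""Parametric aortic-root phantoms with analytically known motion metrics.

Real inputs to the pipeline are a registration-derived displacement field on
a patient mesh — not reproducible at desk scale.  The phantom stands in: a
tube along +z with a three-lobed sinus-of-Valsalva bulge, coronary-ostium
landmarks on the surface at the sinus level, the z-axis as centerline, and a
smooth prescribed deformation (in-plane dilation, twist about the plane
normal, tilt about an in-plane axis, rigid translation) whose plane-level
metric values are known in closed form:

* mean displacement = the rigid translation (dilation, twist and tilt
  average to zero over the symmetric contour),
* axial tilt = the prescribed tilt angle,
* aortic rotation = the prescribed twist angle,
* area ratio = dilation_factor^2.

Motion is constant at and below the analysis plane and decays exponentially
above it (root motion is transmitted from the ventricle below), so the
plane-level ground truth stays analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .geometry import AnalysisPlane, Centerline, GeometryError, TriSurfaceMesh
from .metrics import VertexDisplacementField

__all__ = [
    "PhantomParams",
    "DeformationParams",
    "PhantomGroundTruth",
    "make_root_phantom",
    "apply_deformation",
]

# fraction of tube length at which the sinus bulge is centered, and the
# Gaussian width of the bulge as a fraction of tube length
_SINUS_LEVEL_FRAC = 0.3
_SINUS_SIGMA_FRAC = 0.12


@dataclass(frozen=True)
class PhantomParams:
    """Geometry parameters of the synthetic root (all lengths in mm)."""

    root_radius: float = 15.0
    sinus_bulge_amplitude: float = 4.0
    sinus_lobes: int = 3
    tube_length: float = 60.0
    axial_resolution: int = 64
    circumferential_resolution: int = 128
    seed: int = 0
    vertex_noise_sd: float = 0.0

    def __post_init__(self):
        if self.root_radius <= 0:
            raise ValueError("root_radius must be positive")
        if self.axial_resolution < 16 or self.circumferential_resolution < 16:
            raise ValueError("axial_resolution and circumferential_resolution must be >= 16")
        if self.sinus_lobes < 0:
            raise ValueError("sinus_lobes must be >= 0")
        if self.vertex_noise_sd < 0:
            raise ValueError("vertex_noise_sd must be >= 0")
        if self.tube_length <= 0:
            raise ValueError("tube_length must be positive")


@dataclass(frozen=True)
class DeformationParams:
    """Prescribed diastole-to-systole motion components."""

    axial_translation: float = 0.0          # mm, along the plane normal
    inplane_translation: tuple = (0.0, 0.0)  # mm, in the (u, v) frame
    tilt_deg: float = 0.0                    # about an in-plane axis
    tilt_axis_angle_deg: float = 0.0         # direction of that axis in (u, v)
    twist_deg: float = 0.0                   # about the plane normal
    dilation_factor: float = 1.0             # linear in-plane scale
    decay_length: float = 20.0               # mm, axial falloff above the plane

    def __post_init__(self):
        if self.dilation_factor <= 0:
            raise ValueError("dilation_factor must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Metric values implied analytically by a DeformationParams draw."""

    total_disp: float
    axial_disp: float
    inplane_disp: float
    rel_axial: float
    rel_inplane: float
    tilt_deg: float
    rotation_deg: float
    area_ratio: float
    distensibility: float       # 1e-3 / mmHg at pulse_pressure
    pulse_pressure: float       # mmHg

    def as_dict(self) -> dict:
        return asdict(self)


def sinus_level(params: PhantomParams) -> float:
    """z of the analysis plane: the grid ring nearest 30% of tube length."""
    z = np.linspace(0.0, params.tube_length, params.axial_resolution)
    return float(z[np.argmin(np.abs(z - _SINUS_LEVEL_FRAC * params.tube_length))])


def _radius_profile(params: PhantomParams, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    z_s = sinus_level(params)
    sigma = _SINUS_SIGMA_FRAC * params.tube_length
    bulge = params.sinus_bulge_amplitude * np.exp(-((z - z_s) ** 2) / (2 * sigma**2))
    return params.root_radius + bulge * (1.0 + np.cos(params.sinus_lobes * theta)) / 2.0


def make_root_phantom(params: PhantomParams) -> tuple[TriSurfaceMesh, Centerline, dict]:
    """Build the phantom mesh, centerline and landmark dictionary.

    Coronary ostia sit on the surface at the sinus level, 120 degrees apart,
    on circumferential grid nodes so they coincide with mesh vertices.
    Aortic- and mitral-annulus rings (for the LV/Ao angle) are placed below
    the sinuses with a fixed 50-degree inter-normal angle.
    """
    nz, nc = params.axial_resolution, params.circumferential_resolution
    z = np.linspace(0.0, params.tube_length, nz)
    theta = 2.0 * np.pi * np.arange(nc) / nc

    zz, tt = np.meshgrid(z, theta, indexing="ij")
    r = _radius_profile(params, zz, tt)
    verts = np.column_stack(
        [(r * np.cos(tt)).ravel(), (r * np.sin(tt)).ravel(), zz.ravel()]
    )

    if params.vertex_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        verts = verts + rng.normal(0.0, params.vertex_noise_sd, verts.shape)

    tris = []
    for i in range(nz - 1):
        base0, base1 = i * nc, (i + 1) * nc
        for j in range(nc):
            jn = (j + 1) % nc
            tris.append([base0 + j, base1 + j, base1 + jn])
            tris.append([base0 + j, base1 + jn, base0 + jn])
    mesh = TriSurfaceMesh(vertices=verts, triangles=np.array(tris, dtype=np.int64))

    centerline = Centerline(
        np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    )

    z_s = sinus_level(params)
    i_s = int(np.argmin(np.abs(z - z_s)))

    def ostium(angle_deg: float) -> list[float]:
        j = int(round((angle_deg % 360.0) / 360.0 * nc)) % nc
        return [float(c) for c in verts[i_s * nc + j]]

    z_ann = max(z_s - 0.15 * params.tube_length, 0.0)
    ann_theta = 2.0 * np.pi * np.arange(12) / 12
    aortic_annulus = np.column_stack(
        [
            params.root_radius * np.cos(ann_theta),
            params.root_radius * np.sin(ann_theta),
            np.full(12, z_ann),
        ]
    )
    # mitral annulus: ring tilted 50 deg about y, centered left of the root
    eta = math.radians(50.0)
    n_mi = np.array([math.sin(eta), 0.0, math.cos(eta)])
    e1 = np.array([math.cos(eta), 0.0, -math.sin(eta)])
    e2 = np.array([0.0, 1.0, 0.0])
    mi_center = np.array([-2.0 * params.root_radius, 0.0, z_ann - 5.0])
    mi_r = 1.2 * params.root_radius
    mitral_annulus = (
        mi_center
        + mi_r * np.outer(np.cos(ann_theta), e1)
        + mi_r * np.outer(np.sin(ann_theta), e2)
    )

    landmarks = {
        "left_coronary_ostium": ostium(90.0),
        "right_coronary_ostium": ostium(-30.0),
        "centerline": centerline.points.tolist(),
        "aortic_annulus": aortic_annulus.tolist(),
        "mitral_annulus": mitral_annulus.tolist(),
        "lv_apex": (mi_center - 40.0 * n_mi).tolist(),
        "ascending_aorta": [0.0, 0.0, float(params.tube_length)],
        "sinus_level_z": z_s,
    }
    return mesh, centerline, landmarks


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * K + (1 - math.cos(angle_rad)) * (K @ K)


def apply_deformation(
    mesh: TriSurfaceMesh,
    centerline: Centerline,
    landmarks: dict,
    dparams: DeformationParams,
    plane: AnalysisPlane,
    pulse_pressure: float = 56.0,
    level_tol: float = 0.5,
) -> tuple[VertexDisplacementField, PhantomGroundTruth]:
    """Prescribe the deformation field and return it with its ground truth.

    Per vertex: displacement = w(a) * (T(x) - x) where T composes, about the
    plane origin, in-plane dilation -> twist about n -> tilt about the
    in-plane axis -> rigid translation, and w(a) = exp(-max(0, a)/decay)
    with a the signed height above the plane (w = 1 at and below it).
    """
    z_s = landmarks.get("sinus_level_z")
    if z_s is not None:
        # vertex jitter moves the ostium landmarks (and hence the plane
        # origin) by the noise scale; level_tol only guards against a plane
        # placed at a grossly different station
        if abs(float(plane.origin @ plane.n) - float(z_s)) > level_tol:
            raise GeometryError(
                "plane is not at the phantom sinus level; ground truth "
                "is only analytic there"
            )

    o, n, u, v = plane.origin, plane.n, plane.u, plane.v

    s = dparams.dilation_factor
    twist = math.radians(dparams.twist_deg)
    tilt = math.radians(dparams.tilt_deg)
    beta = math.radians(dparams.tilt_axis_angle_deg)
    tilt_axis = math.cos(beta) * u + math.sin(beta) * v
    R_twist = _rotation_about_axis(n, twist)
    R_tilt = _rotation_about_axis(tilt_axis, tilt)
    t_vec = (
        dparams.axial_translation * n
        + dparams.inplane_translation[0] * u
        + dparams.inplane_translation[1] * v
    )

    p = mesh.vertices - o
    a = p @ n
    q = p - np.outer(a, n)                       # in-plane part
    mapped = s * q + np.outer(a, n)              # in-plane dilation
    mapped = mapped @ R_twist.T
    mapped = mapped @ R_tilt.T
    mapped = mapped + t_vec
    w = np.exp(-np.maximum(a, 0.0) / dparams.decay_length)
    field = VertexDisplacementField(vectors=w[:, None] * (mapped - p))

    axial = abs(dparams.axial_translation)
    inplane = math.hypot(*dparams.inplane_translation)
    total = math.hypot(axial, inplane)
    if total > 0:
        rel_ax, rel_in = axial / total, inplane / total
    else:
        rel_ax = rel_in = math.nan
    ratio = s * s
    truth = PhantomGroundTruth(
        total_disp=total,
        axial_disp=axial,
        inplane_disp=inplane,
        rel_axial=rel_ax,
        rel_inplane=rel_in,
        tilt_deg=abs(dparams.tilt_deg),
        rotation_deg=abs(dparams.twist_deg),
        area_ratio=ratio,
        distensibility=(ratio - 1.0) / pulse_pressure * 1e3,
        pulse_pressure=float(pulse_pressure),
    )
    return field, truth
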