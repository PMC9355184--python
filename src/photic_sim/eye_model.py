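"""Geometry of a pseudophakic schematic model eye.

The scene is a Liou-Brennan-type schematic eye in which the crystalline
lens has been replaced by an intraocular lens (IOL): two aspheric corneal
surfaces, a decentered pupil in an absorbing iris plate, a biconvex IOL
(spherical front, conic + even-polynomial back) with a sharp cylindrical
edge, and a hemispherical retina.

Coordinate frame: origin at the corneal front vertex, +z posterior (into
the eye), +x nasal, +y superior.  All lengths are in millimetres.  All
optical surfaces are centred on the optical axis except the pupil
aperture, which is decentered nasally; the visual axis is slanted 5
degrees to the optical axis in the horizontal meridian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MediumSpec",
    "SurfaceSpec",
    "SceneConfig",
    "EyeScene",
    "sag",
    "sag_slope",
    "surface_normal",
    "build_scene",
    "locate_fovea",
]

EDGE_MODES = ("reflective", "antireflective", "absorbing")

# Refractive indices (design wavelength; no dispersion is modelled).
N_AIR = 1.0
N_CORNEA = 1.376
N_HUMOR = 1.336  # aqueous humor and vitreous body share this index
N_IOL = 1.458

# Structural parameters of the model eye (radii and thicknesses in mm).
CORNEA_FRONT_R = 7.77
CORNEA_FRONT_Q = -0.18
CORNEA_BACK_R = 6.40
CORNEA_BACK_Q = -0.60
CORNEA_THICKNESS = 0.5
ANTERIOR_CHAMBER = 3.16  # corneal back vertex -> iris plane
IRIS_TO_IOL = 1.0  # iris plane -> IOL front vertex
IOL_FRONT_R = 13.86  # spherical front surface
IOL_BACK_R = -11.66
IOL_BACK_Q = -1.5
IOL_BACK_ALPHAS = (-6.34e-3, 1.15e-3, -3.86e-7, -2.47e-8)  # mm^-1..mm^-7
IOL_CENTER_THICKNESS = 0.97
RETINA_R = -12.0
AXIAL_LENGTH = 23.95  # corneal front vertex -> retina apex
CORNEA_SEMI = 7.0  # 14 mm optical zone
IRIS_PLATE_SEMI = 7.0  # absorbing iris plate extent (14 mm diameter)
RETINA_SEMI = 12.0  # half sphere, 24 mm aperture
FOVEA_DIAMETER = 1.5

_SURFACE_KINDS = ("conic_asphere", "plane_with_aperture", "sphere_cap", "cylinder_band")


@dataclass(frozen=True)
class MediumSpec:
    """A homogeneous optical medium."""

    name: str
    refractive_index: float

    def __post_init__(self) -> None:
        if self.refractive_index < 1.0:
            raise ValueError(f"refractive index of {self.name!r} must be >= 1")


@dataclass(frozen=True)
class SurfaceSpec:
    """One optical boundary: geometry, placement, aperture and media.

    ``radius`` is the signed radius of curvature at the vertex
    (``math.inf`` for a plane); ``conic_q`` the conic constant;
    ``poly_alpha`` the even-power sag coefficients (alpha_2 .. alpha_8, in
    mm^-1 .. mm^-7).  For a ``cylinder_band`` the cylinder radius equals
    ``semi_diameter`` and the band spans ``start_z`` to ``end_z``.  The
    iris plane additionally carries ``plate_semi_diameter``, the lateral
    extent of the absorbing plate around its clear (pupil) aperture.
    """

    label: str
    kind: str
    vertex_z: float
    radius: float
    semi_diameter: float
    conic_q: float = 0.0
    poly_alpha: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    decenter_x: float = 0.0
    medium_before: str = ""
    medium_after: str = ""
    start_z: float | None = None
    end_z: float | None = None
    plate_semi_diameter: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _SURFACE_KINDS:
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if not self.semi_diameter > 0:
            raise ValueError("semi_diameter must be positive")
        if self.kind in ("conic_asphere", "sphere_cap") and math.isfinite(self.radius):
            c = 1.0 / self.radius
            arg = 1.0 - (1.0 + self.conic_q) * c * c * self.semi_diameter**2
            if arg < -1e-12:
                raise ValueError(
                    f"surface {self.label!r}: sag is not real over the clear aperture"
                )
        if self.kind == "cylinder_band":
            if self.start_z is None or self.end_z is None or not self.start_z < self.end_z:
                raise ValueError("cylinder_band needs start_z < end_z")

    @property
    def curvature(self) -> float:
        return 0.0 if math.isinf(self.radius) else 1.0 / self.radius


def _sag_raw(c: float, q: float, alphas, r2):
    """Conic + even-polynomial sag as a function of r^2 (no domain checks)."""
    u = 1.0 - (1.0 + q) * c * c * r2
    z = c * r2 / (1.0 + np.sqrt(np.maximum(u, 0.0)))
    a2, a4, a6, a8 = alphas
    return z + r2 * (a2 + r2 * (a4 + r2 * (a6 + r2 * a8)))


def _sag_slope_raw(c: float, q: float, alphas, r):
    """d(sag)/dr (no domain checks)."""
    r2 = r * r
    u = 1.0 - (1.0 + q) * c * c * r2
    dz = c * r / np.sqrt(np.maximum(u, 1e-300))
    a2, a4, a6, a8 = alphas
    return dz + r * (2 * a2 + r2 * (4 * a4 + r2 * (6 * a6 + r2 * 8 * a8)))


def sag(surface: SurfaceSpec, r):
    """Axial sag z(r) of a rotationally symmetric cap at radial distance r.

    z(r) = c r^2 / (1 + sqrt(1 - (1+Q) c^2 r^2)) + sum_k alpha_2k r^2k,
    with c = 1/radius; the sign follows the signed radius.

    Raises ``ValueError`` outside the clear aperture or where the conic
    square root would go negative.
    """
    if surface.kind not in ("conic_asphere", "sphere_cap"):
        raise ValueError(f"sag undefined for kind {surface.kind!r}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > surface.semi_diameter + 1e-9):
        raise ValueError("r outside [0, semi_diameter]")
    c = surface.curvature
    u = 1.0 - (1.0 + surface.conic_q) * c * c * r * r
    if np.any(u < -1e-12):
        raise ValueError("conic sag square-root argument is negative")
    out = _sag_raw(c, surface.conic_q, surface.poly_alpha, r * r)
    return float(out) if out.ndim == 0 else out


def sag_slope(surface: SurfaceSpec, r):
    """Radial derivative d(sag)/dr of a rotationally symmetric cap."""
    if surface.kind not in ("conic_asphere", "sphere_cap"):
        raise ValueError(f"sag slope undefined for kind {surface.kind!r}")
    r = np.asarray(r, dtype=float)
    out = _sag_slope_raw(surface.curvature, surface.conic_q, surface.poly_alpha, r)
    return float(out) if out.ndim == 0 else out


def surface_normal(surface: SurfaceSpec, point, tol: float = 1e-6) -> np.ndarray:
    """Unit surface normal at a point lying on the surface.

    Orientation convention: normals of refracting caps and of the iris
    plane point toward the -z half-space (anterior); the edge-cylinder
    normal points radially outward; the retinal sphere normal points away
    from the sphere center.
    """
    p = np.asarray(point, dtype=float)
    x, y, z = p
    r = math.hypot(x, y)
    if surface.kind == "plane_with_aperture":
        if abs(z - surface.vertex_z) > tol:
            raise ValueError("point is not on the plane")
        return np.array([0.0, 0.0, -1.0])
    if surface.kind == "cylinder_band":
        if abs(r - surface.semi_diameter) > tol:
            raise ValueError("point is not on the cylinder")
        return np.array([x / r, y / r, 0.0])
    if surface.label == "retina":
        center = np.array([0.0, 0.0, surface.vertex_z + surface.radius])
        v = p - center
        dist = float(np.linalg.norm(v))
        if abs(dist - abs(surface.radius)) > tol:
            raise ValueError("point is not on the retinal sphere")
        return v / dist
    # rotationally symmetric refracting cap: gradient of z - sag(r)
    if abs((z - surface.vertex_z) - float(sag(surface, min(r, surface.semi_diameter)))) > tol:
        raise ValueError(f"point is not on surface {surface.label!r}")
    if r < 1e-12:
        return np.array([0.0, 0.0, -1.0])
    s = float(sag_slope(surface, r))
    n = np.array([s * x / r, s * y / r, -1.0])
    return n / np.linalg.norm(n)


@dataclass(frozen=True)
class SceneConfig:
    """Configuration of one simulation variant.

    ``iol_diameter_mm`` selects the 6 mm or 7 mm optic; ``edge_mode`` one
    of the three idealized edge designs.  ``iol_center_thickness_mm`` may
    be overridden (the structural table lists 0.97 mm for both optics);
    the retina stays at the fixed axial length.
    """

    iol_diameter_mm: float = 6.0
    edge_mode: str = "reflective"
    pupil_diameter_mm: float = 4.5
    pupil_decenter_nasal_mm: float = 0.5
    visual_axis_slant_deg: float = 5.0
    n_rays: int = 200_000
    angle_start_deg: float = 0.0
    angle_stop_deg: float = 90.0
    angle_step_deg: float = 1.0
    rng_seed: int = 0
    max_events: int = 50
    iol_center_thickness_mm: float = IOL_CENTER_THICKNESS

    def __post_init__(self) -> None:
        if float(self.iol_diameter_mm) not in (6.0, 7.0):
            raise ValueError("iol_diameter_mm must be 6 or 7")
        if self.edge_mode not in EDGE_MODES:
            raise ValueError(f"edge_mode must be one of {EDGE_MODES}")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if not (0.0 <= self.angle_start_deg <= self.angle_stop_deg <= 90.0):
            raise ValueError("angle range must lie within [0, 90] degrees")
        if self.angle_step_deg <= 0:
            raise ValueError("angle_step_deg must be positive")
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")

    def angles(self) -> np.ndarray:
        n = int(round((self.angle_stop_deg - self.angle_start_deg) / self.angle_step_deg))
        return self.angle_start_deg + self.angle_step_deg * np.arange(n + 1)


@dataclass
class EyeScene:
    """The assembled scene: ordered surfaces, media, fovea and edge mode."""

    surfaces: list[SurfaceSpec]
    media: dict[str, MediumSpec]
    edge_mode: str
    config: SceneConfig
    fovea_center: np.ndarray | None = None
    fovea_diameter_mm: float = FOVEA_DIAMETER
    extent_mm: float = 40.0  # bounding extent for escape bookkeeping
    _by_label: dict[str, SurfaceSpec] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_label = {s.label: s for s in self.surfaces}

    def surface(self, label: str) -> SurfaceSpec:
        return self._by_label[label]

    def index(self, n_or_name) -> float:
        """Refractive index of a medium by name."""
        return self.media[n_or_name].refractive_index

    @property
    def retina_center(self) -> np.ndarray:
        s = self.surface("retina")
        return np.array([0.0, 0.0, s.vertex_z + s.radius])

    @property
    def fovea_radius_mm(self) -> float:
        return 0.5 * self.fovea_diameter_mm


def _scene_surfaces(config: SceneConfig) -> list[SurfaceSpec]:
    optic_semi = float(config.iol_diameter_mm) / 2.0
    z_cb = CORNEA_THICKNESS
    z_iris = z_cb + ANTERIOR_CHAMBER
    z_iol_f = z_iris + IRIS_TO_IOL
    z_iol_b = z_iol_f + config.iol_center_thickness_mm

    cornea_front = SurfaceSpec(
        "cornea_front", "conic_asphere", 0.0, CORNEA_FRONT_R, CORNEA_SEMI,
        conic_q=CORNEA_FRONT_Q, medium_before="air", medium_after="cornea",
    )
    cornea_back = SurfaceSpec(
        "cornea_back", "conic_asphere", z_cb, CORNEA_BACK_R, CORNEA_SEMI,
        conic_q=CORNEA_BACK_Q, medium_before="cornea", medium_after="aqueous",
    )
    iris = SurfaceSpec(
        "iris_plane", "plane_with_aperture", z_iris, math.inf,
        config.pupil_diameter_mm / 2.0,
        decenter_x=config.pupil_decenter_nasal_mm,
        medium_before="aqueous", medium_after="aqueous",
        plate_semi_diameter=IRIS_PLATE_SEMI,
    )
    iol_front = SurfaceSpec(
        "iol_front", "conic_asphere", z_iol_f, IOL_FRONT_R, optic_semi,
        medium_before="aqueous", medium_after="iol",
    )
    iol_back = SurfaceSpec(
        "iol_back", "conic_asphere", z_iol_b, IOL_BACK_R, optic_semi,
        conic_q=IOL_BACK_Q, poly_alpha=IOL_BACK_ALPHAS,
        medium_before="iol", medium_after="vitreous",
    )
    # The sharp circular edge spans the axial gap between the two rim sags.
    rim_front = z_iol_f + float(sag(iol_front, optic_semi))
    rim_back = z_iol_b + float(sag(iol_back, optic_semi))
    if not rim_front < rim_back:
        raise ValueError("IOL rim is inverted: center thickness too small for this optic")
    edge = SurfaceSpec(
        "iol_edge", "cylinder_band", z_iol_f, math.inf, optic_semi,
        start_z=rim_front, end_z=rim_back,
        medium_before="aqueous", medium_after="iol",
    )
    retina = SurfaceSpec(
        "retina", "sphere_cap", AXIAL_LENGTH, RETINA_R, RETINA_SEMI,
        medium_before="vitreous", medium_after="vitreous",
    )
    return [cornea_front, cornea_back, iris, iol_front, iol_back, edge, retina]


def build_scene(config: SceneConfig) -> EyeScene:
    """Assemble the seven-boundary pseudophakic scene for a configuration.

    Deterministic: identical configs produce identical scenes.  The fovea
    is located by tracing the 0-degree chief ray (see :func:`locate_fovea`).
    """
    media = {
        "air": MediumSpec("air", N_AIR),
        "cornea": MediumSpec("cornea", N_CORNEA),
        "aqueous": MediumSpec("aqueous", N_HUMOR),
        "iol": MediumSpec("iol", N_IOL),
        "vitreous": MediumSpec("vitreous", N_HUMOR),
    }
    scene = EyeScene(
        surfaces=_scene_surfaces(config), media=media,
        edge_mode=config.edge_mode, config=config,
    )
    scene.fovea_center = locate_fovea(scene)
    # on-sphere invariant
    d = float(np.linalg.norm(scene.fovea_center - scene.retina_center))
    if abs(d - abs(RETINA_R)) > 1e-9:
        raise RuntimeError("fovea does not lie on the retinal sphere")
    return scene


def locate_fovea(scene: EyeScene) -> np.ndarray:
    """Retinal intersection of the 0-degree chief ray (the visual axis).

    The chief ray travels at the visual-axis slant to the optical axis
    (arriving from the nasal field), is aimed so that after corneal
    refraction it passes through the decentered pupil center, and is then
    traced through the IOL to the retina.  Single deterministic ray.
    """
    from . import ray_engine  # deferred: ray_engine depends on this module
    from scipy.optimize import brentq

    cfg = scene.config
    slant = math.radians(cfg.visual_axis_slant_deg)
    d0 = np.array([-math.sin(slant), 0.0, math.cos(slant)])
    pupil_cx = cfg.pupil_decenter_nasal_mm
    z_iris = scene.surface("iris_plane").vertex_z

    def pupil_cross_x(x0: float) -> float:
        """x where the refracted ray crosses the iris plane."""
        o, d = np.array([x0, 0.0, -10.0]), d0.copy()
        for label in ("cornea_front", "cornea_back"):
            s = scene.surface(label)
            ray = ray_engine.Ray(origin=o, direction=d)
            t = ray_engine.intersect(ray, s)
            if t is None:
                raise RuntimeError(f"chief ray missed {label}")
            p = o + t * d
            n = surface_normal(s, p)
            d, tir = ray_engine.refract(
                d, n, scene.index(s.medium_before), scene.index(s.medium_after)
            )
            if tir:
                raise RuntimeError("chief ray TIR at the cornea")
            o = p + 1e-9 * d
        return float(o[0] + (z_iris - o[2]) / d[2] * d[0])

    x0 = brentq(lambda x: pupil_cross_x(x) - pupil_cx, -5.0, 6.0, xtol=1e-12)
    chief = ray_engine.Ray(origin=np.array([x0, 0.0, -10.0]), direction=d0.copy())
    rec = ray_engine.trace(chief, scene, cfg.max_events)
    if rec.status != "terminated_retina":
        raise RuntimeError(f"chief ray did not reach the retina ({rec.status})")
    return np.asarray(rec.retinal_point, dtype=float)
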