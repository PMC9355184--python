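"""Collimated Monte-Carlo ray bundles at a commanded field angle.

The field angle theta is measured from the visual axis, which is itself
slanted (by default 5 degrees) to the optical axis in the horizontal
meridian: a bundle at theta travels at theta_opt = theta - slant to the
optical axis, toward nasal (+x) for positive theta_opt.  At theta = 0
the light arrives from the nasal field along the visual axis; as theta
grows the source swings into the temporal field.

Origins are sampled uniformly on a disc oriented perpendicular to the
beam (so the cross-sectional ray density is unweighted) and placed far
enough in front of the cornea that every origin sits at least the
standoff distance before the corneal vertex plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ray_engine import Ray

__all__ = ["BeamSpec", "direction_of", "generate_beam", "generate_beam_arrays"]

DEFAULT_FOOTPRINT_RADIUS = 8.5  # mm; covers the 14 mm corneal zone silhouette
DEFAULT_STANDOFF = 10.0  # mm in front of the corneal vertex
_AIM_Z = 3.66  # mm; the disc center is aimed back from the pupil plane


@dataclass(frozen=True)
class BeamSpec:
    """A collimated bundle: field angle, size, seed and footprint."""

    theta_deg: float
    n_rays: int
    rng_seed: int = 0
    footprint_radius: float = DEFAULT_FOOTPRINT_RADIUS
    standoff: float = DEFAULT_STANDOFF
    slant_deg: float = 5.0
    aim_x: float = 0.5  # mm; nasal pupil decenter the disc center is aimed at

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError("theta_deg must lie in [0, 90]")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")
        if self.footprint_radius < 7.0:
            raise ValueError("footprint_radius must cover the 14 mm corneal zone")


def direction_of(theta_deg: float, slant_deg: float = 5.0) -> np.ndarray:
    """Unit propagation direction for field angle ``theta_deg``.

    With theta_opt = theta - slant (angle to the optical axis, positive
    travelling toward nasal/+x): d = (sin theta_opt, 0, cos theta_opt).
    """
    if not (0.0 <= theta_deg <= 90.0):
        raise ValueError("theta_deg must lie in [0, 90]")
    th = math.radians(theta_deg - slant_deg)
    return np.array([math.sin(th), 0.0, math.cos(th)])


def generate_beam_arrays(spec: BeamSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded (origins, directions) arrays for a collimated bundle.

    Origins sample a uniform disc of ``footprint_radius`` perpendicular
    to the beam; every origin lies at z <= -standoff.  All directions
    are identical (collimation), one unit of power per ray.
    """
    d = direction_of(spec.theta_deg, spec.slant_deg)
    th = math.radians(spec.theta_deg - spec.slant_deg)
    sin_t, cos_t = math.sin(th), math.cos(th)
    # in-plane basis of the disc (horizontal meridian, and +y)
    e1 = np.array([cos_t, 0.0, -sin_t])
    e2 = np.array([0.0, 1.0, 0.0])
    # back the disc center off from the pupil-plane aim point until the
    # closest disc point is `standoff` in front of the corneal vertex
    length = (_AIM_Z + spec.standoff + spec.footprint_radius * abs(sin_t)) / cos_t
    center = np.array([spec.aim_x, 0.0, _AIM_Z]) - length * d

    rng = np.random.default_rng(spec.rng_seed)
    r = spec.footprint_radius * np.sqrt(rng.random(spec.n_rays))
    phi = 2.0 * math.pi * rng.random(spec.n_rays)
    origins = (center[None, :]
               + (r * np.cos(phi))[:, None] * e1[None, :]
               + (r * np.sin(phi))[:, None] * e2[None, :])
    directions = np.broadcast_to(d, origins.shape).copy()
    return origins, directions


def generate_beam(spec: BeamSpec) -> list[Ray]:
    """The bundle as a list of :class:`Ray` objects (unit power each)."""
    origins, directions = generate_beam_arrays(spec)
    return [Ray(origin=o, direction=v) for o, v in zip(origins, directions)]
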