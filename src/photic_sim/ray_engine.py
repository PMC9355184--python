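"""Non-sequential ray propagation through the pseudophakic eye scene.

Each ray is propagated from surface event to surface event: the nearest
intersected boundary among *all* scene surfaces is found (rays may hit
surfaces in any order, any number of times), then the boundary rule is
applied — vector Snell refraction with total internal reflection at the
refracting caps, absorption at the iris plate, the configured behaviour
at the IOL edge cylinder, and termination at the retina.  Rays carry
unit power throughout: there is no Fresnel partial-power splitting, so
reflection occurs only through TIR or a reflective edge.

Two equivalent entry points are provided: a per-ray API (:func:`step`,
:func:`trace`) and a vectorized bundle tracer (:func:`trace_bundle`)
that propagates the whole Monte-Carlo bundle as numpy arrays.  Both run
the same event kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import eye_model
from .eye_model import EyeScene, SurfaceSpec, _sag_raw, _sag_slope_raw

__all__ = [
    "Ray",
    "TerminalRecord",
    "BundleResult",
    "intersect",
    "refract",
    "reflect",
    "step",
    "trace",
    "trace_bundle",
]

EPS_T = 1e-9  # minimum parametric distance to the next event, mm
OFFSET = 1e-9  # advance past each interaction to avoid self-reintersection, mm

# terminal status codes used by the array kernel
ALIVE, ABSORBED_IRIS, ABSORBED_EDGE, RETINA, ESCAPED, CAPPED = range(6)
STATUS_NAMES = (
    "alive",
    "absorbed_iris",
    "absorbed_edge",
    "terminated_retina",
    "escaped",
    "event_capped",
)

# nearest-surface search order; ties at shared rim points resolve in favour
# of the caps (front, back) over the edge cylinder
_ORDER = ("cornea_front", "cornea_back", "iol_front", "iol_back",
          "iol_edge", "iris_plane", "retina")


@dataclass
class Ray:
    """A single ray with its interaction history."""

    origin: np.ndarray
    direction: np.ndarray
    power: float = 1.0
    medium: str = "air"
    hit_iol: bool = False
    first_edge_hit: bool = False
    pupil_transit: bool = False
    n_events: int = 0
    status: str = "alive"
    retinal_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        self.direction = d / np.linalg.norm(d)


@dataclass(frozen=True)
class TerminalRecord:
    """Outcome of tracing one ray to termination."""

    status: str
    terminal_point: np.ndarray
    terminal_direction: np.ndarray
    hit_iol: bool
    first_edge_hit: bool
    pupil_transit: bool
    n_events: int
    retinal_point: np.ndarray | None = None


# ---------------------------------------------------------------------------
# intersection kernels (vectorized over rays)

def _solve_quadratic(A, B, C):
    """Roots of A t^2 + B t + C = 0, returned sorted; nan where none."""
    A, B, C = np.broadcast_arrays(A, B, C)
    t_lo = np.full(A.shape, np.nan)
    t_hi = np.full(A.shape, np.nan)
    lin = np.abs(A) < 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        tl = np.where(np.abs(B) > 1e-300, -C / B, np.nan)
    t_lo[lin] = tl[lin]
    disc = B * B - 4.0 * A * C
    ok = (~lin) & (disc >= 0.0)
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        b, a, c = B[ok], A[ok], C[ok]
        q = -0.5 * (b + np.copysign(sq, b))
        with np.errstate(divide="ignore", invalid="ignore"):
            r1 = np.where(np.abs(a) > 0, q / a, np.nan)
            r2 = np.where(np.abs(q) > 0, c / q, r1)
        t_lo[ok] = np.minimum(r1, r2)
        t_hi[ok] = np.maximum(r1, r2)
    return t_lo, t_hi


def _t_conic_cap(s: SurfaceSpec, o, d):
    """Nearest valid hit with a conic(+polynomial) cap; inf where none."""
    c, q1 = s.curvature, 1.0 + s.conic_q
    has_poly = any(a != 0.0 for a in s.poly_alpha)
    zr = o[:, 2] - s.vertex_z
    A = c * (d[:, 0] ** 2 + d[:, 1] ** 2) + c * q1 * d[:, 2] ** 2
    B = (2.0 * c * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1])
         + 2.0 * c * q1 * zr * d[:, 2] - 2.0 * d[:, 2])
    C = c * (o[:, 0] ** 2 + o[:, 1] ** 2) + c * q1 * zr * zr - 2.0 * zr
    t_lo, t_hi = _solve_quadratic(A, B, C)

    best = np.full(o.shape[0], np.inf)
    for t_cand in (t_lo, t_hi):
        todo = ~np.isfinite(best)
        cand = np.where(np.isnan(t_cand), -1.0, t_cand)
        m = todo & (cand > EPS_T)
        if not np.any(m):
            continue
        t = cand[m]
        p = o[m] + t[:, None] * d[m]
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        u = 1.0 - q1 * c * c * r2
        # near-branch test against the pure conic (the quadratic solves it)
        zc = np.where(u >= 0.0, c * r2 / (1.0 + np.sqrt(np.maximum(u, 0.0))), np.inf)
        near = (u >= -1e-12) & (np.abs((p[:, 2] - s.vertex_z) - zc) < 1e-6)
        if has_poly:
            ok = near & (r2 <= (1.5 * s.semi_diameter) ** 2)
            t_ref = _refine_poly(s, o[m][ok], d[m][ok], t[ok])
            tt = np.full(t.shape, np.inf)
            tt[ok] = t_ref
            valid = np.isfinite(tt) & (tt > EPS_T)
            t = tt
        else:
            valid = near & (r2 <= (s.semi_diameter + 1e-9) ** 2)
        sel = np.where(valid, t, np.inf)
        idx = np.flatnonzero(m)
        best[idx] = np.minimum(best[idx], sel)
    return best


def _refine_poly(s: SurfaceSpec, o, d, t0):
    """Newton-refine conic-only hits onto the full polynomial asphere.

    Returns inf where the iteration fails to converge or leaves the
    clear aperture.
    """
    if len(t0) == 0:
        return t0.copy()
    c, q1 = s.curvature, 1.0 + s.conic_q
    t = t0.copy()
    g = np.full(t.shape, np.inf)
    for _ in range(20):
        p = o + t[:, None] * d
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        r = np.sqrt(r2)
        g = (p[:, 2] - s.vertex_z) - _sag_raw(c, s.conic_q, s.poly_alpha, r2)
        if np.all(np.abs(g) < 1e-12):
            break
        dsag = _sag_slope_raw(c, s.conic_q, s.poly_alpha, r)
        drdt = (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]) / np.maximum(r, 1e-12)
        gp = d[:, 2] - dsag * drdt
        gp = np.where(np.abs(gp) < 1e-14, np.copysign(1e-14, gp + 1e-300), gp)
        t = t - g / gp
    p = o + t[:, None] * d
    r2 = p[:, 0] ** 2 + p[:, 1] ** 2
    bad = (np.abs(g) > 1e-9) | (r2 > (s.semi_diameter + 1e-9) ** 2) | (t <= EPS_T)
    return np.where(bad, np.inf, t)


def _t_retina(s: SurfaceSpec, o, d):
    """Nearest hit with the posterior retinal hemisphere; inf where none."""
    cz = s.vertex_z + s.radius
    oc = o - np.array([0.0, 0.0, cz])
    B = 2.0 * np.einsum("ij,ij->i", oc, d)
    C = np.einsum("ij,ij->i", oc, oc) - s.radius * s.radius
    t_lo, t_hi = _solve_quadratic(np.ones_like(B), B, C)
    best = np.full(o.shape[0], np.inf)
    for t_cand in (t_lo, t_hi):
        cand = np.where(np.isnan(t_cand), -1.0, t_cand)
        z = o[:, 2] + cand * d[:, 2]
        valid = (cand > EPS_T) & (z >= cz - 1e-9) & ~np.isfinite(best)
        best = np.where(valid, cand, best)
    return best


def _t_iris(s: SurfaceSpec, o, d):
    """Hit with the iris plate (clear pupil included); inf beyond the plate."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (s.vertex_z - o[:, 2]) / d[:, 2]
        t = np.where(np.abs(d[:, 2]) < 1e-14, np.inf, t)
        x = np.where(np.isfinite(t), o[:, 0] + t * d[:, 0], np.inf)
        y = np.where(np.isfinite(t), o[:, 1] + t * d[:, 1], np.inf)
    plate = s.plate_semi_diameter if s.plate_semi_diameter is not None else np.inf
    ok = (t > EPS_T) & (x * x + y * y <= plate * plate)
    return np.where(ok, t, np.inf)


def _t_cylinder(s: SurfaceSpec, o, d):
    """Nearest hit with the edge cylinder band; inf where none."""
    A = d[:, 0] ** 2 + d[:, 1] ** 2
    B = 2.0 * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1])
    C = o[:, 0] ** 2 + o[:, 1] ** 2 - s.semi_diameter**2
    t_lo, t_hi = _solve_quadratic(A, B, C)
    best = np.full(o.shape[0], np.inf)
    for t_cand in (t_lo, t_hi):
        cand = np.where(np.isnan(t_cand), -1.0, t_cand)
        z = o[:, 2] + cand * d[:, 2]
        valid = ((cand > EPS_T) & (z >= s.start_z - 1e-12)
                 & (z <= s.end_z + 1e-12) & ~np.isfinite(best))
        best = np.where(valid, cand, best)
    return best


def _t_surface(s: SurfaceSpec, o, d):
    if s.kind == "conic_asphere":
        return _t_conic_cap(s, o, d)
    if s.kind == "plane_with_aperture":
        return _t_iris(s, o, d)
    if s.kind == "cylinder_band":
        return _t_cylinder(s, o, d)
    if s.kind == "sphere_cap":
        return _t_retina(s, o, d)
    raise ValueError(f"unknown surface kind {s.kind!r}")


def intersect(ray: Ray, surface: SurfaceSpec) -> float | None:
    """Smallest parametric distance t > eps to the surface, or None.

    The hit point must lie inside the surface's aperture (for the iris
    plane: anywhere on the plate, pupil opening included).
    """
    t = _t_surface(surface, ray.origin[None, :], ray.direction[None, :])[0]
    return float(t) if np.isfinite(t) else None


# ---------------------------------------------------------------------------
# local interaction kernels

def _refract_arrays(d, n, n1, n2):
    """Vector Snell refraction; returns (directions, tir_mask).

    Normals may point either way; they are re-oriented against the
    incoming direction internally.
    """
    dot = np.einsum("ij,ij->i", d, n)
    n_or = np.where(dot[:, None] > 0, -n, n)
    cosi = -np.einsum("ij,ij->i", d, n_or)
    eta = n1 / n2
    k = 1.0 - eta * eta * (1.0 - cosi * cosi)
    tir = k < 0.0
    t = eta[:, None] * d + (eta * cosi - np.sqrt(np.maximum(k, 0.0)))[:, None] * n_or
    norm = np.linalg.norm(t, axis=1, keepdims=True)
    t = t / np.where(norm > 0, norm, 1.0)
    return t, tir


def _reflect_arrays(d, n):
    return d - 2.0 * np.einsum("ij,ij->i", d, n)[:, None] * n


def refract(d, n, n1: float, n2: float):
    """Vector Snell's law for one ray: (transmitted direction, tir_flag).

    On total internal reflection the incoming direction is returned
    unchanged together with ``tir=True``.
    """
    d = np.asarray(d, dtype=float)[None, :]
    n = np.asarray(n, dtype=float)[None, :]
    t, tir = _refract_arrays(d, n, np.array([n1]), np.array([n2]))
    if tir[0]:
        return d[0].copy(), True
    return t[0], False


def reflect(d, n) -> np.ndarray:
    """Specular reflection d - 2 (d.n) n (orientation-independent)."""
    d = np.asarray(d, dtype=float)
    n = np.asarray(n, dtype=float)
    return d - 2.0 * float(np.dot(d, n)) * n


def _cap_normals(s: SurfaceSpec, p):
    """Anterior-pointing unit normals of a rotationally symmetric cap."""
    x, y = p[:, 0], p[:, 1]
    r = np.sqrt(x * x + y * y)
    slope = _sag_slope_raw(s.curvature, s.conic_q, s.poly_alpha, r)
    safe_r = np.maximum(r, 1e-12)
    n = np.stack([slope * x / safe_r, slope * y / safe_r, -np.ones_like(r)], axis=1)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# the event kernel and its two drivers

@dataclass
class _BundleState:
    o: np.ndarray
    d: np.ndarray
    status: np.ndarray
    hit_iol: np.ndarray
    first_edge_hit: np.ndarray
    pupil_transit: np.ndarray
    n_events: np.ndarray
    terminal: np.ndarray
    medium: np.ndarray  # medium name per ray (object array; bookkeeping only)


@dataclass
class BundleResult:
    """Terminal state of a traced bundle (arrays indexed per launched ray)."""

    status: np.ndarray
    hit_iol: np.ndarray
    first_edge_hit: np.ndarray
    pupil_transit: np.ndarray
    n_events: np.ndarray
    terminal_points: np.ndarray
    terminal_directions: np.ndarray

    @property
    def retinal_mask(self) -> np.ndarray:
        return self.status == RETINA

    def status_counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.status == code))
                for code, name in enumerate(STATUS_NAMES)}


def _compiled(scene: EyeScene) -> list[SurfaceSpec]:
    present = {s.label for s in scene.surfaces}
    return [scene.surface(lbl) for lbl in _ORDER if lbl in present]


def _advance(state: _BundleState, scene: EyeScene, surfs: list[SurfaceSpec]) -> None:
    """Process one surface event for every alive ray (in place)."""
    alive = np.flatnonzero(state.status == ALIVE)
    if alive.size == 0:
        return
    o, d = state.o[alive], state.d[alive]
    T = np.empty((len(surfs), alive.size))
    for i, s in enumerate(surfs):
        T[i] = _t_surface(s, o, d)
    imin = np.argmin(T, axis=0)
    tmin = T[imin, np.arange(alive.size)]

    # no surface ahead -> escaped
    esc = ~np.isfinite(tmin)
    state.status[alive[esc]] = ESCAPED
    state.terminal[alive[esc]] = o[esc]

    hit = ~esc
    p = o + np.where(hit, tmin, 0.0)[:, None] * d

    for si, s in enumerate(surfs):
        m = hit & (imin == si)
        if not np.any(m):
            continue
        idx = alive[m]
        pm, dm = p[m], d[m]

        if s.label == "retina":
            state.status[idx] = RETINA
            state.terminal[idx] = pm

        elif s.kind == "plane_with_aperture":
            dx = pm[:, 0] - s.decenter_x
            in_pupil = dx * dx + pm[:, 1] ** 2 <= s.semi_diameter**2
            # Detector-P monitor: tally forward pupil transits, ray untouched
            fwd = in_pupil & (dm[:, 2] > 0.0)
            state.pupil_transit[idx[fwd]] = True
            state.o[idx[in_pupil]] = pm[in_pupil] + OFFSET * dm[in_pupil]
            blocked = ~in_pupil
            state.status[idx[blocked]] = ABSORBED_IRIS
            state.terminal[idx[blocked]] = pm[blocked]

        elif s.kind == "cylinder_band":
            state.hit_iol[idx] = True
            state.first_edge_hit[idx] = True
            r = np.sqrt(pm[:, 0] ** 2 + pm[:, 1] ** 2)
            n = np.stack([pm[:, 0] / r, pm[:, 1] / r, np.zeros_like(r)], axis=1)
            if scene.edge_mode == "absorbing":
                state.status[idx] = ABSORBED_EDGE
                state.terminal[idx] = pm
            elif scene.edge_mode == "reflective":
                newd = _reflect_arrays(dm, n)
                state.d[idx] = newd
                state.o[idx] = pm + OFFSET * newd
            else:  # antireflective: forced transmission; no Snell solution -> absorbed
                inside = np.einsum("ij,ij->i", dm, n) > 0.0  # leaving the optic
                n_iol, n_hum = scene.index("iol"), scene.index("aqueous")
                n1 = np.where(inside, n_iol, n_hum)
                n2 = np.where(inside, n_hum, n_iol)
                newd, tir = _refract_arrays(dm, n, n1, n2)
                ok = ~tir
                oki = idx[ok]
                state.d[oki] = newd[ok]
                state.o[oki] = pm[ok] + OFFSET * newd[ok]
                state.medium[oki] = np.where(inside[ok], "aqueous", "iol")
                state.status[idx[tir]] = ABSORBED_EDGE
                state.terminal[idx[tir]] = pm[tir]

        else:  # refracting cap
            n = _cap_normals(s, pm)
            forward = np.einsum("ij,ij->i", dm, n) < 0.0  # anterior -> posterior
            nb, na = scene.index(s.medium_before), scene.index(s.medium_after)
            n1 = np.where(forward, nb, na)
            n2 = np.where(forward, na, nb)
            newd, tir = _refract_arrays(dm, n, n1, n2)
            newd[tir] = _reflect_arrays(dm[tir], n[tir])
            new_med = np.where(forward, s.medium_after, s.medium_before)
            keep = state.medium[idx]
            state.medium[idx] = np.where(tir, keep, new_med)
            state.d[idx] = newd
            state.o[idx] = pm + OFFSET * newd
            if s.label.startswith("iol"):
                state.hit_iol[idx] = True

    state.n_events[alive] += 1
    cap = scene.config.max_events
    capped = (state.status[alive] == ALIVE) & (state.n_events[alive] >= cap)
    state.status[alive[capped]] = CAPPED
    state.terminal[alive[capped]] = state.o[alive[capped]]


def trace_bundle(origins, directions, scene: EyeScene, max_events: int | None = None) -> BundleResult:
    """Trace a whole collimated bundle to termination (vectorized).

    ``origins`` and ``directions`` are (N, 3) arrays; directions must be
    unit length.  Equivalent, ray for ray, to calling :func:`trace` on
    each ray.
    """
    o = np.array(origins, dtype=float)
    d = np.array(directions, dtype=float)
    if max_events is not None and max_events != scene.config.max_events:
        from dataclasses import replace as _replace
        scene = EyeScene(
            surfaces=scene.surfaces, media=scene.media, edge_mode=scene.edge_mode,
            config=_replace(scene.config, max_events=max_events),
            fovea_center=scene.fovea_center,
        )
    n = o.shape[0]
    state = _BundleState(
        o=o, d=d,
        status=np.full(n, ALIVE, dtype=np.int8),
        hit_iol=np.zeros(n, dtype=bool),
        first_edge_hit=np.zeros(n, dtype=bool),
        pupil_transit=np.zeros(n, dtype=bool),
        n_events=np.zeros(n, dtype=np.int16),
        terminal=np.full((n, 3), np.nan),
        medium=np.full(n, "air", dtype=object),
    )
    surfs = _compiled(scene)
    for _ in range(scene.config.max_events):
        if not np.any(state.status == ALIVE):
            break
        _advance(state, scene, surfs)
    return BundleResult(
        status=state.status, hit_iol=state.hit_iol,
        first_edge_hit=state.first_edge_hit, pupil_transit=state.pupil_transit,
        n_events=state.n_events, terminal_points=state.terminal,
        terminal_directions=state.d,
    )


def step(ray: Ray, scene: EyeScene) -> Ray:
    """Advance an alive ray by one surface event and return it.

    Applies the nearest-boundary rule described in the module docstring;
    the ray is mutated in place (and also returned for chaining).
    """
    if ray.status != "alive":
        raise ValueError("step requires an alive ray")
    state = _BundleState(
        o=ray.origin[None, :].copy(), d=ray.direction[None, :].copy(),
        status=np.array([ALIVE], dtype=np.int8),
        hit_iol=np.array([ray.hit_iol]),
        first_edge_hit=np.array([ray.first_edge_hit]),
        pupil_transit=np.array([ray.pupil_transit]),
        n_events=np.array([ray.n_events], dtype=np.int16),
        terminal=np.full((1, 3), np.nan),
        medium=np.array([ray.medium], dtype=object),
    )
    _advance(state, scene, _compiled(scene))
    ray.origin = state.o[0]
    ray.direction = state.d[0]
    ray.hit_iol = bool(state.hit_iol[0])
    ray.first_edge_hit = bool(state.first_edge_hit[0])
    ray.pupil_transit = bool(state.pupil_transit[0])
    ray.n_events = int(state.n_events[0])
    ray.medium = str(state.medium[0])
    ray.status = STATUS_NAMES[int(state.status[0])]
    if ray.status != "alive":
        ray.origin = state.terminal[0]
        if ray.status == "terminated_retina":
            ray.retinal_point = state.terminal[0].copy()
    return ray


def trace(ray: Ray, scene: EyeScene, max_events: int | None = None) -> TerminalRecord:
    """Iterate :func:`step` until the ray terminates; deterministic."""
    cap = scene.config.max_events if max_events is None else max_events
    while ray.status == "alive" and ray.n_events < cap:
        step(ray, scene)
    if ray.status == "alive":
        ray.status = "event_capped"
    return TerminalRecord(
        status=ray.status,
        terminal_point=ray.origin.copy(),
        terminal_direction=ray.direction.copy(),
        hit_iol=ray.hit_iol,
        first_edge_hit=ray.first_edge_hit,
        pupil_transit=ray.pupil_transit,
        n_events=ray.n_events,
        retinal_point=None if ray.retinal_point is None else ray.retinal_point.copy(),
    )
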