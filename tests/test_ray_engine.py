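"""Intersection, refraction and the non-sequential event loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from photic_sim import (Ray, SceneConfig, build_scene, intersect, reflect,
                        refract, step, trace, trace_bundle)
from photic_sim.beam_source import BeamSpec, generate_beam_arrays
from photic_sim.eye_model import sag


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestIntersect:
    def test_axial_ray_hits_cornea_vertex(self, scene6_absorbing):
        ray = Ray(origin=[0, 0, -10.0], direction=[0, 0, 1.0])
        t = intersect(ray, scene6_absorbing.surface("cornea_front"))
        assert t == pytest.approx(10.0, abs=1e-12)

    def test_axial_ray_hits_iris_inside_decentered_pupil(self, scene6_absorbing):
        ray = Ray(origin=[0, 0, -10.0], direction=[0, 0, 1.0])
        s = scene6_absorbing.surface("iris_plane")
        t = intersect(ray, s)
        assert t == pytest.approx(13.66, abs=1e-12)
        hit = ray.origin + t * ray.direction
        assert math.hypot(hit[0] - 0.5, hit[1]) < 2.25  # point-in-disc

    def test_ray_parallel_to_plane_misses(self, scene6_absorbing):
        ray = Ray(origin=[0, 0, 0.0], direction=[1, 0, 0.0])
        assert intersect(ray, scene6_absorbing.surface("iris_plane")) is None

    def test_ray_outside_aperture_misses_cap(self, scene6_absorbing):
        ray = Ray(origin=[5.0, 0, 0.0], direction=[0, 0, 1.0])
        assert intersect(ray, scene6_absorbing.surface("iol_front")) is None

    def test_polynomial_surface_against_bracketing_oracle(self, scene6_absorbing):
        """Engine hit parameter equals an independent bracketed root of
        g(t) = z(t) - vz - sag(r(t)) along the ray."""
        s = scene6_absorbing.surface("iol_back")
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            o = np.array([rng.uniform(-2, 2), rng.uniform(-2, 2), 4.9])
            d = unit([rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4), 1.0])
            t_eng = intersect(Ray(origin=o, direction=d), s)
            if t_eng is None:
                continue

            def g(t):
                p = o + t * d
                return (p[2] - s.vertex_z) - sag(s, min(math.hypot(p[0], p[1]),
                                                        s.semi_diameter))

            lo, hi = t_eng - 1e-3, t_eng + 1e-3
            assert g(lo) * g(hi) < 0
            t_ref = brentq(g, lo, hi, xtol=1e-12)
            assert t_eng == pytest.approx(t_ref, abs=1e-9)
            checked += 1
        assert checked > 100


class TestRefract:
    def test_normal_incidence_unchanged(self):
        d, tir = refract([0, 0, 1.0], [0, 0, -1.0], 1.0, 1.5)
        assert not tir
        assert np.allclose(d, [0, 0, 1.0], atol=1e-12)

    def test_index_match_unchanged(self):
        v = unit([0.3, 0.2, 0.9])
        d, tir = refract(v, unit([0.1, 0.0, -1.0]), 1.336, 1.336)
        assert not tir
        assert np.allclose(d, v, atol=1e-12)

    def test_total_internal_reflection_at_critical_angle(self):
        # arcsin(1.336/1.458) = 66.4 deg: inside the IOL against humor
        for angle, expect_tir in ((66.5, True), (66.3, False)):
            a = math.radians(angle)
            d, tir = refract([math.sin(a), 0, math.cos(a)], [0, 0, -1.0],
                             1.458, 1.336)
            assert tir is expect_tir

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_snell_invariant_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        d = random_unit(rng)
        n = random_unit(rng)
        n1, n2 = rng.uniform(1.0, 1.8, size=2)
        t, tir = refract(d, n, n1, n2)
        sin_i = np.linalg.norm(np.cross(d, n))
        if tir:
            assert n1 * sin_i > n2
        else:
            sin_t = np.linalg.norm(np.cross(t, n))
            assert n1 * sin_i == pytest.approx(n2 * sin_t, abs=1e-10)
            # plane of incidence: t is a linear combination of d and n
            assert abs(np.dot(t, unit(np.cross(d, n)))) < 1e-10 or sin_i < 1e-12


class TestReflect:
    def test_retroreflection(self):
        assert np.allclose(reflect([0, 0, 1.0], [0, 0, -1.0]), [0, 0, -1.0])

    def test_mirror_about_plane(self):
        d = unit([1.0, 0, 1.0])
        assert np.allclose(reflect(d, [0, 0, -1.0]), unit([1.0, 0, -1.0]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_reflection_is_an_isometry(self, seed):
        rng = np.random.default_rng(seed)
        d, n = random_unit(rng), random_unit(rng)
        r = reflect(d, n)
        assert np.linalg.norm(r) == pytest.approx(1.0, abs=1e-12)
        # angle of incidence equals angle of reflection
        assert abs(np.dot(d, n)) == pytest.approx(abs(np.dot(r, n)), abs=1e-12)


class TestStepAndTrace:
    def test_axial_step_enters_cornea(self, scene6_absorbing):
        ray = Ray(origin=[0, 0, -5.0], direction=[0, 0, 1.0])
        step(ray, scene6_absorbing)
        assert ray.medium == "cornea"
        assert ray.status == "alive"
        assert np.allclose(ray.direction, [0, 0, 1.0])

    def test_iris_annulus_absorbs(self, scene6_absorbing):
        # aimed at the iris plate 3 mm from the pupil center
        ray = Ray(origin=[3.5, 0, 3.0], direction=[0, 0, 1.0])
        step(ray, scene6_absorbing)
        assert ray.status == "absorbed_iris"

    def test_absorbing_edge_terminates_with_flag(self, scene6_absorbing):
        edge = scene6_absorbing.surface("iol_edge")
        z = 0.5 * (edge.start_z + edge.end_z)
        ray = Ray(origin=[2.5, 0, z], direction=[1, 0, 0.0], medium="iol")
        step(ray, scene6_absorbing)
        assert ray.status == "absorbed_edge"
        assert ray.first_edge_hit and ray.hit_iol

    def test_reflective_edge_mirrors(self, scene6_reflective):
        edge = scene6_reflective.surface("iol_edge")
        z = 0.5 * (edge.start_z + edge.end_z)
        ray = Ray(origin=[2.5, 0, z], direction=[1, 0, 0.0], medium="iol")
        step(ray, scene6_reflective)
        assert ray.status == "alive"
        assert np.allclose(ray.direction, [-1, 0, 0.0], atol=1e-12)

    def test_chief_ray_reaches_fovea(self, scene6_absorbing):
        # self-consistency: relocating the fovea by the chief-ray trace
        # reproduces the stored fovea center exactly
        from photic_sim import locate_fovea
        p = locate_fovea(scene6_absorbing)
        assert np.allclose(p, scene6_absorbing.fovea_center, atol=1e-9)

    def test_every_launched_ray_gets_one_terminal_status(self, scene6_absorbing):
        o, d = generate_beam_arrays(BeamSpec(theta_deg=40.0, n_rays=4000, rng_seed=3))
        res = trace_bundle(o, d, scene6_absorbing)
        counts = res.status_counts()
        assert counts["alive"] == 0
        assert sum(counts.values()) == 4000  # integer energy conservation

    def test_ray_outside_corneal_zone_never_acquires_iol_flag(self, scene6_absorbing):
        # beyond the 24 mm retinal aperture: leaves the scene untouched
        rec = trace(Ray(origin=[13.0, 0, -5.0], direction=[0, 0, 1.0]),
                    scene6_absorbing)
        assert rec.status == "escaped"
        assert not rec.hit_iol and not rec.pupil_transit
        # inside the retinal aperture but outside the corneal zone: may reach
        # the outer retinal shell, but never the IOL or the pupil monitor
        rec = trace(Ray(origin=[10.0, 0, -5.0], direction=[0, 0, 1.0]),
                    scene6_absorbing)
        assert not rec.hit_iol and not rec.pupil_transit

    def test_event_cap_engages(self, scene6_reflective):
        ray = Ray(origin=[0, 0, -5.0], direction=[0, 0, 1.0])
        rec = trace(ray, scene6_reflective, max_events=2)
        assert rec.status == "event_capped"
        assert rec.n_events == 2


class TestBundleEquivalence:
    @pytest.mark.parametrize("mode", ["reflective", "antireflective", "absorbing"])
    def test_bundle_matches_per_ray_trace(self, mode):
        scene = build_scene(SceneConfig(iol_diameter_mm=6, edge_mode=mode))
        o, d = generate_beam_arrays(BeamSpec(theta_deg=30.0, n_rays=250, rng_seed=9))
        res = trace_bundle(o, d, scene)
        from photic_sim.ray_engine import STATUS_NAMES
        for i in range(len(o)):
            rec = trace(Ray(origin=o[i], direction=d[i]), scene)
            assert rec.status == STATUS_NAMES[res.status[i]]
            assert rec.hit_iol == res.hit_iol[i]
            assert rec.first_edge_hit == res.first_edge_hit[i]
            assert rec.pupil_transit == res.pupil_transit[i]
            if rec.status != "alive":
                assert np.allclose(rec.terminal_point, res.terminal_points[i],
                                   atol=1e-9, equal_nan=True)


class TestParaxialOracle:
    def test_cornea_only_matches_matrix_trace(self, cornea_only_scene):
        """Rays within 0.1 mm of the axis agree with a 2x2 reduced-angle
        matrix model of the two corneal refractions to <1% transversally."""
        n0, n1, n2 = 1.0, 1.376, 1.336
        P1, P2 = (n1 - n0) / 7.77, (n2 - n1) / 6.40
        refr = lambda P: np.array([[1.0, 0.0], [-P, 1.0]])
        tran = lambda t_over_n: np.array([[1.0, t_over_n], [0.0, 1.0]])
        M = refr(P2) @ tran(0.5 / n1) @ refr(P1)
        for h in (0.01, 0.05, 0.1):
            y, u = M @ np.array([h, 0.0])
            y_expected = y + (23.45 / n2) * u
            rec = trace(Ray(origin=[h, 0, -5.0], direction=[0, 0, 1.0]),
                        cornea_only_scene)
            assert rec.status == "terminated_retina"
            err = abs(rec.retinal_point[0] - y_expected) / abs(y_expected)
            assert err < 0.01
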