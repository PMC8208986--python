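import numpy as np
import pytest

from lumenflow import geometry as geo
from oracles import (brute_force_point_surface_distance, helix_tortuosity,
                     polygon_area_quadrature, ray_cast_inside,
                     surface_triangles, torus_inside)


def circular_frames(radius, n_frames, spacing=0.5, m=48):
    return [geo.ContourFrame(index=i, s=i * spacing,
                             radii=np.full(m, float(radius)))
            for i in range(n_frames)]


# ---------------------------------------------------------------------------
# contour frames / frame_area
# ---------------------------------------------------------------------------

class TestContourFrame:
    def test_rejects_too_few_samples(self):
        with pytest.raises(geo.GeometryError):
            geo.ContourFrame(0, 0.0, np.ones(8))

    def test_rejects_nonpositive_radii(self):
        radii = np.ones(32)
        radii[5] = -0.1
        with pytest.raises(geo.GeometryError):
            geo.ContourFrame(0, 0.0, radii)

    def test_circle_area(self):
        f = geo.ContourFrame(0, 0.0, np.ones(256))
        assert geo.frame_area(f) == pytest.approx(np.pi, rel=1e-3)

    def test_square_area_shoelace(self):
        m = 1024
        th = 2 * np.pi * np.arange(m) / m
        r = 0.5 / np.maximum(np.abs(np.cos(th)), np.abs(np.sin(th)))
        f = geo.ContourFrame(0, 0.0, r)
        assert geo.frame_area(f) == pytest.approx(1.0, abs=2e-4)

    def test_star_contour_matches_quadrature(self):
        rng = np.random.default_rng(7)
        amps = 0.15 * rng.standard_normal(4)
        phases = rng.uniform(0, 2 * np.pi, 4)

        def radius_fn(th):
            r = np.ones_like(th)
            for k, (a, p) in enumerate(zip(amps, phases), start=2):
                r = r + a * np.cos(k * th + p)
            return r

        m = 2048
        th = 2 * np.pi * np.arange(m) / m
        f = geo.ContourFrame(0, 0.0, radius_fn(th))
        expected = polygon_area_quadrature(radius_fn)
        assert geo.frame_area(f) == pytest.approx(expected, rel=1e-5)


# ---------------------------------------------------------------------------
# tortuosity
# ---------------------------------------------------------------------------

class TestTortuosity:
    def test_straight_is_one(self):
        cl = geo.Centerline.straight(10.0, n=50)
        assert geo.tortuosity(cl) == pytest.approx(1.0, abs=1e-12)

    def test_semicircle(self):
        t = np.linspace(0, np.pi, 2000)
        cl = geo.Centerline(np.column_stack([np.cos(t), np.sin(t),
                                             np.zeros_like(t)]))
        assert geo.tortuosity(cl) == pytest.approx(np.pi / 2, rel=1e-5)

    def test_helix_closed_form(self):
        radius, pitch, turns = 1.0, 0.8, 1.25
        t = np.linspace(0, 2 * np.pi * turns, 4000)
        pts = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                               pitch / (2 * np.pi) * t])
        cl = geo.Centerline(pts)
        assert geo.tortuosity(cl) == pytest.approx(
            helix_tortuosity(radius, pitch, turns), rel=1e-5)

    def test_coincident_endpoints_rejected(self):
        t = np.linspace(0, 2 * np.pi, 300)
        pts = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        closed = np.vstack([pts[:-1], pts[:1]])   # exact closure
        with pytest.raises(geo.GeometryError):
            geo.tortuosity(geo.Centerline(closed))


# ---------------------------------------------------------------------------
# ideal stenosis
# ---------------------------------------------------------------------------

class TestIdealStenosis:
    def test_zero_severity_constant_area(self):
        spec = geo.IdealStenosisSpec(diameter=2.0, severity=0.0)
        surf = geo.build_ideal_stenosis(spec, n_theta=256)
        areas = surf.section_areas()
        assert np.allclose(areas, np.pi, rtol=1e-3)

    def test_half_severity_min_radius(self):
        spec = geo.IdealStenosisSpec(diameter=2.0, severity=0.5)
        surf = geo.build_ideal_stenosis(spec)
        assert float(np.min(surf.radii)) == pytest.approx(1 / np.sqrt(2),
                                                          rel=1e-12)

    @pytest.mark.parametrize("severity,position", [(0.3, 0.0), (0.7, 1.5)])
    def test_minimum_at_specified_position(self, severity, position):
        spec = geo.IdealStenosisSpec(severity=severity, position=position,
                                     length=14.0)
        surf = geo.build_ideal_stenosis(spec)
        areas = surf.section_areas()
        s_min = surf.s_nodes[np.argmin(areas)]
        assert abs(s_min - position) <= 0.5 / 2 + 1e-12

    def test_full_occlusion_rejected(self):
        with pytest.raises(geo.GeometryError):
            geo.IdealStenosisSpec(severity=1.0)

    def test_area_profile_smooth(self):
        spec = geo.IdealStenosisSpec(severity=0.6, extent=2.0)
        x = np.linspace(-4, 4, 2001)
        r = spec.radius_profile(x)
        # numerical first derivative is continuous (no jumps at the ends)
        dr = np.gradient(r, x)
        assert np.max(np.abs(np.diff(dr))) < 5e-3


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

class TestStackFrames:
    def test_cylinder_area_constant(self):
        frames = circular_frames(1.0, 10)
        cl = geo.Centerline.straight(6.0, origin=(-0.5, 0, 0))
        surf = geo.stack_frames(frames, cl)
        assert np.allclose(surf.section_areas(), surf.section_areas()[0])

    def test_frame_spacing_preserved(self):
        frames = circular_frames(1.0, 12, spacing=0.5)
        cl = geo.Centerline.straight(7.0, origin=(-0.5, 0, 0))
        surf = geo.stack_frames(frames, cl)
        assert np.allclose(np.diff(surf.s_nodes), 0.5)

    def test_area_round_trip(self):
        rng = np.random.default_rng(0)
        frames = []
        for i in range(8):
            radii = 1.0 + 0.1 * rng.standard_normal(48)
            frames.append(geo.ContourFrame(i, 0.5 * i, radii))
        cl = geo.Centerline.straight(5.0, origin=(-0.5, 0, 0))
        surf = geo.stack_frames(frames, cl)
        for f, i in zip(frames, range(8)):
            got = surf.section_areas()[i]
            assert got == pytest.approx(geo.frame_area(f), rel=1e-12)

    def test_out_of_order_rejected(self):
        frames = circular_frames(1.0, 5)
        frames[2], frames[3] = frames[3], frames[2]
        cl = geo.Centerline.straight(5.0, origin=(-0.5, 0, 0))
        with pytest.raises(geo.GeometryError, match="out of order"):
            geo.stack_frames(frames, cl)

    def test_excessive_curvature_reported(self):
        # arc radius 0.8 mm < lumen radius 1.0 mm: planes cross in the lumen
        t = np.linspace(0, np.pi, 400)
        arc_r = 0.8
        pts = np.column_stack([arc_r * np.sin(t), arc_r * (1 - np.cos(t)),
                               np.zeros_like(t)])
        cl = geo.Centerline(pts)
        n = int(cl.length / 0.25)
        frames = [geo.ContourFrame(i, 0.25 * i, np.full(32, 1.0))
                  for i in range(n)]
        with pytest.raises(geo.GeometryError, match="curvature"):
            geo.stack_frames(frames, cl)

    def test_torus_membership_oracle(self):
        rc, a = 10.0, 1.0
        t = np.linspace(0, np.pi / 2, 800)
        pts = np.column_stack([rc * np.cos(t), rc * np.sin(t),
                               np.zeros_like(t)])
        cl = geo.Centerline(pts)
        spacing = 0.25
        n = int(cl.length / spacing) + 1
        frames = [geo.ContourFrame(i, spacing * i, np.full(64, a))
                  for i in range(n)]
        surf = geo.stack_frames(frames, cl)
        rng = np.random.default_rng(42)
        # random points near the mid-arc portion of the tube
        ang = rng.uniform(0.15 * np.pi / 2, 0.85 * np.pi / 2, 1000)
        rad = rng.uniform(rc - 1.8 * a, rc + 1.8 * a, 1000)
        z = rng.uniform(-1.8 * a, 1.8 * a, 1000)
        pts_q = np.column_stack([rad * np.cos(ang), rad * np.sin(ang), z])
        inside_true = torus_inside(pts_q, rc, a)
        sdf = surf.sdf(pts_q)
        # skip points within a facet-size band of the surface
        band = 0.05
        sel = np.abs(np.hypot(np.hypot(pts_q[:, 0], pts_q[:, 1]) - rc,
                              pts_q[:, 2]) - a) > band
        assert np.array_equal(sdf[sel] < 0, inside_true[sel])


class TestStraighten:
    def test_same_area_sequence(self):
        rng = np.random.default_rng(1)
        frames = [geo.ContourFrame(i, 0.5 * i,
                                   1.0 + 0.1 * rng.standard_normal(48))
                  for i in range(10)]
        t = np.linspace(0, 4.5, 300)
        cl = geo.Centerline(np.column_stack(
            [t, 0.4 * np.sin(t), np.zeros_like(t)]))
        # reparameterize to arclength
        surf_r = geo.stack_frames(frames, geo.Centerline(
            cl.position(np.linspace(0, cl.length * 0.999, 500))))
        surf_s = geo.straighten(frames)
        assert np.allclose(surf_r.section_areas(), surf_s.section_areas(),
                           rtol=1e-12)

    def test_idempotent_on_straight_centerline(self):
        frames = circular_frames(1.0, 8)
        cl = geo.Centerline.straight(4.5, origin=(-0.5, 0, 0), s0=-0.5)
        p1 = geo.stack_frames(frames, cl).surface_points()
        p2 = geo.straighten(frames).surface_points()
        assert np.allclose(p1, p2, atol=1e-9)

    def test_straightened_tortuosity_is_one(self):
        frames = circular_frames(1.0, 8)
        surf = geo.straighten(frames)
        cl = geo.Centerline(surf.c_f)
        assert geo.tortuosity(cl) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# extensions
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def base():
    rng = np.random.default_rng(5)
    frames = [geo.ContourFrame(i, 0.5 * i,
                               1.0 + 0.08 * rng.standard_normal(48))
              for i in range(12)]
    return geo.straighten(frames), frames


class TestExtensions:
    def test_default_lengths_5d_8d(self, base):
        surf, _ = base
        d = surf.mean_diameter
        ext = geo.add_extensions(surf)
        assert ext.s_nodes[0] == pytest.approx(surf.s_nodes[0] - 5 * d)
        assert ext.s_nodes[-1] == pytest.approx(surf.s_nodes[-1] + 8 * d)

    def test_inlet_radius_equals_first_frame_mean(self, base):
        surf, frames = base
        ext = geo.add_extensions(surf)
        assert np.allclose(ext.radii[0], frames[0].mean_radius())

    def test_blend_monotone_area(self, base):
        surf, _ = base
        ext = geo.add_extensions(surf)
        areas = ext.section_areas()
        sel = ext.flags == geo.SEG_INLET
        inlet_areas = areas[sel]
        diffs = np.diff(inlet_areas)
        # monotone between the circular inlet and the first frame
        assert np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)

    def test_clinical_segment_unchanged(self, base):
        surf, _ = base
        ext = geo.add_extensions(surf)
        sel = ext.flags == geo.SEG_FRAMES
        assert np.allclose(ext.radii[sel], surf.radii, atol=1e-12)
        p_old = surf.surface_points(surf.s_nodes)
        p_new = ext.surface_points(surf.s_nodes)
        assert np.allclose(p_old, p_new, atol=1e-6)

    def test_outlet_tangent_axis_parallel(self, base):
        surf, _ = base
        ext = geo.add_extensions(surf)
        assert ext.t_f[-1] == pytest.approx([1.0, 0.0, 0.0], abs=1e-6)

    def test_nonpositive_lengths_rejected(self, base):
        surf, _ = base
        with pytest.raises(geo.GeometryError):
            geo.add_extensions(surf, inlet_length=-1.0)


# ---------------------------------------------------------------------------
# signed distance
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cylinder():
    frames = circular_frames(1.0, 20, spacing=0.5, m=64)
    return geo.straighten(frames)


class TestSignedDistance:
    def test_axis_point(self, cylinder):
        assert geo.signed_distance(cylinder, [4.0, 0.0, 0.0]) == \
            pytest.approx(-1.0, abs=1e-9)

    def test_on_surface_zero(self, cylinder):
        assert geo.signed_distance(cylinder, [4.0, 1.0, 0.0]) == \
            pytest.approx(0.0, abs=1e-9)

    def test_nonfinite_rejected(self, cylinder):
        with pytest.raises(geo.GeometryError):
            geo.signed_distance(cylinder, [np.nan, 0.0, 0.0])

    def test_magnitude_matches_brute_force(self, cylinder):
        mesh = cylinder.surface_points(
            np.linspace(1.0, 8.0, 200), 256)
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.uniform(2, 7, 40),
                               rng.uniform(-1.5, 1.5, 40),
                               rng.uniform(-1.5, 1.5, 40)])
        for p in pts:
            expected = brute_force_point_surface_distance(p, mesh)
            got = abs(geo.signed_distance(cylinder, p))
            assert got == pytest.approx(expected, abs=0.05)

    def test_sign_against_ray_parity(self):
        # wavy tube: parity ray casting over the triangulated surface
        rng = np.random.default_rng(11)
        frames = [geo.ContourFrame(
            i, 0.5 * i, 1.0 + 0.15 * np.cos(3 * 2 * np.pi *
                                            np.arange(64) / 64 + i * 0.3))
            for i in range(16)]
        surf = geo.straighten(frames)
        mesh = surf.surface_points(np.linspace(0.2, 7.3, 150), 128)
        v0, v1, v2 = surface_triangles(mesh)
        pts = np.column_stack([rng.uniform(1.0, 6.5, 1000),
                               rng.uniform(-1.4, 1.4, 1000),
                               rng.uniform(-1.4, 1.4, 1000)])
        sdf = surf.sdf(pts)
        sel = np.abs(sdf) > 0.06   # stay clear of the triangulation band
        inside_rc = ray_cast_inside(pts[sel], v0, v1, v2,
                                    direction=(0.0, 0.57, 0.82))
        assert np.mean((sdf[sel] < 0) == inside_rc) > 0.995
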