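"""Membrane polygon geometry, energetics, vertex dynamics, attachments."""

import math

import numpy as np
import pytest

import spinedgg.membrane as mb
import spinedgg.state as st
from spinedgg import analysis
from spinedgg.params import ModelParams
from spinedgg.state import validate_state


def regular_polygon(n, r=1.0):
    ang = 2 * np.pi * np.arange(n) / n
    return r * np.stack([np.cos(ang), np.sin(ang)], axis=1)


class TestPolygonGeometry:
    def test_unit_square(self):
        sq = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        assert mb.polygon_area(sq) == pytest.approx(1.0)
        assert mb.polygon_perimeter(sq) == pytest.approx(4.0)

    def test_triangle(self):
        tri = np.array([(0, 0), (1, 0), (0, 1)], dtype=float)
        assert mb.polygon_area(tri) == pytest.approx(0.5)

    def test_random_polygons_match_shapely(self, rng):
        from shapely.geometry import Polygon
        for _ in range(50):
            # star-shaped random polygon (always simple)
            n = int(rng.integers(5, 20))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(0.5, 2.0, n)
            pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
            poly = Polygon(pts)
            assert mb.polygon_area(pts) == pytest.approx(poly.area, rel=1e-12)
            assert mb.polygon_perimeter(pts) == pytest.approx(
                poly.exterior.length, rel=1e-12)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            mb.polygon_area(np.zeros((2, 2)))


class TestCircularity:
    def test_circle_limit(self):
        pts = regular_polygon(2000)
        c = mb.circularity(mb.polygon_area(pts), mb.polygon_perimeter(pts))
        assert c == pytest.approx(1.0, abs=1e-5)

    def test_square(self):
        sq = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        assert mb.circularity(mb.polygon_area(sq), mb.polygon_perimeter(sq)) \
            == pytest.approx(math.pi / 4)

    def test_isoperimetric_bound(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 30))
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            rad = rng.uniform(0.5, 2.0, n)
            pts = np.stack([rad * np.cos(ang), rad * np.sin(ang)], axis=1)
            c = mb.circularity(mb.polygon_area(pts), mb.polygon_perimeter(pts))
            assert c <= 1.0 + 1e-12

    def test_regular_32gon_value(self):
        pts = regular_polygon(32)
        c = mb.circularity(mb.polygon_area(pts), mb.polygon_perimeter(pts))
        assert c == pytest.approx((math.pi / 32) / math.tan(math.pi / 32),
                                  rel=1e-12)
        assert c == pytest.approx(0.9968, abs=2e-4)


class TestDiscreteCurvature:
    def test_colinear_is_zero(self):
        pts = np.array([(k, 0.0) for k in range(-5, 6)]
                       + [(0.0, 5.0)])  # close the cycle crudely
        # evaluate at a deep-interior colinear vertex
        assert mb.discrete_mean_curvature(pts, 3) == pytest.approx(0.0, abs=1e-12)

    def test_regular_200gon_radius_two(self):
        pts = regular_polygon(200, r=2.0)
        h = mb.discrete_mean_curvature(pts, 17)
        assert h == pytest.approx(0.5, rel=0.01)

    def test_rigid_motion_invariance(self, rng):
        pts = regular_polygon(40, r=1.3)
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        moved = pts @ R.T + np.array([3.0, -2.0])
        for i in (0, 7, 23):
            assert mb.discrete_mean_curvature(pts, i) == pytest.approx(
                mb.discrete_mean_curvature(moved, i), rel=1e-12)

    def test_exact_on_regular_polygons(self):
        for n in (16, 64, 256):
            pts = regular_polygon(n, r=2.0)
            assert mb.discrete_mean_curvature(pts, 0) == pytest.approx(
                0.5, abs=1e-12)

    def test_converges_on_ellipse(self):
        # curvature at the co-vertex (0, b) of an ellipse is b/a²
        a, b = 2.0, 1.0
        errs = []
        for n in (64, 128, 256):
            t = 2 * np.pi * np.arange(n) / n
            pts = np.stack([a * np.cos(t), b * np.sin(t)], axis=1)
            i = n // 4                     # vertex at (0, b)
            errs.append(abs(mb.discrete_mean_curvature(pts, i) - b / a**2))
        assert errs[-1] < errs[0]
        assert errs[-1] < 0.01 * (b / a**2)


class TestMembraneEnergy:
    def test_terms_and_total(self, params):
        pts = regular_polygon(32, r=1.5)
        e = mb.membrane_energy(pts, params)
        assert e.area_term == pytest.approx(
            -params.pressure_u * mb.polygon_area(pts))
        assert e.tension_term == pytest.approx(
            params.tension_u * mb.polygon_perimeter(pts))
        assert e.curvature_term > 0
        assert e.total == e.area_term + e.tension_term + e.curvature_term

    def test_curvature_weighting_switch(self):
        p1 = ModelParams(curvature_arclength_weighted=True)
        p2 = ModelParams(curvature_arclength_weighted=False)
        pts = regular_polygon(32, r=1.5)
        e1 = mb.membrane_energy(pts, p1).curvature_term
        e2 = mb.membrane_energy(pts, p2).curvature_term
        assert abs(e1 - e2) > 0.1 * abs(e2)

    def test_clockwise_raises(self, params):
        with pytest.raises(ValueError):
            mb.membrane_energy(regular_polygon(8)[::-1], params)


class TestMembraneGradient:
    def test_pressure_only_points_inward_uniformly(self):
        # gradient of -P·A points radially inward (the force expands)
        p = ModelParams(tension_strength=0.0, curvature_strength=0.0)
        s = analysis.fixture("polygon_only", n_vertices=16, radius=2.0)
        mags = []
        for v in s.membrane_cycle():
            g = mb.membrane_gradient(s, int(v), p)
            rhat = s.m_pos[v] / np.hypot(*s.m_pos[v])
            assert float(g @ rhat) < 0          # energy decreases outward
            mags.append(math.hypot(*g))
        assert np.ptp(mags) < 1e-9 * mags[0]

    def test_tension_descent_shrinks_perimeter(self):
        p = ModelParams(pressure_strength=0.0, curvature_strength=0.0)
        s = analysis.fixture("polygon_only", n_vertices=24, radius=2.0)
        # squash into an ellipse
        for v in s.membrane_cycle():
            s.m_pos[v, 1] *= 0.5
        per0 = mb.polygon_perimeter(s.membrane_coords())
        for _ in range(200):
            for v in list(s.membrane_cycle()):
                mb.membrane_step(s, int(v), p, check_intersection=False)
        assert mb.polygon_perimeter(s.membrane_coords()) < per0

    def test_matches_global_finite_differences(self, params, rng):
        s = analysis.fixture("polygon_only", n_vertices=24, radius=1.5)
        cyc = [int(v) for v in s.membrane_cycle()]
        for v in cyc:
            s.m_pos[v] += rng.uniform(-0.05, 0.05, 2)

        def etot():
            return mb.membrane_energy_state(s, params).total

        h = 1e-6
        for v in cyc[::5]:
            g = mb.membrane_gradient(s, v, params)
            fd = np.zeros(2)
            for d in range(2):
                s.m_pos[v, d] += h
                e_plus = etot()
                s.m_pos[v, d] -= 2 * h
                e_minus = etot()
                s.m_pos[v, d] += h
                fd[d] = (e_plus - e_minus) / (2 * h)
            assert np.allclose(g, fd, rtol=1e-4, atol=1e-4 * np.abs(fd).max())


class TestMembraneStep:
    def test_kkinetic_scaling(self):
        p1 = ModelParams(k_kinetic=1e6)
        p2 = ModelParams(k_kinetic=2e6)
        s = analysis.fixture("polygon_only", n_vertices=16, radius=2.0)
        v = int(s.membrane_cycle()[0])
        d1 = mb.membrane_step(s, v, p1, apply=False)
        d2 = mb.membrane_step(s, v, p2, apply=False)
        assert np.allclose(d1, 2 * d2)

    def test_reaction_force_pairing(self, params):
        """Attached end and vertex receive equal and opposite spring forces."""
        s = analysis.fixture("straight_filament", n=3)
        end = [int(i) for i in s.actin_ids() if s.is_barbed_end(int(i))][0]
        v = int(s.membrane_cycle()[0])
        s.attach(end, v, rest=0.0)
        import spinedgg.mechanics as mech
        f_end = mech.attachment_force_on_end(s, end, params)
        f_vert = mb.attachment_force_on_vertex(s, v, params)
        assert np.allclose(f_end, -f_vert)

    def test_sweep_over_actin_is_vetoed(self, params):
        s = analysis.fixture("polygon_only", n_vertices=16, radius=2.0)
        v = int(s.membrane_cycle()[0])            # at (2, 0)
        s.add_actin((1.8, 0.0), st.END, atp=50)   # node just inside
        # force a large inward move across the node
        assert mb._sweeps_over_actin(s, v, np.array([1.5, 0.0]))
        assert not mb._sweeps_over_actin(s, v, np.array([2.2, 0.0]))


class TestAttachment:
    def _poking_state(self, params):
        s = analysis.fixture("polygon_only", n_vertices=32, radius=2.0)
        # rotate so the rod crosses an edge midpoint, not an existing vertex
        th = math.pi / 32
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        for v in s.membrane_cycle():
            s.m_pos[v] = R @ s.m_pos[v]
        a = s.add_actin((0.0, 0.0), st.END, atp=50)
        b = s.add_actin((1.7, 0.0), st.END, atp=50)   # rod +0.5 crosses ~r=2
        s.a_next[a] = b
        s.a_prev[b] = a
        return s, b

    def test_perpendicular_rod_attaches_at_crossing(self, params):
        s, end = self._poking_state(params)
        n0 = s.n_mem
        assert mb.attach_filament(s, end, params)
        assert s.n_mem == n0 + 1
        vid = s.attach_end2vert[end]
        assert s.m_pos[vid][1] == pytest.approx(0.0, abs=1e-9)
        assert s.m_pos[vid][0] == pytest.approx(2.0 * math.cos(math.pi / 32),
                                                abs=1e-6)
        assert validate_state(s) == []

    def test_no_crossing_is_noop(self, params):
        s, end = self._poking_state(params)
        s.a_pos[end] = (1.0, 0.0)     # too far inside
        n0 = s.n_mem
        assert not mb.attach_filament(s, end, params)
        assert s.n_mem == n0 and not s.attach_end2vert

    def test_vertex_insertion_preserves_perimeter(self, params):
        s, end = self._poking_state(params)
        per0 = mb.polygon_perimeter(s.membrane_coords())
        mb.attach_filament(s, end, params)
        assert mb.polygon_perimeter(s.membrane_coords()) == pytest.approx(
            per0, abs=1e-9)

    def test_capped_end_cannot_attach(self, params):
        s, end = self._poking_state(params)
        s.a_sub[end] = st.CAPPED
        assert not mb.attach_filament(s, end, params)

    def test_ratchet_detach_thresholds(self, params):
        s, end = self._poking_state(params)
        mb.attach_filament(s, end, params)
        assert not mb.ratchet_detach(s, end, params)     # gap below threshold
        vid = s.attach_end2vert[end]
        s.a_pos[end] = (s.m_pos[vid][0] - 2.5 * params.overgrowth, 0.0)
        assert mb.ratchet_detach(s, end, params)
        assert end not in s.attach_end2vert
        assert s.m_alive[vid]                            # vertex retained

    def test_ratchet_cycle_displaces_membrane_outward(self, params):
        """Attach → clamped elongation → spring push: the local membrane
        vertex moves radially outward over repeated steps."""
        import spinedgg.grammar as gram
        s, end = self._poking_state(params)
        s.pools["actin"] = 1e5
        mb.attach_filament(s, end, params)
        vid = s.attach_end2vert[end]
        r0 = math.hypot(*s.m_pos[vid])
        p = ModelParams(pressure_strength=0.0, curvature_strength=0.0,
                        tension_strength=0.0)
        new = gram.apply_elongation(s, end, p, theta=0.0)
        assert new in s.attach_end2vert                  # transferred
        for _ in range(300):
            mb.membrane_step(s, vid, p)
        assert math.hypot(*s.m_pos[vid]) > r0


class TestRemesh:
    def test_long_edges_split_short_removed(self, params):
        s = analysis.fixture("polygon_only", n_vertices=12, radius=2.0)
        cyc = [int(v) for v in s.membrane_cycle()]
        l0 = mb.polygon_perimeter(s.membrane_coords()) / len(cyc)
        # drag one vertex onto its neighbor: creates a short edge
        s.m_pos[cyc[3]] = s.m_pos[cyc[2]] + 1e-3
        mb.remesh(s, params, l0)
        lens = np.hypot(*(np.roll(s.membrane_coords(), -1, axis=0)
                          - s.membrane_coords()).T)
        assert lens.min() > 0.2 * l0
        assert lens.max() < 2.1 * l0
        assert validate_state(s) == []

    def test_wkt_export(self):
        s = analysis.fixture("polygon_only", n_vertices=6, radius=1.0)
        wkt = mb.membrane_wkt(s)
        from shapely import wkt as shapely_wkt
        poly = shapely_wkt.loads(wkt)
        assert poly.is_valid
        assert poly.area == pytest.approx(mb.polygon_area(s.membrane_coords()))
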