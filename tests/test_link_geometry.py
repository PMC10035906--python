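"""Link-curve geometry: frames, summit, control points, path invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatnetviz import (
    PRESETS,
    ShapeParams,
    barycenter,
    chord_frame,
    control_points,
    degree_bar,
    link_path,
    link_radius,
    summit,
)


def random_pair_and_ref(rng, scale=10.0):
    """A random node pair + reference point with non-degenerate geometry."""
    while True:
        S_i, S_j, C = rng.uniform(-scale, scale, size=(3, 3))
        d = np.linalg.norm(S_j - S_i)
        if d < 1e-3:
            continue
        M = (S_i + S_j) / 2
        u = (S_j - S_i) / d
        v = M - C
        if np.linalg.norm(v - (v @ u) * u) > 1e-3 * d:
            return S_i, S_j, C


def max_chord_deviation(polyline, S_i, S_j):
    u = (S_j - S_i) / np.linalg.norm(S_j - S_i)
    rel = polyline - S_i
    return np.max(np.linalg.norm(rel - np.outer(rel @ u, u), axis=1))


class TestPresets:
    def test_the_eight_preset_tuples(self):
        expected = {
            "Default": (0.75, 0.5, 0.38, 0.0),
            "Bell": (0.75, 0.5, 0.0, 0.5),
            "Triangle": (0.75, 0.0, 0.0, 0.0),
            "Circle": (0.5, 0.5, 0.5, 0.5),
            "Circle2": (0.9, 1.0, 0.8, 1.0),
            "Square": (0.5, 1.0, 0.5, 1.0),
            "Peak": (0.75, 0.0, 0.0, 1.0),
            "Straight": (0.0, 0.0, 0.0, 0.0),
        }
        assert PRESETS == expected
        for name, tup in expected.items():
            p = ShapeParams.preset(name)
            assert (p.a1, p.a2, p.a3, p.a4) == tup

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="Circle2"):
            ShapeParams.preset("Zigzag")

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ShapeParams(a3=1.5)
        with pytest.raises(ValueError):
            ShapeParams(a1=-0.1)


class TestBarycenter:
    def test_mean_of_rows(self):
        assert np.array_equal(barycenter([[0, 0, 0], [2, 0, 0]]), [1, 0, 0])
        cube = [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)]
        assert np.array_equal(barycenter(cube), [0.5, 0.5, 0.5])

    def test_single_node_is_itself(self):
        assert np.array_equal(barycenter([[3, 1, 4]]), [3, 1, 4])

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            barycenter(np.empty((0, 3)))


class TestChordFrame:
    def test_simple_frame(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, -1, 0])
        assert np.allclose(f.M, [1, 0, 0])
        assert np.allclose(f.u, [1, 0, 0])
        assert np.allclose(f.w, [0, 1, 0])
        assert f.d_ij == 2.0

    def test_degenerate_reference_uses_vertical_fallback(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, 0, 0])
        assert np.allclose(f.w, [0, 1, 0])

    def test_vertical_chord_degenerate_uses_lateral_fallback(self):
        f = chord_frame([0, 0, 0], [0, 2, 0], [0, 1, 0])
        assert abs(np.dot(f.w, f.u)) < 1e-9
        assert abs(np.linalg.norm(f.w) - 1) < 1e-12

    def test_coincident_nodes_error(self):
        with pytest.raises(ValueError, match="coincident"):
            chord_frame([1, 1, 1], [1, 1, 1], [0, 0, 0])

    def test_frame_orthonormality_random(self, rng):
        for _ in range(200):
            S_i, S_j, C = random_pair_and_ref(rng)
            f = chord_frame(S_i, S_j, C)
            assert abs(np.linalg.norm(f.u) - 1) < 1e-12
            assert abs(np.linalg.norm(f.w) - 1) < 1e-12
            assert abs(np.dot(f.u, f.w)) < 1e-9


class TestSummit:
    def test_default_preset_height(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, -1, 0])
        assert np.allclose(summit(f, 0.75), [1, 1.5, 0])

    def test_zero_height_is_midpoint(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, -1, 0])
        assert np.array_equal(summit(f, 0.0), f.M)

    def test_height_ratio_equals_a1_on_random_frames(self, rng):
        for _ in range(1000):
            S_i, S_j, C = random_pair_and_ref(rng)
            a1 = float(rng.uniform(0, 2))
            f = chord_frame(S_i, S_j, C)
            U = summit(f, a1)
            assert abs(np.linalg.norm(U - f.M) / f.d_ij - a1) < 1e-12


class TestControlPoints:
    def test_circle_preset_departs_vertically(self):
        f = chord_frame([0, 0, 0], [1, 0, 0], [0.5, -1, 0])
        U = summit(f, 0.5)
        B1, B2, B2p, B1p = control_points(f, U, ShapeParams.preset("Circle"),
                                          S_i=np.zeros(3), S_j=np.array([1.0, 0, 0]))
        assert np.allclose(B1, [0, 0.25, 0], atol=1e-12)  # alpha = pi/2
        assert np.allclose(B1p, [1, 0.25, 0], atol=1e-12)
        assert np.allclose(B2, U - 0.25 * f.u)
        assert np.allclose(B2p, U + 0.25 * f.u)

    def test_zero_node_handle_collapses_onto_endpoints(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, -1, 0])
        U = summit(f, 0.75)
        S_i, S_j = np.zeros(3), np.array([2.0, 0, 0])
        B1, _, _, B1p = control_points(f, U, ShapeParams(0.75, 0.5, 0.38, 0.0),
                                       S_i=S_i, S_j=S_j)
        assert np.array_equal(B1, S_i)
        assert np.array_equal(B1p, S_j)

    def test_zero_summit_handle_collapses_onto_summit(self):
        f = chord_frame([0, 0, 0], [2, 0, 0], [1, -1, 0])
        U = summit(f, 0.75)
        _, B2, B2p, _ = control_points(f, U, ShapeParams(0.75, 0.0, 0.0, 0.0))
        assert np.array_equal(B2, U)
        assert np.array_equal(B2p, U)


class TestLinkPath:
    def test_straight_preset_lies_on_chord(self, rng):
        for _ in range(50):
            S_i, S_j, C = random_pair_and_ref(rng)
            curve = link_path(S_i, S_j, C, ShapeParams.preset("Straight"))
            assert max_chord_deviation(curve.polyline, S_i, S_j) <= 1e-12

    def test_triangle_preset_is_two_segments(self):
        S_i, S_j, C = np.zeros(3), np.array([2.0, 0, 0]), np.array([1.0, -1, 0])
        curve = link_path(S_i, S_j, C, ShapeParams.preset("Triangle"))
        n = len(curve.polyline) // 2
        for leg, a, b in ((curve.polyline[: n + 1], S_i, curve.U),
                          (curve.polyline[n:], curve.U, S_j)):
            u = (b - a) / np.linalg.norm(b - a)
            rel = leg - a
            off = rel - np.outer(rel @ u, u)
            assert np.max(np.linalg.norm(off, axis=1)) <= 1e-12

    def test_endpoint_interpolation_exact(self, rng):
        for name in PRESETS:
            for _ in range(25):
                S_i, S_j, C = random_pair_and_ref(rng)
                curve = link_path(S_i, S_j, C, ShapeParams.preset(name))
                assert np.array_equal(curve.polyline[0], S_i)
                assert np.array_equal(curve.polyline[-1], S_j)

    def test_planarity(self, rng):
        for _ in range(200):
            S_i, S_j, C = random_pair_and_ref(rng)
            curve = link_path(S_i, S_j, C, ShapeParams.preset("Circle2"))
            f = curve.frame
            normal = np.cross(f.u, f.w)
            dev = np.abs((curve.polyline - S_i) @ normal)
            assert np.max(dev) < 1e-9 * f.d_ij

    def test_contralaterality(self, rng):
        for _ in range(200):
            S_i, S_j, C = random_pair_and_ref(rng)
            curve = link_path(S_i, S_j, C, ShapeParams.preset("Default"))
            f = curve.frame
            assert np.dot(curve.U - f.M, f.M - np.asarray(C)) >= 0

    def test_swap_symmetry(self, rng):
        for name in ("Default", "Circle", "Peak"):
            for _ in range(30):
                S_i, S_j, C = random_pair_and_ref(rng)
                a = link_path(S_i, S_j, C, ShapeParams.preset(name))
                b = link_path(S_j, S_i, C, ShapeParams.preset(name))
                assert np.allclose(a.polyline, b.polyline[::-1], atol=1e-12)

    def test_translation_equivariance(self, rng):
        t = np.array([3.0, -7.0, 11.0])
        for _ in range(50):
            S_i, S_j, C = random_pair_and_ref(rng)
            a = link_path(S_i, S_j, C, ShapeParams.preset("Bell"))
            b = link_path(S_i + t, S_j + t, C + t, ShapeParams.preset("Bell"))
            assert np.allclose(a.polyline + t, b.polyline, atol=1e-9)
            assert np.allclose(a.U + t, b.U, atol=1e-9)

    def test_scale_equivariance(self, rng):
        s = 3.5
        for _ in range(50):
            S_i, S_j, C = random_pair_and_ref(rng)
            a = link_path(S_i, S_j, C, ShapeParams.preset("Square"))
            b = link_path(s * S_i, s * S_j, s * C, ShapeParams.preset("Square"))
            assert np.allclose(s * a.polyline, b.polyline, atol=1e-9)
            assert np.isclose(b.h, s * a.h)
            assert np.isclose(b.d_U, s * a.d_U)
            assert np.isclose(b.d_S, s * a.d_S)
            assert b.alpha == a.alpha

    def test_summit_continuity_and_smoothness(self, rng):
        # both halves share U; with a2 > 0 the tangents at U are anti-parallel
        for _ in range(50):
            S_i, S_j, C = random_pair_and_ref(rng)
            curve = link_path(S_i, S_j, C, ShapeParams.preset("Circle"), samples_per_half=16)
            n = len(curve.polyline) // 2
            assert np.array_equal(curve.polyline[n], curve.U)
            t_in = curve.U - curve.B2  # cubic end tangent direction
            t_out = curve.B2p - curve.U
            cross = np.cross(t_in, t_out)
            assert np.linalg.norm(cross) < 1e-9 * np.linalg.norm(t_in) * np.linalg.norm(t_out)
            assert np.dot(t_in, t_out) > 0

    def test_polyline_point_count(self):
        curve = link_path([0, 0, 0], [1, 0, 0], [0.5, -1, 0],
                          ShapeParams.preset("Default"), samples_per_half=32)
        assert len(curve.polyline) == 65


coordinate = st.floats(-100.0, 100.0, allow_nan=False, allow_infinity=False)
vec3 = st.tuples(coordinate, coordinate, coordinate).map(np.array)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(S_i=vec3, S_j=vec3, C=vec3, a1=st.floats(0.0, 3.0))
def test_summit_height_property(S_i, S_j, C, a1):
    """For any non-degenerate pair, |U - M| = a1 * d_ij and U sits on the
    far side of M from C."""
    if np.linalg.norm(S_j - S_i) < 1e-6:
        return
    f = chord_frame(S_i, S_j, C)
    U = summit(f, a1)
    assert abs(np.linalg.norm(U - f.M) - a1 * f.d_ij) < 1e-9 * max(1.0, f.d_ij)
    assert np.dot(U - f.M, f.M - C) >= -1e-9


@settings(max_examples=100, derandomize=True, deadline=None)
@given(S_i=vec3, S_j=vec3, C=vec3,
       a1=st.floats(0, 2), a2=st.floats(0, 2), a3=st.floats(0, 1), a4=st.floats(0, 2))
def test_path_endpoints_property(S_i, S_j, C, a1, a2, a3, a4):
    """Every link path starts at S_i and ends at S_j, for any coefficients."""
    if np.linalg.norm(S_j - S_i) < 1e-6:
        return
    curve = link_path(S_i, S_j, C, ShapeParams(a1, a2, a3, a4), samples_per_half=8)
    assert np.array_equal(curve.polyline[0], S_i)
    assert np.array_equal(curve.polyline[-1], S_j)
    assert len(curve.polyline) == 17


class TestRadiusAndBars:
    def test_inverse_distance_with_clamps(self):
        assert link_radius(2.0, 1.0, 0.01, 10.0) == 0.5
        assert link_radius(1e-9, 1.0, 0.01, 10.0) == 10.0
        assert link_radius(1e9, 1.0, 0.01, 10.0) == 0.01

    def test_monotone_non_increasing(self):
        d = np.linspace(0.1, 50, 200)
        r = [link_radius(x, 0.7, 0.01, 5.0) for x in d]
        assert all(a >= b for a, b in zip(r, r[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            link_radius(0.0, 1.0, 0.01, 1.0)
        with pytest.raises(ValueError):
            link_radius(1.0, 1.0, 0.5, 0.1)

    def test_degree_bar_radial_height(self):
        base, tip = degree_bar([0, 2, 0], [0, 0, 0], 3, 0.1)
        assert np.array_equal(base, [0, 2, 0])
        assert np.allclose(tip, [0, 2.3, 0])

    def test_degree_bars_perpendicular_to_sphere(self, rng):
        # nodes on a sphere centered at C: bars point along the surface normal
        C = np.array([1.0, 2.0, 3.0])
        for _ in range(50):
            v = rng.normal(size=3)
            node = C + v / np.linalg.norm(v)
            base, tip = degree_bar(node, C, 4, 0.05)
            direction = (tip - base) / np.linalg.norm(tip - base)
            assert np.allclose(direction, node - C, atol=1e-9)

    def test_node_at_reference_uses_vertical(self):
        base, tip = degree_bar([1, 1, 1], [1, 1, 1], 2, 0.1)
        assert np.allclose(tip - base, [0, 0.2, 0])
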