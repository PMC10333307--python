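"""Poincare-ball primitives: gyrovector identities, limits and guards."""

import numpy as np
import pytest

from hyperseg import geometry as geo

CURVATURES = (0.2, 1.0, 5.0)
DIMS = (2, 16, 64)


def random_ball_points(rng, n, dim, c, scale=0.7):
    """Uniformish points with norm below ``scale`` of the ball radius."""
    x = rng.normal(size=(n, dim))
    x /= np.linalg.norm(x, axis=-1, keepdims=True)
    r = scale * rng.uniform(0.0, 1.0, (n, 1)) ** (1.0 / dim)
    return x * r / np.sqrt(c)


class TestConformalFactor:
    def test_origin_and_flat(self, rng):
        p = np.zeros(4)
        assert geo.conformal_factor(p, 2.0) == pytest.approx(2.0)
        q = rng.normal(size=(5, 4))
        assert np.allclose(geo.conformal_factor(q, 0.0), 2.0)

    def test_scalar_value(self):
        assert geo.conformal_factor(np.array([0.5, 0.0]), 1.0) == \
            pytest.approx(8.0 / 3.0, abs=1e-12)

    def test_outside_ball_raises(self):
        with pytest.raises(ValueError):
            geo.conformal_factor(np.array([1.1, 0.0]), 1.0)


class TestMobiusAdd:
    @pytest.mark.parametrize("c", CURVATURES)
    @pytest.mark.parametrize("dim", DIMS)
    def test_identities(self, c, dim):
        rng = np.random.default_rng(1000 + dim)
        u = random_ball_points(rng, 1000, dim, c)
        zero = np.zeros_like(u)
        assert np.abs(geo.mobius_add(u, zero, c) - u).max() < 1e-9
        assert np.abs(geo.mobius_add(zero, u, c) - u).max() < 1e-9
        assert np.abs(geo.mobius_add(-u, u, c)).max() < 1e-9
        assert np.abs(geo.mobius_add(u, -u, c)).max() < 1e-9

    def test_collinear_value(self):
        u, v = np.array([0.3, 0.0]), np.array([0.4, 0.0])
        got = geo.mobius_add(u, v, 1.0)
        # oracle: collinear closed form (u+v)/(1+c u.v) = 0.7/1.12
        assert got == pytest.approx([0.7 / 1.12, 0.0], abs=1e-12)
        assert got[0] == pytest.approx(0.784 / 1.2544, abs=1e-12)

    def test_small_c_is_euclidean(self, rng):
        u = rng.uniform(-1, 1, (50, 3))
        v = rng.uniform(-1, 1, (50, 3))
        got = geo.mobius_add(u, v, 1e-10)
        assert np.abs(got - (u + v)).max() < 1e-6

    def test_euclidean_recovery_monotone(self, rng):
        u = rng.uniform(-1, 1, (100, 8))
        v = rng.uniform(-1, 1, (100, 8))
        errs = []
        for k in range(4, 11):
            got = geo.mobius_add(u, v, 10.0 ** -k)
            errs.append(np.linalg.norm(got - (u + v), axis=-1).max())
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[4] < 1e-5          # k = 8

    def test_non_commutative(self, rng):
        u = random_ball_points(rng, 1, 3, 1.0)
        v = random_ball_points(rng, 1, 3, 1.0)
        assert not np.allclose(geo.mobius_add(u, v, 1.0),
                               geo.mobius_add(v, u, 1.0))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            geo.mobius_add(np.zeros(2), np.zeros(3), 1.0)

    def test_negative_curvature_raises(self):
        with pytest.raises(ValueError):
            geo.mobius_add(np.zeros(2), np.zeros(2), -1.0)


class TestScalarMul:
    def test_r_one_is_identity(self, rng):
        u = random_ball_points(rng, 20, 4, 1.0)
        assert np.abs(geo.mobius_scalar_mul(1.0, u, 1.0) - u).max() < 1e-12

    def test_zero_vector(self):
        assert np.all(geo.mobius_scalar_mul(3.5, np.zeros(4), 1.0) == 0)

    def test_doubling_matches_self_addition(self, rng):
        for c in CURVATURES:
            u = random_ball_points(rng, 200, 8, c)
            two_u = geo.mobius_scalar_mul(2.0, u, c)
            assert np.abs(two_u - geo.mobius_add(u, u, c)).max() < 1e-9

    def test_scalar_oracle(self):
        u = np.array([0.3, 0.0])
        got = geo.mobius_scalar_mul(2.0, u, 1.0)
        assert got[0] == pytest.approx(np.tanh(2 * np.arctanh(0.3)), abs=1e-12)
        assert got[1] == 0.0

    def test_flat_branch(self, rng):
        u = rng.normal(size=(5, 3))
        assert np.allclose(geo.mobius_scalar_mul(2.5, u, 0.0), 2.5 * u)


class TestDistance:
    def test_identity_of_indiscernibles(self, rng):
        u = random_ball_points(rng, 30, 5, 1.0)
        assert np.abs(geo.ball_distance(u, u, 1.0)).max() < 1e-12

    def test_origin_closed_form(self):
        d = geo.ball_distance(np.zeros(2), np.array([0.5, 0.0]), 1.0)
        assert d == pytest.approx(2 * np.arctanh(0.5), abs=1e-12)

    def test_symmetry(self, rng):
        u = random_ball_points(rng, 500, 6, 1.0)
        v = random_ball_points(rng, 500, 6, 1.0)
        assert np.abs(geo.ball_distance(u, v, 1.0) -
                      geo.ball_distance(v, u, 1.0)).max() < 1e-9

    @pytest.mark.parametrize("c", CURVATURES)
    def test_triangle_inequality(self, c):
        rng = np.random.default_rng(7)
        u = random_ball_points(rng, 1000, 4, c)
        v = random_ball_points(rng, 1000, 4, c)
        w = random_ball_points(rng, 1000, 4, c)
        slack = (geo.ball_distance(u, w, c) + geo.ball_distance(w, v, c)
                 - geo.ball_distance(u, v, c))
        assert slack.min() >= -1e-9

    def test_flat_branch_doubles_euclidean(self, rng):
        u, v = rng.normal(size=(2, 5, 3))
        assert np.allclose(geo.ball_distance(u, v, 0.0),
                           2 * np.linalg.norm(u - v, axis=-1))


class TestExpMaps:
    def test_zero_tangent_returns_base(self, rng):
        p = random_ball_points(rng, 10, 4, 1.0)
        assert np.all(geo.exp_map(p, np.zeros_like(p), 1.0) == p)

    def test_exp_at_origin_matches_exp_map0(self, rng):
        v = rng.normal(0, 0.5, (20, 4))
        got = geo.exp_map(np.zeros_like(v), v, 1.0)
        assert np.abs(got - geo.exp_map0(v, 1.0)).max() < 1e-12

    def test_exp_map_scalar_oracle(self):
        # independent 1-D evaluation of the exponential-map formula
        p, v, c = 0.2, 0.1, 1.0
        lam = 2.0 / (1.0 - p * p)
        second = np.tanh(np.sqrt(c) * lam * abs(v) / 2) * v / \
            (np.sqrt(c) * abs(v))
        expect = (p + second) * (1 + p * second) / \
            (1 + 2 * p * second + p * p * second * second)
        got = geo.exp_map(np.array([p, 0.0]), np.array([v, 0.0]), c)
        assert got[0] == pytest.approx(expect, abs=1e-12)

    def test_exp_map0_norm(self):
        v = np.array([0.1, 0.0])
        assert np.linalg.norm(geo.exp_map0(v, 1.0)) == \
            pytest.approx(np.tanh(0.1), abs=1e-12)

    def test_exp_map0_flat_limit(self, rng):
        v = rng.uniform(-1, 1, (30, 4))
        assert np.abs(geo.exp_map0(v, 1e-12) - v).max() < 1e-6

    def test_exp_map0_small_vector_distance(self, rng):
        v = rng.normal(size=(100, 6))
        v *= 1e-3 / np.linalg.norm(v, axis=-1, keepdims=True)
        d = geo.ball_distance(np.zeros_like(v), geo.exp_map0(v, 1.0), 1.0)
        assert np.abs(d - 2 * np.linalg.norm(v, axis=-1)).max() < 1e-6

    def test_output_inside_ball(self, rng):
        v = rng.normal(0, 50, (100, 3))
        z = geo.exp_map0(v, 2.0)
        assert np.sqrt(2.0) * np.linalg.norm(z, axis=-1).max() < 1.0


class TestProjection:
    def test_interior_unchanged_bitwise(self, rng):
        x = random_ball_points(rng, 20, 3, 1.0)
        assert np.all(geo.project_to_ball(x, 1.0) == x)

    def test_outside_rescaled(self):
        c, eps = 4.0, 1e-3
        x = np.array([1.5, 0.0]) / np.sqrt(c) * 1.0
        got = geo.project_to_ball(x * 1.5, c, eps)
        assert np.linalg.norm(got) == pytest.approx((1 - eps) / np.sqrt(c),
                                                    rel=1e-12)

    def test_zero_stays_zero(self):
        assert np.all(geo.project_to_ball(np.zeros(4), 1.0) == 0)

    def test_bad_eps_raises(self):
        with pytest.raises(ValueError):
            geo.project_to_ball(np.zeros(2), 1.0, eps=0.5)


class TestGyrovectorProperties:
    """Property-based checks over randomly drawn ball points."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    coords = arrays(np.float64, (3,),
                    elements=st.floats(-0.5, 0.5, allow_nan=False))

    @given(u=coords, v=coords, c=st.sampled_from([0.2, 1.0, 2.0]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_left_cancellation(self, u, v, c):
        # (-u) (+) (u (+) v) recovers v: the gyrogroup left-cancellation law
        u = geo.project_to_ball(u, c)
        v = geo.project_to_ball(v, c)
        w = geo.mobius_add(-u, geo.mobius_add(u, v, c, project=False), c,
                           project=False)
        assert np.abs(w - v).max() < 1e-9

    @given(u=coords, v=coords, c=st.sampled_from([0.2, 1.0, 2.0]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_distance_positivity_and_symmetry(self, u, v, c):
        u = geo.project_to_ball(u, c)
        v = geo.project_to_ball(v, c)
        d = geo.ball_distance(u, v, c)
        assert d >= 0
        assert abs(d - geo.ball_distance(v, u, c)) < 1e-9


class TestBatchPolymorphism:
    """Stacked batches must equal stacked per-element results bit-for-bit."""

    def test_operations_are_batch_transparent(self, rng):
        c = 1.0
        u = random_ball_points(rng, 16, 5, c)
        v = random_ball_points(rng, 16, 5, c)
        batched = {
            "add": geo.mobius_add(u, v, c),
            "dist": geo.ball_distance(u, v, c),
            "exp": geo.exp_map(u, v, c),
            "exp0": geo.exp_map0(v, c),
        }
        for i in range(16):
            assert np.all(geo.mobius_add(u[i], v[i], c) == batched["add"][i])
            assert geo.ball_distance(u[i], v[i], c) == batched["dist"][i]
            assert np.all(geo.exp_map(u[i], v[i], c) == batched["exp"][i])
            assert np.all(geo.exp_map0(v[i], c) == batched["exp0"][i])
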