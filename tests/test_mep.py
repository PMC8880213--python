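"""String-method operations: tangents, projection, evolution,
reparametrization, optimization, observables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathfep.energy import MuellerBrownModel
from pathfep.errors import (
    DegeneratePathError,
    DegenerateTangentError,
    InvalidInputError,
    InvalidTangentError,
    ShapeError,
)
from pathfep.mep import (
    StringPath,
    densify_path,
    evolve_images,
    init_linear_path,
    locate_on_polyline,
    optimize_string,
    path_distance_series,
    perpendicular_project,
    relax_environment,
    reparametrize,
    unit_tangent,
)


def straight_path(n=5, d=2):
    active = np.zeros((n, d))
    active[:, 0] = np.linspace(0.0, 1.0, n)
    return StringPath(np.linspace(0, 1, n), active, np.zeros((n, 0)))


class QuadraticValley:
    """V = x^2 + 100 y^2; the exact MEP is the x axis."""

    has_environment = False

    def active_energy(self, r, R=None):
        return r[0] ** 2 + 100.0 * r[1] ** 2

    def active_gradient(self, r, R=None):
        return np.array([2.0 * r[0], 200.0 * r[1]])


class TestInitLinearPath:
    def test_midpoint(self):
        p = init_linear_path([0.0, 0.0], [1.0, 1.0], n_images=3)
        assert np.allclose(p.active[1], [0.5, 0.5])
        assert p.sigmas[1] == 0.5

    def test_default_16_images(self):
        p = init_linear_path(np.zeros(3), np.ones(3))
        assert p.n_images == 16
        assert np.allclose(np.diff(p.sigmas), 1.0 / 15.0)

    def test_degenerate_endpoints_give_identical_images(self):
        a = np.array([1.0, 2.0, 3.0])
        p = init_linear_path(a, a.copy(), n_images=5)
        assert np.all(p.active == a)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            init_linear_path(np.zeros(3), np.zeros(4))

    def test_too_few_images(self):
        with pytest.raises(InvalidInputError):
            init_linear_path(np.zeros(2), np.ones(2), n_images=2)


class TestTangentAndProjector:
    def test_collinear_tangent(self):
        p = straight_path()
        for k in range(p.n_images):
            assert np.allclose(unit_tangent(p, k), [1.0, 0.0])

    def test_right_angle_central_difference(self):
        p = StringPath([0, 0.5, 1.0], np.array([[0.0, 0], [1, 0], [1, 1]]),
                       np.zeros((3, 0)))
        assert np.allclose(unit_tangent(p, 1), [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_tangent_normalized(self, rng):
        act = np.cumsum(rng.normal(size=(7, 4)), axis=0)
        p = StringPath(np.linspace(0, 1, 7), act, np.zeros((7, 0)))
        for k in range(7):
            assert abs(np.linalg.norm(unit_tangent(p, k)) - 1.0) < 1e-12

    def test_coincident_neighbors_rejected(self):
        act = np.array([[0.0, 0], [1, 0], [0, 0]])  # z0 == z2
        p = StringPath([0, 0.5, 1.0], act, np.zeros((3, 0)))
        with pytest.raises(DegenerateTangentError):
            unit_tangent(p, 1)

    def test_axis_projection(self):
        assert np.allclose(
            perpendicular_project([3.0, 4.0], [1.0, 0.0]), [0.0, 4.0])

    def test_parallel_vector_projects_to_zero(self):
        tau = np.array([0.6, 0.8])
        assert np.allclose(perpendicular_project(3.3 * tau, tau), 0.0,
                           atol=1e-12)

    def test_unnormalized_tangent_rejected(self):
        with pytest.raises(InvalidTangentError):
            perpendicular_project([1.0, 0.0], [1.0, 1.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_projector_algebra(self, seed):
        """P is symmetric, idempotent and annihilates the tangent."""
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 12))
        tau = rng.normal(size=d)
        tau /= np.linalg.norm(tau)
        v, u = rng.normal(size=d), rng.normal(size=d)
        pv = perpendicular_project(v, tau)
        assert np.allclose(perpendicular_project(pv, tau), pv, atol=1e-12)
        assert abs(pv @ tau) < 1e-12
        assert abs(u @ pv - v @ perpendicular_project(u, tau)) < 1e-12


class TestEvolveImages:
    def test_zero_gradient_leaves_path_unchanged(self):
        class Flat:
            def active_gradient(self, r, R=None):
                return np.zeros_like(r)

        p = straight_path()
        q = evolve_images(p, Flat(), dt=0.1, n_steps=3)
        assert np.array_equal(q.active, p.active)

    def test_linear_potential_closed_form(self):
        g = np.array([2.0, -1.0])

        class Linear:
            def active_gradient(self, r, R=None):
                return g

        p = StringPath([0, 0.5, 1.0], np.array([[0.0, 0], [5, 0], [10, 0]]),
                       np.zeros((3, 0)))
        q = evolve_images(p, Linear(), dt=0.01, n_steps=1, project=False,
                          max_step=None)
        assert np.allclose(q.active[1], p.active[1] - g * 0.01, atol=1e-15)
        # fixed endpoints never move
        assert np.array_equal(q.active[0], p.active[0])
        assert np.array_equal(q.active[-1], p.active[-1])

    def test_harmonic_contraction_rate(self):
        k = 3.0

        class Harmonic:
            def active_gradient(self, r, R=None):
                return k * r

        start = np.array([[0.0, 1.0], [0.3, 0.7], [0.0, -1.0]])
        p = StringPath([0, 0.5, 1.0], start, np.zeros((3, 0)),
                       endpoint_policy="free")
        dt, n = 0.01, 7
        q = evolve_images(p, Harmonic(), dt=dt, n_steps=n, project=False,
                          max_step=None)
        assert np.allclose(q.active, start * (1 - k * dt) ** n, rtol=1e-12)

    def test_invalid_dt(self):
        with pytest.raises(InvalidInputError):
            evolve_images(straight_path(), MuellerBrownModel(), dt=0.0)


class TestReparametrize:
    def test_collinear_redistribution(self):
        p = StringPath([0, 0.2, 1.0], np.array([[0.0, 0], [0.2, 0], [1.0, 0]]),
                       np.zeros((3, 0)))
        q = reparametrize(p)
        assert np.allclose(q.active[:, 0], [0.0, 0.5, 1.0])

    def test_equidistant_path_is_fixed_point(self):
        p = straight_path(n=8)
        q = reparametrize(p)
        assert np.allclose(q.active, p.active, atol=1e-12)

    def test_equal_arc_spacing_on_random_paths(self, rng):
        """Oracle: project each new image back onto the original polyline
        and verify the arc-length gaps are equal."""
        for _ in range(5):
            act = np.cumsum(rng.normal(size=(10, 3)), axis=0)
            p = StringPath(np.linspace(0, 1, 10), act, np.zeros((10, 0)))
            q = reparametrize(p)
            params = np.array([locate_on_polyline(im, p.active)
                               for im in q.active])
            gaps = np.diff(params)
            assert np.max(np.abs(gaps - gaps.mean())) / gaps.mean() < 1e-8
            assert np.array_equal(q.active[0], p.active[0])
            assert np.array_equal(q.active[-1], p.active[-1])

    def test_zero_length_path_rejected(self):
        act = np.ones((4, 2))
        p = StringPath(np.linspace(0, 1, 4), act, np.zeros((4, 0)))
        with pytest.raises(DegeneratePathError):
            reparametrize(p)


class TestDensify:
    def test_identity_on_equidistant_path(self):
        p = straight_path(n=6)
        q = densify_path(p, 6)
        assert np.allclose(q.active, p.active, atol=1e-15)

    def test_two_image_segment_to_five(self):
        p = StringPath([0.0, 1.0], np.array([[0.0, 0], [1.0, 1.0]]),
                       np.zeros((2, 0)))
        q = densify_path(p, 5)
        assert np.allclose(q.active[:, 0], [0, 0.25, 0.5, 0.75, 1.0])

    def test_16_to_45_preserves_endpoints_bitwise(self, rng):
        act = np.cumsum(rng.normal(size=(16, 6)), axis=0)
        p = StringPath(np.linspace(0, 1, 16), act, np.zeros((16, 0)))
        q = densify_path(p, 45)
        assert q.n_images == 45
        assert np.array_equal(q.active[0], p.active[0])
        assert np.array_equal(q.active[-1], p.active[-1])

    def test_invalid_counts(self):
        p = straight_path(n=5)
        with pytest.raises(InvalidInputError):
            densify_path(p, 1)
        with pytest.raises(InvalidInputError):
            densify_path(p, 4)


class SingleWellEnv:
    """Environment particle in a quadratic well centered at c."""

    has_environment = True

    def __init__(self, c, k=2.0):
        self.c = np.asarray(c, dtype=float)
        self.k = k

    def active_energy(self, r, R):
        return 0.0

    def active_gradient(self, r, R):
        return np.zeros_like(r)

    def environment_energy(self, r, R):
        d = R - self.c
        return 0.5 * self.k * float(d @ d)

    def env_gradient(self, r, R):
        return self.k * (R - self.c)


class TestRelaxEnvironment:
    def test_relaxes_to_well_center(self):
        c = np.array([1.0, -2.0, 0.5])
        model = SingleWellEnv(c)
        p = StringPath(np.linspace(0, 1, 3), np.zeros((3, 2)),
                       np.tile([3.0, 3.0, 3.0], (3, 1)))
        q, norms, warns = relax_environment(p, model, tol=1e-8)
        assert np.allclose(q.env, c, atol=1e-6)
        assert not warns

    def test_active_coordinates_bitwise_unchanged(self, rng):
        model = SingleWellEnv(np.zeros(3))
        act = rng.normal(size=(3, 4))
        p = StringPath(np.linspace(0, 1, 3), act, rng.normal(size=(3, 3)))
        q, _, _ = relax_environment(p, model)
        assert np.array_equal(q.active, act)

    def test_minimum_left_unchanged(self):
        c = np.array([0.5, 0.5, 0.5])
        model = SingleWellEnv(c)
        p = StringPath(np.linspace(0, 1, 3), np.zeros((3, 2)),
                       np.tile(c, (3, 1)))
        q, norms, _ = relax_environment(p, model, tol=1e-10)
        assert np.allclose(q.env, c, atol=1e-10)


class TestOptimizeString:
    def test_converged_valley_terminates_immediately(self):
        p = straight_path(n=7)

        class AxisValley:
            has_environment = False

            def active_energy(self, r, R=None):
                return 50.0 * r[1] ** 2

            def active_gradient(self, r, R=None):
                return np.array([0.0, 100.0 * r[1]])

        q, rep = optimize_string(p, AxisValley(), dt=1e-3, delta_v_tol=1e-10)
        assert rep.converged
        assert rep.cycles == 1

    def test_quadratic_valley_collapses_to_axis(self):
        model = QuadraticValley()
        n = 12
        x = np.linspace(-1.0, 1.0, n)
        act = np.column_stack([x, 0.5 * np.sin(np.pi * (x + 1) / 2)])
        act[0, 1] = act[-1, 1] = 0.0
        p = StringPath(np.linspace(0, 1, n), act, np.zeros((n, 0)))
        q, rep = optimize_string(p, model, dt=2e-3, evolve_steps_per_cycle=10,
                                 max_cycles=500, delta_v_tol=1e-12)
        assert np.max(np.abs(q.active[:, 1])) < 1e-4

    def test_translation_equivariance(self):
        """Optimizing the translated problem gives the translated path."""
        shift = np.array([8.0, -4.0])  # exactly representable offsets
        base = MuellerBrownModel()

        class Shifted:
            has_environment = False

            def active_energy(self, r, R=None):
                return base.active_energy(r - shift)

            def active_gradient(self, r, R=None):
                return base.active_gradient(r - shift)

        a, b = np.array([-0.558, 1.442]), np.array([0.623, 0.028])
        kw = dict(dt=5e-5, evolve_steps_per_cycle=10, max_cycles=300,
                  delta_v_tol=1e-9, max_step=0.05)
        p1, _ = optimize_string(init_linear_path(a, b, n_images=10), base, **kw)
        p2, _ = optimize_string(
            init_linear_path(a + shift, b + shift, n_images=10), Shifted(), **kw)
        assert np.max(np.abs(p2.active - shift - p1.active)) < 1e-10

    def test_invalid_tolerance(self):
        with pytest.raises(InvalidInputError):
            optimize_string(straight_path(), MuellerBrownModel(), dt=1e-4,
                            delta_v_tol=0.0)


class TestDistanceSeries:
    def test_constant_for_identical_images(self):
        act = np.tile(np.array([0.0, 0, 0, 3.0, 0, 0]), (4, 1))
        p = StringPath(np.linspace(0, 1, 4), act, np.zeros((4, 0)))
        df = path_distance_series(p, [(0, 1)])
        assert np.allclose(df["d0_1"], 3.0)

    def test_linear_separation(self):
        n = 5
        act = np.zeros((n, 6))
        act[:, 3] = 1.0 + np.linspace(0.0, 2.0, n)  # second atom moves in x
        p = StringPath(np.linspace(0, 1, n), act, np.zeros((n, 0)))
        df = path_distance_series(p, [(0, 1)])
        assert np.allclose(df["d0_1"], 1.0 + np.linspace(0, 2, n))

    def test_out_of_range_pair(self):
        p = StringPath(np.linspace(0, 1, 3), np.zeros((3, 6)) + np.arange(6),
                       np.zeros((3, 0)))
        with pytest.raises(IndexError):
            path_distance_series(p, [(0, 5)])
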