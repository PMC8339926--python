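"""Vector field, gates, discrete map, Jacobian, and integration contracts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from grudyn import (GRUParams, discrete_step, gates, integrate, jacobian,
                    rotation_family, vector_field)
from grudyn.core import IntegrationError, candidate_residual

from conftest import random_params


class TestGates:
    def test_zero_params_give_half(self):
        z, r = gates(GRUParams.zeros(2), np.zeros(2))
        assert np.allclose(z, 0.5) and np.allclose(r, 0.5)

    def test_rotation_family_reset_gate_constant_half(self):
        params = rotation_family(1.1, 3.0, 0.0)
        for h in (np.zeros(2), np.array([0.7, -0.3]), np.array([-1.0, 1.0])):
            _, r = gates(params, h)
            assert np.allclose(r, 0.5)

    def test_large_reset_bias_saturates(self):
        params = GRUParams(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)),
                           np.zeros(2), np.array([10.0, 10.0]), np.zeros(2))
        _, r = gates(params, np.array([0.2, -0.4]))
        assert np.allclose(r, 0.9999546021312976, atol=1e-7)

    def test_gates_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            z, r = gates(random_params(rng), rng.uniform(-2, 2, 2))
            assert np.all((z > 0) & (z < 1)) and np.all((r > 0) & (r < 1))

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            gates(GRUParams.zeros(2), np.array([np.nan, 0.0]))


class TestVectorField:
    def test_origin_is_fixed_point_of_zero_params(self):
        assert np.allclose(vector_field(GRUParams.zeros(2), np.zeros(2)), 0.0)

    def test_zero_params_reduce_to_half_decay(self):
        h = np.array([1.0, -1.0])
        assert np.allclose(vector_field(GRUParams.zeros(2), h), -0.5 * h)

    def test_rotation_family_origin_stable_spiral(self):
        params = rotation_family(np.pi / 3, 3.0, 0.0)
        assert np.allclose(vector_field(params, np.zeros(2)), 0.0)
        eig = np.linalg.eigvals(jacobian(params, np.zeros(2)))
        # linearization (1/2)(U_h/2 - I): real part 0.75 cos(pi/3) - 0.5
        assert np.allclose(eig.real, -0.125, atol=1e-12)
        assert np.all(np.abs(eig.imag) > 0.1)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            vector_field(GRUParams.zeros(2), np.zeros(3))

    def test_odd_symmetry_without_gate_weights_or_biases(self):
        rng = np.random.default_rng(3)
        z = np.zeros((2, 2))
        for _ in range(20):
            params = GRUParams(z, z, rng.normal(0, 2, (2, 2)),
                               np.zeros(2), np.zeros(2), np.zeros(2))
            h = rng.uniform(-1.5, 1.5, 2)
            assert np.array_equal(vector_field(params, -h),
                                  -vector_field(params, h))

    def test_factored_field_equals_full_when_update_gate_unparameterized(self):
        params = rotation_family(0.6, 3.0, 0.0)  # U_z = 0, b_z = 0
        rng = np.random.default_rng(1)
        h = rng.uniform(-1, 1, (10, 2))
        assert np.allclose(vector_field(params, h),
                           vector_field(params, h, factored=True))


class TestDiscreteStep:
    def test_euler_identity(self):
        # the discrete map is the unit-step forward-Euler step of the field
        rng = np.random.default_rng(7)
        for _ in range(100):
            d = int(rng.integers(1, 4))
            params = random_params(rng, d)
            h = rng.uniform(-2, 2, d)
            err = discrete_step(params, h) - h - vector_field(params, h)
            assert np.max(np.abs(err)) <= 1e-12

    def test_zero_params_halve_the_state(self):
        assert np.allclose(discrete_step(GRUParams.zeros(2), np.array([1.0, 0.0])),
                           [0.5, 0.0])

    def test_input_without_weights_rejected(self):
        with pytest.raises(ValueError, match="input"):
            discrete_step(GRUParams.zeros(2), np.zeros(2), np.array([1.0, 0.0]))


class TestJacobian:
    def test_zero_params_give_minus_half_identity(self):
        assert np.allclose(jacobian(GRUParams.zeros(2), np.zeros(2)),
                           -0.5 * np.eye(2))

    def test_rotation_family_closed_form_eigenvalues(self):
        for alpha in (0.4, 0.8, 1.2):
            eig = np.sort_complex(np.linalg.eigvals(
                jacobian(rotation_family(alpha, 3.0, 0.0), np.zeros(2))))
            expected = np.sort_complex(np.array(
                [0.75 * np.exp(1j * alpha) - 0.5, 0.75 * np.exp(-1j * alpha) - 0.5]))
            assert np.allclose(eig, expected, atol=1e-12)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            params = random_params(rng)
            for _ in range(10):
                h = rng.uniform(-1.5, 1.5, 2)
                J = jacobian(params, h)
                eps = 1e-6
                Jfd = np.stack(
                    [(vector_field(params, h + eps * e) -
                      vector_field(params, h - eps * e)) / (2 * eps)
                     for e in np.eye(2)], axis=1)
                scale = max(1.0, np.max(np.abs(J)))
                assert np.max(np.abs(J - Jfd)) / scale < 1e-6


class TestIntegrate:
    def test_zero_params_decay_closed_form(self):
        traj = integrate(GRUParams.zeros(2), np.array([1.0, 1.0]), 2.0)
        assert np.allclose(traj.final_state, np.exp(-1.0), atol=1e-8)

    def test_euler_mode_reproduces_discrete_orbit(self):
        rng = np.random.default_rng(2)
        params = random_params(rng)
        h = np.array([0.3, -0.4])
        traj = integrate(params, h, 10.0, method="euler")
        for _ in range(10):
            h = discrete_step(params, h)
        assert np.array_equal(traj.final_state, h)

    def test_trapping_region(self):
        # trajectories from moderate starts end inside the unit cube (the
        # entry time grows exponentially with gate preactivation, so wild
        # initial states are excluded by design)
        rng = np.random.default_rng(5)
        for _ in range(20):
            params = random_params(rng, gate_scale=1.0, rec_scale=2.0,
                                   bias_scale=0.7)
            for _ in range(10):
                traj = integrate(params, rng.uniform(-2, 2, 2), 200.0,
                                 rtol=1e-6, atol=1e-9)
                assert np.max(np.abs(traj.final_state)) <= 1.001

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError, match="duration"):
            integrate(GRUParams.zeros(2), np.zeros(2), -1.0)


@given(hnp.arrays(np.float64, (2,), elements=st.floats(-3, 3)),
       st.integers(0, 2**31 - 1))
def test_map_and_field_identities_hold_for_arbitrary_states(h, seed):
    """Unit-step Euler identity and gate bounds for arbitrary finite states."""
    params = random_params(np.random.default_rng(seed))
    z, r = gates(params, h)
    assert np.all((z > 0) & (z < 1)) and np.all((r > 0) & (r < 1))
    err = discrete_step(params, h) - h - vector_field(params, h)
    assert np.max(np.abs(err)) <= 1e-12


def test_candidate_residual_roots_are_field_roots():
    rng = np.random.default_rng(9)
    params = random_params(rng)
    h = rng.uniform(-1, 1, (50, 2))
    g = candidate_residual(params, h)
    f = vector_field(params, h)
    # the positive gate factor cannot create or destroy zeros
    assert np.all((np.linalg.norm(g, axis=1) < 1e-12)
                  == (np.linalg.norm(f, axis=1) < 1e-12))
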