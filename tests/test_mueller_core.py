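"""Mueller/Stokes algebra, rotation transformation and fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm, logm

from polarmc.mueller import (
    DegenerateMatrixError,
    make_depolarizer,
    make_diattenuator,
    make_retarder,
    normalize,
    random_physical_mueller,
    rotate_mueller,
    rotation_matrix,
)

angles = st.floats(-10.0, 10.0, allow_nan=False)


class TestRotationMatrix:
    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (0.0, np.eye(4)),
            (np.pi / 2, np.diag([1.0, -1.0, -1.0, 1.0])),
        ],
    )
    def test_special_angles(self, alpha, expected):
        np.testing.assert_allclose(rotation_matrix(alpha), expected, atol=1e-12)

    def test_quarter_turn_swaps_linear_components(self):
        R = rotation_matrix(np.pi / 4)
        assert R[1, 2] == pytest.approx(-1.0)
        assert R[2, 1] == pytest.approx(1.0)
        assert abs(R[1, 1]) < 1e-12 and abs(R[2, 2]) < 1e-12

    @given(alpha=angles)
    @settings(max_examples=50, derandomize=True)
    def test_inverse_and_periodicity(self, alpha):
        R = rotation_matrix(alpha)
        np.testing.assert_allclose(R @ rotation_matrix(-alpha), np.eye(4), atol=1e-12)
        np.testing.assert_allclose(R, rotation_matrix(alpha + np.pi), atol=1e-9)


class TestRotateMueller:
    def test_identity_is_fixed_point(self):
        np.testing.assert_allclose(rotate_mueller(np.eye(4), 0.73), np.eye(4), atol=1e-12)

    def test_rotated_retarder_matches_closed_form(self):
        # rotating a fast-axis-0 retarder by alpha is the same matrix as
        # building the retarder at azimuth alpha directly
        direct = make_retarder(0.5, np.pi / 8)
        rotated = rotate_mueller(make_retarder(0.5, 0.0), np.pi / 8)
        np.testing.assert_allclose(rotated, direct, atol=1e-12)

    def test_isotropic_depolarizer_commutes_with_rotation(self):
        M = np.diag([1.0, 0.7, 0.7, 0.4])
        np.testing.assert_allclose(rotate_mueller(M, 1.1), M, atol=1e-12)

    @given(alpha=angles)
    @settings(max_examples=30, derandomize=True)
    def test_round_trip(self, alpha):
        M = random_physical_mueller(7)
        back = rotate_mueller(rotate_mueller(M, alpha), -alpha)
        np.testing.assert_allclose(back, M, atol=1e-12)


class TestNormalize:
    def test_scalar_division(self):
        np.testing.assert_allclose(
            normalize(np.diag([2.0, 1.0, 1.0, 1.0])), np.diag([1.0, 0.5, 0.5, 0.5])
        )

    def test_identity_unchanged(self):
        np.testing.assert_allclose(normalize(np.eye(4)), np.eye(4))

    @pytest.mark.parametrize("m11", [0.0, -1.0])
    def test_degenerate_raises(self, m11):
        M = np.eye(4)
        M[0, 0] = m11
        with pytest.raises(DegenerateMatrixError):
            normalize(M)


class TestFixtures:
    def test_zero_retardance_is_identity(self):
        np.testing.assert_allclose(make_retarder(0.0, 0.3), np.eye(4), atol=1e-12)

    def test_half_wave_plate(self):
        np.testing.assert_allclose(
            make_retarder(np.pi, 0.0), np.diag([1.0, 1.0, -1.0, -1.0]), atol=1e-12
        )

    @pytest.mark.parametrize("delta,theta", [(0.5, 0.3), (1.2, -0.9), (2.9, 1.4)])
    def test_retarder_exp_log_round_trip(self, delta, theta):
        M = make_retarder(delta, theta)
        np.testing.assert_allclose(expm(np.real(logm(M))), M, atol=1e-9)

    @pytest.mark.parametrize("delta,theta", [(0.5, 0.0), (1.0, 0.7)])
    def test_retarder_is_proper_rotation_block(self, delta, theta):
        M = make_retarder(delta, theta)
        assert np.linalg.det(M) == pytest.approx(1.0)
        block = M[1:, 1:]
        np.testing.assert_allclose(block @ block.T, np.eye(3), atol=1e-12)

    def test_diattenuator_identity_at_zero(self):
        np.testing.assert_allclose(make_diattenuator(0.0, 0.5), np.eye(4), atol=1e-12)

    def test_diattenuator_matches_generator_exponential(self):
        L = np.zeros((4, 4))
        L[0, 1] = L[1, 0] = 0.3
        np.testing.assert_allclose(make_diattenuator(0.3, 0.0), expm(L), atol=1e-12)
        # m12 of expm of that generator is sinh(0.3) (cosh on diagonal)
        M = make_diattenuator(0.3, 0.0)
        assert M[0, 1] == pytest.approx(np.sinh(0.3))
        assert M[0, 0] == pytest.approx(np.cosh(0.3))

    def test_depolarizer_closed_form(self):
        M = make_depolarizer(-0.2, -0.4, -0.6)
        np.testing.assert_allclose(
            M, np.diag([1.0, np.exp(-0.2), np.exp(-0.4), np.exp(-0.6)])
        )
        np.testing.assert_allclose(
            np.real(logm(M)), np.diag([0.0, -0.2, -0.4, -0.6]), atol=1e-12
        )

    def test_depolarizer_rejects_gain(self):
        with pytest.raises(ValueError):
            make_depolarizer(0.1, -0.1, -0.1)

    def test_random_matrix_reproducible_and_logmable(self):
        M1 = random_physical_mueller(42)
        M2 = random_physical_mueller(42)
        np.testing.assert_array_equal(M1, M2)
        L = np.real(logm(M1))
        np.testing.assert_allclose(expm(L), M1, atol=1e-10)
        assert np.max(np.abs(L)) <= 0.5 + 1e-6
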