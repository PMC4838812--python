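"""Unit tests for the sigmoid, drift fields, outputs and state mappings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wendling import (
    FULL_DIM,
    ModelParameters,
    SigmoidParameters,
    full_drift,
    map_full_to_reduced,
    map_reduced_to_full,
    output_full,
    output_reduced,
    reduced_drift,
    sigmoid,
    sigmoid_slope,
)
from wendling.dynamics import equilibria

from conftest import TABLE_EQUILIBRIA


class TestSigmoid:
    def test_reference_values(self):
        sp = SigmoidParameters()
        # midpoint: half the saturation rate
        assert sigmoid(6.0, sp) == pytest.approx(2.5, abs=1e-12)
        # direct evaluation of the closed form at v=0
        assert sigmoid(0.0, sp) == pytest.approx(5.0 / (1.0 + math.exp(3.36)),
                                                 rel=1e-12)
        # saturation limits, far beyond float-exp range
        assert sigmoid(1e6, sp) == pytest.approx(5.0, abs=1e-12)
        assert sigmoid(-1e6, sp) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(v=st.floats(-1e6, 1e6), dv=st.floats(1e-6, 1e3))
    def test_bounds_and_monotonicity(self, v, dv):
        sp = SigmoidParameters()
        lo, hi = sigmoid(v, sp), sigmoid(v + dv, sp)
        assert 0.0 <= lo <= 2 * sp.e0
        assert hi >= lo  # non-decreasing (strict away from saturation)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParameters(e0=0.0)
        with pytest.raises(ValueError):
            SigmoidParameters(r=-1.0)


class TestSigmoidSlope:
    def test_midpoint_value_and_symmetry(self):
        sp = SigmoidParameters()
        assert sigmoid_slope(6.0, sp) == pytest.approx(sp.e0 * sp.r / 2, rel=1e-12)
        for x in (0.3, 1.7, 9.0):
            assert sigmoid_slope(6.0 + x, sp) == pytest.approx(
                sigmoid_slope(6.0 - x, sp), rel=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(v=st.floats(-40, 32))
    def test_matches_finite_difference(self, v):
        # above v ~ 32 the sigmoid is within 1e-6 of saturation and a central
        # difference of two ~5.0 values is pure cancellation noise
        sp = SigmoidParameters()
        eps = 1e-3
        fd = (sigmoid(v + eps, sp) - sigmoid(v - eps, sp)) / (2 * eps)
        assert sigmoid_slope(v, sp) == pytest.approx(fd, rel=1e-6)


def _drift_transcription(y, p, pr):
    """Independent, vectorized transcription of the ten drift equations."""
    sp = p.sigmoid
    S = lambda v: 2 * sp.e0 / (1 + np.exp(np.clip(sp.r * (sp.v0 - v), None, 500)))
    y = np.asarray(y, float)
    acc = np.array([
        p.A * p.a * S(y[1] - y[2] - y[3]),
        p.A * p.a * (pr + p.C2 * S(p.C1 * y[0])),
        p.B * p.b * p.C4 * S(p.C3 * y[0]),
        p.G * p.g * p.C7 * S(p.C5 * y[0] - p.C6 * y[4]),
        p.B * p.b * S(p.C3 * y[0]),
    ])
    rates = np.array([p.a, p.a, p.b, p.g, p.b])
    return np.concatenate([y[5:], acc - 2 * rates * y[5:] - rates**2 * y[:5]])


class TestFullDrift:
    def test_vanishes_at_published_equilibrium(self, params):
        p = params.with_gains(B=45.0)
        y = np.array([0.008, 6.097, 5.882, 0.339, 0.174, 0, 0, 0, 0, 0])
        # the published point is rounded to 3 decimals and the acceleration
        # rows amplify that by the squared rate constants (up to g^2 ~ 1e5),
        # so compare the residual on the PSP position scale instead
        d = full_drift(y, p, 90.0)
        rates2 = np.array([p.a, p.a, p.b, p.g, p.b]) ** 2
        assert np.max(np.abs(d[5:]) / rates2) < 0.2
        refined = equilibria(p)[0].state
        assert np.max(np.abs(full_drift(refined, p, 90.0))) < 1e-9

    def test_zero_state_structure(self, params):
        d = full_drift(np.zeros(FULL_DIM), params, 0.0)
        assert np.all(d[:5] == 0.0)
        assert d[5] == pytest.approx(
            params.A * params.a * float(sigmoid(0.0, params.sigmoid)), rel=1e-12)

    def test_matches_independent_transcription(self, params):
        rng = np.random.default_rng(42)
        for _ in range(50):
            y = rng.uniform(-30, 30, FULL_DIM)
            pr = rng.uniform(0, 200)
            got = full_drift(y, params, pr)
            ref = _drift_transcription(y, params, pr)
            np.testing.assert_allclose(got, ref, rtol=1e-12, atol=1e-9)

    def test_wrong_dimension_rejected(self, params):
        with pytest.raises(ValueError):
            full_drift(np.zeros(8), params, 90.0)


class TestReducedDrift:
    def test_vanishes_at_reduced_equilibrium_image(self, params):
        p = params.with_gains(B=45.0)
        full_eq = equilibria(p)[0].state
        red = map_full_to_reduced(full_eq, p, tol=1e-6)
        assert np.max(np.abs(reduced_drift(red, p, 90.0))) < 1e-9

    def test_zero_state(self, params):
        d = reduced_drift(np.zeros(8), params, 0.0)
        assert np.all(d[:4] == 0.0)


class TestOutputs:
    def test_full_output_projection(self):
        y = np.zeros(FULL_DIM)
        assert output_full(y) == 0.0
        y[1], y[2], y[3] = 6.097, 5.882, 0.339
        assert output_full(y) == pytest.approx(-0.124, abs=1e-12)
        y[1], y[2], y[3] = 1.0, 1.0, 0.0
        assert output_full(y) == 0.0

    def test_reduced_output_matches_full_on_consistent_states(self, params):
        rng = np.random.default_rng(3)
        for _ in range(20):
            red = rng.normal(size=8)
            full = map_reduced_to_full(red, params)
            assert output_reduced(red, params) == pytest.approx(
                float(output_full(full)), rel=1e-12, abs=1e-12)


class TestStateMaps:
    def test_round_trip_identity(self, params):
        rng = np.random.default_rng(7)
        for _ in range(20):
            red = rng.normal(scale=10, size=8)
            full = map_reduced_to_full(red, params)
            back = map_full_to_reduced(full, params, tol=1e-9)
            np.testing.assert_allclose(back, red, rtol=0, atol=1e-12)

    def test_zero_maps_to_zero(self, params):
        np.testing.assert_array_equal(
            map_full_to_reduced(np.zeros(FULL_DIM), params), np.zeros(8))
        np.testing.assert_array_equal(
            map_reduced_to_full(np.zeros(8), params), np.zeros(FULL_DIM))

    def test_published_point_is_consistent_within_rounding(self, params):
        # slow-inhibition PSP duplication: y2 = C4*y4 up to print rounding
        y2, y4 = 5.882, 0.174
        assert y2 == pytest.approx(params.C4 * y4, abs=0.05)
        y = np.array([0.008, 6.097, y2, 0.339, y4, 0, 0, 0, 0, 0])
        red = map_full_to_reduced(y, params, tol=0.05)
        assert red[2] == y4

    def test_inconsistent_state_rejected(self, params):
        y = np.zeros(FULL_DIM)
        y[2], y[4] = 1.0, 1.0  # violates y2 = C4*y4 grossly
        with pytest.raises(ValueError, match="not consistent"):
            map_full_to_reduced(y, params, tol=1e-6)


def test_parameter_validation():
    with pytest.raises(ValueError):
        ModelParameters(a=-1.0)
    with pytest.raises(ValueError):
        ModelParameters(C3=0.0)
    with pytest.raises(ValueError):
        ModelParameters(input_variance=-5.0)


def test_published_table_consistency(params):
    """Every printed equilibrium is a near-fixed-point on the PSP scale."""
    for B, rows in TABLE_EQUILIBRIA.items():
        p = params.with_gains(B=float(B))
        rates2 = np.array([p.a, p.a, p.b, p.g, p.b]) ** 2
        for y_out, psp, _stab in rows:
            y = np.array(list(psp) + [0.0] * 5)
            d = full_drift(y, p, 90.0)
            assert np.max(np.abs(d[5:]) / rates2) < 0.2
            assert y_out == pytest.approx(psp[1] - psp[2] - psp[3], abs=2e-3)
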