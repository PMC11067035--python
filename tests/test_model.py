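"""Unit and property tests of the four-state kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synprime import (
    CalciumParameters,
    PrimingParameters,
    StateVector,
    apply_ap,
    ca_trace,
    evolve,
    k1_of_ca,
    k2_of_ca,
    resting_steady_state,
    state_derivative,
    ts_fraction,
)
from synprime.model import StateError, tsl_decay
from synprime.params import ParameterError


@pytest.fixture
def params(fsin):
    return fsin


class TestRates:
    def test_k1_zero_at_zero_calcium(self, params):
        assert k1_of_ca(0.0, params) == 0.0

    def test_k1_saturates_at_k1_max(self, params):
        assert k1_of_ca(1e12, params) == pytest.approx(params.k1_max, rel=1e-6)

    def test_k1_half_saturation_at_km(self, params):
        assert k1_of_ca(params.K_M, params) == pytest.approx(params.k1_max / 2)

    def test_k1_monotone_in_calcium(self, params):
        cas = np.linspace(0, 5000, 200)
        vals = [k1_of_ca(c, params) for c in cas]
        assert np.all(np.diff(vals) > 0)

    def test_k2_resting_identity(self, params):
        assert k2_of_ca(50.0, params, ca_rest=50.0) == params.k2_0

    def test_k2_calcium_insensitive_when_slope_zero(self, params):
        p = params.replace(s2=0.0)
        for ca in (0.0, 50.0, 500.0):
            assert k2_of_ca(ca, p, ca_rest=50.0) == p.k2_0

    def test_k2_linear_slope(self, params):
        # k2_0 = 1/s, s2 = 0.01/(s nM), 110 nM above rest -> 2.1/s
        p = params.replace(k2_0=1.0, s2=0.01)
        assert k2_of_ca(160.0, p, ca_rest=50.0) == pytest.approx(2.1)

    def test_negative_calcium_rejected(self, params):
        with pytest.raises(StateError):
            k1_of_ca(-1.0, params)
        with pytest.raises(StateError):
            k2_of_ca(-1.0, params)


class TestCalciumTrace:
    def test_resting_before_first_ap(self, cap):
        assert ca_trace(-0.01, [0.0], cap) == pytest.approx(cap.ca_rest)

    def test_jump_at_ap(self, cap):
        assert ca_trace(0.0, [0.0], cap) == pytest.approx(
            cap.ca_rest + cap.delta_ca
        )

    def test_superposition_of_two_aps(self):
        cap = CalciumParameters(ca_rest=50.0, delta_ca=110.0, tau_ca=0.04)
        # two APs 10 ms apart, evaluated at the second AP
        expected = 50.0 + 110.0 * math.exp(-0.01 / 0.04) + 110.0
        assert ca_trace(0.01, [0.0, 0.01], cap) == pytest.approx(expected)

    def test_vectorized_matches_scalar(self, cap):
        ts = np.array([0.005, 0.02, 0.2])
        aps = [0.0, 0.01, 0.05]
        vec = ca_trace(ts, aps, cap)
        for t, v in zip(ts, vec):
            assert ca_trace(float(t), aps, cap) == pytest.approx(v)

    def test_non_increasing_ap_times_rejected(self, cap):
        with pytest.raises(StateError):
            ca_trace(0.1, [0.0, 0.0], cap)


class TestStateVector:
    def test_sum_must_be_one(self):
        with pytest.raises(StateError):
            StateVector(es=0.5, ls=0.5, ts=0.5, tsl=0.0)

    def test_components_must_be_fractions(self):
        with pytest.raises(StateError):
            StateVector(es=-0.2, ls=0.7, ts=0.5, tsl=0.0)


class TestDerivative:
    def test_resting_steady_state_is_fixed_point(self, params, cap):
        rest = resting_steady_state(params, cap)
        d = state_derivative(rest, cap.ca_rest, params, cap)
        assert max(abs(x) for x in d) < 1e-12

    def test_isolated_tsl_decay_flow(self, cap):
        p = PrimingParameters(
            b1=1e-9, k1_max=1e-9, K_M=100.0, k2_0=0.0, s2=0.0,
            b2=1e-9, b3=0.04, f_tsl=0.0, p_fusion=0.5,
        )
        state = StateVector(es=0.3, ls=0.3, ts=0.2, tsl=0.2)
        d = state_derivative(state, cap.ca_rest, p, cap)
        assert d[3] == pytest.approx(-0.2 / 0.04)
        assert d[1] == pytest.approx(0.2 / 0.04)

    @given(
        es=st.floats(0.01, 0.97),
        ls=st.floats(0.0, 0.5),
        ts=st.floats(0.0, 0.3),
        ca=st.floats(0.0, 2000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_of_total_occupancy(self, fsin, cap, es, ls, ts, ca):
        total = es + ls + ts
        if total > 1.0:
            es, ls, ts = es / total, ls / total, ts / total
        tsl = max(0.0, 1.0 - es - ls - ts)
        state = StateVector(es=es, ls=ls, ts=ts, tsl=tsl)
        d = state_derivative(state, ca, fsin, cap)
        assert sum(d) == pytest.approx(0.0, abs=1e-12)


class TestApplyAp:
    def test_single_pool_release(self, cap):
        p = PrimingParameters(
            b1=1.0, k1_max=1.0, K_M=100.0, k2_0=1.0, s2=0.0,
            b2=1.0, b3=0.04, f_tsl=0.0, p_fusion=0.6,
        )
        state = StateVector(es=0.0, ls=0.0, ts=1.0, tsl=0.0)
        new, released = apply_ap(state, p)
        assert released == pytest.approx(0.6)
        assert new.es == pytest.approx(0.6)
        assert new.ts == pytest.approx(0.4)

    def test_transfer_only(self, cap):
        p = PrimingParameters(
            b1=1.0, k1_max=1.0, K_M=100.0, k2_0=1.0, s2=0.0,
            b2=1.0, b3=0.04, f_tsl=0.2, p_fusion=0.0,
        )
        state = StateVector(es=0.5, ls=0.5, ts=0.0, tsl=0.0)
        new, released = apply_ap(state, p)
        assert released == 0.0
        assert new.tsl == pytest.approx(0.1)
        assert new.ls == pytest.approx(0.4)

    def test_low_occupancy_release_matches_low_pv(self, cap):
        # 7% tight-state fraction and p_fusion 0.36 give ~0.025 released per
        # docked vesicle, the facilitating connection's resting Pv
        state = StateVector(es=0.0, ls=0.93, ts=0.07, tsl=0.0)
        p = PrimingParameters(
            b1=1.0, k1_max=1.0, K_M=100.0, k2_0=1.0, s2=0.0,
            b2=1.0, b3=0.04, f_tsl=0.0, p_fusion=0.36,
        )
        _, released = apply_ap(state, p)
        assert released == pytest.approx(0.0252)

    @given(
        es=st.floats(0.0, 1.0),
        ls=st.floats(0.0, 1.0),
        ts=st.floats(0.0, 1.0),
        tsl=st.floats(0.0, 1.0),
        pf=st.floats(0.0, 1.0),
        ft=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_conservation_and_linearity(self, es, ls, ts, tsl, pf, ft):
        total = es + ls + ts + tsl
        if total == 0:
            return
        es, ls, ts, tsl = (x / total for x in (es, ls, ts, tsl))
        state = StateVector(es=es, ls=ls, ts=ts, tsl=tsl)
        p = PrimingParameters(
            b1=1.0, k1_max=1.0, K_M=100.0, k2_0=1.0, s2=0.0,
            b2=1.0, b3=0.04, f_tsl=ft, p_fusion=pf,
        )
        new, released = apply_ap(state, p)
        assert new.es + new.ls + new.ts + new.tsl == pytest.approx(1.0, abs=1e-12)
        assert released == pytest.approx(pf * (ts + tsl), abs=1e-12)


class TestEvolve:
    def test_zero_duration_is_identity(self, params, cap):
        rest = resting_steady_state(params, cap)
        out = evolve(rest, lambda t: cap.ca_rest, 0.0, params=params, cap=cap)
        assert out == rest

    def test_fixed_point_over_ten_seconds(self, params, cap):
        rest = resting_steady_state(params, cap)
        out = evolve(
            rest, lambda t: cap.ca_rest, 10.0, dt=1e-3, params=params, cap=cap
        )
        for name in ("es", "ls", "ts", "tsl"):
            assert getattr(out, name) == pytest.approx(
                getattr(rest, name), abs=1e-6
            )

    def test_tsl_relaxes_exponentially(self, params, cap):
        state = StateVector(es=0.3, ls=0.3, ts=0.2, tsl=0.2)
        t = 0.05
        out = evolve(
            state, lambda _: cap.ca_rest, t, dt=1e-5, params=params, cap=cap
        )
        assert out.tsl == pytest.approx(tsl_decay(0.2, t, params), rel=1e-3)

    def test_euler_against_rk4_cross_oracle(self, params, cap):
        state = StateVector(es=0.7, ls=0.2, ts=0.05, tsl=0.05)
        ca_fn = lambda t: cap.ca_rest + 300.0 * math.exp(-t / 0.1)
        fine_euler = evolve(
            state, ca_fn, 1.0, dt=1e-5, method="euler", params=params, cap=cap
        )
        coarse_rk4 = evolve(
            state, ca_fn, 1.0, dt=1e-3, method="rk4", params=params, cap=cap
        )
        for name in ("es", "ls", "ts", "tsl"):
            assert abs(
                getattr(fine_euler, name) - getattr(coarse_rk4, name)
            ) < 1e-4


class TestRestingSteadyState:
    def test_no_forward_priming_empties_tight_state(self, params, cap):
        rest = resting_steady_state(params.replace(k2_0=0.0), cap)
        assert rest.ts == 0.0
        assert ts_fraction(rest) == 0.0

    def test_symmetric_rates_give_half(self, params, cap):
        rest = resting_steady_state(params.replace(k2_0=params.b2), cap)
        assert ts_fraction(rest) == pytest.approx(0.5)

    def test_reference_sets_hit_printed_fractions(self, fsin, olm, cap):
        assert ts_fraction(resting_steady_state(fsin, cap)) == pytest.approx(0.44)
        assert ts_fraction(resting_steady_state(olm, cap)) == pytest.approx(0.07)

    def test_ts_fraction_undefined_without_docked_vesicles(self):
        with pytest.raises(StateError):
            ts_fraction(StateVector(es=1.0, ls=0.0, ts=0.0, tsl=0.0))


class TestParameterValidation:
    def test_rates_must_be_positive(self, fsin):
        with pytest.raises(ParameterError):
            fsin.replace(b1=0.0)
        with pytest.raises(ParameterError):
            fsin.replace(b3=-0.1)

    def test_probabilities_bounded(self, fsin):
        with pytest.raises(ParameterError):
            fsin.replace(p_fusion=1.2)

    def test_long_lived_labile_state_warns(self, fsin):
        with pytest.warns(UserWarning):
            fsin.replace(b3=5.0)

    def test_unknown_keys_rejected(self, fsin):
        with pytest.raises(ParameterError):
            PrimingParameters.from_dict({**fsin.to_dict(), "bogus": 1.0})
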