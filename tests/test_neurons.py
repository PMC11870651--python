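"""Point-neuron dynamics, activation function, and FFFB inhibition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chunkwm.neurons import (
    InhibParams,
    Layer,
    Projection,
    UnitParams,
    UnitState,
    activation,
    fffb_inhibition,
    g_e_theta,
    net_excitation,
    settle,
    step_membrane,
)

P = UnitParams()


class TestNetExcitation:
    def test_zero_input_gives_zero(self):
        proj = Projection(weights=np.full((3, 2), 0.5))
        ge = net_excitation(np.zeros(3), proj)
        np.testing.assert_array_equal(ge, 0.0)

    def test_full_drive_is_mean_one(self):
        proj = Projection(weights=np.ones((4, 4)))
        ge = net_excitation(np.ones(4), proj)
        np.testing.assert_allclose(ge, 1.0)

    def test_hand_evaluated_two_senders(self):
        # (1*0.2 + 0.5*0.8) / 2 = 0.3
        proj = Projection(weights=np.array([[0.2], [0.8]]))
        ge = net_excitation(np.array([1.0, 0.5]), proj)
        np.testing.assert_allclose(ge, [0.3])

    def test_scale_weighted_average_of_projections(self):
        pa = Projection(weights=np.ones((2, 1)), rel_scale=2.0)
        pb = Projection(weights=np.ones((2, 1)), rel_scale=1.0)
        # layer a fully active, layer b silent: (2*1 + 1*0)/3
        ge = net_excitation([np.ones(2), np.zeros(2)], [pa, pb])
        np.testing.assert_allclose(ge, [2.0 / 3.0])

    def test_one_to_one_projection_passes_through(self):
        proj = Projection.one_to_one(5)
        x = np.array([0.0, 0.2, 0.9, 0.0, 1.0])
        np.testing.assert_allclose(net_excitation(x, proj), x)

    def test_dimension_mismatch_is_hard_error(self):
        proj = Projection(weights=np.ones((3, 2)))
        with pytest.raises(ValueError):
            net_excitation(np.ones(4), proj)

    def test_weights_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            Projection(weights=np.array([[1.5]]))


class TestStepMembrane:
    @staticmethod
    def _state(vm, ge, gi, n=1):
        return UnitState(
            Vm=np.full(n, vm), ge=np.full(n, ge),
            gi=np.full(n, gi), y=np.zeros(n),
        )

    def test_fixed_point_has_zero_drift(self):
        ge, gi = 0.4, 0.3
        num = ge * P.gbar_e * P.E_e + gi * P.gbar_i * P.E_i + P.gbar_l * P.E_l
        den = ge * P.gbar_e + gi * P.gbar_i + P.gbar_l
        v_eq = num / den
        out = step_membrane(self._state(v_eq, ge, gi), P)
        np.testing.assert_allclose(out.Vm, v_eq, atol=1e-12)

    def test_leak_only_converges_to_e_l(self):
        s = self._state(0.9, 0.0, 0.0)
        for _ in range(2000):  # leak-only time constant is long (g_tot=0.1)
            s = step_membrane(s, P)
        np.testing.assert_allclose(s.Vm, P.E_l, atol=1e-6)

    def test_single_euler_step_hand_evaluated(self):
        # Vm=0.3, ge=0.5, gi=0.2, dt=0.15, default params:
        # g_tot = 0.5 + 0.2 + 0.1 = 0.8
        # v_eq = (0.5*1 + 0.2*0.25 + 0.1*0.3)/0.8 = 0.725
        # Vm' = 0.3 + 0.15*0.8*(0.725 - 0.3) = 0.351
        out = step_membrane(self._state(0.3, 0.5, 0.2), P, dt=0.15)
        np.testing.assert_allclose(out.Vm, [0.351], atol=1e-12)

    def test_monotone_convergence_from_below_and_above(self):
        for v0 in (0.0, 1.0):
            s = self._state(v0, 0.6, 0.1)
            prev = s.Vm.copy()
            diffs = []
            for _ in range(50):
                s = step_membrane(s, P)
                diffs.append(s.Vm[0] - prev[0])
                prev = s.Vm.copy()
            signs = np.sign([d for d in diffs if abs(d) > 1e-12])
            assert len(set(signs)) <= 1  # never overshoots

    @given(
        vm=st.floats(0.25, 1.0),
        ge=st.floats(0, 50),
        gi=st.floats(0, 50),
        steps=st.integers(1, 30),
    )
    @settings(max_examples=100, deadline=None)
    def test_vm_bounded_by_reversal_potentials(self, vm, ge, gi, steps):
        s = self._state(vm, ge, gi)
        for _ in range(steps):
            s = step_membrane(s, P)
        assert min(P.E_i, P.E_l) - 1e-9 <= s.Vm[0] <= P.E_e + 1e-9


class TestActivation:
    def test_zero_at_threshold_conductance(self):
        gi = 0.5
        assert activation(g_e_theta(gi, P), gi, P) == 0.0

    def test_below_threshold_is_zero(self):
        assert activation(0.0, 1.0, P) == 0.0

    def test_saturates_toward_one(self):
        assert activation(1e6, 0.0, P) > 0.999
        assert activation(1e6, 0.0, P) < 1.0

    def test_half_activation_point(self):
        # gamma*(ge - geTheta) = 1  =>  y = 0.5
        gi = 0.2
        ge = g_e_theta(gi, P) + 1.0 / P.gamma
        assert activation(ge, gi, P) == pytest.approx(0.5)

    @given(
        ge=st.floats(0, 3), ge2=st.floats(0, 3),
        gi=st.floats(0, 3), gi2=st.floats(0, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_arguments(self, ge, ge2, gi, gi2):
        lo, hi = sorted([ge, ge2])
        assert activation(hi, gi, P) >= activation(lo, gi, P)
        lo_i, hi_i = sorted([gi, gi2])
        assert activation(ge, hi_i, P) <= activation(ge, lo_i, P)


class TestFFFB:
    I = InhibParams(Gi=2.0, ff_gain=1.0, fb_gain=1.0, ff_floor=0.1)

    def test_silent_layer_no_inhibition(self):
        gi, _ = fffb_inhibition(np.zeros(10), np.zeros(10), self.I)
        assert gi == 0.0

    def test_hand_evaluated(self):
        # ff = 1*(0.5-0.1) = 0.4 ; fb = 1*0.25 ; gi = 2*(0.65) = 1.3
        gi, _ = fffb_inhibition(np.full(4, 0.5), np.full(4, 0.25), self.I)
        assert gi == pytest.approx(1.3)

    def test_scale_monotone(self):
        rng = np.random.default_rng(0)
        netin = rng.uniform(0, 1, 10)
        act = rng.uniform(0, 1, 10)
        gi1, _ = fffb_inhibition(netin, act, self.I)
        gi2, _ = fffb_inhibition(2 * netin, act, self.I)
        gi3, _ = fffb_inhibition(netin, 2 * act, self.I)
        assert gi2 >= gi1 and gi3 >= gi1

    def test_fb_time_average_carries_state(self):
        gi1, fb1 = fffb_inhibition(
            np.zeros(5), np.full(5, 0.8), self.I, fb_prev=0.0
        )
        assert 0 < fb1 < 0.8  # partial step toward fb_gain * mean act
        gi2, fb2 = fffb_inhibition(
            np.zeros(5), np.full(5, 0.8), self.I, fb_prev=fb1
        )
        assert fb1 < fb2 < 0.8

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fffb_inhibition(np.array([-0.1]), np.zeros(1), self.I)


class TestSettle:
    def test_zero_external_input_settles_to_silence(self):
        src = Layer("in", 6)
        src.clamp(np.zeros(6))
        dst = Layer("out", 6)
        res = settle(
            [src, dst],
            {"out": [(src, Projection(weights=np.full((6, 6), 0.8)))]},
        )
        np.testing.assert_allclose(res.activities["out"], 0.0, atol=1e-6)
        assert res.converged

    def test_single_unit_strong_drive_active_above_half(self):
        src = Layer("in", 1)
        src.clamp(np.ones(1))
        dst = Layer("out", 1, inhib=InhibParams(Gi=0.5))
        res = settle(
            [src, dst], {"out": [(src, Projection.one_to_one(1))]},
            n_cycles=100,
        )
        assert res.activities["out"][0] > 0.5

    def test_settle_is_idempotent(self):
        rng = np.random.default_rng(3)
        src = Layer("in", 8)
        src.clamp(rng.uniform(0, 1, 8))
        dst = Layer("out", 8)
        wiring = {"out": [(src, Projection(weights=rng.uniform(0, 1, (8, 8))))]}
        res1 = settle([src, dst], wiring, n_cycles=200)
        res2 = settle([src, dst], wiring, n_cycles=200)
        np.testing.assert_allclose(
            res1.activities["out"], res2.activities["out"], atol=2e-4
        )

    def test_nonfinite_activity_names_layer(self):
        src = Layer("in", 2)
        src.clamp(np.array([np.nan, 0.0]))
        dst = Layer("bad", 2)
        with pytest.raises(FloatingPointError, match="bad"):
            settle([src, dst], {"bad": [(src, Projection.one_to_one(2))]})

    def test_invalid_cycle_count(self):
        with pytest.raises(ValueError):
            settle([], {}, n_cycles=0)


def test_unit_params_invariants_enforced():
    with pytest.raises(ValueError):
        UnitParams(E_i=0.6)  # violates E_i <= E_l
    with pytest.raises(ValueError):
        UnitParams(gamma=0.0)
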