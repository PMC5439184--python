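"""Calcium-control plasticity: waveforms, driving force, Omega, updates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famnet import (NMDACurrentParams, PlasticityParams, STDPParams,
                    SynapseState, WaveformParams, bpap, calcium_step,
                    driving_force, epsp, nmda_current, omega, stdp_pair_update,
                    weight_update)


class TestWaveforms:
    def test_peak_at_zero(self):
        wf = WaveformParams(bpap_max=100.0)
        assert bpap(0.0, wf) == pytest.approx(100.0)
        assert epsp(0.0, wf, amplitude=3.0) == pytest.approx(3.0)

    def test_decay_values(self):
        wf = WaveformParams(bpap_max=1.0)
        # t = tau_f_bpap: 0.75 e^-1 + 0.25 e^-0.12
        assert bpap(1.2, wf) == pytest.approx(
            0.75 * math.exp(-1) + 0.25 * math.exp(-0.12), rel=1e-9)
        assert epsp(20.0, wf, amplitude=1.0) == pytest.approx(
            0.5 * math.exp(-10) + 0.5 * math.exp(-1), rel=1e-9)

    def test_vanish_at_long_times(self):
        wf = WaveformParams()
        assert bpap(1e4, wf) < 1e-6
        assert epsp(1e4, wf, amplitude=1.0) < 1e-6

    def test_epsp_tail_outlasts_bpap(self):
        wf = WaveformParams(bpap_max=1.0)
        for t in (5.0, 10.0, 20.0, 40.0):
            assert epsp(t, wf, amplitude=1.0) > bpap(t, wf)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bpap(-1.0)


class TestDrivingForce:
    def test_zero_at_reversal(self):
        assert driving_force(130.0) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero_mv(self):
        # -0.42*(-130) / (1 + 0.6/3.57)
        assert driving_force(0.0, mg=1.0) == pytest.approx(46.74, abs=0.01)

    def test_monotone_decreasing_in_mg(self):
        h = [driving_force(-30.0, mg=m) for m in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(h, h[1:]))

    def test_magnesium_block_at_hyperpolarized_potentials(self):
        # steep relief of the block from rest toward 0 mV
        assert driving_force(-65.0) < 2.0
        assert driving_force(0.0) / driving_force(-65.0) > 20.0

    def test_product_reading_available(self):
        hp = driving_force(0.0, product_reading=True)
        assert hp == pytest.approx(-0.42 * (-130) * (1 + 0.6 / 3.57), rel=1e-9)


class TestNMDACurrent:
    def test_zero_at_reversal_or_before_first_spike(self):
        assert nmda_current(5.0, 130.0) == pytest.approx(0.0, abs=1e-12)
        assert nmda_current(None, -65.0) == 0.0

    def test_inward_flux_below_reversal(self):
        assert nmda_current(0.0, -20.0) > 0.0

    def test_trace_decay(self):
        p = NMDACurrentParams()
        i0 = nmda_current(0.0, 0.0, p)
        i1 = nmda_current(1000.0, 0.0, p)
        assert 0 < i1 < i0


class TestCalciumStep:
    def test_pure_decay_over_tau(self):
        ca = 1.0
        for _ in range(2500):
            ca = calcium_step(ca, 0.0, 0.02, tau_ca=50.0)
        assert ca == pytest.approx(math.exp(-1), rel=1e-3)

    def test_steady_state_is_tau_times_current(self):
        ca = 0.0
        for _ in range(20000):
            ca = calcium_step(ca, 0.004, 0.1, tau_ca=50.0)
        assert ca == pytest.approx(0.2, rel=1e-3)

    def test_zero_stays_zero_and_floor(self):
        assert calcium_step(0.0, 0.0, 0.1) == 0.0
        assert calcium_step(0.01, -10.0, 0.1) == 0.0

    def test_inactivation_bounds_influx(self):
        ca = 0.0
        for _ in range(40000):
            ca = calcium_step(ca, 1.0, 0.1, tau_ca=50.0, ca_max=2.0)
        assert ca < 2.0

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            calcium_step(0.0, 0.0, 0.0)


class TestOmega:
    def test_plateaus(self):
        p = PlasticityParams()
        assert omega(0.0, p) == pytest.approx(-1.3e-4, abs=5e-5)
        assert omega(0.25, p) == pytest.approx(-0.4, abs=1e-3)
        assert omega(1.0, p) == pytest.approx(0.6, abs=1e-3)

    def test_adjusted_variant_parameters(self):
        p = PlasticityParams(variant="ltp_ltd_adjusted")
        assert (p.alpha1, p.alpha2, p.omega_rate) == (0.3, 0.4, 0.3)
        assert omega(1.0, p) == pytest.approx(0.7, abs=1e-3)

    def test_alpha_order_enforced(self):
        with pytest.raises(ValueError):
            PlasticityParams(alpha1=0.5, alpha2=0.4)


class TestWeightUpdate:
    def test_fixed_point(self):
        p = PlasticityParams()
        ca = 1.0
        w_star = p.omega_to_weight_scale * omega(ca, p)
        assert weight_update(w_star, ca, 1e-3, p) == pytest.approx(w_star)

    def test_sustained_high_calcium_potentiates_to_plateau(self):
        p = PlasticityParams()
        w = 1e-8
        for _ in range(20000):
            w = weight_update(w, 1.0, 1e-3, p)
        assert w == pytest.approx(min(p.omega_to_weight_scale * 0.6,
                                      p.weight_max), rel=1e-2)

    def test_clipping_at_upper_bound(self):
        p = PlasticityParams()
        assert weight_update(p.weight_max, 1.0, 10.0, p) <= p.weight_max

    @given(w=st.floats(1e-9, 6.5e-8), ca=st.floats(0.0, 3.0),
           dt=st.floats(1e-5, 0.1))
    @settings(max_examples=200, deadline=None)
    def test_bounds_invariant(self, w, ca, dt):
        p = PlasticityParams()
        w2 = weight_update(w, ca, dt, p)
        assert p.weight_min <= w2 <= p.weight_max


class TestSTDPPair:
    def test_signs_and_vanishing(self):
        w0 = 3e-8
        assert stdp_pair_update(w0, +10.0) > w0
        assert stdp_pair_update(w0, -10.0) < w0
        assert stdp_pair_update(w0, 1e6) == pytest.approx(w0, rel=1e-9)
        assert stdp_pair_update(w0, -1e6) == pytest.approx(w0, rel=1e-9)


def _pairing_peak(delta_t_ms, weight=3e-8, variant="full", n_pairs=3):
    """Peak calcium of a scalar synapse under pre/post pairing at 1 Hz."""
    wf = WaveformParams()
    pl = PlasticityParams(variant=variant, eta_max=0.0)
    syn = SynapseState(weight, waveform=wf, plasticity=pl)
    dt = 0.1
    peak = 0.0
    for p in range(n_pairs):
        t_pre = 50.0 + max(0.0, -delta_t_ms)
        t_post = t_pre + delta_t_ms
        for i in range(10000):  # 1 s cycle
            t = i * dt
            if abs(t - t_pre) < dt / 2:
                syn.pre_spike()
            if abs(t - t_post) < dt / 2:
                syn.post_spike()
            syn.step(dt)
            peak = max(peak, syn.ca)
    return peak


class TestTimingAsymmetry:
    def test_pre_post_exceeds_post_pre(self):
        assert _pairing_peak(+10.0) > _pairing_peak(-10.0)

    def test_bpap_removal_abolishes_asymmetry(self):
        plus = _pairing_peak(+10.0, variant="ltp_ltd_only")
        minus = _pairing_peak(-10.0, variant="ltp_ltd_only")
        assert plus == pytest.approx(minus, rel=0.02)

    def test_calcium_never_negative(self):
        wf = WaveformParams()
        syn = SynapseState(6.5e-8, waveform=wf)
        for i in range(5000):
            if i % 500 == 0:
                syn.pre_spike()
                syn.post_spike()
            syn.step(0.2)
            assert syn.ca >= 0.0
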