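"""NMDAR synapse state: waveforms, calcium dynamics and the weight rule.

The calcium control hypothesis as implemented here: each presynaptic spike
opens NMDA channels (double-exponential open-probability trace) and
generates a local EPSP proportional to the synaptic weight; each
postsynaptic spike back-propagates as a BPAP.  The calcium driving force
H(V) is evaluated at the local membrane potential of the spine,
``v_rest_nmda + EPSP + BPAP`` (the magnesium block operates on the
biological voltage scale, ~59x block at -65 mV, steep relief toward 0 mV).
Calcium integrates the NMDA flux with a 50 ms decay; the weight relaxes
toward ``kappa * Omega(Ca)`` at the calcium-dependent rate ``eta(Ca)``,
clipped to [weight_min, weight_max].

All functions here are scalar/ndarray pure math; the time-stepped network
simulation uses the table builders at the bottom for speed.
"""

from __future__ import annotations

import numpy as np

from .params import NMDACurrentParams, PlasticityParams, STDPParams, WaveformParams

__all__ = [
    "bpap",
    "epsp",
    "driving_force",
    "nmda_current",
    "calcium_step",
    "omega",
    "eta",
    "weight_update",
    "stdp_pair_update",
    "SynapseState",
]


def _double_exp(t, amp, i_f, tau_f, i_s, tau_s):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    v = amp * (i_f * np.exp(-t / tau_f) + i_s * np.exp(-t / tau_s))
    return float(v) if v.ndim == 0 else v


def bpap(t, params: WaveformParams | None = None):
    """Back-propagating action potential waveform (t in ms, result mV)."""
    p = params or WaveformParams()
    return _double_exp(t, p.bpap_max, p.i_f_bpap, p.tau_f_bpap,
                       p.i_s_bpap, p.tau_s_bpap)


def epsp(t, params: WaveformParams | None = None, amplitude: float | None = None):
    """Local EPSP waveform at the synapse (t in ms, result mV).

    ``amplitude`` defaults to the unit-weight amplitude ``epsp_gain * 1``;
    for a synapse of weight ``w`` pass ``amplitude=params.epsp_gain * w``.
    """
    p = params or WaveformParams()
    amp = 1.0 if amplitude is None else amplitude
    return _double_exp(t, amp, p.i_f_epsp, p.tau_f_epsp,
                       p.i_s_epsp, p.tau_s_epsp)


def driving_force(v, mg: float = 1.0, v_reversal: float = 130.0,
                  product_reading: bool = False):
    """Calcium driving force through the NMDAR at membrane potential ``v`` (mV).

    Jahr-Stevens style magnesium block: ``-0.42 (V - Vr)`` divided by
    ``1 + 0.6 exp(-0.09 V) [Mg]/3.57``; zero at the calcium reversal
    potential.  ``product_reading=True`` multiplies instead of dividing
    (the literal typography of the printed formula; comparison only).
    """
    v = np.asarray(v, dtype=float)
    block = 1.0 + 0.6 * np.exp(-0.09 * v) * mg / 3.57
    num = -0.42 * (v - v_reversal)
    h = num * block if product_reading else num / block
    return float(h) if h.ndim == 0 else h


def nmda_current(t_since_pre, v, params: NMDACurrentParams | None = None):
    """Calcium flux through NMDARs (uM/ms) at ``t_since_pre`` ms after the
    last presynaptic spike, with local membrane potential ``v`` (mV).

    Zero before the first presynaptic spike (pass ``t_since_pre=None`` or a
    negative value).  Successive presynaptic spikes restart the trace
    (latest spike dominates).
    """
    p = params or NMDACurrentParams()
    if t_since_pre is None:
        return 0.0
    t = np.asarray(t_since_pre, dtype=float)
    theta = (t >= 0).astype(float)
    trace = p.i_f * np.exp(-np.maximum(t, 0.0) / p.tau_f) + \
        p.i_s * np.exp(-np.maximum(t, 0.0) / p.tau_s)
    h = driving_force(v, p.mg, p.v_reversal_ca, p.mg_block_product)
    i = p.gain * theta * trace * h
    return float(i) if np.ndim(i) == 0 else i


def calcium_step(ca, i_nmda, dt, tau_ca: float = 50.0,
                 ca_max: float | None = None):
    """One Euler step of synaptic calcium (dt and tau_ca in ms, ca in uM).

    With ``ca_max`` set, the influx is scaled by ``max(0, 1 - Ca/ca_max)``
    (calcium-dependent NMDAR inactivation); without it the step is the
    plain linear leaky integrator with steady state ``tau_ca * I``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ca = np.asarray(ca, dtype=float)
    i = np.asarray(i_nmda, dtype=float)
    if ca_max:
        i = i * np.maximum(0.0, 1.0 - ca / ca_max)
    nxt = np.maximum(ca + dt * (i - ca / tau_ca), 0.0)
    return float(nxt) if nxt.ndim == 0 else nxt


def _sig(x):
    # numerically safe logistic
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def omega(ca, params: PlasticityParams | None = None):
    """Calcium control function: sig(Ca-a2, b2) - Omega_rate * sig(Ca-a1, b1)."""
    p = params or PlasticityParams()
    ca = np.asarray(ca, dtype=float)
    om = _sig((ca - p.alpha2) * p.beta2) - p.omega_rate * _sig((ca - p.alpha1) * p.beta1)
    return float(om) if om.ndim == 0 else om


def eta(ca, params: PlasticityParams | None = None):
    """Calcium-dependent learning rate (1/s): two gated sigmoid branches."""
    p = params or PlasticityParams()
    ca = np.asarray(ca, dtype=float)
    lo = p.eta_lo_weight * _sig((ca - p.eta_lo_theta) * p.eta_lo_beta)
    hi = (1.0 - p.eta_lo_weight) * _sig((ca - p.eta_hi_theta) * p.eta_hi_beta)
    e = p.eta_max * (lo + hi)
    return float(e) if e.ndim == 0 else e


def weight_update(w, ca, dt_s, params: PlasticityParams | None = None):
    """One step of the bidirectional rule:
    ``W += dt * eta(Ca) * (kappa * Omega(Ca) - W)``, clipped to bounds.

    ``dt_s`` in seconds (eta is per second); ``ca`` in uM.
    """
    p = params or PlasticityParams()
    w = np.asarray(w, dtype=float)
    target = p.omega_to_weight_scale * omega(ca, p)
    nxt = w + dt_s * eta(ca, p) * (target - w)
    nxt = np.clip(nxt, p.weight_min, p.weight_max)
    return float(nxt) if nxt.ndim == 0 else nxt


def stdp_pair_update(w, delta_t_ms, params: STDPParams | None = None,
                     weight_min: float = 1.0e-9, weight_max: float = 6.5e-8):
    """Pair-based exponential STDP: pre-before-post (delta_t > 0) potentiates,
    post-before-pre depresses; additive, clipped to bounds."""
    p = params or STDPParams()
    dt = np.asarray(delta_t_ms, dtype=float)
    up = p.a_plus * np.exp(-np.abs(dt) / p.tau_plus)
    down = -p.a_minus * np.exp(-np.abs(dt) / p.tau_minus)
    dw = np.where(dt > 0, up, np.where(dt < 0, down, 0.0))
    nxt = np.clip(np.asarray(w, float) + dw, weight_min, weight_max)
    return float(nxt) if nxt.ndim == 0 else nxt


class SynapseState:
    """Scalar NMDAR synapse state for single-synapse protocols and tests.

    Tracks weight, calcium and the EPSP/NMDA/BPAP trace variables with the
    same conventions as the network engine: presynaptic spikes restart the
    traces or, by default, sum across spikes (temporal summation of channel
    opening and depolarization); BPAPs restart on each postsynaptic spike.
    """

    def __init__(self, weight: float,
                 waveform: WaveformParams | None = None,
                 nmda: NMDACurrentParams | None = None,
                 plasticity: PlasticityParams | None = None):
        self.w = float(weight)
        self.ca = 0.0
        self.ca_eff = 0.0  # slow effector pool driving the weight rule
        self.waveform = waveform or WaveformParams()
        self.nmda = nmda or NMDACurrentParams()
        self.plasticity = plasticity or PlasticityParams()
        # trace variables (unit amplitudes; EPSP scaled by epsp_gain*w)
        self.ef = self.es = 0.0   # EPSP fast/slow
        self.nf = self.ns = 0.0   # NMDA open fraction fast/slow
        self.bf = self.bs = 0.0   # BPAP fast/slow (mV)

    def pre_spike(self) -> None:
        wf, nm = self.waveform, self.nmda
        if nm.trace_restart:
            self.ef, self.es = wf.i_f_epsp, wf.i_s_epsp
            self.nf, self.ns = nm.i_f, nm.i_s
        else:
            self.ef += wf.i_f_epsp
            self.es += wf.i_s_epsp
            self.nf += nm.i_f
            self.ns += nm.i_s

    def post_spike(self) -> None:
        wf = self.waveform
        self.bf = wf.i_f_bpap * wf.bpap_max
        self.bs = wf.i_s_bpap * wf.bpap_max

    def local_potential(self) -> float:
        v = self.nmda.v_rest_nmda
        v += self.waveform.epsp_gain * self.w * (self.ef + self.es)
        if self.plasticity.bpap_enabled:
            v += self.bf + self.bs
        return v

    def nmda_flux(self) -> float:
        h = driving_force(self.local_potential(), self.nmda.mg,
                          self.nmda.v_reversal_ca, self.nmda.mg_block_product)
        return self.nmda.gain * (self.nf + self.ns) * h

    def step(self, dt_ms: float, plastic: bool = True) -> None:
        self.ca = calcium_step(self.ca, self.nmda_flux(), dt_ms,
                               self.plasticity.tau_ca, self.nmda.ca_max)
        te = self.plasticity.tau_eff
        if te > 0:
            self.ca_eff += dt_ms * (self.ca - self.ca_eff) / te
        else:
            self.ca_eff = self.ca
        if plastic:
            self.w = weight_update(self.w, self.ca_eff, dt_ms * 1e-3,
                                   self.plasticity)
        wf, nm = self.waveform, self.nmda
        self.ef *= np.exp(-dt_ms / wf.tau_f_epsp)
        self.es *= np.exp(-dt_ms / wf.tau_s_epsp)
        self.nf *= np.exp(-dt_ms / nm.tau_f)
        self.ns *= np.exp(-dt_ms / nm.tau_s)
        self.bf *= np.exp(-dt_ms / wf.tau_f_bpap)
        self.bs *= np.exp(-dt_ms / wf.tau_s_bpap)


# ---------------------------------------------------------------------------
# lookup tables for the compiled network engine
# ---------------------------------------------------------------------------

V_TABLE_MIN, V_TABLE_MAX, V_TABLE_STEP = -150.0, 250.0, 0.05
CA_TABLE_MAX, CA_TABLE_STEP = 6.0, 0.001


def build_h_table(nmda: NMDACurrentParams) -> np.ndarray:
    v = np.arange(V_TABLE_MIN, V_TABLE_MAX + V_TABLE_STEP / 2, V_TABLE_STEP)
    return driving_force(v, nmda.mg, nmda.v_reversal_ca, nmda.mg_block_product)


def build_ca_tables(p: PlasticityParams) -> tuple[np.ndarray, np.ndarray]:
    ca = np.arange(0.0, CA_TABLE_MAX + CA_TABLE_STEP / 2, CA_TABLE_STEP)
    return omega(ca, p), eta(ca, p)
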