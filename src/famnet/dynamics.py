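"""Leaky integrate-and-fire network dynamics.

``Simulation`` owns the mutable state of one network instance (membrane
potentials, synaptic currents, plasticity state) and advances it through
successive ``run`` calls, so an experiment can alternate plasticity-on and
plasticity-off phases on the same network.  ``run_network`` is the
single-shot functional wrapper.

Timestep is fixed at 0.2 ms by default (all model time constants are
>= 1.2 ms).  Membrane integration is exponential Euler, exact for constant
current within a step.  Spike transmission carries a uniform one-step
delay; membrane reset and initial values are drawn uniformly from
[-1, 1] mV out of a dedicated RNG stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from . import _engine
from ._rng import stream_rng, stream_seed
from .construction import InputProjection, Network
from .params import NeuronParams, NMDACurrentParams, PlasticityParams, STDPParams, WaveformParams
from .plasticity import build_ca_tables, build_h_table, CA_TABLE_STEP, V_TABLE_MIN, V_TABLE_STEP

__all__ = ["SpikeRecord", "Simulation", "run_network", "membrane_step", "firing_rate"]

DEFAULT_DT = 2e-4  # s


@dataclass
class SpikeRecord:
    """Spikes of one simulation interval (times in s, relative to interval)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float
    n_neurons: int
    t_start: float = 0.0  # absolute start within the session

    def __post_init__(self) -> None:
        order = np.lexsort((self.neuron_ids, self.times))
        self.neuron_ids = np.asarray(self.neuron_ids)[order]
        self.times = np.asarray(self.times)[order]

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def spike_times(self, neuron: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == neuron])

    def counts(self, window: tuple[float, float] | None = None,
               population: Optional[Sequence[int]] = None) -> np.ndarray:
        """Per-neuron spike counts in ``window`` (defaults to whole record)."""
        t0, t1 = window if window is not None else (0.0, self.duration)
        mask = (self.times >= t0) & (self.times < t1)
        counts = np.bincount(self.neuron_ids[mask], minlength=self.n_neurons)
        if population is not None:
            counts = counts[np.asarray(population)]
        return counts

    def binned_counts(self, bin_width: float,
                      window: tuple[float, float] | None = None) -> np.ndarray:
        """Population spike count per time bin."""
        t0, t1 = window if window is not None else (0.0, self.duration)
        if bin_width > t1 - t0:
            raise ValueError("bin larger than record window")
        edges = np.arange(t0, t1 + bin_width / 2, bin_width)
        hist, _ = np.histogram(self.times, bins=edges)
        return hist

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.neuron_ids, self.times]),
                   fmt=["%d", "%.6f"], header="neuron_id time_s")

    def plot_raster(self, ax=None, **scatter_kwargs):
        """Spike raster (matplotlib); returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scatter_kwargs.setdefault("s", 2)
        scatter_kwargs.setdefault("color", "k")
        ax.scatter(self.times, self.neuron_ids, marker="|", **scatter_kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("neuron")
        ax.set_xlim(0, self.duration)
        return ax


def firing_rate(record: SpikeRecord, window: tuple[float, float] | None = None,
                population: Optional[Sequence[int]] = None) -> float:
    """Mean firing rate (spikes/s) over a population within a window."""
    t0, t1 = window if window is not None else (0.0, record.duration)
    if not t1 > t0:
        raise ValueError("empty window")
    n_pop = record.n_neurons if population is None else len(list(population))
    if n_pop == 0:
        raise ValueError("empty population")
    return float(record.counts((t0, t1), population).sum() / n_pop / (t1 - t0))


def membrane_step(v: float, i_total: float, dt: float,
                  params: NeuronParams | None = None) -> float:
    """Exponential-Euler membrane update toward V_inf = V_rest + R*I."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or NeuronParams()
    v_inf = p.v_resting + p.r_m * i_total
    return v_inf + (v - v_inf) * math.exp(-dt / p.tau_m)


def _csr(group: np.ndarray, n_groups: int, n_items: int):
    order = np.argsort(group, kind="stable")
    indptr = np.zeros(n_groups + 1, dtype=np.int64)
    np.add.at(indptr, group + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, order.astype(np.int64)


class Simulation:
    """Stateful simulator for one network + input projection.

    ``recurrent_efficacy`` scales spike transmission (not plasticity state)
    at recurrent synapses.  It stands in for the steady-state effect of
    short-term synaptic depression in cortical microcircuits, which is not
    modeled dynamically here; without it a reservoir of near-threshold
    neurons with static synapses ignites network-wide avalanches for any
    input and loses stimulus specificity.  The default (0.35) lies in the
    range of steady-state depressing-synapse efficacies at the firing
    rates these reservoirs visit (roughly 1-20 Hz).  Input synapses are
    delivered at full weight.
    """

    def __init__(self, network: Network,
                 input_projection: Optional[InputProjection] = None,
                 neuron: Optional[NeuronParams] = None,
                 waveform: Optional[WaveformParams] = None,
                 nmda: Optional[NMDACurrentParams] = None,
                 plasticity: Optional[PlasticityParams] = None,
                 stdp: Optional[STDPParams] = None,
                 plasticity_model: str = "nmdar",
                 dt: float = DEFAULT_DT,
                 recurrent_efficacy: float = 0.35,
                 clip_initial_weights: bool = True,
                 seed: int = 0):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.network = network
        self.input_projection = input_projection or network.input_projection
        self.neuron = neuron or NeuronParams()
        self.waveform = waveform or WaveformParams()
        self.nmda = nmda or NMDACurrentParams()
        self.plasticity = plasticity or PlasticityParams()
        self.stdp = stdp or STDPParams()
        if plasticity_model not in ("nmdar", "stdp"):
            raise ValueError("plasticity_model must be 'nmdar' or 'stdp'")
        self.plasticity_model = plasticity_model
        self.dt = float(dt)
        if not 0.0 < recurrent_efficacy <= 1.0:
            raise ValueError("recurrent_efficacy must be in (0, 1]")
        self.recurrent_efficacy = float(recurrent_efficacy)
        self.seed = int(seed)
        self._run_counter = 0
        self.t = 0.0  # absolute session time (s)

        n = network.n_neurons
        rng = stream_rng(seed, "dynamics/init")
        lo, hi = self.neuron.v_reset_range
        self.v = rng.uniform(lo, hi, size=n)
        self.refrac_left = np.zeros(n, dtype=np.int64)
        refrac = np.where(network.is_excitatory,
                          self.neuron.refractory_e, self.neuron.refractory_i)
        self.refrac_steps = np.maximum(1, np.round(refrac / dt)).astype(np.int64)
        self.disabled = np.zeros(n, dtype=np.int64)
        self.psc = np.zeros(n)
        self.epsp_f = np.zeros(n)
        self.epsp_s = np.zeros(n)
        self.nmda_f = np.zeros(n)
        self.nmda_s = np.zeros(n)
        self.bpap_f = np.zeros(n)
        self.bpap_s = np.zeros(n)
        self.last_pre_ms = np.full(n, -1e12)
        self.last_post_ms = np.full(n, -1e12)
        self._pending = np.empty(0, dtype=np.int64)

        self.syn_pre = network.pre.astype(np.int64)
        self.syn_post = network.post.astype(np.int64)
        self.syn_w = network.weight.astype(np.float64).copy()
        self.syn_plastic = network.is_plastic.copy()
        # NMDAR synapses live inside the plasticity bounds from the start;
        # boundary-removal experiments (bursting regimes) disable the clip
        if clip_initial_weights:
            pl_ = self.plasticity
            np.clip(self.syn_w, pl_.weight_min, pl_.weight_max,
                    out=self.syn_w, where=self.syn_plastic)
        self.syn_ca = np.zeros(network.n_synapses)
        self.syn_ca_eff = np.zeros(network.n_synapses)
        self.out_indptr, self.out_syn = _csr(self.syn_pre, n, network.n_synapses)
        self.in_indptr, self.in_syn = _csr(self.syn_post, n, network.n_synapses)

        proj = self.input_projection
        if proj is not None and len(proj):
            self.inp_indptr, order = _csr(proj.channel, proj.n_channels, len(proj))
            self.inp_post = proj.post[order].astype(np.int64)
            self.inp_w = proj.weight[order].astype(np.float64)
            self.n_channels = proj.n_channels
        else:
            self.inp_indptr = np.zeros(1, dtype=np.int64)
            self.inp_post = np.empty(0, dtype=np.int64)
            self.inp_w = np.empty(0)
            self.n_channels = 0

        self._h_table = build_h_table(self.nmda)
        self._omega_table, self._eta_table = build_ca_tables(self.plasticity)

    # -- state access -----------------------------------------------------
    @property
    def weights(self) -> np.ndarray:
        """Current synaptic weights (copy)."""
        return self.syn_w.copy()

    @property
    def calcium(self) -> np.ndarray:
        return self.syn_ca.copy()

    def set_weights(self, w: np.ndarray) -> None:
        if len(w) != len(self.syn_w):
            raise ValueError("weight vector length mismatch")
        self.syn_w[:] = w

    def reset_dynamics(self) -> None:
        """Reset membrane potentials, currents, traces and the kernel seed
        sequence to their initial values, leaving weights untouched.

        Probe phases call this so that baseline and test responses are
        compared from an identical network state: with unchanged weights
        and stimuli the resulting spike records are bitwise identical.
        """
        rng = stream_rng(self.seed, "dynamics/init")
        lo, hi = self.neuron.v_reset_range
        self.v[:] = rng.uniform(lo, hi, size=len(self.v))
        self.refrac_left[:] = 0
        for arr in (self.psc, self.epsp_f, self.epsp_s, self.nmda_f,
                    self.nmda_s, self.bpap_f, self.bpap_s, self.syn_ca,
                    self.syn_ca_eff):
            arr[:] = 0.0
        self.last_pre_ms[:] = -1e12
        self.last_post_ms[:] = -1e12
        self._pending = np.empty(0, dtype=np.int64)
        self._run_counter = 0
        self.t = 0.0

    def disable_spiking(self, neurons: Iterable[int]) -> None:
        """Prevent the given neurons from firing (membrane still integrates)."""
        self.disabled[np.asarray(list(neurons), dtype=np.int64)] = 1

    # -- running ----------------------------------------------------------
    def run(self, duration: float,
            input_spikes: Optional[Dict[int, np.ndarray]] = None,
            stimulus=None,
            plasticity_on: bool = False,
            forced_spikes: Optional[Dict[int, np.ndarray]] = None,
            record_v: Optional[Sequence[int]] = None,
            record_synapses: Optional[Sequence[int]] = None,
            trace_every: int = 5) -> SpikeRecord:
        """Advance the simulation by ``duration`` seconds.

        ``input_spikes`` maps input channel -> spike times (s, relative to
        this run); ``stimulus`` (a ``Stimulus``) is the usual way to supply
        them.  ``forced_spikes`` maps reservoir neuron -> spike times,
        forcing spikes regardless of threshold (driver electrodes).
        Returns the spikes of this interval; optional voltage/synapse
        traces are attached as ``record.v_traces`` / ``record.ca_traces`` /
        ``record.w_traces`` (sampled every ``trace_every`` steps).
        """
        if duration <= 0:
            raise ValueError("duration must be positive")
        n_steps = int(round(duration / self.dt))
        if stimulus is not None:
            if input_spikes is not None:
                raise ValueError("pass either stimulus or input_spikes")
            if stimulus.n_channels != self.n_channels:
                raise ValueError(
                    f"stimulus has {stimulus.n_channels} channels, input layer "
                    f"expects {self.n_channels}")
            input_spikes = stimulus.as_dict()

        inp_step, inp_chan = self._event_arrays(input_spikes, n_steps,
                                                self.n_channels, "channel")
        f_step, f_neuron = self._event_arrays(forced_spikes, n_steps,
                                              self.network.n_neurons, "neuron")

        mode = _engine.MODE_OFF
        if plasticity_on:
            mode = (_engine.MODE_NMDAR if self.plasticity_model == "nmdar"
                    else _engine.MODE_STDP)

        trace_syn = np.asarray(record_synapses if record_synapses is not None else [],
                               dtype=np.int64)
        trace_neu = np.asarray(record_v if record_v is not None else [],
                               dtype=np.int64)
        do_trace = len(trace_syn) or len(trace_neu)
        t_every = trace_every if do_trace else 0
        rows = (n_steps + t_every - 1) // t_every if t_every else 0
        trace_ca = np.zeros((rows, len(trace_syn)))
        trace_w = np.zeros((rows, len(trace_syn)))
        trace_v = np.zeros((rows, len(trace_neu)))

        p, wf, nm, pl = self.neuron, self.waveform, self.nmda, self.plasticity
        dt = self.dt
        dt_ms = dt * 1e3
        dec = lambda tau_ms: math.exp(-dt_ms / tau_ms)
        kernel_seed = stream_seed(self.seed, "dynamics/run", self._run_counter)
        self._run_counter += 1

        cap = max(100_000, int(self.network.n_neurons * duration * 250))
        while True:
            rec_n = np.empty(cap, dtype=np.int64)
            rec_t = np.empty(cap, dtype=np.float64)
            state = (self.v.copy(), self.refrac_left.copy(), self.syn_w.copy(),
                     (self.syn_ca.copy(), self.syn_ca_eff.copy()),
                     self.psc.copy(), self.epsp_f.copy(),
                     self.epsp_s.copy(), self.nmda_f.copy(), self.nmda_s.copy(),
                     self.bpap_f.copy(), self.bpap_s.copy(),
                     self.last_pre_ms.copy(), self.last_post_ms.copy(),
                     self._pending.copy())
            n_rec, overflow, resid = _engine.run_kernel(
                n_steps, dt, kernel_seed,
                self.v, self.refrac_left, self.refrac_steps, self.disabled,
                self.psc, self.epsp_f, self.epsp_s, self.nmda_f, self.nmda_s,
                self.bpap_f, self.bpap_s,
                math.exp(-dt / p.tau_m), p.v_resting, p.r_m, p.i_inject,
                p.noise_amplitude, p.v_thresh,
                p.v_reset_range[0], p.v_reset_range[1],
                math.exp(-dt / p.tau_psc),
                dec(wf.tau_f_epsp), dec(wf.tau_s_epsp),
                dec(nm.tau_f), dec(nm.tau_s),
                dec(wf.tau_f_bpap), dec(wf.tau_s_bpap),
                wf.i_f_epsp, wf.i_s_epsp, nm.i_f, nm.i_s,
                wf.i_f_bpap * wf.bpap_max, wf.i_s_bpap * wf.bpap_max,
                self.recurrent_efficacy,
                self.syn_pre, self.syn_post, self.syn_w, self.syn_plastic,
                self.syn_ca, self.syn_ca_eff, self.out_indptr, self.out_syn,
                self.in_indptr, self.in_syn,
                self.inp_indptr, self.inp_post, self.inp_w,
                inp_step, inp_chan, f_step, f_neuron, self._pending,
                mode, 1 if nm.trace_restart else 0,
                wf.epsp_gain, nm.v_rest_nmda, nm.gain, dt_ms, pl.tau_ca,
                nm.ca_max, pl.tau_eff,
                self._h_table, V_TABLE_MIN, V_TABLE_STEP,
                self._omega_table, self._eta_table, CA_TABLE_STEP,
                pl.omega_to_weight_scale, pl.weight_min, pl.weight_max,
                1 if pl.bpap_enabled else 0,
                self.stdp.a_plus, self.stdp.a_minus,
                self.stdp.tau_plus, self.stdp.tau_minus,
                self.last_pre_ms, self.last_post_ms,
                rec_n, rec_t, round(self.t / dt),
                trace_syn, t_every, trace_ca, trace_w, trace_neu, trace_v,
            )
            if not overflow:
                self._pending = resid
                break
            # roll back and retry with a larger spike buffer
            (self.v[:], self.refrac_left[:], self.syn_w[:],
             (self.syn_ca[:], self.syn_ca_eff[:]),
             self.psc[:], self.epsp_f[:], self.epsp_s[:], self.nmda_f[:],
             self.nmda_s[:], self.bpap_f[:], self.bpap_s[:],
             self.last_pre_ms[:], self.last_post_ms[:]) = state[:13]
            self._pending = state[13]
            cap *= 4

        if not plasticity_on and self.plasticity_model == "nmdar":
            # calcium decays analytically while the plasticity loop is gated off
            self.syn_ca *= math.exp(-duration * 1e3 / pl.tau_ca)
            if pl.tau_eff > 0:
                self.syn_ca_eff *= math.exp(-duration * 1e3 / pl.tau_eff)

        if np.any(~np.isfinite(self.v)):
            raise FloatingPointError("membrane potential diverged (NaN/Inf)")

        record = SpikeRecord(rec_n[:n_rec].copy(), rec_t[:n_rec].copy(),
                             duration=n_steps * dt, dt=dt,
                             n_neurons=self.network.n_neurons,
                             t_start=self.t)
        if do_trace:
            record.trace_dt = dt * t_every
            record.ca_traces = trace_ca
            record.w_traces = trace_w
            record.v_traces = trace_v
        self.t += n_steps * dt
        return record

    def _event_arrays(self, events, n_steps, n_max, what):
        if not events:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy()
        steps, ids = [], []
        for key, times in events.items():
            if not 0 <= key < n_max:
                raise ValueError(f"{what} index {key} out of range")
            t = np.asarray(times, dtype=float)
            s = np.round(t / self.dt).astype(np.int64)
            s = s[(s >= 0) & (s < n_steps)]
            steps.append(s)
            ids.append(np.full(len(s), key, dtype=np.int64))
        steps = np.concatenate(steps)
        ids = np.concatenate(ids)
        order = np.argsort(steps, kind="stable")
        return steps[order], ids[order]


def run_network(network: Network, stimulus=None, duration: float = 1.0,
                plasticity_on: bool = False, noise_amplitude: float = 0.0,
                seed: int = 0, **kwargs) -> SpikeRecord:
    """Build a fresh ``Simulation`` and run it once (convenience wrapper)."""
    neuron = kwargs.pop("neuron", None) or NeuronParams(noise_amplitude=noise_amplitude)
    sim = Simulation(network, neuron=neuron, seed=seed, **{
        k: v for k, v in kwargs.items()
        if k in ("input_projection", "waveform", "nmda", "plasticity", "stdp",
                 "plasticity_model", "dt")})
    run_kwargs = {k: v for k, v in kwargs.items()
                  if k in ("forced_spikes", "record_v", "record_synapses",
                           "trace_every", "input_spikes")}
    return sim.run(duration, stimulus=stimulus, plasticity_on=plasticity_on,
                   **run_kwargs)
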