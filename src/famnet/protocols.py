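"""Experiment protocols: single-synapse validation, familiarity learning,
capacity and robustness sweeps.

All protocols follow the three-phase design of the recognition
experiments: baseline recording with plasticity disabled, a learning phase
with plasticity enabled on a subset of stimuli, and a testing phase with
plasticity disabled again.  Baseline and testing reuse identical
per-stimulus spike trains (fixed encoding seeds) so that any
baseline-to-test response difference isolates the synaptic weight changes;
learning-phase presentations are re-encoded with fresh seeds (trial-to-
trial variability of real spike trains).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from ._rng import stream_rng, stream_seed
from .construction import Network, build_input_projection, build_network  # noqa: F401
from .dynamics import Simulation, SpikeRecord, firing_rate
from .params import (NetworkConfig, NeuronParams, NMDACurrentParams,
                     PlasticityParams, STDPParams, WaveformParams)
from .stimulus import (ImagePattern, Stimulus, encode_image,
                       generate_synthetic_faces, normalize_image_set)

__all__ = [
    "ExperimentSchedule",
    "ExperimentResult",
    "single_synapse_simulation",
    "run_tetanus_protocol",
    "run_pairing_protocol",
    "measure_calcium_response",
    "run_familiarity_experiment",
    "accuracy_topk",
    "robustness_sweep",
    "TABLE_CALCIUM",
]

#: Published single-synapse peak calcium table (uM): weight -> condition -> Ca.
#: Frequency conditions are Hz (int), pairing conditions are ("dt", ms).
TABLE_CALCIUM = {
    1e-8: {1: 0.11, 10: 0.14, 20: 0.22, 50: 0.60, 100: 1.0,
           ("dt", -15): 0.12, ("dt", -5): 0.16, ("dt", 5): 0.69, ("dt", 15): 0.40},
    3e-8: {1: 0.15, 10: 0.19, 20: 0.30, 50: 0.85, 100: 1.0,
           ("dt", -15): 0.17, ("dt", -5): 0.21, ("dt", 5): 0.78, ("dt", 15): 0.46},
    6e-8: {1: 0.27, 10: 0.32, 20: 0.52, 50: 0.90, 100: 1.0,
           ("dt", -15): 0.29, ("dt", -5): 0.33, ("dt", 5): 0.93, ("dt", 15): 0.61},
}


# ---------------------------------------------------------------------------
# single-synapse protocols
# ---------------------------------------------------------------------------

def single_synapse_simulation(weight: float, seed: int = 0,
                              disable_post: bool = True,
                              **params) -> Simulation:
    """A two-neuron circuit joined by one NMDAR synapse.

    The presynaptic neuron is driven only by forced spikes; the
    postsynaptic neuron is prevented from firing naturally when
    ``disable_post`` (current-clamped, as in the tetanus experiment) but
    still integrates EPSPs.
    """
    net = Network(positions=np.array([[0, 0, 0], [1, 0, 0]]),
                  is_excitatory=np.array([True, True]),
                  pre=np.array([0]), post=np.array([1]),
                  weight=np.array([float(weight)]))
    sim = Simulation(net, None, seed=seed, **params)
    sim.disable_spiking([0])
    if disable_post:
        sim.disable_spiking([1])
    return sim


def _measure_epsp_amplitudes(rec, probe_times, dt, window_ms=40.0):
    """Peak postsynaptic depolarization after each probe spike."""
    v = rec.v_traces[:, 0]
    tdt = rec.trace_dt
    amps = []
    for t in probe_times:
        i0 = int(t / tdt) + 1
        i1 = min(len(v), i0 + int(window_ms * 1e-3 / tdt))
        if i1 <= i0:
            continue
        base = v[i0 - 1]
        amps.append(float(v[i0:i1].max() - base))
    return np.asarray(amps)


def run_tetanus_protocol(freq: float, tetanus_duration: float = 2.0,
                         probe_rate: float = 0.2, initial_weight: float = 3e-8,
                         baseline_probes: int = 4, post_probes: int = 6,
                         seed: int = 0, **params) -> dict:
    """Frequency LTP/LTD induction at a single synapse.

    Probe presynaptic spikes at ``probe_rate`` measure the EPSP amplitude
    before and after a ``freq``-Hz tetanus of ``tetanus_duration`` seconds;
    the postsynaptic neuron never fires.  Returns probe times, EPSP
    amplitudes, the weight trace, and the after/before amplitude ratio.
    """
    sim = single_synapse_simulation(initial_weight, seed=seed, **params)
    probe_gap = 1.0 / probe_rate
    t = 1.0
    pre_times, probes = [], []
    for _ in range(baseline_probes):
        pre_times.append(t); probes.append(t); t += probe_gap
    tet_start = t
    pre_times.extend(np.arange(t, t + tetanus_duration, 1.0 / freq))
    t += tetanus_duration + probe_gap
    for _ in range(post_probes):
        pre_times.append(t); probes.append(t); t += probe_gap
    duration = t + 1.0
    rec = sim.run(duration, forced_spikes={0: np.asarray(pre_times)},
                  plasticity_on=True, record_v=[1], record_synapses=[0],
                  trace_every=1)
    amps = _measure_epsp_amplitudes(rec, probes, sim.dt)
    n_base = baseline_probes
    ratio = float(amps[n_base:].mean() / amps[:n_base].mean())
    return {"probe_times": np.asarray(probes), "epsp_amplitudes": amps,
            "ratio": ratio, "tetanus_start": tet_start,
            "w_trace": rec.w_traces[:, 0], "ca_trace": rec.ca_traces[:, 0],
            "final_weight": float(sim.weights[0]),
            "initial_weight": initial_weight}


def run_pairing_protocol(delta_t: float, n_pairings: int = 15,
                         pairing_rate: float = 20.0, probe_rate: float = 0.125,
                         initial_weight: float = 3e-8,
                         baseline_probes: int = 3, post_probes: int = 4,
                         seed: int = 0, **params) -> dict:
    """Spike-timing pairing at a single synapse (dual patch-clamp analog).

    ``delta_t`` (ms) is t_post - t_pre; positive pairs potentiate, negative
    depress.  Both neurons are driven (forced spikes); probes at
    ``probe_rate`` on the presynaptic side measure EPSP amplitude.
    """
    sim = single_synapse_simulation(initial_weight, seed=seed, **params)
    probe_gap = 1.0 / probe_rate
    t = 1.0
    pre_times, post_times, probes = [], [], []
    for _ in range(baseline_probes):
        pre_times.append(t); probes.append(t); t += probe_gap
    pair_start = t
    for _ in range(int(n_pairings)):
        pre = t + max(0.0, -delta_t * 1e-3)
        post = t + max(0.0, delta_t * 1e-3)
        pre_times.append(pre); post_times.append(post)
        t += 1.0 / pairing_rate
    t += probe_gap
    for _ in range(post_probes):
        pre_times.append(t); probes.append(t); t += probe_gap
    duration = t + 1.0
    rec = sim.run(duration, forced_spikes={0: np.asarray(pre_times),
                                           1: np.asarray(post_times)},
                  plasticity_on=True, record_v=[1], record_synapses=[0],
                  trace_every=1)
    amps = _measure_epsp_amplitudes(rec, probes, sim.dt)
    base = amps[:baseline_probes].mean() if baseline_probes else 1.0
    ratio = float(amps[baseline_probes:].mean() / base) if len(amps) > baseline_probes else 1.0
    return {"probe_times": np.asarray(probes), "epsp_amplitudes": amps,
            "ratio": ratio, "pairing_start": pair_start,
            "w_trace": rec.w_traces[:, 0], "ca_trace": rec.ca_traces[:, 0],
            "final_weight": float(sim.weights[0]),
            "initial_weight": initial_weight}


def measure_calcium_response(initial_weight: float, mode: str, value: float,
                             readout_saturation: float = 1.0,
                             seed: int = 0, **params) -> float:
    """Peak synaptic calcium (uM) per the published readout convention.

    ``mode='frequency'``: sustained regular presynaptic train at ``value``
    Hz, postsynaptic spiking disabled; readout is the steady-state peak
    over the final second.  ``mode='pairing'``: pre-post pairs at 1 Hz with
    interval ``value`` ms; readout is the maximum over a late pairing
    cycle.  Weights are held fixed during the measurement.  Readouts at or
    above ``readout_saturation`` report the saturation value (pass None
    for the raw peak).
    """
    pl = params.pop("plasticity", None) or PlasticityParams()
    frozen = PlasticityParams(**{**_params_dict(pl), "eta_max": 0.0})
    sim = single_synapse_simulation(initial_weight, seed=seed,
                                    plasticity=frozen, **params)
    if mode == "frequency":
        T = 3.0
        times = np.arange(0.2, T, 1.0 / value)
        rec = sim.run(T + 0.2, forced_spikes={0: times}, plasticity_on=True,
                      record_synapses=[0], trace_every=1)
        ca = rec.ca_traces[:, 0]
        peak = float(ca[int((T - 0.8) / sim.dt):].max())
    elif mode == "pairing":
        n_pair = 4
        pre = np.arange(0.05, n_pair * 1.0, 1.0) + max(0.0, -value * 1e-3)
        post = pre + value * 1e-3
        rec = sim.run(n_pair + 0.3, forced_spikes={0: pre, 1: post},
                      plasticity_on=True, record_synapses=[0], trace_every=1)
        ca = rec.ca_traces[:, 0]
        peak = float(ca[int((n_pair - 1.0) / sim.dt):].max())
    else:
        raise ValueError("mode must be 'frequency' or 'pairing'")
    if readout_saturation is not None and peak >= readout_saturation:
        return float(readout_saturation)
    return peak


def _params_dict(p) -> dict:
    from dataclasses import asdict
    d = asdict(p)
    return d


# ---------------------------------------------------------------------------
# familiarity experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentSchedule:
    """Timing and gating of the three experiment phases."""

    exposure: float = 15.0            # seconds of learning per image
    presentation: str = "sequential"  # 'sequential' blocks or 'looping'
    active: float = 0.5
    silence: float = 0.5
    stimulus_seed: int = 101          # base seed for fixed probe encodings
    learn_seed: int = 202             # base seed for fresh learning encodings

    def __post_init__(self) -> None:
        if self.presentation not in ("sequential", "looping"):
            raise ValueError("presentation must be 'sequential' or 'looping'")
        if self.exposure < 0:
            raise ValueError("exposure must be >= 0")


@dataclass
class ExperimentResult:
    baseline: np.ndarray         # per-stimulus baseline response (spikes/s)
    test: np.ndarray             # per-stimulus test response
    ranks: np.ndarray            # rank of each stimulus by test response (1 = top)
    baseline_ranks: np.ndarray
    learn_ids: List[int]
    weights_before: np.ndarray
    weights_after: np.ndarray
    weights_after_test: np.ndarray
    baseline_records: list = field(default_factory=list)
    test_records: list = field(default_factory=list)

    @property
    def familiar_ranks(self) -> np.ndarray:
        return self.ranks[self.learn_ids]

    @property
    def accuracy_top1(self) -> float:
        return accuracy_topk(self.familiar_ranks, 1)


def _ranks(responses: np.ndarray) -> np.ndarray:
    """Rank by response descending; ties broken by stimulus index."""
    order = np.lexsort((np.arange(len(responses)), -responses))
    ranks = np.empty(len(responses), dtype=np.int64)
    ranks[order] = np.arange(1, len(responses) + 1)
    return ranks


def _probe_phase(sim: Simulation, stimuli: Sequence[Stimulus],
                 keep_records: bool = False):
    """Present each stimulus once with plasticity off; response = firing
    rate over the active window.

    The dynamic state (not the weights) is reset to the seeded initial
    condition and settled for 0.2 s before every probe, so probes are
    order-independent and phases before and after learning differ only
    through the weights.
    """
    responses = np.empty(len(stimuli))
    records = []
    for i, st in enumerate(stimuli):
        sim.reset_dynamics()
        sim.run(0.2)  # charge membranes to the steady background level
        rec = sim.run(st.duration, stimulus=st, plasticity_on=False)
        responses[i] = firing_rate(rec, (0.0, st.active))
        if keep_records:
            records.append(rec)
    return responses, records


def run_familiarity_experiment(sim: Simulation,
                               patterns: Sequence[ImagePattern],
                               learn_ids: Sequence[int],
                               schedule: Optional[ExperimentSchedule] = None,
                               keep_records: bool = False) -> ExperimentResult:
    """Baseline -> learning -> testing on one network.

    ``patterns`` should already be baseline-normalized.  During learning
    the images in ``learn_ids`` are presented repeatedly (fresh Poisson
    encodings each presentation) with plasticity enabled, either as
    sequential blocks per image or looping over the set.  Baseline and
    test phases use identical fixed-seed encodings with plasticity off.
    """
    sch = schedule or ExperimentSchedule()
    learn_ids = list(learn_ids)
    if any(i < 0 or i >= len(patterns) for i in learn_ids):
        raise ValueError("learn_ids must index into patterns")

    probe_stimuli = [encode_image(p, active=sch.active, silence=sch.silence,
                                  seed=stream_seed(sch.stimulus_seed, "probe", i))
                     for i, p in enumerate(patterns)]

    baseline, base_records = _probe_phase(sim, probe_stimuli, keep_records)
    w_before = sim.weights

    reps = int(round(sch.exposure / (sch.active + sch.silence)))
    order: List[int] = []
    if sch.presentation == "sequential":
        for i in learn_ids:
            order.extend([i] * reps)
    else:
        for r in range(reps):
            order.extend(learn_ids)
    for k, i in enumerate(order):
        st = encode_image(patterns[i], active=sch.active, silence=sch.silence,
                          seed=stream_seed(sch.learn_seed, "learn", k))
        sim.run(st.duration, stimulus=st, plasticity_on=True)
    w_after = sim.weights

    test, test_records = _probe_phase(sim, probe_stimuli, keep_records)
    w_after_test = sim.weights

    return ExperimentResult(
        baseline=baseline, test=test, ranks=_ranks(test),
        baseline_ranks=_ranks(baseline), learn_ids=learn_ids,
        weights_before=w_before, weights_after=w_after,
        weights_after_test=w_after_test,
        baseline_records=base_records, test_records=test_records)


def accuracy_topk(familiar_ranks, k: int) -> float:
    """Fraction of familiar stimuli ranking in the top k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranks = np.asarray(familiar_ranks)
    return float((ranks <= k).sum() / len(ranks))


def run_single_image_recognition(dims=(10, 10, 5), n_images: int = 12,
                                 learn_id: int = 0, exposure: float = 15.0,
                                 network_seed: int = 0, seed: int = 77,
                                 lambda_: float = 2.0, wscale: float = 0.5,
                                 sh_w: float = 0.25,
                                 noise_amplitude: float = 0.0,
                                 recurrent_efficacy: float = 0.35,
                                 plasticity: Optional[PlasticityParams] = None,
                                 normalize_iters: int = 6,
                                 keep_records: bool = False,
                                 **sim_kwargs) -> ExperimentResult:
    """End-to-end single-image recognition trial on synthetic images.

    Builds a reservoir, generates and baseline-normalizes a synthetic image
    set (three classes), learns one image for ``exposure`` seconds and
    tests all images.  This is the workhorse behind the recognition
    experiments and sweeps.
    """
    from .params import NeuronParams

    cfg = NetworkConfig(dims=dims, lambda_=lambda_, wscale=wscale, sh_w=sh_w,
                        seed=network_seed)
    net = build_network(cfg)
    proj = build_input_projection(net, dims[:2])
    imgs = generate_synthetic_faces(3, max(1, n_images // 3), size=dims[:2],
                                    seed=50 + network_seed)[:n_images]
    neuron = NeuronParams(noise_amplitude=noise_amplitude)
    sim_common = dict(neuron=neuron, plasticity=plasticity,
                      recurrent_efficacy=recurrent_efficacy, **sim_kwargs)

    def probe(ims):
        psim = Simulation(net, proj, seed=seed, **sim_common)
        stims = [encode_image(im, seed=stream_seed(901, "probe", i))
                 for i, im in enumerate(ims)]
        resp, _ = _probe_phase(psim, stims)
        return resp

    imgs, _ = normalize_image_set(imgs, probe, tolerance=0.05,
                                  max_iters=normalize_iters)
    sim = Simulation(net, proj, seed=seed + network_seed, **sim_common)
    return run_familiarity_experiment(
        sim, imgs, [learn_id], ExperimentSchedule(exposure=exposure),
        keep_records=keep_records)


def permute_plastic_weights(sim: Simulation, seed: int = 0) -> None:
    """Randomly permute the initial weights among the plastic synapses.

    Control for the role of pre-imposed circuitry: the weight distribution
    is preserved while the mapping of weights onto connections is
    destroyed.
    """
    rng = stream_rng(seed, "analysis/permute")
    idx = np.flatnonzero(sim.syn_plastic)
    sim.syn_w[idx] = sim.syn_w[idx[rng.permutation(len(idx))]]


def run_baseline_rank_experiment(n_images: int = 30, dims=(10, 10, 5),
                                 n_networks: int = 4,
                                 n_designations: int = 15,
                                 seed: int = 0, bin_width: float = 0.01,
                                 normalize_iters: int = 6) -> dict:
    """Chance-level structure of pre-learning responses.

    For each of ``n_networks`` reservoirs, ``n_images`` synthetic images
    are baseline-normalized and probed once (plasticity off).  For
    ``n_designations`` randomly designated to-be-learned images per
    network, the experiment records (a) the baseline rank of the
    designated image (uniform over ranks by exchangeability; mean
    (n+1)/2) and (b) the fraction of 10-ms time bins in which the
    designated stimulus evokes the strictly largest population count
    (chance 1/n).
    """
    from .params import NeuronParams

    rng = stream_rng(seed, "analysis/designation")
    ranks, bin_fractions = [], []
    for k in range(n_networks):
        cfg = NetworkConfig(dims=dims, lambda_=2.0, wscale=0.5, sh_w=0.25,
                            seed=stream_seed(seed, "baseline/net", k))
        net = build_network(cfg)
        proj = build_input_projection(net, dims[:2])
        imgs = generate_synthetic_faces(3, max(1, n_images // 3), size=dims[:2],
                                        seed=stream_seed(seed, "baseline/img", k)
                                        )[:n_images]

        def probe(ims, keep=False):
            sim = Simulation(net, proj, seed=stream_seed(seed, "baseline/sim", k))
            stims = [encode_image(im, seed=stream_seed(901, "probe", i))
                     for i, im in enumerate(ims)]
            return _probe_phase(sim, stims, keep_records=keep)

        imgs, _ = normalize_image_set(imgs, lambda ims: probe(ims)[0],
                                      tolerance=0.05, max_iters=normalize_iters)
        responses, records = probe(imgs, keep=True)
        rank_perm = _ranks(responses)
        chosen = rng.choice(n_images, size=min(n_designations, n_images),
                            replace=False)
        ranks.extend(rank_perm[chosen].tolist())

        binned = np.vstack([r.binned_counts(bin_width, (0.0, 0.5))
                            for r in records])  # (n_images, n_bins)
        top = binned.max(axis=0)
        unique = (binned == top).sum(axis=0) == 1
        if unique.any():
            winner = binned.argmax(axis=0)[unique]
            for c in chosen:
                bin_fractions.append(float(np.mean(winner == c)))
    ranks = np.asarray(ranks, dtype=float)
    return {"ranks": ranks, "mean_rank": float(ranks.mean()),
            "expected_rank": (n_images + 1) / 2.0,
            "bin_max_fraction": float(np.mean(bin_fractions)),
            "expected_bin_fraction": 1.0 / n_images}


# ---------------------------------------------------------------------------
# robustness sweeps
# ---------------------------------------------------------------------------

def _bursting_indicator(record: SpikeRecord, active: float, duration: float,
                        bin_width: float = 0.01, frac: float = 0.1) -> bool:
    """Population-synchronous spiking during the silent interval."""
    if duration <= active:
        return False
    hist = record.binned_counts(bin_width, (active, duration))
    return bool((hist >= frac * record.n_neurons).any())


def robustness_sweep(parameter: str, values: Sequence[float],
                     base_protocol: Callable[..., dict],
                     **kwargs) -> List[dict]:
    """Re-run a familiarity protocol while sweeping one robustness knob.

    ``parameter`` is one of ``noise_amplitude`` (nA of background current
    noise), ``wscale_mult`` or ``lambda_mult`` (multipliers on the
    construction parameters).  ``base_protocol(noise_amplitude=...,
    wscale_mult=..., lambda_mult=...) -> dict`` runs one experiment and
    returns at least ``result`` (an ExperimentResult) and ``records`` (test
    records for the bursting indicator).  Returns one summary per value.
    """
    if parameter not in ("noise_amplitude", "wscale_mult", "lambda_mult"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    if len(values) == 0:
        raise ValueError("empty value list")
    out = []
    for v in values:
        res = base_protocol(**{parameter: v}, **kwargs)
        result: ExperimentResult = res["result"]
        bursting = False
        for rec in res.get("records", []):
            if _bursting_indicator(rec, res.get("active", 0.5), rec.duration):
                bursting = True
                break
        out.append({"value": v, "result": result,
                    "familiar_ranks": result.familiar_ranks,
                    "accuracy_top1": result.accuracy_top1,
                    "bursting": bursting})
    return out
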