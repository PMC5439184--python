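"""Parameter containers with validation.

Defaults reproduce the published operating point of the model: a leaky
integrate-and-fire reservoir (30 ms membrane time constant, 13.5 nA
background current, 15 mV threshold) whose excitatory recurrent synapses
carry an NMDAR calcium module implementing the calcium control hypothesis
(depression for intermediate synaptic [Ca2+], potentiation above a higher
threshold).  Constants that the reference model leaves free (NMDA conductance
scale, EPSP millivolts per unit weight, BPAP amplitude, the calcium
dependence of the learning rate) carry the values frozen by the
calibration script in ``scripts/calibrate_synapse.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Tuple

import math

__all__ = [
    "NeuronParams",
    "WaveformParams",
    "NMDACurrentParams",
    "PlasticityParams",
    "STDPParams",
    "NetworkConfig",
    "BASE_C",
    "BASE_W",
]

#: Base connection probabilities by (pre, post) type, first letter = presynaptic.
BASE_C = {"EE": 0.3, "EI": 0.2, "IE": 0.4, "II": 0.1}

#: Base mean weights (CSIM weight units, i.e. amperes of PSC jump) by type.
BASE_W = {"EE": 3e-8, "EI": 6e-8, "IE": -1.9e-8, "II": -1.9e-8}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron constants.

    Units: time constants in seconds, voltages in mV, currents in nA,
    resistance in MOhm (so ``r_m * i`` is directly in mV).
    """

    tau_m: float = 30e-3
    v_resting: float = 0.0
    r_m: float = 1.0
    i_inject: float = 13.5
    v_thresh: float = 15.0
    v_reset_range: Tuple[float, float] = (-1.0, 1.0)
    refractory_e: float = 3e-3
    refractory_i: float = 2e-3
    tau_psc: float = 3e-3  # single-exponential postsynaptic current decay
    noise_amplitude: float = 0.0  # nA, std of per-step Gaussian current

    def __post_init__(self) -> None:
        _require(self.tau_m > 0, "tau_m must be positive")
        _require(self.tau_psc > 0, "tau_psc must be positive")
        _require(self.refractory_e > 0 and self.refractory_i > 0,
                 "refractory periods must be positive")
        _require(self.v_thresh > self.v_resting,
                 "v_thresh must exceed v_resting")
        _require(self.noise_amplitude >= 0, "noise_amplitude must be >= 0")


@dataclass
class WaveformParams:
    """Double-exponential BPAP and EPSP shapes (times in ms, amplitudes mV).

    ``epsp_gain`` converts synaptic weight (CSIM units) into the local EPSP
    amplitude seen by the NMDAR; it is a calibrated constant, since the
    original model description fixes only decay constants and proportions.
    """

    bpap_max: float = 88.67
    tau_f_bpap: float = 1.2
    i_f_bpap: float = 0.75
    tau_s_bpap: float = 10.0
    i_s_bpap: float = 0.25
    epsp_gain: float = 3.6535e8  # mV per weight unit; calibrated
    tau_f_epsp: float = 2.0
    i_f_epsp: float = 0.5
    tau_s_epsp: float = 20.0
    i_s_epsp: float = 0.5

    def __post_init__(self) -> None:
        for t in (self.tau_f_bpap, self.tau_s_bpap, self.tau_f_epsp, self.tau_s_epsp):
            _require(t > 0, "waveform time constants must be positive")
        _require(math.isclose(self.i_f_bpap + self.i_s_bpap, 1.0, abs_tol=1e-9),
                 "BPAP fast+slow proportions must sum to 1")
        _require(math.isclose(self.i_f_epsp + self.i_s_epsp, 1.0, abs_tol=1e-9),
                 "EPSP fast+slow proportions must sum to 1")


@dataclass
class NMDACurrentParams:
    """NMDA calcium-current constants (times in ms).

    The product ``p_open * g_nmda`` sets the calcium flux scale (uM/ms at
    unit driving force); it is frozen by calibration.  ``v_rest_nmda`` is
    the biological resting potential at which the magnesium-block curve
    operates; the local depolarization (EPSP + BPAP) rides on top of it.
    ``mg_block_product`` switches to the literal product reading of the
    driving-force formula (kept for comparison; the denominator reading is
    the physically meaningful one).
    """

    p_open: float = 0.5
    g_nmda: float = 2.51189e-2  # calibrated; uM/ms per unit H
    i_f: float = 0.822442
    i_s: float = 0.177558
    tau_f: float = 17.1735
    tau_s: float = 49.0483
    mg: float = 1.0  # mM
    v_reversal_ca: float = 130.0  # mV
    v_rest_nmda: float = -72.7121  # mV
    ca_max: float = 8.0  # uM; calcium-dependent inactivation scale (0 disables)
    trace_restart: bool = False  # True: latest presynaptic spike dominates
    mg_block_product: bool = False

    def __post_init__(self) -> None:
        _require(self.mg > 0, "mg must be positive")
        _require(self.tau_f > 0 and self.tau_s > 0,
                 "NMDA time constants must be positive")
        _require(self.i_f + self.i_s <= 1.0 + 1e-9,
                 "i_f + i_s must not exceed 1")

    @property
    def gain(self) -> float:
        return self.p_open * self.g_nmda


_VARIANTS = ("full", "ltp_ltd_only", "ltp_ltd_adjusted")


@dataclass
class PlasticityParams:
    """Calcium-controlled bidirectional weight update.

    The Omega function maps synaptic calcium (uM) to a weight attractor:
    below ``alpha1`` nothing happens, between ``alpha1`` and ``alpha2`` the
    attractor is depressing (depth ``omega_rate``), above ``alpha2`` it is
    potentiating.  ``omega_to_weight_scale`` (kappa) converts Omega into
    weight units; with the default, the potentiation plateau
    ``kappa * (1 - omega_rate)`` sits exactly at ``weight_max``.

    The learning rate ``eta(Ca)`` (1/s) is a sum of two sigmoids gated just
    above the depression and potentiation thresholds, standing in for the
    calcium-dependent activation of phosphatase- and kinase-driven
    signalling; its constants are calibrated, not published.
    """

    alpha1: float = 0.1
    alpha2: float = 0.4
    beta1: float = 80.0
    beta2: float = 80.0
    omega_rate: float = 0.4
    tau_ca: float = 50.0  # ms
    tau_eff: float = 200.0  # ms; effector-calcium integration (0: instantaneous)
    weight_min: float = 1.0e-9
    weight_max: float = 6.5e-8
    omega_to_weight_scale: float = 6.5e-8 / 0.6
    eta_max: float = 0.3          # 1/s; calibrated
    eta_lo_weight: float = 0.15   # low-calcium (phosphatase) branch weight
    eta_lo_theta: float = 0.10    # uM; at the depression threshold alpha1
    eta_lo_beta: float = 80.0     # 1/uM
    eta_hi_theta: float = 0.42    # uM; just above the potentiation threshold
    eta_hi_beta: float = 33.0     # 1/uM
    variant: str = "full"

    def __post_init__(self) -> None:
        _require(self.variant in _VARIANTS, f"variant must be one of {_VARIANTS}")
        if self.variant == "ltp_ltd_adjusted":
            # retuned calcium control hypothesis compensating for BPAP removal
            self.alpha1, self.alpha2, self.omega_rate = 0.3, 0.4, 0.3
        _require(self.alpha1 < self.alpha2, "alpha1 must be < alpha2")
        _require(self.tau_ca > 0, "tau_ca must be positive")
        _require(self.weight_min < self.weight_max,
                 "weight_min must be < weight_max")
        _require(self.eta_max >= 0, "eta_max must be >= 0")

    @property
    def bpap_enabled(self) -> bool:
        return self.variant == "full"


@dataclass
class STDPParams:
    """Pair-based exponential STDP (used by the STDP-only synapse variant).

    The original model description adopts unprinted constants from earlier reservoir
    work; these defaults follow the common additive rule with a slight
    depression bias and are fully configurable.
    """

    a_plus: float = 6.5e-10   # weight units per pairing
    a_minus: float = 6.8e-10
    tau_plus: float = 20.0    # ms
    tau_minus: float = 20.0

    def __post_init__(self) -> None:
        _require(self.tau_plus > 0 and self.tau_minus > 0,
                 "STDP time constants must be positive")
        _require(self.a_plus >= 0 and self.a_minus >= 0,
                 "STDP amplitudes must be >= 0")


@dataclass
class NetworkConfig:
    """Reservoir geometry, connectivity and weight-distribution parameters."""

    dims: Tuple[int, int, int] = (10, 10, 5)
    excitatory_fraction: float = 0.75
    lambda_: float = 2.0          # grid units; math.inf removes distance limits
    cscale: float = 1.0
    wscale: float = 0.5
    sh_w: float = 0.25
    input_mode: str = "one_to_one"   # or "random"
    input_cscale: float = 0.04
    input_weight: float = 2.7e-7     # fixed weight in one_to_one mode
    input_wscale: float = 3.0
    input_sh_w: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        _require(len(dims) == 3 and all(d >= 1 for d in dims),
                 "dims must be three integers >= 1")
        self.dims = dims
        _require(0.0 < self.excitatory_fraction < 1.0,
                 "excitatory_fraction must be in (0, 1)")
        _require(self.lambda_ > 0, "lambda_ must be positive (may be inf)")
        for name in ("cscale", "wscale", "sh_w", "input_cscale",
                     "input_wscale", "input_sh_w"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(self.input_mode in ("one_to_one", "random"),
                 "input_mode must be 'one_to_one' or 'random'")

    @property
    def n_neurons(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = list(self.dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown NetworkConfig keys: {sorted(unknown)}")
        return cls(**d)
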