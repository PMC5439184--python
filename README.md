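# famnet

Familiarity detection in recurrent spiking networks with NMDAR
calcium-controlled bidirectional synaptic plasticity.

`famnet` is a simulator and experiment suite for studying how generic
cortical microcircuits can recognize previously seen sensory inputs
without supervision. It builds liquid-state-machine-style reservoirs of
leaky integrate-and-fire (LIF) neurons on a 3-D grid, equips the
excitatory recurrent synapses with a calcium control model of synaptic
plasticity — so that rate-based LTP/LTD and spike-timing-dependent
plasticity (STDP) emerge from a single mechanism — converts images into
Poisson spike trains, and runs the three-phase familiarity protocols
(baseline, learning, testing) together with the separability (Fisher
discriminant) and potentiated-subnetwork analyses. It is aimed at
computational neuroscientists who want a compact, reproducible testbed for
recognition-memory models.

## Model

**Neurons.** Each reservoir neuron is a LIF unit,

    tau_m dV/dt = -(V - V_rest) + R_m (I_syn + I_inject + I_noise)

with `tau_m = 30 ms`, `V_rest = 0 mV`, `R_m = 1 MOhm`, background current
`I_inject = 13.5 nA`, threshold 15 mV, and absolute refractory periods of
3 ms (excitatory, 75% of neurons) and 2 ms (inhibitory).

**Wiring.** Neurons sit on integer grid coordinates; the probability of a
directed synapse is `P(D) = C exp(-D^2 / lambda^2)` with base `C` of
0.3/0.2/0.4/0.1 for EE/EI/IE/II pairs. Initial weights are gamma
distributed with mean `W * Wscale` and coefficient of variation `SH_W`;
inhibitory weights are negative and static.

**Plasticity.** Every excitatory recurrent synapse carries an NMDAR
calcium module: presynaptic spikes open NMDA channels (double-exponential
trace) and evoke a local EPSP proportional to the weight; postsynaptic
spikes back-propagate (BPAP). The calcium current is

    I_NMDA = P0 G_NMDA [ I_f e^{-t/tau_f} + I_s e^{-t/tau_s} ] H(V)

with the magnesium-block driving force
`H(V) = -0.42 (V - 130) / (1 + 0.6 e^{-0.09 V} [Mg]/3.57)` evaluated at
the local spine potential (rest + EPSP + BPAP). Synaptic calcium
integrates this flux with a 50-ms decay, and the weight relaxes toward a
calcium-controlled attractor,

    dW/dt = eta(Ca) ( kappa * Omega(Ca) - W ),
    Omega  = sig(Ca - alpha2, beta2) - Omega_rate * sig(Ca - alpha1, beta1)

with `alpha1 = 0.1 uM`, `alpha2 = 0.4 uM`, `Omega_rate = 0.4`: calcium
between the thresholds depresses, calcium above `alpha2` potentiates, and
weights stay inside `[1e-9, 6.5e-8]`. A slow effector pool (a 200-ms
low-pass of calcium) drives `Omega`/`eta`, so only sustained calcium
elevations — tetani, high-rate pre-post pairing, coincidence-rich pathways
— move weights. See `docs/methods.md` for details, calibrated constants
and the modeling choices behind them.

**Analyses.** Responses are network firing rates during the 0.5-s
stimulus window; separability uses Fisher's discriminant ratio
`J = sum_C (mu_C - mu)^2 / sum_C sum_{i in C} (S_i - mu_C)^2` on spike
counts; memory traces are read out as the subnetwork of synapses whose
weight change crosses +/-1e-8, with Watts-Strogatz clustering statistics.

## Worked example

```python
from famnet import measure_calcium_response, run_tetanus_protocol
from famnet.protocols import run_single_image_recognition

# Steady-state peak synaptic calcium at a single synapse (weight 1e-8)
# driven at 50 Hz, postsynaptic spiking disabled:
measure_calcium_response(1e-8, "frequency", 50)   # -> 0.594 (uM)

# A 2-s, 50-Hz tetanus produces a lasting EPSP amplitude increase:
run_tetanus_protocol(50.0)["ratio"]               # -> 1.48

# Single-image recognition: a 10x10x5 reservoir learns one synthetic
# image (15-s exposure) out of a baseline-normalized set of 12:
res = run_single_image_recognition(network_seed=0, learn_id=5)
int(res.ranks[5])                                 # -> 1 (highest response)
float(res.baseline[5]), float(res.test[5])        # -> (1.82, 3.08) spikes/s
```

After learning, the familiar image evokes the largest network response
(rank 1 of 12; its rate rises from 1.8 to 3.1 spikes/s while novel images
average 2.4), and the weight table shows the published memory-trace
structure: a small potentiated subnetwork (89 synapses beyond +1e-8) next
to a comparable depressed set (81 beyond -1e-8) out of ~3800.

A command-line interface mirrors the workflow
(`famnet build | validate-synapse | familiarity | sweep | analyze`), and
`scripts/capacity_experiment.py` scales the multi-image capacity protocol
up to large reservoirs (long-running).

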