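# Methods

This note records the model as implemented, the constants that had to be
chosen or calibrated, and the reasoning behind the design decisions, in
the spirit of a simulator's model documentation. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Reservoir model

Neurons are leaky integrate-and-fire units on a 3-D integer grid
(`tau_m = 30 ms`, `V_rest = 0 mV`, `R_m = 1 MOhm`, `I_inject = 13.5 nA`,
threshold 15 mV, reset and initial membrane potential uniform in
[-1, 1] mV, absolute refractory period 3 ms for excitatory and 2 ms for
inhibitory neurons). 75% of neurons are excitatory —
`ceil(0.75 N)`, chosen by a seeded draw without replacement; the ceiling
convention is fixed so tests can be exact. With the background current
alone the steady-state membrane potential is 13.5 mV, 1.5 mV below
threshold: the reservoir is silent without input but highly excitable.

Connectivity is one independent Bernoulli draw per ordered neuron pair
with `P(D) = C_base * Cscale * exp(-D^2/lambda^2)`;
`C_base = 0.3/0.2/0.4/0.1` for EE/EI/IE/II, first letter presynaptic.
Initial weights are gamma distributed with shape `1/SH_W^2` and scale
`|W_base| * Wscale * SH_W^2` (mean `|W_base| * Wscale`, CV `SH_W`);
`W_base = 3e-8 / 6e-8 / -1.9e-8 / -1.9e-8` for EE/EI/IE/II in CSIM-style
weight units (amperes of postsynaptic-current jump). Inhibitory-
presynaptic weights are negative and static; excitatory recurrent
synapses are plastic and clipped into `[1e-9, 6.5e-8]` at simulation
start (the EI gamma with mean 5.4e-8 otherwise starts above the
plasticity ceiling). Input layers connect either one-to-one onto the
first grid layer with fixed weight 2.7e-7, or randomly with probability
`input_cscale` and gamma weights (`Wscale = 3`, `SH_W = 0.7`); input
synapses are never plastic.

Synaptic transmission is a per-neuron summed exponential current
(`tau_psc = 3 ms`): a presynaptic spike adds the synaptic weight (in nA)
to the postsynaptic current trace, with a uniform one-timestep
transmission delay. Membrane integration is exponential Euler (exact for
constant current within a step) at `dt = 0.2 ms`; all model time
constants are >= 1.2 ms.

### Recurrent transmission efficacy

Cortical-microcircuit reservoir models rely on short-term synaptic
depression to keep recurrent excitation subcritical; that dynamic-synapse
machinery is outside the scope of this package. Its absence matters: with
static synapses at the nominal weights, a single seed spike ignites a
stereotyped network-wide avalanche (any stimulus recruits ~85% of
neurons), all stimuli produce nearly identical activity, and learning
saturates every active synapse. `Simulation(recurrent_efficacy=0.35)`
therefore scales spike *transmission* at recurrent synapses by a constant
standing in for the steady-state efficacy of depressing synapses at the
1-20 Hz rates these reservoirs visit (the steady-state efficacy of a
classic depressing cortical synapse spans roughly 0.1-0.5 over that
range). The plasticity machinery and the calcium model operate on the
full weight scale; only delivery is scaled, so the weight dynamics remain
on the published scale while the network operates in the sparse,
stimulus-specific regime in which familiarity learning is selective.

## NMDAR synapse and calcium control

Each plastic synapse tracks two per-neuron double-exponential trace pairs
(so per-synapse state is just weight and calcium):

- EPSP waveform: fast 2 ms (0.5), slow 20 ms (0.5); local amplitude
  `epsp_gain * weight` (mV).
- BPAP waveform: fast 1.2 ms (0.75), slow 10 ms (0.25); amplitude
  `bpap_max`; restarted on each postsynaptic spike.
- NMDA open-state trace: fast `tau_f` (fraction `i_f`), slow `tau_s`;
  presynaptic spikes *sum* into the trace (temporal summation).

Summation rather than restart-on-spike is essential: the published
calcium table requires a ~9x contrast between 1-Hz and 100-Hz drive,
which a restarting (single-spike-bounded) trace cannot produce. A restart
mode is kept as a configuration switch.

The calcium flux is `gain * trace * H(V_loc) * max(0, 1 - Ca/ca_max)`.
The driving force uses the Jahr-Stevens denominator form,
`H(V) = -0.42 (V - 130) / (1 + 0.6 e^{-0.09 V} [Mg]/3.57)`, `[Mg] = 1 mM`
(the printed formula is typographically ambiguous; the product reading is
available behind a flag but makes the magnesium block *strengthen* with
depolarization). `V_loc = v_rest_nmda + EPSP + BPAP` with
`v_rest_nmda ~ -70 mV`: the magnesium-block curve operates on the
biological voltage scale (~59x block at -65 mV, steep relief toward
0 mV). Inserting the LIF model's 0-mV resting convention literally would
leave the receptor ~86% unblocked at rest and make H *fall* with
depolarization, inverting both the frequency and the timing dependence of
calcium. The final factor is calcium-dependent NMDAR inactivation; it
supplies the saturation of the calcium readout near 1 uM and the
compression of the weight dependence at high rates visible in the
published table.

Calcium integrates the flux with `tau_Ca = 50 ms` (explicit Euler,
floored at 0). Weights follow

    dW/dt = eta(Ca_eff) * (kappa * Omega(Ca_eff) - W)

clipped to `[1e-9, 6.5e-8]`, with
`Omega = sig(Ca-alpha2, 80) - 0.4 * sig(Ca-alpha1, 80)`, `alpha1 = 0.1`,
`alpha2 = 0.4 uM`. `kappa = 6.5e-8/0.6` places the potentiation plateau
exactly at the weight ceiling; with the smaller value that puts the
plateau just *under* the ceiling, a synapse starting at the table's
"large" weight (6e-8) would have zero potentiation drive and the
published LTP sign at 50-100 Hz could not hold there.

### Effector calcium

`Ca_eff` is a first-order low-pass of synaptic calcium
(`tau_eff = 200 ms`), standing for the integration time of the
kinase/phosphatase machinery downstream of calcium. It is the single most
consequential deviation from an instantaneous reading of the weight
equation, and it is forced by the published numbers themselves: the
pairing column of the calcium table pins the transient of *one* pre-post
coincidence at 0.7-0.9 uM — above the potentiation threshold. With
instantaneous coupling, every synapse in a recurrently active network
potentiates on every stray coincidence, and the reservoir runs away
(verified during development: all ~2800 plastic synapses of a 10x10x5
reservoir saturate within a 15-s exposure at any learning-rate scale that
leaves the single-synapse protocols visible). With the low-pass, isolated
coincidences contribute only their time-average (~0.2 uM, in the
depression zone), while tetani, high-rate pairing and coincidence-rich
stimulus pathways sustain `Ca_eff` above threshold. The low-pass also
gives the borderline table cells (e.g. large weight at 20 Hz, whose raw
calcium peak exceeds `alpha2` but whose sawtooth mean does not) their
published depression sign. All calcium *readouts* (the table, the
acceptance targets) report the raw transient; readouts at or above 1.0 uM
report the saturation value 1.0.

### Learning rate

`eta(Ca)` is not published. It is implemented as
`eta_max * [ a_lo * sig(Ca - 0.10, 80) + (1-a_lo) * sig(Ca - 0.42, 33) ]`
— a small branch that activates at the depression threshold (phosphatase
pathway) and a dominant branch activating just above the potentiation
threshold (kinase pathway) — with `eta_max = 0.3 /s` and `a_lo = 0.15`.
The constants were calibrated so that (a) the 2-s tetani produce clear,
lasting EPSP-amplitude changes (about +48% at 50 Hz, -23% at 20 Hz from a
3e-8 synapse), (b) pairing blocks potentiate/depress in the published
directions at every initial weight, and (c) a 15-s familiarity exposure
changes a selective minority of weights (on the order of 10^2 synapses
past +/-1e-8 in a 10x10x5 reservoir) rather than saturating the network.
At rest (`Ca_eff` ~ 0) the rate is ~1e-6/s, so probe stimulation at
0.125-0.2 Hz is subthreshold for plasticity.

### Induction protocols

The tetanus protocol (2 s at 20 or 50 Hz, postsynaptic spiking disabled,
EPSP probed at 0.2 Hz from the postsynaptic membrane potential) follows
the classic frequency experiments. Pairing protocols force pre- and
postsynaptic spikes at a fixed interval; the repetition rate is not
published and is a design choice here: LTP pairings run at 20 Hz and the
long-negative-interval depression protocol at 10 Hz, matching the
cortical pairing literature in which pre-post potentiation requires
elevated pairing rates while low-rate pairing yields depression. The
calcium-table readout instead uses isolated 1-Hz pairs (per-pair
transients, matching a "real-time calcium vs interval" reading). Removing
BPAPs (`variant="ltp_ltd_only"`) eliminates the timing asymmetry;
`variant="ltp_ltd_adjusted"` additionally retunes
`alpha1 = 0.3, alpha2 = 0.4, Omega_rate = 0.3`. A pair-based exponential
STDP synapse (`plasticity_model="stdp"`) is provided for the STDP-only
comparison; its amplitudes/time constants are configurable defaults
(not published).

### Calibration

The unpublished constants (`g_nmda`, `epsp_gain`, `bpap_max`, NMDA trace
`tau_f/tau_s/i_f`, `ca_max`, `v_rest_nmda`) were fitted to the 27
published peak-calcium cells by random search plus Nelder-Mead refinement
(`scripts/calibrate_synapse.py`); the result is frozen in
`famnet.params`. All 27 cells reproduce within +/-0.1 uM of the printed
values under the saturated readout.

## Stimuli

Images (0-255 grayscale) map pixel-per-channel to Poisson spike trains at
`pixel/255 * 50 Hz` over a 0.5-s active window followed by 0.5 s of
silence; a regular-train mode serves the fixed-frequency single-synapse
protocols. Preprocessing offers Sobel edge detection (operator
unspecified in the source; threshold configurable), local-average
downsampling, the 20x20 -> 50x50 upscale (2x2 pixel replication to 40x40,
zero "void" padding to 50x50 — the printed padding description reaches
only 41x41, so right/bottom padding is used), and seeded pixel
scrambling.

The synthetic image generator stands in for the face/car/dog photographs
(not redistributable): each class is a smoothed Gaussian random-field
template, items add item-specific smoothed perturbations, and an
`edge_like` mode keeps only the intensity ridge above the 0.85 quantile
with intensities pushed toward the maximum — mimicking edge-detected line
drawings, which are mostly void pixels. Defaults give within-class pixel
correlations near 0.45 and between-class correlations near 0.1, i.e.
distinct-but-similar category members. Baseline normalization rescales
each image's intensities multiplicatively (preserving line-drawing
sparsity; additive mean-shifting floods void pixels and erases stimulus
specificity) until baseline responses agree within tolerance (2% default;
the scaled experiments use 5% and at most 6-8 iterations). What the
generator does *not* emulate: real image statistics (shading, occlusion,
within-category geometry), so passing tests demonstrate the network
mechanism on structured synthetic inputs, not photograph-level
recognition.

## Experiments

Protocols follow the three-phase design: baseline probing with plasticity
off, learning with plasticity on, testing with plasticity off. Responses
are population firing rates over the 0.5-s active window. Probe phases
reset the dynamic state (not the weights) to the seeded initial condition
and settle for 0.2 s before *every* stimulus, so probes are
order-independent and baseline/test differences isolate weight changes;
probe encodings reuse fixed per-stimulus seeds while learning
presentations are re-encoded freshly each time. Ranks order stimuli by
test response, ties broken by stimulus index. With zero-length learning,
test equals baseline bitwise.

The scaled experiment sizes used by the test suite are a package choice:
10x10x5 reservoirs (one-to-one input) with 12 synthetic images for
recognition trials, 30 images for the baseline-rank experiment, and
(10,10,2)-vs-(10,10,5) for the size-direction comparison. The published
protocol sizes (30 networks x 3 trials at 20x20x5; 50x50x5/6 with up to
200 faces) are supported through the same functions and
`scripts/capacity_experiment.py` as long-running runs.

## Numerical choices

- `dt = 0.2 ms` everywhere; doubling it shifts single-neuron spike times
  by less than a refractory period over 1 s.
- Driving force, `Omega` and `eta` are linear-interpolated lookup tables
  inside the compiled kernel (0.05 mV / 0.001 uM grids).
- Named RNG streams (construction/labels, construction/wiring,
  construction/weights, dynamics/init, dynamics/run, stimulus/...,
  analysis/...) derive from one master seed via `SeedSequence`, so wiring
  is reproducible independently of dynamics.
- Plasticity-off phases skip the synapse loop; calcium then decays
  analytically. Synapses with negligible NMDA trace and calcium are
  skipped inside the learning loop.
- Fisher ratios report a documented sentinel (1e9) when within-class
  scatter is exactly zero with nonzero between-class scatter; bins with
  zero scatter on both sides contribute 0.
- Clustering coefficients use the undirected simple projection of the
  potentiated subnetwork (Watts-Strogatz average, isolated/degree-1 nodes
  contributing 0); the chance overlap of top-k discriminative neurons
  uses all reservoir neurons as the denominator.
- Spike buffers grow on overflow with a state rollback and retry; NaN
  membrane state aborts with a diagnostic.

## Known limitations

- Short-term synaptic dynamics are approximated by a constant
  transmission efficacy (see above); regimes where facilitation or the
  time course of depression matter (e.g. the precise onset of bursting)
  are outside the model.
- The effector-calcium low-pass makes very-low-rate pairing (<1 Hz)
  plasticity-neutral; protocols with tens of isolated pairings produce
  measurable changes only at elevated pairing rates.
- The mean recurrent degree at the published 50x50x5 scale follows the
  stated connectivity law (~54 afferent+efferent synapses per neuron at
  lambda = 3), which is well below the ~100 that the original description quotes
  for that configuration; the law and base probabilities, not the quoted
  degree, are implemented.
- Reported network firing rates in the scaled experiments (~2-4 spikes/s)
  are lower than the published curves (~10 s^-1); the qualitative
  structure (rank-1 familiarity, selective potentiated subnetwork, larger
  depressed subset, stable down-state dynamics) is the reproduction
  target at desk scale.
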