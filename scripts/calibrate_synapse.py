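"""Calibrate the unpublished NMDA-synapse constants against the
single-synapse calcium table.

The reference model fixes the EPSP/BPAP decay constants, the calcium decay
time and the Omega thresholds, but not the NMDA conductance scale, the
EPSP amplitude per unit weight, the NMDA open-state decay constants and
fast fraction, the BPAP amplitude, the calcium-inactivation scale, or the
NMDAR resting potential.  This script fits those against the 27 published
peak-calcium cells (15 frequency conditions, 12 pairing conditions) using
the package's own measurement protocol, by random search followed by
Nelder-Mead refinement.  The result is frozen into the defaults of
``famnet.params`` (WaveformParams / NMDACurrentParams).

Run:  python scripts/calibrate_synapse.py [--iters 300] [--seed 2]
(The full search takes a while; the shipped defaults were produced by this
procedure.)
"""

from __future__ import annotations

import argparse

import numpy as np
from scipy.optimize import minimize

from famnet.params import NMDACurrentParams, WaveformParams
from famnet.protocols import TABLE_CALCIUM, measure_calcium_response

BOUNDS = [
    ("g_nmda", -4.2, -1.6, "log10"),      # uM/ms per unit driving force
    ("epsp_gain", 7.5, 9.3, "log10"),     # mV per weight unit
    ("ca_max", 1.0, 8.0, "lin"),          # uM
    ("tau_f", 5.0, 60.0, "lin"),          # ms
    ("tau_s", 40.0, 400.0, "lin"),        # ms
    ("i_f", 0.05, 0.98, "lin"),
    ("bpap_max", 40.0, 220.0, "lin"),     # mV
    ("v_rest_nmda", -80.0, -55.0, "lin"),  # mV
]


def decode(x):
    vals = {}
    for (name, lo, hi, scale), v in zip(BOUNDS, x):
        vals[name] = 10 ** v if scale == "log10" else v
    wf = WaveformParams(epsp_gain=vals["epsp_gain"], bpap_max=vals["bpap_max"])
    nm = NMDACurrentParams(g_nmda=vals["g_nmda"], ca_max=vals["ca_max"],
                           tau_f=vals["tau_f"], tau_s=vals["tau_s"],
                           i_f=vals["i_f"], i_s=1.0 - vals["i_f"],
                           v_rest_nmda=vals["v_rest_nmda"])
    return wf, nm


def table_error(wf: WaveformParams, nm: NMDACurrentParams,
                verbose: bool = False) -> float:
    """Hinge-augmented squared error over all 27 cells (saturated readout).

    Deviations beyond 0.06 uM are penalized heavily (the acceptance band
    is +/-0.1 uM); saturated cells (printed 1.0) require the raw peak to
    reach the saturation level; the LTP pairing cells (+5/+15 ms) prefer
    landing on the high side so the net weight-change sign is preserved.
    """
    err = 0.0
    for w, row in TABLE_CALCIUM.items():
        for cond, tgt in row.items():
            if isinstance(cond, tuple):
                v = measure_calcium_response(w, "pairing", cond[1],
                                             readout_saturation=None,
                                             waveform=wf, nmda=nm)
                e = min(v, 1.0) - tgt
                err += e * e + 40 * max(0.0, abs(e) - 0.06) ** 2
                if cond[1] > 0 and e < 0:
                    err += 3 * e * e
            else:
                v = measure_calcium_response(w, "frequency", cond,
                                             readout_saturation=None,
                                             waveform=wf, nmda=nm)
                if tgt >= 1.0:
                    miss = max(0.0, 1.0 - v)
                    err += 40 * max(0.0, miss - 0.01) ** 2 + miss ** 2
                else:
                    d = abs(min(v, 1.0) - tgt)
                    err += d * d + 40 * max(0.0, d - 0.06) ** 2
            if verbose:
                print(f"  w={w:.0e} {cond}: model {v:.3f} target {tgt}")
    return err


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--iters", type=int, default=300)
    ap.add_argument("--seed", type=int, default=2)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    pool = []
    for it in range(args.iters):
        x = np.array([rng.uniform(lo, hi) for _, lo, hi, _ in BOUNDS])
        err = table_error(*decode(x))
        pool.append((err, x))
        if it % 20 == 0:
            pool.sort(key=lambda z: z[0])
            print(f"iter {it}: best error {pool[0][0]:.4f}", flush=True)
    pool.sort(key=lambda z: z[0])

    def obj(x):
        for (_, lo, hi, _), v in zip(BOUNDS, x):
            if not lo <= v <= hi:
                return 1e6
        return table_error(*decode(x))

    best = min((minimize(obj, x0, method="Nelder-Mead",
                         options=dict(maxfev=400, xatol=1e-3, fatol=1e-5))
                for _, x0 in pool[:4]), key=lambda r: r.fun)
    wf, nm = decode(best.x)
    print(f"\nfinal error {best.fun:.5f}")
    print("frozen constants:")
    print(f"  epsp_gain   = {wf.epsp_gain:.6g}   # mV per weight unit")
    print(f"  bpap_max    = {wf.bpap_max:.6g}    # mV")
    print(f"  g_nmda      = {nm.g_nmda:.6g}      # uM/ms per unit H")
    print(f"  ca_max      = {nm.ca_max:.6g}      # uM")
    print(f"  tau_f/tau_s = {nm.tau_f:.6g}/{nm.tau_s:.6g} ms")
    print(f"  i_f/i_s     = {nm.i_f:.6g}/{nm.i_s:.6g}")
    print(f"  v_rest_nmda = {nm.v_rest_nmda:.6g} mV")
    print("\ncell-by-cell:")
    table_error(wf, nm, verbose=True)


if __name__ == "__main__":
    main()
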