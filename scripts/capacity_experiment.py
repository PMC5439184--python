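"""Multi-image capacity experiment (long-running; not part of the tests).

Reproduces the multi-face protocol at configurable scale: a large
reservoir learns ``--n-learn`` synthetic faces (6 s each by default) and
is tested on the learned faces pooled with an equal number of novel ones;
accuracy is the fraction of learned faces above the hypothetical
threshold (top half of the ranking).  At the published scale
(50x50x5 or 50x50x6, 200-face pool, 1000 testing trials) this is an
overnight run; the defaults below are a reduced configuration.

Example:
    python scripts/capacity_experiment.py --dims 20 20 5 --n-learn 2 \
        --pool 30 --out results/capacity.json
"""

from __future__ import annotations

import argparse
import json
import time
from pathlib import Path

import numpy as np

from famnet import (NetworkConfig, Simulation, build_input_projection,
                    build_network, encode_image, generate_synthetic_faces,
                    normalize_image_set)
from famnet.protocols import (ExperimentSchedule, _probe_phase, accuracy_topk,
                              run_familiarity_experiment)
from famnet._rng import stream_seed


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dims", type=int, nargs=3, default=[20, 20, 5])
    ap.add_argument("--n-learn", type=int, default=2)
    ap.add_argument("--pool", type=int, default=30,
                    help="total images (learned + novel candidates)")
    ap.add_argument("--exposure", type=float, default=6.0)
    ap.add_argument("--n-networks", type=int, default=3)
    ap.add_argument("--input-mode", choices=["one_to_one", "random"],
                    default="one_to_one")
    ap.add_argument("--input-cscale", type=float, default=0.04)
    ap.add_argument("--lambda", dest="lambda_", type=float, default=2.0)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/capacity.json"))
    args = ap.parse_args()

    dims = tuple(args.dims)
    rows = []
    for k in range(args.n_networks):
        t0 = time.time()
        cfg = NetworkConfig(dims=dims, lambda_=args.lambda_, wscale=0.5,
                            sh_w=0.25, input_mode=args.input_mode,
                            input_cscale=args.input_cscale,
                            seed=stream_seed(args.seed, "capacity/net", k))
        net = build_network(cfg)
        proj = build_input_projection(net, dims[:2])
        imgs = generate_synthetic_faces(
            1, args.pool, size=dims[:2],
            seed=stream_seed(args.seed, "capacity/img", k))

        def probe(ims):
            sim = Simulation(net, proj,
                             seed=stream_seed(args.seed, "capacity/probe", k))
            stims = [encode_image(im, seed=stream_seed(901, "probe", i))
                     for i, im in enumerate(ims)]
            return _probe_phase(sim, stims)[0]

        imgs, _ = normalize_image_set(imgs, probe, tolerance=0.05, max_iters=8)
        learn_ids = list(range(args.n_learn))
        sim = Simulation(net, proj,
                         seed=stream_seed(args.seed, "capacity/sim", k))
        res = run_familiarity_experiment(
            sim, imgs, learn_ids, ExperimentSchedule(exposure=args.exposure))
        # hypothetical threshold between ranks n_learn and n_learn+1 among
        # learned + as many novel images
        subset = learn_ids + list(range(args.n_learn, 2 * args.n_learn))
        sub_resp = res.test[subset]
        order = np.argsort(-sub_resp, kind="stable")
        sub_ranks = np.empty(len(subset), dtype=int)
        sub_ranks[order] = np.arange(1, len(subset) + 1)
        acc = accuracy_topk(sub_ranks[:args.n_learn], args.n_learn)
        rows.append({"network": k, "accuracy": acc,
                     "familiar_ranks": res.familiar_ranks.tolist(),
                     "seconds": round(time.time() - t0, 1)})
        print(rows[-1], flush=True)

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(
        {"config": vars(args) | {"out": str(args.out)}, "results": rows},
        indent=2, default=str))


if __name__ == "__main__":
    main()
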