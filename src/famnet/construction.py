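"""Randomized 3-D grid reservoirs with distance-dependent connectivity.

Neurons sit on integer grid coordinates; the probability that neuron ``a``
connects to neuron ``b`` falls off as a Gaussian of their Euclidean
distance, ``P(D) = C * exp(-D^2 / lambda^2)``, with the base probability
``C`` depending on the excitatory/inhibitory identity of the (pre, post)
pair.  Initial weights are gamma distributed with mean ``W * wscale`` and
coefficient of variation ``SH_W``; inhibitory presynaptic weights are
negative and static, excitatory recurrent synapses are NMDAR-plastic and
bounded to [1e-9, 6.5e-8] under plasticity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._rng import stream_rng
from .params import BASE_C, BASE_W, NetworkConfig

__all__ = [
    "Network",
    "InputProjection",
    "build_grid",
    "connection_probability",
    "sample_weights",
    "build_network",
    "build_input_projection",
]

KIND_NMDAR = "nmdar_plastic"
KIND_INHIB = "static_inhibitory"
KIND_INPUT = "static_input"


@dataclass
class InputProjection:
    """Static synapses from an input layer onto the reservoir."""

    n_channels: int
    channel: np.ndarray  # (S,) int
    post: np.ndarray     # (S,) int
    weight: np.ndarray   # (S,) float, CSIM weight units
    mode: str = "one_to_one"

    def __len__(self) -> int:
        return len(self.channel)


@dataclass
class Network:
    """Reservoir: neuron positions/labels plus the directed synapse table."""

    positions: np.ndarray       # (N, 3) int
    is_excitatory: np.ndarray   # (N,) bool
    pre: np.ndarray             # (S,) int
    post: np.ndarray            # (S,) int
    weight: np.ndarray          # (S,) float
    config: Optional[NetworkConfig] = None
    input_projection: Optional[InputProjection] = None

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    @property
    def is_plastic(self) -> np.ndarray:
        """Excitatory-presynaptic recurrent synapses carry NMDAR plasticity."""
        return self.is_excitatory[self.pre]

    @property
    def kind(self) -> np.ndarray:
        return np.where(self.is_plastic, KIND_NMDAR, KIND_INHIB)

    def synapse_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pre": self.pre, "post": self.post, "kind": self.kind,
             "weight": self.weight}
        )

    def mean_out_degree(self) -> float:
        return self.n_synapses / self.n_neurons

    def mean_total_degree(self) -> float:
        """Mean number of synapses a neuron participates in (in + out)."""
        return 2.0 * self.n_synapses / self.n_neurons


def build_grid(dims: Tuple[int, int, int], excitatory_fraction: float = 0.75,
               seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Place ``nx*ny*nz`` neurons on an integer grid and assign E/I labels.

    ``ceil(excitatory_fraction * N)`` neurons are excitatory, chosen by a
    seeded draw without replacement.  Neuron index order is C order over
    (x, y, z), i.e. index = (x*ny + y)*nz + z.
    """
    nx, ny, nz = (int(d) for d in dims)
    if min(nx, ny, nz) < 1:
        raise ValueError("all grid dimensions must be >= 1")
    if not 0.0 < excitatory_fraction < 1.0:
        raise ValueError("excitatory_fraction must be in (0, 1)")
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    positions = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()]).astype(np.int64)
    n = nx * ny * nz
    n_exc = math.ceil(excitatory_fraction * n)
    rng = stream_rng(seed, "construction/labels")
    exc_idx = rng.choice(n, size=min(n_exc, n), replace=False)
    is_exc = np.zeros(n, dtype=bool)
    is_exc[exc_idx] = True
    return positions, is_exc


def connection_probability(pos_a, pos_b, conn_type: str,
                           lambda_: float = 2.0, cscale: float = 1.0):
    """Gaussian distance-dependent connection probability.

    ``P = C_base(conn_type) * cscale * exp(-D^2 / lambda^2)``; an infinite
    ``lambda_`` removes the distance dependence.  Accepts single positions
    or arrays broadcastable to (.., 3).
    """
    if conn_type not in BASE_C:
        raise ValueError(f"unknown connection type {conn_type!r}")
    if not lambda_ > 0:
        raise ValueError("lambda_ must be positive")
    if not cscale > 0:
        raise ValueError("cscale must be positive")
    base = BASE_C[conn_type] * cscale
    if math.isinf(lambda_):
        d2 = np.zeros(np.broadcast(np.asarray(pos_a, float),
                                   np.asarray(pos_b, float)).shape[:-1])
        p = np.full_like(d2, base, dtype=float)
        return float(p) if p.ndim == 0 else p
    diff = np.asarray(pos_a, dtype=float) - np.asarray(pos_b, dtype=float)
    d2 = np.sum(diff * diff, axis=-1)
    p = base * np.exp(-d2 / (lambda_ ** 2))
    return float(p) if np.ndim(p) == 0 else p


def sample_weights(conn_type: str, wscale: float, sh_w: float, n: int,
                   seed: int = 0, rng: Optional[np.random.Generator] = None
                   ) -> np.ndarray:
    """Draw ``n`` initial weights from the gamma distribution for one type.

    Shape ``a = 1/SH_W**2`` and scale ``b = |W_base| * wscale * SH_W**2``
    give mean ``|W_base| * wscale`` and CV ``SH_W``; inhibitory-presynaptic
    types (IE, II) are flipped to negative.
    """
    if conn_type not in BASE_W:
        raise ValueError(f"unknown connection type {conn_type!r}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if not (wscale > 0 and sh_w > 0):
        raise ValueError("wscale and sh_w must be positive")
    if rng is None:
        rng = stream_rng(seed, "construction/weights")
    base = BASE_W[conn_type]
    a = 1.0 / sh_w ** 2
    b = abs(base) * wscale * sh_w ** 2
    w = rng.gamma(shape=a, scale=b, size=int(n))
    if base < 0:
        w = -w
    return w


_TYPE_NAME = {(True, True): "EE", (True, False): "EI",
              (False, True): "IE", (False, False): "II"}


def build_network(config: NetworkConfig) -> Network:
    """Construct the reservoir: one Bernoulli draw per ordered neuron pair.

    Deterministic given ``config.seed``; no self-connections; at most one
    synapse per ordered pair.  Excitatory presynaptic synapses are
    NMDAR-plastic, inhibitory ones static with negative weights.
    """
    positions, is_exc = build_grid(config.dims, config.excitatory_fraction,
                                   seed=config.seed)
    n = len(positions)
    rng = stream_rng(config.seed, "construction/wiring")
    lam2 = None if math.isinf(config.lambda_) else config.lambda_ ** 2

    c_pre = np.where(is_exc, 1, 0)
    # base C matrix lookup by (pre_exc, post_exc)
    cmat = np.array([[BASE_C["II"], BASE_C["IE"]],
                     [BASE_C["EI"], BASE_C["EE"]]]) * config.cscale

    pre_list, post_list = [], []
    pos_f = positions.astype(np.float64)
    block = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, block):
        stop = min(start + block, n)
        if lam2 is None:
            p = np.ones((stop - start, n))
        else:
            diff = pos_f[start:stop, None, :] - pos_f[None, :, :]
            p = np.exp(-np.einsum("ijk,ijk->ij", diff, diff) / lam2)
        p *= cmat[c_pre[start:stop][:, None], c_pre[None, :]]
        draws = rng.random(p.shape) < p
        rows = np.arange(start, stop)
        draws[rows - start, rows] = False  # no autapses
        pr, po = np.nonzero(draws)
        pre_list.append(pr + start)
        post_list.append(po)
    pre = np.concatenate(pre_list).astype(np.int64)
    post = np.concatenate(post_list).astype(np.int64)

    weight = np.empty(len(pre), dtype=np.float64)
    wrng = stream_rng(config.seed, "construction/weights")
    for (pe, po_), name in _TYPE_NAME.items():
        mask = (is_exc[pre] == pe) & (is_exc[post] == po_)
        weight[mask] = sample_weights(name, config.wscale, config.sh_w,
                                      int(mask.sum()), rng=wrng)

    net = Network(positions=positions, is_excitatory=is_exc,
                  pre=pre, post=post, weight=weight, config=config)
    return net


def build_input_projection(network: Network, input_dims: Tuple[int, int],
                           mode: Optional[str] = None,
                           input_cscale: Optional[float] = None,
                           input_weight: Optional[float] = None,
                           input_wscale: Optional[float] = None,
                           input_sh_w: Optional[float] = None,
                           seed: Optional[int] = None) -> InputProjection:
    """Wire an input layer onto the reservoir.

    ``one_to_one``: each input channel contacts the matching first-layer
    (z = 0) neuron with a fixed weight.  ``random``: each (channel, neuron)
    pair connects with probability ``input_cscale``, weights gamma
    distributed (excitatory presynaptic, base W by postsynaptic type).
    Input synapses are static and never plastic.
    """
    cfg = network.config or NetworkConfig()
    mode = mode or cfg.input_mode
    input_cscale = cfg.input_cscale if input_cscale is None else input_cscale
    input_weight = cfg.input_weight if input_weight is None else input_weight
    input_wscale = cfg.input_wscale if input_wscale is None else input_wscale
    input_sh_w = cfg.input_sh_w if input_sh_w is None else input_sh_w
    seed = cfg.seed if seed is None else seed

    h, w = (int(d) for d in input_dims)
    n_channels = h * w
    if n_channels < 1:
        raise ValueError("input layer must be nonempty")
    if mode == "one_to_one":
        nx, ny, nz = cfg.dims if network.config else (0, 0, 0)
        if network.config is None or (h, w) != (nx, ny):
            # fall back to matching against actual first-layer geometry
            first = np.flatnonzero(network.positions[:, 2] == 0)
            if len(first) != n_channels:
                raise ValueError(
                    f"one_to_one input of {n_channels} channels does not match "
                    f"first layer of {len(first)} neurons")
        # z = 0 neurons, ordered by (x, y) to match pattern.ravel()
        first = np.flatnonzero(network.positions[:, 2] == 0)
        order = np.lexsort((network.positions[first, 1],
                            network.positions[first, 0]))
        post = first[order]
        channel = np.arange(n_channels, dtype=np.int64)
        weight = np.full(n_channels, float(input_weight))
        return InputProjection(n_channels, channel, post, weight, mode)
    if mode != "random":
        raise ValueError("mode must be 'one_to_one' or 'random'")
    rng = stream_rng(seed, "construction/input")
    draws = rng.random((n_channels, network.n_neurons)) < input_cscale
    channel, post = np.nonzero(draws)
    weight = np.empty(len(channel), dtype=np.float64)
    post_exc = network.is_excitatory[post]
    for name, mask in (("EE", post_exc), ("EI", ~post_exc)):
        weight[mask] = sample_weights(name, input_wscale, input_sh_w,
                                      int(mask.sum()), rng=rng)
    return InputProjection(n_channels, channel.astype(np.int64),
                           post.astype(np.int64), weight, mode)
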