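"""Separability and memory-trace analyses.

Fisher's discriminant ratio (FDR) on spike counts quantifies how well a
stimulus class is separated from the rest: between-class scatter of class
means over within-class scatter.  Network FDR sums per-time-bin FDRs of
population spike counts; neuronal FDR uses each neuron's spike count over
the whole recording.  The potentiated/depressed subnetwork is the set of
synapses whose weight change after learning crosses +/- a threshold
(default 1e-8); its node structure and Watts-Strogatz clustering
coefficient characterize the stored memory trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FDRResult",
    "SubnetworkGraph",
    "fisher_discriminant_ratio",
    "network_fdr",
    "extract_subnetwork",
    "clustering_coefficient",
    "critical_neuron_overlap",
]

#: Reported when between-class scatter is positive but within-class scatter
#: is exactly zero (perfect separation); documented sentinel, not infinity.
J_SENTINEL = 1e9


def fisher_discriminant_ratio(counts, labels) -> float:
    """FDR of per-trial counts grouped by class labels.

    ``J = sum_C (mu_C - mu)^2 / sum_C sum_{i in C} (S_i - mu_C)^2`` with
    ``mu`` the mean of class means.  Requires >= 2 nonempty classes.  A
    zero denominator yields 0 if the numerator is also zero, else the
    documented sentinel ``J_SENTINEL``.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    mus, within = [], 0.0
    for c in classes:
        grp = counts[labels == c]
        if len(grp) == 0:
            raise ValueError(f"class {c!r} is empty")
        mu_c = grp.mean()
        mus.append(mu_c)
        within += float(((grp - mu_c) ** 2).sum())
    mus = np.asarray(mus)
    between = float(((mus - mus.mean()) ** 2).sum())
    if within == 0.0:
        return 0.0 if between == 0.0 else J_SENTINEL
    return between / within


@dataclass
class FDRResult:
    per_bin: np.ndarray        # network FDR per time bin
    network_fdr: float         # sum over bins
    per_neuron: np.ndarray     # neuronal FDR over the whole recording
    labeling: Dict[str, Sequence[int]]
    bin_width: float


def network_fdr(records: Sequence, class_i: Sequence[int], bin_width: float = 0.01,
                window: Optional[tuple] = None) -> FDRResult:
    """Two-class FDR of network activity across stimuli.

    ``records`` is one spike record per stimulus (a common time grid);
    ``class_i`` gives the indices of Class I stimuli (e.g. the familiar
    one), the rest form Class II.  Network FDR is computed per time bin on
    population spike counts and summed; neuronal FDR is computed per
    neuron on whole-recording counts.
    """
    n = len(records)
    class_i = sorted(class_i)
    if not class_i or len(class_i) >= n:
        raise ValueError("class I must be a nonempty proper subset")
    labels = np.array([0 if i in class_i else 1 for i in range(n)])
    binned = np.vstack([r.binned_counts(bin_width, window) for r in records])
    per_bin = np.array([fisher_discriminant_ratio(binned[:, b], labels)
                        for b in range(binned.shape[1])])
    total_counts = np.vstack([r.counts(window) for r in records])  # (n, N)
    per_neuron = np.array([fisher_discriminant_ratio(total_counts[:, j], labels)
                           for j in range(total_counts.shape[1])])
    return FDRResult(per_bin=per_bin, network_fdr=float(per_bin.sum()),
                     per_neuron=per_neuron,
                     labeling={"class_i": class_i},
                     bin_width=bin_width)


@dataclass
class SubnetworkGraph:
    """Synapses whose weight change crossed +/- threshold, with endpoints."""

    potentiated: np.ndarray  # synapse indices
    depressed: np.ndarray
    pre: np.ndarray          # pre neuron of each potentiated synapse
    post: np.ndarray
    threshold: float

    @property
    def nodes(self) -> np.ndarray:
        """Endpoint neurons of the potentiated set."""
        return np.unique(np.concatenate([self.pre, self.post]))

    def node_roles(self) -> dict:
        pre_set, post_set = set(self.pre.tolist()), set(self.post.tolist())
        both = pre_set & post_set
        return {"pre_only": np.array(sorted(pre_set - both)),
                "post_only": np.array(sorted(post_set - both)),
                "both": np.array(sorted(both))}

    def to_graph(self) -> nx.Graph:
        """Undirected simple projection of the potentiated subnetwork."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes.tolist())
        g.add_edges_from(zip(self.pre.tolist(), self.post.tolist()))
        return g


def extract_subnetwork(pre: np.ndarray, post: np.ndarray,
                       weights_before: np.ndarray, weights_after: np.ndarray,
                       threshold: float = 1e-8) -> SubnetworkGraph:
    """Classify synapses by weight change: potentiated (dW > +threshold),
    depressed (dW < -threshold); nodes are the potentiated endpoints."""
    wb = np.asarray(weights_before, float)
    wa = np.asarray(weights_after, float)
    if wb.shape != wa.shape or len(wb) != len(pre):
        raise ValueError("mismatched synapse tables")
    dw = wa - wb
    pot = np.flatnonzero(dw > threshold)
    dep = np.flatnonzero(dw < -threshold)
    return SubnetworkGraph(potentiated=pot, depressed=dep,
                           pre=np.asarray(pre)[pot], post=np.asarray(post)[pot],
                           threshold=threshold)


def clustering_coefficient(subnetwork: SubnetworkGraph | nx.Graph) -> float:
    """Watts-Strogatz average clustering of the undirected potentiated
    subnetwork; isolated and degree-1 nodes contribute 0."""
    g = subnetwork.to_graph() if isinstance(subnetwork, SubnetworkGraph) else subnetwork
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return float(nx.average_clustering(g, count_zeros=True))


def critical_neuron_overlap(neuronal_fdr: np.ndarray, subnetwork_nodes,
                            k: int = 200, n_total: Optional[int] = None) -> dict:
    """Overlap of the top-k FDR neurons ("critical neurons") with the
    subnetwork node set, plus the chance expectation k*|nodes|/N.

    Ranking is by FDR descending, ties broken by neuron index.
    """
    fdr = np.asarray(neuronal_fdr, dtype=float)
    if k < 1 or k > len(fdr):
        raise ValueError("k out of range")
    order = np.lexsort((np.arange(len(fdr)), -fdr))
    top = set(order[:k].tolist())
    nodes = set(int(i) for i in np.asarray(subnetwork_nodes).ravel())
    n_total = len(fdr) if n_total is None else n_total
    overlap = len(top & nodes)
    return {"overlap": overlap,
            "top_k": np.array(sorted(top)),
            "chance": k * len(nodes) / n_total}
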