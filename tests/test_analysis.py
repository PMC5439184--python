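"""Fisher discriminant ratios, subnetwork extraction, clustering."""

import networkx as nx
import numpy as np
import pytest

from famnet import (SpikeRecord, clustering_coefficient,
                    critical_neuron_overlap, extract_subnetwork,
                    fisher_discriminant_ratio, network_fdr)
from famnet.analysis import J_SENTINEL


class TestFDR:
    def test_hand_computed_example(self):
        # classes {1,2} vs {3,4}: between = 2, within = 1
        j = fisher_discriminant_ratio([1, 2, 3, 4], [0, 0, 1, 1])
        assert j == pytest.approx(2.0)

    def test_identical_class_means_zero(self):
        j = fisher_discriminant_ratio([1, 3, 1, 3], [0, 0, 1, 1])
        assert j == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fisher_discriminant_ratio([1, 2, 3], [0, 0, 0])

    def test_zero_within_scatter_sentinel(self):
        assert fisher_discriminant_ratio([1, 1, 2, 2], [0, 0, 1, 1]) \
            == J_SENTINEL
        assert fisher_discriminant_ratio([1, 1, 1, 1], [0, 0, 1, 1]) == 0.0

    def test_shift_invariance_and_scale(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(10, size=40).astype(float)
        labels = np.repeat([0, 1], 20)
        j0 = fisher_discriminant_ratio(counts, labels)
        assert fisher_discriminant_ratio(counts + 7.0, labels) \
            == pytest.approx(j0)
        assert fisher_discriminant_ratio(counts * 3.0, labels) \
            == pytest.approx(j0)

    def test_true_labels_beat_permutations(self):
        rng = np.random.default_rng(1)
        counts = np.concatenate([rng.normal(20, 1, 15), rng.normal(10, 1, 15)])
        labels = np.repeat([0, 1], 15)
        j_true = fisher_discriminant_ratio(counts, labels)
        j_perm = [fisher_discriminant_ratio(counts, rng.permutation(labels))
                  for _ in range(200)]
        assert j_true > np.quantile(j_perm, 0.99)


def _record(times_by_neuron, n_neurons, duration=1.0):
    ids, ts = [], []
    for n, t in times_by_neuron.items():
        ids.extend([n] * len(t))
        ts.extend(t)
    return SpikeRecord(np.asarray(ids, int), np.asarray(ts, float),
                       duration, 2e-4, n_neurons)


class TestNetworkFDR:
    def _records(self):
        rng = np.random.default_rng(2)
        recs = []
        for i in range(5):
            rate = 40 if i == 0 else 10  # stimulus 0 is distinctive
            times = {n: np.sort(rng.uniform(0, 1, rng.poisson(rate)))
                     for n in range(4)}
            recs.append(_record(times, 4))
        return recs

    def test_sum_consistency_and_argmax(self):
        recs = self._records()
        res = network_fdr(recs, class_i=[0], bin_width=0.1)
        assert res.network_fdr == pytest.approx(res.per_bin.sum())
        # labeling each stimulus in turn: the distinctive one maximizes FDR
        totals = [network_fdr(recs, class_i=[i], bin_width=0.1).network_fdr
                  for i in range(5)]
        assert int(np.argmax(totals)) == 0

    def test_identical_records_give_zero(self):
        t = {0: [0.1, 0.3], 1: [0.2]}
        recs = [_record(t, 2) for _ in range(4)]
        res = network_fdr(recs, class_i=[1], bin_width=0.25)
        assert res.network_fdr == 0.0
        assert np.all(res.per_neuron == 0.0)

    def test_improper_class_rejected(self):
        recs = [_record({0: [0.1]}, 1) for _ in range(3)]
        with pytest.raises(ValueError):
            network_fdr(recs, class_i=[])
        with pytest.raises(ValueError):
            network_fdr(recs, class_i=[0, 1, 2])


class TestSubnetwork:
    def test_threshold_rule(self):
        pre = np.array([0, 1, 2])
        post = np.array([3, 4, 5])
        wb = np.array([1e-8, 3e-8, 2e-8])
        wa = wb + np.array([2e-8, -2e-8, 0.5e-8])
        sub = extract_subnetwork(pre, post, wb, wa, threshold=1e-8)
        assert list(sub.potentiated) == [0]
        assert list(sub.depressed) == [1]
        assert set(sub.nodes.tolist()) == {0, 3}

    def test_no_learning_gives_empty_sets(self):
        w = np.array([1e-8, 2e-8])
        sub = extract_subnetwork([0, 1], [1, 0], w, w)
        assert len(sub.potentiated) == 0 and len(sub.depressed) == 0

    def test_node_roles_partition(self):
        pre = np.array([0, 1, 1, 2])
        post = np.array([1, 2, 3, 0])
        wb = np.zeros(4)
        wa = np.full(4, 2e-8)
        sub = extract_subnetwork(pre, post, wb, wa)
        roles = sub.node_roles()
        all_nodes = np.concatenate([roles["pre_only"], roles["post_only"],
                                    roles["both"]])
        assert sorted(all_nodes.tolist()) == sorted(sub.nodes.tolist())
        assert len(all_nodes) == len(set(all_nodes.tolist()))

    def test_mismatched_tables_rejected(self):
        with pytest.raises(ValueError):
            extract_subnetwork([0], [1], np.zeros(1), np.zeros(2))


class TestClustering:
    def test_triangle_and_star(self):
        tri = nx.cycle_graph(3)
        assert clustering_coefficient(tri) == 1.0
        star = nx.star_graph(3)
        assert clustering_coefficient(star) == 0.0

    def test_erdos_renyi_matches_p(self):
        p = 0.3
        vals = [nx.average_clustering(nx.gnp_random_graph(60, p, seed=s))
                for s in range(20)]
        mine = [clustering_coefficient(nx.gnp_random_graph(60, p, seed=s))
                for s in range(20)]
        assert np.mean(mine) == pytest.approx(np.mean(vals))
        assert np.mean(mine) == pytest.approx(p, abs=0.03)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            clustering_coefficient(nx.Graph())


class TestCriticalNeurons:
    def test_disjoint_and_full_overlap(self):
        fdr = np.arange(10.0)[::-1]  # neuron 0 has the largest FDR
        res = critical_neuron_overlap(fdr, [7, 8, 9], k=3)
        assert res["overlap"] == 0
        res = critical_neuron_overlap(fdr, [0, 1, 2], k=3)
        assert res["overlap"] == 3

    def test_tie_break_by_index(self):
        fdr = np.zeros(6)
        res = critical_neuron_overlap(fdr, [0, 1], k=2)
        assert list(res["top_k"]) == [0, 1]
        assert res["overlap"] == 2

    def test_chance_matches_hypergeometric_resampling(self):
        rng = np.random.default_rng(3)
        n, k, m = 200, 30, 50  # N neurons, top-k, subnetwork size
        nodes = rng.choice(n, m, replace=False)
        res = critical_neuron_overlap(rng.random(n), nodes, k=k)
        sims = [len(set(rng.choice(n, k, replace=False)) & set(nodes))
                for _ in range(2000)]
        assert res["chance"] == pytest.approx(k * m / n)
        assert np.mean(sims) == pytest.approx(res["chance"], rel=0.1)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            critical_neuron_overlap(np.ones(5), [0], k=6)
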