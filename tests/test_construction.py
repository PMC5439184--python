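"""Reservoir construction: grid, connectivity law, weight distributions."""

import math

import numpy as np
import pytest

from famnet import (BASE_C, NetworkConfig, build_grid, build_input_projection,
                    build_network, connection_probability, sample_weights)


class TestBuildGrid:
    @pytest.mark.parametrize("dims,n", [((10, 10, 5), 500), ((1, 1, 1), 1),
                                        ((6, 6, 3), 108)])
    def test_neuron_count(self, dims, n):
        positions, is_exc = build_grid(dims)
        assert len(positions) == n
        assert len(is_exc) == n

    def test_grid_coordinates_and_distance(self):
        positions, _ = build_grid((5, 5, 2))
        # integer coordinates covering the grid exactly once
        assert positions.dtype.kind == "i"
        assert len(np.unique(positions, axis=0)) == 50
        # 3-4-5 triangle on the grid
        a, b = np.array([0, 0, 0]), np.array([3, 4, 0])
        assert np.linalg.norm(a - b) == 5.0

    def test_excitatory_fraction_is_ceil(self):
        for dims in ((10, 10, 5), (3, 3, 3), (2, 2, 1)):
            _, is_exc = build_grid(dims, 0.75, seed=3)
            assert is_exc.sum() == math.ceil(0.75 * is_exc.size)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            build_grid((0, 5, 5))


class TestConnectionProbability:
    def test_zero_distance_gives_base_probability(self):
        p = connection_probability([0, 0, 0], [0, 0, 0], "EE", 2.0, 1.0)
        assert p == pytest.approx(0.3)

    def test_infinite_lambda_removes_distance(self):
        p_near = connection_probability([0, 0, 0], [1, 0, 0], "EE",
                                        math.inf, 0.04)
        p_far = connection_probability([0, 0, 0], [40, 40, 4], "EE",
                                       math.inf, 0.04)
        assert p_near == pytest.approx(0.012)
        assert p_far == pytest.approx(0.012)

    def test_distance_equal_lambda(self):
        p = connection_probability([0, 0, 0], [2, 0, 0], "EE", 2.0, 1.0)
        assert p == pytest.approx(0.3 * math.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("ct,base", sorted(BASE_C.items()))
    def test_base_values(self, ct, base):
        assert connection_probability([0, 0, 0], [0, 0, 0], ct, 1.0, 1.0) \
            == pytest.approx(base)

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            connection_probability([0, 0, 0], [1, 0, 0], "XX", 2.0, 1.0)


class TestSampleWeights:
    def test_gamma_moments(self):
        w = sample_weights("EE", wscale=0.5, sh_w=0.25, n=100_000, seed=11)
        # mean = W_base * wscale = 1.5e-8, CV = SH_W
        assert w.mean() == pytest.approx(1.5e-8, rel=0.01)
        assert w.std() / w.mean() == pytest.approx(0.25, rel=0.02)

    def test_inhibitory_draws_negative(self):
        for ct in ("IE", "II"):
            w = sample_weights(ct, 1.0, 0.7, 1000, seed=4)
            assert (w < 0).all()

    def test_empty_draw(self):
        assert len(sample_weights("EE", 1.0, 0.7, 0)) == 0


class TestBuildNetwork:
    def test_deterministic_given_seed(self, small_config):
        a = build_network(small_config)
        b = build_network(small_config)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
        assert np.array_equal(a.weight, b.weight)

    def test_no_autapses_no_duplicates(self, small_network):
        assert (small_network.pre != small_network.post).all()
        pairs = small_network.pre * small_network.n_neurons + small_network.post
        assert len(np.unique(pairs)) == len(pairs)

    def test_inhibitory_synapses_negative_static(self, small_network):
        inhib = ~small_network.is_excitatory[small_network.pre]
        assert (small_network.weight[inhib] < 0).all()
        assert (~small_network.is_plastic[inhib]).all()
        assert (small_network.is_plastic[~inhib]).all()

    def test_synapse_count_matches_bernoulli_expectation(self):
        """Total edges across seeds agree with sum of P(D) within 3 SE."""
        cfg_kw = dict(dims=(6, 6, 3), lambda_=2.0, wscale=0.9, sh_w=0.25)
        nets = [build_network(NetworkConfig(seed=s, **cfg_kw)) for s in range(8)]
        # expectation: sum over ordered pairs of C(pre,post)*exp(-D^2/lam^2)
        exp_total, var_total = 0.0, 0.0
        for net in nets:
            pos = net.positions.astype(float)
            d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
            e = np.where(net.is_excitatory, 1, 0)
            cmat = np.array([[BASE_C["II"], BASE_C["IE"]],
                             [BASE_C["EI"], BASE_C["EE"]]])
            p = cmat[e[:, None], e[None, :]] * np.exp(-d2 / 4.0)
            np.fill_diagonal(p, 0.0)
            exp_total += p.sum()
            var_total += (p * (1 - p)).sum()
        observed = sum(net.n_synapses for net in nets)
        assert abs(observed - exp_total) < 3 * math.sqrt(var_total)


class TestInputProjection:
    def test_one_to_one(self, small_network):
        proj = build_input_projection(small_network, (6, 6), mode="one_to_one")
        assert len(proj) == 36
        assert np.all(proj.weight == 2.7e-7)
        # every first-layer neuron contacted exactly once
        first = small_network.positions[proj.post]
        assert (first[:, 2] == 0).all()
        assert len(np.unique(proj.post)) == 36

    def test_one_to_one_dimension_mismatch(self, small_network):
        with pytest.raises(ValueError):
            build_input_projection(small_network, (5, 5), mode="one_to_one")

    def test_empty_input_layer_rejected(self, small_network):
        with pytest.raises(ValueError):
            build_input_projection(small_network, (0, 0), mode="random")

    def test_random_projection_count(self, small_network):
        proj = build_input_projection(small_network, (10, 10), mode="random",
                                      input_cscale=0.05, seed=5)
        n_expected = 100 * small_network.n_neurons * 0.05
        sd = math.sqrt(n_expected * 0.95)
        assert abs(len(proj) - n_expected) < 4 * sd
        assert (proj.weight > 0).all()  # input neurons are excitatory
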