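"""Gaussian memberships, uninorm/nullnorm algebra and logical neurons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efnn import neuro_layers as nl
from efnn.neuro_layers import (MIN_MAX, PRODUCT_PROBSUM, GaussianSet, LogicNeuron,
                               nullnorm, uninorm, uninullnorm)

unit = st.floats(min_value=0.0, max_value=1.0)


class TestGaussianMembership:
    def test_center_and_one_sigma(self):
        gs = GaussianSet(center=2.0, sigma=0.5)
        assert nl.gaussian_membership(2.0, gs) == pytest.approx(1.0)
        assert nl.gaussian_membership(2.5, gs) == pytest.approx(np.exp(-0.5))

    def test_even_function(self, rng):
        gs = GaussianSet(center=1.0, sigma=2.0)
        for delta in rng.normal(size=5):
            assert nl.gaussian_membership(1 + delta, gs) == pytest.approx(
                nl.gaussian_membership(1 - delta, gs))

    def test_positive_sigma_required(self):
        with pytest.raises(ValueError):
            GaussianSet(center=0.0, sigma=0.0)


class TestUninorm:
    @pytest.mark.parametrize("y", [0.0, 0.3, 0.7, 1.0])
    def test_identity_element(self, y):
        assert uninorm(0.5, y, 0.5) == pytest.approx(y, abs=1e-12)

    def test_known_values(self):
        assert uninorm(0.25, 0.25, 0.5) == pytest.approx(0.125)
        assert uninorm(0.75, 0.75, 0.5) == pytest.approx(0.875)

    def test_limits(self):
        assert uninorm(0.3, 0.6, 0.0) == pytest.approx(0.3 + 0.6 - 0.18)
        assert uninorm(0.3, 0.6, 1.0) == pytest.approx(0.18)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(unit, unit, st.floats(min_value=0.01, max_value=0.99))
    def test_commutative_and_closed(self, x, y, g):
        a, b = uninorm(x, y, g), uninorm(y, x, g)
        assert a == pytest.approx(b, abs=1e-12)
        assert -1e-12 <= a <= 1 + 1e-12


class TestNullnorm:
    @pytest.mark.parametrize("y", [0.0, 0.3, 0.7, 1.0])
    def test_absorbing_element(self, y):
        assert nullnorm(0.5, y, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_known_values(self):
        assert nullnorm(0.25, 0.25, 0.5) == pytest.approx(0.375)
        assert nullnorm(0.75, 0.75, 0.5) == pytest.approx(0.625)

    def test_limits(self):
        assert nullnorm(0.3, 0.6, 0.0) == pytest.approx(0.18)
        assert nullnorm(0.3, 0.6, 1.0) == pytest.approx(0.3 + 0.6 - 0.18)


class TestUninullnorm:
    def test_degenerate_knots(self):
        # beta = 1 -> single uninorm with identity g; beta = 0 -> identity u
        for x, y in [(0.2, 0.7), (0.9, 0.9), (0.1, 0.1)]:
            assert uninullnorm(x, y, 1.0, 0.3, 0.8) == pytest.approx(
                uninorm(x, y, 0.3))
            assert uninullnorm(x, y, 0.0, 0.3, 0.8) == pytest.approx(
                uninorm(x, y, 0.8))

    def test_branches_agree_at_knot(self):
        beta, g, u = 0.4, 0.2, 0.7
        lower = beta * uninorm(1.0, 1.0, g / beta)
        upper = beta + (1 - beta) * uninorm(0.0, 0.0, (u - beta) / (1 - beta))
        assert lower == pytest.approx(beta)
        assert upper == pytest.approx(beta)
        assert uninullnorm(beta, beta, beta, g, u) == pytest.approx(beta)

    @pytest.mark.parametrize("g,u,beta,expected", [
        (0, 0, 0, "tconorm"), (0, 0, 1, "tconorm"), (0, 1, 0, "tnorm"),
        (0, 1, 1, "tconorm"), (1, 0, 0, "tconorm"), (1, 0, 1, "tnorm"),
        (1, 1, 0, "tnorm"), (1, 1, 1, "tnorm"),
    ])
    def test_parameter_corners(self, g, u, beta, expected):
        """At the corners of the (g, u, beta) cube the composed operator
        collapses to the pure conjunction or disjunction."""
        grid = np.linspace(0, 1, 7)
        for x in grid:
            for y in grid:
                ref = x * y if expected == "tnorm" else x + y - x * y
                assert uninullnorm(x, y, beta, g, u) == pytest.approx(ref, abs=1e-12)


class TestAggregatorProperties:
    def _ops(self):
        return [lambda x, y: uninorm(x, y, 0.5),
                lambda x, y: nullnorm(x, y, 0.5),
                lambda x, y: uninullnorm(x, y, 0.5, 0.25, 0.75),
                PRODUCT_PROBSUM.tnorm, PRODUCT_PROBSUM.tconorm]

    def test_monotone_and_closed_on_grid(self, rng):
        xs = rng.random(300)
        ys = rng.random(300)
        eps = 1e-9
        for op in self._ops():
            vals = np.array([op(x, y) for x, y in zip(xs, ys)])
            assert np.all(vals >= -eps) and np.all(vals <= 1 + eps)
            bumped = np.array([op(min(x + 0.05, 1.0), y) for x, y in zip(xs, ys)])
            assert np.all(bumped >= vals - 1e-12)

    def test_norm_pair_axioms_on_grid(self):
        grid = np.linspace(0, 1, 5)
        for norms in (PRODUCT_PROBSUM, MIN_MAX):
            for x in grid:
                assert norms.tnorm(1.0, x) == pytest.approx(x)
                assert norms.tconorm(0.0, x) == pytest.approx(x)
                for y in grid:
                    assert norms.tnorm(x, y) == pytest.approx(norms.tnorm(y, x))
                    assert norms.tconorm(x, y) == pytest.approx(norms.tconorm(y, x))


class TestRelevancyTransform:
    def test_full_and_zero_relevance(self):
        assert nl.relevancy_transform(1.0, 0.8, "UNI", g=0.3) == pytest.approx(0.8)
        assert nl.relevancy_transform(0.0, 0.8, "UNI", g=0.3) == pytest.approx(0.3)
        assert nl.relevancy_transform(0.0, 0.8, "NULL", u=0.6) == pytest.approx(0.6)

    def test_blend(self):
        assert nl.relevancy_transform(0.5, 0.8, "UNI", g=0.5) == pytest.approx(0.65)

    def test_uninull_fill_depends_on_region(self):
        assert nl.relevancy_transform(0.0, 0.2, "UNINULL", g=0.3, u=0.7,
                                      beta=0.5) == pytest.approx(0.3)
        assert nl.relevancy_transform(0.0, 0.9, "UNINULL", g=0.3, u=0.7,
                                      beta=0.5) == pytest.approx(0.7)


def _neuron(kind, n, **kw):
    gsets = [GaussianSet(center=0.0, sigma=1.0, dimension=j) for j in range(n)]
    return LogicNeuron(kind=kind, gaussians=gsets, **kw)


class TestNeuronActivation:
    def test_or_neuron_example(self):
        z = nl.neuron_activation(_neuron("OR", 2), np.array([0.8, 0.9]),
                                 np.array([1.0, 0.0]))
        assert z == pytest.approx(0.8)

    def test_and_neuron_strict_zero_weights(self):
        a = np.array([0.3, 0.6, 0.9])
        z = nl.neuron_activation(_neuron("AND", 3, strict_weights=True), a,
                                 np.zeros(3))
        assert z == pytest.approx(np.prod(a))

    def test_and_neuron_default_zero_weights_neutral(self):
        # with importance semantics, weight 0 means "ignore this feature"
        a = np.array([0.3, 0.6, 0.9])
        z = nl.neuron_activation(_neuron("AND", 3), a, np.zeros(3))
        assert z == pytest.approx(1.0)

    def test_uni_single_input_full_weight(self):
        z = nl.neuron_activation(_neuron("UNI", 1), np.array([0.42]),
                                 np.array([1.0]))
        assert z == pytest.approx(0.42)

    @pytest.mark.parametrize("kind", nl.NEURON_KINDS)
    def test_closure(self, kind, rng):
        for _ in range(20):
            a, w = rng.random(4), rng.random(4)
            z = nl.neuron_activation(_neuron(kind, 4), a, w)
            assert -1e-12 <= z <= 1 + 1e-12


class TestLayerActivations:
    @pytest.mark.parametrize("kind", nl.NEURON_KINDS)
    def test_fast_path_matches_slow(self, kind, rng):
        L, n = 5, 4
        centers = rng.normal(size=(L, n))
        sigmas = rng.random((L, n)) + 0.2
        x = rng.normal(size=n)
        w = rng.random(n)
        neurons = [LogicNeuron(kind=kind,
                               gaussians=[GaussianSet(centers[l, j], sigmas[l, j],
                                                      dimension=j)
                                          for j in range(n)])
                   for l in range(L)]
        slow = nl.layer_activations(neurons, x, w)
        fast = nl.layer_activations_fast(centers, sigmas, x, w, kind)
        assert np.allclose(slow, fast, atol=1e-12)

    def test_feature_permutation_invariance(self, rng):
        n = 5
        centers = rng.normal(size=(3, n))
        sigmas = rng.random((3, n)) + 0.2
        x, w = rng.normal(size=n), rng.random(n)
        base = nl.layer_activations_fast(centers, sigmas, x, w, "AND")
        perm = rng.permutation(n)
        permuted = nl.layer_activations_fast(centers[:, perm], sigmas[:, perm],
                                             x[perm], w[perm], "AND")
        assert np.allclose(base, permuted, atol=1e-12)

    def test_empty_layer(self):
        assert nl.layer_activations([], np.zeros(2), np.ones(2)).size == 0
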