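"""Behaviour of the EP engine: reductions, symmetries, predictive form."""

import numpy as np
import pytest

from nbsbm import (Dataset, EPControls, NoisePrior, SlabSpec, ValidationError,
                   ep_fit, generate_dataset, generate_network, noise_estimate,
                   predict_proba)
from .conftest import random_network, small_instance


def _edgeless(d, lam=0.0, seed=0):
    return random_network(d, lam, 0.0, seed, p_edge=0.0)


class TestPriorReduction:
    def test_no_data_returns_prior(self):
        net = _edgeless(2)
        ds = Dataset(X=np.ones((0, 3)), y=np.zeros(0), gene_names=net.nodes)
        post = ep_fit(ds, net, SlabSpec.constant(2), NoisePrior())
        assert np.allclose(post.incl_prob, 0.5)
        assert np.allclose(post.beta_mean, 0.0)
        assert (post.eps_a, post.eps_b) == (1.0, 8.0)

    def test_single_class_labels_rejected(self):
        net = _edgeless(1)
        ds = Dataset.from_features(np.ones((4, 1)), np.ones(4), net.nodes)
        with pytest.raises(ValidationError):
            ep_fit(ds, net, SlabSpec.constant(1), NoisePrior())


class TestSignalDetection:
    def test_separating_gene_found_with_correct_sign(self):
        rng = np.random.default_rng(4)
        net = _edgeless(1)
        x = np.concatenate([rng.uniform(0.5, 2, 10), rng.uniform(-2, -0.5, 10)])
        ds = Dataset.from_features(x[:, None], np.sign(x), net.nodes)
        post = ep_fit(ds, net, SlabSpec.constant(1), NoisePrior())
        assert post.incl_prob[0] > 0.5
        assert post.beta_mean[1] > 0


class TestSymmetries:
    def test_label_flip_negates_weights_only(self):
        ds, net = small_instance(3, 8, 0.5, 1.0, seed=9)
        slab, noise = SlabSpec.constant(3), NoisePrior()
        ctl = EPControls(seed=5)
        a = ep_fit(ds, net, slab, noise, ctl)
        flipped = Dataset(X=ds.X, y=-ds.y, gene_names=ds.gene_names)
        b = ep_fit(flipped, net, slab, noise, ctl)
        assert np.allclose(a.beta_mean, -b.beta_mean, atol=1e-8)
        assert np.allclose(a.incl_prob, b.incl_prob, atol=1e-8)
        assert np.isclose(noise_estimate(a), noise_estimate(b), atol=1e-8)

    def test_gene_permutation_equivariance(self):
        ds, net = small_instance(3, 8, 0.5, 1.0, seed=13)
        slab, noise = SlabSpec.constant(3), NoisePrior()
        ctl = EPControls(seed=5, tol=1e-9, max_iter=500)
        a = ep_fit(ds, net, slab, noise, ctl)
        perm = [2, 0, 1]
        ds_p = Dataset.from_features(ds.features[:, perm], ds.y,
                                     [ds.gene_names[i] for i in perm])
        net_p = net.aligned(ds_p.gene_names)
        b = ep_fit(ds_p, net_p, slab, noise, ctl)
        assert np.allclose(a.incl_prob[perm], b.incl_prob, atol=1e-4)
        assert np.allclose(a.beta_mean[1:][perm], b.beta_mean[1:], atol=1e-4)

    def test_sbc_reduction_is_bitwise(self):
        """gamma = 0 on the full network must equal the edgeless fit exactly."""
        ds, net = small_instance(4, 10, 0.5, 0.0, seed=17)
        slab, noise = SlabSpec.constant(4), NoisePrior()
        ctl = EPControls(seed=7)
        full = ep_fit(ds, net.with_hyperparams(0.5, 0.0), slab, noise, ctl)
        bare = ep_fit(ds, _edgeless(4, lam=0.5, seed=17).aligned(ds.gene_names),
                      slab, noise, ctl)
        assert np.array_equal(full.incl_prob, bare.incl_prob)
        assert np.array_equal(full.beta_mean, bare.beta_mean)
        assert np.array_equal(full.beta_var, bare.beta_var)
        assert full.eps_a == bare.eps_a and full.eps_b == bare.eps_b
        assert full.iterations == bare.iterations


class TestOutputContracts:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_probabilities_and_variances_valid(self, seed):
        ds, net = small_instance(3, 8, 0.5, 1.0, seed=50 + seed)
        post = ep_fit(ds, net, SlabSpec.constant(3), NoisePrior(), EPControls(seed=seed))
        assert np.all((post.incl_prob >= 0) & (post.incl_prob <= 1))
        assert np.all(post.beta_var > 0)
        probs = predict_proba(post, ds.X)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_serialization_roundtrip(self):
        ds, net = small_instance(2, 6, 0.5, 1.0, seed=3)
        post = ep_fit(ds, net, SlabSpec.constant(2), NoisePrior())
        doc = post.to_json()
        assert '"converged"' in doc and ds.gene_names[0] in doc


class TestPredictProba:
    def test_symmetric_posterior_gives_half(self):
        net = _edgeless(2)
        ds = Dataset(X=np.ones((0, 3)), y=np.zeros(0), gene_names=net.nodes)
        post = ep_fit(ds, net, SlabSpec.constant(2), NoisePrior())
        x = np.array([1.0, 0.7, -1.3])
        assert np.isclose(predict_proba(post, x), 0.5)

    def test_antisymmetry_under_negation(self):
        ds, net = small_instance(2, 8, 0.5, 0.0, seed=8)
        post = ep_fit(ds, net, SlabSpec.constant(2), NoisePrior())
        x = np.array([1.0, 0.4, -0.9])
        # negating the whole input (including bias) mirrors the margin
        assert np.isclose(predict_proba(post, x) + predict_proba(post, -x), 1.0)

    def test_degenerate_zero_variance_point(self):
        net = _edgeless(1)
        ds = Dataset(X=np.ones((0, 2)), y=np.zeros(0), gene_names=net.nodes)
        post = ep_fit(ds, net, SlabSpec.constant(1), NoisePrior())
        post.beta_cov = None
        post.beta_var = np.zeros(2)
        assert predict_proba(post, np.array([0.0, 0.0])) == 0.5


class TestNoiseEstimate:
    def test_prior_only_mean(self):
        net = _edgeless(1)
        ds = Dataset(X=np.ones((0, 2)), y=np.zeros(0), gene_names=net.nodes)
        post = ep_fit(ds, net, SlabSpec.constant(1), NoisePrior(a0=1, b0=8))
        assert np.isclose(noise_estimate(post), 1.0 / 9.0)

    def test_flip_rate_recovery(self):
        hits = 0
        for seed in range(3):
            net = generate_network(4, 5, seed=seed)
            ds, truth = generate_dataset(net, 200, 1, 1.0, flip_rate=0.2, seed=seed)
            post = ep_fit(ds, net.with_hyperparams(0.0, 0.0), SlabSpec.constant(20),
                          NoisePrior(), EPControls(seed=seed))
            if 0.1 <= noise_estimate(post) <= 0.3:
                hits += 1
        assert hits >= 2

    def test_clean_data_contracts_below_prior_mean(self):
        net = generate_network(4, 5, seed=1)
        ds, _ = generate_dataset(net, 200, 1, 1.5, flip_rate=0.0, seed=1)
        post = ep_fit(ds, net.with_hyperparams(0.0, 0.0), SlabSpec.constant(20),
                      NoisePrior(), EPControls(seed=1))
        assert noise_estimate(post) < NoisePrior().mean
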