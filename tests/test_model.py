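"""Likelihood, spike-and-slab joint density and tabular IO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nbsbm import (Dataset, NoisePrior, SlabSpec, ValidationError, heaviside,
                   likelihood_point, load_dataset, log_joint)
from .conftest import random_network


class TestHeaviside:
    @pytest.mark.parametrize("t,expected", [(3.2, 1.0), (-0.001, 0.0), (0.0, 0.5)])
    def test_values(self, t, expected):
        assert heaviside(t) == expected


class TestLikelihoodPoint:
    def test_correct_side(self):
        assert np.isclose(likelihood_point(1.0, np.array([2.0]), np.array([1.0]), 0.1), 0.9)

    def test_wrong_side(self):
        assert np.isclose(likelihood_point(-1.0, np.array([2.0]), np.array([1.0]), 0.1), 0.1)

    def test_complete_noise_washes_out(self):
        assert likelihood_point(1.0, np.array([5.0]), np.array([1.0]), 0.5) == 0.5

    def test_eps_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            likelihood_point(1.0, np.array([1.0]), np.array([1.0]), 0.7)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0),
           eps=st.floats(0.0, 0.5))
    def test_error_counting_scale_invariance(self, seed, scale, eps):
        """The likelihood depends only on the sign of the margin, so positive
        rescaling of the weights changes nothing."""
        rng = np.random.default_rng(seed)
        beta = rng.standard_normal(4)
        x = rng.standard_normal(4)
        y = rng.choice([-1.0, 1.0])
        assert np.isclose(likelihood_point(y, beta, x, eps),
                          likelihood_point(y, scale * beta, x, eps))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), eps=st.floats(0.0, 0.5))
    def test_bounded_by_noise_floor(self, seed, eps):
        rng = np.random.default_rng(seed)
        val = likelihood_point(1.0, rng.standard_normal(3), rng.standard_normal(3), eps)
        assert min(eps, 1 - eps) - 1e-12 <= val <= max(eps, 1 - eps) + 1e-12


class TestLogJoint:
    def _fixture(self, seed=0, d=2, n=2):
        rng = np.random.default_rng(seed)
        net = random_network(d, 0.3, 0.7, seed)
        y = np.array([1.0, -1.0] * (n // 2) + ([1.0] if n % 2 else []))
        ds = Dataset.from_features(rng.standard_normal((n, d)), y, net.nodes)
        return ds, net, SlabSpec.constant(d), NoisePrior()

    def test_prior_only_reduction(self):
        net = random_network(2, 0.0, 0.0, 0)
        ds = Dataset(X=np.ones((0, 3)), y=np.zeros(0), gene_names=net.nodes)
        beta = np.array([0.7, 0.0, 0.0])
        val = log_joint(beta, np.zeros(2), 0.2, ds, SlabSpec.constant(2),
                        NoisePrior(), net)
        expected = stats.norm.logpdf(0.7) + stats.beta.logpdf(0.2, 1, 8)
        assert np.isclose(val, expected)

    def test_label_flip_sign_symmetry(self):
        ds, net, slab, noise = self._fixture()
        beta = np.array([0.3, -1.2, 0.8])
        z = np.ones(2)
        flipped = Dataset(X=ds.X, y=-ds.y, gene_names=ds.gene_names)
        a = log_joint(beta, z, 0.1, ds, slab, noise, net)
        b = log_joint(-beta, z, 0.1, flipped, slab, noise, net)
        assert np.isclose(a, b)

    def test_term_by_term_hand_computation(self):
        """Cross-check against an explicit sum of the four log factors."""
        ds, net, slab, noise = self._fixture(seed=3)
        beta = np.array([0.2, 0.9, 0.0])
        z = np.array([1.0, 0.0])
        eps = 0.15
        margins = ds.y * (ds.X @ beta)
        lik = sum(np.log(eps if m < 0 else (1 - eps) if m > 0 else 0.5) for m in margins)
        prior_b = stats.norm.logpdf(0.2) + stats.norm.logpdf(0.9)
        mrf = net.lambda_ * 1.0 + net.coupling_sign * net.gamma_ * float(
            z @ net.laplacian @ z)
        expected = lik + prior_b + mrf + stats.beta.logpdf(eps, 1, 8)
        assert np.isclose(log_joint(beta, z, eps, ds, slab, noise, net), expected)

    def test_support_violation_rejected(self):
        ds, net, slab, noise = self._fixture()
        with pytest.raises(ValidationError):
            log_joint(np.array([0.0, 0.5, 0.1]), np.array([1.0, 0.0]), 0.1,
                      ds, slab, noise, net)

    def test_gene_permutation_invariance(self):
        ds, net, slab, noise = self._fixture(seed=7, d=3, n=4)
        beta = np.array([0.1, 0.4, -0.3, 0.9])
        z = np.ones(3)
        perm = [2, 0, 1]
        ds_p = Dataset.from_features(ds.features[:, perm], ds.y,
                                     [ds.gene_names[i] for i in perm])
        net_p = net.aligned(ds_p.gene_names)
        beta_p = np.concatenate([[beta[0]], beta[1:][perm]])
        a = log_joint(beta, z, 0.1, ds, slab, noise, net)
        b = log_joint(beta_p, z[perm], 0.1, ds_p, slab, noise, net_p)
        assert np.isclose(a, b)


class TestDatasetValidation:
    def test_bias_column_enforced(self):
        with pytest.raises(ValidationError):
            Dataset(X=np.zeros((2, 3)), y=np.array([1.0, -1.0]), gene_names=("a", "b"))

    def test_labels_must_be_pm1(self):
        with pytest.raises(ValidationError):
            Dataset.from_features(np.zeros((2, 1)), [0.0, 1.0], ("a",))


class TestIO:
    def _write(self, tmp_path, genes_as_rows=True):
        expr = tmp_path / "expr.tsv"
        rows = ["gene\ts1\ts2\ts3", "g1\t0.1\t0.2\t0.3", "g2\t1.0\t2.0\t3.0"]
        expr.write_text("\n".join(rows) + "\n")
        labels = tmp_path / "labels.tsv"
        labels.write_text("s1\t1\ns2\t-1\ns3\tsensitive\n")
        return expr, labels

    def test_load_and_orient(self, tmp_path):
        expr, labels = self._write(tmp_path)
        ds = load_dataset(expr, labels)
        assert ds.gene_names == ("g1", "g2")
        assert ds.n == 3
        assert list(ds.y) == [1.0, -1.0, 1.0]
        assert np.allclose(ds.features[:, 1], [1.0, 2.0, 3.0])

    def test_transposed_table_detected(self, tmp_path):
        expr = tmp_path / "expr_t.tsv"
        expr.write_text("sample\tg1\tg2\ns1\t0.1\t1.0\ns2\t0.2\t2.0\ns3\t0.3\t3.0\n")
        labels = tmp_path / "labels.tsv"
        labels.write_text("s1\t1\ns2\t-1\ns3\t1\n")
        ds = load_dataset(expr, labels)
        assert ds.gene_names == ("g1", "g2")
        assert np.allclose(ds.features[:, 0], [0.1, 0.2, 0.3])

    def test_missing_samples_rejected(self, tmp_path):
        expr, _ = self._write(tmp_path)
        labels = tmp_path / "bad.tsv"
        labels.write_text("sX\t1\nsY\t-1\n")
        with pytest.raises(ValidationError):
            load_dataset(expr, labels)
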