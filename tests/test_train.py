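"""Standardization, grids, model selection and the fit/predict API."""

import numpy as np
import pytest

from nbsbm import (Dataset, EPControls, GridSpec, ModelConfig, NoisePrior, SlabSpec,
                   ValidationError, fit, make_grid, predict, select_hyperparams,
                   standardize)
from nbsbm.train import TrainedModel, apply_standardization
from .conftest import small_instance


class TestStandardize:
    def test_population_sd_convention(self):
        X = np.column_stack([np.ones(3), [1.0, 2.0, 3.0]])
        Xs, stats = standardize(X)
        assert np.allclose(Xs[:, 1], [-1.22474487, 0.0, 1.22474487])
        assert np.allclose(Xs[:, 0], 1.0)

    def test_zero_variance_flagged_and_zeroed(self):
        X = np.column_stack([np.ones(3), [5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        Xs, stats = standardize(X)
        assert np.allclose(Xs[:, 1], 0.0)
        assert stats.zero_variance.tolist() == [True, False]

    def test_replay_is_bit_exact(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(10), rng.standard_normal((10, 3))])
        Xs, stats = standardize(X)
        assert np.array_equal(apply_standardization(stats, X), Xs)


class TestMakeGrid:
    def test_default_lambda_grid(self):
        g = make_grid(GridSpec(), "lambda")
        assert len(g) == 500
        assert np.isclose(g[0], np.exp(-5))
        assert np.isclose(g[-1], np.exp(2))
        ratios = g[1:] / g[:-1]
        assert np.allclose(ratios, np.exp(7 / 499))

    def test_default_gamma_grid_span(self):
        g = make_grid(GridSpec(), "gamma")
        assert len(g) == 500
        assert np.isclose(g[0], np.exp(-5)) and np.isclose(g[-1], np.exp(1))

    def test_linear_spacing_option(self):
        g = make_grid(GridSpec(spacing="linear", n_lambda=5), "lambda")
        assert np.allclose(np.diff(g), np.diff(g)[0])


def _tiny_grid(lams, gams):
    return GridSpec(lambda_bounds=(min(lams), max(lams)), n_lambda=len(lams),
                    gamma_bounds=(min(gams), max(gams)), n_gamma=len(gams))


class TestSelectHyperparams:
    def test_degenerate_grid_returns_that_pair(self):
        ds, net = small_instance(2, 10, 0.5, 0.5, seed=2)
        Xs, _ = standardize(ds.X)
        dss = Dataset(X=Xs, y=ds.y, gene_names=ds.gene_names)
        lam, gam, log = select_hyperparams(
            dss, net, SlabSpec.constant(2), NoisePrior(),
            _tiny_grid([0.3], [0.7]), EPControls(seed=0))
        assert (lam, gam) == (0.3, 0.7)
        assert len(log) == 1

    def test_ties_break_to_larger_lambda(self):
        # strongly separated data: every grid point achieves zero training error
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.uniform(1, 2, 6), rng.uniform(-2, -1, 6)])
        ds = Dataset.from_features(x[:, None] * 3.0, np.sign(x), ("g0",))
        net = small_instance(1, 4, 0.0, 0.0, seed=0)[1].aligned(("g0",))
        Xs, _ = standardize(ds.X)
        dss = Dataset(X=Xs, y=ds.y, gene_names=ds.gene_names)
        lam, gam, log = select_hyperparams(
            dss, net, SlabSpec.constant(1), NoisePrior(),
            _tiny_grid([0.1, 1.0], [0.2, 0.9]), EPControls(seed=0))
        errors = {r["error"] for r in log}
        assert errors == {0.0}
        assert (lam, gam) == (1.0, 0.9)

    def test_search_log_covers_full_grid(self):
        ds, net = small_instance(2, 10, 0.5, 0.5, seed=2)
        Xs, _ = standardize(ds.X)
        dss = Dataset(X=Xs, y=ds.y, gene_names=ds.gene_names)
        _, _, log = select_hyperparams(
            dss, net, SlabSpec.constant(2), NoisePrior(),
            _tiny_grid([0.1, 0.5, 1.0], [0.2, 0.9]), EPControls(seed=0))
        assert len(log) == 6


def _small_config(**kw):
    return ModelConfig(grids=_tiny_grid([0.3], [0.5]), ep=EPControls(seed=1), **kw)


class TestFitPredict:
    def test_training_error_reproduced_by_predict(self):
        ds, net = small_instance(3, 20, 0.5, 0.5, seed=11)
        model = fit(ds, net, _small_config())
        probs, labels = predict(model, ds.features)
        assert np.isclose(np.mean(labels != ds.y), model.training_error)

    def test_probability_half_maps_to_positive(self):
        ds, net = small_instance(2, 10, 0.5, 0.5, seed=4)
        model = fit(ds, net, _small_config())
        # craft an input that lands exactly on the decision threshold:
        # the (prior-only-like) symmetric posterior at x = 0 gives p = 1/2
        probs, labels = predict(model, np.zeros((1, 2)) + model.standardization.mean)
        if np.isclose(probs[0], 0.5):
            assert labels[0] == 1.0

    def test_missing_genes_imputed_as_zero(self):
        ds, net = small_instance(3, 20, 0.5, 0.5, seed=12)
        model = fit(ds, net, _small_config())
        sub = ds.features[:, :2]
        probs, _ = predict(model, sub, gene_names=list(ds.gene_names[:2]))
        assert probs.shape == (20,)

    def test_no_overlap_rejected(self):
        ds, net = small_instance(2, 10, 0.5, 0.5, seed=4)
        model = fit(ds, net, _small_config())
        with pytest.raises(ValidationError):
            predict(model, np.zeros((2, 2)), gene_names=["x1", "x2"])

    def test_generalization_on_planted_model(self):
        """With 10% label flips the Bayes error is 0.1; a fitted model on 120
        training samples should land well under 0.25 held-out error."""
        from nbsbm import generate_dataset, generate_network
        cfg = ModelConfig(grids=_tiny_grid([0.3], [1.0]), ep=EPControls(seed=1))
        errs = []
        for seed in range(3):
            net = generate_network(4, 5, seed=seed)
            ds, _ = generate_dataset(net, 320, 1, 1.0, flip_rate=0.1, seed=seed)
            train = Dataset.from_features(ds.features[:120], ds.y[:120], ds.gene_names)
            model = fit(train, net, cfg)
            _, labels = predict(model, ds.features[120:])
            errs.append(np.mean(labels != ds.y[120:]))
        assert np.mean(errs) < 0.25

    def test_json_roundtrip_preserves_predictions(self, tmp_path):
        ds, net = small_instance(3, 20, 0.5, 0.5, seed=11)
        model = fit(ds, net, _small_config())
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = TrainedModel.from_json(path)
        p1, l1 = predict(model, ds.features)
        p2, l2 = predict(restored, ds.features)
        assert np.allclose(p1, p2, atol=1e-12)
        assert np.array_equal(l1, l2)
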