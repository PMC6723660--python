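"""Training pipeline: standardization, hyperparameter grids, fit/predict.

The sparsity parameter ``lambda`` and network-coupling parameter
``gamma`` are chosen from log-even grids spanning [e^-5, e^2] and
[e^-5, e^1] respectively (500 points each by default) by the lowest
training error rate, with ties broken toward the sparser, smoother
model (larger lambda, then larger gamma).  Because a full 500 x 500
joint search means a quarter-million EP fits, a budgeted mode (coarse
grid then local refinement) is available and is the default of the
command-line interface; the full joint grid remains available for small
problems.

Features are standardized to zero mean and unit population standard
deviation per gene before fitting, which is what makes unit slab
variances scale-appropriate; the training statistics are replayed at
prediction time.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .ep import EPControls, PosteriorApproximation, ep_fit, predict_proba
from .exceptions import NBSBMError, ValidationError
from .model import Dataset, NoisePrior, SlabSpec
from .netprior import NetworkPrior

__all__ = [
    "GridSpec",
    "ModelConfig",
    "Standardization",
    "TrainedModel",
    "standardize",
    "apply_standardization",
    "make_grid",
    "select_hyperparams",
    "fit",
    "predict",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Log-even hyperparameter grids; spans follow the evaluation protocol."""

    lambda_bounds: tuple[float, float] = (math.exp(-5.0), math.exp(2.0))
    gamma_bounds: tuple[float, float] = (math.exp(-5.0), math.exp(1.0))
    n_lambda: int = 500
    n_gamma: int = 500
    spacing: str = "log"  # or "linear"

    def __post_init__(self) -> None:
        if self.n_lambda < 1 or self.n_gamma < 1:
            raise ValidationError("grids must be non-empty")
        if self.spacing not in ("log", "linear"):
            raise ValidationError(f"spacing must be 'log' or 'linear', got {self.spacing!r}")
        for lo, hi in (self.lambda_bounds, self.gamma_bounds):
            if not (0 < lo <= hi):
                raise ValidationError("grid bounds must satisfy 0 < low <= high")


def make_grid(spec: GridSpec, which: str) -> np.ndarray:
    """Materialize the lambda or gamma grid (endpoints included, increasing)."""
    if which == "lambda":
        lo, hi, num = (*spec.lambda_bounds, spec.n_lambda)
    elif which == "gamma":
        lo, hi, num = (*spec.gamma_bounds, spec.n_gamma)
    else:
        raise ValidationError(f"which must be 'lambda' or 'gamma', got {which!r}")
    if num == 1:
        return np.array([lo])
    if spec.spacing == "log":
        return np.exp(np.linspace(math.log(lo), math.log(hi), num))
    return np.linspace(lo, hi, num)


@dataclass(frozen=True)
class ModelConfig:
    """Everything `fit` needs besides the data and network topology."""

    slab_sigma2: float = 1.0
    bias_sigma2: float = 1.0
    noise: NoisePrior = field(default_factory=NoisePrior)
    grids: GridSpec = field(default_factory=GridSpec)
    ep: EPControls = field(default_factory=EPControls)
    budget: bool = True            # coarse-to-fine search instead of the full grid
    coarse_points: int = 25
    refine_points: int = 11
    coupling_sign: int = -1

    def to_dict(self) -> dict:
        return {
            "slab_sigma2": self.slab_sigma2,
            "bias_sigma2": self.bias_sigma2,
            "noise": {"a0": self.noise.a0, "b0": self.noise.b0},
            "grids": {
                "lambda_bounds": list(self.grids.lambda_bounds),
                "gamma_bounds": list(self.grids.gamma_bounds),
                "n_lambda": self.grids.n_lambda,
                "n_gamma": self.grids.n_gamma,
                "spacing": self.grids.spacing,
            },
            "ep": {"max_iter": self.ep.max_iter, "tol": self.ep.tol,
                   "damping": self.ep.damping, "seed": self.ep.seed,
                   "shuffle": self.ep.shuffle},
            "budget": self.budget,
            "coupling_sign": self.coupling_sign,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ModelConfig":
        grids = doc.get("grids", {})
        ep = doc.get("ep", {})
        noise = doc.get("noise", {})
        return cls(
            slab_sigma2=doc.get("slab_sigma2", 1.0),
            bias_sigma2=doc.get("bias_sigma2", 1.0),
            noise=NoisePrior(a0=noise.get("a0", 1.0), b0=noise.get("b0", 8.0)),
            grids=GridSpec(
                lambda_bounds=tuple(grids.get("lambda_bounds", (math.exp(-5), math.exp(2)))),
                gamma_bounds=tuple(grids.get("gamma_bounds", (math.exp(-5), math.exp(1)))),
                n_lambda=grids.get("n_lambda", 500),
                n_gamma=grids.get("n_gamma", 500),
                spacing=grids.get("spacing", "log"),
            ),
            ep=EPControls(max_iter=ep.get("max_iter", 200), tol=ep.get("tol", 1e-4),
                          damping=ep.get("damping", 0.5), seed=ep.get("seed", 0),
                          shuffle=ep.get("shuffle", True)),
            budget=doc.get("budget", True),
            coupling_sign=doc.get("coupling_sign", -1),
        )


@dataclass(frozen=True)
class Standardization:
    """Per-gene training mean/sd (population convention) for test-time replay."""

    mean: np.ndarray
    sd: np.ndarray
    zero_variance: np.ndarray  # boolean flags


def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardization]:
    """Center/scale each gene column of an n x (d+1) matrix (bias untouched).

    Zero-variance genes are mapped to 0 and flagged.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("standardize needs at least 2 samples")
    feats = X[:, 1:]
    mean = feats.mean(axis=0)
    sd = feats.std(axis=0)  # population sd
    zero = sd == 0.0
    stats = Standardization(mean=mean, sd=np.where(zero, 1.0, sd), zero_variance=zero)
    return apply_standardization(stats, X), stats


def apply_standardization(stats: Standardization, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = X.copy()
    out[:, 1:] = (X[:, 1:] - stats.mean) / stats.sd
    out[:, 1:][:, stats.zero_variance] = 0.0
    return out


@dataclass(frozen=True)
class TrainedModel:
    posterior: PosteriorApproximation
    chosen_lambda: float
    chosen_gamma: float
    standardization: Standardization
    training_error: float
    gene_names: tuple[str, ...]
    config: ModelConfig
    search_log: tuple = ()

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "chosen_lambda": self.chosen_lambda,
            "chosen_gamma": self.chosen_gamma,
            "training_error": self.training_error,
            "gene_names": list(self.gene_names),
            "standardization": {
                "mean": self.standardization.mean.tolist(),
                "sd": self.standardization.sd.tolist(),
                "zero_variance": self.standardization.zero_variance.astype(int).tolist(),
            },
            "posterior": json.loads(self.posterior.to_json()),
            "beta_mean_raw": list(self.posterior.beta_mean),
            "beta_var_raw": list(self.posterior.beta_var),
            "beta_cov_raw": (self.posterior.beta_cov.tolist()
                             if self.posterior.beta_cov is not None
                             and len(self.gene_names) <= 500 else None),
            "incl_prob_raw": list(self.posterior.incl_prob),
            "eps": [self.posterior.eps_a, self.posterior.eps_b],
            "config": self.config.to_dict(),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        doc = json.loads(Path(path).read_text())
        genes = tuple(doc["gene_names"])
        post = PosteriorApproximation(
            beta_mean=np.array(doc["beta_mean_raw"]),
            beta_var=np.array(doc["beta_var_raw"]),
            incl_prob=np.array(doc["incl_prob_raw"]),
            beta_cov=(np.array(doc["beta_cov_raw"])
                      if doc.get("beta_cov_raw") is not None else None),
            eps_a=doc["eps"][0], eps_b=doc["eps"][1],
            converged=doc["posterior"]["converged"],
            iterations=doc["posterior"]["iterations"],
            gene_names=genes,
        )
        std = doc["standardization"]
        return cls(
            posterior=post,
            chosen_lambda=doc["chosen_lambda"],
            chosen_gamma=doc["chosen_gamma"],
            standardization=Standardization(
                mean=np.array(std["mean"]), sd=np.array(std["sd"]),
                zero_variance=np.array(std["zero_variance"], dtype=bool)),
            training_error=doc["training_error"],
            gene_names=genes,
            config=ModelConfig.from_dict(doc["config"]),
        )


def _training_error(posterior: PosteriorApproximation, dataset: Dataset) -> float:
    probs = predict_proba(posterior, dataset.X)
    labels = np.where(probs >= 0.5, 1.0, -1.0)  # ties to +1
    return float(np.mean(labels != dataset.y))


def _fit_one(dataset, network, slab, noise, controls, lam, gam):
    post = ep_fit(dataset, network.with_hyperparams(lam, gam), slab, noise, controls)
    return post, _training_error(post, dataset)


def select_hyperparams(
    dataset: Dataset,
    network: NetworkPrior,
    slab: SlabSpec,
    noise: NoisePrior,
    grids: GridSpec,
    controls: EPControls,
    budget: bool = False,
    coarse_points: int = 25,
    refine_points: int = 11,
) -> tuple[float, float, list[dict]]:
    """Grid-search (lambda, gamma) by lowest training error rate.

    Ties go to the largest lambda, then largest gamma.  With
    ``budget=True`` a coarse subgrid is scanned first and the full grid
    is then sampled locally around the coarse winner.
    """
    lam_grid = make_grid(grids, "lambda")
    gam_grid = make_grid(grids, "gamma")
    log: list[dict] = []

    def _scan(lams: np.ndarray, gams: np.ndarray) -> None:
        for lam in lams:
            for gam in gams:
                post, err = _fit_one(dataset, network, slab, noise, controls, lam, gam)
                log.append({"lambda": float(lam), "gamma": float(gam),
                            "error": err, "converged": bool(post.converged)})

    def _subsample(grid: np.ndarray, k: int) -> np.ndarray:
        if len(grid) <= k:
            return grid
        return grid[np.unique(np.linspace(0, len(grid) - 1, k).round().astype(int))]

    if not budget:
        _scan(lam_grid, gam_grid)
    else:
        coarse_l = _subsample(lam_grid, coarse_points)
        coarse_g = _subsample(gam_grid, coarse_points)
        _scan(coarse_l, coarse_g)
        best = _pick(log)
        lam0, gam0 = best["lambda"], best["gamma"]
        refine_l = _neighbourhood(lam_grid, coarse_l, lam0, refine_points)
        refine_g = _neighbourhood(gam_grid, coarse_g, gam0, refine_points)
        done = {(r["lambda"], r["gamma"]) for r in log}
        for lam in refine_l:
            for gam in refine_g:
                if (float(lam), float(gam)) in done:
                    continue
                post, err = _fit_one(dataset, network, slab, noise, controls, lam, gam)
                log.append({"lambda": float(lam), "gamma": float(gam),
                            "error": err, "converged": bool(post.converged)})

    if all(not r["converged"] for r in log):
        raise NBSBMError(f"no EP fit converged anywhere on the grid; log: {log[:5]}...")
    best = _pick(log)
    return best["lambda"], best["gamma"], log


def _pick(log: list[dict]) -> dict:
    best_err = min(r["error"] for r in log)
    candidates = [r for r in log if r["error"] <= best_err + 1e-12]
    return max(candidates, key=lambda r: (r["lambda"], r["gamma"]))


def _neighbourhood(full: np.ndarray, coarse: np.ndarray, center: float, k: int) -> np.ndarray:
    ci = int(np.argmin(np.abs(coarse - center)))
    lo = coarse[max(ci - 1, 0)]
    hi = coarse[min(ci + 1, len(coarse) - 1)]
    window = full[(full >= lo) & (full <= hi)]
    if len(window) <= k:
        return window
    return window[np.unique(np.linspace(0, len(window) - 1, k).round().astype(int))]


def fit(dataset: Dataset, network: NetworkPrior, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Standardize, (optionally) search the grids, and fit the final posterior."""
    Xs, stats = standardize(dataset.X)
    ds = Dataset(X=Xs, y=dataset.y, gene_names=dataset.gene_names,
                 sample_names=dataset.sample_names)
    network = network.aligned(ds.gene_names)
    network = replace(network, coupling_sign=config.coupling_sign)
    slab = SlabSpec.constant(ds.d, config.slab_sigma2, bias_value=config.bias_sigma2)

    grids = config.grids
    if grids.n_lambda == 1 and grids.n_gamma == 1:
        lam, gam = grids.lambda_bounds[0], grids.gamma_bounds[0]
        log: list[dict] = []
    else:
        lam, gam, log = select_hyperparams(
            ds, network, slab, config.noise, grids, config.ep,
            budget=config.budget, coarse_points=config.coarse_points,
            refine_points=config.refine_points)

    posterior = ep_fit(ds, network.with_hyperparams(lam, gam), slab, config.noise, config.ep)
    err = _training_error(posterior, ds)
    return TrainedModel(
        posterior=posterior, chosen_lambda=float(lam), chosen_gamma=float(gam),
        standardization=stats, training_error=err, gene_names=ds.gene_names,
        config=config, search_log=tuple(tuple(sorted(r.items())) for r in log))


def predict(
    model: TrainedModel,
    features: np.ndarray,
    gene_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample sensitive-class probabilities and +-1 labels for new data.

    ``features`` is n x d (no bias column).  When ``gene_names`` differ
    from the training genes, columns are realigned; genes missing from
    the new data are imputed as 0 (the standardized mean) and logged.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    train_genes = model.gene_names
    if gene_names is not None and tuple(gene_names) != train_genes:
        gene_names = [str(g) for g in gene_names]
        pos = {g: i for i, g in enumerate(gene_names)}
        overlap = [g for g in train_genes if g in pos]
        if not overlap:
            raise ValidationError("no overlap between model genes and supplied genes")
        missing = [g for g in train_genes if g not in pos]
        if missing:
            logger.info("imputing %d genes absent from the new data as 0 (first: %s)",
                        len(missing), missing[:5])
        aligned = np.zeros((features.shape[0], len(train_genes)))
        mean, sd = model.standardization.mean, model.standardization.sd
        for j, g in enumerate(train_genes):
            if g in pos:
                aligned[:, j] = (features[:, pos[g]] - mean[j]) / sd[j]
        aligned[:, model.standardization.zero_variance] = 0.0
        Xs = np.column_stack([np.ones(aligned.shape[0]), aligned])
    else:
        if features.shape[1] != len(train_genes):
            raise ValidationError(
                f"expected {len(train_genes)} features, got {features.shape[1]}")
        X = np.column_stack([np.ones(features.shape[0]), features])
        Xs = apply_standardization(model.standardization, X)
    probs = np.atleast_1d(predict_proba(model.posterior, Xs))
    labels = np.where(probs >= 0.5, 1.0, -1.0)
    return probs, labels
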