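"""Synthetic benchmarks with exactly the model's assumed structure.

The generator emulates the study setting — a modular disease network
whose differentially expressed modules carry the predictive signal —
as a planted-partition graph plus a linear ground-truth classifier
supported on whole modules, with labels flipped at a known rate.
Because the data satisfy the model's own assumptions exactly,
parameter-recovery results measure inference quality, not model misfit.

Also houses the IC50 labeling convention: cell lines with IC50 below
200 nM are called drug-sensitive (+1), at or above it resistant (-1).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model import Dataset
from .netprior import NetworkPrior

__all__ = ["SyntheticTruth", "generate_network", "generate_dataset", "binarize_ic50",
           "write_bundle"]

_MODULE_RE = re.compile(r"^(m\d+)_g\d+$")


@dataclass(frozen=True)
class SyntheticTruth:
    true_support: np.ndarray       # binary, length d
    true_beta: np.ndarray          # length d+1 (index 0 = intercept)
    flip_rate: float
    module_assignment: dict
    seed: int
    flip_mask: np.ndarray = None   # which labels were actually flipped

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "true_support": self.true_support.astype(int).tolist(),
            "true_beta": self.true_beta.tolist(),
            "flip_rate": self.flip_rate,
            "module_assignment": self.module_assignment,
            "seed": self.seed,
            "flip_mask": self.flip_mask.astype(int).tolist()
            if self.flip_mask is not None else None,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def generate_network(
    n_modules: int,
    module_size: int,
    p_intra: float = 0.3,
    p_inter: float = 0.02,
    seed: int = 0,
    lambda_: float = 0.0,
    gamma_: float = 0.0,
) -> NetworkPrior:
    """Planted-partition random graph with unit edge weights.

    Node names encode module membership (``m00_g000`` etc.) so that
    downstream generators can plant module-level signal.
    """
    if n_modules < 1 or module_size < 1:
        raise ValidationError("need at least one module of at least one gene")
    if not p_intra > p_inter:
        raise ValidationError(f"p_intra ({p_intra}) must exceed p_inter ({p_inter})")
    rng = np.random.default_rng(seed)
    names = [f"m{k:02d}_g{k * module_size + j:03d}"
             for k in range(n_modules) for j in range(module_size)]
    module_of = np.repeat(np.arange(n_modules), module_size)
    d = len(names)
    graph = nx.Graph()
    graph.add_nodes_from(names)
    iu, ju = np.triu_indices(d, k=1)
    same = module_of[iu] == module_of[ju]
    probs = np.where(same, p_intra, p_inter)
    keep = rng.random(len(iu)) < probs
    for i, j in zip(iu[keep], ju[keep]):
        graph.add_edge(names[i], names[j], weight=1.0)
    return NetworkPrior.from_graph(graph, lambda_=lambda_, gamma_=gamma_, nodes=names)


def module_assignment(network: NetworkPrior) -> dict:
    """Recover gene -> module-id mapping from the generator's node names."""
    out = {}
    for g in network.nodes:
        m = _MODULE_RE.match(g)
        out[g] = m.group(1) if m else g
    return out


def generate_dataset(
    network: NetworkPrior,
    n_samples: int,
    n_active_modules: int = 1,
    effect_size: float = 1.0,
    flip_rate: float = 0.1,
    seed: int = 0,
    within_module_rho: float = 0.0,
) -> tuple[Dataset, SyntheticTruth]:
    """Expression + noisy labels generated from a planted linear rule.

    All genes of ``n_active_modules`` randomly chosen modules form the
    true support; their weights are +-``effect_size`` with random sign.
    Clean labels are ``sign(X beta + b0)`` with the intercept set to the
    negated median margin (exact class balance); each label is then
    flipped independently with probability ``flip_rate``.  Expression is
    i.i.d. standard normal by default; ``within_module_rho`` adds
    equicorrelation inside modules for robustness experiments.
    """
    if not 0.0 <= flip_rate < 0.5:
        raise ValidationError(f"flip_rate must lie in [0, 0.5), got {flip_rate}")
    assign = module_assignment(network)
    modules = sorted(set(assign.values()))
    if n_active_modules > len(modules):
        raise ValidationError(
            f"asked for {n_active_modules} active modules, network has {len(modules)}")
    rng = np.random.default_rng(seed)
    d = network.n_nodes
    genes = list(network.nodes)

    X = rng.standard_normal((n_samples, d))
    if within_module_rho > 0.0:
        shared = {m: rng.standard_normal(n_samples) for m in modules}
        for j, g in enumerate(genes):
            X[:, j] = (np.sqrt(1 - within_module_rho) * X[:, j]
                       + np.sqrt(within_module_rho) * shared[assign[g]])

    active = set(rng.choice(modules, size=n_active_modules, replace=False))
    support = np.array([assign[g] in active for g in genes])
    beta = np.zeros(d + 1)
    signs = rng.choice([-1.0, 1.0], size=int(support.sum()))
    beta[1:][support] = signs * effect_size
    margin = X @ beta[1:]
    beta[0] = -float(np.median(margin))
    clean = np.where(margin + beta[0] >= 0, 1.0, -1.0)
    flips = rng.random(n_samples) < flip_rate
    y = np.where(flips, -clean, clean)

    dataset = Dataset.from_features(X, y, gene_names=genes,
                                    sample_names=[f"s{i:03d}" for i in range(n_samples)])
    truth = SyntheticTruth(true_support=support.astype(float), true_beta=beta,
                           flip_rate=flip_rate, module_assignment=assign, seed=seed,
                           flip_mask=flips)
    return dataset, truth


def binarize_ic50(values: np.ndarray, threshold: float = 200.0) -> np.ndarray:
    """Sensitive (+1) iff IC50 < threshold (nM), else resistant (-1).

    The boundary value itself counts as resistant (strict less-than).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValidationError("IC50 values must be positive")
    return np.where(values < threshold, 1.0, -1.0)


def write_bundle(outdir: str | Path, dataset: Dataset, truth: SyntheticTruth,
                 network: NetworkPrior) -> None:
    """Write expression TSV, labels TSV, network edge TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = list(dataset.sample_names) or [f"s{i:03d}" for i in range(dataset.n)]
    expr = pd.DataFrame(dataset.features.T, index=list(dataset.gene_names), columns=samples)
    expr.index.name = "gene"
    expr.to_csv(outdir / "expression.tsv", sep="\t")
    pd.Series(dataset.y.astype(int), index=samples, name="label").to_csv(
        outdir / "labels.tsv", sep="\t", header=True, index_label="sample")
    with open(outdir / "network.tsv", "w") as fh:
        for u, v, w in network.graph.edges(data="weight", default=1.0):
            fh.write(f"{u}\t{v}\t{w}\n")
    truth.to_json(outdir / "truth.json")
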