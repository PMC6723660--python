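"""Evaluation protocol: repeated stratified CV, ROC/AUC, paired Wilcoxon.

Cross-validation defaults to 5 folds x 5 repeats (25 held-out fold
results).  Standardization and hyperparameter selection happen inside
each training fold, so no information leaks from the test fold.  Folds
are stratified: with as few as five resistant lines, unstratified
splits can produce one-class test folds on which AUC is undefined.

ROC curves are averaged vertically: each fold curve is interpolated
onto a common 101-point false-positive-rate grid and the mean, median
and interquartile range of the true-positive rate are reported per grid
point.  Method comparison uses the Wilcoxon signed-rank test on paired
per-fold AUCs (exact null distribution up to 25 pairs, midranks for
ties) or the rank-sum test for unpaired samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .model import Dataset
from .netprior import NetworkPrior
from .train import ModelConfig, fit, predict

__all__ = ["FoldResult", "CVReport", "repeated_cv", "roc_auc", "average_roc", "compare_auc"]

_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    test_index: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    auc: float


@dataclass(frozen=True)
class CVReport:
    fold_results: tuple[FoldResult, ...]
    mean_roc: dict
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def auc_list(self) -> np.ndarray:
        return np.array([f.auc for f in self.fold_results])

    @property
    def mean_auc(self) -> float:
        return float(self.auc_list.mean())

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "seed": self.seed,
            "config": self.config,
            "mean_auc": self.mean_auc,
            "auc_list": self.auc_list.tolist(),
            "fold_results": [
                {"repeat": f.repeat, "fold": f.fold,
                 "test_index": f.test_index.tolist(),
                 "probabilities": f.probabilities.tolist(),
                 "labels": f.labels.tolist(), "auc": f.auc}
                for f in self.fold_results
            ],
            "mean_roc": {k: np.asarray(v).tolist() for k, v in self.mean_roc.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_roc)


def repeated_cv(
    dataset: Dataset,
    network: NetworkPrior,
    config: ModelConfig = ModelConfig(),
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV repeated with reshuffled folds; leak-free."""
    y = dataset.y
    n_pos, n_neg = int((y > 0).sum()), int((y < 0).sum())
    if min(n_pos, n_neg) < folds:
        raise ValidationError(
            f"both classes need >= {folds} members for {folds}-fold stratified CV "
            f"(have {n_pos} positive, {n_neg} negative)")
    results: list[FoldResult] = []
    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(repeats)]
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=repeat_seeds[rep])
        for fold_i, (tr, te) in enumerate(splitter.split(dataset.X, y)):
            train_ds = Dataset(X=dataset.X[tr], y=y[tr], gene_names=dataset.gene_names)
            model = fit(train_ds, network, config)
            probs, _ = predict(model, dataset.features[te])
            auc = roc_auc(probs, y[te])[1]
            results.append(FoldResult(repeat=rep, fold=fold_i, test_index=np.asarray(te),
                                      probabilities=probs, labels=y[te], auc=auc))
    curves = [roc_auc(f.probabilities, f.labels)[0] for f in results]
    return CVReport(fold_results=tuple(results), mean_roc=average_roc(curves),
                    seed=seed, config=config.to_dict())


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and Mann-Whitney AUC (ties count one half).

    Returns ``(points, auc)`` with ``points`` an array of (fpr, tpr) rows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC/AUC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def average_roc(curves: list[np.ndarray]) -> dict:
    """Vertical averaging of fold ROC curves onto a fixed FPR grid."""
    if len(curves) < 2:
        raise ValidationError("average_roc needs at least two curves")
    interped = []
    for pts in curves:
        pts = np.asarray(pts, dtype=float)
        fpr, tpr = pts[:, 0], pts[:, 1]
        # keep the best tpr at each distinct fpr (vertical segments)
        order = np.lexsort((tpr, fpr))
        fpr, tpr = fpr[order], tpr[order]
        uniq, last = np.unique(fpr[::-1], return_index=True)
        tpr_u = tpr[::-1][last]
        interped.append(np.interp(_FPR_GRID, uniq, tpr_u))
    T = np.vstack(interped)
    return {
        "fpr": _FPR_GRID.copy(),
        "tpr_mean": T.mean(axis=0),
        "tpr_median": np.median(T, axis=0),
        "tpr_q25": np.percentile(T, 25, axis=0),
        "tpr_q75": np.percentile(T, 75, axis=0),
    }


def compare_auc(aucs_a: np.ndarray, aucs_b: np.ndarray, paired: bool = True) -> float:
    """Two-sided p-value comparing two sets of fold AUCs.

    Paired mode: Wilcoxon signed-rank on per-fold differences (zeros
    dropped; exact sign-flip distribution for up to 25 non-zero pairs,
    normal approximation beyond).  Unpaired mode: Wilcoxon rank-sum.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if not paired:
        return float(sps.ranksums(a, b).pvalue)
    if a.shape != b.shape:
        raise ValidationError("paired comparison needs equal-length AUC lists")
    diff = a - b
    diff = diff[diff != 0.0]
    if diff.size == 0:
        warnings.warn("all AUC differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    if diff.size <= 25:
        return _exact_signed_rank_p(diff)
    return float(sps.wilcoxon(diff, alternative="two-sided", method="approx").pvalue)


def _exact_signed_rank_p(diff: np.ndarray) -> float:
    """Exact two-sided sign-flip p-value of the signed-rank statistic.

    Uses midranks of |diff| (doubled so tied ranks stay integral) and a
    convolution over all 2^n sign assignments.
    """
    ranks2 = np.round(2.0 * sps.rankdata(np.abs(diff))).astype(int)
    w_obs = int(ranks2[diff > 0].sum())
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    p_le = dist[: w_obs + 1].sum()
    p_ge = dist[w_obs:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
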