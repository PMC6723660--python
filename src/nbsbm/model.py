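"""Probabilistic model: noisy-label likelihood, spike-and-slab prior, joint density.

The classifier assumes a true linear rule ``y = sign(beta' x)`` whose
observed labels have been flipped independently with probability
``eps``.  Each observation therefore contributes

    p(y | beta, eps, x) = eps * (1 - H(y beta' x)) + (1 - eps) * H(y beta' x)

with ``H`` the Heaviside step function.  Because the likelihood depends
on the margin only through its sign, it counts errors rather than
weighing their size, which makes the model robust to outliers.  Weights
get a spike-and-slab prior: ``beta_i`` is exactly zero when the
inclusion indicator ``z_i`` is zero and Gaussian ``N(0, sigma_i^2)``
otherwise.  The flip rate carries a Beta(a0, b0) prior restricted to
[0, 1/2] (rates above one half merely relabel the classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .netprior import NetworkPrior, mrf_log_potential

__all__ = [
    "Dataset",
    "SlabSpec",
    "NoisePrior",
    "heaviside",
    "likelihood_point",
    "log_joint",
    "load_expression",
    "load_labels",
    "load_dataset",
]

_LABEL_ALIASES = {
    "1": 1, "+1": 1, "sensitive": 1,
    "-1": -1, "resistant": -1,
}


@dataclass(frozen=True)
class Dataset:
    """Samples-as-rows design matrix with a leading all-ones bias column."""

    X: np.ndarray  # n x (d+1), column 0 identically 1
    y: np.ndarray  # length n, entries in {-1, +1}
    gene_names: tuple[str, ...]
    sample_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[1] != len(self.gene_names) + 1:
            raise ValidationError(
                f"X must be n x (d+1) with d={len(self.gene_names)} genes; got {X.shape}")
        if y.shape != (X.shape[0],):
            raise ValidationError(f"y length {y.shape} does not match n={X.shape[0]}")
        if X.shape[0] and not np.all(X[:, 0] == 1.0):
            raise ValidationError("column 0 of X must be identically 1 (bias)")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains non-finite values")
        if y.size and not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValidationError("labels must be -1 or +1")

    @classmethod
    def from_features(
        cls,
        features: np.ndarray,
        y: Sequence[float],
        gene_names: Sequence[str],
        sample_names: Sequence[str] = (),
    ) -> "Dataset":
        """Build a Dataset from an n x d feature matrix (bias column added)."""
        features = np.asarray(features, dtype=float)
        X = np.column_stack([np.ones(features.shape[0]), features])
        return cls(X=X, y=np.asarray(y, dtype=float), gene_names=tuple(gene_names),
                   sample_names=tuple(sample_names))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return len(self.gene_names)

    @property
    def features(self) -> np.ndarray:
        return self.X[:, 1:]


@dataclass(frozen=True)
class SlabSpec:
    """Slab variances for the d+1 weight components (index 0 = bias)."""

    sigma2: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "sigma2", s)
        if s.ndim != 1 or np.any(s <= 0):
            raise ValidationError("slab variances must be a vector of strictly positive reals")

    @classmethod
    def constant(cls, d: int, value: float = 1.0, bias_value: float | None = None) -> "SlabSpec":
        s = np.full(d + 1, float(value))
        if bias_value is not None:
            s[0] = float(bias_value)
        return cls(sigma2=s)


@dataclass(frozen=True)
class NoisePrior:
    """Beta(a0, b0) prior on the label-flip rate, truncated to [0, 1/2]."""

    a0: float = 1.0
    b0: float = 8.0

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValidationError("Beta prior parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a0 / (self.a0 + self.b0)


def heaviside(t: np.ndarray | float) -> np.ndarray | float:
    """Step function: 1 for t>0, 0 for t<0, 1/2 at t=0 (sigmoid limit)."""
    return np.heaviside(t, 0.5)


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if not 0.0 <= eps <= 0.5:
        raise ValidationError(f"flip rate must lie in [0, 0.5], got {eps}")
    return eps


def likelihood_point(y: float, beta: np.ndarray, x: np.ndarray, eps: float) -> float:
    """Single-observation likelihood ``eps + (1-2 eps) H(y beta' x)``."""
    eps = _check_eps(eps)
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape != x.shape:
        raise ValidationError(f"beta {beta.shape} and x {x.shape} dimensions differ")
    h = float(heaviside(y * float(beta @ x)))
    return eps * (1.0 - h) + (1.0 - eps) * h


def log_joint(
    beta: np.ndarray,
    z: np.ndarray,
    eps: float,
    dataset: Dataset,
    slab: SlabSpec,
    noise: NoisePrior,
    network: NetworkPrior,
) -> float:
    """Unnormalized log joint of (beta, z, eps, y): likelihood x slab x MRF x Beta.

    The intractable constants (MRF normalizer, evidence) are omitted.
    ``z`` covers the d genes; the bias indicator is fixed to 1 and its
    weight always carries a slab.
    """
    beta = np.asarray(beta, dtype=float)
    z = np.asarray(z)
    eps = _check_eps(eps)
    d = dataset.d
    if beta.shape != (d + 1,) or z.shape != (d,):
        raise ValidationError("beta must have length d+1 and z length d")
    off = (z == 0) & (beta[1:] != 0.0)
    if np.any(off):
        raise ValidationError(
            f"beta must vanish on the spike support (violated at genes {np.where(off)[0][:5]})")

    margins = dataset.y * (dataset.X @ beta)
    h = heaviside(margins)
    lik = eps * (1.0 - h) + (1.0 - eps) * h
    total = float(np.sum(np.log(lik))) if dataset.n else 0.0

    active = np.concatenate([[True], z.astype(bool)])
    total += float(np.sum(stats.norm.logpdf(beta[active], scale=np.sqrt(slab.sigma2[active]))))
    total += mrf_log_potential(z.astype(float), network)
    total += float(stats.beta.logpdf(eps, noise.a0, noise.b0))
    return total


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def load_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression table (first column gene identifiers) as genes x samples."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.empty:
        raise ValidationError(f"expression table {path} is empty")
    return df


def load_labels(path: str | Path) -> pd.Series:
    """Read sample labels; values may be +-1 or sensitive/resistant strings."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, header=None
                     if _headerless(path) else 0)
    ser = df.iloc[:, 0]

    def _convert(v: object) -> int:
        key = str(v).strip().lower()
        if key in _LABEL_ALIASES:
            return _LABEL_ALIASES[key]
        try:
            iv = int(float(key))
        except ValueError:
            raise ValidationError(f"unrecognized label {v!r}") from None
        if iv in (-1, 1):
            return iv
        raise ValidationError(f"labels must be +-1 or sensitive/resistant, got {v!r}")

    return ser.map(_convert)


def _headerless(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    fields = first.replace(",", "\t").split("\t")
    tail = fields[-1].strip().lower()
    return tail in _LABEL_ALIASES or _is_number(tail)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_dataset(expression_path: str | Path, labels_path: str | Path) -> Dataset:
    """Join an expression table and a label file into a Dataset.

    Orientation of the expression table is auto-detected by matching the
    label sample names against its rows or columns; the internal
    convention is samples-as-rows.
    """
    expr = load_expression(expression_path)
    labels = load_labels(labels_path)
    samples = [str(s) for s in labels.index]
    cols = set(map(str, expr.columns))
    rows = set(map(str, expr.index))
    hits_cols = sum(s in cols for s in samples)
    hits_rows = sum(s in rows for s in samples)
    if hits_cols == 0 and hits_rows == 0:
        raise ValidationError(
            "no label sample names found in the expression table "
            f"(first labels: {samples[:5]})")
    if hits_rows > hits_cols:
        expr = expr.T  # was samples x genes
    expr.columns = expr.columns.map(str)
    missing = [s for s in samples if s not in set(expr.columns)]
    if missing:
        raise ValidationError(f"samples missing from expression table: {missing[:5]}")
    mat = expr.loc[:, samples].to_numpy(dtype=float).T  # samples x genes
    return Dataset.from_features(mat, labels.to_numpy(dtype=float),
                                 gene_names=[str(g) for g in expr.index],
                                 sample_names=samples)
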