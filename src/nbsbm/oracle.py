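"""Brute-force reference posteriors for small instances.

Two independent routes to the exact posterior anchor the EP engine:

* :func:`exact_posterior_small` enumerates all 2^d inclusion vectors,
  integrates the flip rate by Gauss-Legendre quadrature on [0, 1/2] and
  the weights by Monte Carlo from the slab prior (common random numbers
  across configurations for variance reduction);
* :func:`gibbs_sample` runs a blocked Gibbs sampler over (z_i, beta_i)
  pairs and the flip rate.  The step-function likelihood makes every
  univariate weight conditional piecewise Gaussian — each observation
  contributes a factor that switches between ``eps`` and ``1 - eps`` at
  one breakpoint — so the conditional is sampled exactly by choosing an
  inter-breakpoint interval and then a truncated normal within it.  The
  per-observation error indicators implied by the current weights drive
  the conjugate (truncated) Beta update of the flip rate.

Agreement of the two, and of either with EP, is the package's
correctness foundation; neither scales beyond toy sizes by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import logsumexp, ndtr, ndtri

from .exceptions import CapacityError, NBSBMError, ValidationError
from .model import Dataset, NoisePrior, SlabSpec, heaviside
from .netprior import NetworkPrior

__all__ = ["OracleSummary", "exact_posterior_small", "gibbs_sample"]

_EXACT_MAX_D = 10
_EXACT_MAX_N = 12
_GIBBS_MAX_D = 50
_QUAD_NODES = 64


@dataclass(frozen=True)
class OracleSummary:
    incl_marginals: np.ndarray
    beta_mean: np.ndarray
    eps_mean: float
    predictive: np.ndarray          # one probability per requested test point
    mc_error: dict = field(default_factory=dict)


def _eps_quadrature(noise: NoisePrior) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights integrating against Beta(a0,b0) truncated to [0, 1/2]."""
    x, w = np.polynomial.legendre.leggauss(_QUAD_NODES)
    t = 0.25 * (x + 1.0)            # map [-1,1] -> [0, 0.5]
    dens = t ** (noise.a0 - 1.0) * (1.0 - t) ** (noise.b0 - 1.0)
    wq = w * 0.25 * dens
    return t, wq / wq.sum()


def exact_posterior_small(
    dataset: Dataset,
    network: NetworkPrior,
    slab: SlabSpec,
    noise: NoisePrior,
    mc_samples: int = 20000,
    seed: int = 0,
    test_points: np.ndarray | None = None,
    n_batches: int = 10,
) -> OracleSummary:
    """Posterior summaries by enumeration over z + Monte Carlo over beta."""
    d, n = dataset.d, dataset.n
    if d > _EXACT_MAX_D or n > _EXACT_MAX_N:
        raise CapacityError(
            f"exact_posterior_small handles d <= {_EXACT_MAX_D}, n <= {_EXACT_MAX_N}; "
            f"got d={d}, n={n}")
    if tuple(network.nodes) != tuple(dataset.gene_names):
        network = network.aligned(dataset.gene_names)
    if mc_samples % n_batches:
        mc_samples += n_batches - mc_samples % n_batches
    B = n_batches
    S = mc_samples
    per = S // B

    rng = np.random.default_rng(seed)
    beta_draws = rng.standard_normal((S, d + 1)) * np.sqrt(slab.sigma2)
    t_nodes, wq = _eps_quadrature(noise)
    wq_eps = wq * t_nodes

    Xt = np.atleast_2d(test_points) if test_points is not None else np.zeros((0, d + 1))
    n_test = Xt.shape[0]

    L = network.laplacian
    sgn = network.coupling_sign
    batch_idx = np.repeat(np.arange(B), per)

    tot = np.zeros(B)
    marg = np.zeros((B, d))
    beta_acc = np.zeros((B, d + 1))
    eps_acc = np.zeros(B)
    pred_acc = np.zeros((B, n_test))

    # precompute log prior weights over all z for a stable common shift
    zs = [np.array(bits, dtype=float) for bits in product((0.0, 1.0), repeat=d)]
    logw_all = np.array([
        network.lambda_ * z.sum() + sgn * network.gamma_ * float(z @ L @ z) for z in zs])
    shift = logw_all.max() if len(logw_all) else 0.0

    for z, logw in zip(zs, logw_all):
        act = np.concatenate([[0], 1 + np.flatnonzero(z)]).astype(int)
        if n:
            T = dataset.y[:, None] * (dataset.X[:, act] @ beta_draws[:, act].T)  # n x S
            k_err = (T < 0).sum(axis=0)
            k_tie = (T == 0).sum(axis=0)
            k_cor = n - k_err - k_tie
            lik = (t_nodes[None, :] ** k_err[:, None]
                   * (1.0 - t_nodes[None, :]) ** k_cor[:, None]
                   * 0.5 ** k_tie[:, None])              # S x Q
            A = lik @ wq                                  # E_eps[lik] per draw
            Beps = lik @ wq_eps                           # E_eps[eps*lik]
        else:
            A = np.ones(S)
            Beps = np.full(S, wq_eps.sum())
        w = np.exp(logw - shift)
        for b in range(B):
            sel = batch_idx == b
            Ab = A[sel]
            tot[b] += w * Ab.mean()
            marg[b] += w * Ab.mean() * z
            beta_b = np.zeros(d + 1)
            beta_b[act] = (Ab[:, None] * beta_draws[sel][:, act]).mean(axis=0)
            beta_acc[b] += w * beta_b
            eps_acc[b] += w * Beps[sel].mean()
            if n_test:
                theta = heaviside(Xt[:, act] @ beta_draws[sel][:, act].T)  # n_test x per
                integ = theta * (Ab - 2.0 * Beps[sel])[None, :] + Beps[sel][None, :]
                pred_acc[b] += w * integ.mean(axis=1)

    total = tot.sum()
    incl = marg.sum(axis=0) / total
    beta_mean = beta_acc.sum(axis=0) / total
    eps_mean = float(eps_acc.sum() / total)
    predictive = pred_acc.sum(axis=0) / total if n_test else np.zeros(0)

    def _se(per_batch: np.ndarray) -> np.ndarray:
        vals = per_batch / tot[:, None] if per_batch.ndim == 2 else per_batch / tot
        return np.std(vals, axis=0, ddof=1) / np.sqrt(B)

    mc_error = {
        "incl_marginals": _se(marg),
        "beta_mean": _se(beta_acc),
        "eps_mean": float(_se(eps_acc)),
        "predictive": _se(pred_acc) if n_test else np.zeros(0),
    }
    return OracleSummary(incl_marginals=incl, beta_mean=beta_mean, eps_mean=eps_mean,
                         predictive=predictive, mc_error=mc_error)


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _sample_trunc_beta(rng, a: float, b: float, hi: float = 0.5) -> float:
    cap = stats.beta.cdf(hi, a, b)
    if cap <= 0.0:
        return hi
    return float(stats.beta.ppf(rng.random() * cap, a, b))


def _piecewise_intervals(coef: np.ndarray, rest: np.ndarray, y: np.ndarray):
    """Breakpoints of prod_i [eps or 1-eps] as a function of one weight.

    Observation i is correct when ``y_i (rest_i + coef_i * b) > 0``; for
    ``coef_i != 0`` the factor switches at ``b = -rest_i / coef_i``.
    Returns sorted breakpoints.
    """
    nz = coef != 0.0
    return np.sort(-rest[nz] / coef[nz])


def _interval_log_weights(bps: np.ndarray, coef, rest, y, log_eps, log_1meps, sigma):
    """Log weight of each inter-breakpoint interval: error-count term x slab mass."""
    edges = np.concatenate([[-np.inf], bps, [np.inf]])
    n_int = len(edges) - 1
    logws = np.full(n_int, -np.inf)
    cdf = ndtr(edges / sigma)
    for k in range(n_int):
        lo, hi = edges[k], edges[k + 1]
        if hi <= lo:
            continue
        mass = cdf[k + 1] - cdf[k]
        if mass <= 0.0:
            continue
        mid = _interior_point(lo, hi)
        margins = y * (rest + coef * mid)
        k_err = int((margins < 0).sum())
        logws[k] = k_err * log_eps + (len(y) - k_err) * log_1meps + np.log(mass)
    return edges, logws


def _interior_point(lo: float, hi: float) -> float:
    if np.isinf(lo) and np.isinf(hi):
        return 0.0
    if np.isinf(lo):
        return hi - 1.0
    if np.isinf(hi):
        return lo + 1.0
    return 0.5 * (lo + hi)


def _sample_trunc_norm(rng, lo: float, hi: float, sigma: float) -> float:
    plo, phi = ndtr(lo / sigma), ndtr(hi / sigma)
    u = plo + rng.random() * (phi - plo)
    return float(sigma * ndtri(np.clip(u, 1e-15, 1 - 1e-15)))


def gibbs_sample(
    dataset: Dataset,
    network: NetworkPrior,
    slab: SlabSpec,
    noise: NoisePrior,
    iters: int = 4000,
    burn_in: int | None = None,
    seed: int = 0,
    test_points: np.ndarray | None = None,
    fix_eps: float | None = None,
    n_batches: int = 10,
) -> OracleSummary:
    """Blocked Gibbs over (z_i, beta_i), the bias weight and the flip rate."""
    d, n = dataset.d, dataset.n
    if d > _GIBBS_MAX_D:
        raise CapacityError(f"gibbs_sample handles d <= {_GIBBS_MAX_D}, got {d}")
    if tuple(network.nodes) != tuple(dataset.gene_names):
        network = network.aligned(dataset.gene_names)
    if burn_in is None:
        burn_in = iters // 5
    rng = np.random.default_rng(seed)
    X, y = dataset.X, dataset.y
    sigma = np.sqrt(slab.sigma2)
    L = network.laplacian
    sgn = network.coupling_sign
    lam, gam = network.lambda_, network.gamma_

    Xt = np.atleast_2d(test_points) if test_points is not None else np.zeros((0, d + 1))
    n_test = Xt.shape[0]

    z = np.ones(d)
    beta = np.zeros(d + 1)
    beta[0] = sigma[0] * rng.standard_normal()
    eps = fix_eps if fix_eps is not None else noise.mean
    margins_lin = X @ beta if n else np.zeros(0)

    keep = iters - burn_in
    z_sum = np.zeros((n_batches, d))
    b_sum = np.zeros((n_batches, d + 1))
    e_sum = np.zeros(n_batches)
    p_sum = np.zeros((n_batches, n_test))
    counts = np.zeros(n_batches)

    for it in range(iters):
        # flip rate | beta
        if fix_eps is None:
            k_err = int((y * margins_lin < 0).sum()) if n else 0
            eps = _sample_trunc_beta(rng, noise.a0 + k_err, noise.b0 + n - k_err)
        log_eps = np.log(max(eps, 1e-300))
        log_1meps = np.log(max(1.0 - eps, 1e-300))

        # weights and indicators, random scan
        for j in rng.permutation(d + 1):
            coef = X[:, j] if n else np.zeros(0)
            rest = margins_lin - coef * beta[j]
            bps = _piecewise_intervals(coef, rest, y) if n else np.array([])
            edges, logws = _interval_log_weights(bps, coef, rest, y, log_eps,
                                                 log_1meps, sigma[j])
            if j == 0:
                new_b = _draw_from_piecewise(rng, edges, logws, sigma[j])
                beta[j] = new_b
            else:
                g = j - 1
                # prior log odds of z_g given neighbours
                lprior = lam + sgn * gam * (L[g, g] + 2.0 * float(L[g] @ z) - 2.0 * L[g, g] * z[g])
                logw1 = lprior + logsumexp(logws)
                if n:
                    marg0 = y * rest
                    k0 = int((marg0 < 0).sum())
                else:
                    k0 = 0
                logw0 = k0 * log_eps + (n - k0) * log_1meps
                p1 = 1.0 / (1.0 + np.exp(np.clip(logw0 - logw1, -700, 700)))
                if rng.random() < p1:
                    z[g] = 1.0
                    beta[j] = _draw_from_piecewise(rng, edges, logws, sigma[j])
                else:
                    z[g] = 0.0
                    beta[j] = 0.0
            margins_lin = rest + coef * beta[j] if n else margins_lin
        if not np.all(np.isfinite(beta)):
            raise NBSBMError(f"gibbs_sample: non-finite state at iteration {it}")

        if it >= burn_in:
            b = min((it - burn_in) * n_batches // keep, n_batches - 1)
            counts[b] += 1
            z_sum[b] += z
            b_sum[b] += beta
            e_sum[b] += eps
            if n_test:
                p_sum[b] += eps + (1.0 - 2.0 * eps) * heaviside(Xt @ beta)

    z_b = z_sum / counts[:, None]
    b_b = b_sum / counts[:, None]
    e_b = e_sum / counts
    mc_error = {
        "incl_marginals": np.std(z_b, axis=0, ddof=1) / np.sqrt(n_batches),
        "beta_mean": np.std(b_b, axis=0, ddof=1) / np.sqrt(n_batches),
        "eps_mean": float(np.std(e_b, ddof=1) / np.sqrt(n_batches)),
    }
    predictive = p_sum.sum(axis=0) / counts.sum() if n_test else np.zeros(0)
    if n_test:
        p_b = p_sum / counts[:, None]
        mc_error["predictive"] = np.std(p_b, axis=0, ddof=1) / np.sqrt(n_batches)
    return OracleSummary(
        incl_marginals=z_sum.sum(axis=0) / counts.sum(),
        beta_mean=b_sum.sum(axis=0) / counts.sum(),
        eps_mean=float(e_sum.sum() / counts.sum()),
        predictive=predictive,
        mc_error=mc_error,
    )


def _draw_from_piecewise(rng, edges: np.ndarray, logws: np.ndarray, sigma: float) -> float:
    finite = np.isfinite(logws)
    if not finite.any():
        return 0.0
    probs = np.exp(logws - logsumexp(logws))
    probs[~finite] = 0.0
    probs /= probs.sum()
    k = rng.choice(len(probs), p=probs)
    lo, hi = edges[k], edges[k + 1]
    return _sample_trunc_norm(rng, lo, hi, sigma)
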