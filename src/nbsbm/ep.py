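"""Expectation-propagation inference for the network-based sparse Bayesian machine.

The posterior over (beta, z, eps) is approximated by a Gaussian with
full covariance over the weight vector, a Bernoulli per inclusion
indicator and a Beta factor over the label-flip rate.  Three kinds of
intractable factors are replaced by exponential-family sites that EP
refines by cavity removal and moment matching:

* one scalar Gaussian site per observation, acting along the direction
  ``y_i x_i`` (the noisy step-function likelihood; the flip rate enters
  through the current Beta mean),
* one Gaussian x Bernoulli site per gene for the spike-and-slab factor
  (scalar Gaussian on that gene's weight),
* one Bernoulli-pair site per network edge for the MRF coupling.

The sparsity field ``lambda + s*gamma*L_ii`` on each indicator, the
Gaussian slab on the bias weight and the Beta prior on the flip rate
are exponential-family factors already and are kept exact.  Once per
sweep the Beta factor is refreshed from the per-observation posterior
responsibilities of having been label-flipped, which keeps the
flip-rate update closed-form.

Each site update is a rank-one Sherman-Morrison correction of the
covariance; the covariance is additionally recomputed exactly from the
site parameters at the end of every sweep to stop round-off drift.
Site updates are damped (natural-parameter interpolation) because MRF
coupling is a classic source of EP oscillation.  A site whose cavity
would have non-positive variance is skipped that sweep and counted in
``skipped_updates`` rather than clamped.  Non-convergence within
``max_iter`` sweeps is reported via the ``converged`` flag, never
raised: hyperparameter grid search has to tolerate hard settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.special import expit, ndtr

from .exceptions import ValidationError
from .model import Dataset, NoisePrior, SlabSpec, heaviside
from .netprior import NetworkPrior

__all__ = ["EPControls", "PosteriorApproximation", "ep_fit", "predict_proba", "noise_estimate"]

_TAU_FLOOR = 1e-10
_VAR_FLOOR = 1e-12
_SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class EPControls:
    """Knobs of the EP loop; defaults are conservative and rarely need touching."""

    max_iter: int = 200
    tol: float = 1e-4
    damping: float = 0.5
    seed: int = 0
    shuffle: bool = True  # reshuffle sweep order of each site group per sweep

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValidationError("tol must be positive")
        if not 0.0 < self.damping <= 1.0:
            raise ValidationError("damping must lie in (0, 1]")


@dataclass
class PosteriorApproximation:
    """EP posterior: Gaussian over beta, Bernoullis over z, Beta over eps."""

    beta_mean: np.ndarray          # length d+1, index 0 = bias
    beta_var: np.ndarray           # length d+1, strictly positive (diagonal of cov)
    incl_prob: np.ndarray          # length d, approximate P(z_i = 1 | data)
    eps_a: float
    eps_b: float
    converged: bool
    iterations: int
    gene_names: tuple[str, ...]
    beta_cov: np.ndarray | None = None
    skipped_updates: int = 0
    site_params: dict[str, Any] = field(default_factory=dict, repr=False)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "beta_mean": {"__bias__": self.beta_mean[0],
                          **dict(zip(self.gene_names, self.beta_mean[1:].tolist()))},
            "beta_var": {"__bias__": self.beta_var[0],
                         **dict(zip(self.gene_names, self.beta_var[1:].tolist()))},
            "incl_prob": dict(zip(self.gene_names, self.incl_prob.tolist())),
            "eps_a": self.eps_a,
            "eps_b": self.eps_b,
            "eps_mean": noise_estimate(self),
            "converged": self.converged,
            "iterations": self.iterations,
            "skipped_updates": self.skipped_updates,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _step_moments(m_c: float, v_c: float, eps_bar: float) -> tuple[float, float, float]:
    """Tilted mean/variance of u ~ N(m_c, v_c) against eps + (1-2 eps) H(u),
    plus the flip responsibility of the observation."""
    s = math.sqrt(v_c)
    r = m_c / s
    Phi = float(ndtr(r))
    phi = math.exp(-0.5 * r * r) / _SQRT2PI
    Z = eps_bar + (1.0 - 2.0 * eps_bar) * Phi
    alpha = (1.0 - 2.0 * eps_bar) * phi / (Z * s)
    kappa = -(1.0 - 2.0 * eps_bar) * phi * r / (Z * v_c) - alpha * alpha
    m_u = m_c + v_c * alpha
    v_u = max(v_c * (1.0 + v_c * kappa), _VAR_FLOOR)
    resp = eps_bar * (1.0 - Phi) / Z
    return m_u, v_u, resp


def ep_fit(
    dataset: Dataset,
    network: NetworkPrior,
    slab: SlabSpec,
    noise: NoisePrior,
    controls: EPControls = EPControls(),
) -> PosteriorApproximation:
    """Run EP to convergence (or ``max_iter``) and return the approximation."""
    if tuple(network.nodes) != tuple(dataset.gene_names):
        network = network.aligned(dataset.gene_names)
    d = dataset.d
    p = d + 1
    n = dataset.n
    if slab.sigma2.shape != (p,):
        raise ValidationError(f"slab must provide {p} variances, got {slab.sigma2.shape}")
    if n > 0 and len(np.unique(dataset.y)) < 2:
        raise ValidationError("training labels contain a single class")

    A = dataset.y[:, None] * dataset.X if n else np.zeros((0, p))  # rows y_i * x_i
    sigma2 = slab.sigma2

    # scalar site parameters ------------------------------------------
    lik_tau = np.zeros(n)
    lik_eta = np.zeros(n)
    ss_tau = 1.0 / sigma2[1:].copy()   # start at the slab: Q(beta)=prior Gaussian
    ss_eta = np.zeros(d)
    ss_s = np.zeros(d)                 # Bernoulli log-odds contributions
    eu, ev, c_edge = network.edge_couplings()
    m_edges = len(eu)
    es_u = np.zeros(m_edges)
    es_v = np.zeros(m_edges)

    base_tau = np.zeros(p)
    base_tau[0] = 1.0 / sigma2[0]      # exact Gaussian slab on the bias

    def _recompute() -> tuple[np.ndarray, np.ndarray]:
        P = np.diag(base_tau + np.concatenate([[0.0], ss_tau]))
        if n:
            P += (A * lik_tau[:, None]).T @ A
        V = np.linalg.inv(P)
        V = 0.5 * (V + V.T)
        h = np.concatenate([[0.0], ss_eta])
        if n:
            h = h + A.T @ lik_eta
        return V, V @ h

    V, m_vec = _recompute()
    field_z = network.node_field()
    logit_q = field_z + ss_s.copy()
    eps_a, eps_b = float(noise.a0), float(noise.b0)
    q_resp = np.zeros(n)

    # one independent stream per site group so that a group's sweep order
    # is invariant to the other groups' sizes
    seq = np.random.SeedSequence(controls.seed)
    rng_lik, rng_ss, rng_edge = (np.random.default_rng(s) for s in seq.spawn(3))
    damp = controls.damping

    def _rank_one(a_vec: np.ndarray, Va: np.ndarray, s2: float, mu: float,
                  d_tau: float, d_eta: float) -> bool:
        nonlocal V, m_vec
        denom = 1.0 + d_tau * s2
        if denom <= _TAU_FLOOR:
            return False
        V -= (d_tau / denom) * np.outer(Va, Va)
        m_vec = m_vec + ((d_eta - d_tau * mu) / denom) * Va
        return True

    skipped = 0
    converged = False
    it = 0
    for it in range(1, controls.max_iter + 1):
        old_state = _state_vector(m_vec, V, logit_q, eps_a, eps_b)

        # --- likelihood sites ----------------------------------------
        order = rng_lik.permutation(n) if controls.shuffle else np.arange(n)
        eps_bar = float(np.clip(eps_a / (eps_a + eps_b), 1e-10, 0.5))
        for i in order:
            a_vec = A[i]
            Va = V @ a_vec
            s2 = float(a_vec @ Va)
            mu = float(a_vec @ m_vec)
            tau_c = 1.0 / s2 - lik_tau[i]
            if tau_c <= _TAU_FLOOR:
                skipped += 1
                continue
            v_c = 1.0 / tau_c
            m_c = (mu / s2 - lik_eta[i]) * v_c
            m_u, v_u, resp = _step_moments(m_c, v_c, eps_bar)
            tau_full = 1.0 / v_u - tau_c
            eta_full = m_u / v_u - (m_c / v_c)
            new_tau = (1 - damp) * lik_tau[i] + damp * tau_full
            new_eta = (1 - damp) * lik_eta[i] + damp * eta_full
            if _rank_one(a_vec, Va, s2, mu, new_tau - lik_tau[i], new_eta - lik_eta[i]):
                lik_tau[i] = new_tau
                lik_eta[i] = new_eta
                q_resp[i] = resp
            else:
                skipped += 1

        # --- spike-and-slab sites ------------------------------------
        order = rng_ss.permutation(d) if controls.shuffle else np.arange(d)
        for g in order:
            j = g + 1
            s2 = float(V[j, j])
            mu = float(m_vec[j])
            tau_c = 1.0 / s2 - ss_tau[g]
            if tau_c < 0.0:
                skipped += 1
                continue
            tau_c = max(tau_c, _TAU_FLOOR)
            v_c = 1.0 / tau_c
            m_c = (mu / s2 - ss_eta[g]) * v_c
            l_c = logit_q[g] - ss_s[g]
            s2slab = sigma2[j]
            v_sum = v_c + s2slab
            logZ1 = -0.5 * math.log(2 * math.pi * v_sum) - 0.5 * m_c * m_c / v_sum
            logZ0 = -0.5 * math.log(2 * math.pi * v_c) - 0.5 * m_c * m_c / v_c
            dlogZ = logZ1 - logZ0
            p1 = float(expit(l_c + dlogZ))
            shrink = s2slab / v_sum
            m1 = m_c * shrink
            v1 = v_c * shrink
            m_t = p1 * m1
            v_t = max(p1 * (v1 + m1 * m1) - m_t * m_t, _VAR_FLOOR)
            tau_full = 1.0 / v_t - tau_c
            eta_full = m_t / v_t - (m_c / v_c)
            new_tau = (1 - damp) * ss_tau[g] + damp * tau_full
            new_eta = (1 - damp) * ss_eta[g] + damp * eta_full
            e_j = np.zeros(p)
            e_j[j] = 1.0
            if _rank_one(e_j, V[:, j].copy(), s2, mu, new_tau - ss_tau[g],
                         new_eta - ss_eta[g]):
                new_s = (1 - damp) * ss_s[g] + damp * dlogZ
                logit_q[g] += new_s - ss_s[g]
                ss_tau[g], ss_eta[g], ss_s[g] = new_tau, new_eta, new_s
            else:
                skipped += 1

        # --- MRF edge sites ------------------------------------------
        order = rng_edge.permutation(m_edges) if controls.shuffle else np.arange(m_edges)
        for k in order:
            u, v = eu[k], ev[k]
            lu = logit_q[u] - es_u[k]
            lv = logit_q[v] - es_v[k]
            su_t = np.logaddexp(0.0, lv + c_edge[k]) - np.logaddexp(0.0, lv)
            sv_t = np.logaddexp(0.0, lu + c_edge[k]) - np.logaddexp(0.0, lu)
            new_su = (1 - damp) * es_u[k] + damp * su_t
            new_sv = (1 - damp) * es_v[k] + damp * sv_t
            logit_q[u] += new_su - es_u[k]
            logit_q[v] += new_sv - es_v[k]
            es_u[k], es_v[k] = new_su, new_sv

        # --- flip-rate refresh and exact covariance refresh ----------
        if n:
            total_q = float(q_resp.sum())
            eps_a = noise.a0 + total_q
            eps_b = noise.b0 + (n - total_q)
        V, m_vec = _recompute()

        delta = np.max(np.abs(_state_vector(m_vec, V, logit_q, eps_a, eps_b) - old_state))
        if delta < controls.tol:
            converged = True
            break

    beta_var = np.maximum(np.diag(V).copy(), _VAR_FLOOR)
    return PosteriorApproximation(
        beta_mean=m_vec.copy(),
        beta_var=beta_var,
        incl_prob=expit(logit_q),
        eps_a=eps_a,
        eps_b=eps_b,
        converged=converged,
        iterations=it,
        gene_names=tuple(dataset.gene_names),
        beta_cov=V,
        skipped_updates=skipped,
        site_params={
            "lik_tau": lik_tau, "lik_eta": lik_eta,
            "ss_tau": ss_tau, "ss_eta": ss_eta, "ss_s": ss_s,
            "edge_u": eu, "edge_v": ev, "es_u": es_u, "es_v": es_v,
        },
    )


def _state_vector(m_vec, V, logit_q, eps_a, eps_b) -> np.ndarray:
    eps_mean = eps_a / (eps_a + eps_b)
    return np.concatenate([m_vec, np.diag(V), expit(logit_q), [eps_mean]])


def predict_proba(
    posterior: PosteriorApproximation,
    x: np.ndarray,
    noise_mean: float | None = None,
) -> float | np.ndarray:
    """Probability of the sensitive class (+1) for feature vector(s) ``x``.

    Uses the Gaussian approximation of the predictive integral:
    ``eps + (1 - 2 eps) * PhiN(m / s)`` with ``m`` the posterior-mean
    projection and ``s`` the predictive standard deviation of beta'x.
    ``x`` must include the leading bias 1.
    """
    if noise_mean is None:
        noise_mean = noise_estimate(posterior)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != posterior.beta_mean.shape[0]:
        raise ValidationError(
            f"x has {X.shape[1]} components, posterior expects {posterior.beta_mean.shape[0]}")
    m = X @ posterior.beta_mean
    if posterior.beta_cov is not None:
        s2 = np.einsum("ij,jk,ik->i", X, posterior.beta_cov, X)
    else:
        s2 = (X * X) @ posterior.beta_var
    s2 = np.maximum(s2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s2 > 0, m / np.sqrt(np.maximum(s2, _VAR_FLOOR)), np.nan)
    inner = np.where(s2 > 0, ndtr(ratio), heaviside(m))
    prob = noise_mean + (1.0 - 2.0 * noise_mean) * inner
    return float(prob[0]) if single else prob


def noise_estimate(posterior: PosteriorApproximation) -> float:
    """Posterior mean flip rate, clipped to the identifiable range [0, 1/2]."""
    return float(np.clip(posterior.eps_a / (posterior.eps_a + posterior.eps_b), 0.0, 0.5))
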