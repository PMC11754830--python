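"""Bernoulli-mixture EM over bit vectors with BIC model selection.

Each retained read is modelled as a draw from one of K conformations;
conformation k modifies position j independently with probability mu_kj
(A/C positions only — the informative mask — since G/U carry no DMS
signal). Reads contribute to the likelihood only at positions informative
in that read (missing-at-random treatment of uninformative codes).

Because the quality filters discard any read with two mutations closer
than ``min_mutation_gap``, surviving reads live on a truncated sample
space. With the validity correction enabled, each cluster's per-read
likelihood is divided by ``valid_read_probability(mu_k)`` — the chance a
read drawn from cluster k survives the close-mutation rule. The fitted
mixing weights of that truncated model converge to the *post-filter*
cluster proportions; the model therefore also reports de-truncated
proportions ``pi`` (weights divided by each cluster's survival probability
and renormalized), which estimate the pre-filter ensemble composition.

The corrected M-step is no longer closed-form (the survival term depends
on mu), so mu is updated by bounded quasi-Newton ascent of the complete
-data objective, warm-started from the current value; the line search only
accepts improvements, preserving EM's monotone log-likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .bitvectors import MATCH, MUTATION, BitMatrix

__all__ = [
    "EnsembleModel",
    "valid_read_probability",
    "em_fit",
    "bic",
    "select_k",
    "cluster_abundances",
]

_MU_EPS = 1e-6
_MU_INIT_RANGE = (0.001, 0.2)  # typical DMS per-position mutation rates


def valid_read_probability(mu, min_gap: int = 4):
    """Probability that independent Bernoulli(mu_j) draws contain no two
    successes at distance < ``min_gap``.

    Dynamic program over positions tracking the (capped) distance since the
    last success; O(M * min_gap). ``mu`` may be a single profile of shape
    (M,) or a batch (..., M); the result drops the last axis.
    """
    mu = np.asarray(mu, dtype=float)
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("mu must lie in [0, 1]")
    scalar_in = mu.ndim == 1
    if scalar_in:
        mu = mu[None, :]
    g = min_gap
    M = mu.shape[-1]
    # state d = min(distance since last success, g); start: no success yet
    s = np.zeros(mu.shape[:-1] + (g + 1,))
    s[..., g] = 1.0
    for j in range(M):
        m = mu[..., j]
        fail = s * (1.0 - m)[..., None]
        new = np.zeros_like(s)
        new[..., 1:] = fail[..., :-1]
        new[..., -1] += fail[..., -1]
        # a success is valid only if the previous success is >= g back
        new[..., 0] = (s[..., g - 1] + s[..., g]) * m
        s = new
    p = s.sum(axis=-1)
    return float(p[0]) if scalar_in else p


def _survival_and_grad(
    mu_full: np.ndarray, min_gap: int, grad_idx: np.ndarray
) -> tuple[float, np.ndarray]:
    """p_valid and its exact gradient at positions ``grad_idx``.

    p is multilinear in each mu_j, so dp/dmu_j = p(mu_j=1) - p(mu_j=0);
    all 2*len(grad_idx)+1 evaluations run as one batched DP.
    """
    m = grad_idx.size
    batch = np.broadcast_to(mu_full, (2 * m + 1, mu_full.size)).copy()
    rows = np.arange(m)
    batch[rows, grad_idx] = 1.0
    batch[m + rows, grad_idx] = 0.0
    p = valid_read_probability(batch, min_gap)
    return float(p[-1]), p[:m] - p[m : 2 * m]


@dataclass
class EnsembleModel:
    """A fitted K-cluster Bernoulli mixture over one bit-vector population.

    ``pi`` is the reported ensemble composition (de-truncated when the
    validity correction is on); ``pi_observed`` is the raw fitted mixing
    weight, which tracks the post-filter read population. ``mu`` has one
    row per cluster over the full window, NaN outside the informative
    mask. Clusters are ordered by descending ``pi``.
    """

    K: int
    pi: np.ndarray
    pi_observed: np.ndarray
    mu: np.ndarray
    responsibilities: np.ndarray
    log_likelihood: float
    bic: float
    n_params: int
    converged: bool
    n_iter: int
    seed: int
    restarts: int
    validity_correction: bool
    min_mutation_gap: int
    loglik_history: np.ndarray
    informative_mask: np.ndarray
    n_reads: float
    collapsed: list[int] = field(default_factory=list)

    def survival_probabilities(self) -> np.ndarray:
        """Per-cluster probability of surviving the close-mutation rule."""
        mu_full = np.nan_to_num(self.mu, nan=0.0)
        return valid_read_probability(mu_full, self.min_mutation_gap)

    def to_json(self) -> str:
        d = {
            "K": self.K,
            "pi": self.pi.tolist(),
            "pi_observed": self.pi_observed.tolist(),
            "mu": [[None if np.isnan(v) else v for v in row] for row in self.mu],
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "restarts": self.restarts,
            "validity_correction": self.validity_correction,
            "min_mutation_gap": self.min_mutation_gap,
            "n_reads": self.n_reads,
            "collapsed": self.collapsed,
        }
        return json.dumps(d, indent=2)

    def responsibilities_table(self, read_ids: list[str]) -> str:
        lines = [
            "# seed=%d restarts=%d tol_converged=%s" % (self.seed, self.restarts, self.converged),
            "read_id\t" + "\t".join(f"cluster_{k + 1}" for k in range(self.K)),
        ]
        for rid, row in zip(read_ids, self.responsibilities):
            lines.append(rid + "\t" + "\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def bic(log_likelihood: float, K: int, M: int, n_reads: float) -> float:
    """Bayesian Information Criterion: -2*logL + (K*M + K - 1)*ln(n)."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    n_params = K * M + K - 1
    return -2.0 * log_likelihood + n_params * np.log(n_reads)


def _corrected_mu_update(
    mu_k: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    N_k: float,
    mask_idx: np.ndarray,
    width: int,
    min_gap: int,
) -> np.ndarray:
    """Ascend Q(mu) = sum_j [a_j log mu_j + b_j log(1-mu_j)] - N_k log p_valid.

    One fixed-point step: linearize log p_valid at the current mu (exact
    multilinear gradient), solve the resulting per-coordinate stationarity
    condition a/mu - b/(1-mu) = N*c in closed form (a quadratic in mu), and
    backtrack toward the current value until Q improves. Accepting only
    improvements keeps the outer EM monotone (generalized EM).
    """
    mu0 = np.clip(mu_k, _MU_EPS, 1 - _MU_EPS)

    def q_value(mu_masked: np.ndarray) -> float:
        mu_full = np.zeros(width)
        mu_full[mask_idx] = mu_masked
        p = valid_read_probability(mu_full, min_gap)
        return float(
            (a * np.log(mu_masked) + b * np.log1p(-mu_masked)).sum()
            - N_k * np.log(p)
        )

    mu_full0 = np.zeros(width)
    mu_full0[mask_idx] = mu0
    p0, dp = _survival_and_grad(mu_full0, min_gap, mask_idx)
    c = N_k * dp / max(p0, 1e-300)  # d/dmu of N_k log p_valid, at mu0
    # stationarity of the linearized Q: c*mu^2 - (c + a + b)*mu + a = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.sqrt(np.maximum((c + a + b) ** 2 - 4.0 * c * a, 0.0))
        cand = np.where(
            np.abs(c) > 1e-12,
            (c + a + b - disc) / (2.0 * c),
            a / np.maximum(a + b, 1e-300),
        )
    cand = np.clip(np.nan_to_num(cand, nan=0.0), _MU_EPS, 1 - _MU_EPS)
    q0 = (a * np.log(mu0) + b * np.log1p(-mu0)).sum() - N_k * np.log(max(p0, 1e-300))
    step = 1.0
    for _ in range(8):
        trial = np.clip(mu0 + step * (cand - mu0), _MU_EPS, 1 - _MU_EPS)
        if q_value(trial) >= q0:
            return trial
        step *= 0.5
    return mu0


def _em_single(
    Mut: np.ndarray,
    Match: np.ndarray,
    w: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    validity_correction: bool,
    min_gap: int,
    mask_idx: np.ndarray,
    width: int,
):
    n, M = Mut.shape
    mu = rng.uniform(*_MU_INIT_RANGE, size=(K, M))
    pi = np.full(K, 1.0 / K)
    w_sum = w.sum()
    history: list[float] = []
    converged = False
    gamma = np.full((n, K), 1.0 / K)
    for it in range(max_iter):
        mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
        if validity_correction:
            mu_full = np.zeros((K, width))
            mu_full[:, mask_idx] = mu
            log_p_valid = np.log(valid_read_probability(mu_full, min_gap))
        else:
            log_p_valid = np.zeros(K)
        logB = Mut @ np.log(mu).T + Match @ np.log1p(-mu).T
        logw = logB - log_p_valid[None, :] + np.log(np.maximum(pi, 1e-300))[None, :]
        lse = logsumexp(logw, axis=1)
        logL = float((w * lse).sum())
        history.append(logL)
        if it > 0 and abs(logL - history[-2]) < tol:
            converged = True
            break
        gamma = np.exp(logw - lse[:, None])
        gw = gamma * w[:, None]
        N_k = gw.sum(axis=0)
        pi = N_k / w_sum
        a = gw.T @ Mut
        b = gw.T @ Match
        denom = a + b
        if not validity_correction:
            with np.errstate(invalid="ignore"):
                mu_new = np.where(denom > 0, a / np.maximum(denom, 1e-300), mu)
            mu = mu_new
        else:
            for k in range(K):
                if N_k[k] <= 1e-12:
                    continue  # collapsed cluster: leave mu in place
                mu[k] = _corrected_mu_update(
                    mu[k], a[k], b[k], N_k[k], mask_idx, width, min_gap
                )
    return {
        "pi": pi,
        "mu": mu,
        "gamma": gamma,
        "logL": history[-1],
        "history": np.array(history),
        "converged": converged,
        "n_iter": len(history),
    }


def em_fit(
    matrix: BitMatrix,
    K: int,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 0.05,
    max_iter: int = 300,
    validity_correction: bool = True,
    min_mutation_gap: int = 4,
) -> EnsembleModel:
    """Fit a K-cluster Bernoulli mixture; best of ``restarts`` random starts.

    Non-convergence within ``max_iter`` is reported via ``converged=False``,
    not raised. Raises if K exceeds the number of distinct bit vectors.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    mask = matrix.informative_mask
    mask_idx = np.flatnonzero(mask)
    width = matrix.window.width
    codes = matrix.codes
    n_distinct = len(np.unique(codes, axis=0)) if len(codes) else 0
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds {n_distinct} distinct bit vectors")
    Mut = (codes[:, mask_idx] == MUTATION).astype(float)
    Match = (codes[:, mask_idx] == MATCH).astype(float)
    w = matrix.weights
    M = mask_idx.size

    if K == 1 and not validity_correction:
        # closed form: mu_j is the population mutation fraction at j
        a = (Mut * w[:, None]).sum(axis=0)
        d = ((Mut + Match) * w[:, None]).sum(axis=0)
        mu = np.clip(
            np.where(d > 0, a / np.maximum(d, 1e-300), 0.0), _MU_EPS, 1 - _MU_EPS
        )[None, :]
        logL = float(
            (w * (Mut @ np.log(mu[0]) + Match @ np.log1p(-mu[0]))).sum()
        )
        best = {
            "pi": np.array([1.0]),
            "mu": mu,
            "gamma": np.ones((len(codes), 1)),
            "logL": logL,
            "history": np.array([logL]),
            "converged": True,
            "n_iter": 1,
        }
    else:
        children = np.random.SeedSequence(seed).spawn(restarts)
        best = None
        for child in children:
            fit = _em_single(
                Mut,
                Match,
                w,
                K,
                np.random.default_rng(child),
                tol,
                max_iter,
                validity_correction,
                min_mutation_gap,
                mask_idx,
                width,
            )
            if best is None or fit["logL"] > best["logL"]:
                best = fit

    mu_masked = best["mu"]
    mu_full = np.full((K, width), np.nan)
    mu_full[:, mask_idx] = mu_masked
    pi_obs = np.asarray(best["pi"], dtype=float)
    if validity_correction:
        surv = valid_read_probability(np.nan_to_num(mu_full, nan=0.0), min_mutation_gap)
        pi_rep = pi_obs / np.maximum(surv, 1e-300)
        pi_rep = pi_rep / pi_rep.sum()
    else:
        pi_rep = pi_obs.copy()
    order = np.argsort(-pi_rep, kind="stable")
    pi_rep, pi_obs = pi_rep[order], pi_obs[order]
    mu_full = mu_full[order]
    gamma = best["gamma"][:, order]
    collapsed = [int(k) for k in range(K) if pi_obs[k] <= 1e-8]
    n_reads = float(w.sum())
    model = EnsembleModel(
        K=K,
        pi=pi_rep,
        pi_observed=pi_obs,
        mu=mu_full,
        responsibilities=gamma,
        log_likelihood=best["logL"],
        bic=bic(best["logL"], K, M, n_reads),
        n_params=K * M + K - 1,
        converged=best["converged"],
        n_iter=best["n_iter"],
        seed=seed,
        restarts=restarts,
        validity_correction=validity_correction,
        min_mutation_gap=min_mutation_gap,
        loglik_history=best["history"],
        informative_mask=mask,
        n_reads=n_reads,
    )
    return model


def select_k(
    matrix: BitMatrix,
    k_max: int = 3,
    restarts: int = 10,
    seed: int = 0,
    tol: float = 0.05,
    max_iter: int = 300,
    validity_correction: bool = True,
    min_mutation_gap: int = 4,
) -> tuple[EnsembleModel, pd.DataFrame]:
    """Fit K = 1..k_max and return the minimum-BIC model plus the BIC table."""
    rows = []
    models = []
    for K in range(1, k_max + 1):
        seed_k = (seed * 1000003 + K) % (2**31)
        model = em_fit(
            matrix,
            K,
            restarts=restarts,
            seed=seed_k,
            tol=tol,
            max_iter=max_iter,
            validity_correction=validity_correction,
            min_mutation_gap=min_mutation_gap,
        )
        models.append(model)
        rows.append(
            {
                "K": K,
                "log_likelihood": model.log_likelihood,
                "bic": model.bic,
                "converged": model.converged,
                "n_iter": model.n_iter,
            }
        )
    table = pd.DataFrame(rows)
    best = models[int(table["bic"].idxmin())]
    return best, table


def cluster_abundances(model: EnsembleModel) -> np.ndarray:
    """Cluster abundances as percentages in descending order (sum 100)."""
    pct = 100.0 * np.sort(model.pi)[::-1]
    return pct
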