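"""Multivariate hidden Markov model of dive behavioural states.

The observation for each dive is the transformed 4-vector (max depth, bottom
time, dive time, post-dive surface interval), all in [0, 1].  Emissions are
independent Gaussians per feature within a state (diagonal covariance);
parameters (pi, A, mu, sigma) are shared across all sequences (trips) and
fitted by Baum-Welch EM with scaled forward/backward recursions.  Model
selection runs 2-5 states, many random restarts each, retaining the
lowest-AIC converged fit per state count; the choice among state counts is a
user decision informed by the AIC table and biological interpretability.
States are decoded by Viterbi plus forward-backward posteriors, and a
canonical labelling maps fitted states to the field's State 1-4 semantics
(1: longest bottom time; 2: deepest; 4: shallowest; 3: the remainder).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, InputError

__all__ = [
    "HmmFit",
    "StateSeries",
    "fit_em",
    "forward_loglik",
    "select_model",
    "decode",
    "summarise_states",
    "canonical_labels",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_N_FEATURES = 4


# ---------------------------------------------------------------------------
# jitted kernels (scaled linear-domain recursions)

@njit(cache=True)
def _forward_scaled(pi, A, B):  # B: (T, K) emission likelihoods, row-scaled
    T, K = B.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    s = a.sum()
    if not s > 0.0:  # zero or NaN: impossible observation
        return alpha, c, -1
    alpha[0] = a / s
    c[0] = s
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        if not s > 0.0:
            return alpha, c, t - 1
        alpha[t] = a / s
        c[t] = s
    return alpha, c, T


@njit(cache=True)
def _backward_scaled(A, B, c):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def _viterbi_path(log_pi, log_A, logB):
    T, K = logB.shape
    delta = log_pi + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        nd = np.empty(K)
        for k in range(K):
            best, arg = -np.inf, 0
            for j in range(K):
                v = delta[j] + log_A[j, k]
                if v > best:  # strict > keeps the first index on ties
                    best, arg = v, j
            nd[k] = best + logB[t, k]
            psi[t, k] = arg
        delta = nd
    path = np.empty(T, dtype=np.int64)
    best, arg = -np.inf, 0
    for k in range(K):
        if delta[k] > best:
            best, arg = delta[k], k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


def _emission_logpdf(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """(T, K) log density under independent per-feature Gaussians."""
    z = (x[:, None, :] - mu[None, :, :]) / sigma[None, :, :]
    return -0.5 * np.sum(z * z + _LOG2PI, axis=2) - np.sum(np.log(sigma), axis=1)


# ---------------------------------------------------------------------------

@dataclass
class HmmFit:
    """A fitted HMM: shared initial, transition and emission parameters."""

    n_states: int
    pi: np.ndarray
    A: np.ndarray
    mu: np.ndarray  # (K, F), transformed scale
    sigma: np.ndarray  # (K, F)
    loglik: float
    aic: float
    n_params: int
    seed: int
    converged: bool
    n_iter: int = 0
    sigma_floored: bool = False

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_states": self.n_states,
                    "pi": self.pi.tolist(),
                    "A": self.A.tolist(),
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "loglik": self.loglik,
                    "aic": self.aic,
                    "n_params": self.n_params,
                    "seed": self.seed,
                    "converged": self.converged,
                    "n_iter": self.n_iter,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "HmmFit":
        with open(path) as fh:
            doc = json.load(fh)
        for k in ("pi", "A", "mu", "sigma"):
            doc[k] = np.asarray(doc[k], dtype=float)
        return cls(**doc)


@dataclass
class StateSeries:
    """Decoded states: Viterbi paths and posterior probabilities per sequence."""

    viterbi: list[np.ndarray]  # int arrays, 0-based fitted state indices
    posterior: list[np.ndarray]  # (T, K) forward-backward probabilities
    sequence_ids: list[str] = field(default_factory=list)


def _n_params(K: int, F: int) -> int:
    return (K - 1) + K * (K - 1) + 2 * K * F


def _check_sequences(sequences: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for s in sequences:
        a = np.asarray(s, dtype=float)
        if a.ndim != 2:
            raise InputError("each sequence must be a 2-d (T, features) array")
        if a.shape[0] < 2:
            raise InputError("each sequence must have length >= 2")
        out.append(a)
    return out


def _init_params(obs, K, rng, sigma_floor):
    """Random initialisation: k-means++-style means, pooled sds, Dirichlet pi/A."""
    T, F = obs.shape
    centers = np.empty((K, F))
    centers[0] = obs[rng.integers(T)]
    for k in range(1, K):
        d2 = np.min(
            ((obs[:, None, :] - centers[None, :k, :]) ** 2).sum(axis=2), axis=1
        )
        tot = d2.sum()
        p = d2 / tot if tot > 0 else None
        centers[k] = obs[rng.choice(T, p=p)]
    sigma = np.maximum(obs.std(axis=0), sigma_floor)
    sigma = np.tile(sigma, (K, 1))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), size=K)
    return pi, A, centers, sigma


def fit_em(
    sequences: list[np.ndarray],
    n_states: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    sigma_floor: float = 1e-4,
) -> HmmFit:
    """Baum-Welch EM over multiple independent sequences sharing parameters.

    Convergence when the relative log-likelihood change drops below ``tol``
    (or ``max_iter`` is reached, in which case the fit is marked
    non-converged).  Collapsing emission scales are floored at
    ``sigma_floor`` and flagged; a NaN likelihood marks the fit
    non-converged.
    """
    seqs = _check_sequences(sequences)
    obs = np.vstack(seqs)
    F = obs.shape[1]
    rng = np.random.default_rng(seed)
    pi, A, mu, sigma = _init_params(obs, n_states, rng, sigma_floor)
    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    floored = False
    it = 0
    for it in range(1, max_iter + 1):
        ll = 0.0
        g0 = np.zeros(n_states)
        xi_sum = np.zeros((n_states, n_states))
        w_sum = np.zeros(n_states)
        wx = np.zeros((n_states, F))
        wx2 = np.zeros((n_states, F))
        ok = True
        for x in seqs:
            logB = _emission_logpdf(x, mu, sigma)
            m = logB.max(axis=1)
            if not np.all(np.isfinite(m)):
                ok = False
                break
            B = np.exp(logB - m[:, None])
            alpha, c, good = _forward_scaled(pi, A, B)
            if good < x.shape[0]:
                ok = False
                break
            ll += float(np.sum(np.log(c)) + np.sum(m))
            beta = _backward_scaled(A, B, c)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            # xi_t(i,j) prop. alpha_t(i) A(i,j) B(t+1,j) beta(t+1,j) / c(t+1)
            xi = np.einsum(
                "ti,ij,tj->ij",
                alpha[:-1] / c[1:, None],
                A,
                B[1:] * beta[1:],
            )
            xi_sum += xi
            g0 += gamma[0]
            w_sum += gamma.sum(axis=0)
            wx += gamma.T @ x
            wx2 += gamma.T @ (x * x)
        if not ok or not np.isfinite(ll):
            converged = False
            break
        # M-step
        pi = g0 / g0.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), 1.0 / n_states)
        w = np.maximum(w_sum, 1e-300)[:, None]
        mu = wx / w
        var = np.maximum(wx2 / w - mu * mu, 0.0)
        sigma = np.sqrt(var)
        if np.any(sigma < sigma_floor):
            floored = True
            sigma = np.maximum(sigma, sigma_floor)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
    k = _n_params(n_states, F)
    return HmmFit(
        n_states=n_states,
        pi=pi,
        A=A,
        mu=mu,
        sigma=sigma,
        loglik=float(ll),
        aic=float(2 * k - 2 * ll),
        n_params=k,
        seed=seed,
        converged=converged,
        n_iter=it,
        sigma_floored=floored,
    )


def forward_loglik(fit: HmmFit, sequence: np.ndarray) -> float:
    """Exact marginal log-likelihood of one sequence under a fit (scaled forward)."""
    x = np.asarray(sequence, dtype=float)
    logB = _emission_logpdf(x, fit.mu, fit.sigma)
    m = logB.max(axis=1)
    if not np.all(np.isfinite(m)):
        warnings.warn("observation impossible under every state; -inf likelihood")
        return -np.inf
    B = np.exp(logB - m[:, None])
    _, c, good = _forward_scaled(fit.pi, fit.A, B)
    if good < x.shape[0]:
        warnings.warn("observation impossible under every state; -inf likelihood")
        return -np.inf
    return float(np.sum(np.log(c)) + np.sum(m))


def select_model(
    sequences: list[np.ndarray],
    states: tuple[int, ...] = (2, 3, 4, 5),
    n_restarts: int = 100,
    base_seed: int = 0,
    **em_kwargs,
) -> tuple[pd.DataFrame, dict[int, HmmFit]]:
    """Best-of-``n_restarts`` AIC per state count.

    Restart r uses seed ``base_seed + r`` so every fit is individually
    reproducible.  Returns the AIC comparison table and the retained
    (lowest-AIC converged) fit per state count; rows where no restart
    converged are flagged with a NaN AIC.
    """
    rows = []
    best: dict[int, HmmFit] = {}
    for K in states:
        fits = [
            fit_em(sequences, K, seed=base_seed + r, **em_kwargs)
            for r in range(n_restarts)
        ]
        conv = [f for f in fits if f.converged]
        n_conv = len(conv)
        if conv:
            b = min(conv, key=lambda f: f.aic)
            best[K] = b
            rows.append(
                {
                    "n_states": K,
                    "aic": b.aic,
                    "loglik": b.loglik,
                    "n_params": b.n_params,
                    "seed": b.seed,
                    "n_converged": n_conv,
                }
            )
        else:
            rows.append(
                {
                    "n_states": K,
                    "aic": np.nan,
                    "loglik": np.nan,
                    "n_params": _n_params(K, sequences[0].shape[1]),
                    "seed": -1,
                    "n_converged": 0,
                }
            )
    return pd.DataFrame(rows), best


def decode(fit: HmmFit, sequences: list[np.ndarray], sequence_ids=None) -> StateSeries:
    """Viterbi paths and forward-backward posteriors for each sequence."""
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    log_pi = np.log(np.maximum(fit.pi, 1e-300))
    log_A = np.log(np.maximum(fit.A, 1e-300))
    paths, posts = [], []
    for x in seqs:
        logB = _emission_logpdf(x, fit.mu, fit.sigma)
        path, _ = _viterbi_path(log_pi, log_A, logB)
        m = logB.max(axis=1)
        B = np.exp(logB - m[:, None])
        alpha, c, good = _forward_scaled(fit.pi, fit.A, B)
        if good < x.shape[0]:
            raise InputError("impossible observation; cannot decode")
        beta = _backward_scaled(fit.A, B, c)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        paths.append(path)
        posts.append(gamma)
    ids = list(sequence_ids) if sequence_ids is not None else [
        f"seq{i}" for i in range(len(seqs))
    ]
    return StateSeries(viterbi=paths, posterior=posts, sequence_ids=ids)


def canonical_labels(state_means: pd.DataFrame) -> tuple[dict[int, int], bool]:
    """Map fitted state indices to canonical labels 1-4 from raw-scale means.

    State 1 is the state with the largest mean bottom time, State 2 the
    deepest, State 4 the shallowest and State 3 the remainder.  When those
    criteria collide the fallback orders states by depth: deepest = 2,
    shallowest = 4, and of the middle two the longer bottom time = 1.
    Returns (mapping fitted-index -> label, fallback_used).
    """
    if len(state_means) != 4:
        order = np.argsort(-state_means["max_depth"].to_numpy())
        return {int(state_means.index[i]): r + 1 for r, i in enumerate(order)}, False
    idx = state_means.index.to_numpy()
    bt = state_means["bottom_time"].to_numpy()
    dp = state_means["max_depth"].to_numpy()
    s1 = idx[int(np.argmax(bt))]
    s2 = idx[int(np.argmax(dp))]
    s4 = idx[int(np.argmin(dp))]
    if len({s1, s2, s4}) == 3:
        s3 = next(i for i in idx if i not in (s1, s2, s4))
        return {int(s1): 1, int(s2): 2, int(s3): 3, int(s4): 4}, False
    order = idx[np.argsort(-dp)]
    mid = sorted(order[1:3], key=lambda i: -bt[list(idx).index(i)])
    mapping = {int(order[0]): 2, int(mid[0]): 1, int(mid[1]): 3, int(order[3]): 4}
    return mapping, True


def summarise_states(
    fit: HmmFit,
    decoded: StateSeries,
    features: pd.DataFrame,
) -> dict:
    """Transition structure and raw-scale state summaries after decoding.

    ``features`` must hold the raw per-dive metrics, row-aligned with the
    concatenation of the decoded sequences.  Reports the fitted pi and A
    (rows re-ordered to canonical labels), per-state raw means and medians,
    and per-individual state proportions.
    """
    states = np.concatenate(decoded.viterbi)
    if len(states) != len(features):
        raise InputError("features must align with the decoded sequences")
    df = features.copy()
    df["fitted_state"] = states
    raw_cols = ["max_depth", "bottom_time", "dive_time", "surface_interval"]
    means = df.groupby("fitted_state")[raw_cols].mean()
    mapping, fallback = canonical_labels(means)
    for k in range(fit.n_states):  # states never decoded keep their own index
        mapping.setdefault(k, max(mapping.values(), default=0) + 1)
    df["state"] = df["fitted_state"].map(mapping)
    perm = np.array(sorted(mapping, key=lambda k: mapping[k]))
    A = fit.A[np.ix_(perm, perm)]
    pi = fit.pi[perm]
    summary = df.groupby("state")[raw_cols].agg(["mean", "median"])
    props = (
        df.groupby(["id", "state"]).size().unstack(fill_value=0)
        if "id" in df.columns
        else None
    )
    if props is not None:
        props = props.div(props.sum(axis=1), axis=0)
    return {
        "pi": pi,
        "A": A,
        "label_mapping": mapping,
        "fallback_labelling": fallback,
        "state_summary": summary,
        "individual_proportions": props,
        "states": df["state"].to_numpy(),
        "self_transition_dominant": bool(
            np.all(np.diag(A) >= A.max(axis=1) - 1e-12)
        ),
    }
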