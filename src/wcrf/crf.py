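"""Exact linear-chain CRF computations in log space.

The chain scores a label path y_1..y_N as

    s(X, y) = A[start, y_1] + sum_i A[y_{i-1}, y_i] + sum_i P[i, y_i]
              + A[y_N, end]

with an N x K emission table ``P`` and a (K+2) x (K+2) transition table
``A`` that carries mandatory synthetic start/end states (row/column K and
K+1).  The partition function over all K^N paths is computed by the forward
recursion in O(N K^2); posterior per-position marginals come from
forward-backward.  Everything runs in log space with the log-sum-exp trick,
since exponentiated path scores overflow immediately for realistic lengths.

A brute-force path-enumeration oracle is included for testing: every
quantity here must agree with exhaustive enumeration on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "PotentialTables",
    "score_path",
    "forward_log_alphas",
    "backward_log_betas",
    "log_partition",
    "posterior_marginals",
    "crf_nll",
    "crf_nll_gradient",
    "viterbi_decode",
    "enumerate_oracle",
    "weighted_marginal_nll",
    "weighted_marginal_nll_gradient",
]


@dataclass
class PotentialTables:
    """Per-sequence emission scores P (N x K) and transitions A ((K+2) x (K+2))."""

    emissions: np.ndarray
    transitions: np.ndarray

    def __post_init__(self):
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[0] < 1:
            raise ValueError("emissions must be N x K with N >= 1")
        n, k = self.emissions.shape
        if self.transitions.shape != (k + 2, k + 2):
            raise ValueError(
                f"transitions must be ({k + 2}, {k + 2}) for K={k} tags, "
                f"got {self.transitions.shape}"
            )
        if not (np.isfinite(self.emissions).all() and np.isfinite(self.transitions).all()):
            raise ValueError("potentials must be finite")

    @property
    def n(self) -> int:
        return self.emissions.shape[0]

    @property
    def k(self) -> int:
        return self.emissions.shape[1]

    @property
    def start(self) -> int:
        return self.k

    @property
    def end(self) -> int:
        return self.k + 1


def _check_labels(pot: PotentialTables, labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    if y.shape != (pot.n,):
        raise ValueError(f"need {pot.n} labels, got shape {y.shape}")
    if y.min() < 0 or y.max() >= pot.k:
        raise IndexError("label index out of range")
    return y


def score_path(pot: PotentialTables, labels) -> float:
    """Unnormalized log score of one label path, start/end included."""
    y = _check_labels(pot, labels)
    a, p = pot.transitions, pot.emissions
    s = a[pot.start, y[0]] + a[y[-1], pot.end]
    s += p[np.arange(pot.n), y].sum()
    s += a[y[:-1], y[1:]].sum()
    return float(s)


def forward_log_alphas(pot: PotentialTables) -> np.ndarray:
    """Forward table: alpha[i, k] = log sum over prefixes ending in tag k at i."""
    n, k = pot.n, pot.k
    a = pot.transitions[:k, :k]
    alpha = np.empty((n, k))
    alpha[0] = pot.transitions[pot.start, :k] + pot.emissions[0]
    for i in range(1, n):
        alpha[i] = pot.emissions[i] + logsumexp(alpha[i - 1][:, None] + a, axis=0)
    return alpha


def backward_log_betas(pot: PotentialTables) -> np.ndarray:
    """Backward table: beta[i, j] = log sum over suffixes given tag j at i.

    beta excludes the emission at position i itself, so that
    alpha + beta - logZ gives the posterior log-marginals.
    """
    n, k = pot.n, pot.k
    a = pot.transitions[:k, :k]
    beta = np.empty((n, k))
    beta[n - 1] = pot.transitions[:k, pot.end]
    for i in range(n - 2, -1, -1):
        beta[i] = logsumexp(a + (pot.emissions[i + 1] + beta[i + 1])[None, :], axis=1)
    return beta


def log_partition(pot: PotentialTables) -> float:
    """log Z: log-sum-exp of the scores of all K^N label paths."""
    alpha = forward_log_alphas(pot)
    return float(logsumexp(alpha[-1] + pot.transitions[: pot.k, pot.end]))


def posterior_marginals(pot: PotentialTables) -> np.ndarray:
    """Posterior P(y_i = k | X) for every position, rows summing to one."""
    alpha = forward_log_alphas(pot)
    beta = backward_log_betas(pot)
    log_z = logsumexp(alpha[-1] + pot.transitions[: pot.k, pot.end])
    m = np.exp(alpha + beta - log_z)
    # renormalize away accumulated rounding so each row sums to 1 exactly
    return m / m.sum(axis=1, keepdims=True)


def crf_nll(pot: PotentialTables, labels) -> float:
    """Standard CRF negative log-likelihood: log Z - s(X, y) >= 0."""
    return log_partition(pot) - score_path(pot, labels)


def crf_nll_gradient(pot: PotentialTables, labels) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of ``crf_nll`` w.r.t. emissions and transitions.

    d/dP = posterior marginals - one-hot(y); d/dA = expected minus observed
    transition counts (start/end rows included).
    """
    y = _check_labels(pot, labels)
    n, k = pot.n, pot.k
    alpha = forward_log_alphas(pot)
    beta = backward_log_betas(pot)
    log_z = logsumexp(alpha[-1] + pot.transitions[:k, pot.end])

    d_p = np.exp(alpha + beta - log_z)
    d_a = np.zeros_like(pot.transitions)
    a = pot.transitions[:k, :k]
    for i in range(1, n):
        # pairwise posterior P(y_{i-1}=j, y_i=k | X)
        pair = np.exp(
            alpha[i - 1][:, None] + a + (pot.emissions[i] + beta[i])[None, :] - log_z
        )
        d_a[:k, :k] += pair
    d_a[pot.start, :k] += d_p[0]
    d_a[:k, pot.end] += d_p[-1]

    d_p[np.arange(n), y] -= 1.0
    d_a[pot.start, y[0]] -= 1.0
    d_a[y[-1], pot.end] -= 1.0
    for i in range(1, n):
        d_a[y[i - 1], y[i]] -= 1.0
    return d_p, d_a


def viterbi_decode(pot: PotentialTables) -> list[int]:
    """Argmax label path; ties broken toward the lowest tag index."""
    n, k = pot.n, pot.k
    a = pot.transitions[:k, :k]
    delta = pot.transitions[pot.start, :k] + pot.emissions[0]
    back = np.empty((n, k), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + a  # cand[j, k']
        back[i] = np.argmax(cand, axis=0)  # argmax takes first (lowest) index
        delta = cand[back[i], np.arange(k)] + pot.emissions[i]
    delta = delta + pot.transitions[:k, pot.end]
    path = [int(np.argmax(delta))]
    for i in range(n - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def enumerate_oracle(pot: PotentialTables) -> tuple[float, list[int], np.ndarray]:
    """Exhaustive enumeration over all K^N paths (reference implementation).

    Returns (log_partition, best_path, marginals).  Ties in the best path
    are broken lexicographically (lowest tag indices first), matching the
    Viterbi tie-break.
    """
    n, k = pot.n, pot.k
    if k**n > 10**6:
        raise ValueError(f"instance too large to enumerate: K^N = {k}^{n}")
    scores = []
    paths = list(product(range(k), repeat=n))
    for path in paths:
        scores.append(score_path(pot, path))
    scores = np.array(scores)
    log_z = float(logsumexp(scores))
    best = paths[int(np.argmax(scores))]  # argmax -> first max -> lexicographic
    probs = np.exp(scores - log_z)
    marg = np.zeros((n, k))
    for path, pr in zip(paths, probs):
        for i, yi in enumerate(path):
            marg[i, yi] += pr
    return log_z, list(best), marg


def weighted_marginal_nll(
    pot: PotentialTables, labels, token_weights
) -> float:
    """Class-weighted CRF loss: sum_i w_i * (-log m[i, y_i]).

    ``m`` are the forward-backward posterior marginals, so transition
    structure still shapes each token's term; with all weights 1 and zero
    transitions this reduces to the sum of per-token softmax cross-entropies.
    ``token_weights`` holds one positive weight per position (the class
    weight of that position's gold tag).
    """
    y = _check_labels(pot, labels)
    w = np.asarray(token_weights, dtype=float)
    if w.shape != (pot.n,):
        raise ValueError(f"need {pot.n} token weights, got shape {w.shape}")
    alpha = forward_log_alphas(pot)
    beta = backward_log_betas(pot)
    log_z = logsumexp(alpha[-1] + pot.transitions[: pot.k, pot.end])
    idx = np.arange(pot.n)
    log_m = alpha[idx, y] + beta[idx, y] - log_z
    return float(-(w * log_m).sum())


def weighted_marginal_nll_gradient(
    pot: PotentialTables, labels, token_weights
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of ``weighted_marginal_nll`` w.r.t. (P, A).

    The loss is W*logZ - sum_i w_i (alpha[i,y_i] + beta[i,y_i]); reverse-mode
    adjoints are propagated by hand through the forward and backward
    log-sum-exp recursions, costing the same O(N K^2) as the loss itself.
    """
    y = _check_labels(pot, labels)
    n, k = pot.n, pot.k
    w = np.asarray(token_weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"need {n} token weights, got shape {w.shape}")
    a = pot.transitions[:k, :k]
    p = pot.emissions
    alpha = forward_log_alphas(pot)
    beta = backward_log_betas(pot)
    final = alpha[-1] + pot.transitions[:k, pot.end]
    log_z = logsumexp(final)
    w_total = w.sum()

    d_p = np.zeros_like(p)
    d_a = np.zeros_like(pot.transitions)

    # seed adjoints: dL/d alpha[i, y_i] = -w_i, dL/d beta[i, y_i] = -w_i
    alpha_bar = np.zeros((n, k))
    beta_bar = np.zeros((n, k))
    idx = np.arange(n)
    alpha_bar[idx, y] -= w
    beta_bar[idx, y] -= w

    # dL/d logZ = W; logZ = LSE_k(alpha[N-1,k] + A[k, end])
    g = softmax(final)
    alpha_bar[n - 1] += w_total * g
    d_a[:k, pot.end] += w_total * g

    # reverse the forward recursion: alpha[i] = P[i] + LSE_j(alpha[i-1,j] + A[j,:])
    for i in range(n - 1, 0, -1):
        ab = alpha_bar[i]
        d_p[i] += ab
        # sigma[j, k'] = softmax over j of alpha[i-1,j] + A[j,k']
        sigma = np.exp(alpha[i - 1][:, None] + a - (alpha[i] - p[i])[None, :])
        contrib = sigma * ab[None, :]
        alpha_bar[i - 1] += contrib.sum(axis=1)
        d_a[:k, :k] += contrib
    d_p[0] += alpha_bar[0]
    d_a[pot.start, :k] += alpha_bar[0]

    # reverse the backward recursion:
    # beta[i,j] = LSE_k(A[j,k] + P[i+1,k] + beta[i+1,k])
    for i in range(0, n - 1):
        bb = beta_bar[i]
        sigma = np.exp(a + (p[i + 1] + beta[i + 1])[None, :] - beta[i][:, None])
        contrib = sigma * bb[:, None]
        d_a[:k, :k] += contrib
        d_p[i + 1] += contrib.sum(axis=0)
        beta_bar[i + 1] += contrib.sum(axis=0)
    # beta[N-1, j] = A[j, end]
    d_a[:k, pot.end] += beta_bar[n - 1]

    return d_p, d_a
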