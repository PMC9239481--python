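"""Class-weight strategies and loss functions for imbalanced sequence labeling.

The central quantity is the per-class cost parameter w_k.  The recommended
strategy sets

    w_k = N / (K * n_k)

where N is the total token count, K the number of classes and n_k the token
count of class k: a class holding exactly its balanced share N/K of the
tokens gets weight 1, rarer classes get proportionally more.  This strategy
conserves sum_k w_k * n_k = N exactly.  Two simpler alternatives are kept
for comparison: the inverse count 1/n_k and the inverse ratio N/n_k, which
are elementwise rescalings of the recommended weights (by K/N and K
respectively).

Weights are defined per entity class, with B- and I- tags of a class
sharing one weight and O its own, because token counts pool B/I.

Alongside the weighted CRF objective, the module provides the baseline
losses used in imbalance comparisons: weighted softmax cross-entropy, focal
loss, and dice loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .crf import (
    PotentialTables,
    weighted_marginal_nll,
    weighted_marginal_nll_gradient,
)
from .io import LabelAlphabet, tag_class

__all__ = [
    "ClassWeights",
    "TokenClassCounts",
    "STRATEGIES",
    "compute_class_weights",
    "weighted_crf_nll",
    "weighted_crf_nll_gradient",
    "weighted_softmax_ce",
    "weighted_softmax_ce_gradient",
    "focal_loss",
    "focal_loss_from_logits",
    "focal_loss_from_logits_gradient",
    "dice_loss",
    "dice_loss_gradient",
]

STRATEGIES = ("balanced", "inverse_count", "inverse_ratio", "uniform")


@dataclass(frozen=True)
class TokenClassCounts:
    """Token counts n_k per class; N = sum n_k, K = number of classes."""

    classes: tuple[str, ...]
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.classes) != len(self.counts):
            raise ValueError("classes and counts length mismatch")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return sum(self.counts)

    @property
    def k(self) -> int:
        return len(self.classes)

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "TokenClassCounts":
        items = sorted(counts.items())
        return cls(tuple(k for k, _ in items), tuple(v for _, v in items))


@dataclass(frozen=True)
class ClassWeights:
    """Positive per-class cost parameters, aligned with ``classes``."""

    classes: tuple[str, ...]
    weights: tuple[float, ...]
    strategy: str

    def __post_init__(self):
        if len(self.classes) != len(self.weights):
            raise ValueError("classes and weights length mismatch")
        if any(w <= 0 for w in self.weights):
            raise ValueError("all class weights must be positive")

    def weight_of_class(self, class_name: str) -> float:
        return self.weights[self.classes.index(class_name)]

    def weight_of_tag(self, tag: str) -> float:
        """B-X and I-X share class X's weight; O has its own."""
        return self.weight_of_class(tag_class(tag))

    def per_tag(self, alphabet: LabelAlphabet) -> np.ndarray:
        """Weight vector indexed like the alphabet's K tags."""
        return np.array([self.weight_of_tag(t) for t in alphabet.tags])

    @classmethod
    def uniform(cls, classes) -> "ClassWeights":
        classes = tuple(classes)
        return cls(classes, (1.0,) * len(classes), "uniform")


def compute_class_weights(
    counts: TokenClassCounts, strategy: str = "balanced", smooth: bool = False
) -> ClassWeights:
    """Compute per-class weights from token counts.

    strategy:
      - ``balanced``: w_k = N / (K * n_k)  (recommended; conserves
        sum w_k n_k = N, balanced counts give all weights exactly 1)
      - ``inverse_count``: w_k = 1 / n_k
      - ``inverse_ratio``: w_k = N / n_k
      - ``uniform``: w_k = 1

    A zero count is an error unless ``smooth`` is set, in which case every
    count is incremented by one (off by default so corpus bugs surface).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    n_k = np.array(counts.counts, dtype=float)
    if smooth:
        n_k = n_k + 1.0
    if strategy != "uniform" and (n_k == 0).any():
        zero = [c for c, v in zip(counts.classes, n_k) if v == 0]
        raise ValueError(
            f"zero token count for class(es) {zero}; enable smoothing or fix the corpus"
        )
    n = n_k.sum()
    k = counts.k
    if strategy == "balanced":
        w = n / (k * n_k)
    elif strategy == "inverse_count":
        w = 1.0 / n_k
    elif strategy == "inverse_ratio":
        w = n / n_k
    else:
        w = np.ones(k)
    return ClassWeights(counts.classes, tuple(float(x) for x in w), strategy)


def _token_weights(labels, alphabet: LabelAlphabet, class_weights: ClassWeights):
    per_tag = class_weights.per_tag(alphabet)
    if per_tag.shape != (alphabet.size,):
        raise ValueError("weight vector length mismatch with alphabet")
    return per_tag[np.asarray(labels, dtype=int)]


def weighted_crf_nll(
    pot: PotentialTables,
    labels,
    class_weights: ClassWeights,
    alphabet: LabelAlphabet,
) -> float:
    """Class-weighted CRF objective for one sequence.

    Each position contributes w_{c(y_i)} * (-log m[i, y_i]) with m the
    forward-backward posterior marginals, so label dependencies encoded in
    the transition matrix still shape every term.  Reduction is the sum
    over tokens; any batch averaging happens in the trainer.
    """
    w = _token_weights(labels, alphabet, class_weights)
    return weighted_marginal_nll(pot, labels, w)


def weighted_crf_nll_gradient(
    pot: PotentialTables,
    labels,
    class_weights: ClassWeights,
    alphabet: LabelAlphabet,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient of ``weighted_crf_nll`` w.r.t. (emissions, transitions)."""
    w = _token_weights(labels, alphabet, class_weights)
    return weighted_marginal_nll_gradient(pot, labels, w)


def weighted_softmax_ce(logits, labels, token_weights) -> float:
    """Weighted per-token softmax cross-entropy: sum_i w_i * (-log p_i[y_i])."""
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=int)
    w = np.asarray(token_weights, dtype=float)
    if logits.ndim != 2 or y.shape != (logits.shape[0],) or w.shape != y.shape:
        raise ValueError("shape mismatch between logits, labels and weights")
    log_p = log_softmax(logits, axis=1)
    return float(-(w * log_p[np.arange(len(y)), y]).sum())


def weighted_softmax_ce_gradient(logits, labels, token_weights) -> np.ndarray:
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=int)
    w = np.asarray(token_weights, dtype=float)
    p = softmax(logits, axis=1)
    grad = p.copy()
    grad[np.arange(len(y)), y] -= 1.0
    return grad * w[:, None]


def focal_loss(probs_of_true, gamma: float = 2.0, alpha=None) -> float:
    """Focal loss: sum_i alpha_i * (1 - p_i)^gamma * (-log p_i).

    ``probs_of_true`` are the model's probabilities of each token's gold
    label.  gamma=0 recovers plain cross-entropy; larger gamma down-weights
    easy (high-probability) tokens so training focuses on hard ones.
    ``alpha`` is an optional per-token weight, defaulting to 1 everywhere.
    """
    p = np.asarray(probs_of_true, dtype=float)
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in (0, 1]")
    a = np.ones_like(p) if alpha is None else np.asarray(alpha, dtype=float)
    return float((a * (1.0 - p) ** gamma * (-np.log(p))).sum())


def focal_loss_from_logits(logits, labels, gamma: float = 2.0) -> float:
    p = softmax(np.asarray(logits, dtype=float), axis=1)
    y = np.asarray(labels, dtype=int)
    return focal_loss(p[np.arange(len(y)), y], gamma=gamma)


def focal_loss_from_logits_gradient(logits, labels, gamma: float = 2.0) -> np.ndarray:
    """d focal / d logits, via the chain rule through softmax.

    With p_t the gold-label probability, d loss_i / d p_t =
    -gamma (1-p_t)^{gamma-1} (-log p_t) - (1-p_t)^gamma / p_t, and
    d p_t / d logits = p_t * (onehot - p).
    """
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=int)
    p = softmax(logits, axis=1)
    idx = np.arange(len(y))
    pt = p[idx, y]
    one_minus = 1.0 - pt
    # guard the gamma-1 power at pt == 1 (term vanishes there)
    with np.errstate(divide="ignore", invalid="ignore"):
        dldp = np.where(
            one_minus > 0,
            gamma * one_minus ** np.maximum(gamma - 1.0, 0.0) * np.log(pt)
            - one_minus**gamma / pt,
            -0.0 if gamma > 0 else -1.0 / pt,
        )
    if gamma == 0:
        dldp = -1.0 / pt
    dpt_dz = -p * pt[:, None]
    dpt_dz[idx, y] += pt
    return dldp[:, None] * dpt_dz


def dice_loss(probs, one_hot_labels, eps: float = 1.0) -> float:
    """Soft Sørensen–Dice loss: 1 - (2 sum(p*y) + eps) / (sum p^2 + sum y^2 + eps).

    Approximates 1 - F1 over the token-label assignment, so minimizing it
    targets overlap rather than accuracy.  eps=1 is the standard smoothing
    that keeps the ratio finite on empty inputs.
    """
    p = np.asarray(probs, dtype=float)
    yv = np.asarray(one_hot_labels, dtype=float)
    if p.shape != yv.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs labels {yv.shape}")
    inter = (p * yv).sum()
    denom = (p**2).sum() + (yv**2).sum() + eps
    return float(1.0 - (2.0 * inter + eps) / denom)


def dice_loss_gradient(probs, one_hot_labels, eps: float = 1.0) -> np.ndarray:
    """d dice / d probs (quotient rule on the soft overlap ratio)."""
    p = np.asarray(probs, dtype=float)
    yv = np.asarray(one_hot_labels, dtype=float)
    inter = (p * yv).sum()
    num = 2.0 * inter + eps
    denom = (p**2).sum() + (yv**2).sum() + eps
    return -(2.0 * yv * denom - num * 2.0 * p) / denom**2
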