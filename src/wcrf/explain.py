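"""Perturbation-based local explanation of one token's predicted label.

The tagger's decision for a single token is rephrased as a multiclass
classification problem: the model's probability of the target label at the
target position (the CRF posterior marginal for CRF heads) is probed on
randomly perturbed copies of the sentence, and a weighted linear surrogate
is fitted to those probes.  The surrogate's coefficient for a context token
is its signed contribution to the prediction: removing tokens is then
expected to shift the probability down by the sum of their contributions
(e.g. base probability 0.95 minus contributions 0.33 and 0.31 leaves an
expected 0.31).

"Removing" a token substitutes the unknown-word id rather than deleting
the position, so sequence length — and with it the target index and the
CRF's label positions — is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import UNK_ID

__all__ = [
    "Explanation",
    "perturb_sequence",
    "fit_local_surrogate",
    "removal_effect",
    "explain_token",
]


@dataclass
class Explanation:
    """Local explanation of one token's predicted label."""

    target_index: int
    target_label: str
    base_probability: float
    context_indices: list[int]
    contributions: np.ndarray

    def __post_init__(self):
        if not 0.0 <= self.base_probability <= 1.0:
            raise ValueError("base_probability must lie in [0, 1]")
        if len(self.context_indices) != len(self.contributions):
            raise ValueError("one contribution per context token required")

    def contribution_of(self, index: int) -> float:
        return float(self.contributions[self.context_indices.index(index)])

    def expected_after_removing(self, removed_indices) -> float:
        positions = [self.context_indices.index(i) for i in removed_indices]
        return removal_effect(self.base_probability, self.contributions, positions)


def perturb_sequence(
    token_ids,
    target_index: int,
    n_samples: int,
    seed: int,
    removal_rate: float = 0.5,
    unk_id: int = UNK_ID,
):
    """Generate masked variants of a sentence around one target token.

    Each variant independently removes (replaces with ``unk_id``) every
    context token with probability ``removal_rate``; the target token is
    always kept.  Returns (variants, masks) with ``masks[s, j] = 1`` when
    context token j is present in variant s; the first variant is always
    the unperturbed sentence (all-ones mask).  Deterministic given seed.
    """
    ids = np.asarray(token_ids, dtype=int)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len(ids) < 2:
        raise ValueError("cannot perturb a single-token sequence (no context)")
    if not 0 <= target_index < len(ids):
        raise IndexError("target_index out of range")
    context = [j for j in range(len(ids)) if j != target_index]
    rng = np.random.default_rng(seed)
    masks = (rng.random((n_samples, len(context))) >= removal_rate).astype(float)
    masks[0] = 1.0
    variants = np.tile(ids, (n_samples, 1))
    for s in range(n_samples):
        for cj, j in enumerate(context):
            if masks[s, cj] == 0:
                variants[s, j] = unk_id
    return variants, masks


def fit_local_surrogate(
    masks: np.ndarray,
    probabilities: np.ndarray,
    proximity_kernel_width: float = 25.0,
) -> np.ndarray:
    """Weighted least-squares linear surrogate of probability on mask bits.

    Sample s is weighted by exp(-(d_s)^2 / width^2) with d_s the Hamming
    distance of its mask from the full sentence (number of removed tokens),
    so near-intact variants dominate the local fit.  Returns one signed
    weight per context token (the intercept is fitted but not returned).
    """
    m = np.asarray(masks, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if m.ndim != 2 or p.shape != (m.shape[0],):
        raise ValueError("masks must be S x J and probabilities length S")
    if np.unique(m, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct masks to fit a surrogate")
    d = (1.0 - m).sum(axis=1)
    kernel = np.exp(-(d**2) / proximity_kernel_width**2)
    x = np.hstack([np.ones((m.shape[0], 1)), m])
    sw = np.sqrt(kernel)[:, None]
    xw = x * sw
    rank = np.linalg.matrix_rank(xw)
    if rank < x.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient weighted design (rank {rank} < {x.shape[1]}); "
            "increase n_samples or the kernel width"
        )
    coef, *_ = np.linalg.lstsq(xw, p * sw[:, 0], rcond=None)
    return coef[1:]


def removal_effect(base_probability: float, contributions, removed_indices) -> float:
    """Expected probability after removing tokens: base - sum(contributions).

    Additive contract of the linear surrogate, clipped to [0, 1] so the
    result stays a probability.
    """
    c = np.asarray(contributions, dtype=float)
    removed = list(removed_indices)
    for i in removed:
        if not 0 <= i < len(c):
            raise IndexError(f"removed index {i} out of range")
    return float(np.clip(base_probability - c[removed].sum(), 0.0, 1.0))


def explain_token(
    results,
    tokens,
    target_index: int,
    target_label: str | None = None,
    n_samples: int = 1000,
    proximity_kernel_width: float = 25.0,
    removal_rate: float = 0.5,
    seed: int = 0,
) -> Explanation:
    """Explain a fitted tagger's label at one position of one sentence.

    ``results`` is a :class:`~wcrf.model.TaggerResults`; the probed
    quantity is its per-token probability of ``target_label`` (the
    predicted label when omitted).  A pure function of (model state,
    sentence, seed).
    """
    tokens = list(tokens)
    if target_label is None:
        target_label = results.predict_labels(tokens)[target_index]
    ids = results.model.vocab.encode(tokens)
    variants, masks = perturb_sequence(
        ids, target_index, n_samples, seed, removal_rate=removal_rate
    )
    probs = np.empty(len(variants))
    for s, var in enumerate(variants):
        var_tokens = [
            tokens[j] if var[j] == ids[j] else "[UNK]" for j in range(len(tokens))
        ]
        probs[s] = results.marginal(var_tokens, target_index, target_label)
    contributions = fit_local_surrogate(masks, probs, proximity_kernel_width)
    context = [j for j in range(len(tokens)) if j != target_index]
    return Explanation(
        target_index=target_index,
        target_label=target_label,
        base_probability=float(probs[0]),
        context_indices=context,
        contributions=contributions,
    )
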