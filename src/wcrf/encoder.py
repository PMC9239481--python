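"""Per-token context encoders producing emission features.

The desk-scale encoder is a trainable word-embedding table feeding a
bidirectional LSTM, optionally augmented with a character-level
bidirectional RNN (concatenated to the word embedding) and a scaled
dot-product self-attention layer over the BiLSTM states.  A pretrained
transformer can stand in for the embedding table through the same
``HiddenStates`` contract (an adapter hook, not implemented here); the
class-weighted loss this package exists for is encoder-agnostic.

Everything is plain numpy with hand-written reverse-mode gradients; every
forward function returns a cache consumed by the matching backward
function, and all gradients are validated against central differences in
the test suite.

Subword handling follows the first-piece convention: when a tokenizer
splits a word, only the first piece keeps the word's label and the
remaining pieces receive the sentinel ``[IGN]``, which is excluded from
loss and metrics downstream (label index -1, never part of the tag
alphabet or the transition matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

__all__ = [
    "PAD_ID",
    "UNK_ID",
    "IGN_LABEL",
    "EncoderConfig",
    "Vocabulary",
    "init_encoder_params",
    "encode_tokens",
    "encode_batch",
    "encode_batch_backward",
    "self_attention",
    "align_subword_labels",
]

PAD_ID = 0
UNK_ID = 1
IGN_LABEL = "[IGN]"


@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of the desk-scale encoder.

    ``hidden_dim`` is per direction, so hidden states have 2*hidden_dim
    features.  Dropout is applied after the context-encoder stack, as is
    conventional, and only during training.
    """

    vocab_size: int
    embed_dim: int = 32
    hidden_dim: int = 32
    use_char: bool = False
    char_vocab_size: int = 96
    char_dim: int = 16
    use_attention: bool = False
    dropout_rate: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("vocab_size", "embed_dim", "hidden_dim", "char_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_dim


@dataclass
class Vocabulary:
    """Token-to-id mapping with reserved PAD and UNK slots."""

    tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        self._index = {t: i + 2 for i, t in enumerate(self.tokens)}

    @property
    def size(self) -> int:
        return len(self.tokens) + 2

    def id_of(self, token: str) -> int:
        return self._index.get(token, UNK_ID)

    def encode(self, tokens) -> list[int]:
        return [self.id_of(t) for t in tokens]

    @classmethod
    def from_corpus(cls, sequences) -> "Vocabulary":
        seen: dict[str, None] = {}
        for seq in sequences:
            for tok in seq.tokens:
                seen.setdefault(tok, None)
        return cls(list(seen))


def _uniform(rng: np.random.Generator, shape, scale: float):
    return rng.uniform(-scale, scale, size=shape)


def init_encoder_params(config: EncoderConfig) -> dict[str, np.ndarray]:
    """Initialize all trainable encoder parameters.

    Embeddings are uniform(-0.25, 0.25) (the usual initialization for
    out-of-vocabulary word vectors); recurrent weights use scaled uniform
    fan-in initialization; LSTM forget-gate biases start at 1.
    """
    rng = np.random.default_rng(config.seed)
    p: dict[str, np.ndarray] = {}
    p["embed"] = _uniform(rng, (config.vocab_size, config.embed_dim), 0.25)
    p["embed"][PAD_ID] = 0.0
    in_dim = config.embed_dim
    if config.use_char:
        p["char_embed"] = _uniform(rng, (config.char_vocab_size, config.char_dim), 0.25)
        h = config.char_dim
        for d in ("f", "b"):
            p[f"char_wx_{d}"] = _uniform(rng, (config.char_dim, h), (3.0 / config.char_dim) ** 0.5)
            p[f"char_wh_{d}"] = _uniform(rng, (h, h), (3.0 / h) ** 0.5)
            p[f"char_b_{d}"] = np.zeros(h)
        in_dim += 2 * h
    h = config.hidden_dim
    for d in ("f", "b"):
        p[f"lstm_w_{d}"] = _uniform(rng, (in_dim, 4 * h), (3.0 / in_dim) ** 0.5)
        p[f"lstm_u_{d}"] = _uniform(rng, (h, 4 * h), (3.0 / h) ** 0.5)
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        p[f"lstm_b_{d}"] = b
    if config.use_attention:
        d_model = 2 * h
        for name in ("attn_wq", "attn_wk", "attn_wv"):
            p[name] = _uniform(rng, (d_model, d_model), (3.0 / d_model) ** 0.5)
    return p


# ---------------------------------------------------------------------------
# LSTM (batched, masked)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_direction(x, mask, w, u, b, reverse: bool):
    """Run one LSTM direction over x (B, T, Din); returns (h_seq, cache).

    Padded steps (mask 0) copy the previous hidden/cell state so padding
    never leaks into real positions.
    """
    bsz, t_len, _ = x.shape
    hdim = u.shape[0]
    h = np.zeros((bsz, hdim))
    c = np.zeros((bsz, hdim))
    order = range(t_len - 1, -1, -1) if reverse else range(t_len)
    h_seq = np.zeros((bsz, t_len, hdim))
    cache_steps = []
    for t in order:
        m = mask[:, t][:, None]
        z = x[:, t] @ w + h @ u + b
        i = _sigmoid(z[:, :hdim])
        f = _sigmoid(z[:, hdim : 2 * hdim])
        g = np.tanh(z[:, 2 * hdim : 3 * hdim])
        o = _sigmoid(z[:, 3 * hdim :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache_steps.append((t, h.copy(), c.copy(), i, f, g, o, c_new, tanh_c, m))
        h = m * h_new + (1 - m) * h
        c = m * c_new + (1 - m) * c
        h_seq[:, t] = h
    return h_seq, (cache_steps, x, w, u)


def _lstm_direction_backward(d_h_seq, cache):
    """Backprop one direction; returns (d_x, d_w, d_u, d_b)."""
    cache_steps, x, w, u = cache
    bsz, t_len, _ = x.shape
    hdim = u.shape[0]
    d_x = np.zeros_like(x)
    d_w = np.zeros_like(w)
    d_u = np.zeros_like(u)
    d_b = np.zeros(4 * hdim)
    d_h = np.zeros((bsz, hdim))
    d_c = np.zeros((bsz, hdim))
    for t, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m in reversed(cache_steps):
        d_h_total = d_h + d_h_seq[:, t]
        # gate through the mask: only real steps updated h/c
        d_h_new = m * d_h_total
        d_c_new = m * d_c
        d_h_prev_skip = (1 - m) * d_h_total
        d_c_prev_skip = (1 - m) * d_c

        d_o = d_h_new * tanh_c
        d_c_new = d_c_new + d_h_new * o * (1 - tanh_c**2)
        d_f = d_c_new * c_prev
        d_i = d_c_new * g
        d_g = d_c_new * i
        d_c_prev = d_c_new * f

        dz = np.concatenate(
            [
                d_i * i * (1 - i),
                d_f * f * (1 - f),
                d_g * (1 - g**2),
                d_o * o * (1 - o),
            ],
            axis=1,
        )
        d_x[:, t] += dz @ w.T
        d_w += x[:, t].T @ dz
        d_u += h_prev.T @ dz
        d_b += dz.sum(axis=0)
        d_h = dz @ u.T + d_h_prev_skip
        d_c = d_c_prev + d_c_prev_skip
    return d_x, d_w, d_u, d_b


# ---------------------------------------------------------------------------
# Self-attention


def self_attention(hidden: np.ndarray, params: dict[str, np.ndarray]):
    """Scaled dot-product self-attention over positions of one sequence.

    Returns (output, attention) where attention rows sum to one and
    ``output = attention @ (hidden @ Wv)``; for a single position the
    output is exactly the value-projected input.
    """
    h = np.asarray(hidden, dtype=float)
    if h.ndim != 2 or h.shape[0] < 1:
        raise ValueError("hidden must be a nonempty N x D matrix")
    q = h @ params["attn_wq"]
    k = h @ params["attn_wk"]
    v = h @ params["attn_wv"]
    scores = q @ k.T / np.sqrt(h.shape[1])
    attn = softmax(scores, axis=1)
    return attn @ v, attn


def _attention_batch(h, mask, params):
    """Batched masked self-attention; returns (out, cache)."""
    d = h.shape[2]
    q = h @ params["attn_wq"]
    k = h @ params["attn_wk"]
    v = h @ params["attn_wv"]
    scores = q @ k.transpose(0, 2, 1) / np.sqrt(d)
    scores = np.where(mask[:, None, :] > 0, scores, -1e9)
    attn = softmax(scores, axis=2)
    out = attn @ v
    out = out * mask[:, :, None]
    return out, (h, q, k, v, attn, mask, params)


def _attention_batch_backward(d_out, cache):
    h, q, k, v, attn, mask, params = cache
    d = h.shape[2]
    d_out = d_out * mask[:, :, None]
    d_attn = d_out @ v.transpose(0, 2, 1)
    d_v = attn.transpose(0, 2, 1) @ d_out
    # softmax Jacobian row-wise
    d_scores = attn * (d_attn - (d_attn * attn).sum(axis=2, keepdims=True))
    d_scores = d_scores * mask[:, None, :]
    d_q = d_scores @ k / np.sqrt(d)
    d_k = d_scores.transpose(0, 2, 1) @ q / np.sqrt(d)
    d_h = (
        d_q @ params["attn_wq"].T
        + d_k @ params["attn_wk"].T
        + d_v @ params["attn_wv"].T
    )
    flat = lambda a: a.reshape(-1, a.shape[-1])
    grads = {
        "attn_wq": flat(h).T @ flat(d_q),
        "attn_wk": flat(h).T @ flat(d_k),
        "attn_wv": flat(h).T @ flat(d_v),
    }
    return d_h, grads


# ---------------------------------------------------------------------------
# Character composition (per-token bidirectional vanilla RNN)


def _char_encode_token(char_ids, params):
    """Bidirectional tanh-RNN over one token's characters; returns (vec, cache)."""
    e = params["char_embed"][char_ids]  # (L, Dc)
    outs = []
    caches = []
    for d in ("f", "b"):
        wx, wh, b = params[f"char_wx_{d}"], params[f"char_wh_{d}"], params[f"char_b_{d}"]
        seq = e if d == "f" else e[::-1]
        h = np.zeros(wh.shape[0])
        hs = []
        for x_t in seq:
            h = np.tanh(x_t @ wx + h @ wh + b)
            hs.append(h)
        outs.append(h)
        caches.append((seq, hs))
    return np.concatenate(outs), (char_ids, e, caches)


def _char_encode_token_backward(d_vec, cache, params, grads):
    char_ids, e, caches = cache
    hdim = params["char_wh_f"].shape[0]
    d_e = np.zeros_like(e)
    for di, d in enumerate(("f", "b")):
        wx, wh = params[f"char_wx_{d}"], params[f"char_wh_{d}"]
        seq, hs = caches[di]
        d_h = d_vec[di * hdim : (di + 1) * hdim].copy()
        d_seq = np.zeros_like(seq)
        for t in range(len(hs) - 1, -1, -1):
            h = hs[t]
            dz = d_h * (1 - h**2)
            x_t = seq[t]
            h_prev = hs[t - 1] if t > 0 else np.zeros(hdim)
            grads[f"char_wx_{d}"] += np.outer(x_t, dz)
            grads[f"char_wh_{d}"] += np.outer(h_prev, dz)
            grads[f"char_b_{d}"] += dz
            d_seq[t] += dz @ wx.T
            d_h = dz @ wh.T
        d_e += d_seq if d == "f" else d_seq[::-1]
    np.add.at(grads["char_embed"], char_ids, d_e)


# ---------------------------------------------------------------------------
# Full encoder


def encode_batch(
    token_ids: np.ndarray,
    mask: np.ndarray,
    params: dict[str, np.ndarray],
    config: EncoderConfig,
    char_ids: list[list[list[int]]] | None = None,
    train: bool = False,
    dropout_rng: np.random.Generator | None = None,
):
    """Encode a padded batch (B, T) of token ids into hidden states (B, T, 2H).

    Returns (hidden, cache).  In eval mode (train=False) the computation is
    a pure function of (params, inputs); dropout only fires in train mode.
    """
    token_ids = np.asarray(token_ids, dtype=int)
    mask = np.asarray(mask, dtype=float)
    if token_ids.max(initial=0) >= config.vocab_size:
        raise IndexError("token id out of vocabulary range")
    x = params["embed"][token_ids]  # (B, T, De)
    char_caches = None
    if config.use_char:
        if char_ids is None:
            raise ValueError("encoder configured with use_char but no char_ids given")
        bsz, t_len = token_ids.shape
        cvecs = np.zeros((bsz, t_len, 2 * config.char_dim))
        char_caches = {}
        for bi in range(bsz):
            for ti in range(t_len):
                if mask[bi, ti] > 0 and char_ids[bi][ti]:
                    vec, cc = _char_encode_token(np.asarray(char_ids[bi][ti]), params)
                    cvecs[bi, ti] = vec
                    char_caches[(bi, ti)] = cc
        x = np.concatenate([x, cvecs], axis=2)
    h_f, cache_f = _lstm_direction(
        x, mask, params["lstm_w_f"], params["lstm_u_f"], params["lstm_b_f"], reverse=False
    )
    h_b, cache_b = _lstm_direction(
        x, mask, params["lstm_w_b"], params["lstm_u_b"], params["lstm_b_b"], reverse=True
    )
    h = np.concatenate([h_f, h_b], axis=2) * mask[:, :, None]
    attn_cache = None
    if config.use_attention:
        h, attn_cache = _attention_batch(h, mask, params)
    drop_mask = None
    if train and config.dropout_rate > 0:
        if dropout_rng is None:
            raise ValueError("train-mode encoding needs a dropout rng")
        keep = 1.0 - config.dropout_rate
        drop_mask = (dropout_rng.random(h.shape) < keep) / keep
        h = h * drop_mask
    cache = (token_ids, mask, cache_f, cache_b, attn_cache, drop_mask, char_caches, config)
    return h, cache


def encode_batch_backward(d_h, cache, params):
    """Backprop through the full encoder; returns dict of parameter grads."""
    token_ids, mask, cache_f, cache_b, attn_cache, drop_mask, char_caches, config = cache
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    if drop_mask is not None:
        d_h = d_h * drop_mask
    if attn_cache is not None:
        d_h, attn_grads = _attention_batch_backward(d_h, attn_cache)
        for k, v in attn_grads.items():
            grads[k] += v
    d_h = d_h * mask[:, :, None]
    hdim = config.hidden_dim
    d_x_f, d_w_f, d_u_f, d_b_f = _lstm_direction_backward(d_h[:, :, :hdim], cache_f)
    d_x_b, d_w_b, d_u_b, d_b_b = _lstm_direction_backward(d_h[:, :, hdim:], cache_b)
    grads["lstm_w_f"] += d_w_f
    grads["lstm_u_f"] += d_u_f
    grads["lstm_b_f"] += d_b_f
    grads["lstm_w_b"] += d_w_b
    grads["lstm_u_b"] += d_u_b
    grads["lstm_b_b"] += d_b_b
    d_x = d_x_f + d_x_b
    d_embed_part = d_x[:, :, : config.embed_dim]
    np.add.at(grads["embed"], token_ids, d_embed_part * mask[:, :, None])
    if config.use_char and char_caches is not None:
        d_char = d_x[:, :, config.embed_dim :]
        for (bi, ti), cc in char_caches.items():
            _char_encode_token_backward(d_char[bi, ti], cc, params, grads)
    grads["embed"][PAD_ID] = 0.0
    return grads


def encode_tokens(
    token_ids,
    params: dict[str, np.ndarray],
    config: EncoderConfig,
    char_ids: list[list[int]] | None = None,
) -> np.ndarray:
    """Encode one sequence of token ids into an N x 2H hidden-state matrix.

    Bidirectional by construction: every output position depends on the
    whole input, so perturbing the last token changes the first state.
    """
    ids = np.asarray(token_ids, dtype=int)[None, :]
    mask = np.ones_like(ids, dtype=float)
    h, _ = encode_batch(
        ids,
        mask,
        params,
        config,
        char_ids=[char_ids] if char_ids is not None else None,
    )
    return h[0]


def align_subword_labels(words, labels, subword_splits):
    """First-piece label alignment for subword tokenizers.

    ``subword_splits`` maps a word to its pieces (a dict or a callable);
    the first piece of each word keeps the word's label, later pieces get
    ``[IGN]`` and are excluded from loss and metrics downstream.  A word
    absent from the mapping is its own single piece.
    """
    if len(words) != len(labels):
        raise ValueError("words and labels length mismatch")
    lookup = subword_splits if callable(subword_splits) else subword_splits.get
    subtokens: list[str] = []
    subtoken_labels: list[str] = []
    for word, label in zip(words, labels):
        pieces = lookup(word) if callable(subword_splits) else subword_splits.get(word, [word])
        if pieces is None:
            pieces = [word]
        if len(pieces) == 0:
            raise ValueError(f"empty subword split for word {word!r}")
        subtokens.extend(pieces)
        subtoken_labels.append(label)
        subtoken_labels.extend([IGN_LABEL] * (len(pieces) - 1))
    return subtokens, subtoken_labels
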