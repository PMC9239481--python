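"""Sequence-tagging model objects.

``CRFTagger`` is built from a labeled :class:`~wcrf.io.Corpus` (statsmodels
style: the model object holds data + design, ``fit`` returns a
:class:`TaggerResults` carrying the estimates).  The architecture is the
desk-scale context encoder (embedding + BiLSTM, optional char/attention)
followed by a linear emission projection and either a CRF output layer
(optionally with the class-weighted objective) or an independent per-token
classifier trained with (weighted) softmax cross-entropy, focal, or dice
loss.

Training is plain Adam over hand-computed analytic gradients; a numerical
central-difference checker is provided and is the arbiter of gradient
correctness in the test suite.  Fits are exactly reproducible from the
configuration seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.special import softmax

from . import losses as L
from .crf import PotentialTables, crf_nll, crf_nll_gradient, posterior_marginals, viterbi_decode
from .encoder import (
    EncoderConfig,
    Vocabulary,
    encode_batch,
    encode_batch_backward,
    init_encoder_params,
)
from .io import Corpus, LabeledSequence, LabelAlphabet, class_token_counts
from .metrics import evaluate_corpus

__all__ = [
    "TrainingConfig",
    "CRFTagger",
    "TaggerResults",
    "numerical_gradient_check",
]

LOSS_KINDS = ("crf", "wcrf", "softmax", "wsoftmax", "focal", "dice")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    The default learning rate (1e-2) suits the small randomly-initialized
    encoder; pretrained-transformer fine-tuning conventionally uses 2e-5
    with batch size 16, which is why both are plain config fields rather
    than constants.
    """

    epochs: int = 30
    batch_size: int = 16
    learning_rate: float = 1e-2
    loss_kind: str = "wcrf"
    weight_strategy: str = "balanced"
    optimizer_name: str = "adam"
    seed: int = 0
    focal_gamma: float = 2.0
    dice_eps: float = 1.0
    dev_split: float = 0.0
    encoder: EncoderConfig | None = None

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("need epochs >= 1, batch_size >= 1, learning_rate > 0")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if self.weight_strategy not in L.STRATEGIES:
            raise ValueError(f"weight_strategy must be one of {L.STRATEGIES}")
        if not 0.0 <= self.dev_split < 1.0:
            raise ValueError("dev_split must lie in [0, 1)")


def _pad_batch(id_seqs: list[list[int]]):
    bsz = len(id_seqs)
    t_len = max(len(s) for s in id_seqs)
    ids = np.zeros((bsz, t_len), dtype=int)
    mask = np.zeros((bsz, t_len))
    for i, s in enumerate(id_seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class CRFTagger:
    """Sequence tagger built from a labeled corpus.

    Parameters
    ----------
    corpus : Corpus
        Training sentences; the label alphabet and vocabulary are inferred
        from it.
    config : TrainingConfig, optional
        Loss/optimizer settings; the encoder sub-config's ``vocab_size`` is
        filled in automatically.
    """

    def __init__(self, corpus: Corpus, config: TrainingConfig | None = None):
        if len(corpus) == 0:
            raise ValueError("cannot build a model from an empty corpus")
        self.corpus = corpus
        self.alphabet: LabelAlphabet = corpus.alphabet
        self.vocab = Vocabulary.from_corpus(corpus.sequences)
        config = config or TrainingConfig()
        enc = config.encoder or EncoderConfig(vocab_size=self.vocab.size, seed=config.seed)
        if enc.vocab_size != self.vocab.size:
            enc = EncoderConfig(**{**asdict(enc), "vocab_size": self.vocab.size})
        self.config = TrainingConfig(**{**asdict(config), "encoder": None})
        self.encoder_config = enc
        counts = class_token_counts(corpus)
        strategy = config.weight_strategy if config.loss_kind in ("wcrf", "wsoftmax") else "uniform"
        self.class_weights = L.compute_class_weights(
            L.TokenClassCounts.from_dict(counts), strategy
        )

    @classmethod
    def from_conll(cls, path, config: TrainingConfig | None = None) -> "CRFTagger":
        from .io import read_conll

        with open(path, encoding="utf-8") as fh:
            return cls(read_conll(fh), config)

    # -- parameters ---------------------------------------------------------

    def init_params(self) -> dict[str, np.ndarray]:
        k = self.alphabet.size
        params = init_encoder_params(self.encoder_config)
        rng = np.random.default_rng(self.encoder_config.seed + 1)
        d = self.encoder_config.output_dim
        params["emission_w"] = rng.uniform(-1, 1, size=(d, k)) * (3.0 / d) ** 0.5
        params["emission_b"] = np.zeros(k)
        params["trans"] = np.zeros((k + 2, k + 2))
        return params

    @property
    def uses_crf(self) -> bool:
        return self.config.loss_kind in ("crf", "wcrf")

    # -- loss and gradient for one padded batch -----------------------------

    def _batch_loss_and_grads(self, params, id_seqs, label_seqs, train_rng):
        ids, mask = _pad_batch(id_seqs)
        h, cache = encode_batch(
            ids, mask, params, self.encoder_config, train=True, dropout_rng=train_rng
        )
        emis = h @ params["emission_w"] + params["emission_b"]
        d_emis = np.zeros_like(emis)
        d_trans = np.zeros_like(params["trans"])
        total_loss = 0.0
        n_tokens = int(mask.sum())
        kind = self.config.loss_kind
        for bi, labels in enumerate(label_seqs):
            n = len(labels)
            p_i = emis[bi, :n]
            y = np.asarray(labels)
            if kind in ("crf", "wcrf"):
                pot = PotentialTables(p_i, params["trans"])
                if kind == "crf":
                    total_loss += crf_nll(pot, y)
                    d_p, d_a = crf_nll_gradient(pot, y)
                else:
                    total_loss += L.weighted_crf_nll(pot, y, self.class_weights, self.alphabet)
                    d_p, d_a = L.weighted_crf_nll_gradient(
                        pot, y, self.class_weights, self.alphabet
                    )
                d_emis[bi, :n] += d_p
                d_trans += d_a
            elif kind in ("softmax", "wsoftmax"):
                w = self.class_weights.per_tag(self.alphabet)[y]
                total_loss += L.weighted_softmax_ce(p_i, y, w)
                d_emis[bi, :n] += L.weighted_softmax_ce_gradient(p_i, y, w)
            elif kind == "focal":
                total_loss += L.focal_loss_from_logits(p_i, y, self.config.focal_gamma)
                d_emis[bi, :n] += L.focal_loss_from_logits_gradient(
                    p_i, y, self.config.focal_gamma
                )
            else:  # dice
                probs = softmax(p_i, axis=1)
                one_hot = np.zeros_like(probs)
                one_hot[np.arange(n), y] = 1.0
                total_loss += L.dice_loss(probs, one_hot, self.config.dice_eps)
                d_probs = L.dice_loss_gradient(probs, one_hot, self.config.dice_eps)
                d_emis[bi, :n] += probs * (
                    d_probs - (d_probs * probs).sum(axis=1, keepdims=True)
                )
        # mean over tokens in the batch (per-sequence losses are sums over tokens)
        scale = 1.0 / max(n_tokens, 1)
        total_loss *= scale
        d_emis *= scale
        d_trans *= scale
        flat_h = h.reshape(-1, h.shape[-1])
        flat_de = d_emis.reshape(-1, d_emis.shape[-1])
        grads = encode_batch_backward(d_emis @ params["emission_w"].T, cache, params)
        grads["emission_w"] = flat_h.T @ flat_de
        grads["emission_b"] = flat_de.sum(axis=0)
        grads["trans"] = d_trans
        return total_loss, grads

    # -- fitting -------------------------------------------------------------

    def fit(self, params: dict[str, np.ndarray] | None = None, verbose: bool = False):
        """Train and return a :class:`TaggerResults`.

        Fully reproducible: shuffling, dropout and initialization all
        derive from the configuration seeds.
        """
        cfg = self.config
        params = params if params is not None else self.init_params()
        rng = np.random.default_rng(cfg.seed)
        sequences = list(self.corpus.sequences)
        dev: list[LabeledSequence] = []
        if cfg.dev_split > 0:
            order = rng.permutation(len(sequences))
            n_dev = int(round(cfg.dev_split * len(sequences)))
            dev = [sequences[i] for i in order[:n_dev]]
            sequences = [sequences[i] for i in order[n_dev:]]
        id_seqs = [self.vocab.encode(s.tokens) for s in sequences]
        label_seqs = [self.alphabet.encode(s.labels) for s in sequences]
        opt = _Adam(params, cfg.learning_rate)
        history: list[dict] = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(sequences))
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, len(sequences), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                loss, grads = self._batch_loss_and_grads(
                    params,
                    [id_seqs[i] for i in sel],
                    [label_seqs[i] for i in sel],
                    rng,
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}: {loss}"
                    )
                opt.step(params, grads)
                epoch_loss += loss
                n_batches += 1
            record = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            history.append(record)
            if verbose:
                print(f"epoch {epoch}: loss {record['loss']:.6f}")
        results = TaggerResults(self, params, history)
        if dev:
            results.dev_metrics = results.evaluate(Corpus(dev, self.alphabet))
        return results


class TaggerResults:
    """Fitted tagger: parameters, training history, prediction and scoring."""

    def __init__(self, model: CRFTagger, params: dict[str, np.ndarray], history: list[dict]):
        self.model = model
        self.params = params
        self.history = history
        self.dev_metrics: dict | None = None

    # -- inference -----------------------------------------------------------

    def _emissions(self, tokens: Sequence[str]) -> np.ndarray:
        ids = np.asarray(self.model.vocab.encode(tokens), dtype=int)[None, :]
        mask = np.ones_like(ids, dtype=float)
        h, _ = encode_batch(ids, mask, self.params, self.model.encoder_config)
        return h[0] @ self.params["emission_w"] + self.params["emission_b"]

    def predict_labels(self, tokens: Sequence[str]) -> list[str]:
        """Decode one sentence: Viterbi for CRF heads, argmax otherwise."""
        emis = self._emissions(tokens)
        if self.model.uses_crf:
            path = viterbi_decode(PotentialTables(emis, self.params["trans"]))
        else:
            path = list(np.argmax(emis, axis=1))
        return self.model.alphabet.decode(path)

    def predict(self, sequences) -> list[LabeledSequence]:
        """Label a list of token sequences (or LabeledSequences)."""
        out = []
        for seq in sequences:
            tokens = seq.tokens if isinstance(seq, LabeledSequence) else tuple(seq)
            out.append(LabeledSequence(tuple(tokens), tuple(self.predict_labels(tokens))))
        return out

    def marginal(self, tokens: Sequence[str], position: int, tag: str) -> float:
        """Model probability of ``tag`` at ``position``.

        CRF heads use the forward-backward posterior marginal, softmax
        heads the per-position softmax probability.
        """
        emis = self._emissions(tokens)
        k = self.model.alphabet.index(tag)
        if self.model.uses_crf:
            m = posterior_marginals(PotentialTables(emis, self.params["trans"]))
            return float(m[position, k])
        return float(softmax(emis, axis=1)[position, k])

    # -- scoring -------------------------------------------------------------

    def evaluate(self, corpus: Corpus, mode: str = "approx") -> dict:
        predicted = self.predict(corpus.sequences)
        return evaluate_corpus(
            [s.labels for s in corpus.sequences],
            [s.labels for s in predicted],
            corpus.alphabet.classes,
            mode=mode,
        )

    def summary(self) -> str:
        """Human-readable fit summary table."""
        cfg = self.model.config
        n_params = sum(v.size for v in self.params.values())
        lines = [
            "Sequence tagger results",
            "=" * 47,
            f"{'loss kind':<24}{cfg.loss_kind:>23}",
            f"{'weight strategy':<24}{self.model.class_weights.strategy:>23}",
            f"{'tags (K)':<24}{self.model.alphabet.size:>23}",
            f"{'vocabulary':<24}{self.model.vocab.size:>23}",
            f"{'parameters':<24}{n_params:>23}",
            f"{'epochs':<24}{len(self.history):>23}",
            f"{'final loss':<24}{self.history[-1]['loss']:>23.6f}",
        ]
        classes = self.model.class_weights.classes
        weights = self.model.class_weights.weights
        lines.append("-" * 47)
        for c, w in zip(classes, weights):
            lines.append(f"{'w[' + c + ']':<24}{w:>23.4f}")
        lines.append("=" * 47)
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Serialize parameters + configs to JSON (lossless for float64)."""
        payload = {
            "training_config": asdict(self.model.config),
            "encoder_config": asdict(self.model.encoder_config),
            "alphabet_classes": list(self.model.alphabet.classes),
            "vocab_tokens": self.model.vocab.tokens,
            "class_weights": {
                "classes": list(self.model.class_weights.classes),
                "weights": list(self.model.class_weights.weights),
                "strategy": self.model.class_weights.strategy,
            },
            "history": self.history,
            "params": {k: v.tolist() for k, v in self.params.items()},
        }
        payload["training_config"].pop("encoder", None)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "TaggerResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        enc = EncoderConfig(**payload["encoder_config"])
        cfg = TrainingConfig(**payload["training_config"], encoder=enc)
        alphabet = LabelAlphabet(tuple(payload["alphabet_classes"]))
        # rebuild a shell model without retracing the corpus
        model = CRFTagger.__new__(CRFTagger)
        model.corpus = None
        model.alphabet = alphabet
        model.vocab = Vocabulary(payload["vocab_tokens"])
        model.config = TrainingConfig(**payload["training_config"])
        model.encoder_config = enc
        cw = payload["class_weights"]
        model.class_weights = L.ClassWeights(
            tuple(cw["classes"]), tuple(cw["weights"]), cw["strategy"]
        )
        params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
        return cls(model, params, payload["history"])


def numerical_gradient_check(
    loss_closure,
    params: dict[str, np.ndarray],
    epsilon: float = 1e-5,
    n_samples: int = 30,
    seed: int = 0,
) -> float:
    """Central-difference audit of an analytic gradient.

    ``loss_closure(params)`` must return ``(loss, grads)`` with ``grads``
    keyed like ``params``.  Random coordinates are perturbed by ±epsilon and
    the relative deviation |numeric - analytic| / max(1, |numeric|,
    |analytic|) is returned at its maximum over the sample.
    """
    if not 0 < epsilon <= 1e-2:
        raise ValueError("epsilon must lie in (0, 1e-2]")
    loss0, grads = loss_closure(params)
    if not np.isfinite(loss0):
        raise ValueError(f"non-finite loss: {loss0}")
    rng = np.random.default_rng(seed)
    keys = sorted(params)
    worst = 0.0
    for _ in range(n_samples):
        k = keys[rng.integers(len(keys))]
        flat_index = int(rng.integers(params[k].size))
        idx = np.unravel_index(flat_index, params[k].shape)
        orig = params[k][idx]
        params[k][idx] = orig + epsilon
        lp, _ = loss_closure(params)
        params[k][idx] = orig - epsilon
        lm, _ = loss_closure(params)
        params[k][idx] = orig
        numeric = (lp - lm) / (2 * epsilon)
        analytic = grads[k][idx]
        dev = abs(numeric - analytic) / max(1.0, abs(numeric), abs(analytic))
        worst = max(worst, dev)
    return worst
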