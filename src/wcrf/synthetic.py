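"""Synthetic imbalanced-corpus generator.

Real ADR corpora are dominated by O tokens: roughly 86.5% of tokens carry
no entity label, ADR mentions cover ~12% and Indications ~1%, with sentence
lengths around 19-21 tokens and entity spans of 1-3 tokens.  The generator
reproduces that regime so every module in the package is testable without
external data.

Sentences are built by a renewal process over {outside, in-span} states:
at each outside position the process either emits an O token or opens a
span of some entity class, with opening probabilities solved from the
target token ratios (a class with token ratio r and mean span length L is
opened with odds proportional to r/L, so long-run token ratios converge to
the targets).  Words come from class-specific vocabulary blocks: a token in
class c is drawn from c's block with probability ``emission_sharpness`` and
from the global vocabulary otherwise, so sharpness sets how strongly word
identity signals its class (1.0 = perfectly separable, 0 = no signal).

What this emulates is the label imbalance and local word-class association
of real corpora; what it does not emulate is syntax, discourse, spelling
variation, or any long-range dependency, so models that pass here are
validated for their handling of imbalance, not for linguistic coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Corpus, LabeledSequence, Span, class_token_counts

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PROFILES",
    "generate_corpus",
    "corpus_stats",
]

# Default profiles mirror the published corpus statistics tables (samples,
# max/mean length, vocabulary, class token ratios).  Ratios are taken from
# the exact token counts rather than the rounded percentages (which sum to
# 100.1% for the Twitter-style corpus).
PROFILES: dict[str, dict] = {
    "twitter": dict(
        n_sentences=844,
        mean_length=19.0,
        max_length=36,
        vocab_size=2843,
        class_ratios={
            "O": 13852 / 16023,        # 86.5%
            "ADR": 1970 / 16023,       # 12.3%
            "Indication": 201 / 16023,  # 1.3%
        },
    ),
    "pubmed": dict(
        n_sentences=4858,
        mean_length=21.3,
        max_length=93,
        vocab_size=7950,
        class_ratios={"O": 89331 / 103302, "ADR": 13971 / 103302},
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Generation parameters; defaults follow the Twitter-style profile."""

    n_sentences: int = 844
    mean_length: float = 19.0
    max_length: int = 36
    vocab_size: int = 2843
    class_ratios: dict = field(
        default_factory=lambda: dict(PROFILES["twitter"]["class_ratios"])
    )
    span_length_dist: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    emission_sharpness: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        if not self.max_length >= self.mean_length >= 1:
            raise ValueError("need max_length >= mean_length >= 1")
        if abs(sum(self.class_ratios.values()) - 1.0) > 1e-9:
            raise ValueError("class ratios must sum to 1")
        if "O" not in self.class_ratios:
            raise ValueError("class_ratios must include 'O'")
        if any(r < 0 for r in self.class_ratios.values()):
            raise ValueError("ratios must be non-negative")
        if abs(sum(self.span_length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("span length distribution must sum to 1")
        if not 0.0 <= self.emission_sharpness <= 1.0:
            raise ValueError("emission_sharpness must lie in [0, 1]")

    @classmethod
    def profile(cls, name: str, **overrides) -> "GeneratorConfig":
        if name not in PROFILES:
            raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
        kw = dict(PROFILES[name])
        kw.update(overrides)
        return cls(**kw)


@dataclass
class GroundTruth:
    """Generator bookkeeping: spans per sentence and per-class token counts."""

    spans: list[list[Span]]
    token_counts: dict[str, int]


def _vocab_blocks(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Partition vocabulary ids into per-class blocks sized by token ratio."""
    classes = sorted(c for c in config.class_ratios if c != "O")
    blocks: dict[str, np.ndarray] = {}
    cursor = 0
    for c in classes:
        size = max(5, int(round(config.vocab_size * config.class_ratios[c])))
        size = min(size, config.vocab_size - cursor - 1)
        blocks[c] = np.arange(cursor, cursor + size)
        cursor += size
    blocks["O"] = np.arange(cursor, config.vocab_size)
    return blocks


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a labeled corpus plus its ground-truth bookkeeping.

    Deterministic given ``config.seed``: one root SeedSequence is split
    into an independent child stream per sentence, so the i-th sentence is
    reproducible regardless of generation order.
    """
    entity_classes = sorted(c for c in config.class_ratios if c != "O")
    lengths = np.array(sorted(config.span_length_dist), dtype=int)
    length_p = np.array([config.span_length_dist[l] for l in lengths])
    mean_span = float((lengths * length_p).sum())

    # renewal-reward odds: opening class c consumes mean_span tokens
    weights = {"O": config.class_ratios["O"]}
    for c in entity_classes:
        weights[c] = config.class_ratios[c] / mean_span
    cats = ["O"] + entity_classes
    cat_p = np.array([weights[c] for c in cats])
    cat_p = cat_p / cat_p.sum()

    blocks = _vocab_blocks(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_sentences)

    sequences: list[LabeledSequence] = []
    all_spans: list[list[Span]] = []
    counts: dict[str, int] = {c: 0 for c in ["O"] + entity_classes}

    for child in children:
        rng = np.random.default_rng(child)
        n = int(np.clip(rng.poisson(config.mean_length), 1, config.max_length))
        labels: list[str] = []
        spans: list[Span] = []
        tok_classes: list[str] = []
        pos = 0
        while pos < n:
            cat = cats[rng.choice(len(cats), p=cat_p)]
            if cat == "O":
                labels.append("O")
                tok_classes.append("O")
                pos += 1
            else:
                span_len = int(rng.choice(lengths, p=length_p))
                span_len = min(span_len, n - pos)
                labels.append(f"B-{cat}")
                labels.extend(f"I-{cat}" for _ in range(span_len - 1))
                tok_classes.extend([cat] * span_len)
                spans.append(Span(cat, pos, pos + span_len))
                pos += span_len
        tokens = []
        for cls in tok_classes:
            if rng.random() < config.emission_sharpness:
                block = blocks[cls]
            else:
                block = np.arange(config.vocab_size)
            tokens.append(f"w{int(rng.choice(block))}")
            counts[cls] += 1
        sequences.append(LabeledSequence(tuple(tokens), tuple(labels)))
        all_spans.append(spans)

    corpus = Corpus(sequences)
    return corpus, GroundTruth(all_spans, counts)


def corpus_stats(corpus: Corpus) -> dict:
    """Corpus summary: samples, max/mean length, vocabulary, class counts.

    Mirrors the columns of the standard imbalance-statistics table: number
    of samples, max and mean sentence length, vocabulary size, total token
    count, and per-class token counts with percentage ratios.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    lengths = [len(s) for s in corpus]
    vocab = {t for s in corpus for t in s.tokens}
    counts = class_token_counts(corpus)
    total = sum(counts.values())
    return {
        "samples": len(corpus),
        "max_length": max(lengths),
        "mean_length": sum(lengths) / len(lengths),
        "vocab": len(vocab),
        "tokens": total,
        "classes": {
            c: {"tokens": n, "ratio": 100.0 * n / total} for c, n in counts.items()
        },
    }
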