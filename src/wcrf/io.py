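"""Labeled-corpus containers and CoNLL-style I/O for BIO span tagging.

The corpus dialect is one token per line, ``token<TAB>label``, with a blank
line terminating each sentence.  Labels follow the BIO scheme over an
arbitrary set of entity classes (``O``, ``B-ADR``, ``I-ADR``,
``B-Indication`` ...); the label alphabet is always inferred from the data,
never hard-coded, because different corpora carry different class sets.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

__all__ = [
    "LabeledSequence",
    "LabelAlphabet",
    "Span",
    "Corpus",
    "ParseError",
    "read_conll",
    "write_conll",
    "validate_boi",
    "extract_spans",
    "class_token_counts",
    "adr_token_ratio",
    "tag_class",
]

_TAG_RE = re.compile(r"^(?:O|[BI]-\S+)$")


class ParseError(ValueError):
    """Raised on a malformed corpus file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def tag_class(tag: str) -> str:
    """Entity class of a tag: ``B-ADR``/``I-ADR`` -> ``ADR``; ``O`` -> ``O``."""
    if tag == "O":
        return "O"
    return tag[2:]


@dataclass(frozen=True)
class LabeledSequence:
    """One sentence: tokens with aligned BIO labels."""

    tokens: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.labels)} labels"
            )
        for lab in self.labels:
            if not _TAG_RE.match(lab):
                raise ValueError(f"malformed tag {lab!r}")

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class LabelAlphabet:
    """Tag inventory K = 2*|classes| + 1 plus synthetic start/end states.

    Tag indices are 0..K-1 (``O`` first, then ``B-c``, ``I-c`` per class in
    sorted order); the transition matrix used by the CRF has size K+2 with
    the start state at index K and the end state at K+1.
    """

    classes: tuple[str, ...]

    def __post_init__(self):
        if "O" in self.classes:
            raise ValueError("'O' is not an entity class")
        object.__setattr__(self, "classes", tuple(sorted(set(self.classes))))

    @property
    def tags(self) -> tuple[str, ...]:
        out = ["O"]
        for c in self.classes:
            out.append(f"B-{c}")
            out.append(f"I-{c}")
        return tuple(out)

    @property
    def size(self) -> int:
        return 2 * len(self.classes) + 1

    @property
    def start_index(self) -> int:
        return self.size

    @property
    def end_index(self) -> int:
        return self.size + 1

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise KeyError(f"tag {tag!r} not in alphabet {self.tags}") from None

    def tag(self, index: int) -> str:
        return self.tags[index]

    def encode(self, labels: Sequence[str]) -> list[int]:
        return [self.index(t) for t in labels]

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.tags[i] for i in indices]

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "LabelAlphabet":
        classes = {tag_class(t) for t in labels} - {"O"}
        return cls(tuple(classes))


@dataclass(frozen=True)
class Span:
    """Entity span: half-open token interval [start, end) of one class."""

    class_name: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Corpus:
    sequences: list[LabeledSequence]
    alphabet: LabelAlphabet = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.alphabet is None:
            labs = [t for s in self.sequences for t in s.labels]
            self.alphabet = LabelAlphabet.from_labels(labs)
        tags = set(self.alphabet.tags)
        for s in self.sequences:
            for t in s.labels:
                if t not in tags:
                    raise ValueError(f"tag {t!r} outside alphabet {tags}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sequences)


def read_conll(stream: TextIO | str) -> Corpus:
    """Parse a token<TAB>label corpus; sentences separated by blank lines."""
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    sequences: list[LabeledSequence] = []
    tokens: list[str] = []
    labels: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            if tokens:
                sequences.append(LabeledSequence(tuple(tokens), tuple(labels)))
                tokens, labels = [], []
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"expected 2 tab-separated fields, got {len(fields)}", lineno
            )
        token, tag = fields
        if not _TAG_RE.match(tag):
            raise ParseError(f"malformed tag {tag!r}", lineno)
        tokens.append(token)
        labels.append(tag)
    if tokens:
        sequences.append(LabeledSequence(tuple(tokens), tuple(labels)))
    return Corpus(sequences)


def write_conll(corpus: Corpus, stream: TextIO) -> None:
    """Emit the exact dialect ``read_conll`` accepts (trailing blank line)."""
    for seq in corpus.sequences:
        for token, label in zip(seq.tokens, seq.labels):
            stream.write(f"{token}\t{label}\n")
        stream.write("\n")


def validate_boi(
    labels: Sequence[str], alphabet: LabelAlphabet | None = None
) -> list[tuple[int, str]]:
    """Report BIO violations: every I-X not preceded by B-X or I-X.

    Returns (position, rule) pairs; an empty list means the sequence is a
    valid BIO encoding (e.g. I-ADR directly after B-Indication is invalid).
    """
    if alphabet is not None:
        known = set(alphabet.tags)
        for t in labels:
            if t not in known:
                raise KeyError(f"tag {t!r} not in alphabet")
    violations: list[tuple[int, str]] = []
    prev = "O"
    for i, tag in enumerate(labels):
        if tag.startswith("I-"):
            cls = tag_class(tag)
            if not (prev == f"B-{cls}" or prev == f"I-{cls}"):
                violations.append(
                    (i, f"{tag} cannot follow {prev} (needs B-{cls} or I-{cls})")
                )
        prev = tag
    return violations


def extract_spans(labels: Sequence[str]) -> list[Span]:
    """Materialize maximal B-X (I-X)* runs as half-open spans.

    Invalid I-X (after O or a different class) is repaired as a fresh B-X,
    the standard CoNLL convention, so extraction is total.
    """
    spans: list[Span] = []
    start = None
    cls = None
    for i, tag in enumerate(labels):
        if tag == "O":
            if start is not None:
                spans.append(Span(cls, start, i))
                start, cls = None, None
        elif tag.startswith("B-"):
            if start is not None:
                spans.append(Span(cls, start, i))
            start, cls = i, tag_class(tag)
        else:  # I-
            icls = tag_class(tag)
            if start is None or icls != cls:
                if start is not None:
                    spans.append(Span(cls, start, i))
                start, cls = i, icls  # repaired as B-
    if start is not None:
        spans.append(Span(cls, start, len(labels)))
    return spans


def class_token_counts(corpus: Corpus) -> dict[str, int]:
    """Token counts per entity class (B- and I- pooled) plus O.

    Every tag in the alphabet's class set appears in the result, so the
    counts vector lines up with the class-weight machinery even for classes
    absent from a particular corpus slice.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    counts = {"O": 0}
    for c in corpus.alphabet.classes:
        counts[c] = 0
    for seq in corpus:
        for tag in seq.labels:
            counts[tag_class(tag)] += 1
    return counts


def adr_token_ratio(sequence: LabeledSequence, class_name: str = "ADR") -> float:
    """Percentage of tokens carrying the given entity class.

    100 * (#tokens labeled B-class or I-class) / (#tokens), rounded half-up
    to two decimals (a 12-token sentence with one ADR token gives 8.33;
    displayed with trailing zeros stripped that is 8.33%, and at one-decimal
    rounding 8.3%).
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    n = sum(1 for t in sequence.labels if tag_class(t) == class_name)
    raw = 100.0 * n / len(sequence)
    # round half-up at 2 decimals
    import decimal

    d = decimal.Decimal(repr(raw)).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)
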