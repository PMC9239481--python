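"""Approximate-match precision/recall/F1 for span tagging.

ADR evaluation conventionally uses approximate matching: a prediction that
overlaps a gold entity span counts as correct, so for a gold span "sleep
paralysis" both the longer "lasting sleep paralysis" and the shorter
"paralysis" are credited.  Counting is token-level:

  - a predicted token of class c is a TP when its predicted span overlaps
    some gold span of class c, otherwise an FP;
  - a gold token of class c is an FN when its gold span is overlapped by no
    predicted span of class c.

Strict mode (exact span equality) is available for debugging; it can never
produce more true positives than approximate matching on the same input.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Span, extract_spans

__all__ = [
    "MatchCounts",
    "approximate_match_counts",
    "strict_match_counts",
    "match_counts",
    "precision_recall_f1",
    "evaluate_corpus",
]


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _class_spans(labels, class_name: str) -> list[Span]:
    return [s for s in extract_spans(labels) if s.class_name == class_name]


def approximate_match_counts(gold_labels, predicted_labels, class_name: str) -> MatchCounts:
    """Token-level overlap counting for one sentence and one class."""
    if len(gold_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(gold_labels)} gold vs {len(predicted_labels)} predicted"
        )
    gold = _class_spans(gold_labels, class_name)
    pred = _class_spans(predicted_labels, class_name)
    tp = fp = 0
    for p in pred:
        n_tokens = p.end - p.start
        if any(p.overlaps(g) for g in gold):
            tp += n_tokens
        else:
            fp += n_tokens
    fn = sum(
        g.end - g.start for g in gold if not any(g.overlaps(p) for p in pred)
    )
    return MatchCounts(tp, fp, fn)


def strict_match_counts(gold_labels, predicted_labels, class_name: str) -> MatchCounts:
    """Exact-span counting: only identical (class, start, end) spans match."""
    if len(gold_labels) != len(predicted_labels):
        raise ValueError("length mismatch between gold and predicted labels")
    gold = set(_class_spans(gold_labels, class_name))
    pred = set(_class_spans(predicted_labels, class_name))
    tp = sum(s.end - s.start for s in pred & gold)
    fp = sum(s.end - s.start for s in pred - gold)
    fn = sum(s.end - s.start for s in gold - pred)
    return MatchCounts(tp, fp, fn)


def match_counts(gold_labels, predicted_labels, class_name: str, mode: str = "approx"):
    if mode == "approx":
        return approximate_match_counts(gold_labels, predicted_labels, class_name)
    if mode == "strict":
        return strict_match_counts(gold_labels, predicted_labels, class_name)
    raise ValueError(f"unknown match mode {mode!r}")


def precision_recall_f1(counts: MatchCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 their harmonic mean; 0/0 := 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate_corpus(
    gold_sequences, predicted_sequences, classes, mode: str = "approx"
) -> dict[str, dict[str, float]]:
    """Corpus-level metrics per class plus a micro average over classes.

    Inputs are parallel lists of label sequences (sentence order does not
    affect the result: counts are summed before any ratio is taken).
    """
    if len(gold_sequences) != len(predicted_sequences):
        raise ValueError("corpus length mismatch")
    report: dict[str, dict[str, float]] = {}
    total = MatchCounts()
    for cls in classes:
        counts = MatchCounts()
        for g, p in zip(gold_sequences, predicted_sequences):
            counts = counts + match_counts(g, p, cls, mode)
        prec, rec, f1 = precision_recall_f1(counts)
        report[cls] = {
            "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
            "precision": prec, "recall": rec, "f1": f1,
        }
        total = total + counts
    prec, rec, f1 = precision_recall_f1(total)
    report["micro"] = {
        "tp": total.tp, "fp": total.fp, "fn": total.fn,
        "precision": prec, "recall": rec, "f1": f1,
    }
    return report
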