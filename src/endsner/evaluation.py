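"""Entity-level scoring, k-fold cross-validation, inter-annotator agreement,
and mention-share reporting.

Scoring is micro-averaged within entity type: true/false positive and false
negative counts are summed over posts before the precision, recall, and F1
ratios are formed.  A predicted span is a true positive under exact matching
only if its start, end, and label all equal a gold span's; under partial
matching a same-label prediction overlapping a gold span by at least one
character counts, with one-to-one greedy pairing by descending overlap.
Zero-denominator metrics are reported as undefined (None) rather than
coerced to 0, and are excluded from fold means with a logged note.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold

from .preprocessing import AnnotatedPost, ENTITY_LABELS, EntitySpan, decode_tags

logger = logging.getLogger("endsner")

METRICS = ("precision", "recall", "f1")


class ValidationError(ValueError):
    """Invalid inputs to a scoring operation."""


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalResult:
    """Precision/recall/F1 with the counts they derive from; None = undefined."""

    precision: float | None
    recall: float | None
    f1: float | None
    counts: ConfusionCounts
    match_mode: str = "exact"

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, match_mode: str = "exact") -> "EvalResult":
        return cls(precision(counts), recall(counts), f1(counts), counts, match_mode)


# ---------------------------------------------------------------------------
# span matching and the metric formulas
# ---------------------------------------------------------------------------


def _check_no_overlap(spans: Sequence[EntitySpan], which: str) -> None:
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise ValidationError(f"{which} spans overlap: {a} and {b}")


def match_entities(
    gold_spans: Sequence[EntitySpan],
    pred_spans: Sequence[EntitySpan],
    mode: str = "exact",
) -> dict[str, ConfusionCounts]:
    """Per-entity-type confusion counts for one post's gold and predicted spans."""
    if mode not in ("exact", "partial"):
        raise ValidationError(f"unknown match mode {mode!r}")
    _check_no_overlap(gold_spans, "gold")
    _check_no_overlap(pred_spans, "predicted")
    counts = {label: ConfusionCounts() for label in ENTITY_LABELS}
    for label in ENTITY_LABELS:
        gold = [s for s in gold_spans if s.label == label]
        pred = [s for s in pred_spans if s.label == label]
        if mode == "exact":
            gold_keys = {(s.start, s.end) for s in gold}
            pred_keys = {(s.start, s.end) for s in pred}
            tp = len(gold_keys & pred_keys)
        else:
            pairs = []
            for gi, g in enumerate(gold):
                for pi, p in enumerate(pred):
                    overlap = min(g.end, p.end) - max(g.start, p.start)
                    if overlap >= 1:
                        pairs.append((-overlap, g.start, p.start, gi, pi))
            used_g: set[int] = set()
            used_p: set[int] = set()
            tp = 0
            for _, _, _, gi, pi in sorted(pairs):
                if gi not in used_g and pi not in used_p:
                    used_g.add(gi)
                    used_p.add(pi)
                    tp += 1
        counts[label] = ConfusionCounts(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)
    return counts


def precision(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FP); undefined (None) when nothing was predicted positive."""
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else None


def recall(counts: ConfusionCounts) -> float | None:
    """TP / (TP + FN); undefined (None) when there are no gold positives."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else None


def f1(counts: ConfusionCounts) -> float | None:
    """Harmonic mean of precision and recall, 2/((1/R) + (1/P))."""
    p, r = precision(counts), recall(counts)
    if p is None or r is None or p + r == 0:
        return None
    return 2 / ((1 / r) + (1 / p))


def evaluate_posts(
    gold_posts: Sequence[AnnotatedPost],
    predictions: Sequence[Sequence[EntitySpan]],
    mode: str = "exact",
) -> dict[str, EvalResult]:
    """Micro-averaged per-type results over a set of posts and predictions."""
    if len(gold_posts) != len(predictions):
        raise ValidationError("gold posts and predictions differ in length")
    totals = {label: ConfusionCounts() for label in ENTITY_LABELS}
    for post, pred in zip(gold_posts, predictions):
        for label, c in match_entities(post.spans, pred, mode).items():
            totals[label] += c
    return {label: EvalResult.from_counts(c, mode) for label, c in totals.items()}


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-fold entity-level results with mean and sample SD per metric."""

    k: int
    seed: int
    match_mode: str
    per_fold: dict[str, list[EvalResult]]
    mean: dict[str, dict[str, float | None]] = field(default_factory=dict)
    sd: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            self._aggregate()

    def _aggregate(self) -> None:
        for label, results in self.per_fold.items():
            self.mean[label], self.sd[label] = {}, {}
            for metric in METRICS:
                values = [getattr(r, metric) for r in results]
                defined = [v for v in values if v is not None]
                if len(defined) < len(values):
                    logger.info(
                        "%s %s undefined in %d of %d folds; excluded from the mean",
                        label, metric, len(values) - len(defined), len(values),
                    )
                if not defined:
                    self.mean[label][metric] = self.sd[label][metric] = None
                    continue
                self.mean[label][metric] = float(np.mean(defined))
                self.sd[label][metric] = (
                    float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
                )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "match_mode": self.match_mode,
            "per_fold": {
                label: [
                    {
                        "precision": r.precision,
                        "recall": r.recall,
                        "f1": r.f1,
                        "tp": r.counts.tp,
                        "fp": r.counts.fp,
                        "fn": r.counts.fn,
                    }
                    for r in results
                ]
                for label, results in self.per_fold.items()
            },
            "mean": self.mean,
            "sd": self.sd,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Aligned-column table of mean (SD) per entity type and metric."""
        lines = [f"{self.k}-fold cross-validation (seed {self.seed}, {self.match_mode} match)"]
        header = f"{'type':<8}" + "".join(f"{m:>18}" for m in METRICS)
        lines.append(header)
        for label in self.per_fold:
            cells = []
            for metric in METRICS:
                m, s = self.mean[label][metric], self.sd[label][metric]
                cells.append("N/A" if m is None else f"{m:.3f} ({s:.3f})")
            lines.append(f"{label:<8}" + "".join(f"{c:>18}" for c in cells))
        return "\n".join(lines)


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of range(n) into k near-equal test folds."""
    if k < 2:
        raise ValidationError("k must be at least 2")
    if n < k:
        raise ValidationError(f"corpus of {n} posts cannot be split into {k} folds")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.arange(n))]


def cross_validate(
    corpus: Sequence[AnnotatedPost],
    tagger_factory: Callable[[], "object"],
    k: int = 5,
    seed: int = 0,
    match_mode: str = "exact",
) -> CVReport:
    """k-fold cross-validation of any Tagger over an annotated corpus.

    Posts are randomly partitioned into k near-equal folds; for each fold a
    fresh tagger is fitted on the remaining posts and scored on the held-out
    fold at the entity level.
    """
    folds = make_folds(len(corpus), k, seed)
    per_fold: dict[str, list[EvalResult]] = {label: [] for label in ENTITY_LABELS}
    for test_idx in folds:
        test_set = set(int(i) for i in test_idx)
        train = [p for i, p in enumerate(corpus) if i not in test_set]
        test = [corpus[i] for i in sorted(test_set)]
        tagger = tagger_factory()
        tagger.fit(train)
        predictions = []
        for post in test:
            tags = tagger.predict(post.tokens)
            predictions.append(decode_tags(post.tokens, tags, post.normalized_text))
        results = evaluate_posts(test, predictions, match_mode)
        for label in ENTITY_LABELS:
            per_fold[label].append(results[label])
    return CVReport(k=k, seed=seed, match_mode=match_mode, per_fold=per_fold)


# ---------------------------------------------------------------------------
# inter-annotator agreement
# ---------------------------------------------------------------------------


def cohen_kappa(labels_a: Sequence[str], labels_b: Sequence[str]) -> float:
    """Cohen's κ = (p_o − p_e)/(1 − p_e) between two categorical labelings.

    Expected agreement p_e comes from the product of the two raters' marginal
    distributions.  The degenerate case p_o = p_e = 1 (both raters constant
    and identical) returns 1.
    """
    if len(labels_a) != len(labels_b):
        raise ValidationError("label sequences differ in length")
    if not labels_a:
        raise ValidationError("label sequences are empty")
    n = len(labels_a)
    cats = sorted(set(labels_a) | set(labels_b))
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for a, b in zip(labels_a, labels_b):
        table[index[a], index[b]] += 1
    p_o = float(np.trace(table)) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if math.isclose(p_e, 1.0):
        return 1.0
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# mention shares and ranking comparison
# ---------------------------------------------------------------------------


@dataclass
class MentionShareTable:
    """Mentions grouped by surface form with percentage shares of the total."""

    label: str
    rows: list[tuple[str, int, float]]  # (display name, count, share %)
    total: int

    def to_text(self) -> str:
        lines = [f"{self.label} mentions (n={self.total})"]
        width = max([len(r[0]) for r in self.rows], default=4)
        for name, count, share in self.rows:
            lines.append(f"{name:<{width}}  {count:>5}  ({share:.1f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "total": self.total,
            "rows": [{"name": n, "count": c, "share": s} for n, c, s in self.rows],
        }

    def top_names(self, top_n: int) -> list[str]:
        return [name.casefold() for name, _, _ in self.rows[:top_n]]


def _round_half_up(value: float, digits: int = 1) -> float:
    return float(Decimal(repr(value)).quantize(Decimal(f"1e-{digits}"), rounding=ROUND_HALF_UP))


def mention_share(
    corpus: Sequence[AnnotatedPost], label: str, total: int | None = None
) -> MentionShareTable:
    """Share of each surface form among all mentions of one entity type.

    Mentions group by case-folded surface; each row's share is
    100·count/total rounded half-up to one decimal.  Rows sort by count
    descending, then name ascending.  ``total`` defaults to the number of
    mentions in the corpus but may be given explicitly (e.g. when tabulating
    a published subset).
    """
    counts: dict[str, int] = {}
    display: dict[str, str] = {}
    n_mentions = 0
    for post in corpus:
        for span in post.spans:
            if span.label != label:
                continue
            n_mentions += 1
            key = span.surface.casefold()
            counts[key] = counts.get(key, 0) + 1
            display.setdefault(key, span.surface)
    total = n_mentions if total is None else total
    if total == 0:
        return MentionShareTable(label, [], 0)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = [
        (display[key], count, _round_half_up(100.0 * count / total))
        for key, count in ordered
    ]
    return MentionShareTable(label, rows, total)


def compare_rankings(
    table_a: MentionShareTable | Sequence[str],
    table_b: MentionShareTable | Sequence[str],
    top_n: int = 10,
) -> dict[str, list[str]]:
    """Overlap of the top-n names of two share tables (case-folded)."""

    def names(table) -> list[str]:
        if isinstance(table, MentionShareTable):
            return table.top_names(top_n)
        return [str(x).casefold() for x in list(table)[:top_n]]

    a, b = names(table_a), names(table_b)
    return {
        "in_both": sorted(set(a) & set(b)),
        "only_a": sorted(set(a) - set(b)),
        "only_b": sorted(set(b) - set(a)),
    }
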