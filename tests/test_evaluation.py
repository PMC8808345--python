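"""Entity-level metrics, cross-validation, agreement, and share tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from endsner.evaluation import (
    ConfusionCounts,
    ValidationError,
    cohen_kappa,
    compare_rankings,
    cross_validate,
    evaluate_posts,
    f1,
    make_folds,
    match_entities,
    mention_share,
    precision,
    recall,
)
from endsner.preprocessing import (
    AnnotatedPost,
    EntitySpan,
    RawPost,
    TagSequence,
    encode_tags,
    tokenize,
)

# -- span matching ----------------------------------------------------------


def _span(start, end, label="BRAND"):
    return EntitySpan(start, end, label, "x" * (end - start))


def test_identical_sets_all_true_positive():
    spans = [_span(0, 4), _span(10, 14, "FLAVOR")]
    counts = match_entities(spans, list(spans))
    assert counts["BRAND"] == ConfusionCounts(1, 0, 0)
    assert counts["FLAVOR"] == ConfusionCounts(1, 0, 0)


def test_truncated_prediction_exact_vs_partial():
    """A prediction covering only part of the gold mention (e.g. "BANG Bars"
    for gold "BANG Bars XL") is wrong under exact matching but a true
    positive under partial matching."""
    gold = [EntitySpan(0, 12, "BRAND", "BANG Bars XL")]
    pred = [EntitySpan(0, 9, "BRAND", "BANG Bars")]
    exact = match_entities(gold, pred, "exact")["BRAND"]
    assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
    partial = match_entities(gold, pred, "partial")["BRAND"]
    assert (partial.tp, partial.fp, partial.fn) == (1, 0, 0)


def test_wrong_label_counts_both_ways():
    gold = [_span(0, 4, "BRAND")]
    pred = [_span(0, 4, "FLAVOR")]
    counts = match_entities(gold, pred)
    assert counts["BRAND"] == ConfusionCounts(0, 0, 1)
    assert counts["FLAVOR"] == ConfusionCounts(0, 1, 0)


def test_overlapping_annotation_set_rejected():
    with pytest.raises(ValidationError):
        match_entities([_span(0, 5), _span(3, 8)], [])


@given(
    st.lists(st.tuples(st.integers(0, 60), st.integers(1, 6)), max_size=8),
    st.lists(st.tuples(st.integers(0, 60), st.integers(1, 6)), max_size=8),
)
@settings(max_examples=150, deadline=None)
def test_partial_tp_never_below_exact_tp(gold_raw, pred_raw):
    def build(raw):
        spans, cursor = [], 0
        for gap, width in raw:
            start = cursor + gap
            spans.append(_span(start, start + width))
            cursor = start + width
        return spans

    gold, pred = build(gold_raw), build(pred_raw)
    exact = match_entities(gold, pred, "exact")["BRAND"]
    partial = match_entities(gold, pred, "partial")["BRAND"]
    assert partial.tp >= exact.tp


# -- metric formulas --------------------------------------------------------


def test_metric_hand_values():
    counts = ConfusionCounts(tp=4, fp=1, fn=4)
    assert precision(counts) == 0.8
    assert recall(counts) == 0.5
    assert math.isclose(f1(counts), 2 / ((1 / 0.5) + (1 / 0.8)))
    assert round(f1(counts), 4) == 0.6154


def test_zero_denominators_are_undefined():
    assert precision(ConfusionCounts(0, 0, 5)) is None
    assert recall(ConfusionCounts(0, 3, 0)) is None
    assert f1(ConfusionCounts(0, 3, 5)) is None  # P = R = 0


@given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
@settings(max_examples=200, deadline=None)
def test_f1_is_harmonic_mean_between_p_and_r(tp, fp, fn):
    counts = ConfusionCounts(tp, fp, fn)
    p, r, h = precision(counts), recall(counts), f1(counts)
    if p is None or r is None or p + r == 0:
        assert h is None or (p is not None and r is not None)
        return
    assert math.isclose(h, 2 * p * r / (p + r))
    assert min(p, r) - 1e-12 <= h <= max(p, r) + 1e-12
    if p == r:
        assert math.isclose(h, p)


def test_micro_aggregation_consistency():
    """Metrics from summed counts equal metrics of the concatenated corpus."""
    posts, preds = [], []
    rng = np.random.default_rng(0)
    for i in range(30):
        text = "Smokio and mango ice all day"
        tokens = tokenize(text)
        gold = [EntitySpan(0, 6, "BRAND", "Smokio"), EntitySpan(11, 20, "FLAVOR", "mango ice")]
        posts.append(AnnotatedPost(RawPost(f"p{i}", text), text, tokens, gold))
        pred = list(gold) if rng.random() < 0.6 else [EntitySpan(0, 6, "BRAND", "Smokio")]
        preds.append(pred)
    combined = evaluate_posts(posts, preds)
    total = ConfusionCounts()
    for post, pred in zip(posts, preds):
        total = total + match_entities(post.spans, pred)["FLAVOR"]
    assert combined["FLAVOR"].counts == total
    assert combined["FLAVOR"].precision == precision(total)


# -- cross-validation -------------------------------------------------------


def test_folds_form_a_partition():
    for k, seed in [(5, 0), (5, 99), (3, 7), (10, 1)]:
        folds = make_folds(100, k, seed)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 100
        assert set(all_idx.tolist()) == set(range(100))
        sizes = {len(f) for f in folds}
        assert max(sizes) - min(sizes) <= 1


def test_too_few_posts_for_folds():
    with pytest.raises(ValidationError):
        make_folds(3, 5, 0)


class _ConstantTagger:
    """Predicts no entities at all; fitting is a no-op."""

    def fit(self, corpus):
        return self

    def predict(self, tokens):
        return TagSequence(["O"] * len(tokens), "IO")


class _OracleTagger:
    """Replays the gold annotation (looked up by token identity)."""

    def fit(self, corpus):
        self.memory = {
            tuple(t.surface for t in p.tokens): encode_tags(p.tokens, p.spans, "IO")
            for p in corpus
        }
        return self

    def predict(self, tokens):
        key = tuple(t.surface for t in tokens)
        return self.memory.get(key, TagSequence(["O"] * len(tokens), "IO"))


def test_cross_validation_is_deterministic(small_corpus):
    posts, _ = small_corpus
    a = cross_validate(posts, _ConstantTagger, k=5, seed=13)
    b = cross_validate(posts, _ConstantTagger, k=5, seed=13)
    assert a.to_dict() == b.to_dict()


def test_constant_metric_has_zero_sd(small_corpus):
    posts, _ = small_corpus

    class _GoldTagger(_OracleTagger):
        def fit(self, corpus):
            super().fit(posts)  # memorizes every post, incl. held-out
            return self

    report = cross_validate(posts, _GoldTagger, k=5, seed=1)
    assert report.mean["BRAND"]["f1"] == 1.0
    assert report.sd["BRAND"]["f1"] == 0.0


def test_all_outside_tagger_has_undefined_precision(small_corpus):
    posts, _ = small_corpus
    report = cross_validate(posts, _ConstantTagger, k=5, seed=2)
    assert report.mean["BRAND"]["precision"] is None
    assert report.mean["BRAND"]["recall"] == 0.0


# -- Cohen kappa ------------------------------------------------------------


def test_kappa_perfect_agreement():
    assert cohen_kappa(["O", "I-BRAND", "O"], ["O", "I-BRAND", "O"]) == 1.0


def test_kappa_hand_computed_confusion_table():
    # table [[20, 5], [10, 15]] over n=50: p_o = 0.7, p_e = 0.5, kappa = 0.4
    a = ["x"] * 25 + ["y"] * 25
    b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
    assert math.isclose(cohen_kappa(a, b), 0.4)


def test_kappa_complete_symmetric_disagreement():
    a = ["x", "y", "x", "y"]
    b = ["y", "x", "y", "x"]
    assert math.isclose(cohen_kappa(a, b), -1.0)


def test_kappa_degenerate_identical_constant_sequences():
    assert cohen_kappa(["O"] * 10, ["O"] * 10) == 1.0


def test_kappa_length_mismatch():
    with pytest.raises(ValidationError):
        cohen_kappa(["O"], ["O", "O"])


def test_kappa_agrees_with_sklearn():
    rng = np.random.default_rng(17)
    a = rng.choice(["O", "I-BRAND", "I-FLAVOR"], size=200).tolist()
    b = rng.choice(["O", "I-BRAND", "I-FLAVOR"], size=200).tolist()
    assert math.isclose(cohen_kappa(a, b), cohen_kappa_score(a, b), abs_tol=1e-12)


# -- mention shares ---------------------------------------------------------


def _posts_with_mentions(counts: dict, total: int):
    posts = []
    i = 0
    for name, count in counts.items():
        for _ in range(count):
            text = f"the {name} device"
            posts.append(
                AnnotatedPost(
                    RawPost(f"m{i}", text), text, tokenize(text),
                    [EntitySpan(4, 4 + len(name), "BRAND", name)],
                )
            )
            i += 1
    filler = total - sum(counts.values())
    for j in range(filler):
        name = f"brand{j:04d}"
        text = f"the {name} device"
        posts.append(
            AnnotatedPost(
                RawPost(f"f{j}", text), text, tokenize(text),
                [EntitySpan(4, 4 + len(name), "BRAND", name)],
            )
        )
    return posts


def test_mention_share_rounds_half_up_to_one_decimal():
    posts = _posts_with_mentions({"This is Salts": 16, "Adore eLiquid": 13, "Chief of Vapes": 9}, 392)
    table = mention_share(posts, "BRAND")
    assert table.total == 392
    by_name = {name: (count, share) for name, count, share in table.rows}
    assert by_name["This is Salts"] == (16, 4.1)
    assert by_name["Adore eLiquid"] == (13, 3.3)
    assert by_name["Chief of Vapes"] == (9, 2.3)


def test_single_surface_full_share():
    posts = _posts_with_mentions({"Smokio": 3}, 3)
    table = mention_share(posts, "BRAND")
    assert table.rows == [("Smokio", 3, 100.0)]


def test_mention_share_groups_casefolded_and_sorts():
    posts = _posts_with_mentions({"Smokio": 1, "smokio": 1, "Vyper": 1, "Aero": 1}, 4)
    table = mention_share(posts, "BRAND")
    assert table.rows[0][:2] == ("Smokio", 2)
    assert [r[0] for r in table.rows[1:]] == ["Aero", "Vyper"]  # ties sort by name


def test_mention_share_empty_corpus():
    table = mention_share([], "BRAND")
    assert table.rows == [] and table.total == 0


def test_compare_rankings():
    a = _posts_with_mentions({"Smokio": 5, "Vyper": 2}, 7)
    b = _posts_with_mentions({"Smokio": 4, "Aero": 3}, 7)
    ta, tb = mention_share(a, "BRAND"), mention_share(b, "BRAND")
    overlap = compare_rankings(ta, tb, top_n=2)
    assert overlap["in_both"] == ["smokio"]
    assert overlap["only_a"] == ["vyper"] and overlap["only_b"] == ["aero"]
    assert compare_rankings(ta, ta, 2)["only_a"] == []
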