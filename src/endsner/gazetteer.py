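"""Dictionary look-up baseline: match lexicon surface forms in post text.

Matching is case-insensitive and, by default, anchored to token boundaries —
an entry only matches a contiguous run of whole tokens whose lower-cased
surfaces equal the entry's tokenization.  A raw substring mode is available
behind a flag for the recall-favoring variant.  Overlapping candidate
matches are resolved longest-first, then leftmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .preprocessing import AnnotatedPost, EntitySpan, Token, tokenize


class LexiconError(ValueError):
    """Empty or malformed lexicon."""


@dataclass
class Lexicon:
    """A labeled list of entity surface forms with a provenance tag."""

    label: str
    entries: list[str]
    name: str = "lexicon"

    def __post_init__(self) -> None:
        cleaned = [e.strip() for e in self.entries]
        if not cleaned or any(not e for e in cleaned):
            raise LexiconError(f"lexicon {self.name!r} has empty entries")
        self.entries = cleaned


@dataclass
class CompiledMatcher:
    """Token-sequence (or substring) index over a lexicon's normalized entries."""

    label: str
    name: str
    mode: str
    patterns: set[tuple[str, ...]] = field(default_factory=set)  # token mode
    strings: set[str] = field(default_factory=set)  # substring mode
    max_len: int = 0


def compile_lexicon(lexicon: Lexicon, mode: str = "token") -> CompiledMatcher:
    """Normalize lexicon entries with the post tokenizer and index them.

    Entries are lower-cased and tokenized exactly as post text is, so that
    ``"Puff Bar"`` and ``"puff  bar"`` collapse to the same two-token
    pattern; duplicates collapse.
    """
    if mode not in ("token", "substring"):
        raise LexiconError(f"unknown match mode {mode!r}")
    matcher = CompiledMatcher(lexicon.label, lexicon.name, mode)
    for entry in lexicon.entries:
        lowered = entry.lower()
        toks = tuple(t.surface for t in tokenize(lowered))
        if not toks:
            raise LexiconError(f"entry {entry!r} has no tokens")
        matcher.patterns.add(toks)
        matcher.strings.add(" ".join(toks))
        matcher.max_len = max(matcher.max_len, len(toks))
    return matcher


def _resolve_overlaps(candidates: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep a non-overlapping subset, preferring longer then leftmost matches."""
    chosen: list[tuple[int, int]] = []
    for start, end in sorted(candidates, key=lambda c: (c[0] - c[1], c[0])):
        if all(end <= s or start >= e for s, e in chosen):
            chosen.append((start, end))
    return sorted(chosen)


def gazetteer_tag(
    tokens: Sequence[Token],
    matcher: CompiledMatcher,
    text: str | None = None,
) -> list[EntitySpan]:
    """Emit an entity span for every lexicon occurrence in the token sequence.

    In token mode an occurrence is a run of tokens whose lower-cased surfaces
    equal an entry's token pattern (so ``"pop"`` never matches inside
    ``"lollipop"``).  In substring mode the lower-cased normalized text is
    searched directly.  Output spans never overlap.
    """
    if matcher.mode == "substring":
        if text is None:
            text = _reconstruct_text(tokens)
        hay = text.lower()
        candidates = []
        for needle in matcher.strings:
            start = hay.find(needle)
            while start != -1:
                candidates.append((start, start + len(needle)))
                start = hay.find(needle, start + 1)
        return [
            EntitySpan(s, e, matcher.label, text[s:e])
            for s, e in _resolve_overlaps(candidates)
        ]

    lowered = [t.surface.lower() for t in tokens]
    candidates_tok: list[tuple[int, int]] = []
    for i in range(len(tokens)):
        for width in range(1, min(matcher.max_len, len(tokens) - i) + 1):
            if tuple(lowered[i : i + width]) in matcher.patterns:
                candidates_tok.append((i, i + width))
    spans = []
    for i, j in _resolve_overlaps(candidates_tok):
        start, end = tokens[i].start, tokens[j - 1].end
        surface = text[start:end] if text is not None else _reconstruct_text(tokens[i:j])
        spans.append(EntitySpan(start, end, matcher.label, surface))
    return spans


def _reconstruct_text(tokens: Sequence[Token]) -> str:
    if not tokens:
        return ""
    pieces = []
    prev_end = tokens[0].start
    for t in tokens:
        pieces.append(" " * (t.start - prev_end))
        pieces.append(t.surface)
        prev_end = t.end
    return "".join(pieces)


class GazetteerTagger:
    """Lexicon look-up wrapped in the Tagger contract (fit is a no-op)."""

    def __init__(self, lexicon: Lexicon, mode: str = "token", scheme: str = "IO"):
        self.matcher = compile_lexicon(lexicon, mode)
        self.scheme = scheme

    def fit(self, corpus) -> "GazetteerTagger":
        return self

    def predict(self, tokens: Sequence[Token]):
        from .preprocessing import encode_tags

        spans = gazetteer_tag(tokens, self.matcher)
        return encode_tags(tokens, spans, self.scheme)


def benchmark_lexicon(
    corpus: Sequence[AnnotatedPost],
    lexicon: Lexicon,
    folds: int = 5,
    seed: int = 0,
    mode: str = "token",
    match_mode: str = "exact",
):
    """Entity-level cross-validated scores of the dictionary look-up baseline.

    The look-up needs no training, but it is evaluated on the same fold
    partition as the learned taggers so the reports are comparable.
    """
    from .evaluation import cross_validate

    return cross_validate(
        corpus,
        lambda: GazetteerTagger(lexicon, mode=mode),
        k=folds,
        seed=seed,
        match_mode=match_mode,
    )
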