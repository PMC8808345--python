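"""Synthetic Instagram-like annotated corpus generator.

Every pipeline stage is testable without the private annotated data set:
this module emits posts whose summary shape matches the study corpus —
roughly 35 tokens per post, about 0.54 brand mentions and 0.22 flavor
mentions per post, hashtag and emoji noise — with gold spans exact by
construction.  Posts are assembled from short phrase templates with entity
slots, filled from configurable brand/flavor vocabularies with casing and
spacing variants, padded with generic filler words, and optionally salted
with homographs: generic words (e.g. "pop", "epic") that double as entries
of a polluted look-up lexicon while appearing as plain non-entity text.

Generation is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gazetteer import Lexicon
from .preprocessing import (
    AnnotatedPost,
    EntitySpan,
    RawPost,
    project_spans,
    normalize_post,
    tokenize,
)

# ---------------------------------------------------------------------------
# default vocabularies (invented surface forms; no real trademarks implied)
# ---------------------------------------------------------------------------

_BRAND_SINGLE = [
    "Smokio", "Juulex", "Vapetron", "Geekler", "Modzilla", "Nebulo", "Vyper",
    "Kloudz", "Drakon", "Zephyrus", "Fumaro", "Quillox", "Brimstone", "Aetherion",
    "Voltaro", "Mistiq", "Hazel8", "Cumulon", "Pyroz", "Stratovape",
]
_BRAND_FIRST = ["Vapor", "Cloud", "Puff", "Drip", "Mist", "Ember", "Nova", "Onyx", "Titan", "Frost"]
_BRAND_SECOND = ["Bar", "King", "Labs", "Works", "Society", "Supply", "Nation", "House", "Craft", "Republic"]

_FLAVOR_PLAIN = [
    "mango", "strawberry", "blue razz", "watermelon", "grape", "peach",
    "banana", "lychee", "pineapple", "melon", "cherry", "green apple",
    "kiwi", "guava", "papaya",
]
_FLAVOR_SUFFIX = ["ice", "freeze", "burst", "custard", "cream"]

#: generic words that double as look-up entries when planted as plain text
DEFAULT_HOMOGRAPHS = ["pop", "epic", "square", "carbon", "zoom", "logic", "bolt", "metro"]

_FILLER = (
    "just got my new setup today loving this the and so smooth clouds all day "
    "best juice in stock now check out link bio shop local store fresh drop "
    "restock hits different cant stop vaping on it really nice throat hit good "
    "vibes only come grab yours while supplies last we are open till late dm "
    "for orders fast shipping available tag your friends who need to see crazy "
    "deals weekend coils ready premium quality batch small local makers every "
    "order ships same evening"
).split()

_HASHTAGS = [
    "#vape", "#vapelife", "#ecigs", "#vapecommunity", "#vapenation",
    "#cloudchaser", "#vapefam", "#eliquid", "#vapeon", "#vapedaily",
]
_EMOJI = ["🔥", "💨", "😍", "👌", "💯", "✨", "🍓", "🍉", "😎", "🙌"]

_BRAND_TEMPLATES = [
    "check out {}",
    "new {} just dropped",
    "got my {} today",
    "the {} hits so smooth",
    "restock on {} now",
    "{} back in stock",
    "try the {} kit",
    "full review of the {} mod",
]
_FLAVOR_TEMPLATES = [
    "tastes like {}",
    "{} flavor all day",
    "craving some {}",
    "new {} juice",
    "this {} blend is amazing",
    "{} notes on the exhale",
]


def default_brand_vocab(n: int = 50) -> list[str]:
    """Deterministic bank of n brand names, roughly 60% two-word forms."""
    doubles = [f"{a} {b}" for a in _BRAND_FIRST for b in _BRAND_SECOND]
    out: list[str] = []
    i = j = 0
    for k in range(n):
        if k % 5 < 3 or j >= len(_BRAND_SINGLE):
            out.append(doubles[i]); i += 1
        else:
            out.append(_BRAND_SINGLE[j]); j += 1
    return out


def default_flavor_vocab(n: int = 30) -> list[str]:
    combos = [f"{p} {s}" for p, s in zip(_FLAVOR_PLAIN, _FLAVOR_SUFFIX * 3)]
    pool = _FLAVOR_PLAIN + combos
    return pool[:n]


@dataclass
class GeneratorConfig:
    """Knobs for corpus generation; defaults follow the study corpus shape
    (≈35 tokens/post, ≈0.54 brand and ≈0.22 flavor mentions per post)."""

    n_posts: int = 2272
    brand_vocab: list[str] = field(default_factory=default_brand_vocab)
    flavor_vocab: list[str] = field(default_factory=default_flavor_vocab)
    template_bank: dict[str, list[str]] = field(
        default_factory=lambda: {"BRAND": list(_BRAND_TEMPLATES), "FLAVOR": list(_FLAVOR_TEMPLATES)}
    )
    p_brand_mention: float = 0.54
    p_flavor_mention: float = 0.22
    tokens_per_post: float = 35.0
    p_hashtag: float = 0.7
    p_emoji: float = 0.5
    homograph_rate: float = 0.1
    homographs: list[str] = field(default_factory=lambda: list(DEFAULT_HOMOGRAPHS))
    truncated_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hashtag", "p_emoji", "homograph_rate", "truncated_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_brand_mention < 0 or self.p_flavor_mention < 0:
            raise ValueError("mention rates must be non-negative")
        if self.n_posts < 1:
            raise ValueError("n_posts must be positive")
        if not self.brand_vocab or not self.flavor_vocab:
            raise ValueError("vocabularies must be non-empty")


@dataclass
class CorpusStatistics:
    posts: int
    tokens: int
    unique_tokens: int
    brand_mentions: int
    flavor_mentions: int


def _mention_count(rate: float, rng: np.random.Generator) -> int:
    """floor(rate) guaranteed mentions plus a Bernoulli fractional part."""
    base = int(rate)
    return base + (1 if rng.random() < rate - base else 0)


def _brand_variant(canonical: str, rng: np.random.Generator) -> str:
    """Casing/spacing variant of a canonical brand name as posts render it."""
    r = rng.random()
    if r < 0.55:
        return canonical
    if r < 0.70:
        return canonical.lower()
    if r < 0.80:
        return canonical.upper()
    if " " in canonical:  # squashed spelling, e.g. "Puff Bar" -> "PuffBar"
        return "".join(part.capitalize() for part in canonical.split())
    return canonical.lower()


def _flavor_variant(canonical: str, rng: np.random.Generator) -> str:
    return canonical.title() if rng.random() < 0.2 else canonical


def generate_post(
    config: GeneratorConfig, rng: np.random.Generator, post_id: str = "p0"
) -> tuple[AnnotatedPost, list[str]]:
    """Generate one annotated post; returns it with the canonical names of
    the brands mentioned (for frequency-ranked lexicon construction)."""
    items: list[tuple[str, ...]] = []  # ("w", word) or ("ent", label, surface)
    n_filler = max(3, int(round(rng.normal(config.tokens_per_post - 6, config.tokens_per_post / 5))))
    for w in rng.choice(_FILLER, size=n_filler):
        items.append(("w", str(w)))

    mentioned_brands: list[str] = []
    phrases: list[list[tuple[str, ...]]] = []
    for _ in range(_mention_count(config.p_brand_mention, rng)):
        canonical = str(rng.choice(config.brand_vocab))
        mentioned_brands.append(canonical)
        surface = _brand_variant(canonical, rng)
        template = str(rng.choice(config.template_bank["BRAND"]))
        phrases.append(_fill_template(template, "BRAND", surface))
    for _ in range(_mention_count(config.p_flavor_mention, rng)):
        surface = _flavor_variant(str(rng.choice(config.flavor_vocab)), rng)
        template = str(rng.choice(config.template_bank["FLAVOR"]))
        phrases.append(_fill_template(template, "FLAVOR", surface))
    if config.homographs and rng.random() < config.homograph_rate:
        phrases.append([("w", str(rng.choice(config.homographs)))])

    for phrase in phrases:
        at = int(rng.integers(0, len(items) + 1))
        items[at:at] = phrase
    items = _separate_adjacent_entities(items)

    if rng.random() < config.p_emoji:
        at = int(rng.integers(0, len(items) + 1))
        items.insert(at, ("w", str(rng.choice(_EMOJI))))
    if rng.random() < config.p_hashtag:
        for tag in rng.choice(_HASHTAGS, size=int(rng.integers(1, 4)), replace=False):
            items.append(("w", str(tag)))

    # realize raw text and raw-offset gold spans
    pieces: list[str] = []
    raw_spans: list[EntitySpan] = []
    pos = 0
    for item in items:
        if pieces:
            pieces.append(" ")
            pos += 1
        text = item[-1]
        if item[0] == "ent":
            raw_spans.append(EntitySpan(pos, pos + len(text), item[1], text))
        pieces.append(text)
        pos += len(text)
    raw_text = "".join(pieces)

    normalized, offset_map = normalize_post(raw_text)
    spans, _ = project_spans(raw_spans, offset_map)
    post = AnnotatedPost(
        post=RawPost(post_id, raw_text),
        normalized_text=normalized,
        tokens=tokenize(normalized),
        spans=sorted(spans, key=lambda s: s.start),
    )
    return post, mentioned_brands


def _fill_template(template: str, label: str, surface: str) -> list[tuple[str, ...]]:
    before, _, after = template.partition("{}")
    phrase: list[tuple[str, ...]] = [("w", w) for w in before.split()]
    phrase.append(("ent", label, surface))
    phrase += [("w", w) for w in after.split()]
    return phrase


def _separate_adjacent_entities(items: list[tuple[str, ...]]) -> list[tuple[str, ...]]:
    """Insert a filler word between directly adjacent entity items so the IO
    encoding stays lossless on generated corpora."""
    out: list[tuple[str, ...]] = []
    for item in items:
        if item[0] == "ent" and out and out[-1][0] == "ent":
            out.append(("w", "and"))
        out.append(item)
    return out


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedPost], dict[str, Lexicon]]:
    """Generate a corpus plus companion look-up lexicons.

    Companion lexicons: ``FULL`` holds every canonical brand name in the
    vocabulary; ``TRUNCATED`` the top fraction of names ranked by how often
    they were planted (emulating a smaller top-sellers list); ``POLLUTED``
    is FULL plus generic homograph words (added entries can only create
    false positives, never remove recall); ``FLAVOR_FULL`` holds the
    canonical flavor names.
    """
    rng = np.random.default_rng(config.seed)
    posts: list[AnnotatedPost] = []
    brand_counts: dict[str, int] = {name: 0 for name in config.brand_vocab}
    for i in range(config.n_posts):
        post, mentioned = generate_post(config, rng, post_id=f"post-{i:05d}")
        posts.append(post)
        for name in mentioned:
            brand_counts[name] += 1

    ranked = sorted(brand_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_keep = max(1, math.ceil(len(ranked) * config.truncated_fraction))
    lexicons = {
        "FULL": Lexicon("BRAND", list(config.brand_vocab), "full"),
        "TRUNCATED": Lexicon("BRAND", [name for name, _ in ranked[:n_keep]], "truncated"),
        "POLLUTED": Lexicon(
            "BRAND", list(config.brand_vocab) + list(config.homographs), "polluted"
        ),
        "FLAVOR_FULL": Lexicon("FLAVOR", list(config.flavor_vocab), "flavor-full"),
    }
    return posts, lexicons


def corpus_statistics(corpus: Sequence[AnnotatedPost]) -> CorpusStatistics:
    """Summary counts in the shape of the study's data-statistics table."""
    tokens = 0
    unique: set[str] = set()
    brands = flavors = 0
    for post in corpus:
        tokens += len(post.tokens)
        unique.update(t.surface for t in post.tokens)
        brands += sum(1 for s in post.spans if s.label == "BRAND")
        flavors += sum(1 for s in post.spans if s.label == "FLAVOR")
    return CorpusStatistics(len(corpus), tokens, len(unique), brands, flavors)
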