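"""Social-media text normalization, tokenization, and span/tag conversion.

The pipeline normalizes raw post text (hashtag removal, emoji replacement by
CLDR short names, whitespace collapsing), tokenizes the normalized text into
word and single-character punctuation tokens with character offsets, and
converts between character-offset entity spans and per-token tag sequences
under the IO, IOB, or BILOU encoding schemes.

All character offsets are 0-based and half-open.  Normalization is the
canonical coordinate system: entity spans live on the normalized text, and an
:class:`OffsetMap` relates raw-text offsets to normalized offsets so that
annotations made on raw text can be projected forward.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

logger = logging.getLogger("endsner")

ENTITY_LABELS = ("BRAND", "FLAVOR")
SCHEMES = ("IO", "IOB", "BILOU")

#: tag prefixes admitted by each encoding scheme
_SCHEME_PREFIXES = {"IO": {"I"}, "IOB": {"B", "I"}, "BILOU": {"B", "I", "L", "U"}}


class AlignmentError(ValueError):
    """An entity span does not align with token or normalization boundaries."""


class SchemeError(ValueError):
    """A tag string is invalid for the requested encoding scheme."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawPost:
    """One social-media post as collected: an opaque id and its raw text."""

    post_id: str
    text: str

    def __post_init__(self) -> None:
        if not self.post_id:
            raise ValueError("post_id must be non-empty")


@dataclass(frozen=True)
class Token:
    """A token of the normalized text with its character offsets."""

    surface: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"token offsets must satisfy start < end: {self}")


@dataclass(frozen=True)
class EntitySpan:
    """A labeled entity mention as character offsets into normalized text."""

    start: int
    end: int
    label: str
    surface: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"span offsets must satisfy start < end: {self}")
        if self.label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label {self.label!r}")


@dataclass
class AnnotatedPost:
    """A post with normalized text, its tokens, and gold entity spans."""

    post: RawPost
    normalized_text: str
    tokens: list[Token]
    spans: list[EntitySpan]

    @property
    def post_id(self) -> str:
        return self.post.post_id


@dataclass
class TagSequence:
    """Per-token labels under one of the supported encoding schemes."""

    labels: list[str]
    scheme: str = "IO"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise SchemeError(f"unknown scheme {self.scheme!r}")
        for tag in self.labels:
            _validate_tag(tag, self.scheme)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def _validate_tag(tag: str, scheme: str) -> None:
    if tag == "O":
        return
    prefix, _, etype = tag.partition("-")
    if prefix not in _SCHEME_PREFIXES[scheme] or etype not in ENTITY_LABELS:
        raise SchemeError(f"tag {tag!r} is invalid for scheme {scheme}")


@dataclass
class OffsetMap:
    """Total, monotone map from raw-text offsets to normalized-text offsets.

    ``positions[i]`` is the normalized offset of raw offset ``i`` for every
    ``0 <= i <= len(raw)``; offsets inside removed regions map to the position
    of the gap.  ``removed[i]`` flags raw characters deleted outright (hashtag
    removal), as opposed to characters merely rewritten (emoji replacement)
    or collapsed (whitespace).
    """

    raw_text: str
    normalized_text: str
    positions: list[int]
    removed: list[bool]

    def __call__(self, raw_offset: int) -> int:
        return self.positions[raw_offset]


# ---------------------------------------------------------------------------
# emoji / CLDR short names
# ---------------------------------------------------------------------------

_JOINERS = {0x200D, 0xFE0E, 0xFE0F, 0x20E3}  # ZWJ, variation selectors, keycap
_MODIFIER_RANGE = (0x1F3FB, 0x1F3FF)  # skin tones
# Single codepoints outside the main blocks that render as emoji.
_EXTRA_EMOJI = {0x2B05, 0x2B06, 0x2B07, 0x2B1B, 0x2B1C, 0x2B50, 0x2B55, 0x203C, 0x2049}


def _is_emoji_char(ch: str) -> bool:
    cp = ord(ch)
    return (
        0x1F000 <= cp <= 0x1FAFF
        or 0x2600 <= cp <= 0x27BF
        or cp in _EXTRA_EMOJI
    )


def _is_emoji_part(ch: str) -> bool:
    cp = ord(ch)
    return _is_emoji_char(ch) or cp in _JOINERS or _MODIFIER_RANGE[0] <= cp <= _MODIFIER_RANGE[1]


def _load_cldr_table() -> dict[str, str]:
    table: dict[str, str] = {}
    data = resources.files("endsner.data").joinpath("cldr_short_names.tsv").read_text("utf-8")
    for line in data.splitlines():
        if not line or line.startswith("#"):
            continue
        emoji_seq, _, name = line.partition("\t")
        if emoji_seq and name:
            table[emoji_seq] = name.strip()
    return table


_CLDR_TABLE: dict[str, str] | None = None


def cldr_short_name(sequence: str) -> str:
    """CLDR English short name of an emoji codepoint or sequence.

    Looks the full sequence up in the pinned table; unknown sequences fall
    back to the Unicode character name of each non-joiner codepoint,
    lower-cased.  Returns "" for sequences with no resolvable name.
    """
    global _CLDR_TABLE
    if _CLDR_TABLE is None:
        _CLDR_TABLE = _load_cldr_table()
        logger.debug("loaded pinned CLDR short-name table (%d entries)", len(_CLDR_TABLE))
    if sequence in _CLDR_TABLE:
        return _CLDR_TABLE[sequence]
    stripped = "".join(ch for ch in sequence if ord(ch) not in _JOINERS)
    if stripped in _CLDR_TABLE:
        return _CLDR_TABLE[stripped]
    parts = []
    for ch in stripped:
        if _MODIFIER_RANGE[0] <= ord(ch) <= _MODIFIER_RANGE[1]:
            continue
        if ch in _CLDR_TABLE:
            parts.append(_CLDR_TABLE[ch])
        else:
            name = unicodedata.name(ch, "")
            if name:
                parts.append(name.lower())
    return " ".join(parts)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

_HASHTAG_RE = re.compile(r"#+\w+")


def normalize_post(text: str) -> tuple[str, OffsetMap]:
    """Normalize raw post text and return it with a raw→normalized offset map.

    Hashtag tokens (maximal ``#``-initiated word tokens) are removed, each
    emoji codepoint or joined sequence is replaced by its CLDR short name as
    plain space-separated words, and runs of whitespace collapse to single
    spaces with leading/trailing whitespace stripped.
    """
    n = len(text)
    out: list[str] = []
    positions = [0] * (n + 1)
    removed = [False] * n
    pending_space = False

    def emit(piece: str) -> None:
        nonlocal pending_space
        if pending_space and out:
            out.append(" ")
        pending_space = False
        out.extend(piece)

    i = 0
    while i < n:
        ch = text[i]
        m = _HASHTAG_RE.match(text, i) if ch == "#" else None
        if m is not None:
            for j in range(i, m.end()):
                positions[j] = len(out)
                removed[j] = True
            i = m.end()
        elif ch.isspace():
            j = i
            while j < n and text[j].isspace():
                positions[j] = len(out)
                j += 1
            if out:
                pending_space = True
            i = j
        elif _is_emoji_char(ch):
            j = i + 1
            while j < n and _is_emoji_part(text[j]):
                j += 1
            name = cldr_short_name(text[i:j])
            if name:
                if out and not pending_space:
                    pending_space = True
                start_pos = len(out) + (1 if (pending_space and out) else 0)
                emit(name)
                for k in range(i, j):
                    positions[k] = start_pos
                pending_space = True
            else:
                for k in range(i, j):
                    positions[k] = len(out)
            i = j
        else:
            pos = len(out) + (1 if (pending_space and out) else 0)
            emit(ch)
            positions[i] = pos
            i += 1
    positions[n] = len(out)
    normalized = "".join(out)
    return normalized, OffsetMap(text, normalized, positions, removed)


def project_spans(
    spans: Sequence[EntitySpan], offset_map: OffsetMap
) -> tuple[list[EntitySpan], int]:
    """Project raw-text spans onto the normalized text.

    Returns the projected spans and the number of spans dropped because they
    lay entirely inside removed regions (e.g. inside a removed hashtag).
    A span that is only partially removed cannot be represented and raises
    :class:`AlignmentError`.
    """
    projected: list[EntitySpan] = []
    dropped = 0
    for span in spans:
        if span.end > len(offset_map.raw_text):
            raise AlignmentError(f"span {span} exceeds raw text length")
        flags = offset_map.removed[span.start : span.end]
        chars = offset_map.raw_text[span.start : span.end]
        any_removed = any(flags)
        any_kept = any(
            not f and not c.isspace() for f, c in zip(flags, chars)
        )
        if any_removed and any_kept:
            raise AlignmentError(f"span {span} partially overlaps a removed region")
        if any_removed or not any_kept:
            logger.warning("dropping span %r: entirely within removed text", span.surface)
            dropped += 1
            continue
        start = offset_map(span.start)
        end = offset_map(span.end)
        surface = offset_map.normalized_text[start:end]
        projected.append(EntitySpan(start, end, span.label, surface))
    return projected, dropped


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch)[0] in ("P", "S")


def tokenize(text: str) -> list[Token]:
    """Split normalized text into word tokens and single-char punctuation tokens.

    Tokens are delimited by whitespace; within a whitespace-delimited chunk,
    every punctuation or symbol character (Unicode categories P and S) forms
    its own one-character token.  Offsets index into ``text``.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, base = m.group(), m.start()
        run_start = 0
        for k, ch in enumerate(chunk):
            if _is_punct(ch):
                if run_start < k:
                    tokens.append(
                        Token(chunk[run_start:k], base + run_start, base + k, len(tokens))
                    )
                tokens.append(Token(ch, base + k, base + k + 1, len(tokens)))
                run_start = k + 1
        if run_start < len(chunk):
            tokens.append(
                Token(chunk[run_start:], base + run_start, base + len(chunk), len(tokens))
            )
    return tokens


# ---------------------------------------------------------------------------
# span <-> tag conversion
# ---------------------------------------------------------------------------


def _check_disjoint(spans: Sequence[EntitySpan]) -> list[EntitySpan]:
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise AlignmentError(f"spans overlap: {a} and {b}")
    return ordered

def encode_tags(
    tokens: Sequence[Token], spans: Sequence[EntitySpan], scheme: str = "IO"
) -> TagSequence:
    """Encode entity spans as one tag per token under the chosen scheme.

    Every span must start at some token's start offset and end at some
    token's end offset; a span crossing a token boundary mid-token raises
    :class:`AlignmentError` naming the span.
    """
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}")
    starts = {t.start: t.index for t in tokens}
    ends = {t.end: t.index for t in tokens}
    labels = ["O"] * len(tokens)
    for span in _check_disjoint(spans):
        if span.start not in starts or span.end not in ends:
            raise AlignmentError(f"span {span} does not align with token boundaries")
        first, last = starts[span.start], ends[span.end]
        for idx in range(first, last + 1):
            if scheme == "IO":
                labels[idx] = f"I-{span.label}"
            elif scheme == "IOB":
                labels[idx] = ("B-" if idx == first else "I-") + span.label
            else:  # BILOU
                if first == last:
                    labels[idx] = f"U-{span.label}"
                elif idx == first:
                    labels[idx] = f"B-{span.label}"
                elif idx == last:
                    labels[idx] = f"L-{span.label}"
                else:
                    labels[idx] = f"I-{span.label}"
    return TagSequence(labels, scheme)


def decode_tags(
    tokens: Sequence[Token],
    tag_sequence: TagSequence,
    text: str | None = None,
) -> list[EntitySpan]:
    """Decode a tag sequence back to entity spans.

    Under IO, maximal runs of same-type inside tags merge into one span (the
    scheme cannot separate adjacent same-type entities).  Under IOB and BILOU
    the boundary markers are respected; a continuation tag without a matching
    opener starts a new span.  ``text`` supplies span surfaces; when omitted,
    inter-token gaps are reconstructed as spaces.
    """
    if len(tokens) != len(tag_sequence):
        raise ValueError("token and tag sequence lengths differ")
    scheme = tag_sequence.scheme
    spans: list[EntitySpan] = []
    open_first: int | None = None
    open_type: str | None = None

    def close(last_idx: int) -> None:
        nonlocal open_first, open_type
        if open_first is None:
            return
        start = tokens[open_first].start
        end = tokens[last_idx].end
        spans.append(EntitySpan(start, end, open_type, _surface(tokens, open_first, last_idx, text)))
        open_first = open_type = None

    for idx, tag in enumerate(tag_sequence):
        if tag == "O":
            close(idx - 1)
            continue
        prefix, _, etype = tag.partition("-")
        begins = prefix in ("B", "U") or (
            open_type != etype
        )
        if begins:
            close(idx - 1)
            open_first, open_type = idx, etype
        if prefix in ("L", "U"):
            close(idx)
    close(len(tokens) - 1)
    return spans


def _surface(tokens: Sequence[Token], first: int, last: int, text: str | None) -> str:
    start, end = tokens[first].start, tokens[last].end
    if text is not None:
        return text[start:end]
    pieces = []
    prev_end = start
    for t in tokens[first : last + 1]:
        pieces.append(" " * (t.start - prev_end))
        pieces.append(t.surface)
        prev_end = t.end
    return "".join(pieces)


def annotate(post: RawPost, raw_spans: Iterable[EntitySpan] = ()) -> AnnotatedPost:
    """Run the full preprocessing pipeline on one raw post.

    Normalizes the text, tokenizes it, and projects any raw-text spans onto
    the normalized coordinates.
    """
    normalized, offset_map = normalize_post(post.text)
    spans, _ = project_spans(list(raw_spans), offset_map)
    return AnnotatedPost(post, normalized, tokenize(normalized), spans)
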