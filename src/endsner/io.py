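"""Reading and writing the on-disk formats: JSONL corpora, lexicon TSVs,
CoNLL-style token/tag exports, and JSON model files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

from .preprocessing import (
    AnnotatedPost,
    EntitySpan,
    RawPost,
    TagSequence,
    Token,
    tokenize,
)


def post_to_dict(post: AnnotatedPost) -> dict:
    return {
        "id": post.post_id,
        "text": post.normalized_text,
        "spans": [
            {"start": s.start, "end": s.end, "label": s.label, "text": s.surface}
            for s in post.spans
        ],
    }


def post_from_dict(obj: dict) -> AnnotatedPost:
    """Build an AnnotatedPost from one corpus record, validating invariants.

    The record's ``text`` is taken to be normalized already; spans must match
    the covered text exactly.
    """
    text = obj["text"]
    spans = []
    for s in obj.get("spans", []):
        span = EntitySpan(s["start"], s["end"], s["label"], s.get("text", text[s["start"] : s["end"]]))
        if text[span.start : span.end] != span.surface:
            raise ValueError(
                f"post {obj['id']!r}: span surface {span.surface!r} does not match "
                f"text {text[span.start:span.end]!r}"
            )
        spans.append(span)
    return AnnotatedPost(
        post=RawPost(str(obj["id"]), text),
        normalized_text=text,
        tokens=tokenize(text),
        spans=sorted(spans, key=lambda s: s.start),
    )


def read_corpus(path: str | Path) -> list[AnnotatedPost]:
    """Read a JSONL corpus (one ``{"id", "text", "spans"}`` object per line)."""
    posts = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            post = post_from_dict(json.loads(line))
            if post.post_id in seen:
                raise ValueError(f"duplicate post id {post.post_id!r}")
            seen.add(post.post_id)
            posts.append(post)
    return posts


def write_corpus(posts: Iterable[AnnotatedPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post_to_dict(post), ensure_ascii=False) + "\n")


def write_conll(
    items: Iterable[tuple[Sequence[Token], TagSequence]], path: str | Path
) -> None:
    """Export posts as two-column ``token<TAB>tag`` blocks, blank-line separated."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags in items:
            for token, tag in zip(tokens, tags):
                fh.write(f"{token.surface}\t{tag}\n")
            fh.write("\n")


def read_lexicon_tsv(path: str | Path):
    """Read a ``surface<TAB>label`` lexicon TSV with an optional ``# name:`` header."""
    from .gazetteer import Lexicon

    name = Path(path).stem
    entries: list[str] = []
    labels: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                _, _, value = line[1:].partition("name:")
                if value.strip():
                    name = value.strip()
                continue
            surface, _, label = line.partition("\t")
            entries.append(surface)
            labels.add(label.strip() or "BRAND")
    if len(labels) > 1:
        raise ValueError(f"lexicon {path} mixes labels {sorted(labels)}")
    return Lexicon(label=labels.pop() if labels else "BRAND", entries=entries, name=name)


def write_lexicon_tsv(lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# name: {lexicon.name}\n")
        for entry in lexicon.entries:
            fh.write(f"{entry}\t{lexicon.label}\n")
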