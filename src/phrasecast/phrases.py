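"""Phrase-mention detection and confirmation.

A :class:`PhrasePattern` describes the target phrase: keyword variants
(inflections of the head word), synonym variants, explicit misspellings, and
context terms used by the automatic confirmation rule.  Detection is
keyword search over tokenized posts; semantic confirmation comes either
from the context rule (a weak automatable proxy) or from a manual
annotation table, which always wins.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from ._util import percent_half_up, tokenize
from .forum import Forum

CANDIDATE = "candidate"
CONFIRMED = "confirmed"
REJECTED = "rejected"
STATUSES = (CANDIDATE, CONFIRMED, REJECTED)

TOPIC_FATIGUE = "fatigue"
TOPIC_OTHER = "other"
TOPIC_UNLABELED = "unlabeled"
TOPICS = (TOPIC_FATIGUE, TOPIC_OTHER, TOPIC_UNLABELED)

SAME_POST = "same-post"


class AnnotationError(ValueError):
    """An annotation row refers to a post that has no candidate mention."""


@dataclass(frozen=True)
class PhrasePattern:
    """Search pattern for the target phrase and its variants."""

    canonical: str
    keywords: tuple[str, ...]
    synonyms: tuple[str, ...] = ()
    context_terms: tuple[str, ...] = ()
    context_window: int | str = SAME_POST

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError("keywords must be non-empty")
        if isinstance(self.context_window, str) and self.context_window != SAME_POST:
            raise ValueError(
                f"context_window must be an integer or {SAME_POST!r}"
            )
        if isinstance(self.context_window, int) and self.context_window < 0:
            raise ValueError("context_window must be non-negative")

    @property
    def variants(self) -> tuple[str, ...]:
        return self.keywords + self.synonyms

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "PhrasePattern":
        return cls(
            canonical=str(data["canonical"]),
            keywords=tuple(data.get("keywords", ())),  # type: ignore[arg-type]
            synonyms=tuple(data.get("synonyms", ())),  # type: ignore[arg-type]
            context_terms=tuple(data.get("context_terms", ())),  # type: ignore[arg-type]
            context_window=data.get("context_window", SAME_POST),  # type: ignore[arg-type]
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PhrasePattern":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            if path.suffix == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_mapping(data)

    def to_mapping(self) -> dict[str, object]:
        return {
            "canonical": self.canonical,
            "keywords": list(self.keywords),
            "synonyms": list(self.synonyms),
            "context_terms": list(self.context_terms),
            "context_window": self.context_window,
        }


@dataclass(frozen=True)
class Mention:
    """One (post, matched variant) occurrence of the phrase."""

    post_index: int
    thread_id: str
    author_id: str
    matched_variant: str
    status: str = CANDIDATE
    topic: str = TOPIC_UNLABELED

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"invalid status {self.status!r}")
        if self.topic not in TOPICS:
            raise ValueError(f"invalid topic {self.topic!r}")


def _variant_positions(tokens: Sequence[str], variant_tokens: Sequence[str]) -> list[int]:
    """Start positions where the variant's token sequence occurs."""
    n, k = len(tokens), len(variant_tokens)
    if k == 0 or k > n:
        return []
    return [
        i for i in range(n - k + 1) if list(tokens[i : i + k]) == list(variant_tokens)
    ]


def find_candidates(forum: Forum, pattern: PhrasePattern) -> list[Mention]:
    """Scan every post for variant occurrences.

    One candidate per (post, distinct variant hit); sorted by post index
    then variant.  Matching is case-insensitive at token boundaries, so
    "legacy" does not match inside "legacies".
    """
    variant_tokens = {v: tuple(tokenize(v)) for v in pattern.variants}
    out: list[Mention] = []
    for post in forum:
        tokens = tokenize(post.text)
        hit_variants = sorted(
            v
            for v, vt in variant_tokens.items()
            if vt and _variant_positions(tokens, vt)
        )
        for v in hit_variants:
            out.append(
                Mention(
                    post_index=post.post_index,
                    thread_id=post.thread_id,
                    author_id=post.author_id,
                    matched_variant=v,
                )
            )
    return out


def apply_context_rule(
    forum: Forum, candidates: Iterable[Mention], pattern: PhrasePattern
) -> list[Mention]:
    """Auto-confirm candidates whose post satisfies the context rule.

    With ``context_window = "same-post"`` a candidate is confirmed when any
    context term occurs anywhere in the post; with an integer window the
    context term must occur within that many tokens of a variant occurrence.
    Everything else stays a candidate pending annotation.
    """
    context_tokens = {tuple(tokenize(t)) for t in pattern.context_terms}
    context_tokens.discard(())
    out = []
    for m in candidates:
        tokens = tokenize(forum.post(m.post_index).text)
        if _context_satisfied(tokens, tokenize(m.matched_variant), context_tokens,
                              pattern.context_window):
            out.append(replace(m, status=CONFIRMED))
        else:
            out.append(m)
    return out


def _context_satisfied(
    tokens: list[str],
    variant_tokens: list[str],
    context_tokens: set[tuple[str, ...]],
    window: int | str,
) -> bool:
    if not context_tokens:
        return False
    ctx_positions = [
        i for ct in context_tokens for i in _variant_positions(tokens, ct)
    ]
    if not ctx_positions:
        return False
    if window == SAME_POST:
        return True
    assert isinstance(window, int)
    for vp in _variant_positions(tokens, variant_tokens):
        if any(abs(cp - vp) <= window for cp in ctx_positions):
            return True
    return False


@dataclass(frozen=True)
class Annotation:
    post_index: int
    decision: str  # confirm | reject
    topic: str = TOPIC_UNLABELED


def read_annotations(path: str | Path) -> list[Annotation]:
    """Annotation CSV: post_index,decision,topic (topic may be blank)."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Annotation(
                    post_index=int(row["post_index"]),
                    decision=row["decision"].strip().lower(),
                    topic=(row.get("topic") or TOPIC_UNLABELED).strip().lower()
                    or TOPIC_UNLABELED,
                )
            )
    return out


def merge_annotations(
    mentions: Iterable[Mention], annotations: Iterable[Annotation]
) -> list[Mention]:
    """Apply manual decisions on top of the context rule.

    Annotations are authoritative: confirm/reject overrides whatever the
    context rule decided, and topic labels ride along.  An annotation whose
    post has no candidate mention is a consistency error.
    """
    mentions = list(mentions)
    known = {m.post_index for m in mentions}
    by_post: dict[int, Annotation] = {}
    for a in annotations:
        if a.decision not in {"confirm", "reject"}:
            raise AnnotationError(
                f"annotation for post {a.post_index}: decision must be "
                f"confirm or reject, got {a.decision!r}"
            )
        if a.post_index not in known:
            raise AnnotationError(
                f"annotation refers to post {a.post_index}, which has no "
                "candidate mention"
            )
        by_post[a.post_index] = a
    out = []
    for m in mentions:
        a = by_post.get(m.post_index)
        if a is None:
            out.append(m)
        elif a.decision == "confirm":
            out.append(replace(m, status=CONFIRMED, topic=a.topic))
        else:
            out.append(replace(m, status=REJECTED))
    return out


def confirmed_mentions(mentions: Iterable[Mention]) -> list[Mention]:
    return [m for m in mentions if m.status == CONFIRMED]


def topic_percentages(mentions: Iterable[Mention]) -> dict[str, int]:
    """Integer percentages (half-up) of confirmed mentions per topic."""
    conf = confirmed_mentions(mentions)
    posts = {m.post_index: m.topic for m in conf}
    total = len(posts)
    counts: dict[str, int] = {}
    for topic in posts.values():
        counts[topic] = counts.get(topic, 0) + 1
    return {t: percent_half_up(c, total) for t, c in sorted(counts.items())}


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["post_index", "thread_id", "author", "variant", "status", "topic"]
        )
        for m in sorted(mentions, key=lambda m: (m.post_index, m.matched_variant)):
            writer.writerow(
                [m.post_index, m.thread_id, m.author_id, m.matched_variant,
                 m.status, m.topic]
            )


# -- local-corpus frequency (novelty check) --------------------------------


@dataclass
class CorpusFrequency:
    counts: dict[str, int]

    @property
    def novelty(self) -> bool:
        """True when no query string occurs anywhere in the corpus."""
        return all(c == 0 for c in self.counts.values())


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def corpus_frequency(
    corpus_paths: Iterable[str | Path],
    phrase_strings: Sequence[str],
) -> CorpusFrequency:
    """Exact, case-insensitive, whitespace-normalized occurrence counts of
    each query string across a set of local text files.

    This is the desk-scale stand-in for querying an external reference
    corpus or a web search engine for the phrase's prior existence.
    """
    queries = {s: _normalize(s) for s in phrase_strings}
    counts = {s: 0 for s in phrase_strings}
    for path in corpus_paths:
        try:
            with open(path, encoding="utf-8") as fh:
                text = _normalize(fh.read())
        except OSError as exc:
            raise OSError(f"cannot read corpus file {path}: {exc}") from exc
        for s, q in queries.items():
            if q:
                counts[s] += _count_overlapping_free(text, q)
    return CorpusFrequency(counts=counts)


def _count_overlapping_free(haystack: str, needle: str) -> int:
    # str.count is non-overlapping, which is the conventional phrase count
    return haystack.count(needle)
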