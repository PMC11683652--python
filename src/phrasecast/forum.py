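"""Domain model for a threaded forum archive.

The archive is a flat list of posts in global chronological order.  No
timestamps exist: the 1-based global ordinal (``post_index``) is the only
temporal information, and every downstream "before"/"after" judgement uses
it.  Threads are derived from the posts and numbered 1-based by their
earliest post; a thread's posts may interleave with other threads' posts in
global order (no contiguity assumption).
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


class ForumFormatError(ValueError):
    """A file could not be parsed into posts (e.g. a missing column)."""


class ForumValidationError(ValueError):
    """Posts violate a structural invariant (e.g. duplicate post_index)."""


@dataclass(frozen=True, slots=True)
class Post:
    """One forum post.

    ``post_index`` is the 1-based position of the post in the global
    chronological order of the whole archive.
    """

    post_index: int
    thread_id: str
    author_id: str
    text: str

    def __post_init__(self) -> None:
        if self.post_index < 1:
            raise ForumValidationError(
                f"post_index must be a positive integer, got {self.post_index}"
            )


@dataclass(frozen=True, slots=True)
class Thread:
    """A discussion thread: its identifier, 1-based rank by earliest post,
    and the strictly increasing global indices of its posts."""

    thread_id: str
    thread_number: int
    post_indices: tuple[int, ...]

    @property
    def first_post_index(self) -> int:
        return self.post_indices[0]

    @property
    def size(self) -> int:
        return len(self.post_indices)


class Forum:
    """An immutable, validated forum archive.

    Construct with :meth:`from_posts`; posts are sorted by ``post_index``,
    threads derived and numbered by earliest post.
    """

    def __init__(self, posts: list[Post], threads: dict[str, Thread]):
        self._posts = posts
        self._threads = threads
        self._by_index = {p.post_index: p for p in posts}
        self._user_threads: dict[str, dict[str, list[int]]] = {}
        for p in posts:
            self._user_threads.setdefault(p.author_id, {}).setdefault(
                p.thread_id, []
            ).append(p.post_index)

    @classmethod
    def from_posts(cls, posts: Iterable[Post]) -> "Forum":
        ordered = sorted(posts, key=lambda p: p.post_index)
        dupes = _duplicates(p.post_index for p in ordered)
        if dupes:
            raise ForumValidationError(
                f"duplicate post_index values: {sorted(dupes)}"
            )
        return cls(ordered, _derive_threads(ordered))

    # -- accessors ---------------------------------------------------------

    @property
    def posts(self) -> list[Post]:
        return list(self._posts)

    @property
    def threads(self) -> dict[str, Thread]:
        return dict(self._threads)

    @property
    def users(self) -> frozenset[str]:
        return frozenset(self._user_threads)

    @property
    def n_posts(self) -> int:
        return len(self._posts)

    @property
    def n_threads(self) -> int:
        return len(self._threads)

    def __len__(self) -> int:
        return len(self._posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self._posts)

    def post(self, post_index: int) -> Post:
        try:
            return self._by_index[post_index]
        except KeyError:
            raise LookupError(f"no post with index {post_index}") from None

    def thread(self, thread_id: str) -> Thread:
        try:
            return self._threads[thread_id]
        except KeyError:
            raise LookupError(f"no thread with id {thread_id!r}") from None

    def posts_in_thread(self, thread_id: str) -> list[Post]:
        return [self._by_index[i] for i in self.thread(thread_id).post_indices]

    def user_post_counts(self) -> dict[str, int]:
        return {
            u: sum(len(v) for v in tmap.values())
            for u, tmap in self._user_threads.items()
        }

    def user_thread_indices(self, user_id: str) -> dict[str, list[int]]:
        """Map thread_id -> sorted global indices of the user's posts in it."""
        try:
            tmap = self._user_threads[user_id]
        except KeyError:
            raise LookupError(f"unknown user {user_id!r}") from None
        return {t: sorted(v) for t, v in tmap.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Forum):
            return NotImplemented
        return self._posts == other._posts


def _duplicates(values: Iterable[int]) -> set[int]:
    counts = Counter(values)
    return {v for v, c in counts.items() if c > 1}


def _derive_threads(ordered_posts: list[Post]) -> dict[str, Thread]:
    grouped: dict[str, list[int]] = {}
    for p in ordered_posts:
        grouped.setdefault(p.thread_id, []).append(p.post_index)
    ranked = sorted(grouped, key=lambda t: grouped[t][0])
    return {
        tid: Thread(tid, number, tuple(grouped[tid]))
        for number, tid in enumerate(ranked, start=1)
    }


# -- I/O -------------------------------------------------------------------

_REQUIRED_COLUMNS = ("thread_id", "author", "text")
_AUTHOR_ALIASES = ("author", "author_id")
_INDEX_ALIASES = ("post_index", "post_id")


def read_forum(path: str | Path, dialect: str | None = None) -> Forum:
    """Read a forum archive from CSV or JSON-lines.

    Required columns/keys: ``thread_id``, ``author`` (or ``author_id``),
    ``text``.  ``post_id``/``post_index`` is optional; when absent, row order
    is taken as chronological order and indices are assigned 1..n.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if dialect not in {"csv", "jsonl"}:
        raise ValueError(f"unknown dialect {dialect!r}; expected csv or jsonl")
    if dialect == "csv":
        rows = _read_csv_rows(path)
    else:
        rows = _read_jsonl_rows(path)
    return Forum.from_posts(_rows_to_posts(rows))


def _read_csv_rows(path: Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        _check_columns(set(reader.fieldnames))
        return list(reader)


def _read_jsonl_rows(path: Path) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rows.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise ForumFormatError(
                    f"{path}: line {lineno} is not valid JSON: {exc}"
                ) from exc
    if rows:
        _check_columns(set(rows[0]))
    return rows


def _check_columns(present: set[str]) -> None:
    for col in _REQUIRED_COLUMNS:
        aliases = _AUTHOR_ALIASES if col == "author" else (col,)
        if not any(a in present for a in aliases):
            raise ForumFormatError(f"missing required column: {col!r}")


def _rows_to_posts(rows: list[Mapping[str, object]]) -> list[Post]:
    posts = []
    for order, row in enumerate(rows, start=1):
        index = order
        for alias in _INDEX_ALIASES:
            if alias in row and row[alias] not in (None, ""):
                try:
                    index = int(row[alias])  # type: ignore[arg-type]
                except (TypeError, ValueError):
                    raise ForumFormatError(
                        f"non-integer {alias} value {row[alias]!r}"
                    ) from None
                break
        author = None
        for alias in _AUTHOR_ALIASES:
            if alias in row:
                author = str(row[alias])
                break
        posts.append(
            Post(
                post_index=index,
                thread_id=str(row["thread_id"]),
                author_id=str(author),
                text=str(row.get("text", "")),
            )
        )
    return posts


def write_forum(forum: Forum, path: str | Path) -> None:
    """Write the canonical CSV form: explicit post_index column, posts in
    chronological order, LF line endings (byte-stable for a given forum)."""
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["post_index", "thread_id", "author", "text"])
        for p in forum:
            writer.writerow([p.post_index, p.thread_id, p.author_id, p.text])


# -- queries and validation -----------------------------------------------


def thread_participants(forum: Forum, thread_id: str) -> frozenset[str]:
    """Authors with at least one post in the thread.

    Each user counts once no matter how many posts they wrote in it; thread
    membership is the unit of all downstream exposure reasoning.
    """
    return frozenset(p.author_id for p in forum.posts_in_thread(thread_id))


@dataclass
class ValidationReport:
    """Structural health report; never raises, never mutates."""

    n_posts: int
    n_threads: int
    n_users: int
    duplicate_post_indices: list[int] = field(default_factory=list)
    empty_text_post_indices: list[int] = field(default_factory=list)
    single_author_thread_fraction: float = 0.0
    user_post_counts: dict[str, int] = field(default_factory=dict)
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_posts(posts: Iterable[Post]) -> ValidationReport:
    """Validate a raw post list (duplicates are reported, not raised)."""
    plist = sorted(posts, key=lambda p: p.post_index)
    dupes = sorted(_duplicates(p.post_index for p in plist))
    empty = [p.post_index for p in plist if not p.text.strip()]
    threads: dict[str, set[str]] = {}
    counts: Counter[str] = Counter()
    for p in plist:
        threads.setdefault(p.thread_id, set()).add(p.author_id)
        counts[p.author_id] += 1
    single = sum(1 for authors in threads.values() if len(authors) == 1)
    issues = []
    for d in dupes:
        issues.append(f"duplicate post_index {d}")
    if empty:
        issues.append(f"{len(empty)} post(s) with empty text")
    return ValidationReport(
        n_posts=len(plist),
        n_threads=len(threads),
        n_users=len(counts),
        duplicate_post_indices=dupes,
        empty_text_post_indices=empty,
        single_author_thread_fraction=(single / len(threads)) if threads else 0.0,
        user_post_counts=dict(sorted(counts.items())),
        issues=issues,
    )


def validate_forum(forum: Forum) -> ValidationReport:
    return validate_posts(forum.posts)
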