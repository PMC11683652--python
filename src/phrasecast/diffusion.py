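"""Adoption timelines, exposure-route classification, and diffusion trees.

Given the archive and the confirmed phrase mentions, this module answers:
who picked the phrase up, in what order, from whom, and through which
channel.  Everything is deterministic given the archive — there is no
probabilistic cascade inference — and all "before" relations are judged by
the global post ordinal.

Route taxonomy for a non-root adopter ``u`` with first phrase use at global
index ``p``:

* ``direct_metaphor_thread`` — some thread contains an earlier adopter's
  phrase post with index < ``p`` and ``u`` posted in that thread.  The
  phrase was visibly on the page ``u`` participated in.
* ``unrelated_co_thread`` — no such thread, but ``u`` and some earlier
  adopter both posted (both posts before ``p``) in a shared thread that
  carried no qualifying phrase post: a social tie existed, the phrase
  itself travelled out of band.
* ``lurking_presumed`` — ``u`` shares no thread with any earlier adopter
  before first use; reading without posting is the only remaining channel.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .forum import Forum, thread_participants
from .phrases import CONFIRMED, Mention, confirmed_mentions

ROUTE_DIRECT = "direct_metaphor_thread"
ROUTE_UNRELATED = "unrelated_co_thread"
ROUTE_LURKING = "lurking_presumed"
ROUTES = (ROUTE_DIRECT, ROUTE_UNRELATED, ROUTE_LURKING)

KIND_SPREADING = "spreading_instance"
KIND_ADOPTION = "adoption"

MECH_SOCIAL = "social"
MECH_SELF_PROMOTION = "self_promotion_exposure"
MECH_LURKING = "lurking_presumed"

TIE_EARLIEST = "earliest"
TIE_LATEST = "latest"

FLAG_METAPHOR_BY_USER = "metaphor_by_user"
FLAG_METAPHOR_BY_OTHER = "metaphor_by_other"
FLAG_NO_METAPHOR = "no_metaphor"


class DiffusionConsistencyError(ValueError):
    """Inputs disagree with each other (e.g. an adopter missing from the forum)."""


@dataclass(frozen=True)
class AdoptionEvent:
    """A user's entry into the adopter set: their first phrase post and the
    ordered distinct threads in which they ever used the phrase."""

    user_id: str
    first_use_post_index: int
    first_use_thread: str
    metaphor_thread_ids: tuple[str, ...]


@dataclass(frozen=True)
class ExposureRecord:
    adopter: str
    route: str
    source: Optional[str]
    evidence_threads: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiffusionEdge:
    source: str
    recipient: str
    kind: str  # spreading_instance | adoption
    mechanism: str  # social | self_promotion_exposure | lurking_presumed
    thread_id: Optional[str] = None


@dataclass
class DiffusionTree:
    """Rooted diffusion structure over adopters and recipients.

    ``depth`` is the length in edges of the longest root-to-leaf path over
    adoption and spreading edges together; breadth (number of distinct
    recipients) is reported separately.
    """

    root: str
    adopters: frozenset[str]
    recipients: frozenset[str]
    edges: list[DiffusionEdge]
    depth: int

    @property
    def nodes(self) -> frozenset[str]:
        return self.adopters | self.recipients

    @property
    def adoption_edges(self) -> list[DiffusionEdge]:
        return [e for e in self.edges if e.kind == KIND_ADOPTION]

    @property
    def spreading_edges(self) -> list[DiffusionEdge]:
        return [e for e in self.edges if e.kind == KIND_SPREADING]


# -- timelines and adoption events ----------------------------------------


@dataclass(frozen=True)
class TimelineEntry:
    thread_id: str
    thread_number: int
    first_post_index: int
    flag: str


def participation_timeline(
    forum: Forum, user_id: str, mentions: Iterable[Mention]
) -> list[TimelineEntry]:
    """Threads the user took part in, ordered by their earliest post in
    each, flagged by whether the phrase appears there (and by whom).

    Each thread appears exactly once no matter how many posts the user
    contributed to it.
    """
    by_thread = forum.user_thread_indices(user_id)  # raises on unknown user
    mine: set[str] = set()
    others: set[str] = set()
    for m in confirmed_mentions(mentions):
        if m.author_id == user_id:
            mine.add(m.thread_id)
        else:
            others.add(m.thread_id)
    entries = []
    for tid, indices in by_thread.items():
        if tid in mine:
            flag = FLAG_METAPHOR_BY_USER
        elif tid in others:
            flag = FLAG_METAPHOR_BY_OTHER
        else:
            flag = FLAG_NO_METAPHOR
        entries.append(
            TimelineEntry(
                thread_id=tid,
                thread_number=forum.thread(tid).thread_number,
                first_post_index=indices[0],
                flag=flag,
            )
        )
    return sorted(entries, key=lambda e: e.first_post_index)


def detect_adoptions(mentions: Iterable[Mention]) -> list[AdoptionEvent]:
    """One adoption event per distinct confirmed-mention author, ordered by
    first use; the earliest event is the root adopter."""
    conf = sorted(confirmed_mentions(mentions), key=lambda m: m.post_index)
    by_user: dict[str, list[Mention]] = defaultdict(list)
    for m in conf:
        by_user[m.author_id].append(m)
    events = []
    for user, ms in by_user.items():
        threads: list[str] = []
        for m in ms:
            if m.thread_id not in threads:
                threads.append(m.thread_id)
        events.append(
            AdoptionEvent(
                user_id=user,
                first_use_post_index=ms[0].post_index,
                first_use_thread=ms[0].thread_id,
                metaphor_thread_ids=tuple(threads),
            )
        )
    return sorted(events, key=lambda e: e.first_use_post_index)


def self_promotion_count(event: AdoptionEvent) -> int:
    """Distinct threads in which the user posted the phrase — each thread
    counts once regardless of how many phrase posts it holds."""
    return len(set(event.metaphor_thread_ids))


# -- exposure classification ----------------------------------------------


def classify_exposure(
    forum: Forum,
    mentions: Iterable[Mention],
    adoptions: Sequence[AdoptionEvent],
    tie_break: str = TIE_EARLIEST,
) -> list[ExposureRecord]:
    """Classify how each non-root adopter plausibly met the phrase.

    Direct route: the source is the earlier adopter whose qualifying phrase
    post has the smallest global index (first exposure is the most
    parsimonious causal candidate); ``tie_break="latest"`` selects the last
    qualifying phrase post before first use instead, for sensitivity
    analysis.  Unrelated co-thread route: the source is the earlier adopter
    whose shared-thread co-presence was established earliest (the later of
    the two users' first posts in the shared thread, minimized).
    """
    if tie_break not in {TIE_EARLIEST, TIE_LATEST}:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    if not adoptions:
        return []
    conf = sorted(confirmed_mentions(mentions), key=lambda m: m.post_index)
    mention_posts = [(m.post_index, m.author_id, m.thread_id) for m in conf]
    order = sorted(adoptions, key=lambda a: a.first_use_post_index)
    records = []
    for a in order[1:]:
        u, p = a.user_id, a.first_use_post_index
        if u not in forum.users:
            raise DiffusionConsistencyError(
                f"adopter {u!r} has no posts in the forum"
            )
        u_threads = forum.user_thread_indices(u)

        # (1) direct: earlier adopter's phrase post in a thread u posted in
        direct = [
            (idx, author, tid)
            for idx, author, tid in mention_posts
            if idx < p and author != u and tid in u_threads
        ]
        if direct:
            pick = min(direct) if tie_break == TIE_EARLIEST else max(direct)
            records.append(
                ExposureRecord(
                    adopter=u,
                    route=ROUTE_DIRECT,
                    source=pick[1],
                    evidence_threads=(pick[2],),
                )
            )
            continue

        # (2) unrelated co-thread with an earlier adopter, both posts before p
        co: list[tuple[int, int, str, str]] = []
        for b in order:
            if b.first_use_post_index >= p or b.user_id == u:
                continue
            v_threads = forum.user_thread_indices(b.user_id)
            for tid, u_idx in u_threads.items():
                if tid not in v_threads:
                    continue
                u_first = next((i for i in u_idx if i < p), None)
                v_first = next((i for i in v_threads[tid] if i < p), None)
                if u_first is None or v_first is None:
                    continue
                co.append(
                    (max(u_first, v_first), b.first_use_post_index, b.user_id, tid)
                )
        if co:
            pick2 = min(co) if tie_break == TIE_EARLIEST else max(co)
            records.append(
                ExposureRecord(
                    adopter=u,
                    route=ROUTE_UNRELATED,
                    source=pick2[2],
                    evidence_threads=(pick2[3],),
                )
            )
            continue

        # (3) no observable contact at all
        records.append(
            ExposureRecord(adopter=u, route=ROUTE_LURKING, source=None)
        )
    return records


# -- tree construction -----------------------------------------------------


def build_diffusion_tree(
    forum: Forum,
    mentions: Iterable[Mention],
    exposures: Sequence[ExposureRecord],
    adoptions: Optional[Sequence[AdoptionEvent]] = None,
) -> DiffusionTree:
    """Assemble the rooted diffusion structure.

    Nodes are the adopters plus every distinct non-adopter co-participant
    of a phrase-bearing thread (recipients of a spreading instance).  One
    spreading edge per (phrase poster, recipient) pair, attributed to the
    earliest exposing thread; one adoption edge per non-root adopter, with
    presumed lurkers attached to the root.  A phrase post in the author's
    first phrase thread counts as social exposure; repeat posting of one's
    own phrase in further threads is self-promotion.
    """
    mentions = list(mentions)
    if adoptions is None:
        adoptions = detect_adoptions(mentions)
    if not adoptions:
        raise DiffusionConsistencyError("cannot build a tree without adopters")
    order = sorted(adoptions, key=lambda a: a.first_use_post_index)
    root = order[0].user_id
    adopters = frozenset(a.user_id for a in order)
    first_thread = {a.user_id: a.first_use_thread for a in order}

    conf = sorted(confirmed_mentions(mentions), key=lambda m: m.post_index)
    recipients: set[str] = set()
    spreading: dict[tuple[str, str], DiffusionEdge] = {}
    for m in conf:
        for r in sorted(thread_participants(forum, m.thread_id) - adopters):
            key = (m.author_id, r)
            if key in spreading:
                continue
            mech = (
                MECH_SOCIAL
                if m.thread_id == first_thread[m.author_id]
                else MECH_SELF_PROMOTION
            )
            spreading[key] = DiffusionEdge(
                source=m.author_id,
                recipient=r,
                kind=KIND_SPREADING,
                mechanism=mech,
                thread_id=m.thread_id,
            )
            recipients.add(r)

    first_use = {a.user_id: a.first_use_post_index for a in order}
    mention_by_author_thread: dict[tuple[str, str], int] = {}
    for m in conf:
        key = (m.author_id, m.thread_id)
        mention_by_author_thread.setdefault(key, m.post_index)

    adoption_edges = []
    for rec in exposures:
        if rec.adopter not in adopters:
            raise DiffusionConsistencyError(
                f"exposure record for non-adopter {rec.adopter!r}"
            )
        if rec.route == ROUTE_LURKING:
            adoption_edges.append(
                DiffusionEdge(
                    source=root,
                    recipient=rec.adopter,
                    kind=KIND_ADOPTION,
                    mechanism=MECH_LURKING,
                )
            )
            continue
        assert rec.source is not None
        tid = rec.evidence_threads[0] if rec.evidence_threads else None
        if rec.route == ROUTE_DIRECT:
            mech = (
                MECH_SOCIAL
                if tid == first_thread.get(rec.source)
                else MECH_SELF_PROMOTION
            )
        else:
            mech = MECH_SOCIAL
        adoption_edges.append(
            DiffusionEdge(
                source=rec.source,
                recipient=rec.adopter,
                kind=KIND_ADOPTION,
                mechanism=mech,
                thread_id=tid,
            )
        )

    # temporal sanity: an adoption source must have used the phrase before
    # its recipient's first use; the index ordering makes cycles impossible.
    for e in adoption_edges:
        if e.mechanism == MECH_LURKING:
            continue
        if first_use[e.source] >= first_use[e.recipient]:
            raise DiffusionConsistencyError(
                f"adoption edge {e.source}->{e.recipient} violates first-use order"
            )

    edges = adoption_edges + [
        spreading[k] for k in sorted(spreading)
    ]
    depth = _longest_path_from(root, edges)
    return DiffusionTree(
        root=root,
        adopters=adopters,
        recipients=frozenset(recipients),
        edges=edges,
        depth=depth,
    )


def _longest_path_from(root: str, edges: Iterable[DiffusionEdge]) -> int:
    """Longest path (in edges) from root over the edge list.

    Adoption edges always point forward in first-use time and spreading
    edges end at sinks, so the graph is a DAG; a memoized DFS suffices.
    """
    succ: dict[str, list[str]] = defaultdict(list)
    for e in edges:
        succ[e.source].append(e.recipient)
    memo: dict[str, int] = {}

    def dfs(node: str) -> int:
        if node in memo:
            return memo[node]
        memo[node] = 0  # placeholder guards against (impossible) cycles
        best = 0
        for nxt in succ.get(node, ()):
            best = max(best, 1 + dfs(nxt))
        memo[node] = best
        return best

    return dfs(root)


def adoption_depth(tree: DiffusionTree) -> int:
    """Longest root-to-leaf chain counting adoption edges only."""
    return _longest_path_from(tree.root, tree.adoption_edges)


# -- summaries and I/O -----------------------------------------------------


def mechanism_summary(
    tree: DiffusionTree,
    adoptions: Sequence[AdoptionEvent],
    exposures: Sequence[ExposureRecord],
    superusers: Optional[frozenset[str]] = None,
) -> dict[str, object]:
    """Aggregate view of the cascade: per-user self-promotion thread
    counts, adopters by route, depth/breadth, and superuser overlap."""
    route_counts = {r: 0 for r in ROUTES}
    for rec in exposures:
        route_counts[rec.route] += 1
    out: dict[str, object] = {
        "root": tree.root,
        "depth": tree.depth,
        "adoption_depth": adoption_depth(tree),
        "n_nodes": len(tree.nodes),
        "n_adopters": len(tree.adopters),
        "n_nonroot_adopters": len(tree.adopters) - 1,
        "n_recipients": len(tree.recipients),
        "routes": route_counts,
        "self_promotion_threads": {
            a.user_id: self_promotion_count(a) for a in adoptions
        },
    }
    if superusers is not None:
        nonroot = tree.adopters - {tree.root}
        out["n_superuser_nonroot_adopters"] = len(nonroot & superusers)
        out["n_superuser_adopters"] = len(tree.adopters & superusers)
    return out


def write_adoptions(events: Sequence[AdoptionEvent], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["user", "first_use_post_index", "first_use_thread",
                    "n_metaphor_threads", "metaphor_threads"])
        for e in events:
            w.writerow([e.user_id, e.first_use_post_index, e.first_use_thread,
                        self_promotion_count(e), ";".join(e.metaphor_thread_ids)])


def write_exposures(records: Sequence[ExposureRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["adopter", "route", "source", "evidence_threads"])
        for r in records:
            w.writerow([r.adopter, r.route, r.source or "",
                        ";".join(r.evidence_threads)])


def write_edges(tree: DiffusionTree, path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["source", "recipient", "kind", "mechanism", "thread_id"])
        for e in tree.edges:
            w.writerow([e.source, e.recipient, e.kind, e.mechanism,
                        e.thread_id or ""])
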