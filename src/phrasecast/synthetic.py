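"""Synthetic threaded forums with a planted phrase cascade.

The generator produces the statistical structure the inference relies on:
heavy-tailed per-user activity (a Zipf propensity over users), threads of
varying size, a single phrase originator, per-thread self-promotion by
adopters, exposure through posting in phrase-bearing threads (certain) or
through lurking (Bernoulli), and exposure-conditional adoption — all driven
by one seed, with the full event log kept as ground truth so the inference
can be scored against what was actually planted.

Generator conventions worth knowing:

* Threads are emitted contiguously in chronological order (real archives
  may interleave; nothing downstream assumes contiguity, the generator just
  does not need it).
* A user gets exactly one adoption trial, at the moment they first become
  exposed; the planted source is the author of the earliest phrase post in
  the exposing thread — the same parsimony convention the inference uses.
* An adopter starts including the phrase (with probability ``s`` per
  thread, in their first post there) only in threads after the one that
  exposed them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cohort import UserProfile
from .diffusion import (
    ROUTE_DIRECT,
    ROUTE_LURKING,
    ROUTE_UNRELATED,
    DiffusionTree,
    ExposureRecord,
    adoption_depth,
    _longest_path_from,
    DiffusionEdge,
    KIND_ADOPTION,
)
from .forum import Forum, Post

VIA_POSTING = "posting"
VIA_LURKING = "lurking"
VIA_ORIGINATION = "origination"
VIA_REINVENTION = "reinvention"

_FILLER = (
    "today", "morning", "walking", "garden", "coffee", "weather", "feeling",
    "better", "thanks", "update", "sleep", "slowly", "hoping", "week",
    "visit", "family", "doctor", "exercise", "reading", "music", "dinner",
    "sunshine", "progress", "question", "answer", "helpful", "kind",
)


class SyntheticConfigError(ValueError):
    """The requested configuration cannot produce a forum."""


class DiffusionTreeMismatch(ValueError):
    """Inference and ground truth describe different user universes."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_users: int = 200
    n_threads: int = 500
    mean_thread_size: float = 4.0
    activity_exponent: float = 1.0
    origin_thread: int = 2
    self_promotion_rate: float = 0.9
    adoption_prob: float = 0.3
    lurk_prob: float = 0.0
    reinvention_prob: float = 0.0  # robustness studies only; keep 0 normally
    phrase: str = "legacy of stroke"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise SyntheticConfigError("n_users must be >= 1")
        if self.n_threads < 1:
            raise SyntheticConfigError("n_threads must be >= 1")
        if not 1 <= self.origin_thread <= self.n_threads:
            raise SyntheticConfigError(
                "origin_thread must lie in [1, n_threads]"
            )
        if self.mean_thread_size < 1:
            raise SyntheticConfigError("mean_thread_size must be >= 1")
        for name in ("self_promotion_rate", "adoption_prob", "lurk_prob",
                     "reinvention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantedExposure:
    user: str
    thread_id: str
    via: str  # posting | lurking


@dataclass(frozen=True)
class PlantedAdoption:
    user: str
    source: Optional[str]  # None for the originator / a reinvention
    thread_id: Optional[str]
    via: str  # posting | lurking | origination | reinvention


@dataclass
class SyntheticGroundTruth:
    originator: str
    exposures: list[PlantedExposure] = field(default_factory=list)
    adoptions: list[PlantedAdoption] = field(default_factory=list)
    phrase_post_indices: list[int] = field(default_factory=list)

    @property
    def adopters(self) -> frozenset[str]:
        return frozenset(a.user for a in self.adoptions)

    @property
    def posting_exposure_threads(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for e in self.exposures:
            if e.via == VIA_POSTING:
                out.setdefault(e.user, set()).add(e.thread_id)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "originator": self.originator,
                "exposures": [asdict(e) for e in self.exposures],
                "adoptions": [asdict(a) for a in self.adoptions],
                "phrase_post_indices": self.phrase_post_indices,
            },
            indent=2,
            sort_keys=True,
        )


def generate_forum(
    config: SyntheticConfig,
) -> tuple[Forum, list[UserProfile], SyntheticGroundTruth]:
    """Generate a forum, matching profiles, and the planted ground truth.

    All randomness comes from ``numpy.random.default_rng(config.seed)``;
    the same config therefore yields byte-identical CSV exports.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    users = [f"u{i + 1:04d}" for i in range(n)]
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-config.activity_exponent)
    weights /= weights.sum()
    originator = users[0]  # the highest-propensity user seeds the phrase

    sizes = 1 + rng.poisson(max(config.mean_thread_size - 1.0, 0.0),
                            size=config.n_threads)

    truth = SyntheticGroundTruth(originator=originator)
    posts: list[Post] = []
    # user -> thread rank at which adoption happened (phrase use allowed
    # strictly after that thread)
    adopted_at: dict[str, int] = {}
    exposed: set[str] = set()
    seen_exposure: set[tuple[str, str]] = set()
    next_index = 1

    for rank in range(1, config.n_threads + 1):
        tid = f"t{rank:05d}"
        size = int(sizes[rank - 1])
        author_ids = list(rng.choice(n, size=size, p=weights))
        authors = [users[int(i)] for i in author_ids]
        if rank == config.origin_thread:
            authors[0] = originator

        phrase_flags = [False] * size
        if rank == config.origin_thread:
            phrase_flags[0] = True
            adopted_at[originator] = rank
            exposed.add(originator)
            truth.adoptions.append(
                PlantedAdoption(user=originator, source=None, thread_id=tid,
                                via=VIA_ORIGINATION)
            )
        else:
            tried: set[str] = set()
            for k, author in enumerate(authors):
                if author in tried:
                    continue
                tried.add(author)
                if author in adopted_at and adopted_at[author] < rank:
                    if rng.random() < config.self_promotion_rate:
                        phrase_flags[k] = True
            if not any(phrase_flags) and config.reinvention_prob > 0.0:
                first_author = authors[0]
                if first_author not in exposed and rng.random() < config.reinvention_prob:
                    phrase_flags[0] = True
                    adopted_at[first_author] = rank
                    exposed.add(first_author)
                    truth.adoptions.append(
                        PlantedAdoption(user=first_author, source=None,
                                        thread_id=tid, via=VIA_REINVENTION)
                    )

        # emit the posts
        for k, author in enumerate(authors):
            text = _post_text(rng, config.phrase if phrase_flags[k] else None)
            posts.append(
                Post(post_index=next_index, thread_id=tid, author_id=author,
                     text=text)
            )
            if phrase_flags[k]:
                truth.phrase_post_indices.append(next_index)
            next_index += 1

        if not any(phrase_flags):
            continue

        # exposure bookkeeping for a phrase-bearing thread
        first_phrase_author = authors[phrase_flags.index(True)]
        poster_order: list[str] = []
        for author in authors:
            if author not in poster_order:
                poster_order.append(author)
        for author in poster_order:
            if (author, tid) not in seen_exposure:
                seen_exposure.add((author, tid))
                truth.exposures.append(
                    PlantedExposure(user=author, thread_id=tid, via=VIA_POSTING)
                )
            if author not in exposed:
                exposed.add(author)
                if rng.random() < config.adoption_prob:
                    adopted_at[author] = rank
                    truth.adoptions.append(
                        PlantedAdoption(user=author, source=first_phrase_author,
                                        thread_id=tid, via=VIA_POSTING)
                    )
        if config.lurk_prob > 0.0:
            poster_set = set(poster_order)
            draws = rng.random(n)
            for i, user in enumerate(users):
                if user in poster_set or draws[i] >= config.lurk_prob:
                    continue
                if (user, tid) not in seen_exposure:
                    seen_exposure.add((user, tid))
                    truth.exposures.append(
                        PlantedExposure(user=user, thread_id=tid, via=VIA_LURKING)
                    )
                if user not in exposed:
                    exposed.add(user)
                    if rng.random() < config.adoption_prob:
                        adopted_at[user] = rank
                        truth.adoptions.append(
                            PlantedAdoption(user=user, source=first_phrase_author,
                                            thread_id=tid, via=VIA_LURKING)
                        )

    forum = Forum.from_posts(posts)
    profiles = _make_profiles(rng, forum, truth, config)
    return forum, profiles, truth


def _post_text(rng: np.random.Generator, phrase: Optional[str]) -> str:
    words = [_FILLER[int(i)] for i in rng.integers(0, len(_FILLER), size=6)]
    if phrase is not None:
        words.insert(3, phrase)
    return " ".join(words)


def _make_profiles(
    rng: np.random.Generator,
    forum: Forum,
    truth: SyntheticGroundTruth,
    config: SyntheticConfig,
) -> list[UserProfile]:
    counts = forum.user_post_counts()
    phrase_threads: dict[str, set[str]] = {}
    for idx in truth.phrase_post_indices:
        p = forum.post(idx)
        phrase_threads.setdefault(p.author_id, set()).add(p.thread_id)
    profiles = []
    for user in sorted(counts):
        age_at_stroke = int(rng.integers(30, 81))
        since = int(rng.integers(0, 13))
        profiles.append(
            UserProfile(
                user_id=user,
                age_when_posting=age_at_stroke + since,
                age_at_stroke=age_at_stroke,
                time_since_stroke=float(since),
                sex="F" if rng.random() < 0.5 else "M",
                identity="survivor" if rng.random() < 0.8 else "caregiver",
                times_metaphor_used=len(phrase_threads.get(user, ())),
                total_posts=counts[user],
                superuser=counts[user] > 100,
            )
        )
    return profiles


# -- recovery scoring ------------------------------------------------------


@dataclass
class RecoveryMetrics:
    """How well the inference recovered the planted cascade."""

    precision: float
    recall: float
    degenerate: bool
    route_confusion: dict[str, int]  # "planted_via->inferred_route" -> count
    n_direct_false_evidence: int
    inferred_adoption_depth: int
    true_adoption_depth: int

    @property
    def depth_difference(self) -> int:
        return self.inferred_adoption_depth - self.true_adoption_depth

    def to_dict(self) -> dict[str, object]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "degenerate": self.degenerate,
            "route_confusion": dict(sorted(self.route_confusion.items())),
            "n_direct_false_evidence": self.n_direct_false_evidence,
            "inferred_adoption_depth": self.inferred_adoption_depth,
            "true_adoption_depth": self.true_adoption_depth,
            "depth_difference": self.depth_difference,
        }


def manifest_adopters(truth: SyntheticGroundTruth, forum: Forum) -> frozenset[str]:
    """Planted adopters who actually posted the phrase at least once.

    Only these are observable: a user who adopted but never wrote the
    phrase leaves no trace in the archive and is outside the inference's
    contract.
    """
    return frozenset(
        forum.post(i).author_id for i in truth.phrase_post_indices
    )


def recovery_metrics(
    tree: DiffusionTree,
    exposures: Sequence[ExposureRecord],
    truth: SyntheticGroundTruth,
    forum: Forum,
) -> RecoveryMetrics:
    """Score inferred adoption edges and routes against the planted log.

    Precision/recall are over non-lurking adoption edges (source, adopter)
    restricted to manifest adopters.  A *direct false evidence* event is a
    direct-classified adopter whose evidence thread is not a planted
    posting exposure for them — i.e. the inference invented a reading
    opportunity that never happened.
    """
    observable = manifest_adopters(truth, forum)
    if tree.adopters != observable:
        raise DiffusionTreeMismatch(
            f"inferred adopters {sorted(tree.adopters)} != observable planted "
            f"adopters {sorted(observable)}"
        )

    planted_nonlurk = {
        (a.source, a.user)
        for a in truth.adoptions
        if a.via == VIA_POSTING and a.user in observable
    }
    inferred_nonlurk = {
        (r.source, r.adopter) for r in exposures if r.route != ROUTE_LURKING
    }
    hits = len(planted_nonlurk & inferred_nonlurk)
    degenerate = not planted_nonlurk and not inferred_nonlurk
    precision = 1.0 if not inferred_nonlurk else hits / len(inferred_nonlurk)
    recall = 1.0 if not planted_nonlurk else hits / len(planted_nonlurk)

    route_by_user = {r.adopter: r for r in exposures}
    confusion: dict[str, int] = {}
    for a in truth.adoptions:
        if a.user == truth.originator or a.user not in observable:
            continue
        rec = route_by_user.get(a.user)
        inferred_route = rec.route if rec is not None else "missing"
        key = f"{a.via}->{inferred_route}"
        confusion[key] = confusion.get(key, 0) + 1

    posting_threads = truth.posting_exposure_threads
    n_false = 0
    for r in exposures:
        if r.route != ROUTE_DIRECT:
            continue
        if not set(r.evidence_threads) <= posting_threads.get(r.adopter, set()):
            n_false += 1

    true_edges = [
        DiffusionEdge(source=a.source, recipient=a.user, kind=KIND_ADOPTION,
                      mechanism="planted")
        for a in truth.adoptions
        if a.source is not None and a.user in observable
    ]
    true_depth = _longest_path_from(truth.originator, true_edges)
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        degenerate=degenerate,
        route_confusion=confusion,
        n_direct_false_evidence=n_false,
        inferred_adoption_depth=adoption_depth(tree),
        true_adoption_depth=true_depth,
    )
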