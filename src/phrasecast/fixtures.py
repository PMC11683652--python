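"""Packaged fixtures: the participant table and a narrative mini-forum.

The mini-forum is constructed programmatically to be consistent with the
participant table and the documented cascade shape: the phrase first
appears in thread number 2, the root adopter promotes it in 51 distinct
threads, three later adopters were co-present in those threads, two met the
root (or an earlier adopter) only in unrelated threads, and two never
shared a thread with anyone — so the full pipeline run on it exercises
every exposure route.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .cohort import UserProfile, read_profiles, write_profiles
from .forum import Forum, Post, write_forum
from .phrases import (
    TOPIC_FATIGUE,
    TOPIC_OTHER,
    Annotation,
    PhrasePattern,
)

_DATA = resources.files("phrasecast") / "data"

N_ROOT_PROMOTION_THREADS = 51
N_FATIGUE_MENTIONS = 34


def table1_profiles() -> list[UserProfile]:
    """The packaged 8-row participant table."""
    with resources.as_file(_DATA / "participants_table.csv") as path:
        return read_profiles(path)


def default_pattern() -> PhrasePattern:
    """The shipped phrase pattern: head-word inflections, the two named
    synonym variants, and same-post context confirmation."""
    with resources.as_file(_DATA / "pattern_default.yaml") as path:
        return PhrasePattern.from_file(path)


@dataclass
class NarrativeFixture:
    forum: Forum
    profiles: list[UserProfile]
    pattern: PhrasePattern
    annotations: list[Annotation]


class _Builder:
    def __init__(self) -> None:
        self.posts: list[Post] = []
        self.metaphor_indices: list[int] = []

    def add(self, thread: str, author: str, text: str, metaphor: bool = False) -> int:
        idx = len(self.posts) + 1
        self.posts.append(Post(idx, thread, author, text))
        if metaphor:
            self.metaphor_indices.append(idx)
        return idx


_OPENER_TEXT = "my relative had a stroke recently and we could use some advice"
_FILLER_REPLY = "thinking of you and hoping things improve soon"
_METAPHOR_FATIGUE = "the tiredness you describe is a legacy of stroke and it can last"
_METAPHOR_OTHER = "these changes can be a legacy of stroke as my consultant told me"


def narrative_forum() -> NarrativeFixture:
    """Deterministically build the mini-forum described above.

    Adopters and their phrase-thread counts match the participant table
    (51, 2, 1, 1, 1, 3, 1, 1 across users A-H); openers q01..q60 appear
    only as recipients, with q01 reused across three of A's threads so the
    tree has 68 nodes (8 adopters + 60 recipients) and depth 3 via the
    A -> B -> H -> recipient path.
    """
    b = _Builder()

    # thread 1: unrelated exchange between the first opener and A
    b.add("t0001", "q01", _OPENER_TEXT)
    b.add("t0001", "A", _FILLER_REPLY)

    # thread 2: first phrase use ever, A replying to a plea about tiredness
    b.add("t0002", "q01", "my husband tires so easily since his stroke please help")
    b.add("t0002", "A", "fatigue is a stroke legacy and he may tire easily in future",
          metaphor=True)

    # A's remaining 50 promotion threads (t0003..t0052); B, C and F are
    # co-present in three of them before their own first use
    co_present = {"t0005": "B", "t0010": "C", "t0015": "F"}
    for i in range(3, 53):
        tid = f"t{i:04d}"
        opener = "q01" if i == 52 else f"q{i - 1:02d}"
        b.add(tid, opener, _OPENER_TEXT)
        if tid in co_present:
            b.add(tid, co_present[tid], _FILLER_REPLY)
        b.add(tid, "A", _METAPHOR_FATIGUE, metaphor=True)

    # unrelated co-thread of A and D (no phrase anywhere in it)
    b.add("t0053", "A", "nice weather for a slow walk in the park today")
    b.add("t0053", "D", "yes we managed a short walk as well")

    # subsequent adopters' own phrase threads
    def adopter_thread(tid: str, opener: str, author: str) -> None:
        b.add(tid, opener, _OPENER_TEXT)
        b.add(tid, author, _METAPHOR_OTHER, metaphor=True)

    adopter_thread("t0054", "q51", "B")
    adopter_thread("t0055", "q52", "B")
    adopter_thread("t0056", "q53", "C")
    adopter_thread("t0057", "q54", "F")
    adopter_thread("t0058", "q55", "F")
    adopter_thread("t0059", "q56", "F")
    adopter_thread("t0060", "q57", "D")

    # unrelated co-thread of B and H, then H's first use
    b.add("t0061", "B", "has anyone tried the new community exercise class")
    b.add("t0061", "H", "we go every week and find it helpful")
    adopter_thread("t0062", "q58", "H")

    # isolated adopters: E and G never share a thread with anyone else
    adopter_thread("t0063", "q59", "E")
    adopter_thread("t0064", "q60", "G")

    forum = Forum.from_posts(b.posts)
    annotations = [
        Annotation(
            post_index=idx,
            decision="confirm",
            topic=TOPIC_FATIGUE if k < N_FATIGUE_MENTIONS else TOPIC_OTHER,
        )
        for k, idx in enumerate(b.metaphor_indices)
    ]
    return NarrativeFixture(
        forum=forum,
        profiles=table1_profiles(),
        pattern=default_pattern(),
        annotations=annotations,
    )


def write_fixture_files(out_dir: str | Path) -> dict[str, Path]:
    """Materialize the narrative fixture as plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = narrative_forum()
    paths = {
        "posts": out / "posts.csv",
        "profiles": out / "profiles.csv",
        "pattern": out / "pattern.yaml",
        "annotations": out / "annotations.csv",
    }
    write_forum(fx.forum, paths["posts"])
    write_profiles(fx.profiles, paths["profiles"])
    import yaml

    with open(paths["pattern"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(fx.pattern.to_mapping(), fh, sort_keys=False)
    with open(paths["annotations"], "w", newline="\n", encoding="utf-8") as fh:
        fh.write("post_index,decision,topic\n")
        for a in fx.annotations:
            fh.write(f"{a.post_index},{a.decision},{a.topic}\n")
    return paths
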