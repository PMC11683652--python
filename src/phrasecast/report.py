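"""Pipeline orchestration and artifact writing.

``run_pipeline`` chains the stages (read archive -> mentions -> cohort ->
diffusion -> summaries) and writes every artifact as deterministic plain
text: identical inputs and config produce byte-identical outputs.  The
Markdown report is a pure view — every number in it is re-derivable from
the CSV/JSON artifacts next to it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from . import cohort as cohort_mod
from . import diffusion as diff_mod
from . import phrases as phrase_mod
from .cohort import SuperuserRule, UserProfile, summarize_cohort
from .diffusion import (
    AdoptionEvent,
    DiffusionTree,
    ExposureRecord,
    TIE_EARLIEST,
)
from .fixtures import default_pattern
from .forum import Forum, read_forum
from .phrases import Annotation, Mention, PhrasePattern

logger = logging.getLogger("phrasecast")


@dataclass
class RunConfig:
    posts: Path
    profiles: Optional[Path] = None
    pattern: Optional[Path] = None
    annotations: Optional[Path] = None
    superuser_rule: SuperuserRule = field(default_factory=SuperuserRule)
    tie_break: str = TIE_EARLIEST
    out_dir: Path = Path("phrasecast_out")
    dialect: Optional[str] = None


@dataclass
class PipelineResult:
    forum: Forum
    mentions: list[Mention]
    adoptions: list[AdoptionEvent]
    exposures: list[ExposureRecord]
    tree: Optional[DiffusionTree]
    summary: dict[str, object]
    artifacts: dict[str, Path]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def compute_mentions(
    forum: Forum,
    pattern: PhrasePattern,
    annotations: Sequence[Annotation] = (),
) -> list[Mention]:
    """find -> context rule -> manual annotations, in one call."""
    cands = phrase_mod.find_candidates(forum, pattern)
    ruled = phrase_mod.apply_context_rule(forum, cands, pattern)
    return phrase_mod.merge_annotations(ruled, annotations)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    forum = _stage("read")(read_forum)(config.posts, config.dialect)
    logger.info("read %d posts in %d threads from %s",
                forum.n_posts, forum.n_threads, config.posts)

    pattern = (
        PhrasePattern.from_file(config.pattern)
        if config.pattern
        else default_pattern()
    )
    annotations = (
        phrase_mod.read_annotations(config.annotations)
        if config.annotations
        else []
    )
    mentions = _stage("mentions")(compute_mentions)(forum, pattern, annotations)
    confirmed = phrase_mod.confirmed_mentions(mentions)
    logger.info("%d candidate mentions, %d confirmed", len(mentions),
                len(confirmed))
    artifacts["mentions"] = out / "mentions.csv"
    phrase_mod.write_mentions(mentions, artifacts["mentions"])

    profiles: list[UserProfile] = []
    cohort_summary = None
    if config.profiles:
        profiles = _stage("cohort")(cohort_mod.read_profiles)(config.profiles)
        cohort_summary = summarize_cohort(profiles)
        artifacts["cohort_summary"] = out / "cohort_summary.json"
        _write_json(artifacts["cohort_summary"], cohort_summary.to_dict())
        logger.info("cohort: %d profiles", len(profiles))

    post_counts = (
        {p.user_id: p.total_posts for p in profiles}
        if profiles
        else forum.user_post_counts()
    )
    superusers = cohort_mod.classify_superusers(post_counts, config.superuser_rule)

    adoptions = _stage("diffusion")(diff_mod.detect_adoptions)(mentions)
    tree = None
    exposures: list[ExposureRecord] = []
    summary: dict[str, object] = {
        "n_posts": forum.n_posts,
        "n_threads": forum.n_threads,
        "n_users": len(forum.users),
        "n_confirmed_mentions": len(confirmed),
        "topic_percentages": phrase_mod.topic_percentages(mentions),
        "n_adopters": len(adoptions),
        "superuser_rule": f"{config.superuser_rule.mode}",
        "n_superusers": len(superusers),
    }
    if adoptions:
        exposures = _stage("diffusion")(diff_mod.classify_exposure)(
            forum, mentions, adoptions, config.tie_break
        )
        tree = _stage("diffusion")(diff_mod.build_diffusion_tree)(
            forum, mentions, exposures, adoptions
        )
        summary["diffusion"] = diff_mod.mechanism_summary(
            tree, adoptions, exposures, superusers
        )
        artifacts["adoptions"] = out / "adoptions.csv"
        diff_mod.write_adoptions(adoptions, artifacts["adoptions"])
        artifacts["exposures"] = out / "exposures.csv"
        diff_mod.write_exposures(exposures, artifacts["exposures"])
        artifacts["edges"] = out / "edges.csv"
        diff_mod.write_edges(tree, artifacts["edges"])
        artifacts["tree_dot"] = out / "tree.dot"
        export_graph(tree, "dot", artifacts["tree_dot"], superusers)
        artifacts["tree_graphml"] = out / "tree.graphml"
        export_graph(tree, "graphml", artifacts["tree_graphml"], superusers)
        logger.info("diffusion: %d adopters, depth %d, %d nodes",
                    len(adoptions), tree.depth, len(tree.nodes))
    else:
        logger.warning("no confirmed mentions: skipping diffusion stages")

    artifacts["summary"] = out / "summary.json"
    _write_json(artifacts["summary"], summary)
    artifacts["report"] = out / "report.md"
    _write_report(artifacts["report"], summary, cohort_summary)
    return PipelineResult(
        forum=forum,
        mentions=mentions,
        adoptions=adoptions,
        exposures=exposures,
        tree=tree,
        summary=summary,
        artifacts=artifacts,
    )


def _write_json(path: Path, data: dict) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_report(path: Path, summary: dict, cohort_summary) -> None:
    lines = ["# Phrase diffusion report", ""]
    lines.append(f"- posts: {summary['n_posts']}")
    lines.append(f"- threads: {summary['n_threads']}")
    lines.append(f"- users: {summary['n_users']}")
    lines.append(f"- confirmed mentions: {summary['n_confirmed_mentions']}")
    topics = summary.get("topic_percentages") or {}
    if topics:
        topic_str = ", ".join(f"{k} {v}%" for k, v in sorted(topics.items()))
        lines.append(f"- topic split: {topic_str}")
    diff = summary.get("diffusion")
    if diff:
        lines += [
            "",
            "## Diffusion",
            "",
            f"- root adopter: {diff['root']}",
            f"- adopters: {diff['n_adopters']} ({diff['n_nonroot_adopters']} after the root)",
            f"- tree: {diff['n_nodes']} nodes, depth {diff['depth']} "
            f"(adoption-only depth {diff['adoption_depth']})",
            f"- recipients (breadth): {diff['n_recipients']}",
            f"- routes: {json.dumps(diff['routes'], sort_keys=True)}",
        ]
        promo = diff["self_promotion_threads"]
        lines.append("- phrase threads per adopter: "
                     + ", ".join(f"{u}={c}" for u, c in sorted(promo.items())))
        if "n_superuser_nonroot_adopters" in diff:
            lines.append(
                f"- non-root adopters who are superusers: "
                f"{diff['n_superuser_nonroot_adopters']}"
            )
    if cohort_summary is not None:
        lines += ["", "## Cohort", "", cohort_summary.to_markdown()]
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# -- graph export ----------------------------------------------------------


def tree_to_networkx(
    tree: DiffusionTree, superusers: Optional[frozenset[str]] = None
) -> "nx.DiGraph":
    g = nx.DiGraph()
    superusers = superusers or frozenset()
    for node in sorted(tree.nodes):
        g.add_node(
            node,
            role="adopter" if node in tree.adopters else "recipient",
            superuser=node in superusers,
            root=node == tree.root,
        )
    for e in tree.edges:
        g.add_edge(
            e.source,
            e.recipient,
            kind=e.kind,
            mechanism=e.mechanism,
            thread_id=e.thread_id or "",
        )
    return g


def export_graph(
    tree: DiffusionTree,
    fmt: str,
    path: str | Path,
    superusers: Optional[frozenset[str]] = None,
) -> None:
    """Write the tree as DOT or GraphML (node role/superuser attributes,
    edge kind/mechanism attributes)."""
    if fmt == "graphml":
        nx.write_graphml(tree_to_networkx(tree, superusers), path)
        return
    if fmt != "dot":
        raise ValueError(f"unsupported graph format {fmt!r}")
    superusers = superusers or frozenset()
    lines = ["digraph diffusion {"]
    for node in sorted(tree.nodes):
        role = "adopter" if node in tree.adopters else "recipient"
        shape = "doublecircle" if node == tree.root else (
            "circle" if role == "adopter" else "point")
        su = "true" if node in superusers else "false"
        lines.append(
            f'  "{node}" [role="{role}" superuser="{su}" shape="{shape}"];'
        )
    for e in tree.edges:
        style = "solid" if e.kind == "adoption" else "dashed"
        lines.append(
            f'  "{e.source}" -> "{e.recipient}" '
            f'[kind="{e.kind}" mechanism="{e.mechanism}" style="{style}"];'
        )
    lines.append("}")
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
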