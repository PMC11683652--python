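import networkx as nx
import pytest

from phrasecast.diffusion import (
    FLAG_METAPHOR_BY_OTHER,
    FLAG_METAPHOR_BY_USER,
    FLAG_NO_METAPHOR,
    KIND_ADOPTION,
    KIND_SPREADING,
    MECH_LURKING,
    MECH_SELF_PROMOTION,
    MECH_SOCIAL,
    ROUTE_DIRECT,
    ROUTE_LURKING,
    ROUTE_UNRELATED,
    DiffusionConsistencyError,
    build_diffusion_tree,
    classify_exposure,
    detect_adoptions,
    mechanism_summary,
    participation_timeline,
    self_promotion_count,
)
from phrasecast.forum import Forum
from phrasecast.phrases import CONFIRMED, Mention, apply_context_rule, find_candidates
from phrasecast.report import compute_mentions
from phrasecast.synthetic import SyntheticConfig, generate_forum

from conftest import make_forum


def _mention(idx, thread, author, topic="unlabeled"):
    return Mention(idx, thread, author, "legacy", CONFIRMED, topic)


def _chain_fixture():
    """root -> x -> y -> z: each adopter's phrase post is in a thread the
    next user also posted in."""
    forum = make_forum(
        [
            ("t1", "root", "the legacy of stroke begins"),   # 1 root first use
            ("t1", "x", "interesting thought"),              # 2
            ("t2", "x", "indeed a legacy of stroke"),        # 3 x first use
            ("t2", "y", "I see what you mean"),              # 4
            ("t3", "y", "a legacy of stroke for sure"),      # 5 y first use
            ("t3", "z", "thanks for explaining"),            # 6
            ("t4", "z", "it truly is a legacy of stroke"),   # 7 z first use
        ]
    )
    mentions = [
        _mention(1, "t1", "root"),
        _mention(3, "t2", "x"),
        _mention(5, "t3", "y"),
        _mention(7, "t4", "z"),
    ]
    return forum, mentions


class TestParticipationTimeline:
    def test_threads_deduplicated_and_ordered(self):
        forum = make_forum(
            [
                ("t2", "u", "a"),
                ("t5", "u", "b"),
                ("t2", "u", "c"),
            ]
        )
        timeline = participation_timeline(forum, "u", [])
        assert [e.thread_id for e in timeline] == ["t2", "t5"]
        assert all(e.flag == FLAG_NO_METAPHOR for e in timeline)

    def test_root_first_metaphor_flag_is_thread_number_2(
        self, narrative, narrative_mentions
    ):
        timeline = participation_timeline(
            narrative.forum, "A", narrative_mentions
        )
        flagged = [e for e in timeline if e.flag == FLAG_METAPHOR_BY_USER]
        assert flagged[0].thread_number == 2

    def test_metaphor_by_other_flag(self, narrative, narrative_mentions):
        timeline = participation_timeline(
            narrative.forum, "B", narrative_mentions
        )
        flags = {e.thread_id: e.flag for e in timeline}
        assert flags["t0005"] == FLAG_METAPHOR_BY_OTHER  # A's phrase thread
        assert flags["t0054"] == FLAG_METAPHOR_BY_USER

    def test_unknown_user_raises(self, tiny_forum):
        with pytest.raises(LookupError):
            participation_timeline(tiny_forum, "ghost", [])

    def test_matches_bruteforce_grouping_on_synthetic(self, pattern):
        forum, _, _ = generate_forum(
            SyntheticConfig(n_users=15, n_threads=40, seed=5)
        )
        mentions = apply_context_rule(
            forum, find_candidates(forum, pattern), pattern
        )
        for user in sorted(forum.users):
            # brute force: first index per (user, thread) over a raw scan
            seen = {}
            for p in forum:
                if p.author_id == user and p.thread_id not in seen:
                    seen[p.thread_id] = p.post_index
            expected = sorted(seen, key=seen.get)
            got = [e.thread_id for e in
                   participation_timeline(forum, user, mentions)]
            assert got == expected


class TestDetectAdoptions:
    def test_narrative_has_8_events_rooted_at_A(self, narrative_mentions):
        events = detect_adoptions(narrative_mentions)
        assert len(events) == 8
        assert events[0].user_id == "A"
        assert events[0].first_use_thread == "t0002"

    def test_single_mention_single_event(self):
        events = detect_adoptions([_mention(4, "t9", "solo")])
        assert len(events) == 1
        assert events[0].user_id == "solo"
        assert events[0].first_use_post_index == 4

    def test_empty_mentions_empty_list(self):
        assert detect_adoptions([]) == []

    def test_metaphor_threads_deduplicated(self):
        events = detect_adoptions(
            [_mention(1, "t1", "u"), _mention(2, "t1", "u"), _mention(3, "t2", "u")]
        )
        assert events[0].metaphor_thread_ids == ("t1", "t2")

    def test_synthetic_events_equal_manifest_planted_adopters(self, pattern):
        forum, _, truth = generate_forum(
            SyntheticConfig(n_users=40, n_threads=150, seed=9)
        )
        mentions = apply_context_rule(
            forum, find_candidates(forum, pattern), pattern
        )
        events = detect_adoptions(mentions)
        manifest = {forum.post(i).author_id for i in truth.phrase_post_indices}
        assert {e.user_id for e in events} == manifest
        assert events[0].user_id == truth.originator


class TestSelfPromotionCount:
    def test_root_on_narrative_fixture_is_51(self, narrative_mentions):
        events = detect_adoptions(narrative_mentions)
        assert self_promotion_count(events[0]) == 51

    def test_single_use_adopter_is_1(self):
        events = detect_adoptions([_mention(2, "t", "u")])
        assert self_promotion_count(events[0]) == 1

    def test_matches_planted_thread_count(self, pattern):
        forum, _, truth = generate_forum(
            SyntheticConfig(n_users=30, n_threads=120, seed=2,
                            self_promotion_rate=0.8)
        )
        mentions = apply_context_rule(
            forum, find_candidates(forum, pattern), pattern
        )
        events = {e.user_id: e for e in detect_adoptions(mentions)}
        planted = {}
        for i in truth.phrase_post_indices:
            p = forum.post(i)
            planted.setdefault(p.author_id, set()).add(p.thread_id)
        for user, threads in planted.items():
            assert self_promotion_count(events[user]) == len(threads)


class TestClassifyExposure:
    def test_narrative_routes(self, narrative, narrative_mentions):
        adoptions = detect_adoptions(narrative_mentions)
        records = {
            r.adopter: r
            for r in classify_exposure(
                narrative.forum, narrative_mentions, adoptions
            )
        }
        for u in ("B", "C", "F"):
            assert records[u].route == ROUTE_DIRECT
            assert records[u].source == "A"
        assert records["D"].route == ROUTE_UNRELATED
        assert records["D"].source == "A"
        assert records["H"].route == ROUTE_UNRELATED
        assert records["H"].source == "B"
        for u in ("E", "G"):
            assert records[u].route == ROUTE_LURKING
            assert records[u].source is None

    def test_root_has_no_record(self, narrative, narrative_mentions):
        adoptions = detect_adoptions(narrative_mentions)
        records = classify_exposure(
            narrative.forum, narrative_mentions, adoptions
        )
        assert "A" not in {r.adopter for r in records}
        assert len(records) == 7

    def test_tie_break_policies(self):
        # u reads the phrase in two threads: a's post (earlier) and b's post
        forum = make_forum(
            [
                ("t1", "a", "legacy of stroke first"),     # 1
                ("t1", "u", "hello"),                      # 2
                ("t2", "b", "legacy of stroke too"),       # 3
                ("t2", "u", "hello again"),                # 4
                ("t3", "u", "my own legacy of stroke"),    # 5
            ]
        )
        mentions = [
            _mention(1, "t1", "a"),
            _mention(3, "t2", "b"),
            _mention(5, "t3", "u"),
        ]
        adoptions = detect_adoptions(mentions)
        earliest = classify_exposure(forum, mentions, adoptions, "earliest")
        latest = classify_exposure(forum, mentions, adoptions, "latest")
        rec_e = [r for r in earliest if r.adopter == "u"][0]
        rec_l = [r for r in latest if r.adopter == "u"][0]
        assert rec_e.source == "a" and rec_e.evidence_threads == ("t1",)
        assert rec_l.source == "b" and rec_l.evidence_threads == ("t2",)

    def test_counterfactual_root_removal(self, narrative, narrative_mentions):
        # with the root's posts gone, nobody can be directly sourced to it
        forum = Forum.from_posts(
            p for p in narrative.forum.posts if p.author_id != "A"
        )
        mentions = [m for m in narrative_mentions if m.author_id != "A"]
        adoptions = detect_adoptions(mentions)
        records = classify_exposure(forum, mentions, adoptions)
        for r in records:
            assert not (r.route == ROUTE_DIRECT and r.source == "A")

    def test_adopter_missing_from_forum_raises(self):
        forum = make_forum([("t1", "a", "legacy of stroke")])
        mentions = [_mention(1, "t1", "a"), _mention(2, "t9", "ghost")]
        adoptions = detect_adoptions(mentions)
        with pytest.raises(DiffusionConsistencyError):
            classify_exposure(forum, mentions, adoptions)


class TestBuildDiffusionTree:
    def test_adoption_chain_depth_3(self):
        forum, mentions = _chain_fixture()
        adoptions = detect_adoptions(mentions)
        exposures = classify_exposure(forum, mentions, adoptions)
        tree = build_diffusion_tree(forum, mentions, exposures, adoptions)
        assert {(e.source, e.recipient) for e in tree.adoption_edges} == {
            ("root", "x"), ("x", "y"), ("y", "z"),
        }
        assert tree.depth == 3

    def test_lone_root_single_node_depth_0(self):
        forum = make_forum([("t1", "only", "a legacy of stroke")])
        mentions = [_mention(1, "t1", "only")]
        tree = build_diffusion_tree(forum, mentions, [])
        assert tree.nodes == {"only"}
        assert tree.depth == 0
        assert tree.edges == []

    def test_narrative_tree_shape(self, narrative, narrative_mentions):
        adoptions = detect_adoptions(narrative_mentions)
        exposures = classify_exposure(
            narrative.forum, narrative_mentions, adoptions
        )
        tree = build_diffusion_tree(
            narrative.forum, narrative_mentions, exposures, adoptions
        )
        assert len(tree.nodes) == 68
        assert tree.depth == 3
        assert len(tree.recipients) == 60
        lurk_edges = [e for e in tree.adoption_edges
                      if e.mechanism == MECH_LURKING]
        assert {e.recipient for e in lurk_edges} == {"E", "G"}
        assert all(e.source == "A" for e in lurk_edges)
        # B, C, F adopted inside the root's repeat-promotion threads
        for u in ("B", "C", "F"):
            (edge,) = [e for e in tree.adoption_edges if e.recipient == u]
            assert edge.mechanism == MECH_SELF_PROMOTION

    def test_depth_matches_independent_longest_path_oracle(self, pattern):
        for seed in range(5):
            forum, _, _ = generate_forum(
                SyntheticConfig(n_users=40, n_threads=120, seed=seed,
                                lurk_prob=0.1, adoption_prob=0.4)
            )
            mentions = apply_context_rule(
                forum, find_candidates(forum, pattern), pattern
            )
            adoptions = detect_adoptions(mentions)
            exposures = classify_exposure(forum, mentions, adoptions)
            tree = build_diffusion_tree(forum, mentions, exposures, adoptions)
            g = nx.DiGraph()
            g.add_node(tree.root)
            g.add_edges_from((e.source, e.recipient) for e in tree.edges)
            reachable = nx.descendants(g, tree.root) | {tree.root}
            oracle = nx.dag_longest_path_length(g.subgraph(reachable))
            assert tree.depth == oracle

    def test_temporal_consistency_of_adoption_edges(self, pattern):
        forum, _, _ = generate_forum(
            SyntheticConfig(n_users=50, n_threads=200, seed=13,
                            adoption_prob=0.5)
        )
        mentions = apply_context_rule(
            forum, find_candidates(forum, pattern), pattern
        )
        adoptions = detect_adoptions(mentions)
        first_use = {a.user_id: a.first_use_post_index for a in adoptions}
        exposures = classify_exposure(forum, mentions, adoptions)
        tree = build_diffusion_tree(forum, mentions, exposures, adoptions)
        for e in tree.adoption_edges:
            if e.mechanism == MECH_LURKING:
                continue
            assert first_use[e.source] < first_use[e.recipient]

    def test_spreading_edges_unique_per_pair(self, narrative, narrative_mentions):
        adoptions = detect_adoptions(narrative_mentions)
        exposures = classify_exposure(
            narrative.forum, narrative_mentions, adoptions
        )
        tree = build_diffusion_tree(
            narrative.forum, narrative_mentions, exposures, adoptions
        )
        pairs = [(e.source, e.recipient) for e in tree.spreading_edges]
        assert len(pairs) == len(set(pairs))
        # q01 opened three of the root's phrase threads -> still one edge
        assert pairs.count(("A", "q01")) == 1


class TestMechanismSummary:
    def test_narrative_summary(self, narrative, narrative_mentions):
        adoptions = detect_adoptions(narrative_mentions)
        exposures = classify_exposure(
            narrative.forum, narrative_mentions, adoptions
        )
        tree = build_diffusion_tree(
            narrative.forum, narrative_mentions, exposures, adoptions
        )
        superusers = frozenset({"A", "B", "C", "F"})
        summary = mechanism_summary(tree, adoptions, exposures, superusers)
        assert summary["n_nonroot_adopters"] == 7
        assert summary["n_superuser_nonroot_adopters"] == 3
        assert summary["routes"] == {
            ROUTE_DIRECT: 3, ROUTE_UNRELATED: 2, ROUTE_LURKING: 2,
        }
        assert summary["self_promotion_threads"]["A"] == 51

    def test_single_adopter_summary(self):
        forum = make_forum([("t1", "only", "a legacy of stroke")])
        mentions = [_mention(1, "t1", "only")]
        adoptions = detect_adoptions(mentions)
        tree = build_diffusion_tree(forum, mentions, [], adoptions)
        summary = mechanism_summary(tree, adoptions, [])
        assert summary["n_nonroot_adopters"] == 0
        assert summary["depth"] == 0
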