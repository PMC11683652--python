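import pytest

from phrasecast.fixtures import NarrativeFixture, default_pattern, narrative_forum
from phrasecast.forum import Forum, Post
from phrasecast.report import compute_mentions


@pytest.fixture(scope="session")
def narrative() -> NarrativeFixture:
    return narrative_forum()


@pytest.fixture(scope="session")
def narrative_mentions(narrative):
    return compute_mentions(
        narrative.forum, narrative.pattern, narrative.annotations
    )


@pytest.fixture(scope="session")
def pattern():
    return default_pattern()


def make_forum(rows):
    """rows: (thread_id, author, text) in chronological order."""
    return Forum.from_posts(
        Post(i, t, a, x) for i, (t, a, x) in enumerate(rows, start=1)
    )


@pytest.fixture
def tiny_forum():
    return make_forum(
        [
            ("t1", "ann", "hello there everyone"),
            ("t2", "bob", "a question about sleep"),
            ("t1", "ann", "replying to myself"),
            ("t2", "cat", "an answer about sleep"),
        ]
    )
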