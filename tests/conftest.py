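from datetime import datetime, timezone

import pytest

from switchminer.corpus import Post
from switchminer.detect import Grammar
from switchminer.lexicon import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session")
def grammar():
    return Grammar.load()


def make_post(text, post_id="p1", platform="twitter", author="u1",
              when=datetime(2014, 3, 1, 12, 0, tzinfo=timezone.utc), declared=None):
    return Post(post_id=post_id, platform=platform, timestamp=when,
                author_key=author, text=text, declared=declared or {})


@pytest.fixture
def post_factory():
    return make_post
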