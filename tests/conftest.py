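from datetime import datetime, timezone

import pytest

from campaignimpact.corpus import Post
from campaignimpact.gender import NameDictionary
from campaignimpact.lexicon import Lexicon
from campaignimpact._resources import default_lexicon_path


def make_post(text="hello world", user_id="u1", ts="2020-02-20T10:00:00",
              post_id=None, is_retweet=False, retweeted_user_id=None,
              retweet_count=0, like_count=0, follower_count=10,
              display_name="Test User"):
    """Construct a post with sensible defaults for fixtures."""
    when = datetime.fromisoformat(ts).replace(tzinfo=timezone.utc)
    return Post(
        post_id=post_id or f"{user_id}-{ts}",
        user_id=user_id, timestamp=when, text=text,
        is_retweet=is_retweet, retweeted_user_id=retweeted_user_id,
        retweet_count=retweet_count, like_count=like_count,
        follower_count=follower_count, display_name=display_name)


@pytest.fixture(scope="session")
def bundled_lexicon():
    return Lexicon.from_dic(default_lexicon_path())


@pytest.fixture(scope="session")
def bundled_names():
    return NameDictionary.from_tsv()


@pytest.fixture
def mini_lexicon():
    """Tiny hand-specified lexicon for arithmetic checks."""
    return Lexicon({
        "Female": ["women", "she", "her"],
        "Anxiety": ["worr*", "risk", "stress", "upset"],
    })
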