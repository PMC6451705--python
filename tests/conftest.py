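from __future__ import annotations

from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import HealthCheck, settings

from tweetfacets.tweet_io import ConditionCorpus, TweetRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_DAY0 = datetime(2018, 4, 20, 12, 0, tzinfo=timezone.utc)


def _t(i: int, **kw) -> TweetRecord:
    kw.setdefault("created_at", _DAY0 + timedelta(days=i))
    return TweetRecord(tweet_id=f"t{i}", **kw)


@pytest.fixture(scope="session")
def reference_corpus() -> ConditionCorpus:
    """Hand-built 12-tweet gout community: 5 users, 9 originals, 3 retweets.

    Exercises every profile variable: retweets, likes, a reply, a quote,
    mentions, URLs, media, an empty text, a follower outlier, multi-hashtag
    tweets and follower counts that drift between a user's tweets.
    """
    tweets = [
        _t(1, author_id="A", text="new study new hope", hashtags=["gout"],
           mention_ids=["B"], url_count=1, retweet_count=2, like_count=1,
           author_followers=100),
        _t(2, author_id="A", text="hi", hashtags=["gout"], author_followers=110),
        _t(3, author_id="B", text="new study new hope", hashtags=["gout"],
           is_retweet=True, source_author_id="A", author_followers=50),
        _t(4, author_id="B", text="w x", hashtags=["gout"], is_retweet=True,
           source_author_id="C", author_followers=55),
        _t(5, author_id="C", text="thanks a lot", hashtags=["gout"],
           mention_ids=["A"], media_count=1, retweet_count=1, is_reply=True,
           reply_to_user_id="A", author_followers=2000),
        _t(6, author_id="C", text="see this", hashtags=["gout"], like_count=3,
           is_quote=True, quoted_author_id="B", author_followers=2000),
        _t(7, author_id="D", text="gout flare again", hashtags=["gout"],
           author_followers=10),
        _t(8, author_id="D", text="ouch ouch ouch", hashtags=["gout"],
           url_count=2, media_count=1, retweet_count=5, like_count=2,
           author_followers=12),
        _t(9, author_id="E", text="ouch ouch ouch", hashtags=["gout"],
           is_retweet=True, source_author_id="D", author_followers=7),
        _t(10, author_id="A", text="check https://t.co/x now",
           hashtags=["gout", "diet"], mention_ids=["C", "D"], url_count=1,
           like_count=1, author_followers=120),
        _t(11, author_id="E", text="", hashtags=["gout"], author_followers=8),
        _t(12, author_id="B", text="hello hello", hashtags=["gout"],
           retweet_count=3, author_followers=60),
    ]
    return ConditionCorpus(condition="gout", tweets=tweets)


#: spot-checked by hand, independently of both implementations
REFERENCE_EXPECTED = {
    "total_tweets": 12,
    "total_users": 5,
    "pct_retweet": 100.0 * 4 / 9,
    "mean_retweet_freq": 2.75,
    "pct_like": 100.0 * 4 / 9,
    "mean_like_freq": 7 / 12,
    "pct_reply": 100.0 / 12,
    "pct_quote": 100.0 / 12,
    "pct_ncc": 100.0,
    "pct_cp": 40.0,
    "mean_ncc_new_tweets": 1.8,
    "mean_cp_retweets": 1.5,
    "pct_ncc_outlier_by_nt": 0.0,
    "pct_cp_outlier_by_rt": 0.0,
    "mean_ncc_followers": 440.0,
    "mean_cp_followers": 34.0,
    "pct_ncc_outlier_by_followers": 20.0,
    "pct_cp_outlier_by_followers": 0.0,
    "mean_hashtags": 13 / 12,
    "mean_mentions": 4 / 12,
    "mean_urls": 4 / 12,
    "mean_media": 2 / 12,
    "mean_unique_words": 22 / 12,
    "mean_length": 29 / 12,
}


@pytest.fixture(scope="session")
def reference_expected() -> dict:
    return dict(REFERENCE_EXPECTED)
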