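"""The multifacet, multivariate profile of one condition community.

A community is summarised by 24 variables across three facets:

* engagement — %Retweet, mean retweet frequency, %Like, mean like frequency,
  %Reply, %Quote;
* user — total users, %NCC (new-content creators), %CP (content propagators),
  their mean activity and followers, and IQR-based outlier fractions;
* content — total tweets plus per-tweet means of hashtags, mentions, URLs,
  media, unique words and length.

NCC and CP are non-exclusive sets: a user who both authored an original tweet
and retweeted counts in both.  Replies and quotes are "new" content (they are
not retweets).  A user's follower count is the value observed on their latest
tweet in the corpus, because followers drift over a collection window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .tweet_io import ConditionCorpus, TweetRecord, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityProfile",
    "UserActivity",
    "engagement_metrics",
    "user_activity",
    "iqr_outlier_fraction",
    "content_metrics",
    "profile_community",
    "profiles_to_frame",
    "write_profiles",
    "read_profiles",
    "TABLE_COLUMNS",
    "FACET_OF",
]


@dataclass
class UserActivity:
    """Per-user activity within one corpus."""

    user_id: str
    n_new_tweets: int
    n_retweets: int
    followers: int


@dataclass
class CommunityProfile:
    """The full variable vector for one condition community."""

    condition: str
    total_tweets: int
    total_users: int
    pct_retweet: float
    mean_retweet_freq: float
    pct_like: float
    mean_like_freq: float
    pct_reply: float
    pct_quote: float
    pct_ncc: float
    pct_cp: float
    mean_ncc_new_tweets: float
    mean_cp_retweets: float
    pct_ncc_outlier_by_nt: float
    pct_cp_outlier_by_rt: float
    mean_ncc_followers: float
    mean_cp_followers: float
    pct_ncc_outlier_by_followers: float
    pct_cp_outlier_by_followers: float
    mean_hashtags: float
    mean_mentions: float
    mean_urls: float
    mean_media: float
    mean_unique_words: float
    mean_length: float


#: stable column order for the profile matrix (condition is the row index)
TABLE_COLUMNS: list[str] = [f.name for f in fields(CommunityProfile)][1:]

#: facet tag of every column
FACET_OF: dict[str, str] = {
    "total_tweets": "totals",
    "total_users": "totals",
    "pct_retweet": "engagement",
    "mean_retweet_freq": "engagement",
    "pct_like": "engagement",
    "mean_like_freq": "engagement",
    "pct_reply": "engagement",
    "pct_quote": "engagement",
    "pct_ncc": "user",
    "pct_cp": "user",
    "mean_ncc_new_tweets": "user",
    "mean_cp_retweets": "user",
    "pct_ncc_outlier_by_nt": "user",
    "pct_cp_outlier_by_rt": "user",
    "mean_ncc_followers": "user",
    "mean_cp_followers": "user",
    "pct_ncc_outlier_by_followers": "user",
    "pct_cp_outlier_by_followers": "user",
    "mean_hashtags": "content",
    "mean_mentions": "content",
    "mean_urls": "content",
    "mean_media": "content",
    "mean_unique_words": "content",
    "mean_length": "content",
}


def _mean(values) -> float:
    values = list(values)
    return float(sum(values)) / len(values) if values else 0.0


def engagement_metrics(
    tweets: list[TweetRecord], retweet_share_mode: str = "originals"
) -> dict[str, float]:
    """The six engagement variables of a corpus.

    ``pct_retweet`` (default mode ``"originals"``) is the share of original
    (non-retweet) tweets whose ``retweet_count`` is at least 1: a collected
    retweet's counts describe its source tweet.  Mode ``"corpus"`` instead
    reports the share of corpus tweets that *are* retweets.  ``pct_like`` is
    always the share of originals with at least one like; ``mean_like_freq``
    averages ``like_count`` over *all* tweets, while ``mean_retweet_freq``
    averages ``retweet_count`` over the retweeted originals only.
    """
    if not tweets:
        raise ValueError("engagement_metrics: empty corpus")
    if retweet_share_mode not in ("originals", "corpus"):
        raise ValueError(f"unknown retweet_share_mode {retweet_share_mode!r}")
    n = len(tweets)
    originals = [t for t in tweets if not t.is_retweet]
    retweeted = [t for t in originals if t.retweet_count >= 1]
    liked = [t for t in originals if t.like_count >= 1]
    if retweet_share_mode == "originals":
        pct_retweet = 100.0 * len(retweeted) / len(originals) if originals else 0.0
    else:
        pct_retweet = 100.0 * sum(t.is_retweet for t in tweets) / n
    if not retweeted:
        logger.warning("engagement_metrics: no retweeted tweets; mean_retweet_freq=0")
    return {
        "pct_retweet": pct_retweet,
        "mean_retweet_freq": _mean(t.retweet_count for t in retweeted),
        "pct_like": 100.0 * len(liked) / len(originals) if originals else 0.0,
        "mean_like_freq": _mean(t.like_count for t in tweets),
        "pct_reply": 100.0 * sum(t.is_reply for t in tweets) / n,
        "pct_quote": 100.0 * sum(t.is_quote for t in tweets) / n,
    }


def user_activity(tweets: list[TweetRecord]) -> list[UserActivity]:
    """One activity record per distinct author, ordered by user id.

    Follower count is taken from the author's latest tweet (latest
    ``created_at``; ties and missing timestamps resolved by corpus position).
    """
    new_counts: dict[str, int] = {}
    rt_counts: dict[str, int] = {}
    followers: dict[str, tuple] = {}
    epoch = None
    for pos, t in enumerate(tweets):
        uid = t.author_id
        if t.is_retweet:
            rt_counts[uid] = rt_counts.get(uid, 0) + 1
            new_counts.setdefault(uid, 0)
        else:
            new_counts[uid] = new_counts.get(uid, 0) + 1
            rt_counts.setdefault(uid, 0)
        key = (t.created_at is not None, t.created_at or epoch, pos)
        if uid not in followers or key >= followers[uid][0]:
            followers[uid] = (key, t.author_followers)
    return [
        UserActivity(user_id=uid, n_new_tweets=new_counts[uid],
                     n_retweets=rt_counts[uid], followers=followers[uid][1])
        for uid in sorted(new_counts)
    ]


def iqr_outlier_fraction(values, mode: str = "tukey", factor: float = 1.5) -> float:
    """Percentage of values above an interquartile-range outlier threshold.

    ``tukey``: v > Q3 + factor*(Q3-Q1), the standard Tukey fence.
    ``literal``: v > factor*Q3 (a cruder upper-quartile multiple, retained for
    sensitivity analysis).  Quartiles use linear interpolation (type 7).
    Fewer than 4 values cannot support a quartile estimate: returns 0 with a
    warning.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("iqr_outlier_fraction: empty input")
    if arr.size < 4:
        logger.warning("iqr_outlier_fraction: only %d value(s); returning 0", arr.size)
        return 0.0
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # numpy default is type-7 linear
    if mode == "tukey":
        fence = q3 + factor * (q3 - q1)
    elif mode == "literal":
        fence = factor * q3
    else:
        raise ValueError(f"unknown IQR mode {mode!r}")
    return 100.0 * float(np.sum(arr > fence)) / arr.size


def content_metrics(tweets: list[TweetRecord]) -> dict[str, float]:
    """Per-tweet means of the six content variables."""
    if not tweets:
        raise ValueError("content_metrics: empty corpus")
    lengths = []
    uniques = []
    for t in tweets:
        toks = tokenize(t.text)
        lengths.append(len(toks))
        uniques.append(len(set(toks)))
    return {
        "mean_hashtags": _mean(len(t.hashtags) for t in tweets),
        "mean_mentions": _mean(len(t.mention_ids) for t in tweets),
        "mean_urls": _mean(t.url_count for t in tweets),
        "mean_media": _mean(t.media_count for t in tweets),
        "mean_unique_words": _mean(uniques),
        "mean_length": _mean(lengths),
    }


def profile_community(
    corpus: ConditionCorpus,
    iqr_mode: str = "tukey",
    retweet_share_mode: str = "originals",
) -> CommunityProfile:
    """Assemble the full 24-variable profile for one condition corpus."""
    tweets = corpus.tweets
    if not tweets:
        raise ValueError(f"profile_community: empty corpus for {corpus.condition!r}")
    activities = user_activity(tweets)
    n_users = len(activities)
    ncc = [a for a in activities if a.n_new_tweets >= 1]
    cp = [a for a in activities if a.n_retweets >= 1]

    def outlier(vals) -> float:
        vals = list(vals)
        return iqr_outlier_fraction(vals, mode=iqr_mode) if vals else 0.0

    return CommunityProfile(
        condition=corpus.condition,
        total_tweets=len(tweets),
        total_users=n_users,
        **engagement_metrics(tweets, retweet_share_mode=retweet_share_mode),
        pct_ncc=100.0 * len(ncc) / n_users,
        pct_cp=100.0 * len(cp) / n_users,
        mean_ncc_new_tweets=_mean(a.n_new_tweets for a in ncc),
        mean_cp_retweets=_mean(a.n_retweets for a in cp),
        pct_ncc_outlier_by_nt=outlier(a.n_new_tweets for a in ncc),
        pct_cp_outlier_by_rt=outlier(a.n_retweets for a in cp),
        mean_ncc_followers=_mean(a.followers for a in ncc),
        mean_cp_followers=_mean(a.followers for a in cp),
        pct_ncc_outlier_by_followers=outlier(a.followers for a in ncc),
        pct_cp_outlier_by_followers=outlier(a.followers for a in cp),
        **content_metrics(tweets),
    )


def profiles_to_frame(profiles: list[CommunityProfile]) -> pd.DataFrame:
    """Profiles as a condition x variable matrix with stable column order."""
    rows = {p.condition: [getattr(p, c) for c in TABLE_COLUMNS] for p in profiles}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=TABLE_COLUMNS)
    df.index.name = "condition"
    return df.sort_index()


def write_profiles(profiles: list[CommunityProfile] | pd.DataFrame, path: str | Path) -> None:
    df = profiles if isinstance(profiles, pd.DataFrame) else profiles_to_frame(profiles)
    df.to_csv(path, float_format="%.10g")


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="condition")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing profile columns {missing}")
    return df[TABLE_COLUMNS]
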