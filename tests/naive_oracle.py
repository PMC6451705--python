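"""Independent plain-Python recount of every community-profile variable.

Deliberately written without numpy/pandas and without importing any profile
code from the package, so it can serve as an equivalence oracle: simple loops,
explicit quantile interpolation, one pass per variable.
"""

from __future__ import annotations

import math
import string

_URL_MARKS = ("http://", "https://", "www.")


def naive_tokens(text: str) -> list[str]:
    out = []
    for raw in text.lower().split():
        cut = len(raw)
        for mark in _URL_MARKS:
            idx = raw.find(mark)
            if idx != -1:
                cut = min(cut, idx)
        tok = raw[:cut].strip(string.punctuation)
        if tok:
            out.append(tok)
    return out


def naive_quantile(values: list[float], p: float) -> float:
    """Type-7 (linear interpolation) quantile, written out longhand."""
    v = sorted(values)
    h = (len(v) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def naive_iqr_outlier_pct(values: list[float], mode: str = "tukey") -> float:
    if len(values) < 4:
        return 0.0
    q1 = naive_quantile(values, 0.25)
    q3 = naive_quantile(values, 0.75)
    fence = q3 + 1.5 * (q3 - q1) if mode == "tukey" else 1.5 * q3
    return 100.0 * sum(1 for v in values if v > fence) / len(values)


def naive_profile(tweets) -> dict[str, float]:
    """Recount all 24 profile variables from a list of TweetRecords."""
    n = len(tweets)
    originals = [t for t in tweets if not t.is_retweet]
    retweeted = [t for t in originals if t.retweet_count >= 1]
    liked = [t for t in originals if t.like_count >= 1]

    new_count: dict[str, int] = {}
    rt_count: dict[str, int] = {}
    for t in tweets:
        u = t.author_id
        new_count.setdefault(u, 0)
        rt_count.setdefault(u, 0)
        if t.is_retweet:
            rt_count[u] += 1
        else:
            new_count[u] += 1
    # followers from each user's latest tweet (position breaks ties/missing)
    follow: dict[str, int] = {}
    best: dict[str, tuple] = {}
    for pos, t in enumerate(tweets):
        u = t.author_id
        key = (t.created_at is not None, t.created_at, pos)
        if u not in best or key >= best[u]:
            best[u] = key
            follow[u] = t.author_followers

    users = sorted(new_count)
    ncc = [u for u in users if new_count[u] >= 1]
    cp = [u for u in users if rt_count[u] >= 1]

    def mean(vals):
        vals = list(vals)
        return sum(vals) / len(vals) if vals else 0.0

    token_lens, token_uniq = [], []
    for t in tweets:
        toks = naive_tokens(t.text)
        token_lens.append(len(toks))
        token_uniq.append(len(set(toks)))

    return {
        "total_tweets": n,
        "total_users": len(users),
        "pct_retweet": 100.0 * len(retweeted) / len(originals) if originals else 0.0,
        "mean_retweet_freq": mean(t.retweet_count for t in retweeted),
        "pct_like": 100.0 * len(liked) / len(originals) if originals else 0.0,
        "mean_like_freq": mean(t.like_count for t in tweets),
        "pct_reply": 100.0 * sum(1 for t in tweets if t.is_reply) / n,
        "pct_quote": 100.0 * sum(1 for t in tweets if t.is_quote) / n,
        "pct_ncc": 100.0 * len(ncc) / len(users),
        "pct_cp": 100.0 * len(cp) / len(users),
        "mean_ncc_new_tweets": mean(new_count[u] for u in ncc),
        "mean_cp_retweets": mean(rt_count[u] for u in cp),
        "pct_ncc_outlier_by_nt": naive_iqr_outlier_pct([new_count[u] for u in ncc]),
        "pct_cp_outlier_by_rt": naive_iqr_outlier_pct([rt_count[u] for u in cp]),
        "mean_ncc_followers": mean(follow[u] for u in ncc),
        "mean_cp_followers": mean(follow[u] for u in cp),
        "pct_ncc_outlier_by_followers": naive_iqr_outlier_pct([follow[u] for u in ncc]),
        "pct_cp_outlier_by_followers": naive_iqr_outlier_pct([follow[u] for u in cp]),
        "mean_hashtags": mean(len(t.hashtags) for t in tweets),
        "mean_mentions": mean(len(t.mention_ids) for t in tweets),
        "mean_urls": mean(t.url_count for t in tweets),
        "mean_media": mean(t.media_count for t in tweets),
        "mean_unique_words": mean(token_uniq),
        "mean_length": mean(token_lens),
    }
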