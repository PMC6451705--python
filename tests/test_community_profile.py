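import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tweetfacets.community_profile import (
    TABLE_COLUMNS,
    content_metrics,
    engagement_metrics,
    iqr_outlier_fraction,
    profile_community,
    profiles_to_frame,
    read_profiles,
    user_activity,
    write_profiles,
)
from tweetfacets.tweet_io import ConditionCorpus, TweetRecord

from naive_oracle import naive_profile


def _tw(i, author="A", **kw):
    return TweetRecord(tweet_id=f"x{i}", author_id=author, **kw)


class TestEngagementMetrics:
    def test_retweet_share_and_freq(self):
        tweets = [_tw(i, retweet_count=c) for i, c in enumerate([0, 2, 5, 0])]
        m = engagement_metrics(tweets)
        assert m["pct_retweet"] == pytest.approx(50.0)
        assert m["mean_retweet_freq"] == pytest.approx(3.5)

    def test_like_share_over_originals_and_freq_over_all(self):
        tweets = [_tw(i, like_count=c) for i, c in enumerate([1, 0, 0, 3])]
        m = engagement_metrics(tweets)
        assert m["pct_like"] == pytest.approx(50.0)
        assert m["mean_like_freq"] == pytest.approx(1.0)

    def test_reply_and_quote_shares(self):
        tweets = [
            _tw(0), _tw(1),
            _tw(2, is_reply=True, reply_to_user_id="B"),
            _tw(3, is_quote=True, quoted_author_id="B"),
        ]
        m = engagement_metrics(tweets)
        assert m["pct_reply"] == pytest.approx(25.0)
        assert m["pct_quote"] == pytest.approx(25.0)

    def test_corpus_mode_counts_retweet_records(self):
        tweets = [_tw(0), _tw(1, is_retweet=True, source_author_id="B")]
        m = engagement_metrics(tweets, retweet_share_mode="corpus")
        assert m["pct_retweet"] == pytest.approx(50.0)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            engagement_metrics([])

    def test_no_retweeted_tweets_flagged(self, caplog):
        with caplog.at_level("WARNING"):
            m = engagement_metrics([_tw(0)])
        assert m["mean_retweet_freq"] == 0.0
        assert "no retweeted" in caplog.text


class TestUserActivity:
    def test_ncc_cp_overlap(self):
        tweets = [
            _tw(0, author="A"), _tw(1, author="A"),
            _tw(2, author="B", is_retweet=True, source_author_id="A"),
            _tw(3, author="C"),
            _tw(4, author="C", is_retweet=True, source_author_id="A"),
        ]
        acts = {a.user_id: a for a in user_activity(tweets)}
        assert acts["A"].n_new_tweets == 2 and acts["A"].n_retweets == 0
        assert acts["B"].n_new_tweets == 0 and acts["B"].n_retweets == 1
        assert acts["C"].n_new_tweets == 1 and acts["C"].n_retweets == 1

    def test_followers_from_latest_tweet(self):
        from datetime import datetime, timezone
        d1 = datetime(2018, 4, 1, tzinfo=timezone.utc)
        d2 = datetime(2018, 4, 9, tzinfo=timezone.utc)
        tweets = [
            _tw(0, author="A", created_at=d2, author_followers=200),
            _tw(1, author="A", created_at=d1, author_followers=100),
        ]
        (act,) = user_activity(tweets)
        assert act.followers == 200


class TestIqrOutlierFraction:
    def test_no_spread_no_outliers(self):
        assert iqr_outlier_fraction([5, 5, 5, 5]) == 0.0
        assert iqr_outlier_fraction([5, 5, 5, 5], mode="literal") == 0.0

    def test_type7_tukey_fence(self):
        # Q1=2.25, Q3=4.75, fence 8.5 -> only 100 is outside
        assert iqr_outlier_fraction([1, 2, 3, 4, 5, 100]) == pytest.approx(100 / 6)

    def test_literal_mode_upper_quartile_multiple(self):
        # literal fence 1.5*Q3 = 7.125
        assert iqr_outlier_fraction([1, 2, 3, 4, 5, 100], mode="literal") == \
            pytest.approx(100 / 6)

    def test_small_samples_return_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert iqr_outlier_fraction([1, 2, 3]) == 0.0
        assert "only 3" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_fraction([])

    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=40),
           st.integers(-10**5, 10**5))
    def test_translation_and_permutation_invariance(self, values, shift):
        # integer inputs keep the quantile arithmetic dyadic, hence exact
        base = iqr_outlier_fraction(values)
        assert iqr_outlier_fraction(list(reversed(values))) == base
        assert iqr_outlier_fraction([v + shift for v in values]) == base


class TestContentMetrics:
    def test_hashtag_mean(self):
        tweets = [_tw(0, hashtags=["a", "b"]), _tw(1)]
        assert content_metrics(tweets)["mean_hashtags"] == pytest.approx(1.0)

    def test_token_statistics(self):
        tweets = [_tw(0, text="new study new hope"), _tw(1, text="hi")]
        m = content_metrics(tweets)
        assert m["mean_length"] == pytest.approx(2.5)
        assert m["mean_unique_words"] == pytest.approx(2.0)

    def test_absent_media_is_zero(self):
        assert content_metrics([_tw(0), _tw(1)])["mean_media"] == 0.0


def _random_corpus(rng, n_tweets):
    users = [f"u{i}" for i in range(rng.integers(2, 6))]
    tweets = []
    for i in range(n_tweets):
        author = str(rng.choice(users))
        is_rt = bool(rng.random() < 0.3)
        kind = rng.random()
        tweets.append(TweetRecord(
            tweet_id=f"r{i}",
            author_id=author,
            text=" ".join(f"w{rng.integers(0, 9)}" for _ in range(rng.integers(0, 7))),
            hashtags=["gout"] + (["x"] if rng.random() < 0.3 else []),
            mention_ids=[str(rng.choice(users))] if rng.random() < 0.4 else [],
            url_count=int(rng.poisson(0.5)),
            media_count=int(rng.poisson(0.3)),
            retweet_count=0 if is_rt else int(rng.poisson(1.2)),
            like_count=0 if is_rt else int(rng.poisson(0.8)),
            author_followers=int(rng.lognormal(4, 1.5)),
            is_retweet=is_rt,
            source_author_id=str(rng.choice(users)) if is_rt else "",
            is_reply=bool(not is_rt and kind < 0.15),
            reply_to_user_id=str(rng.choice(users)) if not is_rt and kind < 0.15 else "",
            is_quote=bool(not is_rt and 0.15 <= kind < 0.25),
            quoted_author_id=str(rng.choice(users)) if not is_rt and 0.15 <= kind < 0.25 else "",
        ))
    return ConditionCorpus(condition="rand", tweets=tweets)


class TestProfileCommunity:
    def test_reference_fixture_matches_hand_computation(
            self, reference_corpus, reference_expected):
        prof = profile_community(reference_corpus)
        for field, expected in reference_expected.items():
            assert getattr(prof, field) == pytest.approx(expected, rel=1e-12), field

    def test_matches_naive_recount_on_random_corpora(self):
        rng = np.random.default_rng(42)
        for trial in range(50):
            corpus = _random_corpus(rng, int(rng.integers(1, 21)))
            prof = profile_community(corpus)
            naive = naive_profile(corpus.tweets)
            for field, expected in naive.items():
                got = getattr(prof, field)
                assert math.isclose(got, expected, rel_tol=1e-12, abs_tol=1e-12), \
                    f"trial {trial}: {field}: {got} != {expected}"

    def test_single_original_tweet(self):
        prof = profile_community(ConditionCorpus("solo", [_tw(0, text="hi")]))
        assert prof.pct_retweet == 0.0
        assert prof.pct_reply == 0.0 and prof.pct_quote == 0.0
        assert prof.total_users == 1 and prof.pct_ncc == 100.0

    def test_percentages_bounded_and_unique_le_length(self, reference_corpus):
        prof = profile_community(reference_corpus)
        for col in TABLE_COLUMNS:
            v = getattr(prof, col)
            assert v >= 0.0
            if col.startswith("pct_"):
                assert v <= 100.0
        assert prof.mean_unique_words <= prof.mean_length

    def test_profiles_csv_round_trip(self, reference_corpus, tmp_path):
        prof = profile_community(reference_corpus)
        df = profiles_to_frame([prof])
        path = tmp_path / "profiles.csv"
        write_profiles(df, path)
        back = read_profiles(path)
        assert list(back.columns) == TABLE_COLUMNS
        assert np.allclose(back.to_numpy(), df.to_numpy())
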