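"""Synthetic condition-community tweet streams with known ground truth.

The generator emulates a month-long hashtag-filtered collection of health
condition tweets: per condition, a log-uniform number of users split into
new-content creators (NCC) and content propagators (CP), overdispersed
(negative-binomial) retweet/like counts, log-normal follower counts, Poisson
content features and one of three interaction topologies (broadcast hubs,
planted community blocks, or pure isolates).

The cross-facet dependence the correlation analysis should recover is planted
at the condition level: each condition carries a latent content score and a
latent engagement score drawn from a standard bivariate normal with
correlation ``rho``.  All content links (mentions, URLs, media, tweet length)
are linear in the content latent and all engagement links (retweet/like count
means, reply/quote probabilities) are linear in the engagement latent, so the
population canonical correlation between the two facets equals ``rho`` and
shrinks only by within-condition sampling noise.

A single global seed drives a hierarchical RNG (one child seed per condition),
so regeneration of any one condition is stable and whole datasets are
byte-identical for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

import networkx as nx
import numpy as np

from .tweet_io import ConditionCorpus, ConditionMap, TweetRecord, write_tweets

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationResult",
    "simulate_condition_map",
    "simulate_community",
    "simulate_dataset",
    "simulate_planted_partition_graph",
]

TOPOLOGIES = ("broadcast", "community_clusters", "isolates")

_COLLECTION_START = datetime(2018, 4, 15, tzinfo=timezone.utc)
_COLLECTION_SECONDS = 30 * 24 * 3600


def _default_engagement_link() -> dict[str, float]:
    return {
        "retweet_base": 1.5, "retweet_slope": 0.75, "retweet_disp": 0.8,
        "like_base": 1.1, "like_slope": 0.55, "like_disp": 0.8,
        "reply_base": 0.07, "reply_slope": 0.030,
        "quote_base": 0.06, "quote_slope": 0.025,
    }


def _default_content_link() -> dict[str, float]:
    return {
        "mention_base": 0.9, "mention_slope": 0.40,
        "url_base": 0.55, "url_slope": 0.25,
        "media_base": 0.35, "media_slope": 0.16,
        "length_base": 10.0, "length_slope": 3.0,
        "hashtag_extra_mean": 0.8,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults define the study conditions."""

    n_conditions: int = 200
    users_range: tuple[int, int] = (25, 250)
    tweets_per_ncc: float = 1.8
    ncc_share: float = 0.7
    cp_share: float = 0.5
    cp_retweets: float = 1.5
    rho: float = 0.7
    engagement_link: dict[str, float] = field(default_factory=_default_engagement_link)
    content_link: dict[str, float] = field(default_factory=_default_content_link)
    followers_lognormal: tuple[float, float] = (5.5, 1.4)
    topology_mix: tuple[float, float, float] = (0.55, 0.45, 0.0)
    n_blocks: int = 4
    vocab_size: int = 800
    tags_per_condition: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be >= 1")
        lo, hi = self.users_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid users_range {self.users_range}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if any(f < 0 for f in self.topology_mix) or sum(self.topology_mix) > 1 + 1e-9:
            raise ValueError("topology_mix fractions must be >= 0 and sum to <= 1")
        if self.tweets_per_ncc < 1 or self.cp_retweets < 1:
            raise ValueError("per-user tweet means are shifted Poisson: must be >= 1")
        if not 0 < self.ncc_share <= 1:
            raise ValueError("ncc_share must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Planted parameters paired with a generated corpus."""

    rho: float
    latent_engagement: dict[str, float]
    latent_content: dict[str, float]
    topology: dict[str, str]
    planted_blocks: dict[str, dict[str, int]]

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimulationResult:
    corpora: list[ConditionCorpus]
    condition_map: ConditionMap
    truth: SimulationTruth


def simulate_condition_map(
    n_conditions: int, tags_per_condition: int = 2,
    rng: np.random.Generator | None = None,
) -> ConditionMap:
    """Synthetic condition names ``cond_0001``... with unique pseudo-hashtags."""
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    if tags_per_condition < 1:
        raise ValueError("tags_per_condition must be >= 1")
    entries = {
        f"cond_{i + 1:04d}": {
            f"tag{i + 1:04d}{chr(ord('a') + j)}" for j in range(tags_per_condition)
        }
        for i in range(n_conditions)
    }
    return ConditionMap(entries=entries)


def _negbin(rng: np.random.Generator, mean: np.ndarray | float, disp: float, size: int):
    """Negative binomial with given mean and dispersion (size) parameter."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    return rng.negative_binomial(disp, disp / (disp + mean), size=size)


def _pick_targets(
    rng: np.random.Generator, n: int, topology: str, author_idx: np.ndarray,
    n_users: int, hubs: np.ndarray, blocks: np.ndarray,
) -> np.ndarray:
    """Interaction targets (user indices) under the condition's topology.

    Targets never equal the author: collisions are re-pointed at another user
    uniformly, so expected interaction counts do not depend on who authored
    the tweet (hubs would otherwise lose their frequent self-collisions).
    """
    uniform = rng.integers(0, n_users, size=n)
    if topology == "broadcast" and hubs.size:
        hub_pick = hubs[rng.integers(0, hubs.size, size=n)]
        use_hub = rng.random(n) < 0.75
        out = np.where(use_hub, hub_pick, uniform)
    elif topology == "community_clusters":
        # same-block target with high probability (planted partition)
        out = uniform.copy()
        same = rng.random(n) < 0.9
        for i in np.nonzero(same)[0]:
            members = np.nonzero(blocks == blocks[author_idx[i]])[0]
            if members.size:
                out[i] = members[rng.integers(0, members.size)]
    else:
        out = uniform
    if n_users > 1:
        clash = out == author_idx
        if np.any(clash):
            shift = 1 + rng.integers(0, n_users - 1, size=int(clash.sum()))
            out[clash] = (out[clash] + shift) % n_users
    return out


def simulate_community(
    config: SimulationConfig,
    condition: str,
    latent_e: float,
    latent_c: float,
    rng: np.random.Generator,
    tags: list[str] | None = None,
    topology: str = "broadcast",
) -> tuple[ConditionCorpus, dict[str, int]]:
    """Generate one condition corpus; returns (corpus, planted user blocks)."""
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    tags = tags or [f"{condition}tag"]
    el, cl = config.engagement_link, config.content_link
    lo, hi = config.users_range
    n_users = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    n_users = max(1, n_users)
    user_ids = [f"{condition}_u{i:04d}" for i in range(n_users)]
    mu_f, sd_f = config.followers_lognormal
    followers = np.floor(rng.lognormal(mu_f, sd_f, size=n_users)).astype(int)
    # exact role quotas: the NCC/CP shares are community parameters, not
    # per-user coin flips, so the originals share is stable across conditions
    is_ncc = np.zeros(n_users, dtype=bool)
    is_cp = np.zeros(n_users, dtype=bool)
    is_ncc[rng.permutation(n_users)[: max(1, round(config.ncc_share * n_users))]] = True
    is_cp[rng.permutation(n_users)[: round(config.cp_share * n_users)]] = True
    if topology == "isolates":
        is_cp[:] = False  # retweets would create edges
    is_ncc |= ~is_cp  # every user authors at least one tweet
    blocks = rng.integers(0, config.n_blocks, size=n_users)
    ncc_idx = np.nonzero(is_ncc)[0]
    hubs = ncc_idx[: max(2, n_users // 25)]

    # per-condition linear links, floored to keep rates valid
    mu_rt = max(0.05, el["retweet_base"] + el["retweet_slope"] * latent_e)
    mu_like = max(0.05, el["like_base"] + el["like_slope"] * latent_e)
    p_reply = min(0.6, max(0.0, el["reply_base"] + el["reply_slope"] * latent_e))
    p_quote = min(0.6, max(0.0, el["quote_base"] + el["quote_slope"] * latent_e))
    if topology == "isolates":
        p_reply = 0.0  # replies would create edges
    mu_mention = 0.0 if topology == "isolates" else max(
        0.02, cl["mention_base"] + cl["mention_slope"] * latent_c)
    mu_url = max(0.02, cl["url_base"] + cl["url_slope"] * latent_c)
    mu_media = max(0.01, cl["media_base"] + cl["media_slope"] * latent_c)
    mu_len = max(1.0, cl["length_base"] + cl["length_slope"] * latent_c)

    n_new = 1 + rng.poisson(config.tweets_per_ncc - 1.0, size=ncc_idx.size)
    total_new = int(n_new.sum())
    authors = np.repeat(ncc_idx, n_new)
    order = rng.permutation(total_new)
    authors = authors[order]

    mention_counts = rng.poisson(mu_mention, size=total_new) if mu_mention > 0 else \
        np.zeros(total_new, dtype=int)
    if n_users < 2:
        mention_counts[:] = 0
    url_counts = rng.poisson(mu_url, size=total_new)
    media_counts = rng.poisson(mu_media, size=total_new)
    extra_tags = rng.poisson(cl["hashtag_extra_mean"], size=total_new)
    lengths = np.maximum(1, rng.poisson(mu_len, size=total_new))
    rt_counts = _negbin(rng, mu_rt, el["retweet_disp"], total_new)
    like_counts = _negbin(rng, mu_like, el["like_disp"], total_new)
    kind_draw = rng.random(total_new)
    times = np.sort(rng.integers(0, _COLLECTION_SECONDS, size=total_new))

    n_mentions_total = int(mention_counts.sum())
    if n_mentions_total:
        mention_authors = np.repeat(authors, mention_counts)
        mention_targets = _pick_targets(
            rng, n_mentions_total, topology, mention_authors, n_users, hubs, blocks)
    else:
        mention_targets = np.empty(0, dtype=int)
    reply_targets = _pick_targets(
        rng, total_new, topology, authors, n_users, hubs, blocks)
    quote_targets = rng.integers(0, n_users, size=total_new)

    tag_pick = rng.integers(0, len(tags), size=total_new)
    vocab = rng.integers(0, config.vocab_size, size=int(lengths.sum()))

    tweets: list[TweetRecord] = []
    counter = 0
    m_pos = 0
    v_pos = 0
    originals_meta: list[tuple[int, int]] = []  # (tweet index in corpus, author idx)
    for i in range(total_new):
        a = int(authors[i])
        n_m = int(mention_counts[i])
        mentions = [user_ids[int(t)] for t in mention_targets[m_pos:m_pos + n_m]]
        m_pos += n_m
        L = int(lengths[i])
        text = " ".join(f"w{vocab[v_pos + j]}" for j in range(L))
        v_pos += L
        hashtags = [tags[tag_pick[i]]] + [f"generic{k:02d}" for k in
                                          range(min(int(extra_tags[i]), 10))]
        is_reply = bool(kind_draw[i] < p_reply)
        is_quote = bool(p_reply <= kind_draw[i] < p_reply + p_quote)
        reply_to = user_ids[int(reply_targets[i])] if is_reply else ""
        quoted = user_ids[int(quote_targets[i])] if is_quote else ""
        tweets.append(TweetRecord(
            tweet_id=f"{condition}_t{counter:06d}",
            author_id=user_ids[a],
            text=text,
            created_at=_COLLECTION_START + timedelta(seconds=int(times[i])),
            hashtags=hashtags,
            mention_ids=mentions,
            url_count=int(url_counts[i]),
            media_count=int(media_counts[i]),
            retweet_count=int(rt_counts[i]),
            like_count=int(like_counts[i]),
            author_followers=int(followers[a]),
            is_reply=is_reply,
            reply_to_user_id=reply_to,
            is_quote=is_quote,
            quoted_author_id=quoted,
        ))
        originals_meta.append((counter, a))
        counter += 1

    # Content propagators retweet uniformly sampled originals.  The planted
    # hub / block interaction structure is carried by mention and reply
    # targeting; keeping retweet sources uniform means the duplicated content
    # of popular originals cannot masquerade as a cross-facet signal.
    cp_idx = np.nonzero(is_cp)[0]
    if cp_idx.size and originals_meta:
        n_rts = 1 + rng.poisson(config.cp_retweets - 1.0, size=cp_idx.size)
        total_rt = int(n_rts.sum())
        rt_authors = np.repeat(cp_idx, n_rts)
        src_uniform = rng.integers(0, len(originals_meta), size=total_rt)
        rt_times = rng.integers(0, _COLLECTION_SECONDS, size=total_rt)
        for i in range(total_rt):
            u = int(rt_authors[i])
            k = int(src_uniform[i])
            src = tweets[originals_meta[k][0]]
            tweets.append(TweetRecord(
                tweet_id=f"{condition}_t{counter:06d}",
                author_id=user_ids[u],
                text=src.text,
                created_at=_COLLECTION_START + timedelta(seconds=int(rt_times[i])),
                hashtags=list(src.hashtags),
                mention_ids=list(src.mention_ids),
                url_count=src.url_count,
                media_count=src.media_count,
                retweet_count=0,
                like_count=0,
                author_followers=int(followers[u]),
                is_retweet=True,
                source_author_id=src.author_id,
            ))
            counter += 1

    planted = {user_ids[i]: int(blocks[i]) for i in range(n_users)} \
        if topology == "community_clusters" else {}
    return ConditionCorpus(condition=condition, tweets=tweets), planted


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulationResult:
    """Generate the full multi-condition dataset (optionally written to disk).

    Writes ``tweets.jsonl``, ``condition_map.csv`` and ``truth.json`` when
    ``out_dir`` is given; the same formats :mod:`tweetfacets.tweet_io`
    consumes.
    """
    n = config.n_conditions
    rng_global = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    cmap = simulate_condition_map(n, config.tags_per_condition, rng_global)
    conditions = cmap.conditions
    latent_c = rng_global.standard_normal(n)
    latent_e = config.rho * latent_c + np.sqrt(1.0 - config.rho**2) * \
        rng_global.standard_normal(n)
    mix = np.asarray(config.topology_mix, dtype=float)
    probs = np.append(mix, max(0.0, 1.0 - mix.sum()))  # any remainder -> broadcast
    probs[0] += probs[-1]
    probs = probs[:3] / probs[:3].sum()
    topo_idx = rng_global.choice(3, size=n, p=probs)

    corpora: list[ConditionCorpus] = []
    truth = SimulationTruth(rho=config.rho, latent_engagement={}, latent_content={},
                            topology={}, planted_blocks={})
    for i, cond in enumerate(conditions):
        rng_i = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i + 1,)))
        topo = TOPOLOGIES[int(topo_idx[i])]
        corpus, planted = simulate_community(
            config, cond, float(latent_e[i]), float(latent_c[i]), rng_i,
            tags=sorted(cmap.entries[cond]), topology=topo)
        corpora.append(corpus)
        truth.latent_engagement[cond] = float(latent_e[i])
        truth.latent_content[cond] = float(latent_c[i])
        truth.topology[cond] = topo
        if planted:
            truth.planted_blocks[cond] = planted

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_tweets((t for c in corpora for t in c.tweets), out_dir / "tweets.jsonl")
        cmap.to_csv(out_dir / "condition_map.csv")
        truth.to_json(out_dir / "truth.json")
    return SimulationResult(corpora=corpora, condition_map=cmap, truth=truth)


def simulate_planted_partition_graph(
    n_nodes: int = 60, n_blocks: int = 2, p_in: float = 0.3, p_out: float = 0.01,
    rng: np.random.Generator | int | None = None,
) -> tuple[nx.Graph, dict[str, int]]:
    """Undirected planted-partition graph for cluster-recovery experiments."""
    rng = np.random.default_rng(rng)
    names = [f"u{i:03d}" for i in range(n_nodes)]
    labels = {names[i]: i % n_blocks for i in range(n_nodes)}
    g = nx.Graph()
    g.add_nodes_from(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = p_in if labels[names[i]] == labels[names[j]] else p_out
            if rng.random() < p:
                g.add_edge(names[i], names[j], weight=1)
    return g, labels
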