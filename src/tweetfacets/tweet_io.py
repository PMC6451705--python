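"""Reading, writing and community assignment of tweet corpora.

Tweets are exchanged as JSON Lines in the classic Twitter API v1.1 dialect
(``retweeted_status``, ``favorite_count``, ``entities`` with ``hashtags`` /
``user_mentions`` / ``urls`` / ``media``).  A hashtag->condition table (CSV
with header ``hashtag,condition``) defines the health-condition communities:
a tweet belongs to every condition whose hashtag set intersects its own.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import string
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "TweetRecord",
    "ConditionMap",
    "ConditionCorpus",
    "TweetParseError",
    "read_tweets",
    "write_tweets",
    "read_condition_map",
    "assign_conditions",
    "tokenize",
]

#: classic v1.1 timestamp, e.g. "Wed Apr 18 12:00:00 +0000 2018"
CREATED_AT_FMT = "%a %b %d %H:%M:%S %z %Y"


class TweetParseError(ValueError):
    """A JSONL line could not be parsed into a valid :class:`TweetRecord`."""


def _norm_tag(tag: str) -> str:
    return tag.lstrip("#").lower()


@dataclass
class TweetRecord:
    """One tweet with its entities, engagement counts and linkage."""

    tweet_id: str
    author_id: str
    text: str = ""
    created_at: datetime | None = None
    hashtags: list[str] = field(default_factory=list)
    mention_ids: list[str] = field(default_factory=list)
    url_count: int = 0
    media_count: int = 0
    retweet_count: int = 0
    like_count: int = 0
    author_followers: int = 0
    is_retweet: bool = False
    source_author_id: str = ""
    is_reply: bool = False
    reply_to_user_id: str = ""
    is_quote: bool = False
    quoted_author_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.tweet_id:
            raise TweetParseError("tweet_id must be non-empty")
        if not self.author_id:
            raise TweetParseError(f"tweet {self.tweet_id}: author_id must be non-empty")
        for name in ("url_count", "media_count", "retweet_count", "like_count",
                     "author_followers"):
            v = getattr(self, name)
            if v < 0:
                raise TweetParseError(f"tweet {self.tweet_id}: {name} is negative ({v})")
        if self.is_retweet and not self.source_author_id:
            raise TweetParseError(
                f"tweet {self.tweet_id}: retweet without source_author_id")
        if self.is_reply and not self.reply_to_user_id:
            raise TweetParseError(
                f"tweet {self.tweet_id}: reply without reply_to_user_id")
        if self.is_quote and not self.quoted_author_id:
            raise TweetParseError(
                f"tweet {self.tweet_id}: quote without quoted_author_id")
        self.hashtags = [_norm_tag(t) for t in self.hashtags]


def _parse_created_at(raw: str | None) -> datetime | None:
    if not raw:
        return None
    try:
        dt = datetime.strptime(raw, CREATED_AT_FMT)
    except ValueError:
        dt = datetime.fromisoformat(raw)
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def parse_tweet(obj: dict) -> TweetRecord:
    """Map one v1.1-dialect JSON object onto a :class:`TweetRecord`."""
    try:
        tweet_id = str(obj["id"])
        user = obj.get("user") or {}
        author_id = str(user.get("id", ""))
    except (KeyError, TypeError) as exc:
        raise TweetParseError(f"missing required field: {exc}") from exc
    entities = obj.get("entities") or {}
    hashtags = [_norm_tag(h["text"]) for h in entities.get("hashtags", [])]
    mentions = [str(m["id"]) for m in entities.get("user_mentions", [])]
    rt = obj.get("retweeted_status")
    reply_to = obj.get("in_reply_to_user_id")
    quoted = obj.get("quoted_status")
    return TweetRecord(
        tweet_id=tweet_id,
        author_id=author_id,
        text=obj.get("text", ""),
        created_at=_parse_created_at(obj.get("created_at")),
        hashtags=hashtags,
        mention_ids=mentions,
        url_count=len(entities.get("urls", [])),
        media_count=len(entities.get("media", [])),
        retweet_count=int(obj.get("retweet_count", 0)),
        like_count=int(obj.get("favorite_count", 0)),
        author_followers=int(user.get("followers_count", 0)),
        is_retweet=rt is not None,
        source_author_id=str(rt["user"]["id"]) if rt else "",
        is_reply=reply_to is not None,
        reply_to_user_id=str(reply_to) if reply_to is not None else "",
        is_quote=quoted is not None,
        quoted_author_id=str(quoted["user"]["id"]) if quoted else "",
    )


def tweet_to_dict(t: TweetRecord) -> dict:
    """Inverse of :func:`parse_tweet` (lossless for validated records)."""
    obj: dict = {
        "id": t.tweet_id,
        "user": {"id": t.author_id, "followers_count": t.author_followers},
        "text": t.text,
        "entities": {
            "hashtags": [{"text": h} for h in t.hashtags],
            "user_mentions": [{"id": m} for m in t.mention_ids],
            "urls": [{} for _ in range(t.url_count)],
            "media": [{} for _ in range(t.media_count)],
        },
        "retweet_count": t.retweet_count,
        "favorite_count": t.like_count,
    }
    if t.created_at is not None:
        obj["created_at"] = t.created_at.astimezone(timezone.utc).strftime(CREATED_AT_FMT)
    if t.is_retweet:
        obj["retweeted_status"] = {"user": {"id": t.source_author_id}}
    if t.is_reply:
        obj["in_reply_to_user_id"] = t.reply_to_user_id
    if t.is_quote:
        obj["quoted_status"] = {"user": {"id": t.quoted_author_id}}
    return obj


def read_tweets(path: str | Path, strict: bool = True) -> Iterator[TweetRecord]:
    """Stream validated TweetRecords from a JSONL file.

    In non-strict mode malformed lines are skipped and counted in the log;
    in strict mode the first malformed line raises :class:`TweetParseError`
    naming the line number.
    """
    path = Path(path)
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                if not isinstance(obj, dict):
                    raise TweetParseError("line is not a JSON object")
                yield parse_tweet(obj)
            except (json.JSONDecodeError, TweetParseError, KeyError, TypeError,
                    ValueError) as exc:
                if strict:
                    raise TweetParseError(f"{path}:{lineno}: {exc}") from exc
                skipped += 1
    if skipped:
        logger.warning("%s: skipped %d malformed line(s)", path, skipped)


def write_tweets(tweets: Iterable[TweetRecord], path: str | Path) -> int:
    """Write records as JSONL in the v1.1 dialect; returns the line count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps(tweet_to_dict(t), sort_keys=True))
            fh.write("\n")
            n += 1
    return n


@dataclass
class ConditionMap:
    """Mapping condition name -> set of (lowercase, '#'-free) hashtags."""

    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        for cond, tags in self.entries.items():
            if not tags:
                raise ValueError(f"condition {cond!r} has an empty hashtag set")
            self.entries[cond] = {_norm_tag(t) for t in tags}

    @property
    def conditions(self) -> list[str]:
        return sorted(self.entries)

    def hashtag_index(self) -> dict[str, list[str]]:
        """Inverse index hashtag -> sorted list of conditions using it."""
        index: dict[str, list[str]] = {}
        for cond in self.conditions:
            for tag in self.entries[cond]:
                index.setdefault(tag, []).append(cond)
        for conds in index.values():
            conds.sort()
        return index

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["hashtag", "condition"])
            for cond in self.conditions:
                for tag in sorted(self.entries[cond]):
                    w.writerow([tag, cond])


def read_condition_map(path: str | Path) -> ConditionMap:
    """Read a ``hashtag,condition`` CSV into a :class:`ConditionMap`.

    Duplicate (hashtag, condition) rows collapse; a hashtag claimed by two
    conditions is kept in both with a warning (a tweet carrying it will then
    count in both communities).
    """
    entries: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"hashtag", "condition"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header columns hashtag,condition")
        for row in reader:
            tag = _norm_tag(row["hashtag"].strip())
            cond = row["condition"].strip()
            if not tag or not cond:
                continue
            if tag in seen and seen[tag] != cond:
                logger.warning("hashtag #%s mapped to both %r and %r; keeping both",
                               tag, seen[tag], cond)
            seen.setdefault(tag, cond)
            entries.setdefault(cond, set()).add(tag)
    return ConditionMap(entries=entries)


@dataclass
class ConditionCorpus:
    """All tweets assigned to one health-condition community."""

    condition: str
    tweets: list[TweetRecord]

    def __len__(self) -> int:
        return len(self.tweets)


def assign_conditions(
    tweets: Iterable[TweetRecord], cmap: ConditionMap
) -> tuple[list[ConditionCorpus], int]:
    """Assign each tweet to every condition whose hashtags it carries.

    Returns (corpora sorted by condition name, number of dropped tweets).
    Tweets matching no condition are dropped and counted.
    """
    if not cmap.entries:
        raise ValueError("condition map is empty")
    index = cmap.hashtag_index()
    buckets: dict[str, list[TweetRecord]] = {}
    dropped = 0
    for t in tweets:
        matched: list[str] = []
        for tag in t.hashtags:
            matched.extend(index.get(tag, ()))
        if not matched:
            dropped += 1
            continue
        for cond in sorted(set(matched)):
            buckets.setdefault(cond, []).append(t)
    if dropped:
        logger.info("assign_conditions: dropped %d tweet(s) matching no condition", dropped)
    corpora = [ConditionCorpus(condition=c, tweets=buckets[c]) for c in sorted(buckets)]
    return corpora, dropped


_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)


def tokenize(text: str) -> list[str]:
    """Word tokens: lowercase, URLs removed, whitespace split, edge punctuation stripped."""
    cleaned = _URL_RE.sub(" ", text).lower()
    tokens = (tok.strip(string.punctuation) for tok in cleaned.split())
    return [tok for tok in tokens if tok]
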