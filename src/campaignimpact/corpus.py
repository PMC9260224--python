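"""The post record and JSON Lines corpus I/O.

A corpus is a UTF-8 JSONL file, one post object per line, with ISO-8601 UTC
timestamps under ``created_at``.  This is the interchange format every other
stage reads and writes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone, date
from pathlib import Path
from typing import Iterable, Iterator

from .errors import CorpusFormatError

#: JSONL fields that must be present on every line.
REQUIRED_FIELDS = (
    "id",
    "user_id",
    "created_at",
    "text",
    "is_retweet",
    "retweet_count",
    "like_count",
    "follower_count",
    "display_name",
)


@dataclass(frozen=True)
class Post:
    """One social-media message with authorship, timing, text and engagement."""

    post_id: str
    user_id: str
    timestamp: datetime  # timezone-aware UTC
    text: str
    is_retweet: bool
    retweeted_user_id: str | None
    retweet_count: int
    like_count: int
    follower_count: int
    display_name: str

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            object.__setattr__(self, "timestamp", self.timestamp.replace(tzinfo=timezone.utc))
        for field in ("retweet_count", "like_count", "follower_count"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0, got {getattr(self, field)}")

    @property
    def date(self) -> date:
        """Calendar date in UTC, the unit used for day-level windows."""
        return self.timestamp.astimezone(timezone.utc).date()

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["id"] = rec.pop("post_id")
        rec["created_at"] = rec.pop("timestamp").strftime("%Y-%m-%dT%H:%M:%S+00:00")
        if rec["retweeted_user_id"] is None:
            del rec["retweeted_user_id"]
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Post":
        missing = [f for f in REQUIRED_FIELDS if f not in rec]
        if missing:
            raise KeyError(f"missing fields: {missing}")
        ts = rec["created_at"]
        if isinstance(ts, str):
            ts = datetime.fromisoformat(ts.replace("Z", "+00:00"))
        return cls(
            post_id=str(rec["id"]),
            user_id=str(rec["user_id"]),
            timestamp=ts,
            text=str(rec["text"]),
            is_retweet=bool(rec["is_retweet"]),
            retweeted_user_id=(None if rec.get("retweeted_user_id") in (None, "")
                               else str(rec["retweeted_user_id"])),
            retweet_count=int(rec["retweet_count"]),
            like_count=int(rec["like_count"]),
            follower_count=int(rec["follower_count"]),
            display_name=str(rec["display_name"]),
        )


def write_jsonl(posts: Iterable[Post], path: str | Path) -> int:
    """Write posts as JSONL; returns the number of lines written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_record(), ensure_ascii=False, sort_keys=True))
            fh.write("\n")
            n += 1
    return n


def read_jsonl(path: str | Path) -> list[Post]:
    """Read a JSONL corpus, raising on any malformed line."""
    posts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                posts.append(Post.from_record(json.loads(line)))
            except (ValueError, KeyError, TypeError) as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
    return posts


def iter_jsonl_lenient(path: str | Path) -> Iterator[tuple[int, Post | None, str | None]]:
    """Yield (lineno, post-or-None, error-or-None) per line, never raising."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield lineno, Post.from_record(json.loads(line)), None
            except (ValueError, KeyError, TypeError) as exc:
                yield lineno, None, str(exc)
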