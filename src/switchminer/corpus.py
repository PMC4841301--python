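"""Post records and line-delimited corpus I/O.

A corpus is a JSONL file, one post per line, UTF-8, with fields
``post_id``, ``platform``, ``timestamp`` (ISO-8601, UTC), ``author_key``,
``text`` and optional self-declared ``declared_*`` fields (e.g.
``declared_location``, ``declared_sex``, ``declared_age``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

PLATFORMS = ("twitter", "facebook", "forum", "blog")


class CorpusFormatError(ValueError):
    """Raised on a malformed corpus line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class Post:
    """One social-media data point (a unique post on a specific platform)."""

    post_id: str
    platform: str
    timestamp: datetime
    author_key: str
    text: str
    declared: dict[str, str] = field(default_factory=dict)

    def month(self) -> str:
        """Calendar month of the post in UTC, as ``YYYY-MM``."""
        ts = self.timestamp.astimezone(timezone.utc)
        return f"{ts.year:04d}-{ts.month:02d}"

    def to_record(self) -> dict:
        rec = {
            "post_id": self.post_id,
            "platform": self.platform,
            "timestamp": self.timestamp.astimezone(timezone.utc).isoformat().replace("+00:00", "Z"),
            "author_key": self.author_key,
            "text": self.text,
        }
        for k in sorted(self.declared):
            rec[f"declared_{k}"] = self.declared[k]
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Post":
        ts = rec["timestamp"]
        if ts.endswith("Z"):
            ts = ts[:-1] + "+00:00"
        stamp = datetime.fromisoformat(ts)
        if stamp.tzinfo is None:
            stamp = stamp.replace(tzinfo=timezone.utc)
        declared = {
            k[len("declared_"):]: v for k, v in rec.items() if k.startswith("declared_")
        }
        return cls(
            post_id=rec["post_id"],
            platform=rec["platform"],
            timestamp=stamp,
            author_key=rec["author_key"],
            text=rec["text"],
            declared=declared,
        )


def corpus_to_jsonl(posts: list[Post], path: str | Path) -> None:
    """Write posts as JSONL (UTF-8, sorted keys, one record per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            fh.write(json.dumps(p.to_record(), sort_keys=True, ensure_ascii=False))
            fh.write("\n")


def read_corpus(path: str | Path) -> list[Post]:
    """Read a JSONL corpus; a malformed line raises CorpusFormatError naming it."""
    posts: list[Post] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                posts.append(Post.from_record(rec))
            except (json.JSONDecodeError, KeyError, ValueError) as exc:
                raise CorpusFormatError(lineno, str(exc)) from exc
    return posts
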