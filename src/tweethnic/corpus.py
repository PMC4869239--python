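"""Core data types and I/O for tweet corpora.

The unit of analysis throughout the package is the *timeline*: the
chronologically ordered collection of tweets posted by one user over the
study window, aggregated into a single writing record.  Tweets are
exchanged as line-delimited JSON (one object per line, UTF-8) with the
fields ``tweet_id``, ``user_id``, ``created_at``, ``text``,
``user_location``, ``latitude``, ``longitude`` and ``lang``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Group",
    "Provenance",
    "EthnicityLabel",
    "TweetRecord",
    "Timeline",
    "STUDY_WINDOW",
    "read_tweets",
    "write_tweets",
    "build_timelines",
    "partition_by_month",
    "write_labels",
    "read_labels",
]

MAX_TWEET_CHARS = 140


class Group(str, Enum):
    """The four enumerated race/ethnicity keys."""

    CAUCASIAN = "Caucasian"
    AFRICAN_AMERICAN = "AfricanAmerican"
    ASIAN = "Asian"
    HISPANIC = "Hispanic"


class Provenance(str, Enum):
    """How a label was obtained."""

    SELF_DECLARED = "self_declared"
    PREDICTED = "predicted"
    GROUND_TRUTH_SYNTHETIC = "ground_truth_synthetic"


@dataclass(frozen=True)
class EthnicityLabel:
    group: Group
    provenance: Provenance

    def __post_init__(self) -> None:
        if not isinstance(self.group, Group):
            object.__setattr__(self, "group", Group(self.group))
        if not isinstance(self.provenance, Provenance):
            object.__setattr__(self, "provenance", Provenance(self.provenance))


@dataclass(frozen=True)
class TweetRecord:
    """One tweet: at most 140 characters of text plus metadata."""

    tweet_id: str
    user_id: str
    created_at: datetime
    text: str
    user_location: str = ""
    latitude: float | None = None
    longitude: float | None = None
    lang: str | None = None

    def __post_init__(self) -> None:
        if len(self.text) > MAX_TWEET_CHARS:
            raise ValueError(
                f"tweet {self.tweet_id!r} has {len(self.text)} characters "
                f"(limit {MAX_TWEET_CHARS})"
            )
        if self.created_at.tzinfo is None:
            object.__setattr__(
                self, "created_at", self.created_at.replace(tzinfo=timezone.utc)
            )

    @property
    def month(self) -> tuple[int, int]:
        """UTC calendar month ``(year, month)`` the tweet falls in."""
        utc = self.created_at.astimezone(timezone.utc)
        return (utc.year, utc.month)

    def to_json(self) -> dict:
        d = {
            "tweet_id": self.tweet_id,
            "user_id": self.user_id,
            "created_at": self.created_at.astimezone(timezone.utc).isoformat(),
            "text": self.text,
            "user_location": self.user_location,
        }
        if self.latitude is not None:
            d["latitude"] = self.latitude
        if self.longitude is not None:
            d["longitude"] = self.longitude
        if self.lang is not None:
            d["lang"] = self.lang
        return d

    @classmethod
    def from_json(cls, obj: dict) -> "TweetRecord":
        for key in ("tweet_id", "user_id", "created_at", "text"):
            if key not in obj:
                raise KeyError(f"missing mandatory field {key!r}")
        created = obj["created_at"]
        if isinstance(created, str):
            created = datetime.fromisoformat(created.replace("Z", "+00:00"))
        return cls(
            tweet_id=str(obj["tweet_id"]),
            user_id=str(obj["user_id"]),
            created_at=created,
            text=obj["text"],
            user_location=obj.get("user_location", "") or "",
            latitude=obj.get("latitude"),
            longitude=obj.get("longitude"),
            lang=obj.get("lang"),
        )


# The nine-month study window: April 2014 - January 2015 with June 2014
# absent (the original collection lost mid-May through late July; May and
# July are partial months, June is missing entirely).
STUDY_WINDOW: tuple[tuple[int, int], ...] = (
    (2014, 4),
    (2014, 5),
    (2014, 7),
    (2014, 8),
    (2014, 9),
    (2014, 10),
    (2014, 11),
    (2014, 12),
    (2015, 1),
)


def _sort_key(t: TweetRecord) -> tuple:
    # chronological, tweet_id lexicographic as a deterministic tie-break
    return (t.created_at, t.tweet_id)


@dataclass
class Timeline:
    """Per-user aggregate of retained tweets.

    ``aggregate_text`` joins the tweet texts with a single space so that
    tokens from adjacent tweets never merge; its length is therefore the
    sum of tweet lengths plus (n - 1) separator characters.
    """

    user_id: str
    tweets: list[TweetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tweets = sorted(self.tweets, key=_sort_key)

    @property
    def aggregate_text(self) -> str:
        return " ".join(t.text for t in self.tweets)

    @property
    def texts(self) -> list[str]:
        return [t.text for t in self.tweets]

    def __len__(self) -> int:
        return len(self.tweets)

    def monthly_slices(
        self, window: Sequence[tuple[int, int]] = STUDY_WINDOW
    ) -> dict[tuple[int, int], list[TweetRecord]]:
        slices, _ = partition_by_month(self, window)
        return slices


def read_tweets(
    path: str | Path, strict: bool = False
) -> tuple[list[TweetRecord], int]:
    """Read a JSONL tweet file.

    Returns ``(records, n_skipped)``.  In lenient mode (default) malformed
    lines are counted and skipped; in strict mode the first malformed line
    raises ``ValueError`` with the offending line number.
    """
    path = Path(path)
    records: list[TweetRecord] = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(TweetRecord.from_json(json.loads(line)))
            except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
                if strict:
                    raise ValueError(f"line {lineno}: {exc}") from exc
                skipped += 1
    return records, skipped


def write_tweets(tweets: Iterable[TweetRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps(t.to_json(), ensure_ascii=False) + "\n")


def build_timelines(tweets: Iterable[TweetRecord]) -> list[Timeline]:
    """Group tweets by user id into chronologically sorted timelines.

    The tweet multiset is preserved: timeline sizes sum to the input size.
    Timelines are returned sorted by user_id for determinism.
    """
    by_user: dict[str, list[TweetRecord]] = {}
    for t in tweets:
        by_user.setdefault(t.user_id, []).append(t)
    return [Timeline(user_id=u, tweets=ts) for u, ts in sorted(by_user.items())]


def partition_by_month(
    timeline: Timeline, window: Sequence[tuple[int, int]] = STUDY_WINDOW
) -> tuple[dict[tuple[int, int], list[TweetRecord]], int]:
    """Assign each tweet to its UTC calendar month within *window*.

    Returns ``(slices, n_excluded)`` where *slices* maps each window month
    to the tweets posted in it and *n_excluded* counts tweets falling
    outside the window (e.g. June 2014, which the study window omits).
    """
    if not window:
        raise ValueError("study window must contain at least one month")
    window_set = set(window)
    slices: dict[tuple[int, int], list[TweetRecord]] = {m: [] for m in window}
    excluded = 0
    for t in timeline.tweets:
        m = t.month
        if m in window_set:
            slices[m].append(t)
        else:
            excluded += 1
    return slices, excluded


def write_labels(labels: dict[str, EthnicityLabel], path: str | Path) -> None:
    """Write a user_id -> group CSV (columns: user_id, group, provenance)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["user_id", "group", "provenance"])
        for user_id in sorted(labels):
            lab = labels[user_id]
            w.writerow([user_id, lab.group.value, lab.provenance.value])


def read_labels(path: str | Path) -> dict[str, EthnicityLabel]:
    labels: dict[str, EthnicityLabel] = {}
    with Path(path).open("r", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            labels[row["user_id"]] = EthnicityLabel(
                Group(row["group"]), Provenance(row["provenance"])
            )
    return labels
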