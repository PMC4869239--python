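"""Corpus cleaning cascade.

Tweets carrying non-language linking elements (URLs, @-mentions, retweet
markers) are removed whole — the linked content, not the words, carries
the information, so such tweets contribute noise to a lexical classifier.
After per-tweet removal, timelines whose cleaned aggregate text is shorter
than 85 characters are dropped (too little text to classify), then users
with a non-US profile location, then non-English users.  Every stage
reports an audit count and the cascade is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .corpus import Timeline, TweetRecord

__all__ = [
    "DropPattern",
    "DEFAULT_DROP_PATTERNS",
    "DEFAULT_US_GAZETTEER",
    "PreprocessConfig",
    "should_drop_tweet",
    "is_us_location",
    "is_english",
    "filter_corpus",
]


@dataclass(frozen=True)
class DropPattern:
    name: str
    regex: re.Pattern

    def matches(self, text: str) -> bool:
        return self.regex.search(text) is not None


# URL pattern covers scheme-ful URLs, bare shortener hosts and bare
# domain.tld tokens ("cnn.com" carries no scheme); mention is "@" plus at
# least one word character; retweet marker is a leading "RT" before a
# mention.
DEFAULT_DROP_PATTERNS: tuple[DropPattern, ...] = (
    DropPattern(
        "retweet",
        re.compile(r"(?:^|\s)RT\s+@\w+", re.IGNORECASE),
    ),
    DropPattern("mention", re.compile(r"@\w+")),
    DropPattern(
        "url",
        re.compile(
            r"(?:https?://\S+"
            r"|www\.\S+"
            r"|\b[a-z0-9-]+\.(?:com|org|net|edu|gov|co|io|ly|me|tv)"
            r"(?:/\S*)?)",
            re.IGNORECASE,
        ),
    ),
)

_US_STATES = """alabama alaska arizona arkansas california colorado
connecticut delaware florida georgia hawaii idaho illinois indiana iowa
kansas kentucky louisiana maine maryland massachusetts michigan minnesota
mississippi missouri montana nebraska nevada ohio oklahoma oregon
pennsylvania tennessee texas utah vermont virginia washington wisconsin
wyoming""".split()

_US_STATE_ABBREVS = """AL AK AZ AR CA CO CT DE FL GA HI ID IL IN IA KS KY
LA ME MD MA MI MN MS MO MT NE NV NH NJ NM NY NC ND OH OK OR PA RI SC SD
TN TX UT VT VA WA WV WI WY DC""".split()

_US_CITIES = [
    "new york", "new york city", "nyc", "los angeles", "chicago", "houston",
    "philadelphia", "phoenix", "san antonio", "san diego", "dallas",
    "san francisco", "austin", "seattle", "denver", "boston", "atlanta",
    "miami", "detroit", "baltimore", "memphis", "nashville", "portland",
    "las vegas", "new orleans", "cleveland", "pittsburgh", "saint louis",
    "st louis", "st. louis", "minneapolis", "tampa", "brooklyn", "bronx",
    "queens", "manhattan", "new hampshire", "new jersey", "new mexico",
    "north carolina", "north dakota", "rhode island", "south carolina",
    "south dakota", "west virginia",
]

DEFAULT_US_GAZETTEER: frozenset[str] = frozenset(
    ["usa", "u.s.a", "u.s.a.", "u.s.", "us", "united states",
     "united states of america", "america"]
    + _US_STATES
    + [a.lower() for a in _US_STATE_ABBREVS]
    + _US_CITIES
)


@dataclass
class PreprocessConfig:
    min_timeline_chars: int = 85
    drop_patterns: Sequence[DropPattern] = DEFAULT_DROP_PATTERNS
    us_gazetteer: frozenset[str] = DEFAULT_US_GAZETTEER
    us_only: bool = True
    english_only: bool = True
    keep_empty_location: bool = True
    english_detector: Callable[[Timeline], bool] | None = None

    def __post_init__(self) -> None:
        if self.min_timeline_chars < 0:
            raise ValueError("min_timeline_chars must be >= 0")


def should_drop_tweet(
    text: str,
    drop_patterns: Sequence[DropPattern] = DEFAULT_DROP_PATTERNS,
) -> tuple[bool, str | None]:
    """Whether a tweet carries a linking element, and which pattern hit.

    The whole tweet is discarded when any pattern matches; patterns are
    checked in order and the first match is reported.
    """
    for p in drop_patterns:
        if p.matches(text):
            return True, p.name
    return False, None


def is_us_location(
    location: str,
    gazetteer: frozenset[str] = DEFAULT_US_GAZETTEER,
    keep_empty: bool = True,
) -> bool:
    """Case-insensitive gazetteer match on the free-text profile location.

    The location is split on commas and word boundaries and matched
    against state names, abbreviations, country designators and major
    cities.  An empty location is retained by default: only *non-US*
    locations are excluded.
    """
    loc = location.strip().lower()
    if not loc:
        return keep_empty
    parts = [p.strip() for p in loc.split(",")]
    for part in parts:
        if part in gazetteer:
            return True
    for token in re.findall(r"[a-z.]+", loc):
        if token in gazetteer:
            return True
    # multi-word city/state names inside a longer string
    for entry in gazetteer:
        if " " in entry and re.search(rf"\b{re.escape(entry)}\b", loc):
            return True
    return False


_ASCII_LETTER_RE = re.compile(r"[a-zA-Z]")
_NON_ASCII_RE = re.compile(r"[^\x00-\x7f]")


def is_english(
    timeline: Timeline,
    detector: Callable[[Timeline], bool] | None = None,
) -> bool:
    """English gate: metadata language tags when present, else heuristic.

    A majority of tweets tagged ``en`` (or an ``en-*`` variant) passes;
    any other majority tag fails.  With no tags at all the fallback
    accepts timelines whose text is dominated by ASCII letters — adequate
    for the synthetic corpora this package is exercised on, and pluggable
    for anything better.
    """
    if detector is not None:
        return detector(timeline)
    tags = [t.lang for t in timeline.tweets if t.lang]
    if tags:
        n_en = sum(1 for t in tags if t.split("-")[0].lower() == "en")
        return n_en * 2 >= len(tags) and n_en > 0
    text = timeline.aggregate_text
    if not text:
        return False
    n_ascii = len(_ASCII_LETTER_RE.findall(text))
    n_non = len(_NON_ASCII_RE.findall(text))
    return n_ascii > 0 and n_non <= 0.2 * n_ascii


def filter_corpus(
    timelines: Iterable[Timeline],
    config: PreprocessConfig | None = None,
) -> tuple[list[Timeline], dict[str, int]]:
    """Run the cleaning cascade; return retained timelines + audit counts.

    Stage order: (1) per-tweet drop-pattern removal, (2) aggregate text
    rebuilt, (3) timelines shorter than ``min_timeline_chars`` dropped
    (strictly-less: an aggregate of exactly the threshold is retained),
    (4) non-US profile locations dropped, (5) non-English dropped.

    Audit counts conserve the input: ``tweets_in == tweets_retained +
    tweets_dropped_pattern + tweets_in_dropped_timelines``.
    """
    if config is None:
        config = PreprocessConfig()
    timelines = list(timelines)
    audit: dict[str, int] = {
        "tweets_in": sum(len(t) for t in timelines),
        "timelines_in": len(timelines),
        "tweets_dropped_pattern": 0,
        "timelines_dropped_short": 0,
        "timelines_dropped_non_us": 0,
        "timelines_dropped_non_english": 0,
        "tweets_in_dropped_timelines": 0,
    }
    retained: list[Timeline] = []
    for tl in timelines:
        kept_tweets: list[TweetRecord] = []
        for tw in tl.tweets:
            drop, _ = should_drop_tweet(tw.text, config.drop_patterns)
            if drop:
                audit["tweets_dropped_pattern"] += 1
            else:
                kept_tweets.append(tw)
        cleaned = Timeline(user_id=tl.user_id, tweets=kept_tweets)
        if len(cleaned.aggregate_text) < config.min_timeline_chars:
            audit["timelines_dropped_short"] += 1
            audit["tweets_in_dropped_timelines"] += len(cleaned)
            continue
        if config.us_only:
            locations = {tw.user_location for tw in cleaned.tweets}
            loc = max(locations, key=len) if locations else ""
            if not is_us_location(
                loc, config.us_gazetteer, keep_empty=config.keep_empty_location
            ):
                audit["timelines_dropped_non_us"] += 1
                audit["tweets_in_dropped_timelines"] += len(cleaned)
                continue
        if config.english_only and not is_english(
            cleaned, config.english_detector
        ):
            audit["timelines_dropped_non_english"] += 1
            audit["tweets_in_dropped_timelines"] += len(cleaned)
            continue
        retained.append(cleaned)
    audit["tweets_retained"] = sum(len(t) for t in retained)
    audit["timelines_retained"] = len(retained)
    return retained, audit
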