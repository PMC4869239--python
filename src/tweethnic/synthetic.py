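"""Synthetic tweet-corpus generator with known ground truth.

The generator emulates the statistical shape of the corpus the pipeline
is designed for — four ethnic groups with group-conditional unigram
vocabulary signatures, sparse first-person self-declarations, short
tweets aggregating to timelines of a few hundred characters, URL /
mention / retweet noise, US and non-US profile locations, and
month-dependent cancer-term injection with awareness-month spikes — while
emitting a ground-truth label for every user.  Group vocabulary
signatures are arbitrary neutral token sets (tree, bird, colour,
instrument, landform and verse-form words), not a model of any group's
actual language; each signature concept has three interchangeable
surface variants linked in the bundled synonym lexicon, and every user
adopts one variant per concept, which is exactly the lexical-variation
regime synonym expansion is designed to bridge.

Fixed seed implies byte-identical output.
"""

from __future__ import annotations

import calendar
import copy
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np

from .corpus import (
    STUDY_WINDOW,
    EthnicityLabel,
    Group,
    Provenance,
    TweetRecord,
)
from .labeling import DEFAULT_TEMPLATES
from .surveillance import AWARENESS_MONTHS, CATEGORIES, default_lexicons

__all__ = [
    "SyntheticCorpusConfig",
    "default_injection",
    "generate_corpus",
    "inject_awareness_spike",
]

# Shared (group-neutral) vocabulary with Zipf-flavoured base weights.
_SHARED_VOCAB: tuple[tuple[str, float], ...] = tuple(
    (w, 1.0 / (i + 1))
    for i, w in enumerate(
        """the to and a of in is it you that for on my me with this so be
        at we was have but not all just like get love day today good time
        going now new one out up about happy life night work home back
        see know think really when what your from they them feel made
        morning coffee weekend friend music game show great best little
        never always still want need right sure thing people year week
        over after before again maybe ready waiting done start
        """.split()
    )
)

# Per-group signature concepts: three interchangeable surface variants
# each, cross-linked in the bundled synthetic synonym lexicon.
_SIGNATURES: dict[Group, tuple[tuple[str, ...], ...]] = {
    Group.CAUCASIAN: (
        ("maple", "birch", "aspen"),
        ("falcon", "hawk", "kestrel"),
        ("copper", "bronze", "brass"),
        ("violin", "fiddle", "viola"),
        ("glacier", "iceberg", "floe"),
        ("sonnet", "haiku", "limerick"),
    ),
    Group.AFRICAN_AMERICAN: (
        ("cedar", "spruce", "juniper"),
        ("heron", "egret", "crane"),
        ("cobalt", "indigo", "azure"),
        ("trumpet", "cornet", "bugle"),
        ("canyon", "ravine", "gorge"),
        ("ballad", "anthem", "chorus"),
    ),
    Group.ASIAN: (
        ("willow", "poplar", "sycamore"),
        ("sparrow", "finch", "wren"),
        ("crimson", "scarlet", "vermilion"),
        ("flute", "piccolo", "fife"),
        ("lagoon", "estuary", "inlet"),
        ("fable", "parable", "allegory"),
    ),
    Group.HISPANIC: (
        ("cypress", "sequoia", "redwood"),
        ("pelican", "gannet", "cormorant"),
        ("amber", "ochre", "sienna"),
        ("cello", "contrabass", "doublebass"),
        ("mesa", "plateau", "butte"),
        ("riddle", "proverb", "maxim"),
    ),
}

_US_LOCATIONS = (
    "New York, NY", "Los Angeles, CA", "Chicago, IL", "Houston, TX",
    "Atlanta, GA", "Philadelphia, PA", "Seattle, WA", "Boston, MA",
    "Miami, FL", "Denver, CO", "Texas", "California", "Brooklyn",
)
_NON_US_LOCATIONS = (
    "London, UK", "Toronto, Canada", "Paris, France", "Sydney, Australia",
    "Lagos, Nigeria", "Mumbai, India", "Berlin, Germany",
)

# Baseline per-user expected mention counts per month, by category and
# group.  The two majority groups differ (the general vocabulary runs
# higher among African-American users, the breast bigram higher among
# Caucasian users); colorectal is rare throughout.
_BASE_RATES: dict[str, dict[Group, float]] = {
    "general_cancer": {
        Group.CAUCASIAN: 0.08, Group.AFRICAN_AMERICAN: 0.10,
        Group.ASIAN: 0.08, Group.HISPANIC: 0.08,
    },
    "breast": {
        Group.CAUCASIAN: 0.025, Group.AFRICAN_AMERICAN: 0.015,
        Group.ASIAN: 0.02, Group.HISPANIC: 0.02,
    },
    "colorectal": {g: 0.003 for g in Group},
    "lung": {g: 0.012 for g in Group},
    "prostate": {g: 0.012 for g in Group},
}

# Awareness-month spike multiplier and month-after retention factors
# (fraction of baseline remaining the month after the campaign; the
# steeper minority-group fall mirrors the post-campaign participation
# drops the method was built to measure).
_SPIKE_MULTIPLIER = 3.0
_POST_CAMPAIGN_RETENTION: dict[str, dict[Group, float]] = {
    "breast": {
        Group.CAUCASIAN: 0.53, Group.AFRICAN_AMERICAN: 0.27,
        Group.ASIAN: 0.5, Group.HISPANIC: 0.5,
    },
    "lung": {
        Group.CAUCASIAN: 0.75, Group.AFRICAN_AMERICAN: 0.50,
        Group.ASIAN: 0.6, Group.HISPANIC: 0.6,
    },
    "prostate": {g: 0.8 for g in Group},
}


def default_injection(
    window: Sequence[tuple[int, int]] = STUDY_WINDOW,
    base_rates: Mapping[str, Mapping[Group, float]] | None = None,
    seasonal: bool = True,
) -> dict[tuple[int, int], dict[str, dict[str, float]]]:
    """Month -> group -> category expected per-user mention counts.

    With ``seasonal=True`` each site-specific category is multiplied in
    its awareness month and damped in the following month; with
    ``seasonal=False`` rates are flat (the null configuration for
    significance-test calibration uses flat *and equal-across-group*
    rates instead, see tests).
    """
    if base_rates is None:
        base_rates = _BASE_RATES
    window = list(window)
    table: dict[tuple[int, int], dict[str, dict[str, float]]] = {}
    for m in window:
        table[m] = {}
        for g in Group:
            table[m][g.value] = {}
            for cat in CATEGORIES:
                rate = float(base_rates[cat][g])
                if seasonal and cat in AWARENESS_MONTHS:
                    campaign = AWARENESS_MONTHS[cat]
                    idx = window.index(campaign)
                    if m == campaign:
                        rate *= _SPIKE_MULTIPLIER
                    elif idx + 1 < len(window) and m == window[idx + 1]:
                        rate *= _POST_CAMPAIGN_RETENTION[cat][g]
                table[m][g.value][cat] = rate
    return table


_DEFAULT_PROPORTIONS = {
    Group.CAUCASIAN: 0.9232,
    Group.AFRICAN_AMERICAN: 0.0712,
    Group.ASIAN: 0.0028,
    Group.HISPANIC: 0.0028,
}


@dataclass
class SyntheticCorpusConfig:
    """All knobs of the generator; defaults are the study conditions.

    ``group_proportions`` default to the stream population shares
    (92.32 / 7.12 / 0.28 / 0.28 percent); classification experiments
    override them with the labeled-set shares.  Timeline-length defaults
    are calibrated so the mean cleaned aggregate is about 324 characters.
    """

    n_users: int = 500
    group_proportions: Mapping[Group, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    signature_strength: float = 0.7
    declaration_rate: float | Mapping[Group, float] = 0.05
    tweets_per_user_lam: float = 7.0
    tweets_per_user_min: int = 2
    tokens_per_tweet_lam: float = 5.0
    tokens_per_tweet_min: int = 2
    noise_rates: Mapping[str, float] = field(
        default_factory=lambda: {"url": 0.10, "mention": 0.08, "retweet": 0.05}
    )
    non_us_location_rate: float = 0.05
    cancer_injection: Mapping | None = None  # None -> default_injection()
    window: Sequence[tuple[int, int]] = STUDY_WINDOW
    shared_vocab: Sequence[tuple[str, float]] = _SHARED_VOCAB
    signature_vocab: Mapping[Group, Sequence[Sequence[str]]] = field(
        default_factory=lambda: dict(_SIGNATURES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"group_proportions must sum to 1 (got {total})"
            )
        rates = [self.non_us_location_rate, self.signature_strength]
        rates += list(self.noise_rates.values())
        if isinstance(self.declaration_rate, Mapping):
            rates += list(self.declaration_rate.values())
        else:
            rates.append(self.declaration_rate)
        for r in rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.n_users <= 0:
            raise ValueError("n_users must be positive")

    def declaration_rate_for(self, group: Group) -> float:
        if isinstance(self.declaration_rate, Mapping):
            return float(self.declaration_rate[group])
        return float(self.declaration_rate)


def inject_awareness_spike(
    config: SyntheticCorpusConfig,
    month: tuple[int, int],
    category: str,
    multiplier: float,
) -> SyntheticCorpusConfig:
    """Return a config whose injection for *month*/*category* is scaled
    by *multiplier* for every group; every other cell is unchanged."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if tuple(month) not in {tuple(m) for m in config.window}:
        raise ValueError(f"month {month} outside the window")
    injection = copy.deepcopy(
        config.cancer_injection
        if config.cancer_injection is not None
        else default_injection(config.window)
    )
    month = tuple(month)
    for g in injection[month]:
        injection[month][g][category] = (
            injection[month][g][category] * multiplier
        )
    return replace(config, cancer_injection=injection)


def _random_instant(
    rng: np.random.Generator, month: tuple[int, int]
) -> datetime:
    year, mon = month
    n_days = calendar.monthrange(year, mon)[1]
    sec = int(rng.integers(0, n_days * 86400))
    day, rem = divmod(sec, 86400)
    hour, rem = divmod(rem, 3600)
    minute, second = divmod(rem, 60)
    return datetime(year, mon, day + 1, hour, minute, second, tzinfo=timezone.utc)


def _truncate(text: str, limit: int = 140) -> str:
    return text if len(text) <= limit else text[:limit].rstrip()


def generate_corpus(
    config: SyntheticCorpusConfig | None = None,
) -> tuple[list[TweetRecord], dict[str, EthnicityLabel]]:
    """Draw a corpus and its ground-truth labels from the config.

    Per user: a group from ``group_proportions``, a US or non-US profile
    location, one adopted surface variant per signature concept, a
    Poisson number of tweets whose tokens mix the shared vocabulary with
    the user's signature variants at ``signature_strength``, optional
    noise elements, at most one verbatim self-declaration, and Poisson
    cancer-phrase tweets per month/category at the configured injection
    rates.  All tweets are clipped to 140 characters.
    """
    if config is None:
        config = SyntheticCorpusConfig()
    rng = np.random.default_rng(config.seed)
    groups = list(Group)
    probs = np.array([config.group_proportions.get(g, 0.0) for g in groups])
    shared_words = [w for w, _ in config.shared_vocab]
    shared_p = np.array([f for _, f in config.shared_vocab])
    shared_p = shared_p / shared_p.sum()
    injection = (
        config.cancer_injection
        if config.cancer_injection is not None
        else default_injection(config.window)
    )
    lexicons = default_lexicons()
    templates_by_group = {
        g: [t for t in DEFAULT_TEMPLATES if t.target_group is g]
        for g in groups
    }
    window = [tuple(m) for m in config.window]

    tweets: list[TweetRecord] = []
    labels: dict[str, EthnicityLabel] = {}
    for i in range(config.n_users):
        uid = f"u{i:06d}"
        group = groups[rng.choice(len(groups), p=probs)]
        labels[uid] = EthnicityLabel(group, Provenance.GROUND_TRUTH_SYNTHETIC)
        if rng.random() < config.non_us_location_rate:
            location = _NON_US_LOCATIONS[
                int(rng.integers(len(_NON_US_LOCATIONS)))
            ]
        else:
            location = _US_LOCATIONS[int(rng.integers(len(_US_LOCATIONS)))]
        concepts = config.signature_vocab[group]
        idiolect = [
            variants[int(rng.integers(len(variants)))]
            for variants in concepts
        ]
        serial = 0

        def emit(text: str, month: tuple[int, int]) -> None:
            nonlocal serial
            tweets.append(
                TweetRecord(
                    tweet_id=f"t{i:06d}_{serial:04d}",
                    user_id=uid,
                    created_at=_random_instant(rng, month),
                    text=_truncate(text),
                    user_location=location,
                    lang="en",
                )
            )
            serial += 1

        n_tweets = config.tweets_per_user_min + int(
            rng.poisson(config.tweets_per_user_lam)
        )
        for _ in range(n_tweets):
            month = window[int(rng.integers(len(window)))]
            n_tok = config.tokens_per_tweet_min + int(
                rng.poisson(config.tokens_per_tweet_lam)
            )
            toks = []
            for _ in range(n_tok):
                if idiolect and rng.random() < config.signature_strength:
                    toks.append(idiolect[int(rng.integers(len(idiolect)))])
                else:
                    toks.append(
                        shared_words[int(rng.choice(len(shared_words), p=shared_p))]
                    )
            text = " ".join(toks)
            if rng.random() < config.noise_rates.get("retweet", 0.0):
                text = f"RT @user{int(rng.integers(1000))} " + text
            elif rng.random() < config.noise_rates.get("mention", 0.0):
                text = f"@user{int(rng.integers(1000))} " + text
            if rng.random() < config.noise_rates.get("url", 0.0):
                text = text + f" www.t.co/{int(rng.integers(16**4)):04x}"
            emit(text, month)

        if rng.random() < config.declaration_rate_for(group):
            tpl = templates_by_group[group][
                int(rng.integers(len(templates_by_group[group])))
            ]
            month = window[int(rng.integers(len(window)))]
            filler = " ".join(
                shared_words[int(rng.choice(len(shared_words), p=shared_p))]
                for _ in range(2)
            )
            emit(tpl.phrase.capitalize() + " " + filler, month)

        for month in window:
            rates = injection.get(month, {}).get(group.value, {})
            for cat in CATEGORIES:
                lam = float(rates.get(cat, 0.0))
                if lam <= 0:
                    continue
                for _ in range(int(rng.poisson(lam))):
                    phrase = lexicons[cat].phrases[
                        int(rng.integers(len(lexicons[cat].phrases)))
                    ]
                    w1 = shared_words[
                        int(rng.choice(len(shared_words), p=shared_p))
                    ]
                    w2 = shared_words[
                        int(rng.choice(len(shared_words), p=shared_p))
                    ]
                    emit(f"{w1} {phrase} {w2}", month)

    return tweets, labels
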