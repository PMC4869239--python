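"""Cancer-term surveillance over monthly timeline slices.

Five keyword lexicons (general cancer vocabulary plus breast, colorectal,
lung and prostate phrase lists) are matched case-insensitively at token
boundaries, longest phrase first, non-overlapping.  Counts are tabulated
per calendar month, group and category; rates are normalized per active
user so cross-group comparisons are population-size-free.  Group
differences within a month are tested with two-sided Welch (unequal
variance) t-tests on per-user mention totals, unadjusted for multiple
comparisons with the conventional 0.05 significance threshold reported
alongside.  A campaign-drop statistic quantifies the fall in usage in the
month after an awareness month (Breast Cancer Awareness Month is October,
Prostate September, Lung November) relative to the preceding baseline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import (
    STUDY_WINDOW,
    EthnicityLabel,
    Group,
    Timeline,
    partition_by_month,
)

__all__ = [
    "CATEGORIES",
    "KeywordLexicon",
    "default_lexicons",
    "count_mentions",
    "build_usage_table",
    "pairwise_term_test",
    "campaign_drop",
    "AWARENESS_MONTHS",
]

CATEGORIES = ("general_cancer", "breast", "colorectal", "lung", "prostate")

# Awareness months within the study window (category -> (year, month)).
AWARENESS_MONTHS: dict[str, tuple[int, int]] = {
    "prostate": (2014, 9),
    "breast": (2014, 10),
    "lung": (2014, 11),
}

# Raw phrase lists; "(s)" expands to singular+plural, "(the)" to
# with/without-article variants, at load time.
_RAW_LEXICONS: dict[str, list[str]] = {
    "general_cancer": [
        "benign", "cancer(s)", "cancerous", "carcinogen", "carcinogenic",
        "chemo", "chemotherapy", "chemotherapeutic", "cyst(s)", "growths",
        "leukemia", "lymphoma", "malignant", "metastases", "metastasis",
        "metastatic", "neoplasm", "oncologist", "oncology", "radiation",
        "radiotherapy", "recurrence", "tumor(s)",
    ],
    "breast": [
        "breast cancer", "breast carcinoma", "cancer of the breast",
        "malignant neoplasm of (the) breast",
        "malignant tumor of (the) breast", "mammary cancer",
    ],
    "colorectal": ["colorectal cancer", "colon cancer"],
    "lung": [
        "lung cancer", "cancer of bronchus", "cancer of the lung",
        "lung malignancies", "lung malignant tumors", "lung neoplasms",
        "malignant lung tumor", "malignant neoplasm of lung",
        "malignant tumor of lung", "pulmonary cancer",
        "pulmonary carcinoma", "pulmonary neoplasms",
        "respiratory carcinoma",
    ],
    "prostate": [
        "prostate cancer", "cancer of the prostate",
        "malignant neoplasm of the prostate", "prostate carcinoma",
        "prostate neoplasm", "prostatic cancer", "prostatic carcinoma",
        "prostatic neoplasm",
    ],
}


def _expand_shorthand(phrase: str) -> list[str]:
    if phrase.endswith("(s)"):
        base = phrase[:-3]
        return [base, base + "s"]
    if "(the) " in phrase:
        return [phrase.replace("(the) ", "the "),
                phrase.replace("(the) ", "")]
    return [phrase]


@dataclass(frozen=True)
class KeywordLexicon:
    """One cancer category's case-insensitive match phrases."""

    category: str
    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.phrases:
            raise ValueError("lexicon phrases must be non-empty")

    @classmethod
    def from_raw(cls, category: str, raw_phrases: Iterable[str]) -> "KeywordLexicon":
        expanded: list[str] = []
        for p in raw_phrases:
            for variant in _expand_shorthand(p):
                if variant not in expanded:  # dedupe repeated entries
                    expanded.append(variant)
        return cls(category=category, phrases=tuple(expanded))

    @property
    def pattern(self) -> re.Pattern:
        # longest-first alternation so multi-word phrases win at a
        # position; finditer is then non-overlapping by construction
        ordered = sorted(self.phrases, key=lambda p: -len(p.split()))
        alts = [re.escape(p).replace(r"\ ", r"\s+") for p in ordered]
        return re.compile(
            r"(?<!\w)(?:" + "|".join(alts) + r")(?!\w)", re.IGNORECASE
        )


def default_lexicons() -> dict[str, KeywordLexicon]:
    """The five shipped lexicons with shorthand expanded."""
    return {
        cat: KeywordLexicon.from_raw(cat, raw)
        for cat, raw in _RAW_LEXICONS.items()
    }


def count_mentions(text_or_tweets, lexicon: KeywordLexicon) -> int:
    """Count non-overlapping, token-boundary phrase occurrences.

    Accepts a string or a sequence of tweets/texts.  Matching is
    case-insensitive; the embedded token "scancer" or "cancerville"
    never matches "cancer"; at each position the longest lexicon phrase
    wins and each occurrence counts once.
    """
    if isinstance(text_or_tweets, str):
        texts = [text_or_tweets]
    else:
        texts = [
            t if isinstance(t, str) else t.text for t in text_or_tweets
        ]
    pattern = lexicon.pattern
    return sum(len(pattern.findall(text)) for text in texts)


def build_usage_table(
    timelines: Sequence[Timeline],
    labels: Mapping[str, EthnicityLabel],
    lexicons: Mapping[str, KeywordLexicon] | None = None,
    window: Sequence[tuple[int, int]] = STUDY_WINDOW,
) -> pd.DataFrame:
    """Tabulate monthly cancer-term usage by group and category.

    Returns a tidy frame with one row per (month, group, category):
    ``count`` (raw mentions), ``users`` (group's active users that month,
    i.e. users with >= 1 retained tweet), ``rate`` (mentions per active
    user), plus the month margins ``month_total_users`` and ``group_pct``
    (the group's share of the month's active users, in percent).

    Every timeline must carry a label; an unlabeled user is an error.
    """
    if lexicons is None:
        lexicons = default_lexicons()
    for tl in timelines:
        if tl.user_id not in labels:
            raise KeyError(f"timeline {tl.user_id!r} has no label")

    groups = [g for g in Group]
    active: dict[tuple[int, int], dict[Group, int]] = {
        m: {g: 0 for g in groups} for m in window
    }
    counts: dict[tuple[tuple[int, int], Group, str], int] = {}
    contributing: dict[tuple[tuple[int, int], Group, str], int] = {}
    for tl in timelines:
        g = labels[tl.user_id].group
        slices, _ = partition_by_month(tl, window)
        for m, tweets in slices.items():
            if not tweets:
                continue
            active[m][g] += 1
            for cat, lex in lexicons.items():
                n = count_mentions(tweets, lex)
                key = (m, g, cat)
                counts[key] = counts.get(key, 0) + n
                if n > 0:
                    contributing[key] = contributing.get(key, 0) + 1

    rows = []
    for m in window:
        total_users = sum(active[m].values())
        for g in groups:
            users = active[m][g]
            pct = 100.0 * users / total_users if total_users else 0.0
            for cat in lexicons:
                c = counts.get((m, g, cat), 0)
                rows.append(
                    {
                        "year": m[0],
                        "month": m[1],
                        "group": g.value,
                        "category": cat,
                        "count": c,
                        "users": users,
                        "contributing_users": contributing.get((m, g, cat), 0),
                        "rate": c / users if users else np.nan,
                        "month_total_users": total_users,
                        "group_pct": pct,
                    }
                )
    return pd.DataFrame(rows)


def per_user_monthly_totals(
    timelines: Sequence[Timeline],
    labels: Mapping[str, EthnicityLabel],
    group: Group,
    lexicon: KeywordLexicon,
    month: tuple[int, int],
    window: Sequence[tuple[int, int]] = STUDY_WINDOW,
) -> np.ndarray:
    """Per-user mention totals for one group/category/month (the t-test
    unit of analysis).  Users active in the month contribute a total,
    zero included."""
    totals = []
    for tl in timelines:
        if labels[tl.user_id].group is not group:
            continue
        slices, _ = partition_by_month(tl, window)
        tweets = slices.get(month, [])
        if tweets:
            totals.append(count_mentions(tweets, lexicon))
    return np.asarray(totals, dtype=float)


def pairwise_term_test(
    totals_a: Sequence[float], totals_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Welch t-test on per-user term-usage totals.

    No multiple-comparison adjustment is applied; callers compare the
    returned p against the conventional 0.05 threshold.  Two identical
    constant samples (zero variance, equal means) return ``(0.0, 1.0)``;
    samples with fewer than two observations are an error.
    """
    a = np.asarray(totals_a, dtype=float)
    b = np.asarray(totals_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 users for a variance")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError(
            "zero-variance samples with unequal means: t undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def campaign_drop(
    series: Mapping[tuple[int, int], float],
    campaign_month: tuple[int, int],
    baseline_months: Sequence[tuple[int, int]] | None = None,
    window: Sequence[tuple[int, int]] = STUDY_WINDOW,
) -> float:
    """Percent drop in the month after an awareness campaign.

    ``100 * (mean baseline rate - rate in the month after the campaign)
    / mean baseline rate``; negative values indicate an increase.  The
    baseline defaults to the two window months preceding the campaign
    month.
    """
    window = list(window)
    idx = window.index(campaign_month)
    if idx + 1 >= len(window):
        raise ValueError("no month after the campaign month in the window")
    following = window[idx + 1]
    if baseline_months is None:
        baseline_months = window[max(0, idx - 2): idx]
        if not baseline_months:
            raise ValueError("no baseline months precede the campaign")
    for m in list(baseline_months) + [following]:
        if m not in series:
            raise KeyError(f"month {m} missing from series")
    baseline = float(np.mean([series[m] for m in baseline_months]))
    if baseline == 0:
        raise ValueError("zero baseline mean: drop undefined")
    return 100.0 * (baseline - series[following]) / baseline
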