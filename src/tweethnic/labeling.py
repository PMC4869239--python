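"""Self-declared ethnicity extraction.

Training labels are minted from first-person declarative statements found
in timelines ("I am African-American", "I'm Asian", "I'm a black man").
The template inventory is a closed, configurable cross-product of copula
frames and ethnic terms; each template maps to exactly one of the four
group keys and race/ethnicity terms are not distinguished beyond those
keys.  Users whose declarations disagree are excluded from training, and
matched spans are excised (masked) from the feature text by default so
the declaration itself cannot leak into the classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus import EthnicityLabel, Group, Provenance, Timeline

__all__ = [
    "DeclarationTemplate",
    "DEFAULT_TEMPLATES",
    "DeclarationMatch",
    "extract_declaration",
    "LabeledTimeline",
    "build_training_set",
]

# term -> group; both hyphenated and spaced compound forms included
_ETHNIC_TERMS: dict[str, Group] = {
    "white": Group.CAUCASIAN,
    "caucasian": Group.CAUCASIAN,
    "black": Group.AFRICAN_AMERICAN,
    "african-american": Group.AFRICAN_AMERICAN,
    "african american": Group.AFRICAN_AMERICAN,
    "asian": Group.ASIAN,
    "hispanic": Group.HISPANIC,
    "latino": Group.HISPANIC,
    "latina": Group.HISPANIC,
}

# copula frames; {} is the ethnic-term slot
_FRAMES = (
    "i am {}",
    "i'm {}",
    "i am a {} man",
    "i am a {} woman",
    "i'm a {} man",
    "i'm a {} woman",
    "i am an {} man",
    "i am an {} woman",
    "i'm an {} man",
    "i'm an {} woman",
)


@dataclass(frozen=True)
class DeclarationTemplate:
    """One case-insensitive declarative pattern mapped to one group."""

    phrase: str
    target_group: Group

    @property
    def regex(self) -> re.Pattern:
        # word-boundary anchored, whitespace-flexible, case-insensitive
        parts = [re.escape(tok) for tok in self.phrase.split()]
        return re.compile(
            r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)", re.IGNORECASE
        )


def _default_templates() -> tuple[DeclarationTemplate, ...]:
    out = []
    for term, group in _ETHNIC_TERMS.items():
        vowel = term[0] in "aeiou"
        for frame in _FRAMES:
            # article agreement: "a" with consonant-initial terms,
            # "an" with vowel-initial ones
            if " a {}" in frame and vowel:
                continue
            if " an {}" in frame and not vowel:
                continue
            out.append(DeclarationTemplate(frame.format(term), group))
    return tuple(out)


DEFAULT_TEMPLATES: tuple[DeclarationTemplate, ...] = _default_templates()


@dataclass(frozen=True)
class DeclarationMatch:
    tweet_id: str
    span: tuple[int, int]
    phrase: str
    group: Group


def extract_declaration(
    timeline: Timeline,
    templates: Sequence[DeclarationTemplate] = DEFAULT_TEMPLATES,
) -> tuple[EthnicityLabel | None, list[DeclarationMatch], bool]:
    """Search a timeline for self-declarations.

    Returns ``(label, matches, conflict)``: the self-declared label when
    at least one template matches and all matches agree; ``None`` with no
    matches when nothing matches; ``None`` with ``conflict=True`` when
    matches point at different groups (such users are excluded from
    training).  Declarations are matched within individual tweets.
    """
    matches: list[DeclarationMatch] = []
    for tweet in timeline.tweets:
        for tpl in templates:
            for m in tpl.regex.finditer(tweet.text):
                matches.append(
                    DeclarationMatch(
                        tweet_id=tweet.tweet_id,
                        span=m.span(),
                        phrase=m.group(0),
                        group=tpl.target_group,
                    )
                )
    if not matches:
        return None, [], False
    groups = {m.group for m in matches}
    if len(groups) > 1:
        return None, matches, True
    label = EthnicityLabel(groups.pop(), Provenance.SELF_DECLARED)
    return label, matches, False


@dataclass
class LabeledTimeline:
    """A declared user ready for supervised training.

    ``feature_texts`` are the tweet texts with matched declaration spans
    excised when masking is on.
    """

    user_id: str
    label: EthnicityLabel
    feature_texts: list[str]
    n_matched_spans: int

    @property
    def group(self) -> Group:
        return self.label.group


def _mask_spans(text: str, spans: list[tuple[int, int]]) -> str:
    if not spans:
        return text
    out = []
    prev = 0
    for start, end in sorted(spans):
        out.append(text[prev:start])
        prev = max(prev, end)
    out.append(text[prev:])
    return re.sub(r"\s+", " ", "".join(out)).strip()


def build_training_set(
    timelines: Iterable[Timeline],
    templates: Sequence[DeclarationTemplate] = DEFAULT_TEMPLATES,
    mask_declarations: bool = True,
) -> tuple[list[LabeledTimeline], dict]:
    """Extract the self-declared training set.

    One labeled record per non-conflicting declared user.  When
    *mask_declarations* is true (default) the matched spans are removed
    from the text used for feature extraction.  Returns the labeled set
    plus a report with per-class counts and the number of conflicting /
    undeclared users.
    """
    labeled: list[LabeledTimeline] = []
    report = {
        "n_users": 0,
        "n_declared": 0,
        "n_conflict": 0,
        "class_counts": {g.value: 0 for g in Group},
    }
    for tl in timelines:
        report["n_users"] += 1
        label, matches, conflict = extract_declaration(tl, templates)
        if conflict:
            report["n_conflict"] += 1
            continue
        if label is None:
            continue
        spans_by_tweet: dict[str, list[tuple[int, int]]] = {}
        for m in matches:
            spans_by_tweet.setdefault(m.tweet_id, []).append(m.span)
        texts = []
        for tweet in tl.tweets:
            if mask_declarations and tweet.tweet_id in spans_by_tweet:
                masked = _mask_spans(tweet.text, spans_by_tweet[tweet.tweet_id])
                if masked:
                    texts.append(masked)
            else:
                texts.append(tweet.text)
        labeled.append(
            LabeledTimeline(
                user_id=tl.user_id,
                label=label,
                feature_texts=texts,
                n_matched_spans=len(matches),
            )
        )
        report["n_declared"] += 1
        report["class_counts"][label.group.value] += 1
    empty = [g for g, n in report["class_counts"].items() if n == 0]
    report["empty_classes"] = empty
    return labeled, report
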