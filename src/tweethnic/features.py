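"""Timeline featurization: tokenization, stemming, synonym expansion, DTM.

Two bag-of-words representations are supported:

* plain stemmed term frequencies over a user's aggregated timeline, and
* *synonym-expanded* term frequencies, where the top-k lexical synonyms of
  every noun and verb in a tweet are appended to the tweet before
  counting.  Expansion increases lexical overlap between users who express
  the same concept with different surface words, which is what makes the
  expanded representation the stronger classifier input.

Both the part-of-speech tagger and the synonym source are pluggable
contracts; defaults are a small rule-based tagger and a JSON-backed
synonym lexicon (a synthetic lexicon ships with the package).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_extraction.text import CountVectorizer

from .corpus import Timeline
from .stemming import porter_stem

__all__ = [
    "tokenize",
    "tokenize_and_stem",
    "HeuristicPosTagger",
    "JsonSynonymLexicon",
    "load_default_synonym_lexicon",
    "expand_tweet",
    "DocumentTermMatrix",
    "TimelineVectorizer",
    "build_dtm",
]

_TOKEN_RE = re.compile(r"[a-z0-9_']+")

# Closed-class function words the tagger never marks as noun/verb.
_FUNCTION_WORDS = frozenset(
    """a an the and or but if then than so of in on at to for from with
    without by about as into over under again once here there all any both
    each few more most other some such no nor not only own same too very
    just i you he she it we they me him her us them my your his its our
    their this that these those am is are was were be been being do does
    did have has had will would can could shall should may might must
    what which who whom when where why how""".split()
)

_VERB_SUFFIXES = ("ing", "ed", "ify", "ise", "ize")
_COMMON_VERBS = frozenset(
    """go get make know think take see come want look use find give tell
    work call try ask need feel become leave put mean keep let begin seem
    help talk turn start show hear play run move like live believe hold
    bring happen write sit stand lose pay meet say eat drink cook love
    sing dance read walk drive sleep""".split()
)


def tokenize(text: str) -> list[str]:
    """Lowercase and split into word tokens (punctuation stripped)."""
    return [
        t.strip("'")
        for t in _TOKEN_RE.findall(text.lower())
        if t.strip("'")
    ]


def tokenize_and_stem(text: str) -> list[str]:
    """Lowercased, punctuation-stripped, Porter-stemmed token sequence."""
    return [porter_stem(t) for t in tokenize(text)]


class HeuristicPosTagger:
    """Rule-based coarse tagger: token -> ``noun`` | ``verb`` | ``other``.

    Closed-class function words are ``other``; common verbs and tokens
    with verbal suffixes are ``verb``; everything else defaults to
    ``noun``.  Crude, but only tokens that also have an entry in the
    synonym lexicon ever trigger an expansion, so precision costs little.
    """

    def __call__(self, token: str) -> str:
        t = token.lower()
        if t in _FUNCTION_WORDS or not t:
            return "other"
        if t in _COMMON_VERBS or t.endswith(_VERB_SUFFIXES):
            return "verb"
        return "noun"


class JsonSynonymLexicon:
    """Deterministic ranked synonym lookup backed by a JSON mapping.

    Two layouts are accepted: POS-keyed ``{"noun": {lemma: [syn, ...]},
    "verb": {...}}`` or flat ``{lemma: [syn, ...]}`` (POS ignored).
    Lookup never returns the query lemma itself; multi-word synonyms are
    joined with underscores so they stay single DTM columns.
    """

    def __init__(self, mapping: dict):
        if set(mapping) <= {"noun", "verb"}:
            self._pos_keyed = True
            self._map = {
                pos: {k.lower(): list(v) for k, v in entries.items()}
                for pos, entries in mapping.items()
            }
        else:
            self._pos_keyed = False
            self._map = {k.lower(): list(v) for k, v in mapping.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "JsonSynonymLexicon":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def lookup(self, lemma: str, pos: str) -> list[str]:
        lemma = lemma.lower()
        if self._pos_keyed:
            ranked = self._map.get(pos, {}).get(lemma, [])
        else:
            ranked = self._map.get(lemma, [])
        return [
            s.replace(" ", "_") for s in ranked if s.lower() != lemma
        ]

    __call__ = lookup


def load_default_synonym_lexicon() -> JsonSynonymLexicon:
    """Load the synthetic synonym lexicon bundled with the package."""
    ref = resources.files("tweethnic.data").joinpath("synonyms_synthetic.json")
    return JsonSynonymLexicon(json.loads(ref.read_text(encoding="utf-8")))


def expand_tweet(
    text: str,
    synonym_source: Callable[[str, str], list[str]] | None,
    top_k: int = 5,
    tagger: Callable[[str], str] | None = None,
) -> str:
    """Append the top-k synonyms of each noun and verb to a tweet.

    The original text is preserved verbatim; synonyms are appended at the
    end in token order then rank order.  Tokens whose lookup returns
    nothing contribute nothing, and fewer than *top_k* synonyms are
    appended when fewer are available.
    """
    if synonym_source is None:
        return text
    if tagger is None:
        tagger = HeuristicPosTagger()
    appended: list[str] = []
    for token in tokenize(text):
        pos = tagger(token)
        if pos not in ("noun", "verb"):
            continue
        syns = synonym_source(token, pos)[:top_k]
        appended.extend(s.replace(" ", "_") for s in syns)
    if not appended:
        return text
    return text + " " + " ".join(appended)


@dataclass
class DocumentTermMatrix:
    """Sparse timelines x stemmed-terms count matrix."""

    matrix: sp.csr_matrix
    vocabulary: list[str]
    row_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def column(self, term: str) -> np.ndarray:
        j = self.vocabulary.index(term)
        return np.asarray(self.matrix[:, j].todense()).ravel()


def _as_tweet_texts(doc) -> list[str]:
    if isinstance(doc, Timeline):
        return doc.texts
    if isinstance(doc, str):
        return [doc]
    return list(doc)


class TimelineVectorizer(TransformerMixin, BaseEstimator):
    """Stemmed bag-of-words vectorizer over timelines, with optional
    per-tweet synonym expansion.

    Documents may be :class:`~tweethnic.corpus.Timeline` objects, lists of
    tweet texts, or plain strings (treated as a single tweet).  Expansion,
    when enabled, is applied symmetrically at fit and transform time.

    Parameters
    ----------
    expansion : bool, default False
        Append top-k synonyms of nouns/verbs to each tweet before counting.
    synonym_source : callable ``(lemma, pos) -> list[str]`` or None
        Ranked synonym lookup; defaults to the bundled synthetic lexicon
        when expansion is on.
    top_k : int, default 5
        Maximum synonyms appended per token.
    min_df : int, default 2
        Prune terms appearing in fewer documents.
    """

    def __init__(
        self,
        expansion: bool = False,
        synonym_source=None,
        top_k: int = 5,
        min_df: int = 2,
        tagger=None,
    ):
        self.expansion = expansion
        self.synonym_source = synonym_source
        self.top_k = top_k
        self.min_df = min_df
        self.tagger = tagger

    def _analyzer(self):
        if self.expansion:
            source = self.synonym_source
            if source is None:
                source = load_default_synonym_lexicon()
            tagger = self.tagger or HeuristicPosTagger()

            def analyze(doc):
                tokens: list[str] = []
                for tweet in _as_tweet_texts(doc):
                    expanded = expand_tweet(
                        tweet, source, top_k=self.top_k, tagger=tagger
                    )
                    tokens.extend(tokenize_and_stem(expanded))
                return tokens

        else:

            def analyze(doc):
                tokens: list[str] = []
                for tweet in _as_tweet_texts(doc):
                    tokens.extend(tokenize_and_stem(tweet))
                return tokens

        return analyze

    def fit(self, documents, y=None):
        if not list(documents):
            raise ValueError("cannot fit a vectorizer on an empty corpus")
        self._vectorizer_ = CountVectorizer(
            analyzer=self._analyzer(), min_df=self.min_df, lowercase=False
        )
        self._vectorizer_.fit(documents)
        self.vocabulary_ = list(self._vectorizer_.get_feature_names_out())
        return self

    def transform(self, documents) -> sp.csr_matrix:
        return self._vectorizer_.transform(documents)

    def fit_transform(self, documents, y=None) -> sp.csr_matrix:
        return self.fit(documents).transform(documents)


def build_dtm(
    timelines: Sequence[Timeline],
    expansion: bool = False,
    min_df: int = 2,
    synonym_source=None,
    top_k: int = 5,
    tagger=None,
) -> DocumentTermMatrix:
    """Build a document-term matrix from timelines.

    Counts are computed after optional synonym expansion and after
    tokenization + stemming; columns with document frequency below
    *min_df* are pruned.  Row order follows the input timelines,
    column order is the vectorizer's fixed lexicographic vocabulary.
    """
    vec = TimelineVectorizer(
        expansion=expansion,
        synonym_source=synonym_source,
        top_k=top_k,
        min_df=min_df,
        tagger=tagger,
    )
    matrix = vec.fit_transform(list(timelines))
    row_ids = [
        t.user_id if isinstance(t, Timeline) else str(i)
        for i, t in enumerate(timelines)
    ]
    return DocumentTermMatrix(
        matrix=matrix.tocsr(), vocabulary=vec.vocabulary_, row_ids=row_ids
    )
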