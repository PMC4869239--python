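"""Tokenization, stemming, synonym expansion and DTM construction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tweethnic.features import (
    JsonSynonymLexicon,
    TimelineVectorizer,
    build_dtm,
    expand_tweet,
    load_default_synonym_lexicon,
    tokenize,
    tokenize_and_stem,
)
from tweethnic.stemming import porter_stem
from tweethnic.synthetic import _SHARED_VOCAB, _SIGNATURES

from .conftest import timeline

# tokens the generator and lexicons actually emit, for fuzzing
_REALISTIC_TOKENS = sorted(
    {w for w, _ in _SHARED_VOCAB}
    | {v for groups in _SIGNATURES.values() for c in groups for v in c}
    | {"cancer", "cancers", "chemotherapy", "metastases", "oncologist",
       "running", "together", "relational", "happiness", "hopeful"}
)


class TestTokenizeAndStem:
    def test_together_stems_to_togeth(self):
        assert tokenize_and_stem("Together we stand") == [
            "togeth", "we", "stand",
        ]

    @pytest.mark.parametrize(
        "word,stem",
        [
            ("running", "run"), ("caresses", "caress"), ("ponies", "poni"),
            ("relational", "relat"), ("hopeful", "hope"),
            ("cancerous", "cancer"), ("metastases", "metasta"),
            ("oscillators", "oscil"), ("generalization", "gener"),
        ],
    )
    def test_canonical_suffix_stripping(self, word, stem):
        assert porter_stem(word) == stem

    def test_empty_text_gives_no_tokens(self):
        assert tokenize_and_stem("") == []

    def test_punctuation_stripped_and_lowercased(self):
        assert tokenize("Hello, WORLD!! it's fine...") == [
            "hello", "world", "it's", "fine",
        ]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.one_of(
            st.sampled_from(_REALISTIC_TOKENS),
            st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1,
                    max_size=15),
        )
    )
    def test_stemmer_idempotent(self, token):
        # the stem map is a projection: re-stemming never changes a stem
        once = porter_stem(token)
        assert porter_stem(once) == once


FIXTURE_LEXICON = JsonSynonymLexicon(
    {
        "spouse": [
            "partner", "mate", "better half", "married person", "helpmate",
        ],
        "wife": ["partner", "spouse"],
        "dog": ["hound", "pooch"],
    }
)


class TestExpandTweet:
    def test_top_five_synonyms_appended(self):
        out = expand_tweet("my spouse cooks", FIXTURE_LEXICON, top_k=5)
        assert out == (
            "my spouse cooks partner mate better_half married_person helpmate"
        )

    def test_fewer_synonyms_when_fewer_available(self):
        out = expand_tweet("the dog barked", FIXTURE_LEXICON, top_k=5)
        assert out == "the dog barked hound pooch"

    def test_empty_source_is_identity(self):
        assert expand_tweet("my spouse cooks", None) == "my spouse cooks"
        empty = JsonSynonymLexicon({})
        assert expand_tweet("my spouse cooks", empty) == "my spouse cooks"

    def test_lookup_never_returns_query_lemma(self):
        lex = JsonSynonymLexicon({"cat": ["cat", "feline"]})
        assert lex.lookup("cat", "noun") == ["feline"]

    def test_default_lexicon_loads_and_is_pos_keyed(self):
        lex = load_default_synonym_lexicon()
        assert "fiddle" in lex.lookup("violin", "noun")
        assert lex.lookup("violin", "verb") == []

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.sampled_from(_REALISTIC_TOKENS), min_size=1, max_size=12)
    )
    def test_original_tokens_are_a_prefix_of_the_expansion(self, tokens):
        text = " ".join(tokens)
        out = expand_tweet(text, load_default_synonym_lexicon())
        assert tokenize(out)[: len(tokens)] == tokenize(text)


class TestDocumentTermMatrix:
    def test_identical_timelines_identical_rows(self):
        tls = [timeline(["happy day today"], uid="a"),
               timeline(["happy day today"], uid="b")]
        dtm = build_dtm(tls, min_df=1)
        assert np.array_equal(dtm.to_dense()[0], dtm.to_dense()[1])

    def test_min_df_one_conserves_token_mass(self):
        tls = [timeline(["one two two"], uid="a"),
               timeline(["three four"], uid="b")]
        dtm = build_dtm(tls, min_df=1)
        total_tokens = sum(
            len(tokenize_and_stem(tl.aggregate_text)) for tl in tls
        )
        assert dtm.matrix.sum() == total_tokens

    def test_empty_corpus_is_an_error(self):
        with pytest.raises(ValueError):
            TimelineVectorizer().fit([])

    def test_permutation_equivariance(self):
        tls = [timeline([t], uid=f"u{i}") for i, t in enumerate(
            ["alpha beta", "beta gamma", "gamma alpha"]
        )]
        fwd = build_dtm(tls, min_df=1)
        rev = build_dtm(tls[::-1], min_df=1)
        assert fwd.vocabulary == rev.vocabulary
        assert np.array_equal(fwd.to_dense(), rev.to_dense()[::-1])

    def test_expansion_creates_shared_concept_column(self):
        # group A says "wife", group B says "spouse"; the lexicon links
        # both to "partner": only the expanded DTM shares a column
        lex = JsonSynonymLexicon(
            {"wife": ["partner"], "spouse": ["partner"]}
        )
        tls = [timeline(["my wife sings"], uid="a"),
               timeline(["my spouse sings"], uid="b")]
        plain = build_dtm(tls, min_df=1)
        expanded = build_dtm(
            tls, expansion=True, synonym_source=lex, min_df=1
        )
        assert "partner" in expanded.vocabulary
        assert (expanded.column("partner") > 0).all()
        assert "partner" not in plain.vocabulary
        # no shared concept column in the plain DTM
        a_terms = {v for v, c in zip(plain.vocabulary, plain.to_dense()[0])
                   if c and v in ("wife", "spous", "partner")}
        b_terms = {v for v, c in zip(plain.vocabulary, plain.to_dense()[1])
                   if c and v in ("wife", "spous", "partner")}
        assert not (a_terms & b_terms)

    def test_expansion_increases_cross_group_cosine_similarity(self):
        lex = JsonSynonymLexicon(
            {"wife": ["partner"], "spouse": ["partner"]}
        )
        tls = [timeline(["my wife sings"], uid="a"),
               timeline(["my spouse sings"], uid="b")]

        def cosine(dtm):
            d = dtm.to_dense().astype(float)
            return float(
                d[0] @ d[1] / (np.linalg.norm(d[0]) * np.linalg.norm(d[1]))
            )

        plain = build_dtm(tls, min_df=1)
        expanded = build_dtm(tls, expansion=True, synonym_source=lex,
                             min_df=1)
        assert cosine(expanded) > cosine(plain)

    def test_transform_reuses_training_vocabulary(self):
        vec = TimelineVectorizer(min_df=1)
        vec.fit([timeline(["alpha beta"], uid="a")])
        X = vec.transform([timeline(["alpha gamma gamma"], uid="b")])
        assert X.shape[1] == len(vec.vocabulary_)  # gamma dropped
        assert X.sum() == 1
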