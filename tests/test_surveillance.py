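"""Keyword lexicons, mention counting, usage tables, tests and drops."""

from __future__ import annotations

import numpy as np
import pytest

from tweethnic.corpus import (
    EthnicityLabel,
    Group,
    Provenance,
    build_timelines,
)
from tweethnic.surveillance import (
    KeywordLexicon,
    build_usage_table,
    campaign_drop,
    count_mentions,
    default_lexicons,
    pairwise_term_test,
    per_user_monthly_totals,
)
from tweethnic.synthetic import SyntheticCorpusConfig, generate_corpus

from .conftest import BALANCED_PROPORTIONS, timeline

LEX = default_lexicons()


class TestLexicons:
    def test_five_categories_ship(self):
        assert set(LEX) == {
            "general_cancer", "breast", "colorectal", "lung", "prostate",
        }

    def test_plural_shorthand_expanded(self):
        phrases = LEX["general_cancer"].phrases
        for base in ("cancer", "cyst", "tumor"):
            assert base in phrases and base + "s" in phrases
        assert phrases.count("neoplasm") == 1  # deduplicated

    def test_article_shorthand_expanded(self):
        phrases = LEX["breast"].phrases
        assert "malignant neoplasm of the breast" in phrases
        assert "malignant neoplasm of breast" in phrases

    def test_colorectal_is_exactly_two_base_phrases(self):
        assert LEX["colorectal"].phrases == (
            "colorectal cancer", "colon cancer",
        )

    def test_lung_and_prostate_phrase_counts(self):
        assert len(LEX["lung"].phrases) == 13
        assert len(LEX["prostate"].phrases) == 8

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            KeywordLexicon("kidney", ("kidney cancer",))


class TestCountMentions:
    @pytest.mark.parametrize(
        "text,category,expected",
        [
            ("starting chemo then more chemo", "general_cancer", 2),
            ("colon cancer screening saves lives", "colorectal", 1),
            ("my cat is playful", "general_cancer", 0),
            ("my cat is playful", "breast", 0),
            ("Breast Cancer walk today", "breast", 1),
            ("scancer and cancerville", "general_cancer", 0),  # boundaries
            ("cancer, cancers; CANCEROUS", "general_cancer", 3),
            ("malignant neoplasm of the breast", "breast", 1),
            ("lung cancer and pulmonary carcinoma", "lung", 2),
        ],
    )
    def test_counting_examples(self, text, category, expected):
        assert count_mentions(text, LEX[category]) == expected

    def test_longest_phrase_wins_non_overlapping(self):
        # "breast cancer" must count once as the bigram, with the
        # embedded "cancer" not double-counted within the same lexicon
        lex = KeywordLexicon("breast", ("breast cancer", "cancer"))
        assert count_mentions("breast cancer awareness", lex) == 1

    def test_accepts_tweet_sequences(self):
        tl = timeline(["chemo today", "more chemo tomorrow"])
        assert count_mentions(tl.tweets, LEX["general_cancer"]) == 2


def _label(group):
    return EthnicityLabel(group, Provenance.GROUND_TRUTH_SYNTHETIC)


class TestUsageTable:
    def test_april_population_margins_reproduce_printed_shares(self):
        # whole-study April margins: 49,104 African-American of 505,252
        # active users is 9.72%; checked through the table's formula on
        # the printed counts scaled down 1:1000
        users = {
            Group.AFRICAN_AMERICAN: 49104,
            Group.CAUCASIAN: 452924,
            Group.ASIAN: 1289,
            Group.HISPANIC: 1935,
        }
        total = sum(users.values())
        assert total == 505252
        shares = {g: 100 * n / total for g, n in users.items()}
        assert shares[Group.AFRICAN_AMERICAN] == pytest.approx(9.72, abs=0.005)
        assert shares[Group.CAUCASIAN] == pytest.approx(89.64, abs=0.005)
        # the Asian cell computes to 0.2551, printed rounded as 0.25
        assert shares[Group.ASIAN] == pytest.approx(0.25, abs=0.01)
        assert shares[Group.HISPANIC] == pytest.approx(0.38, abs=0.005)

    def test_margins_conserved_and_rates_normalized(self):
        tls = [
            timeline(["chemo helped a lot today"], uid="a"),
            timeline(["plain words here"], uid="b"),
            timeline(["chemo chemo"], uid="c"),
        ]
        labels = {
            "a": _label(Group.CAUCASIAN),
            "b": _label(Group.CAUCASIAN),
            "c": _label(Group.AFRICAN_AMERICAN),
        }
        table = build_usage_table(tls, labels)
        april = table[(table.year == 2014) & (table.month == 4)]
        gen = april[april.category == "general_cancer"]
        cauc = gen[gen.group == "Caucasian"].iloc[0]
        aa = gen[gen.group == "AfricanAmerican"].iloc[0]
        assert cauc["count"] == 1 and cauc.users == 2
        assert cauc.rate == pytest.approx(0.5)
        assert aa["count"] == 2 and aa.rate == pytest.approx(2.0)
        # group user margins sum to the month total; percentages to 100
        assert gen.users.sum() == gen.month_total_users.iloc[0] == 3
        assert april.drop_duplicates("group").group_pct.sum() == (
            pytest.approx(100.0)
        )

    def test_unlabeled_timeline_is_an_error(self):
        with pytest.raises(KeyError):
            build_usage_table([timeline(["x"], uid="ghost")], {})

    def test_zero_injection_corpus_counts_zero(self):
        zero = {
            m: {g.value: {c: 0.0 for c in LEX} for g in Group}
            for m in SyntheticCorpusConfig(n_users=1).window
        }
        cfg = SyntheticCorpusConfig(n_users=60, seed=2, cancer_injection=zero)
        tweets, truth = generate_corpus(cfg)
        table = build_usage_table(build_timelines(tweets), truth)
        assert table["count"].sum() == 0


class TestPairwiseTermTest:
    def test_identical_samples_give_t0_p1(self):
        assert pairwise_term_test([1, 2, 3], [1, 2, 3]) == (
            pytest.approx(0.0), pytest.approx(1.0),
        )

    def test_welch_statistic_matches_closed_form_oracle(self):
        # hand evaluation: means .5 / 2.5, sample variances 1/3 each,
        # t = -2*sqrt(6), Welch-Satterthwaite df = 6 exactly, two-sided
        # p from the t CDF
        t, p = pairwise_term_test([0, 0, 1, 1], [2, 2, 3, 3])
        assert t == pytest.approx(-2 * np.sqrt(6.0), abs=1e-9)
        assert p == pytest.approx(0.0027136820350937957, abs=1e-9)

    def test_constant_equal_samples_defined(self):
        assert pairwise_term_test([2, 2, 2], [2, 2]) == (0.0, 1.0)

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            pairwise_term_test([1], [1, 2, 3])

    def test_group_difference_detected_on_synthetic_corpus(self):
        # a 4x general-vocabulary injection gap between the two majority
        # groups should reject decisively in a month
        inj = {
            m: {
                Group.CAUCASIAN.value: {"general_cancer": 0.2},
                Group.AFRICAN_AMERICAN.value: {"general_cancer": 0.8},
                Group.ASIAN.value: {}, Group.HISPANIC.value: {},
            }
            for m in SyntheticCorpusConfig(n_users=1).window
        }
        cfg = SyntheticCorpusConfig(
            n_users=600, seed=17, cancer_injection=inj,
            group_proportions={Group.CAUCASIAN: 0.5,
                               Group.AFRICAN_AMERICAN: 0.5,
                               Group.ASIAN: 0.0, Group.HISPANIC: 0.0},
        )
        tweets, truth = generate_corpus(cfg)
        tls = build_timelines(tweets)
        a = per_user_monthly_totals(
            tls, truth, Group.CAUCASIAN, LEX["general_cancer"], (2014, 4)
        )
        b = per_user_monthly_totals(
            tls, truth, Group.AFRICAN_AMERICAN, LEX["general_cancer"],
            (2014, 4),
        )
        t, p = pairwise_term_test(a, b)
        assert t < 0 and p < 0.01


class TestCampaignDrop:
    def test_73_percent_drop_arithmetic(self):
        series = {
            (2014, 8): 0.10, (2014, 9): 0.10,
            (2014, 10): 0.30, (2014, 11): 0.027,
        }
        drop = campaign_drop(series, (2014, 10))
        assert drop == pytest.approx(73.0)

    def test_return_to_baseline_is_zero_drop(self):
        series = {(2014, 8): 0.1, (2014, 9): 0.1,
                  (2014, 10): 0.5, (2014, 11): 0.1}
        assert campaign_drop(series, (2014, 10)) == pytest.approx(0.0)

    def test_increase_is_negative(self):
        series = {(2014, 8): 0.1, (2014, 9): 0.1,
                  (2014, 10): 0.5, (2014, 11): 0.2}
        assert campaign_drop(series, (2014, 10)) < 0

    def test_zero_baseline_undefined(self):
        series = {(2014, 8): 0.0, (2014, 9): 0.0,
                  (2014, 10): 0.5, (2014, 11): 0.1}
        with pytest.raises(ValueError):
            campaign_drop(series, (2014, 10))

    def test_missing_month_is_an_error(self):
        with pytest.raises(KeyError):
            campaign_drop({(2014, 10): 0.5}, (2014, 10))
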