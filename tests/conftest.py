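from __future__ import annotations

from datetime import datetime, timezone

import pytest

from tweethnic.corpus import Group, Timeline, TweetRecord
from tweethnic.synthetic import SyntheticCorpusConfig, generate_corpus

BALANCED_PROPORTIONS = {
    Group.CAUCASIAN: 0.25,
    Group.AFRICAN_AMERICAN: 0.25,
    Group.ASIAN: 0.25,
    Group.HISPANIC: 0.25,
}

# Labeled-set group shares for classification experiments (the declared
# subpopulation is far less imbalanced than the full stream).
LABELED_PROPORTIONS = {
    Group.CAUCASIAN: 0.452,
    Group.AFRICAN_AMERICAN: 0.323,
    Group.ASIAN: 0.102,
    Group.HISPANIC: 0.123,
}


def tweet(
    tid: str = "t1",
    uid: str = "u1",
    when: str = "2014-04-10T12:00:00",
    text: str = "hello world",
    location: str = "New York, NY",
    lang: str | None = "en",
) -> TweetRecord:
    return TweetRecord(
        tweet_id=tid,
        user_id=uid,
        created_at=datetime.fromisoformat(when).replace(tzinfo=timezone.utc),
        text=text,
        user_location=location,
        lang=lang,
    )


def timeline(texts, uid: str = "u1", **kw) -> Timeline:
    return Timeline(
        user_id=uid,
        tweets=[
            tweet(tid=f"{uid}_t{i}", uid=uid,
                  when=f"2014-04-{10 + i:02d}T12:00:00", text=tx, **kw)
            for i, tx in enumerate(texts)
        ],
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A 200-user balanced corpus shared by the cheaper integration tests."""
    cfg = SyntheticCorpusConfig(
        n_users=200,
        seed=42,
        declaration_rate=0.3,
        group_proportions=BALANCED_PROPORTIONS,
    )
    tweets, truth = generate_corpus(cfg)
    return cfg, tweets, truth
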