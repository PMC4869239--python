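"""LDA topic representation of timelines.

The competing representation to the bag of words: latent Dirichlet
allocation fitted on per-user *aggregated* writing records (never single
tweets — aggregation is what makes a short-text corpus dense enough for
topic inference), compressing each timeline from a vocabulary-sized count
vector to a K-simplex of topic proportions.  K defaults to 45 and can be
chosen by a cross-validated accuracy sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.utils.validation import check_is_fitted

from .classify import ClassifierConfig, crossvalidate, overall_accuracy
from .features import DocumentTermMatrix

__all__ = [
    "TopicModelConfig",
    "LdaTopicRepresenter",
    "fit_topics",
    "select_k",
    "feature_reduction",
]


@dataclass(frozen=True)
class TopicModelConfig:
    """Topic-count, prior and optimizer settings.

    Symmetric Dirichlet priors: document-topic concentration 1/K,
    topic-word 0.01 (standard sparse-topic defaults).  Batch variational
    inference with a fixed iteration budget keeps fitting deterministic
    under a fixed seed.
    """

    K: int = 45
    sweep_grid: tuple[int, ...] = (2, 5, 10, 20, 45)
    doc_topic_prior: float | None = None  # None -> 1/K
    topic_word_prior: float = 0.01
    n_iterations: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if list(self.sweep_grid) != sorted(set(self.sweep_grid)):
            raise ValueError("sweep_grid must be strictly increasing")


class LdaTopicRepresenter(TransformerMixin, BaseEstimator):
    """Fit LDA on a user-aggregated DTM; transform to topic simplices.

    Fitted attributes: ``components_`` (K x V topic-word matrix, rows
    normalized to simplices) and ``n_topics_``.  ``transform`` returns
    one K-vector per timeline summing to 1; a document with all-zero
    counts maps to the prior-mean (uniform under the symmetric prior)
    simplex.
    """

    def __init__(
        self,
        K: int = 45,
        doc_topic_prior: float | None = None,
        topic_word_prior: float = 0.01,
        n_iterations: int = 30,
        seed: int = 0,
    ):
        self.K = K
        self.doc_topic_prior = doc_topic_prior
        self.topic_word_prior = topic_word_prior
        self.n_iterations = n_iterations
        self.seed = seed

    def _counts(self, X):
        if isinstance(X, DocumentTermMatrix):
            return X.matrix
        return X

    def fit(self, X, y=None):
        counts = self._counts(X)
        n_docs = counts.shape[0]
        if self.K >= n_docs:
            raise ValueError(
                f"K={self.K} must be smaller than the number of "
                f"documents ({n_docs})"
            )
        self._lda_ = LatentDirichletAllocation(
            n_components=self.K,
            doc_topic_prior=self.doc_topic_prior or 1.0 / self.K,
            topic_word_prior=self.topic_word_prior,
            learning_method="batch",
            max_iter=self.n_iterations,
            random_state=self.seed,
        )
        self._lda_.fit(counts)
        comp = self._lda_.components_
        self.components_ = comp / comp.sum(axis=1, keepdims=True)
        self.n_topics_ = self.K
        if isinstance(X, DocumentTermMatrix):
            self.vocabulary_ = list(X.vocabulary)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "_lda_")
        counts = self._counts(X)
        theta = self._lda_.transform(counts)
        return theta / theta.sum(axis=1, keepdims=True)

    def top_terms(self, topic: int, n: int = 10) -> list[str]:
        check_is_fitted(self, "components_")
        order = np.argsort(self.components_[topic])[::-1][:n]
        vocab = getattr(self, "vocabulary_", None)
        if vocab is None:
            return [str(i) for i in order]
        return [vocab[i] for i in order]


def fit_topics(
    dtm: DocumentTermMatrix, config: TopicModelConfig | None = None
) -> LdaTopicRepresenter:
    """Fit the topic model on an aggregated-timeline DTM."""
    if config is None:
        config = TopicModelConfig()
    model = LdaTopicRepresenter(
        K=config.K,
        doc_topic_prior=config.doc_topic_prior,
        topic_word_prior=config.topic_word_prior,
        n_iterations=config.n_iterations,
        seed=config.seed,
    )
    return model.fit(dtm)


def select_k(
    dtm: DocumentTermMatrix,
    labels: Sequence,
    sweep_grid: Sequence[int] | None = None,
    cv_folds: int = 10,
    config: TopicModelConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> tuple[int, list[tuple[int, float]]]:
    """Choose K by a cross-validated classification-accuracy sweep.

    For each candidate K the topics are fitted, timelines represented on
    the K-simplex, and overall accuracy measured by pooled k-fold
    cross-validation; the argmax K is returned (smallest K on ties, for
    parsimony) together with the full ``(K, accuracy)`` curve.
    """
    if config is None:
        config = TopicModelConfig()
    grid = list(sweep_grid if sweep_grid is not None else config.sweep_grid)
    if not grid:
        raise ValueError("sweep grid must be non-empty")
    curve: list[tuple[int, float]] = []
    for K in grid:
        model = LdaTopicRepresenter(
            K=K,
            doc_topic_prior=config.doc_topic_prior,
            topic_word_prior=config.topic_word_prior,
            n_iterations=config.n_iterations,
            seed=config.seed,
        ).fit(dtm)
        theta = model.transform(dtm)
        cm = crossvalidate(
            theta, labels, folds=cv_folds, config=classifier_config
        )
        curve.append((K, overall_accuracy(cm)))
    best_k = max(curve, key=lambda kv: (kv[1], -kv[0]))[0]
    return best_k, curve


def feature_reduction(K: int, vocabulary_size: int) -> float:
    """Fractional feature-count reduction of the K-topic representation
    relative to the full vocabulary: ``1 - K / |V|``."""
    if vocabulary_size <= 0:
        raise ValueError("vocabulary_size must be positive")
    return 1.0 - K / vocabulary_size
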