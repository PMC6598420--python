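"""Latent semantic analysis features.

An m x n term-by-document count matrix M (rows = terms, columns =
subject documents) is decomposed as M = T S D^T and truncated to k
dimensions, where k comes from the Kaiser criterion (singular values
> 1.0), a cumulative *share* of the singular-value mass, or a fixed
*fraction* of the spectrum. Unseen or streaming documents are folded
into the space as v^T T_k S_k^{-1}, which maps a training document
exactly onto its own row of D_k. Semantic features are Euclidean
distances between projections, optionally min-max normalized, and
aggregated like the textual similarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .textual import BagDocument, aggregate_scores, SimilarityAggregate

__all__ = [
    "LsaConfig",
    "LsaModel",
    "LsaEmbedding",
    "fit_lsa",
    "select_dimension",
    "project_document",
    "semantic_feature_vector",
    "minmax_normalize",
]


@dataclass
class LsaConfig:
    """Dimensionality rule and preprocessing switches for the embedding."""

    dim_method: str = "kaiser"  # {"kaiser", "share", "fraction"}
    share_value: float = 0.5
    fraction_value: float = 0.5
    stem_stop: bool = False  # Porter stemming + stop-word removal before counting
    normalize: bool = False  # min-max scale distances before aggregation

    def __post_init__(self) -> None:
        if self.dim_method not in ("kaiser", "share", "fraction"):
            raise ValueError(f"unknown dimensionality method {self.dim_method!r}")
        if not 0.0 < self.share_value <= 1.0 or not 0.0 < self.fraction_value <= 1.0:
            raise ValueError("share_value and fraction_value must lie in (0, 1]")


def select_dimension(singular_values: Sequence[float], config: LsaConfig) -> int:
    """Retained dimensionality k for a nonincreasing singular-value sequence.

    kaiser: number of values > 1.0, floored at 1 (a zero-dimensional
    embedding is unusable); share: shortest prefix whose proportional sum
    meets the share; fraction: ceil(fraction * count).
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty singular value sequence")
    if config.dim_method == "kaiser":
        return max(1, int(np.sum(s > 1.0)))
    if config.dim_method == "share":
        cum = np.cumsum(s) / np.sum(s)
        return int(np.searchsorted(cum, config.share_value - 1e-12) + 1)
    return int(np.ceil(config.fraction_value * s.size))


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Affine rescale to [0, 1]: x' = (x - min) / (max - min).

    Constant input maps to all zeros (degenerate chunks occur early in
    streams, so this is not an error).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty sequence")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


class LsaEmbedding(BaseEstimator, TransformerMixin):
    """Truncated-SVD embedding of bag-of-words subject documents.

    Parameters mirror :class:`LsaConfig`. Fitting builds the vocabulary
    and factors from a collection of :class:`BagDocument`;
    ``transform`` folds documents into the k-dimensional space.

    Attributes (after ``fit``): ``vocabulary_`` (term -> row index),
    ``singular_values_`` (all positive values, nonincreasing), ``k_``,
    ``term_factors_`` (m x k), ``doc_factors_`` (n x k),
    ``training_ids_``.
    """

    def __init__(
        self,
        dim_method: str = "kaiser",
        share_value: float = 0.5,
        fraction_value: float = 0.5,
        stem_stop: bool = False,
        normalize: bool = False,
    ):
        self.dim_method = dim_method
        self.share_value = share_value
        self.fraction_value = fraction_value
        self.stem_stop = stem_stop
        self.normalize = normalize

    def _config(self) -> LsaConfig:
        return LsaConfig(
            dim_method=self.dim_method,
            share_value=self.share_value,
            fraction_value=self.fraction_value,
            stem_stop=self.stem_stop,
            normalize=self.normalize,
        )

    def _prep(self, doc: BagDocument) -> BagDocument:
        return doc.transformed(stem_tokens=True, remove_stop=True) if self.stem_stop else doc

    def fit(self, X: Sequence[BagDocument], y=None) -> "LsaEmbedding":
        config = self._config()  # validates parameters
        docs = [self._prep(d) for d in X]
        if len(docs) < 2:
            raise ValueError("need at least 2 documents to fit an LSA space")
        vocab = sorted({t for d in docs for t in d.term_counts})
        if not vocab:
            raise ValueError("all documents are empty after preprocessing")
        index = {t: i for i, t in enumerate(vocab)}
        m, n = len(vocab), len(docs)
        M = np.zeros((m, n))
        for j, d in enumerate(docs):
            for t, c in d.term_counts.items():
                M[index[t], j] = c
        # economy SVD of the term-by-document matrix: M = T diag(s) D^T
        T, s, Dt = np.linalg.svd(M, full_matrices=False)
        tol = max(m, n) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > tol))
        s = s[:rank]
        k = min(select_dimension(s, config), rank) if rank else 1
        self.vocabulary_ = index
        self.singular_values_ = s
        self.k_ = k
        self.term_factors_ = T[:, :k]
        self.doc_factors_ = Dt[:k, :].T
        self.training_ids_ = [d.subject_id for d in docs]
        return self

    def transform(self, X: Sequence[BagDocument]) -> np.ndarray:
        check_is_fitted(self, "term_factors_")
        return np.vstack([self.project(d) for d in X])

    def project(self, doc: BagDocument) -> np.ndarray:
        """Folding-in projection v^T T_k S_k^{-1} of one document.

        A document sharing no vocabulary with the model projects to the
        zero vector (with a warning).
        """
        check_is_fitted(self, "term_factors_")
        d = self._prep(doc)
        v = np.zeros(len(self.vocabulary_))
        seen = 0
        for t, c in d.term_counts.items():
            i = self.vocabulary_.get(t)
            if i is not None:
                v[i] = c
                seen += 1
        if seen == 0:
            warnings.warn(
                f"document {doc.subject_id!r} shares no vocabulary with the LSA model; "
                "projecting to the zero vector"
            )
            return np.zeros(self.k_)
        return (v @ self.term_factors_) / self.singular_values_[: self.k_]


# dataclass view kept for serialization / functional use
@dataclass
class LsaModel:
    vocabulary: dict[str, int]
    singular_values: np.ndarray
    k: int
    term_factors: np.ndarray
    doc_factors: np.ndarray
    training_ids: list[str]
    config: LsaConfig = field(default_factory=LsaConfig)

    @classmethod
    def from_estimator(cls, est: LsaEmbedding) -> "LsaModel":
        return cls(
            vocabulary=est.vocabulary_,
            singular_values=est.singular_values_,
            k=est.k_,
            term_factors=est.term_factors_,
            doc_factors=est.doc_factors_,
            training_ids=est.training_ids_,
            config=est._config(),
        )


def fit_lsa(documents: Sequence[BagDocument], config: LsaConfig | None = None) -> LsaEmbedding:
    """Fit an :class:`LsaEmbedding` on a document collection."""
    config = config or LsaConfig()
    return LsaEmbedding(**vars(config)).fit(documents)


def project_document(model: LsaEmbedding, document: BagDocument) -> np.ndarray:
    return model.project(document)


def semantic_feature_vector(
    active: np.ndarray,
    positive_refs: np.ndarray,
    negative_refs: np.ndarray,
    normalize: bool = False,
) -> SimilarityAggregate:
    """Aggregated Euclidean distances of ``active`` to both reference sets.

    With ``normalize`` the pooled distance vector (positive + negative
    references of this active subject) is min-max scaled to [0, 1]
    before aggregation.
    """
    pos = np.atleast_2d(np.asarray(positive_refs, dtype=float))
    neg = np.atleast_2d(np.asarray(negative_refs, dtype=float))
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both reference classes must be non-empty")
    a = np.asarray(active, dtype=float)
    d_pos = np.linalg.norm(pos - a, axis=1)
    d_neg = np.linalg.norm(neg - a, axis=1)
    if normalize:
        pooled = minmax_normalize(np.concatenate([d_pos, d_neg]))
        d_pos, d_neg = pooled[: d_pos.size], pooled[d_pos.size :]
    out = SimilarityAggregate()
    out.stats[("lsa", "positive")] = aggregate_scores(d_pos)
    out.stats[("lsa", "negative")] = aggregate_scores(d_neg)
    return out
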