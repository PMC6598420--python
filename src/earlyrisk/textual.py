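"""Bag-of-words subject documents and textual similarity features.

Each subject is represented as a single document concatenating the
selected textual fields of all their writings. Two similarity measures
are computed between an *active* subject and the reference documents of
each class: cosine similarity over IDF-weighted term-count vectors
(vector space model, IDF = ln(N/df) following Singhal) and the Okapi
BM25 score (probabilistic model, Robertson-Zaragoza IDF floored at 0).
Pairwise scores against each reference class are aggregated into
average / SD / min / max / median, always excluding the active subject
from its own reference sample (leave-one-out).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import Subject, Writing, chunk_writings, tokenize

__all__ = [
    "BagDocument",
    "IdfTable",
    "Bm25Params",
    "SimilarityAggregate",
    "build_bag",
    "compute_idf",
    "cosine_similarity",
    "bm25_score",
    "similarity_feature_vector",
    "aggregate_scores",
    "FIELD_SCHEMES",
]

FIELD_SCHEMES = {"text_only": ("text",), "all_fields": ("title", "info", "text")}

AGG_NAMES = ("avg", "sd", "min", "max", "median")


@dataclass
class BagDocument:
    """A subject-as-document bag of words."""

    subject_id: str
    field_scheme: str
    term_counts: Counter = field(default_factory=Counter)

    @property
    def length(self) -> int:
        """l(d): total number of term occurrences."""
        return sum(self.term_counts.values())

    def transformed(self, *, stem_tokens: bool = False, remove_stop: bool = False) -> "BagDocument":
        """Bag with stop words removed and/or terms Porter-stemmed."""
        if not (stem_tokens or remove_stop):
            return self
        from .stemming import STOP_WORDS, stem

        counts: Counter = Counter()
        for term, c in self.term_counts.items():
            if remove_stop and term in STOP_WORDS:
                continue
            counts[stem(term) if stem_tokens else term] += c
        return BagDocument(self.subject_id, self.field_scheme, counts)


@dataclass
class IdfTable:
    """Document frequencies and IDF values over a reference collection."""

    n_docs: int
    doc_freq: dict[str, int]

    def idf_cosine(self, term: str) -> float:
        """ln(N / df); 0 for unseen terms."""
        df = self.doc_freq.get(term, 0)
        if df == 0:
            return 0.0
        return math.log(self.n_docs / df)

    def idf_bm25(self, term: str) -> float:
        """ln((N - df + 0.5) / (df + 0.5)), floored at 0; 0 for unseen."""
        df = self.doc_freq.get(term, 0)
        if df == 0:
            return 0.0
        return max(0.0, math.log((self.n_docs - df + 0.5) / (df + 0.5)))


@dataclass
class Bm25Params:
    """k1 scales term frequency, b scales length normalization,
    avg_doc_len is the mean document length l over the collection."""

    k1: float = 1.2
    b: float = 0.75
    avg_doc_len: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or not 0.0 <= self.b <= 1.0 or self.avg_doc_len <= 0:
            raise ValueError("require k1 >= 0, b in [0,1], avg_doc_len > 0")


@dataclass
class SimilarityAggregate:
    """avg/SD/min/max/median of pairwise scores per measure x reference class."""

    stats: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        """Flat mapping with stable column names ``{measure}_{class}_{stat}``."""
        return {
            f"{measure}_{cls}_{agg}": v[agg]
            for (measure, cls), v in self.stats.items()
            for agg in AGG_NAMES
        }


def build_bag(
    subject: Subject,
    field_scheme: str = "all_fields",
    upto_chunk: int | None = None,
    n_chunks: int = 10,
) -> BagDocument:
    """Token counts over the concatenation of the subject's writings.

    With ``upto_chunk=i`` only writings in chunks ``1..i`` of the
    ``n_chunks``-chunk stream are included (the causally available
    history at chunk ``i``).
    """
    if field_scheme not in FIELD_SCHEMES:
        raise ValueError(f"unknown field scheme {field_scheme!r}")
    if upto_chunk is None:
        writings: Sequence[Writing] = subject.writings
    else:
        writings = chunk_writings(subject, n_chunks).upto(upto_chunk)
    counts: Counter = Counter()
    for w in writings:
        for f in FIELD_SCHEMES[field_scheme]:
            counts.update(tokenize(getattr(w, f)))
    return BagDocument(subject_id=subject.id, field_scheme=field_scheme, term_counts=counts)


def compute_idf(documents: Iterable[BagDocument]) -> IdfTable:
    """Document frequencies over ``documents`` (document = subject)."""
    docs = list(documents)
    if not docs:
        raise ValueError("need at least one document to compute IDF")
    df: Counter = Counter()
    for d in docs:
        df.update(d.term_counts.keys())
    return IdfTable(n_docs=len(docs), doc_freq=dict(df))


def average_doc_length(documents: Iterable[BagDocument]) -> float:
    docs = list(documents)
    if not docs:
        raise ValueError("empty collection")
    return max(1e-12, float(np.mean([d.length for d in docs])))


def cosine_similarity(q: BagDocument, d: BagDocument, idf: IdfTable) -> float:
    """Cosine of the IDF-weighted term-count vectors; 0 on zero norms."""
    dot = 0.0
    for term, cq in q.term_counts.items():
        cd = d.term_counts.get(term)
        if cd:
            w = idf.idf_cosine(term)
            dot += (cq * w) * (cd * w)
    if dot == 0.0:
        return 0.0
    nq = math.sqrt(sum((c * idf.idf_cosine(t)) ** 2 for t, c in q.term_counts.items()))
    nd = math.sqrt(sum((c * idf.idf_cosine(t)) ** 2 for t, c in d.term_counts.items()))
    if nq == 0.0 or nd == 0.0:
        return 0.0
    return dot / (nq * nd)


def bm25_score(
    q: BagDocument, d: BagDocument, params: Bm25Params, idf: IdfTable
) -> float:
    """Okapi BM25 score of document ``d`` against query document ``q``.

    Sum over q's distinct terms of
    IDF(w) * cnt(w, d) * (k1 + 1) / (cnt(w, d) + k1 * (1 - b + b * l(d)/l)).
    Asymmetric in (q, d) through the length normalization of ``d``.
    """
    ld = d.length
    norm = params.k1 * (1.0 - params.b + params.b * ld / params.avg_doc_len)
    score = 0.0
    for term in q.term_counts:
        cd = d.term_counts.get(term)
        if cd:
            score += idf.idf_bm25(term) * (cd * (params.k1 + 1.0)) / (cd + norm)
    return score


def aggregate_scores(scores: Sequence[float]) -> dict[str, float]:
    """avg/SD/min/max/median of a non-empty score sequence."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("cannot aggregate an empty score set")
    return {
        "avg": float(x.mean()),
        "sd": float(x.std(ddof=0)),
        "min": float(x.min()),
        "max": float(x.max()),
        "median": float(np.median(x)),
    }


def per_field_bags(
    subject: Subject, upto_chunk: int | None = None, n_chunks: int = 10
) -> dict[str, BagDocument]:
    """One single-field bag per textual field (title, info, text)."""
    if upto_chunk is None:
        writings: Sequence[Writing] = subject.writings
    else:
        writings = chunk_writings(subject, n_chunks).upto(upto_chunk)
    out = {}
    for f in ("title", "info", "text"):
        counts: Counter = Counter()
        for w in writings:
            counts.update(tokenize(getattr(w, f)))
        out[f] = BagDocument(subject_id=subject.id, field_scheme=f, term_counts=counts)
    return out


def summed_field_score(
    active_by_field: Mapping[str, BagDocument],
    ref_by_field: Mapping[str, BagDocument],
    idf_by_field: Mapping[str, IdfTable],
    params_by_field: Mapping[str, Bm25Params],
    measure: str,
) -> float:
    """Aggregation-over-parts variant: score per textual field, summed.

    Each field (title, info, text) is scored with its own IDF statistics
    and, for BM25, its own average field length; the per-field scores are
    added into a single similarity value.
    """
    total = 0.0
    for f, q in active_by_field.items():
        d = ref_by_field[f]
        if measure == "cosine":
            total += cosine_similarity(q, d, idf_by_field[f])
        elif measure == "bm25":
            total += bm25_score(q, d, params_by_field[f], idf_by_field[f])
        else:
            raise ValueError(f"unknown similarity measure {measure!r}")
    return total


def similarity_feature_vector(
    active: BagDocument,
    positive_refs: Sequence[BagDocument],
    negative_refs: Sequence[BagDocument],
    idf: IdfTable,
    params: Bm25Params | None = None,
    measures: Sequence[str] = ("cosine", "bm25"),
) -> SimilarityAggregate:
    """Aggregated similarities of ``active`` against both reference classes.

    The active subject is removed from the reference samples by id
    before scoring (leave-one-out).
    """
    params = params or Bm25Params()
    refs = {
        "positive": [d for d in positive_refs if d.subject_id != active.subject_id],
        "negative": [d for d in negative_refs if d.subject_id != active.subject_id],
    }
    for cls, docs in refs.items():
        if not docs:
            raise ValueError(f"no {cls} reference documents after excluding the active subject")
    out = SimilarityAggregate()
    for measure in measures:
        if measure not in ("cosine", "bm25"):
            raise ValueError(f"unknown similarity measure {measure!r}")
        for cls, docs in refs.items():
            if measure == "cosine":
                scores = [cosine_similarity(active, d, idf) for d in docs]
            else:
                scores = [bm25_score(active, d, params, idf) for d in docs]
            out.stats[(measure, cls)] = aggregate_scores(scores)
    return out
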