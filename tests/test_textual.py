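"""Textual similarity: bags, IDF, cosine/BM25 vs a brute-force oracle."""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from earlyrisk.corpus import Subject, Writing
from earlyrisk.textual import (
    BagDocument,
    Bm25Params,
    IdfTable,
    aggregate_scores,
    average_doc_length,
    bm25_score,
    build_bag,
    compute_idf,
    cosine_similarity,
    per_field_bags,
    similarity_feature_vector,
    summed_field_score,
)

from .conftest import T0, make_subject


def bag(sid: str, counts: dict[str, int]) -> BagDocument:
    return BagDocument(subject_id=sid, field_scheme="all_fields", term_counts=Counter(counts))


# ---------------------------------------------------------------------------
# independent naive implementations (the oracle the fast paths must match)


def naive_cosine(q: BagDocument, d: BagDocument, idf: IdfTable) -> float:
    vocab = sorted(set(q.term_counts) | set(d.term_counts))
    vq = [q.term_counts.get(t, 0) * idf.idf_cosine(t) for t in vocab]
    vd = [d.term_counts.get(t, 0) * idf.idf_cosine(t) for t in vocab]
    nq = math.sqrt(sum(x * x for x in vq))
    nd = math.sqrt(sum(x * x for x in vd))
    if nq == 0 or nd == 0:
        return 0.0
    return sum(a * b for a, b in zip(vq, vd)) / (nq * nd)


def naive_bm25(q: BagDocument, d: BagDocument, p: Bm25Params, idf: IdfTable) -> float:
    total = 0.0
    for term in q.term_counts:
        c = d.term_counts.get(term, 0)
        if c == 0:
            continue
        denom = c + p.k1 * (1 - p.b + p.b * d.length / p.avg_doc_len)
        total += idf.idf_bm25(term) * c * (p.k1 + 1) / denom
    return total


def random_toy_corpus(rng, n_docs=5, n_terms=10):
    terms = [f"t{i}" for i in range(n_terms)]
    docs = []
    for j in range(n_docs):
        counts = {t: int(c) for t, c in zip(terms, rng.integers(0, 5, n_terms)) if c > 0}
        if not counts:
            counts = {terms[0]: 1}
        docs.append(bag(f"d{j}", counts))
    return docs


class TestBags:
    def test_text_only_counts(self):
        s = Subject("s", "unknown", [Writing("", T0, "reddit", "a b a")])
        b = build_bag(s, "text_only")
        assert b.term_counts == Counter({"a": 2, "b": 1}) and b.length == 3

    def test_all_fields_includes_title_and_info(self):
        s = Subject("s", "unknown", [Writing("x", T0, "reddit", "y")])
        b = build_bag(s, "all_fields")
        assert b.term_counts == Counter({"x": 1, "reddit": 1, "y": 1})

    def test_upto_chunk_restricts_history(self):
        s = make_subject("s", n=20, text="tok")
        first = build_bag(s, "text_only", upto_chunk=1, n_chunks=10)
        assert first.length == 2  # oldest 10% of 20 writings
        full = build_bag(s, "text_only", upto_chunk=10, n_chunks=10)
        assert full.term_counts == build_bag(s, "text_only").term_counts

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            build_bag(make_subject("s"), "body_only")


class TestIdf:
    def test_term_in_all_docs_has_zero_cosine_idf(self):
        docs = [bag(f"d{i}", {"x": 1, f"u{i}": 1}) for i in range(4)]
        idf = compute_idf(docs)
        assert idf.idf_cosine("x") == 0.0

    def test_rare_term_idf_ln4(self):
        docs = [bag("a", {"r": 1}), bag("b", {"x": 1}), bag("c", {"x": 1}), bag("d", {"x": 1})]
        idf = compute_idf(docs)
        assert idf.idf_cosine("r") == pytest.approx(math.log(4.0))
        assert idf.idf_bm25("r") == pytest.approx(math.log(3.5 / 1.5))

    def test_common_term_bm25_idf_floored(self):
        docs = [bag(f"d{i}", {"x": 1}) for i in range(4)]
        idf = compute_idf(docs)
        assert idf.idf_bm25("x") == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_idf([])


class TestCosine:
    def test_identity_is_one(self):
        d = bag("d", {"a": 2, "b": 1})
        idf = IdfTable(n_docs=3, doc_freq={"a": 1, "b": 1})
        assert cosine_similarity(d, d, idf) == pytest.approx(1.0)

    def test_disjoint_vocab_is_zero(self):
        idf = IdfTable(n_docs=3, doc_freq={"a": 1, "b": 1})
        assert cosine_similarity(bag("q", {"a": 1}), bag("d", {"b": 1}), idf) == 0.0

    def test_zero_norm_scores_zero(self):
        # all terms in every doc -> idf 0 -> zero-norm vectors
        docs = [bag("a", {"x": 1}), bag("b", {"x": 2})]
        idf = compute_idf(docs)
        assert cosine_similarity(docs[0], docs[1], idf) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            docs = random_toy_corpus(rng, n_docs=6, n_terms=12)
            idf = compute_idf(docs)
            for q in docs:
                for d in docs:
                    assert cosine_similarity(q, d, idf) == pytest.approx(
                        naive_cosine(q, d, idf), abs=1e-12
                    )
                    # symmetry and range
                    assert cosine_similarity(q, d, idf) == pytest.approx(
                        cosine_similarity(d, q, idf), abs=1e-12
                    )
                    assert -1e-12 <= cosine_similarity(q, d, idf) <= 1 + 1e-12


class TestBm25:
    def test_no_shared_terms_is_zero(self):
        idf = IdfTable(n_docs=4, doc_freq={"a": 1, "b": 1})
        p = Bm25Params(avg_doc_len=2.0)
        assert bm25_score(bag("q", {"a": 1}), bag("d", {"b": 3}), p, idf) == 0.0

    def test_k1_zero_reduces_to_idf_sum(self):
        docs = [bag("a", {"x": 1, "y": 2}), bag("b", {"x": 1}), bag("c", {"z": 1})]
        idf = compute_idf(docs)
        p = Bm25Params(k1=0.0, b=0.75, avg_doc_len=average_doc_length(docs))
        got = bm25_score(docs[1], docs[0], p, idf)
        assert got == pytest.approx(idf.idf_bm25("x"))

    def test_monotone_in_term_count(self):
        idf = IdfTable(n_docs=10, doc_freq={"x": 2})
        p = Bm25Params(avg_doc_len=5.0)
        scores = [
            bm25_score(bag("q", {"x": 1}), bag("d", {"x": c, "pad": 1}), p, idf)
            for c in range(1, 6)
        ]
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            docs = random_toy_corpus(rng, n_docs=6, n_terms=12)
            idf = compute_idf(docs)
            p = Bm25Params(k1=1.2, b=0.75, avg_doc_len=average_doc_length(docs))
            for q in docs:
                for d in docs:
                    assert bm25_score(q, d, p, idf) == pytest.approx(
                        naive_bm25(q, d, p, idf), abs=1e-12
                    )
                    assert bm25_score(q, d, p, idf) >= 0.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            Bm25Params(k1=-0.1)
        with pytest.raises(ValueError):
            Bm25Params(b=1.5)


class TestAggregation:
    def test_singleton_reference_collapses_stats(self):
        stats = aggregate_scores([0.6])
        assert stats == {"avg": 0.6, "sd": 0.0, "min": 0.6, "max": 0.6, "median": 0.6}

    def test_order_statistics(self):
        stats = aggregate_scores([0.2, 0.4, 0.9])
        assert stats["median"] == 0.4 and stats["min"] == 0.2 and stats["max"] == 0.9

    def test_active_subject_excluded_from_references(self):
        active = bag("active", {"a": 1, "b": 1})
        pos = [bag("p1", {"a": 1}), bag("active", {"zzz": 9})]
        neg = [bag("n1", {"b": 1})]
        idf = compute_idf(pos + neg)
        agg = similarity_feature_vector(active, pos, neg, idf)
        # with self excluded the positive sample is just p1
        pos_only = similarity_feature_vector(active, [pos[0]], neg, idf)
        assert agg.stats == pos_only.stats

    def test_empty_reference_class_after_exclusion(self):
        active = bag("x", {"a": 1})
        idf = compute_idf([active])
        with pytest.raises(ValueError, match="positive"):
            similarity_feature_vector(active, [bag("x", {"a": 1})], [bag("n", {"a": 1})], idf)

    def test_min_le_median_le_max_invariant(self):
        rng = np.random.default_rng(3)
        docs = random_toy_corpus(rng, n_docs=6)
        idf = compute_idf(docs)
        agg = similarity_feature_vector(docs[0], docs[1:4], docs[4:], idf)
        for stats in agg.stats.values():
            assert stats["min"] <= stats["median"] <= stats["max"]
            assert stats["sd"] >= 0.0


class TestPerFieldAggregation:
    def test_summed_field_score_equals_sum_of_parts(self):
        s1 = Subject("s1", "unknown", [Writing("alpha beta", T0, "reddit", "gamma")])
        s2 = Subject("s2", "unknown", [Writing("alpha", T0, "reddit", "gamma gamma")])
        b1, b2 = per_field_bags(s1), per_field_bags(s2)
        idfs = {f: compute_idf([b1[f], b2[f]]) for f in b1}
        params = {f: Bm25Params(avg_doc_len=average_doc_length([b1[f], b2[f]])) for f in b1}
        total = summed_field_score(b1, b2, idfs, params, "cosine")
        parts = sum(cosine_similarity(b1[f], b2[f], idfs[f]) for f in b1)
        assert total == pytest.approx(parts, abs=1e-12)
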