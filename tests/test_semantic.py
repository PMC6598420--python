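"""LSA embedding: SVD identities, dimensionality rules, distances."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from earlyrisk.semantic import (
    LsaConfig,
    LsaEmbedding,
    fit_lsa,
    minmax_normalize,
    project_document,
    select_dimension,
    semantic_feature_vector,
)
from earlyrisk.textual import BagDocument


def bag(sid, counts):
    return BagDocument(subject_id=sid, field_scheme="all_fields", term_counts=Counter(counts))


class TestSelectDimension:
    @pytest.mark.parametrize(
        "values,config,expected",
        [
            ([3.2, 1.5, 0.9], LsaConfig(dim_method="kaiser"), 2),
            ([4, 3, 2, 1], LsaConfig(dim_method="share", share_value=0.8), 3),
            ([0.5, 0.4], LsaConfig(dim_method="kaiser"), 1),  # floor rule
            ([4, 3, 2, 1], LsaConfig(dim_method="fraction", fraction_value=0.5), 2),
            ([4, 3, 2], LsaConfig(dim_method="fraction", fraction_value=0.34), 2),
            ([10.0], LsaConfig(dim_method="share", share_value=1.0), 1),
        ],
    )
    def test_rules(self, values, config, expected):
        assert select_dimension(values, config) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_dimension([], LsaConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LsaConfig(dim_method="elbow")
        with pytest.raises(ValueError):
            LsaConfig(share_value=0.0)


class TestFit:
    def test_rank_one_matrix_yields_k1(self):
        docs = [bag("a", {"x": 1, "y": 2}), bag("b", {"x": 2, "y": 4})]
        model = fit_lsa(docs)
        assert model.k_ == 1
        assert len(model.singular_values_) == 1

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        docs = [
            bag(f"d{j}", {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 6, 4))})
            for j in range(4)
        ]
        model = LsaEmbedding(dim_method="fraction", fraction_value=1.0).fit(docs)
        vocab = model.vocabulary_
        M = np.zeros((len(vocab), len(docs)))
        for j, d in enumerate(docs):
            for t, c in d.term_counts.items():
                M[vocab[t], j] = c
        approx = (
            model.term_factors_
            * model.singular_values_[: model.k_]
        ) @ model.doc_factors_.T
        assert np.allclose(approx, M, atol=1e-8)

    def test_singular_values_positive_nonincreasing(self):
        rng = np.random.default_rng(1)
        docs = [
            bag(f"d{j}", {f"t{i}": int(c) + 1 for i, c in enumerate(rng.integers(0, 5, 6))})
            for j in range(5)
        ]
        model = fit_lsa(docs)
        s = model.singular_values_
        assert np.all(s > 0) and np.all(np.diff(s) <= 1e-12)

    def test_stem_stop_collapses_vocabulary(self):
        docs = [bag("a", {"running": 1, "runs": 1, "the": 3}), bag("b", {"run": 2})]
        model = LsaEmbedding(stem_stop=True).fit(docs)
        assert set(model.vocabulary_) == {"run"}

    def test_all_empty_documents_rejected(self):
        with pytest.raises(ValueError):
            fit_lsa([bag("a", {}), bag("b", {})])

    def test_too_few_documents_rejected(self):
        with pytest.raises(ValueError):
            fit_lsa([bag("a", {"x": 1})])


class TestProjection:
    def _model_and_docs(self):
        rng = np.random.default_rng(2)
        docs = [
            bag(f"d{j}", {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 7, 5))})
            for j in range(5)
        ]
        return fit_lsa(docs), docs

    def test_training_docs_project_onto_factor_rows(self):
        model, docs = self._model_and_docs()
        for j, d in enumerate(docs):
            assert np.allclose(model.project(d), model.doc_factors_[j], atol=1e-8)

    def test_duplicate_of_training_doc_matches(self):
        model, docs = self._model_and_docs()
        dup = bag("copy", dict(docs[2].term_counts))
        assert np.allclose(model.project(dup), model.doc_factors_[2], atol=1e-8)

    def test_out_of_vocabulary_projects_to_zero_with_warning(self):
        model, _ = self._model_and_docs()
        with pytest.warns(UserWarning, match="no vocabulary"):
            proj = project_document(model, bag("oov", {"zzz": 3}))
        assert np.allclose(proj, 0.0)


class TestDistances:
    def test_identical_reference_gives_zero_min(self):
        agg = semantic_feature_vector(
            np.array([1.0, 2.0]), np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[0.0, 0.0]])
        )
        assert agg.stats[("lsa", "positive")]["min"] == pytest.approx(0.0)

    def test_one_dimensional_example(self):
        agg = semantic_feature_vector(np.array([0.0]), np.array([[1.0], [3.0]]),
                                      np.array([[5.0]]))
        pos = agg.stats[("lsa", "positive")]
        assert pos["avg"] == pytest.approx(2.0) and pos["median"] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        active = rng.normal(size=3)
        pos = rng.normal(size=(4, 3))
        neg = rng.normal(size=(3, 3))
        agg = semantic_feature_vector(active, pos, neg)
        d_pos = sorted(float(np.sqrt(((p - active) ** 2).sum())) for p in pos)
        assert agg.stats[("lsa", "positive")]["min"] == pytest.approx(d_pos[0], abs=1e-12)
        assert agg.stats[("lsa", "positive")]["avg"] == pytest.approx(
            np.mean(d_pos), abs=1e-12
        )

    def test_normalized_distances_in_unit_interval(self):
        rng = np.random.default_rng(5)
        agg = semantic_feature_vector(
            rng.normal(size=2), rng.normal(size=(5, 2)), rng.normal(size=(5, 2)),
            normalize=True,
        )
        for stats in agg.stats.values():
            assert 0.0 <= stats["min"] and stats["max"] <= 1.0


class TestMinMax:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 4, 6], [0.0, 0.5, 1.0]),
            ([5], [0.0]),
            ([5, 5, 5], [0.0, 0.0, 0.0]),
            ([-1, 0, 3], [0.0, 0.25, 1.0]),
        ],
    )
    def test_examples(self, values, expected):
        assert minmax_normalize(values) == pytest.approx(expected)

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_range_and_idempotence(self, values):
        out = minmax_normalize(values)
        assert np.all(out >= 0.0) and np.all(out <= 1.0)
        if out.max() == 1.0 and out.min() == 0.0:
            assert minmax_normalize(out) == pytest.approx(out)
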