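"""Feature-set specification and per-subject feature matrix assembly.

A :class:`FeatureSetSpec` names which feature families enter a model:
textual similarity measures (cosine and/or BM25) under a field scheme,
one LSA variant (plain / normalized / stemmed / normalized_stemmed), and
the writing features. :class:`SubjectFeaturizer` is the fitted object:
``fit`` builds the reference bags, IDF statistics and LSA space from the
training subjects' full histories; ``transform`` turns subjects (full
histories, or the cumulative history up to a chunk when streaming) into
a feature matrix with stable column names. Training subjects are always
left out of their own reference samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import Subject
from .semantic import LsaEmbedding, semantic_feature_vector
from .textual import (
    AGG_NAMES,
    Bm25Params,
    average_doc_length,
    build_bag,
    compute_idf,
    similarity_feature_vector,
)
from .writing import WF_COLUMNS, compute_writing_features

__all__ = ["FeatureSetSpec", "SubjectFeaturizer", "LSA_VARIANTS"]

#: lsa_variant -> (stem_stop, normalize); None disables the family
LSA_VARIANTS = {
    "none": None,
    "plain": (False, False),
    "normalized": (False, True),
    "stemmed": (True, False),
    "normalized_stemmed": (True, True),
}


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which feature families a classifier consumes."""

    measures: tuple[str, ...] = ("cosine", "bm25")
    field_scheme: str = "all_fields"
    lsa_variant: str = "plain"
    include_wf: bool = True

    def __post_init__(self) -> None:
        for m in self.measures:
            if m not in ("cosine", "bm25"):
                raise ValueError(f"unknown measure {m!r}")
        if self.lsa_variant not in LSA_VARIANTS:
            raise ValueError(f"unknown lsa_variant {self.lsa_variant!r}")
        if not self.measures and self.lsa_variant == "none" and not self.include_wf:
            raise ValueError("at least one feature family must be enabled")


class SubjectFeaturizer(BaseEstimator, TransformerMixin):
    """Turn subjects into similarity + writing feature rows.

    Parameters
    ----------
    measures, field_scheme, lsa_variant, include_wf :
        See :class:`FeatureSetSpec`.
    k1, b :
        BM25 term-frequency and length-normalization parameters.
    n_chunks :
        Chunking granularity used when ``transform`` is given
        ``upto_chunk``.

    Attributes (after ``fit``): ``ref_bags_`` per class, ``idf_``,
    ``bm25_params_``, ``lsa_`` (fitted embedding or None),
    ``ref_projections_`` per class, ``feature_names_``.
    """

    def __init__(
        self,
        measures: tuple[str, ...] = ("cosine", "bm25"),
        field_scheme: str = "all_fields",
        lsa_variant: str = "plain",
        include_wf: bool = True,
        k1: float = 1.2,
        b: float = 0.75,
        n_chunks: int = 10,
    ):
        self.measures = measures
        self.field_scheme = field_scheme
        self.lsa_variant = lsa_variant
        self.include_wf = include_wf
        self.k1 = k1
        self.b = b
        self.n_chunks = n_chunks

    @classmethod
    def from_spec(cls, spec: FeatureSetSpec, **kwargs) -> "SubjectFeaturizer":
        return cls(
            measures=spec.measures,
            field_scheme=spec.field_scheme,
            lsa_variant=spec.lsa_variant,
            include_wf=spec.include_wf,
            **kwargs,
        )

    @property
    def spec(self) -> FeatureSetSpec:
        return FeatureSetSpec(
            measures=tuple(self.measures),
            field_scheme=self.field_scheme,
            lsa_variant=self.lsa_variant,
            include_wf=self.include_wf,
        )

    def fit(self, X: list[Subject], y=None) -> "SubjectFeaturizer":
        spec = self.spec  # validates
        pos = [s for s in X if s.label == "positive"]
        neg = [s for s in X if s.label == "negative"]
        if not pos or not neg:
            raise ValueError("training subjects must include both classes")

        names: list[str] = []
        if spec.measures:
            self.ref_bags_ = {
                "positive": [build_bag(s, self.field_scheme) for s in pos],
                "negative": [build_bag(s, self.field_scheme) for s in neg],
            }
            all_bags = self.ref_bags_["positive"] + self.ref_bags_["negative"]
            self.idf_ = compute_idf(all_bags)
            self.bm25_params_ = Bm25Params(
                k1=self.k1, b=self.b, avg_doc_len=average_doc_length(all_bags)
            )
            names += [
                f"{m}_{cls}_{agg}"
                for m in spec.measures
                for cls in ("positive", "negative")
                for agg in AGG_NAMES
            ]
        else:
            self.ref_bags_ = None
            self.idf_ = None
            self.bm25_params_ = None

        variant = LSA_VARIANTS[spec.lsa_variant]
        if variant is not None:
            stem_stop, normalize = variant
            # the LSA space always uses all available textual information
            pos_bags = [build_bag(s, "all_fields") for s in pos]
            neg_bags = [build_bag(s, "all_fields") for s in neg]
            self.lsa_ = LsaEmbedding(stem_stop=stem_stop, normalize=normalize).fit(
                pos_bags + neg_bags
            )
            self.ref_projections_ = {
                "positive": (
                    [b.subject_id for b in pos_bags],
                    self.lsa_.transform(pos_bags),
                ),
                "negative": (
                    [b.subject_id for b in neg_bags],
                    self.lsa_.transform(neg_bags),
                ),
            }
            names += [
                f"lsa_{cls}_{agg}" for cls in ("positive", "negative") for agg in AGG_NAMES
            ]
        else:
            self.lsa_ = None
            self.ref_projections_ = None

        if spec.include_wf:
            names += list(WF_COLUMNS)
        self.feature_names_ = names
        return self

    def _row(self, subject: Subject, upto_chunk: int | None) -> dict[str, float]:
        row: dict[str, float] = {}
        if self.ref_bags_ is not None:
            bag = build_bag(subject, self.field_scheme, upto_chunk, self.n_chunks)
            agg = similarity_feature_vector(
                bag,
                self.ref_bags_["positive"],
                self.ref_bags_["negative"],
                self.idf_,
                self.bm25_params_,
                measures=tuple(self.measures),
            )
            row.update(agg.as_row())
        if self.lsa_ is not None:
            bag = build_bag(subject, "all_fields", upto_chunk, self.n_chunks)
            import warnings as _warnings

            with _warnings.catch_warnings():
                # empty early-chunk histories legitimately project to zero
                _warnings.simplefilter("ignore")
                proj = self.lsa_.project(bag)
            refs = {}
            for cls in ("positive", "negative"):
                ids, mat = self.ref_projections_[cls]
                keep = [i for i, sid in enumerate(ids) if sid != subject.id]
                if not keep:
                    raise ValueError(f"no {cls} LSA references left for {subject.id!r}")
                refs[cls] = mat[keep]
            agg = semantic_feature_vector(
                proj, refs["positive"], refs["negative"], normalize=self.lsa_.normalize
            )
            row.update(agg.as_row())
        if self.include_wf:
            row.update(compute_writing_features(subject, upto_chunk, self.n_chunks))
        return row

    def transform(self, X: list[Subject], upto_chunk: int | None = None) -> pd.DataFrame:
        """Feature matrix for ``X`` (cumulative to ``upto_chunk`` if given)."""
        check_is_fitted(self, "feature_names_")
        rows = [self._row(s, upto_chunk) for s in X]
        df = pd.DataFrame(rows, index=[s.id for s in X])
        return df.reindex(columns=self.feature_names_)
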