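"""Sequential decision models: singleton and dual random-forest detectors.

Both detectors observe each subject's writings chunk by chunk and, at
every chunk boundary, either emit a final verdict (depression /
nondepression) or delay. The *singleton* detector uses one probabilistic
classifier with chunk-indexed threshold functions th+(i) and th-(i)
(decreasing step schedule 0.9, 0.8, 0.7, 0.6, then 0.5). The *dual*
detector uses two independently-featured classifiers: while fewer than
``th_w`` writings have been seen, the positive model may emit depression
at probability >= 0.9; from ``th_w`` writings on, the negative model may
emit nondepression at probability >= 0.5. Decisions are final; subjects
still undecided after the last chunk are forced to nondepression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .corpus import ChunkedStream, Corpus, Subject, chunk_writings
from .features import FeatureSetSpec, SubjectFeaturizer

__all__ = [
    "ThresholdSchedule",
    "threshold_at",
    "Decision",
    "StreamResult",
    "SingletonDetector",
    "DualDetector",
    "run_stream",
    "dual_preset",
    "DEFAULT_STEP_VALUES",
]

#: decreasing step schedule over the tuning grid's values; chunk i >= 5 -> 0.5
DEFAULT_STEP_VALUES = (0.9, 0.8, 0.7, 0.6, 0.5)


@dataclass(frozen=True)
class ThresholdSchedule:
    """Chunk-indexed decision threshold: a decreasing step or a constant."""

    kind: str = "step"  # {"step", "constant"}
    values: tuple[float, ...] = DEFAULT_STEP_VALUES
    constant: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("step", "constant"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        vals = self.values if self.kind == "step" else (self.constant,)
        for v in vals:
            if not 0.5 <= v <= 1.0:
                raise ValueError("threshold values must lie in [0.5, 1.0]")
        if self.kind == "step" and any(
            a < b for a, b in zip(self.values, self.values[1:])
        ):
            raise ValueError("step schedule must be nonincreasing")


def threshold_at(schedule: ThresholdSchedule, i: int, n_chunks: int = 10) -> float:
    """Threshold for chunk ``i`` (1-based); steps saturate at their last value."""
    if not 1 <= i <= n_chunks:
        raise ValueError(f"chunk index {i} out of range 1..{n_chunks}")
    if schedule.kind == "constant":
        return schedule.constant
    return schedule.values[min(i, len(schedule.values)) - 1]


@dataclass(frozen=True)
class Decision:
    """One emitted decision: verdict at chunk ``chunk`` after seeing ``k`` writings."""

    verdict: str  # {"depression", "nondepression", "delay"}
    chunk: int
    k: int

    @property
    def final(self) -> bool:
        return self.verdict != "delay"


@dataclass
class SubjectStreamOutcome:
    subject_id: str
    gt: str  # ground-truth label
    verdict: str  # final: "depression" | "nondepression"
    k: int  # writings seen at emission
    chunk: int  # emission chunk (1-based)
    forced_at_end: bool = False
    at_final_chunk: bool = False


@dataclass
class StreamResult:
    """Per-subject final verdicts of one streaming pass."""

    n_chunks: int
    outcomes: list[SubjectStreamOutcome] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.outcomes)


def _labels(subjects: Sequence[Subject]) -> np.ndarray:
    labels = {s.label for s in subjects}
    if not {"positive", "negative"} <= labels:
        raise ValueError("training data must contain both positive and negative subjects")
    return np.array([1 if s.label == "positive" else 0 for s in subjects])


def _as_subjects(data: Corpus | Sequence[Subject]) -> list[Subject]:
    return list(data.subjects) if isinstance(data, Corpus) else list(data)


class SingletonDetector(BaseEstimator):
    """One random forest plus positive/negative threshold functions.

    The classifier is trained on full-history feature vectors; at stream
    time the active subject's features are recomputed from the cumulative
    history at each chunk. The positive rule is checked before the
    negative one (risk-averse tie-break).
    """

    def __init__(
        self,
        feature_spec: FeatureSetSpec | None = None,
        n_trees: int = 100,
        random_state: int = 0,
        pos_schedule: ThresholdSchedule | None = None,
        neg_schedule: ThresholdSchedule | None = None,
        n_chunks: int = 10,
        k1: float = 1.2,
        b: float = 0.75,
    ):
        self.feature_spec = feature_spec
        self.n_trees = n_trees
        self.random_state = random_state
        self.pos_schedule = pos_schedule
        self.neg_schedule = neg_schedule
        self.n_chunks = n_chunks
        self.k1 = k1
        self.b = b

    def _schedules(self) -> tuple[ThresholdSchedule, ThresholdSchedule]:
        pos = self.pos_schedule or ThresholdSchedule()
        neg = self.neg_schedule or ThresholdSchedule()
        return pos, neg

    def fit(self, X: Corpus | Sequence[Subject], y=None) -> "SingletonDetector":
        subjects = _as_subjects(X)
        spec = self.feature_spec or FeatureSetSpec()
        self.featurizer_ = SubjectFeaturizer.from_spec(
            spec, k1=self.k1, b=self.b, n_chunks=self.n_chunks
        )
        self.featurizer_.fit(subjects)
        features = self.featurizer_.transform(subjects)
        target = _labels(subjects)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        ).fit(features.to_numpy(), target)
        return self

    def predict_proba_at(self, subject: Subject, upto_chunk: int | None = None) -> float:
        """P(positive) from the cumulative history through ``upto_chunk``."""
        check_is_fitted(self, "forest_")
        row = self.featurizer_.transform([subject], upto_chunk=upto_chunk)
        proba = self.forest_.predict_proba(row.to_numpy())[0]
        return float(proba[list(self.forest_.classes_).index(1)])

    def decide(self, p_pos: float, i: int) -> Decision:
        """Apply the threshold functions to P(positive) at chunk ``i``."""
        pos_sched, neg_sched = self._schedules()
        if p_pos >= threshold_at(pos_sched, i, self.n_chunks):
            verdict = "depression"
        elif 1.0 - p_pos >= threshold_at(neg_sched, i, self.n_chunks):
            verdict = "nondepression"
        else:
            verdict = "delay"
        return Decision(verdict=verdict, chunk=i, k=-1)

    def decide_at(self, subject: Subject, stream: ChunkedStream, i: int) -> Decision:
        p_pos = self.predict_proba_at(subject, upto_chunk=i)
        d = self.decide(p_pos, i)
        return Decision(d.verdict, chunk=i, k=stream.cumulative_counts[i - 1])


class DualDetector(BaseEstimator):
    """Two independently-featured random forests switched on writing count.

    ``m+`` (depression detector) applies while the cumulative writing
    count k is strictly below ``th_w``; ``m-`` (nondepression detector)
    applies at k >= ``th_w``. Constant thresholds th+ = 0.9, th- = 0.5.
    """

    def __init__(
        self,
        pos_spec: FeatureSetSpec | None = None,
        neg_spec: FeatureSetSpec | None = None,
        th_w: int = 6,
        th_pos: float = 0.9,
        th_neg: float = 0.5,
        n_trees: int = 100,
        random_state: int = 0,
        n_chunks: int = 10,
        k1: float = 1.2,
        b: float = 0.75,
    ):
        self.pos_spec = pos_spec
        self.neg_spec = neg_spec
        self.th_w = th_w
        self.th_pos = th_pos
        self.th_neg = th_neg
        self.n_trees = n_trees
        self.random_state = random_state
        self.n_chunks = n_chunks
        self.k1 = k1
        self.b = b

    def fit(self, X: Corpus | Sequence[Subject], y=None) -> "DualDetector":
        if self.th_w < 0:
            raise ValueError("th_w must be nonnegative")
        subjects = _as_subjects(X)
        target_pos = _labels(subjects)
        pos_spec = self.pos_spec or dual_preset("erde5_best")[0]
        neg_spec = self.neg_spec or dual_preset("erde5_best")[1]
        self.pos_featurizer_ = SubjectFeaturizer.from_spec(
            pos_spec, k1=self.k1, b=self.b, n_chunks=self.n_chunks
        ).fit(subjects)
        self.neg_featurizer_ = SubjectFeaturizer.from_spec(
            neg_spec, k1=self.k1, b=self.b, n_chunks=self.n_chunks
        ).fit(subjects)
        Xp = self.pos_featurizer_.transform(subjects).to_numpy()
        Xn = self.neg_featurizer_.transform(subjects).to_numpy()
        self.forest_pos_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        ).fit(Xp, target_pos)
        # m- is trained to predict nondepression cases
        self.forest_neg_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state
        ).fit(Xn, 1 - target_pos)
        return self

    def decide(self, p_pos: float, p_neg: float, k: int) -> Decision:
        """Dual decision for cumulative writing count ``k``."""
        if k < self.th_w:
            verdict = "depression" if p_pos >= self.th_pos else "delay"
        else:
            verdict = "nondepression" if p_neg >= self.th_neg else "delay"
        return Decision(verdict=verdict, chunk=-1, k=k)

    def decide_at(self, subject: Subject, stream: ChunkedStream, i: int) -> Decision:
        check_is_fitted(self, "forest_pos_")
        k = stream.cumulative_counts[i - 1]
        if k < self.th_w:
            row = self.pos_featurizer_.transform([subject], upto_chunk=i)
            proba = self.forest_pos_.predict_proba(row.to_numpy())[0]
            p_pos = float(proba[list(self.forest_pos_.classes_).index(1)])
            d = self.decide(p_pos, 0.0, k)
        else:
            row = self.neg_featurizer_.transform([subject], upto_chunk=i)
            proba = self.forest_neg_.predict_proba(row.to_numpy())[0]
            p_neg = float(proba[list(self.forest_neg_.classes_).index(1)])
            d = self.decide(0.0, p_neg, k)
        return Decision(d.verdict, chunk=i, k=k)


def dual_preset(name: str) -> tuple[FeatureSetSpec, FeatureSetSpec, int]:
    """Named dual-model configurations ``(pos_spec, neg_spec, th_w)``.

    ``erde5_best``: positive model = cosine + BM25 on the text field +
    plain LSA + WF; negative model = normalized LSA; th_w = 6.
    ``erde50_best``: same positive model; negative model = LSA with
    stemming and stop-word removal; th_w = 53.
    """
    pos = FeatureSetSpec(
        measures=("cosine", "bm25"),
        field_scheme="text_only",
        lsa_variant="plain",
        include_wf=True,
    )
    if name == "erde5_best":
        neg = FeatureSetSpec(measures=(), lsa_variant="normalized", include_wf=False)
        return pos, neg, 6
    if name == "erde50_best":
        neg = FeatureSetSpec(measures=(), lsa_variant="stemmed", include_wf=False)
        return pos, neg, 53
    raise ValueError(f"unknown dual preset {name!r}")


def run_stream(
    model, data: Corpus | Sequence[Subject], n_chunks: int = 10
) -> StreamResult:
    """Stream every subject through ``model`` chunk by chunk.

    ``model`` must provide ``decide_at(subject, stream, i) -> Decision``.
    The first final verdict freezes a subject (later chunks are never
    evaluated); subjects still undecided after the last chunk are forced
    to nondepression with ``forced_at_end`` set.
    """
    subjects = _as_subjects(data)
    result = StreamResult(n_chunks=n_chunks)
    for subject in subjects:
        stream = chunk_writings(subject, n_chunks)
        outcome = None
        for i in range(1, n_chunks + 1):
            decision = model.decide_at(subject, stream, i)
            if decision.final:
                outcome = SubjectStreamOutcome(
                    subject_id=subject.id,
                    gt=subject.label,
                    verdict=decision.verdict,
                    k=stream.cumulative_counts[i - 1],
                    chunk=i,
                    forced_at_end=False,
                    at_final_chunk=(i == n_chunks),
                )
                break
        if outcome is None:
            outcome = SubjectStreamOutcome(
                subject_id=subject.id,
                gt=subject.label,
                verdict="nondepression",
                k=stream.cumulative_counts[-1],
                chunk=n_chunks,
                forced_at_end=True,
                at_final_chunk=True,
            )
        result.outcomes.append(outcome)
    return result
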