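"""Time-aware scoring: latency cost, ERDE, effectiveness metrics, baselines.

ERDE_o (early risk detection error) charges, per subject: c_fp for a
false positive, c_fn for a false negative, nothing for a true negative,
and lc_o(k) * c_tp for a true positive emitted after seeing k writings,
where lc_o(k) = 1 - 1/(1 + e^(k - o)) is a sigmoid latency cost with
midpoint at o writings. By convention c_fn = 1, c_tp = c_fn, and c_fp
defaults to the proportion of positive subjects in the evaluated set.
A correct depression verdict emitted only at the final chunk is costed
as a false negative (late detections count as missed), which is what
makes a perfect-but-maximally-late oracle score exactly like the
all-nondepression policy. The reported ERDE is the per-subject mean,
displayed x100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .corpus import Corpus, Subject
from .models import Decision, SubjectStreamOutcome, run_stream

__all__ = [
    "ErdeParams",
    "SubjectOutcome",
    "EvalReport",
    "latency_cost",
    "erde",
    "classification_metrics",
    "baseline_policy",
    "evaluate",
]

SubjectOutcome = SubjectStreamOutcome  # gt, verdict, k, chunk, flags


@dataclass(frozen=True)
class ErdeParams:
    """Cost constants for ERDE_o.

    ``c_fp=None`` means "compute as the positive proportion of the
    evaluated set"; pass a number (e.g. 0.1296) to fix it. ``c_tp``
    defaults to ``c_fn`` — a late detection is as bad as a miss.
    """

    o: int = 5
    c_fn: float = 1.0
    c_fp: float | None = None
    c_tp: float | None = None

    def __post_init__(self) -> None:
        if self.o < 1:
            raise ValueError("latency offset o must be >= 1")
        for c in (self.c_fn, self.c_fp, self.c_tp):
            if c is not None and not 0.0 <= c <= 1.0:
                raise ValueError("costs must lie in [0, 1]")

    def resolve(self, outcomes: list[SubjectOutcome]) -> tuple[float, float, float]:
        """(c_fp, c_fn, c_tp) with data-dependent defaults filled in."""
        c_fp = self.c_fp
        if c_fp is None:
            n = len(outcomes)
            c_fp = sum(1 for oc in outcomes if oc.gt == "positive") / n if n else 0.0
        c_tp = self.c_tp if self.c_tp is not None else self.c_fn
        return c_fp, self.c_fn, c_tp


@dataclass
class EvalReport:
    """ERDE plus positive-class effectiveness for one evaluation pass."""

    o: int
    erde: float  # internal [0, 1] mean
    precision: float
    recall: float
    f1: float
    per_subject_cost: list[float] = field(default_factory=list)
    outcomes: list[SubjectOutcome] = field(default_factory=list)

    @property
    def erde_pct(self) -> float:
        """ERDE on the x100 display scale."""
        return 100.0 * self.erde


def latency_cost(k: float, o: float) -> float:
    """lc_o(k) = 1 - 1/(1 + e^(k - o)); 0.5 at k = o, increasing in k."""
    if k < 0:
        raise ValueError("delay k must be nonnegative")
    return float(expit(k - o))


def _subject_cost(
    oc: SubjectOutcome, o: int, c_fp: float, c_fn: float, c_tp: float
) -> float:
    positive_gt = oc.gt == "positive"
    positive_verdict = oc.verdict == "depression"
    if positive_verdict and not positive_gt:
        return c_fp
    if not positive_verdict and positive_gt:
        return c_fn
    if positive_verdict and positive_gt:
        # late-positive rule: a correct depression verdict emitted only at
        # the final chunk counts as a miss
        if oc.at_final_chunk or oc.forced_at_end:
            return c_fn
        return latency_cost(oc.k, o) * c_tp
    return 0.0  # true negative: no repercussion


def classification_metrics(outcomes: list[SubjectOutcome]) -> tuple[float, float, float]:
    """Positive-class (precision, recall, F1); zero-division maps to 0."""
    tp = sum(1 for oc in outcomes if oc.verdict == "depression" and oc.gt == "positive")
    fp = sum(1 for oc in outcomes if oc.verdict == "depression" and oc.gt != "positive")
    fn = sum(1 for oc in outcomes if oc.verdict != "depression" and oc.gt == "positive")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def erde(outcomes: list[SubjectOutcome], params: ErdeParams) -> EvalReport:
    """Mean per-subject ERDE_o cost plus effectiveness metrics."""
    if not outcomes:
        raise ValueError("no subject outcomes to score")
    for oc in outcomes:
        if oc.verdict not in ("depression", "nondepression"):
            raise ValueError(f"subject {oc.subject_id!r} has no final verdict")
        if oc.gt not in ("positive", "negative"):
            raise ValueError(f"subject {oc.subject_id!r} has no ground-truth label")
    c_fp, c_fn, c_tp = params.resolve(outcomes)
    costs = [_subject_cost(oc, params.o, c_fp, c_fn, c_tp) for oc in outcomes]
    precision, recall, f1 = classification_metrics(outcomes)
    return EvalReport(
        o=params.o,
        erde=float(np.mean(costs)),
        precision=precision,
        recall=recall,
        f1=f1,
        per_subject_cost=costs,
        outcomes=list(outcomes),
    )


# ---------------------------------------------------------------------------
# baseline policies


class _Policy:
    """A stream policy: decides per chunk without looking at features."""

    def decide_at(self, subject: Subject, stream, i: int) -> Decision:
        raise NotImplementedError


class _ConstantPolicy(_Policy):
    def __init__(self, verdict: str):
        self.verdict = verdict

    def decide_at(self, subject, stream, i):
        return Decision(self.verdict, chunk=i, k=stream.cumulative_counts[i - 1])


class _OraclePolicy(_Policy):
    def __init__(self, chunk: int):
        self.chunk = chunk

    def decide_at(self, subject, stream, i):
        if subject.label not in ("positive", "negative"):
            raise ValueError(f"oracle policy needs ground truth for {subject.id!r}")
        if i < self.chunk:
            verdict = "delay"
        else:
            verdict = "depression" if subject.label == "positive" else "nondepression"
        return Decision(verdict, chunk=i, k=stream.cumulative_counts[i - 1])


class _RandomPolicy(_Policy):
    """Equiprobable depression / nondepression / delay per subject per chunk."""

    def __init__(self, seed: int | None):
        self._rng = np.random.default_rng(seed)

    def decide_at(self, subject, stream, i):
        verdict = self._rng.choice(["depression", "nondepression", "delay"])
        return Decision(str(verdict), chunk=i, k=stream.cumulative_counts[i - 1])


def baseline_policy(
    kind: str, oracle_chunk: int | None = None, seed: int | None = None
) -> _Policy:
    """Naive stream policies: random, all_depressed, nondepressed, oracle."""
    if kind == "random":
        return _RandomPolicy(seed)
    if kind == "all_depressed":
        return _ConstantPolicy("depression")
    if kind == "nondepressed":
        return _ConstantPolicy("nondepression")
    if kind == "oracle":
        if oracle_chunk is None:
            raise ValueError("oracle policy requires oracle_chunk")
        return _OraclePolicy(oracle_chunk)
    raise ValueError(f"unknown baseline policy {kind!r}")


def evaluate(
    model_or_policy,
    test_data: Corpus | list[Subject],
    offsets: tuple[int, ...] = (5, 50),
    n_chunks: int = 10,
    params: ErdeParams | None = None,
) -> dict[int, EvalReport]:
    """Stream ``test_data`` once and score ERDE_o for each offset."""
    base = params or ErdeParams()
    result = run_stream(model_or_policy, test_data, n_chunks=n_chunks)
    return {o: erde(result.outcomes, replace(base, o=o)) for o in offsets}
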