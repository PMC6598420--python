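"""Descriptive analysis of posting behaviour by subject class.

Covers the three behavioural signals used for screening: textual
spreading (words per writing), time gap between consecutive writings,
and time span (day-of-week / hour-of-day activity), plus the two-group
hypothesis contrasts (variance-ratio F test followed by a two-sample t
test whose pooled/Welch form is chosen by the F outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corpus import Corpus, Subject, tokenize

__all__ = [
    "DistributionSummary",
    "TimespanProfile",
    "TestResult",
    "word_count_distribution",
    "time_gap_summary",
    "timespan_profile",
    "compare_groups",
    "subject_gaps_days",
]

HOUR_CLASS_LABELS = ("0:00-5:59", "6:00-11:59", "12:00-17:59", "18:00-23:59")
DAY_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

_WORD_FIELDS = {"title": ("title",), "text": ("text",), "both": ("title", "text")}


def _stats_dict(x: np.ndarray) -> dict:
    q75, q25 = np.percentile(x, [75, 25])
    return {
        "n": int(x.size),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
        "iqr": float(q75 - q25),
    }


@dataclass
class DistributionSummary:
    """Per-class summary statistics and binned relative percentages."""

    variable: str
    per_class: dict[str, dict] = field(default_factory=dict)
    bin_edges: list[float] | None = None
    binned_percent: dict[str, list[float]] = field(default_factory=dict)
    missing_classes: list[str] = field(default_factory=list)


@dataclass
class TimespanProfile:
    """Percentage of writings per day of week and hour class, per class."""

    day_percent: dict[str, list[float]]
    hour_percent: dict[str, list[float]]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    kind: str  # {"variance-ratio F", "two-sample t"}
    sidedness: str = "two-sided"
    alpha: float = 0.05

    @property
    def rejects(self) -> bool:
        return self.p_value < self.alpha


def _per_writing_word_counts(subject: Subject, fields: tuple[str, ...]) -> np.ndarray:
    return np.array(
        [sum(len(tokenize(getattr(w, f))) for f in fields) for w in subject.writings],
        dtype=float,
    )


def word_count_distribution(
    corpus: Corpus, field_name: str = "both", bins=None
) -> DistributionSummary:
    """Per-class distribution of words per writing for a writing field.

    ``bins`` are histogram edges for the relative-percentage profile
    (default: 0, 1, 11, 101, inf — zero-word, short, medium, long).
    """
    if field_name not in _WORD_FIELDS:
        raise ValueError(f"unknown field {field_name!r}; use title/text/both")
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    if bins is None:
        bins = [0.0, 1.0, 11.0, 101.0, np.inf]
    fields = _WORD_FIELDS[field_name]
    out = DistributionSummary(variable=f"words_{field_name}", bin_edges=list(bins))
    for label in ("positive", "negative"):
        subjects = corpus.by_label(label)
        if not subjects:
            out.missing_classes.append(label)
            continue
        x = np.concatenate([_per_writing_word_counts(s, fields) for s in subjects])
        out.per_class[label] = _stats_dict(x)
        hist, _ = np.histogram(x, bins=np.asarray(bins, dtype=float))
        out.binned_percent[label] = list(100.0 * hist / x.size)
    return out


def subject_gaps_days(subject: Subject) -> np.ndarray:
    """Inter-writing gaps in days; a single-writing subject yields [0]."""
    if len(subject) < 2:
        return np.zeros(1)
    ts = np.array([w.date.timestamp() for w in subject.writings])
    return np.diff(ts) / 86400.0


def time_gap_summary(
    corpus: Corpus, scale: str = "days", log_offset_days: float = 1.0 / 86400.0
) -> DistributionSummary:
    """Per-class summary of inter-writing gaps, in days or natural log.

    The log scale uses ln(gap_days + offset) with a one-second offset so
    zero gaps stay finite, mirroring the writing-features transform.
    """
    if scale not in ("days", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    out = DistributionSummary(variable=f"time_gap_{scale}")
    for label in ("positive", "negative"):
        subjects = corpus.by_label(label)
        if not subjects:
            out.missing_classes.append(label)
            continue
        x = np.concatenate([subject_gaps_days(s) for s in subjects])
        if scale == "log":
            x = np.log(x + log_offset_days)
        out.per_class[label] = _stats_dict(x)
    return out


def timespan_profile(corpus: Corpus) -> TimespanProfile:
    """Writing-weighted day-of-week and hour-class percentages per class."""
    day: dict[str, list[float]] = {}
    hour: dict[str, list[float]] = {}
    for label in ("positive", "negative"):
        subjects = corpus.by_label(label)
        if not subjects:
            continue
        dows = []
        hcs = []
        for s in subjects:
            for w in s.writings:
                dows.append(w.date.weekday())
                hcs.append(w.date.hour // 6)
        n = len(dows)
        day[label] = list(100.0 * np.bincount(dows, minlength=7) / n)
        hour[label] = list(100.0 * np.bincount(hcs, minlength=4) / n)
    return TimespanProfile(day_percent=day, hour_percent=hour)


def compare_groups(
    sample_a, sample_b, alpha: float = 0.05
) -> tuple[TestResult, TestResult]:
    """Two-group contrast: variance-ratio F test, then a two-sample t test.

    The F test is two-sided on F = var(a)/var(b). The mean test uses the
    pooled (Student) form when the F test does not reject equality of
    variances at ``alpha``, and the Welch form otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 or vb == 0.0:
        which = "first" if va == 0.0 else "second"
        raise ValueError(f"zero-variance {which} sample; F test undefined")
    f_stat = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    cdf = stats.f.cdf(f_stat, dfa, dfb)
    f_p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    f_res = TestResult(float(f_stat), f_p, "variance-ratio F", alpha=alpha)

    equal_var = not (f_p < alpha)
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=equal_var)
    t_res = TestResult(float(t_stat), float(t_p), "two-sample t", alpha=alpha)
    return f_res, t_res
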