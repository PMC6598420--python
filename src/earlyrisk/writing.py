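"""Writing features (WF): textual spreading, time gap and time span.

Per-subject behavioural features: number of writings and words-per-
writing statistics (over all textual fields: title, info, text), raw and
log-transformed inter-writing gaps in seconds, and the percentage
profile of writing timestamps over days of the week, weekday/weekend and
four six-hour classes of the day. Column names follow the feature-group
labels (Writing, TimeGap, LogTimeGap, Day, Week, Hour) so feature-group
ablations are scriptable.
"""

from __future__ import annotations

import numpy as np

from .corpus import Subject, Writing, chunk_writings

__all__ = ["inter_writing_gaps", "compute_writing_features", "WF_COLUMNS", "WF_GROUPS"]

WF_GROUPS: dict[str, tuple[str, ...]] = {
    "Writing": ("NWritings", "AvgWords", "DevWords", "MinWords", "MaxWords", "MedWords"),
    "TimeGap": tuple(f"TimeGap_{s}" for s in ("avg", "sd", "min", "max", "median")),
    "LogTimeGap": tuple(f"LogTimeGap_{s}" for s in ("avg", "sd", "min", "max", "median")),
    "Day": tuple(f"Day_{i}" for i in range(1, 8)),  # Day_1 = Monday
    "Week": ("Weekday", "Weekend"),
    "Hour": tuple(f"Hour_{i}" for i in range(1, 5)),  # 0-5:59, 6-11:59, 12-17:59, 18-23:59
}

WF_COLUMNS: tuple[str, ...] = tuple(c for g in WF_GROUPS.values() for c in g)


def _scope(subject: Subject, upto_chunk: int | None, n_chunks: int) -> list[Writing]:
    if upto_chunk is None:
        return list(subject.writings)
    return chunk_writings(subject, n_chunks).upto(upto_chunk)


def inter_writing_gaps(
    subject: Subject, upto_chunk: int | None = None, n_chunks: int = 10
) -> np.ndarray:
    """Gaps in seconds between consecutive writings; [0] for one writing."""
    writings = _scope(subject, upto_chunk, n_chunks)
    if len(writings) < 2:
        return np.zeros(1)
    ts = np.array([w.date.timestamp() for w in writings])
    return np.diff(ts)


def _agg(x: np.ndarray, prefix: str) -> dict[str, float]:
    return {
        f"{prefix}_avg": float(x.mean()),
        f"{prefix}_sd": float(x.std(ddof=0)),
        f"{prefix}_min": float(x.min()),
        f"{prefix}_max": float(x.max()),
        f"{prefix}_median": float(np.median(x)),
    }


def compute_writing_features(
    subject: Subject, upto_chunk: int | None = None, n_chunks: int = 10
) -> dict[str, float]:
    """The WF vector of ``subject`` (optionally restricted to chunks 1..i).

    Word counts include every textual field of a writing; LogTimeGap is
    ln(1 + gap_seconds) so zero gaps stay finite; Day/Week/Hour are
    writing-weighted percentages of the subject's timestamps (UTC),
    weekend = Saturday + Sunday.
    """
    writings = _scope(subject, upto_chunk, n_chunks)
    if not writings:
        raise ValueError(f"subject {subject.id!r}: no writings in scope")

    words = np.array(
        [w.n_words(fields=("title", "info", "text")) for w in writings], dtype=float
    )
    gaps = inter_writing_gaps(subject, upto_chunk, n_chunks)
    log_gaps = np.log1p(gaps)

    n = len(writings)
    dows = np.array([w.date.weekday() for w in writings])
    hcs = np.array([w.date.hour // 6 for w in writings])
    day_pct = 100.0 * np.bincount(dows, minlength=7) / n
    hour_pct = 100.0 * np.bincount(hcs, minlength=4) / n

    out: dict[str, float] = {
        "NWritings": float(n),
        "AvgWords": float(words.mean()),
        "DevWords": float(words.std(ddof=0)),
        "MinWords": float(words.min()),
        "MaxWords": float(words.max()),
        "MedWords": float(np.median(words)),
    }
    out.update(_agg(gaps, "TimeGap"))
    out.update(_agg(log_gaps, "LogTimeGap"))
    out.update({f"Day_{i + 1}": float(day_pct[i]) for i in range(7)})
    out["Weekday"] = float(day_pct[:5].sum())
    out["Weekend"] = float(day_pct[5:].sum())
    out.update({f"Hour_{i + 1}": float(hour_pct[i]) for i in range(4)})
    return out
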