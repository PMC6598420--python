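"""Data model and I/O for subjects, writings and chunked streams.

A *writing* is a single post or comment: a ``(title, date, info, text)``
tuple. A *subject* is a chronologically ordered history of writings with a
binary depression label. For streaming evaluation a subject's history is
partitioned into ``n_chunks`` contiguous, near-equal chunks, oldest first;
decisions may only be emitted at chunk boundaries.

Two on-disk formats are supported: a per-subject XML dialect compatible
with the eRisk distribution (an ``INDIVIDUAL`` document with an ``ID``
element and repeated ``WRITING`` elements holding ``TITLE``/``DATE``/
``INFO``/``TEXT``), and a line-delimited JSON dialect with keys
``id``, ``label``, ``writings[{title, date, info, text}]``.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Writing",
    "Subject",
    "Corpus",
    "ChunkedStream",
    "CorpusFormatError",
    "RecordError",
    "tokenize",
    "chunk_writings",
    "read_corpus",
    "write_corpus",
    "filter_min_writings",
]

DATE_FORMAT = "%Y-%m-%d %H:%M:%S"
LABELS = ("positive", "negative", "unknown")

#: minimum history length in the eRisk dataset-construction rule
ERISK_MIN_WRITINGS = 10

# alphanumeric runs; punctuation and symbols act as separators
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


class CorpusFormatError(ValueError):
    """A file could not be parsed in the requested corpus format."""


class RecordError(ValueError):
    """A single record (writing or subject) is malformed."""


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens of ``text``.

    Words are maximal alphanumeric runs; punctuation, symbols and
    whitespace separate tokens. ``tokenize("") == []``.
    """
    if not text:
        return []
    return _TOKEN_RE.findall(text.lower())


def _parse_date(raw: str, subject_id: str | None = None) -> datetime:
    try:
        return datetime.strptime(raw.strip(), DATE_FORMAT).replace(tzinfo=timezone.utc)
    except ValueError as exc:
        who = f" (subject {subject_id!r})" if subject_id else ""
        raise RecordError(f"unparseable date {raw!r}{who}") from exc


@dataclass(frozen=True)
class Writing:
    """One post or comment: ``(title, date, info, text)``.

    ``title`` is empty for comments (replies to an existing post);
    ``text`` is empty for link submissions. ``date`` is a tz-aware UTC
    timestamp with second resolution.
    """

    title: str
    date: datetime
    info: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        if self.date.tzinfo is None:
            object.__setattr__(self, "date", self.date.replace(tzinfo=timezone.utc))

    def n_words(self, fields: Sequence[str] = ("title", "text")) -> int:
        return sum(len(tokenize(getattr(self, f))) for f in fields)


@dataclass
class Subject:
    """A labelled, chronologically sorted writing history."""

    id: str
    label: str = "unknown"
    writings: list[Writing] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise RecordError(f"subject {self.id!r}: unknown label {self.label!r}")
        if not self.writings:
            raise RecordError(f"subject {self.id!r}: empty writing history")
        self.writings = sorted(self.writings, key=lambda w: w.date)

    def __len__(self) -> int:
        return len(self.writings)


@dataclass
class Corpus:
    """A collection of subjects with unique ids."""

    subjects: list[Subject] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise RecordError(f"duplicate subject ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def by_label(self, label: str) -> list[Subject]:
        return [s for s in self.subjects if s.label == label]

    @property
    def n_positive(self) -> int:
        return len(self.by_label("positive"))

    @property
    def n_negative(self) -> int:
        return len(self.by_label("negative"))


@dataclass
class ChunkedStream:
    """Ordered partition of a subject's sorted writings into chunks.

    Chunk 1 holds the oldest writings; sizes differ by at most one, the
    earliest chunks absorbing any remainder. ``cumulative_counts[i-1]`` is
    the delay ``k`` (writings seen) after chunk ``i``.
    """

    subject_id: str
    chunks: list[list[Writing]]
    cumulative_counts: list[int]

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    def upto(self, i: int) -> list[Writing]:
        """All writings in chunks ``1..i`` (chronological)."""
        if not 1 <= i <= self.n_chunks:
            raise ValueError(f"chunk index {i} out of range 1..{self.n_chunks}")
        return [w for c in self.chunks[:i] for w in c]


def chunk_writings(subject: Subject, n_chunks: int = 10) -> ChunkedStream:
    """Partition ``subject``'s history into ``n_chunks`` contiguous chunks.

    With ``total = q * n_chunks + r`` the first ``r`` chunks receive
    ``q + 1`` writings. A subject with fewer writings than chunks yields
    trailing empty chunks only when total < n_chunks is unavoidable;
    sizes stay as equal as possible.
    """
    if n_chunks < 1:
        raise ValueError(f"n_chunks must be >= 1, got {n_chunks}")
    writings = subject.writings
    total = len(writings)
    q, r = divmod(total, n_chunks)
    chunks: list[list[Writing]] = []
    pos = 0
    for i in range(n_chunks):
        size = q + (1 if i < r else 0)
        chunks.append(writings[pos : pos + size])
        pos += size
    cumulative: list[int] = []
    seen = 0
    for c in chunks:
        seen += len(c)
        cumulative.append(seen)
    return ChunkedStream(subject_id=subject.id, chunks=chunks, cumulative_counts=cumulative)


# ---------------------------------------------------------------------------
# I/O


def _writing_to_dict(w: Writing) -> dict:
    return {
        "title": w.title,
        "date": w.date.strftime(DATE_FORMAT),
        "info": w.info,
        "text": w.text,
    }


def _writing_from_dict(d: dict, subject_id: str) -> Writing:
    try:
        return Writing(
            title=d.get("title", ""),
            date=_parse_date(d["date"], subject_id),
            info=d.get("info", ""),
            text=d.get("text", ""),
        )
    except KeyError as exc:
        raise RecordError(f"subject {subject_id!r}: writing missing field {exc}") from exc


def _read_jsonl(path: Path) -> Corpus:
    subjects = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: invalid JSON record") from exc
            sid = str(rec.get("id", f"line-{lineno}"))
            writings = [_writing_from_dict(w, sid) for w in rec.get("writings", [])]
            subjects.append(Subject(id=sid, label=rec.get("label", "unknown"), writings=writings))
    return Corpus(subjects=subjects)


def _read_subject_xml(path: Path, label: str = "unknown") -> Subject:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise CorpusFormatError(f"{path}: invalid XML: {exc}") from exc
    id_el = root.find("ID")
    sid = (id_el.text or "").strip() if id_el is not None else path.stem
    writings = []
    for wel in root.findall("WRITING"):
        def _text(tag: str) -> str:
            el = wel.find(tag)
            return (el.text or "") if el is not None else ""

        date_el = wel.find("DATE")
        if date_el is None or not (date_el.text or "").strip():
            raise RecordError(f"subject {sid!r}: WRITING without DATE in {path}")
        writings.append(
            Writing(
                title=_text("TITLE").strip(),
                date=_parse_date(date_el.text, sid),
                info=_text("INFO").strip(),
                text=_text("TEXT").strip(),
            )
        )
    return Subject(id=sid, label=label, writings=writings)


def _read_erisk_xml(path: Path) -> Corpus:
    """Read a directory of per-subject eRisk-style XML files.

    An optional ``risk_golden_truth.txt`` in the directory maps subject
    ids to labels (``<id> 1`` positive, ``<id> 0`` negative).
    """
    if path.is_file():
        return Corpus(subjects=[_read_subject_xml(path)])
    labels: dict[str, str] = {}
    truth = path / "risk_golden_truth.txt"
    if truth.exists():
        for line in truth.read_text(encoding="utf-8").splitlines():
            parts = line.split()
            if len(parts) >= 2:
                labels[parts[0]] = "positive" if parts[1].strip() == "1" else "negative"
    files = sorted(path.glob("*.xml"))
    if not files:
        raise CorpusFormatError(f"no .xml files under {path}")
    subjects = []
    for f in files:
        s = _read_subject_xml(f)
        s.label = labels.get(s.id, s.label)
        subjects.append(s)
    return Corpus(subjects=subjects)


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a :class:`Corpus` from ``path`` in ``{"erisk_xml", "jsonl"}``.

    Writings come back chronologically sorted per subject; empty titles
    and texts are preserved as empty strings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "erisk_xml":
        return _read_erisk_xml(path)
    raise ValueError(f"unknown corpus format {format!r}")


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Write ``corpus`` to ``path``; jsonl round-trips field-for-field."""
    if format != "jsonl":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in corpus.subjects:
            rec = {
                "id": s.id,
                "label": s.label,
                "writings": [_writing_to_dict(w) for w in s.writings],
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def filter_min_writings(
    corpus: Corpus, min_writings: int = ERISK_MIN_WRITINGS, *, warn: bool = True
) -> Corpus:
    """Drop subjects with fewer than ``min_writings`` writings.

    Mirrors the dataset-construction rule that only users with at least
    10 submissions are considered; it is a dataset rule, not a model
    requirement, so callers opt in.
    """
    kept = [s for s in corpus.subjects if len(s) >= min_writings]
    dropped = len(corpus.subjects) - len(kept)
    if dropped and warn:
        import logging

        logging.getLogger(__name__).warning(
            "dropped %d subjects with < %d writings", dropped, min_writings
        )
    meta = dict(corpus.metadata)
    meta["min_writings_filter"] = min_writings
    return Corpus(subjects=kept, metadata=meta)
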