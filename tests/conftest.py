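"""Shared fixtures: hand-built tiny corpora and small synthetic corpora."""

from __future__ import annotations

from dataclasses import replace
from datetime import datetime, timedelta, timezone

import pytest
from hypothesis import settings

from earlyrisk.corpus import Corpus, Subject, Writing
from earlyrisk.synthetic import GeneratorConfig, default_profiles, generate_corpus

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

T0 = datetime(2017, 3, 6, 12, 0, 0, tzinfo=timezone.utc)  # a Monday noon


def make_subject(
    sid: str,
    n: int = 10,
    label: str = "unknown",
    start: datetime = T0,
    gap_hours: float = 24.0,
    text: str = "some words here",
    title: str = "",
) -> Subject:
    writings = [
        Writing(
            title=title,
            date=start + timedelta(hours=gap_hours * i),
            info="reddit",
            text=text,
        )
        for i in range(n)
    ]
    return Subject(id=sid, label=label, writings=writings)


def composition_corpus(n_pos: int, n_neg: int, n_writings: int = 10) -> Corpus:
    """Labelled corpus whose content is irrelevant (for policy baselines)."""
    subjects = [
        make_subject(f"p{i}", n=n_writings, label="positive") for i in range(n_pos)
    ] + [make_subject(f"n{i}", n=n_writings, label="negative") for i in range(n_neg)]
    return Corpus(subjects=subjects)


def small_profiles(lexicon_weight: float = 0.5):
    """Default class profiles with short histories for fast model tests."""
    pos, neg = default_profiles()
    pos = replace(
        pos,
        n_writings_mean=30.0,
        n_writings_median=22.0,
        n_writings_bounds=(10.0, 80.0),
        lexicon_weight=lexicon_weight,
    )
    neg = replace(
        neg,
        n_writings_mean=35.0,
        n_writings_median=26.0,
        n_writings_bounds=(10.0, 80.0),
        lexicon_weight=lexicon_weight,
    )
    return pos, neg


def small_corpus(seed: int, n_pos: int = 30, n_neg: int = 60, lexicon_weight: float = 0.5):
    pos, neg = small_profiles(lexicon_weight)
    return generate_corpus(
        GeneratorConfig(
            n_positive=n_pos,
            n_negative=n_neg,
            seed=seed,
            positive_profile=pos,
            negative_profile=neg,
        )
    )


@pytest.fixture(scope="session")
def separable_corpus() -> Corpus:
    """High-signal synthetic corpus with short histories."""
    return small_corpus(seed=11)


@pytest.fixture(scope="session")
def calibration_corpus() -> Corpus:
    """Default-profile corpus, large enough to test calibration recovery."""
    return generate_corpus(GeneratorConfig(n_positive=300, n_negative=300, seed=20170406))
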