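"""Synthetic generator: calibration math, determinism, signal control."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from earlyrisk.corpus import tokenize
from earlyrisk.synthetic import (
    ClassProfile,
    GeneratorConfig,
    calibrate_truncated_lognormal,
    default_profiles,
    generate_corpus,
    lognormal_from_mean_median,
    lognormal_from_mean_sd,
    truncated_lognormal_mean,
)

from .conftest import small_corpus, small_profiles


def pooled_gaps_days(subjects):
    out = []
    for s in subjects:
        ts = np.array([w.date.timestamp() for w in s.writings])
        out.append(np.diff(ts) / 86400.0 if len(ts) > 1 else np.zeros(1))
    return np.concatenate(out)


class TestCalibrationMath:
    def test_sigma_from_mean_median_closed_form(self):
        mu, sigma = lognormal_from_mean_median(367.1, 154.0)
        assert mu == pytest.approx(np.log(154.0))
        assert sigma == pytest.approx(np.sqrt(2.0 * np.log(367.1 / 154.0)))

    def test_mean_sd_moment_match(self):
        mu, sigma = lognormal_from_mean_sd(5.076, 11.048)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(5.076)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(11.048)

    def test_truncation_recalibration_hits_target(self):
        # truncation shifts the mean; the re-solved location restores it
        _, sigma = lognormal_from_mean_median(367.1, 154.0)
        mu = calibrate_truncated_lognormal(367.1, sigma, 10.0, 2000.0)
        assert truncated_lognormal_mean(mu, sigma, 10.0, 2000.0) == pytest.approx(
            367.1, rel=1e-8
        )
        # against a brute-force Monte Carlo of the truncated distribution
        rng = np.random.default_rng(5)
        x = rng.lognormal(mu, sigma, size=400_000)
        x = x[(x >= 10.0) & (x <= 2000.0)]
        assert x.mean() == pytest.approx(367.1, rel=0.02)

    def test_default_profile_targets(self):
        pos, neg = default_profiles()
        assert pos.gap_mean_days == 5.076 and neg.gap_mean_days == 4.037
        assert pos.gap_sd_days == 11.048 and neg.gap_sd_days == 8.330
        assert pos.words_mean == 27.3 and neg.words_mean == 21.9
        assert sum(pos.day_weights) == pytest.approx(1.0)
        assert sum(neg.hour_class_weights) == pytest.approx(1.0)


class TestProfileValidation:
    def test_weight_lengths(self):
        with pytest.raises(ValueError):
            ClassProfile(n_writings_mean=30, n_writings_median=20, day_weights=(1, 1))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            ClassProfile(n_writings_mean=30, n_writings_median=20, p_comment=1.5)


class TestGeneration:
    def test_determinism_byte_identical(self):
        def dump(corpus):
            import json

            return "\n".join(
                json.dumps(
                    {
                        "id": s.id,
                        "label": s.label,
                        "writings": [
                            (w.title, w.date.isoformat(), w.info, w.text)
                            for w in s.writings
                        ],
                    },
                    ensure_ascii=False,
                )
                for s in corpus.subjects
            )

        a = dump(small_corpus(seed=99, n_pos=5, n_neg=5))
        b = dump(small_corpus(seed=99, n_pos=5, n_neg=5))
        assert a == b

    def test_empty_request_is_valid(self):
        corpus = generate_corpus(GeneratorConfig(n_positive=0, n_negative=0, seed=1))
        assert len(corpus) == 0

    def test_chronology_and_bounds(self, separable_corpus):
        lo, hi = 10, 80
        for s in separable_corpus.subjects:
            assert lo <= len(s) <= hi
            ts = [w.date for w in s.writings]
            assert all(a < b for a, b in zip(ts, ts[1:]))  # strictly increasing

    def test_positive_subjects_comment_more(self, separable_corpus):
        def zero_title_share(subjects):
            flags = [not w.title for s in subjects for w in s.writings]
            return np.mean(flags)

        assert zero_title_share(separable_corpus.by_label("positive")) > zero_title_share(
            separable_corpus.by_label("negative")
        )

    def test_no_lexicon_means_no_textual_signal(self):
        corpus = small_corpus(seed=5, n_pos=40, n_neg=40, lexicon_weight=0.0)

        def unigram(subjects):
            c = Counter()
            for s in subjects:
                for w in s.writings:
                    c.update(tokenize(w.title))
                    c.update(tokenize(w.text))
            return c

        cp, cn = unigram(corpus.by_label("positive")), unigram(corpus.by_label("negative"))
        vocab = sorted(set(cp) | set(cn))
        p = np.array([cp[t] for t in vocab], dtype=float)
        q = np.array([cn[t] for t in vocab], dtype=float)
        cos = p @ q / (np.linalg.norm(p) * np.linalg.norm(q))
        assert cos > 0.995  # same generating distribution

    def test_calibration_recovery(self, calibration_corpus):
        """Sample means match profile targets within 3 standard errors."""
        pos = calibration_corpus.by_label("positive")
        neg = calibration_corpus.by_label("negative")

        counts = np.array([len(s) for s in pos], dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 367.1) <= 3 * se

        counts_n = np.array([len(s) for s in neg], dtype=float)
        se_n = counts_n.std(ddof=1) / np.sqrt(counts_n.size)
        assert abs(counts_n.mean() - 640.7) <= 3 * se_n

        gp = pooled_gaps_days(pos)
        assert abs(gp.mean() - 5.076) <= 3 * gp.std(ddof=1) / np.sqrt(gp.size)
        gn = pooled_gaps_days(neg)
        assert abs(gn.mean() - 4.037) <= 3 * gn.std(ddof=1) / np.sqrt(gn.size)

        words = np.array(
            [len(tokenize(w.title)) + len(tokenize(w.text)) for s in pos for w in s.writings],
            dtype=float,
        )
        assert abs(words.mean() - 27.3) <= 3 * words.std(ddof=1) / np.sqrt(words.size)

    def test_day_hour_profiles_track_weights(self, calibration_corpus):
        neg = calibration_corpus.by_label("negative")
        dows = np.array([w.date.weekday() for s in neg for w in s.writings])
        hcs = np.array([w.date.hour // 6 for s in neg for w in s.writings])
        day_marginal = np.bincount(dows, minlength=7) / dows.size
        hour_marginal = np.bincount(hcs, minlength=4) / hcs.size
        _, neg_profile = default_profiles()
        assert np.allclose(day_marginal, neg_profile.day_weights, atol=0.02)
        assert np.allclose(hour_marginal, neg_profile.hour_class_weights, atol=0.02)


class TestSignalControl:
    def test_downstream_auc_increases_with_lexicon_weight(self):
        """More class-lexicon mass -> more separable similarity features.

        Both classes share one behaviour profile so the only class signal
        is the vocabulary mixture; weights stay small because whole-history
        similarities saturate AUC quickly.
        """
        from dataclasses import replace

        from sklearn.ensemble import RandomForestClassifier
        from sklearn.metrics import roc_auc_score

        from earlyrisk.features import FeatureSetSpec, SubjectFeaturizer
        from earlyrisk.workflow import split_corpus

        base, _ = small_profiles()
        aucs = []
        for lw in (0.0, 0.02, 0.05):
            profile = replace(base, lexicon_weight=lw)
            corpus = generate_corpus(
                GeneratorConfig(
                    n_positive=25, n_negative=25, seed=13,
                    positive_profile=profile, negative_profile=profile,
                )
            )
            train, test = split_corpus(corpus, 0.6, seed=3)
            spec = FeatureSetSpec(
                measures=("cosine", "bm25"), lsa_variant="none", include_wf=False
            )
            feat = SubjectFeaturizer.from_spec(spec).fit(train)
            clf = RandomForestClassifier(n_estimators=100, random_state=0).fit(
                feat.transform(train).to_numpy(),
                [1 if s.label == "positive" else 0 for s in train],
            )
            proba = clf.predict_proba(feat.transform(test).to_numpy())[:, 1]
            aucs.append(
                roc_auc_score([1 if s.label == "positive" else 0 for s in test], proba)
            )
        assert aucs[0] < aucs[1] < aucs[2]
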