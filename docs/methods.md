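# Methods

This note documents the models and procedures implemented in
`earlyrisk`, the assumptions behind them, the choices made where the
design was genuinely open, and what the synthetic test bed does and
does not establish.

## Problem formalization

A subject is a chronologically ordered sequence of writings
`(title, date, info, text)` with a binary depression label. Evaluation
is streaming: the history is partitioned into `n_chunks` (default 10)
contiguous chunks, oldest first, sizes differing by at most one with
the remainder absorbed by the earliest chunks. At each chunk boundary a
model emits *depression*, *nondepression*, or *delay*; the first
non-delay verdict is final and the delay `k` is the cumulative writing
count at that chunk. Subjects still undecided after the last chunk are
forced to nondepression — combined with the late-positive rule below,
this makes "never decide" and "decide correctly but maximally late"
cost the same for at-risk subjects.

Tokenization is deliberately minimal and reproducible: Unicode
lowercasing, with maximal alphanumeric runs as tokens (punctuation and
symbols separate tokens). Timestamps are stored and compared as UTC;
no timezone inference is attempted. Day-of-week and hour-class features
derive from these UTC timestamps.

## Features

**Textual similarity.** Each subject is one bag-of-words document over
either the text field only or all fields (title, info, text). Cosine
similarity uses IDF-weighted term counts with IDF(w) = ln(N/df(w));
BM25 uses the Robertson–Zaragoza IDF ln((N−df+0.5)/(df+0.5)) floored at
0, with defaults k₁ = 1.2, b = 0.75 (the conventional defaults; the
original tuning set for these metaparameters is not published).
Zero-norm documents — e.g. a link submission with an empty text field
under the text-only scheme — score 0 against everything rather than
erroring. Scores against each leave-one-out reference class are
aggregated as avg/SD/min/max/median. Reference documents are training
subjects' *full* histories; the active subject's document at chunk i is
its *cumulative* history through chunk i. That asymmetry is the only
causally valid choice in a streaming evaluation: the model may know its
training corpus completely but can only see a test subject's past. An
aggregation-over-parts variant (per-field scores with per-field IDF,
summed) is provided as `textual.summed_field_score`.

**Semantic similarity.** The LSA space is built from raw term counts of
the m×n term-by-document matrix — no tf-idf weighting, which is the
simplest reading of a count-based document-term matrix — always over
all textual fields. Dimensionality uses the Kaiser criterion (singular
values > 1.0) by default, floored at k = 1 since a 0-dimensional
embedding is unusable; *share* (cumulative singular-value mass) and
*fraction* rules are available. Test and streaming documents are folded
in as vᵀT_kS_k⁻¹, the standard LSA identity under which a training
document reproduces its own row of D_k to numerical precision; the LSA
space is fitted once on training subjects and never refitted per chunk.
Variants: optional Porter stemming + stop-word removal before counting
(the stemmer is an in-package implementation of the classic 1980
algorithm, validated against its published example vocabulary; the
stop-word list is frozen in `earlyrisk.stemming` so preprocessing is
stable across environments), and optional min–max normalization of the
distance vector. Normalization is applied per active subject over its
pooled positive+negative distances; constant inputs map to all zeros
because degenerate (e.g. empty-history) cases legitimately occur in
early chunks.

**Writing features.** Words per writing count all textual fields,
including the source label in `info` (one token for typical corpora —
harmless for tree models, and consistent with "all textual information
available"). The log time-gap transform is ln(1 + gap_seconds) so the
zero gap of a single-writing subject stays finite. Day percentages are
writing-weighted; weekend = Saturday + Sunday.

## Decision models

Random forests (scikit-learn, 100 trees by default, fixed seed,
probability = tree-vote fraction) are trained on full-history feature
vectors. The singleton model's threshold functions are the decreasing
step 0.9, 0.8, 0.7, 0.6 over chunks 1–4 and 0.5 from chunk 5 on. The
step-function definition in the source formulation does not bind its
indicator intervals to chunk indices explicitly; mapping chunk index to
successive grid steps is a documented interpretation. When both rules
fire simultaneously (P(pos) = P(neg) = 0.5 at threshold 0.5), the
positive rule wins — the risk-averse choice for a screening system.

The dual model switches on the cumulative writing count: `k < th_w`
(strictly below, a literal reading of "below") uses the depression
detector at threshold 0.9; `k ≥ th_w` uses the nondepression detector
at threshold 0.5. The nondepression detector is a forest trained with
the negative class as its target on its own feature set, so the two
verdicts do not compete through one probability. Presets: `erde5_best`
(th_w = 6; positive model cosine+BM25 on text + plain LSA + WF,
negative model normalized LSA) and `erde50_best` (th_w = 53; same
positive model, negative model stemmed/stop-removed LSA).

## Evaluation

lc_o(k) = 1 − 1/(1+e^(k−o)) is computed via the numerically stable
logistic; it equals 0.5 exactly at k = o and saturates to 1 within
float precision roughly 36 writings past the offset. Costs: c_fn = 1,
c_tp = c_fn, c_fp = positive proportion of the evaluated set by
default (a fixed value, e.g. the published 0.1296, can be passed
instead; note 52/401 = 0.1297 to 4 decimals, so the published constant
appears truncated). The *late-positive rule* charges a correct
depression verdict emitted at the final chunk (or forced) the full
c_fn instead of lc_o(k)·c_tp. This rule is what makes the
oracle-at-last-chunk policy score identically to the all-negative
policy for any per-subject writing counts — the behaviour the
reference evaluation exhibits — whereas a pure latency cost would only
approximate it for subjects with many writings.

Identities used as checks: the all-negative policy's ERDE equals the
positive proportion exactly, for any composition and offset; on the
52/349 test composition this is 12.97 (×100). The all-depressed policy
has recall 1 and precision equal to the positive proportion.

## Synthetic corpus generator

The generator's defaults are the study conditions of the reference
dataset (all per class: depressed / control):

| quantity | depressed | control |
|---|---|---|
| writings per subject, mean / median | 367.1 / 154 | 640.7 / 375 |
| bounds on writings | [10, 2000] | [10, 2000] |
| inter-writing gap (days), mean / SD | 5.076 / 11.048 | 4.037 / 8.330 |
| words per writing (title+text), mean | 27.3 | 21.9 |
| P(comment) (empty title) | 0.70 | 0.55 |
| P(link) among posts (empty text) | 0.20 | 0.45 |
| day weights | near-uniform, weekend dip | midweek peak, weekend trough |
| hour-class weights | tilted 0:00–11:59 | tilted 12:00–23:59 |
| class-lexicon weight | 0.30 | 0.10 |

Writing counts are lognormal, σ from the closed-form mean/median match
σ = √(2 ln(mean/median)), truncated to the bounds, with the location
parameter re-solved (Brent) so the *truncated* mean hits the target —
truncation otherwise shifts the mean by several percent. Gaps are
lognormal moment-matched to (mean, SD). Words per writing are negative
binomial (dispersion 0.6) so the mean is exact and the tail heavy, with
a large zero mass as real submission streams show. The comment / link /
text-post mix controls which fields are empty without changing the
word total. The comment and link probabilities and the profile weights
are this package's own choices, set once to reproduce the *qualitative*
contrasts reported for the reference data (depressed users comment
more, controls post more links and peak midweek/afternoon); only the
table's numeric rows are published calibration targets.

Day/hour placement uses acceptance–rejection on the landing time of
each drawn gap (accept with probability proportional to the day weight
× hour-class weight of the candidate timestamp). The alternative —
drawing a gap and then snapping the timestamp to a sampled
day-of-week/hour — is biased: snapping a small gap forward to the
nearest sampled weekday systematically lengthens it, inflating the mean
gap by an amount (order 0.1 day) that would break the calibration
contract. With near-uniform weights the rejection acceptance
probability is almost independent of the gap length, leaving the gap
mean unbiased to well under 1%, which measurement confirms. A
consequence is that the realized day/hour marginals track the weights
approximately (within ~2 percentage points at n = 300 per class), not
exactly; marginal-profile fidelity is qualitative by design.

Tokens are drawn i.i.d. from a mixture of a Zipf-weighted background
vocabulary (with a heavy stop-word head, so stop-word removal has
something to do) and a small class lexicon — first-person pronouns and
symptom vocabulary for the depressed class, leisure vocabulary for
controls. The lexicons exist to create statistical separation for
testing and carry no clinical validity. At lexicon weight 0 the two
classes share one generating distribution for text.

All randomness flows from one master seed through per-subject
substreams (`numpy` SeedSequence spawning), so corpora are
byte-identical across runs and stable under partial regeneration.

**What passing tests show, and what they do not.** The generator
reproduces marginal statistics and a dialable vocabulary shift. It does
not model topics, threads, reply structure, linguistic style, temporal
nonstationarity (e.g. symptom onset), or correlations between
behaviour and content beyond the class-conditional marginals.
Consequently, pipeline results on synthetic data validate the
*machinery* — feature correctness, decision logic, metric identities,
calibration — not clinical detection performance. In particular, on
short-history, highly separable synthetic corpora the dual and
singleton models both approach zero error and their relative ordering
is uninformative; the dual model's published advantage on real data is
not a reproducible target here. The power property that *is* asserted:
with strong textual signal, the dual preset's ERDE₅₀ beats the
all-negative policy's, as a tendency over 5 seeds.

## Problem sizes and numerical choices

Tests run the pipeline end to end on corpora of 25–90 subjects with
histories truncated to 10–80 writings (the package's chosen
development scale; the feature stage is quadratic in subjects because
of pairwise reference scoring). Generator calibration is checked at
300 subjects per class in the suite and 500 per class in
`scripts/acceptance.py`, with agreement required within 3 standard
errors of each target. Similarity implementations must match
independent brute-force oracles to 1e-12 on toy corpora; SVD
reconstruction and folding-in identities to 1e-8. Subjects with fewer
than 10 writings are excluded only when the dataset-compatibility
filter is explicitly enabled — the floor is a dataset-construction
rule, not a model requirement.

## Known limitations

- The eRisk XML dialect reader covers the public per-subject layout
  (ID + repeated WRITING elements) and an optional golden-truth file;
  other layouts need conversion to the JSONL dialect.
- BM25 uses the document-side formulation summed over the query's
  distinct terms (no query-frequency saturation term).
- LSA uses dense SVD; comfortable at thousands of terms × hundreds of
  subjects, not engineered for much larger vocabularies.
- The published headline results for the full models on the gated
  corpus are out of reproducible scope; only the composition-determined
  baseline rows and the calibration statistics are reproduced
  numerically.
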