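# Methods

This note documents the statistical procedures `vltkit` implements, the
generative model behind its synthetic cohorts, the numerical and design
choices that were genuinely open, and what the shipped tests do and do
not establish about real clinical data.

## The instrument and the scoring model

The 15-word Verbal Learning Test presents 15 unrelated monosyllabic
nouns over five immediate learning trials; after roughly 20 minutes of
unrelated tasks an unannounced delayed free-recall trial follows, and
finally a 30-probe yes/no recognition sheet (the 15 targets intermixed
with 15 foils). A session reaches the package as ordered token
transcripts with optional onset times, in up to two rater variants:
`clinical` (the clinician's record, possibly counts-only) and `asr`
(the speech recognizer's transcript).

Scoring classifies every transcript event exactly once — first correct
recall, repetition, or intrusion — using exact string matching after a
deterministic normalization (lowercase, punctuation stripping, NFKD
diacritic folding). No fuzzy or phonetic matching is attempted, by
design: the divergence between clinical and ASR scores should be a
property of the transcripts, not an artifact of a lenient scorer.
Where the clinician handled dialect or inflected variants is unknowable
from transcripts alone; exact-match-after-normalization is the contract.

## Process-score features

The catalog (101 named features; `vltkit.features.feature_catalog`)
covers:

* **Counts.** Per-trial correct counts, total immediate recall (0–75),
  delayed recall (0–15), recognition true/false positives, per-trial
  repetitions and intrusions, and first-10-seconds counts.
* **Serial position.** Region counts and proportions per trial and in
  total. Default regions: primacy = positions 1–4, midlist = 5–11,
  recency = 12–15 — the standard convention for 15-item list-learning
  process scores; the cut points are configurable because the
  literature names the regions more often than it fixes them.
* **Slopes.** Least-squares slope of count against trial index over
  trials 1–5 (overall), 1–3 (early) and 3–5 (late), the peak
  single-trial gain, and the trial-5 minus trial-1 simple gain. The
  late slope uses 3-point regression rather than the 2-point difference
  (c5−c3)/2 for robustness to a single noisy trial.
* **Consistency.** Constancy learning index
  Σₜ|Cₜ ∩ Cₜ₊₁| / Σₜ|Cₜ| over consecutive immediate trials — the
  classic item-consistency construct; gained/lost access counts; and
  savings = delayed recall / trial-5 recall (undefined when trial 5 is
  zero).
* **Organization.** Serial clustering counts forward-adjacent
  presented-list pairs in the output order (a bidirectional flag
  exists, off by default, since "serial clusters" conventionally means
  forward chaining). Subjective organization is the chance-corrected
  pair frequency PF = O − 2c(c−1)/(hk) between consecutive trials,
  where O counts unordered word pairs output adjacently in both trials
  in either order; the correction term is exactly the expected O under
  random output order within fixed recall sets, so PF has mean zero
  under chance organization (property-tested by Monte Carlo).
* **Timing.** Words recalled within the first 10 seconds of a trial,
  counting first correct recalls only (whether a clinical study would
  count repetitions too is ambiguous; first-correct is the stricter and
  more interpretable choice).

Missing inputs propagate as missing values, never as zeros: a
counts-only clinical variant yields count features and NaN everywhere
else; absent onsets make timing features NaN. Imputation happens only
inside classifier training folds, where it is explicit and logged.

The full 102-item feature list of the reference ASR application is not
public; this catalog is a reconstruction that implements every feature
named in the main text plus systematic region-by-trial and per-trial
expansions, under the instrument's reporting names
(`immediate_midlist_items_trial_3`, `delayed_recall_recency_items`, …).

## Inter-rater reliability

Agreement between clinical and ASR scores uses ICC(A,k): two-way model,
absolute agreement, mean of k = 2 ratings,

    ICC(A,k) = (MS_R − MS_E) / (MS_R + (MS_C − MS_E)/n),

with mean squares from the two-way ANOVA without replication. Absolute
agreement (rather than consistency) is the right definition here: a
recognizer that systematically misses words should be penalized, and
the between-rater mean square MS_C does exactly that. Confidence
intervals use the McGraw–Wong F-based procedure for the single-rating
coefficient with a Satterthwaite df, stepped up to k ratings; alpha
0.05. The implementation is validated to 1e-10 against a brute-force
sums-of-squares oracle and cross-checked against an independent
library implementation (estimate and CI). Note the interval becomes
very wide when a systematic rater offset is present even at large n —
users surprised by a low lower bound under a high ICC are seeing the
absolute-agreement penalty, not a bug.

Degenerate inputs: identical rating columns give exactly 1.0 (the mean
squares are computed so that duplicated columns produce exact zeros);
zero between-subject variance returns 0.0 with a warning, since the
coefficient is undefined. Pairs with a missing side are excluded
listwise per measure and the exclusion count reported. Difference
summaries use clinical − ASR with configurable flag thresholds
(defaults: more than 14 words missed for total immediate recall, more
than 4 for delayed recall).

## Group differences and effect sizes

Process scores are typically skewed, so group comparisons use the
Mann-Whitney U computed through midranks, with the tie-corrected
normal approximation and no continuity correction (matching common
statistical-package output at these sample sizes). The effect size is
r = |Z|/√N with N the per-feature complete sample size, reported
explicitly because missingness differs across features. U/(n₁n₂) is
the univariate ROC AUC; the ranking table also reports the
direction-free max(AUC, 1−AUC). In ranking, the impaired group is
group A, so Z is negative for features on which impaired participants
score lower. Correlation matrices are Pearson on case-wise-complete
rows — one complete-case N for the whole matrix, as clinical heatmaps
report — with entries undefined below 3 complete cases.

## Diagnostic classification

For each subtest (immediate, delayed, recognition, full = all three
clinical totals) three nested models are evaluated: tier 1 the core
score(s) only, tier 2 plus age, tier 3 plus age and the entire feature
catalog. Tier 3 deliberately includes all features rather than a
screened subset; with leave-one-out cross-validation there is no
leakage-free way to screen globally, and tree ensembles tolerate
irrelevant predictors.

Each model is an extremely-randomized-trees ensemble (500 trees,
library-default split rules, fixed seed 1234 — reproducibility over
tuning, recorded in run metadata) scored by LOOCV: each participant's
predicted probability of the impaired class comes from a model trained
on all others, with median imputation fitted on the training fold
only. AUC uses the midrank (Mann-Whitney) estimator; its variance and
the covariance of two AUCs on the same sample come from the DeLong
structural components, giving Wald CIs and two-sided paired tests
between tiers. Identical score vectors short-circuit to p = 1. F1 is
computed for the impaired class at a fixed 0.5 probability threshold
(no thresholding rule is canonical; 0.5 on a probability is the
transparent default). The impaired group (MCI/dementia) is the
positive class throughout. A sensitivity rerun excludes participants
with dementia.

## The synthetic cohort generator

The generator exists so that every pipeline stage is testable without
patient data. Per participant with latent ability u ~ N(0, σᵤ):

* word w on trial t is recalled with probability
  logistic(α + β(t−1) + π·[w∈primacy] + ρ·[w∈recency] + u) — learning
  in the log-odds, serial-position boosts, exchangeable words (no
  per-word difficulty by default: the lists are unrelated nouns and
  per-word effects are not identifiable from group summaries);
* a word recalled on trial 5 survives to delayed recall with
  probability logistic(logit(θ) + λθ·u); non-recalled words resurface
  with reminiscence probability ε. The ability coupling λθ (default
  1.5) is needed to reach the empirical delayed-recall SDs (≈3.2–3.5
  words), which a fixed-θ binomial cannot produce;
* output order sorts recalled words by a key blending normalized list
  rank (weight `order_mix`) and rank in the previous trial's output,
  plus Gaussian noise (scale `order_noise`, default 0.15); at
  order_mix = 1 with zero noise the output is strict list order, which
  at saturated recall yields the maximal 14 serial clusters;
* onsets accumulate log-normal gaps (gap_mu, gap_sigma, log-seconds);
  delayed-trial gaps are scaled by `delayed_gap_scale` = 1.4 (recall
  after consolidation is slower and sparser), which under a single
  miss process reproduces the much smaller clinical−ASR difference at
  delay (≈1 word) than at immediate recall (≈7 words);
* repetitions and intrusions are Poisson-injected; intrusion tokens
  come from a fixed dummy vocabulary disjoint from all word lists;
* recognition thresholds a Gaussian familiarity signal (mean d′ for
  targets, 0 for foils) at criterion c.

The ASR variant drops each spoken target word with probability
`fast_miss` (default 0.38) when its gap to the preceding word is below
`fast_gap_s` (1.0 s) and `base_miss` (0.08) otherwise, and never
carries intrusions (off-list speech is not identified as recall). No
quantitative miss-rate-versus-speech-rate curve exists to calibrate
against; these defaults are chosen to reproduce the qualitative
agreement findings (ICC magnitude, count-dependent differences, mean
immediate difference near 7 words).

**Calibration.** Default group parameters were tuned once against the
published clinic summaries and frozen: simulated ASR total immediate
recall and delayed recall means (and SDs) fall within 10% of
37.6 (12.9) / 24.1 (10.7) and 8.1 (3.5) / 3.6 (3.2) at 500 per
diagnostic group, with the impaired group mixing MCI and dementia in
the clinic's 56:13 ratio. The dementia group reuses MCI parameters
under a severity shift (lower α, β, θ, d′) because 13 reference cases
cannot support a separate calibration. Ages are group-shifted
Gaussians (62.4 (10.8) vs 71.9 (9.5), clipped to 40–95); auxiliary
cognitive and severity variables are group-shifted Gaussians loaded on
standardized ability (loadings 0.15–0.55, negative for severity), so
the heatmap reproduces the qualitative low-to-moderate correlation
pattern without claiming to model those instruments.

**What passing tests do not show.** The generator emulates group-level
learning curves, serial-position structure, consolidation, output
order, timing and an idealized miss process. It does not model real
ASR confusions (substitutions, segmentation errors), acoustic
conditions, per-word difficulty, semantic intrusions, practice or
fatigue effects, or the clinic's covariate structure beyond
group-shifted Gaussians. Pipeline results on synthetic cohorts
therefore validate the *machinery* (scoring identities, estimator
correctness, directional behavior), not clinical effect sizes; the
match of simulated AUCs/ICCs to published ones is qualitative, not
confirmatory.

## Numerical choices and degenerate inputs

* Slopes use the closed-form least-squares formula; an exactly
  constant count vector gives slope 0, a missing trial makes all slope
  features missing.
* PF is undefined (NaN) when either trial's recall is empty; savings
  is undefined when trial-5 recall is zero; constancy is undefined
  when no words were recalled on trials 1–4.
* Ties in Mann-Whitney are handled by midranks with the tie-corrected
  variance; an all-constant sample yields Z = 0, r = 0, p = 1.
* Constant LOOCV score vectors yield AUC 0.5 with a zero-variance
  warning rather than an error.
* Output-order sorting breaks exact key ties by list position
  (Python's stable sort over position-ordered candidates).
* All randomness flows through explicit `numpy.random.Generator`
  objects; cohort generation is byte-identical given the same config
  and seed.

## Problem sizes in the shipped tests and acceptance script

The test suite exercises Monte-Carlo properties at sizes chosen to
keep the default run fast while leaving comfortable statistical
margins: the exhaustive Mann-Whitney check enumerates all 5-vs-5
multiset instances over a 4-value alphabet; DeLong variance is checked
against 2,000-resample bootstraps on 30-sample instances; the LOOCV
null check uses 50 replicates of n = 30 with 50-tree ensembles; the
recognition tier-3-vs-tier-1 reproduction uses 25 replicates of a
60-participant cohort with 100-tree ensembles (ensemble size is a
`ModelSpec` parameter; the production default remains 500).
`scripts/acceptance.py` runs the full 12-model family at production
settings on a 138-participant cohort, which dominates its ~10-minute
runtime.

## Known limitations

* Exact-match scoring cannot credit dialectal or inflected recalls the
  way a human might.
* The ICC confidence interval follows one published F-based method;
  other software variants differ, sometimes substantially, under
  strong rater bias.
* LOOCV without a held-out set estimates discrimination optimistically
  relative to external validation; the package reports it as the
  within-cohort procedure it is.
* The 102-feature reconstruction is a best effort from the named
  features; exact parity with the proprietary catalog is not claimed.
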