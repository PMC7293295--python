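# Methods

`pdvoice` re-implements, as a reusable and fully tested pipeline, a
speech-based approach to discriminating the dopamine-replacement-therapy
"ON" state (symptom relief) from the "OFF" state (reduced relief) in people
with Parkinson's disease. Because clinical voice recordings are identifiable
and typically cannot be shared, the pipeline is exercised end-to-end on a
synthetic paired cohort whose state effects are known and controllable; every
downstream stage therefore has an oracle.

## Feature extraction

### Pause handling

The intensity contour is computed on 32 ms frames stepped every 10 ms as
`10*log10(mean squared amplitude + 1e-10)`, referenced to the loudest frame
(maximum = 0 dB). A **pause** is a maximal run of frames below −25 dB lasting
at least 100 ms. The −25 dB threshold is meaningful only relative to a
reference; using the per-recording maximum (the convention of Praat-style
silence detection) makes every stage invariant to global gain, which we
verify by property test. The 32 ms / 10 ms framing guarantees a 100 ms pause
spans at least 7 frames. Pauses are removed before cepstral analysis and
retained for the tempo features, where intervals are summarised both with
and without the pause time they span.

### Acoustic features (130)

Thirteen MFCCs on 25 ms windows stepped every 10 ms of the pause-removed
recording: pre-emphasis (0.97), Hamming window, power spectrum (FFT size =
next power of two ≥ the window), 26 triangular mel filters from 0 Hz to
Nyquist, natural log with a 1e-10 floor, orthonormal DCT-II. Coefficient 1
is replaced by the log total frame energy so loudness is carried explicitly;
no cepstral liftering is applied (it would rescale columns without changing
any distribution shape statistic used here). Consequences we rely on in
tests: coefficients 2–13 are invariant to global gain; coefficient 1 shifts
by 2·log(gain). Each coefficient's distribution over frames is summarised by
10 statistics — mean (mn), variance (vn, ddof=1), kurtosis (kur, excess,
Fisher, no bias correction), skewness (sk), mode (mod), and percentiles 10,
25, 50, 75, 90 (linear interpolation) — giving 130 named features
("MFCC #k (desc)"). The mode is the midpoint of the fullest histogram bin
with Freedman–Diaconis width (capped at 1024 bins; median fallback on a
degenerate IQR). Zero-variance samples define sk = kur = 0; the variance
guard is relative (sd ≤ 1e-9 × scale) so float residue on identical values
cannot feed the moment ratios.

### Prosodic features (16)

Syllable nuclei are intensity peaks above the −25 dB silence threshold that
rise at least 2 dB (the published default of the nuclei method this follows)
above the intensity minimum between them and the previously kept nucleus.
The greedy forward scan merges ripple maxima on the flank of one loud
syllable into a single nucleus; no voicing check is applied (a documented
simplification — the cited approach optionally adds one). Inter-nucleus
intervals are summarised by 8 statistics (pct10, pct90, mod, mn, vn, sk,
kur, IQR) in two variants: raw gaps ("NS", pauses included) and gaps reduced
by the pause time they span, floored at one frame step ("NSnp"). Fewer than
3 nuclei yields an all-missing vector with a warning, and the subject is
dropped pairwise downstream.

### Semantic features (61)

From a POS-annotated transcript of the picture-description task, nouns and
verbs are compared by cosine similarity against ten fixed seed words — five
action concepts (action, act, move, play, energetic) and five non-action
concepts (inaction, sleep, rest, sit, wait). Per seed, the similarity
distribution over the speaker's content words is summarised by 6 statistics
(md, pct10, pct90, sk, kur, IQR); the total token count `nw` completes the
61. Words are looked up lowercased without lemmatisation (documented knob);
out-of-vocabulary words are skipped and affect only `nw`. POS tags are an
input contract: the synthetic generator tags by pool membership, so no
parser is bundled.

## Group statistics

Each feature is tested with a two-sided **paired** t-test on per-subject
ON−OFF differences (positive t = larger mean when ON); the design is
within-subject, which resolves the paired/unpaired ambiguity in favour of
pairing. Features are ranked by ascending p (ties: |t| descending, then
name) with Bonferroni control at α = 0.05 over the task's full non-degenerate
feature set. Zero-variance features are flagged degenerate and excluded from
ranking. Partial correlations among the top-5 picture features per state are
computed from the inverse correlation matrix, `−P_ij/√(P_ii P_jj)`; a
singular matrix raises with a ridge suggestion rather than silently
regularising.

## Classification

Per subject, the ON−OFF feature difference enters twice: as itself with
label +1 and negated with label −1. This antisymmetric construction makes
the problem exactly balanced (chance = 0.5) and origin-symmetric, which is
why the linear models are fitted without an intercept. Folds partition
subjects (10-fold), never splitting a subject's two samples. Inside each
training fold — and only there — features are standardized, the top 5
features are selected by the paired-test p-value (equivalently a one-sample
t of the training subjects' differences against zero), and hyperparameters
are tuned:

| model | tuning | grid |
|---|---|---|
| EN (elastic-net logistic) | 5-fold subject-wise inner CV | l1_ratio {0.1, 0.5, 0.9} × penalty {0.01, 0.1, 1} |
| LR-l1 (lasso logistic) | 5-fold subject-wise inner CV | penalty {0.01, 0.1, 1, 10} |
| NB (Gaussian naive Bayes) | none | — |
| RF (random forest, 100 trees) | out-of-bag score | max depth {2, 4, ∞} |

RF tunes by OOB score rather than the inner CV used for the linear models:
OOB is the forest's own unbiased internal estimate, needs no refitting per
inner fold, and keeps the repeated-CV experiments tractable on one core; 100
trees stabilise the OOB estimate at these sample sizes (~50 samples). Run
accuracy pools correct predictions over the 10 folds; the report is mean ±
sd over repeated runs with fresh subject partitions (50 runs by default).
Feature-set combinations per task: picture — NS, SF, NS+SF, MFCC, MFCC+NS,
MFCC+SF, MFCC+SF+NS; counting and DDK — NS, MFCC, MFCC+NS. A `k_selected=None`
mode runs all features instead of the top 5.

No-leakage guarantees are tested directly: selection recomputed per fold
differs across folds on noise; poisoning held-out subjects leaves the fitted
pipeline unchanged; flipping every ON/OFF assignment leaves accuracies
unchanged.

## Synthetic cohort generator

Each recording is a train of voiced bursts — a 120 Hz harmonic pulse train
through a single ~500 Hz resonance with aspiration noise, raised-cosine
enveloped — at the task's syllable rate, over a continuous low-level voicing
bridge ~20 dB below the loudest frame. The bridge keeps ordinary
inter-syllable gaps above the −25 dB pause threshold, so only deliberately
spliced silences register as pauses (as in connected speech, where energy
does not fall to the noise floor between syllables). Ground truth — burst
onset times, pause intervals, applied gains — travels with every recording.

State effects (defaults are the strong-effect study condition; `null()`
zeroes them):

* **spectral**: +6 dB when ON in the 9.5–12.6 kHz band. A narrow high band
  is used rather than an everything-above-8-kHz shelf because a shelf acts
  as a spectral tilt that loads the low cepstral coefficients hardest; a
  localized band loads coefficient 11 most strongly (DCT weight +1.6, with
  a −1.5 weight on coefficient 12), so recovery shows up where hoarseness-like
  high-frequency changes are expected. A low-band (< 8 kHz) gain knob exists
  and defaults to 0.
* **tempo**: 0.1 s added to a random quarter of ON inter-syllable intervals,
  lengthening the upper tail (raises NS pct90 when ON).
* **semantic**: verbs drawn from the action pool with probability 0.8 when
  ON vs 0.2 when OFF; transcripts are 120 tokens (≈50 % function words,
  25 % nouns, 25 % verbs).

Between-subject baselines (tempo ±0.25 syll/s, spectral ±0.75 dB, f0
120 ± 5 Hz) and per-recording session jitter (gains ±1.5 dB, tempo
±0.15 syll/s) give the paired differences realistic variance — without them
the effects are deterministic and t-statistics are implausibly large.
Recordings default to 44.1 kHz: 20 s for picture description and counting,
10 s for the DDK task (its clinical protocol length); pauses are spliced in
at ~6/min × 0.5 s for the two narrative tasks. Toy embeddings (16-d, unit
norm) place action words around +u and non-action words around −u for a
random unit axis u with Gaussian spread 0.4, guaranteeing the seed-word
geometry the semantic features assume. RNG streams are keyed per (subject,
task, state), so enlarging a cohort never perturbs existing subjects, and
identical config + seed reproduces cohorts bit-for-bit.

What the generator does **not** emulate: real phonetics (formant dynamics,
coarticulation), speaker identity, dysarthria beyond band-energy and tempo
effects, disfluencies, or transcription/POS errors. Passing tests therefore
demonstrate that the pipeline recovers known effects of these kinds at
realistic sample sizes — not that clinical accuracy figures transfer.

## Validation design and problem sizes

* Structural checks (feature counts 130 / 16 / 61 / top-5) run in seconds.
* Descriptor, paired-t and partial-correlation implementations are compared
  against naive independent oracles (sorting percentiles, explicit moment
  sums, residual-regression partial correlation) to 1e-9 on 1000-sample
  draws.
* Signal oracles: a spliced 200 ms silence must be found (and 50 ms
  rejected) within one frame; nucleus counts match generator burst counts
  within ±1 on 50 random utterances.
* Effect recovery uses a 25-subject strong-effect cohort; the CV grid runs
  5 repetitions of 10-fold subject-wise CV (repetitions kept small because
  the quantity checked is a threshold on the mean, not the run spread).
* The null control keeps 50 CV repetitions on a 25-subject zero-effect
  cohort. A single null cohort's CV accuracy has a sampling sd of ≈0.12
  (measured over 30 independent null cohorts) — far wider than the
  run-to-run sd, because correctness indicators share training data — so
  the cohort's accuracies are judged against an empirical null distribution
  recomputed at run time from 12 independent feature-level null cohorts
  (2-sd band), plus a grand-mean unbiasedness check. Family-wise error is
  checked by 200 null replicates of a 20-feature table: the expected
  Bonferroni-significant count per replicate is α = 0.05.
* Duration robustness truncates the strong cohort to 10 s and compares the
  best accuracy over a reduced picture grid (MFCC+SF, MFCC+SF+NS with the
  EN, LR-l1 and NB classifiers) against full length; the random forest is
  omitted from this sub-grid only for runtime, as its accuracy is not the
  maximum being compared.

## Known limitations

* The nuclei detector has no voicing/pitch gate; on real speech it will
  count loud unvoiced bursts as nuclei.
* The −25 dB pause threshold is relative to the recording maximum, so a
  single clipped transient can shift the reference.
* Gaussian NB and RF are not strictly sign-symmetric in finite samples;
  antisymmetry invariance is exact for the linear models only.
* Clinical accuracy values cannot be reproduced without the original
  recordings; all quantitative claims here concern synthetic cohorts with
  known effects.
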