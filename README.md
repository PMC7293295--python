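# pdvoice

Speech-based discrimination of dopamine-replacement-therapy **ON** vs
**OFF** medication states in Parkinson's disease.

People with Parkinson's cycle between an "ON" state (symptom relief shortly
after an L-DOPA dose) and an "OFF" state (reduced relief before the next
dose). Tracking these fluctuations currently relies on clinician visits or
self-report diaries. Speech is cheap to record and is affected by
dopaminergic state in ways that are subtle but measurable: high-frequency
spectral energy (perceived as hoarseness), speech tempo, and — via embodied
cognition — the use of action verbs. `pdvoice` implements the full analysis
chain for paired ON/OFF recordings of three tasks (picture description,
reverse counting, diadochokinetic "pa-ta-ka"):

* **Acoustic (MFCC, 130 features).** Thirteen mel-frequency cepstral
  coefficients (25 ms windows, 10 ms step, pauses removed; coefficient 1
  replaced by log frame energy), each coefficient's distribution summarised
  by 10 statistics: mn, vn, kur, sk, mod, pct10, pct25, pct50, pct75, pct90.
* **Prosodic (syllable nuclei, 16 features).** Syllable nuclei are intensity
  peaks above a −25 dB relative silence threshold flanked by ≥ 2 dB dips;
  inter-nucleus interval distributions (with and without pause time) are
  summarised by 8 statistics each.
* **Semantic (61 features, picture task).** Cosine similarity of each noun
  and verb to ten seed words (action: *action, act, move, play, energetic*;
  non-action: *inaction, sleep, rest, sit, wait*), 6 statistics per seed,
  plus the word count *nw*.

Statistics and classification follow the within-subject design: paired
t-tests per feature with Bonferroni correction and partial correlations
among top features; then classification of the per-subject ON−OFF feature
difference (each subject contributing ±d with labels ±1, so chance is
exactly 0.5) with elastic net, l1 logistic regression, Gaussian naive Bayes
and random forest, evaluated by 50×10-fold **subject-wise** cross-validation
with standardization, top-5 feature selection and hyperparameter tuning all
nested inside the training folds.

Clinical audio of this kind is not publicly shareable, so the package ships
a synthetic paired-cohort generator (`pdvoice.synth`) producing WAV-level
recordings, transcripts and toy embeddings with controllable state effects
and ground truth attached — every stage of the pipeline is validated against
it. See `docs/methods.md` for the model details and its limits.

## Worked example

```python
import numpy as np
from pdvoice import (RunConfig, SyntheticCohortConfig, CVConfig,
                     extract_feature_table, rank_features, run_cv_grid)
from pdvoice.classify import reports_to_frame

cfg = RunConfig(
    mode="synthetic",
    cohort=SyntheticCohortConfig(n_subjects=25, rng_seed=7, task_set=("picture",)),
    tasks=("picture",), seed=7,
)
table = extract_feature_table(cfg)          # 50 rows x (3 key + 207 feature) cols
ranked = rank_features(table, "picture")
for r in ranked[:3]:
    print(f"{r.feature:18s} t={r.t_statistic:+6.2f} p={r.p_value:.2e}")

reports = run_cv_grid(table, CVConfig(n_runs=5, rng_seed=7, classifiers=("NB",)),
                      tasks=("picture",), feature_sets={"picture": ("MFCC+SF+NS",)})
print(reports_to_frame(reports)[["feature_set", "classifier", "accuracy_mean", "accuracy_sd"]])
```

Output:

```
NS (pct90)         t=+22.01 p=2.01e-17
NSnp (pct90)       t=+21.61 p=3.08e-17
ENERGETIC (md)     t=+19.80 p=2.25e-16
  feature_set classifier  accuracy_mean  accuracy_sd
0  MFCC+SF+NS         NB            1.0          0.0
```

The top-ranked features recover the three injected state effects: the
lengthened upper tail of inter-syllable intervals when ON (`NS (pct90)`,
positive t = larger when ON), the higher action-verb content (action-seed
similarity statistics such as `ENERGETIC (md)`), and — further down the
significant list — the 9.5–12.6 kHz energy boost (positive t on MFCC #11
descriptors, negative on #12). Under these strong synthetic effects the
cross-validated accuracy saturates at 1.0; on clinical data the same
pipeline reports values well below that.

A command-line interface mirrors the library:

```bash
pdvoice simulate --outdir cohort --seed 7 --subjects 25   # WAVs + manifest
pdvoice extract --manifest cohort/manifest.csv --embeddings cohort/embeddings.txt --outdir out
pdvoice stats --features out/features.csv --outdir out
pdvoice classify --features out/features.csv --outdir out --runs 50
pdvoice run-all --outdir out --seed 7                     # everything, synthetic
pdvoice ablate-duration --durations full,10 --outdir out  # duration robustness
```

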