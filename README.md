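# gazefusion

Demographic classification (gender, binary age group) from periocular
eye-tracking signals — pupil diameter, blinks and fixations — with
feature-level fusion (scaled concatenation) and score-level fusion
(weighted sum, weighted product, pairwise Bayes rule, and a second-stage
classifier on concatenated confidence scores).

Because the real dataset behind this line of work is not publicly
distributable, the package ships a first-class synthetic generator that
emits Tobii-style gaze logs (per-eye validity codes 0–4, per-eye pupil
diameter, gaze position at 50 Hz) with configurable demographic effect
structure: an age-dependent pupil baseline, gender-dependent blink rates,
fixation/saccade alternation, blink signatures rendered as both-eyes
validity-4 runs flanked by validity-0 samples, and an optional shared
per-session latent state coupling the three channels.

## Layout

| Module | Role |
| --- | --- |
| `gazefusion.synthetic_data` | cohort + session generator (`CohortConfig`, `generate_cohort`, `simulate_session`) |
| `gazefusion.preprocessing` | validity filtering, blink segmentation (with fast-blink counter), I-DT fixation detection |
| `gazefusion.features` | per-session statistical descriptors, class balancing, max-abs scaled concatenation |
| `gazefusion.classification` | classifier zoo (DT, RF, bagging, AdaBoost, GB, KNN, SVM, SGD) with exhaustive grid × k-fold CV search, held-out confidence scoring, threshold selection |
| `gazefusion.score_fusion` | weighted sum / product / Bayes fusion, brute-force w/10 weight-grid and combination search, classifier-based score fusion |
| `gazefusion.evaluation` | end-to-end experiment orchestration, Spearman cross-modality summaries, JSON/CSV reports |

## CLI

```sh
gazefusion simulate --config cohort.yaml --out-dir gaze/ --seed 1
gazefusion preprocess --in gaze/ --out events/ [--dispersion-px 100] [--min-fix-ms 100]
gazefusion features --gaze-dir gaze/ --metadata gaze/metadata.csv \
    --task gender --out features.csv --seed 1
gazefusion train --features features.csv --task gender --small-grids \
    --seed 1 --out scores.json
gazefusion fuse --scores scores.json --rule all --sizes 2,3 --seed 1 --out fusion.json
gazefusion run --config experiment.yaml --seed 1 --out results/
```

`experiment.yaml` holds `ExperimentConfig` fields (task, with_concatenation,
ratios, selection threshold, fusion sizes, classifier families) plus a nested
`cohort:` block with `CohortConfig` fields.

## Conventions

- Standard deviations are population (divide by n).
- Binary confidence vectors are ordered by sorted label name; the positive
  class for the Bayes rule is the second label. Argmax ties go to the first.
- All stochastic steps derive their seeds from one master seed; identical
  config + seed reproduce byte-identical reports.
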