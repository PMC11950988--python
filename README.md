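# aspectscore

Automated ASPECTS scoring on non-contrast head CT, for stroke imaging
researchers and telestroke tool builders who need a transparent,
non-machine-learning baseline for early-ischemia detection.

The ASPECTS (Alberta Stroke Program Early CT Score) grades early ischemic
change in ten middle-cerebral-artery regions per hemisphere — caudate head
(C), insular ribbon (I), internal capsule (IC), lentiform nucleus (L) and
cortical sectors M1–M6 — starting at 10 and deducting one point per
affected region; a score below 6 contraindicates intravenous thrombolysis.
`aspectscore` standardizes axial CT slices (10–55 HU window, skull
stripping, crop/pad), transfers the ten region masks from a labeled atlas
by mutual-information similarity registration, and decides each region on
the clinically affected hemisphere with two contralateral-comparison
detectors:

- **RELDIF** flags a region when the relative hypodensity
  `Δ = 100·(J − I)/J` of the affected mean `I` versus the contralateral
  mean `J` meets a per-region calibrated threshold (percent).
- **DDET** first runs a one-sided Z equivalence test on `|I − J|` at a
  per-region margin `δm` (HU), using standard errors from the pixel
  samples; equivalence means no infarct, and non-equivalence triggers a
  superiority test that flags the region only when the affected side is
  significantly hypodense.

Per-region thresholds/margins are calibrated by an exhaustive sweep
(Δ over 0.05–50% and δm over 0.05–16 HU, step 0.05) maximizing the
operating-point AUC `(sens + spec)/2` subject to a specificity floor of
0.88.  A synthetic two-slice head phantom with known region masks and
lesion ground truth makes every stage testable without patient data, and
an evaluation module provides the confusion metrics, nonparametric AUC,
paired equivalence/noninferiority/superiority Z tests and Cohen's kappa
used to compare raters.  See `docs/methods.md` for the full model
description and assumptions.

## Worked example

Generate a small synthetic cohort and score it end to end:

```sh
aspectscore synth --n 3 --seed 42 --prevalence 0.35 \
    --decrement-min 4 --decrement-max 6 --noise-sd 1.0 \
    --image-size 128 --out cohort
aspectscore score --cohort cohort --method both --image-size 128 --out reports
```

prints

```
p0000 [DDET] ASPECTS=8 dichotomized=no
p0000 [RELDIF] ASPECTS=8 dichotomized=no
p0001 [DDET] ASPECTS=6 dichotomized=no
p0001 [RELDIF] ASPECTS=6 dichotomized=no
p0002 [DDET] ASPECTS=7 dichotomized=no
p0002 [RELDIF] ASPECTS=7 dichotomized=no
```

Each line is one patient scored by one detector.  With this seed the
generator placed 2, 4 and 3 lesions in the three patients (e.g. p0001 has
lesions in C, I, M5 and M6 on the left), and both detectors recover every
one: ASPECTS = 10 − (#affected regions), and no patient drops below 6, so
none is flagged by the dichotomized criterion.  `reports/` holds a JSON
report per patient and method (per-region calls with Δ% or the equivalence
and superiority p-values, plus the parameter provenance) and a
`scores.csv` summary.

Calibration on a labeled cohort, and rater comparison, follow the same
pattern:

```sh
aspectscore calibrate --cohort cohort --method reldif --image-size 128 --out params.yaml
aspectscore evaluate --calls a.csv --calls b.csv --truth gold.csv --margin 0.1
```

The library mirrors the CLI: `phantom` (synthetic cohorts),
`preprocess`, `segment`, `detect`, `calibrate`, `score`, `evaluate`,
`pipeline` (orchestration) — see the module docstrings.

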