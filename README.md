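# cpetwave

Wavelet-feature SVM classification of breath-by-breath cardiopulmonary
exercise test (CPET) recordings.

Each physiological signal (heart rate, gas exchange, ventilation, ...) is
summarised by the mean and variance of its multilevel Daubechies-2 discrete
wavelet transform bands (details `d1..dL` plus the level-L approximation).
Subjects are classified as heart failure (HF), metabolic syndrome (MS) or
healthy (H) with kernel SVMs — binary, or a one-vs-one ECOC ensemble for
the three-class task — and evaluated with repeated unstratified 5-fold
cross-validation.

## Layout

| module | purpose |
| --- | --- |
| `cpetwave.io` | read/write per-subject CPET CSVs; harmonize the two source dialects into canonical records |
| `cpetwave.wavelets` | multilevel db1/db2 DWT (symmetric or periodized boundary), built in-house |
| `cpetwave.features` | the five feature layouts: `X` (raw mean/variance, 16 cols), `BW3`/`BW5` (binary wavelet, 64/96 cols), `MW3`/`MW5` (three-class wavelet, 40/60 cols) |
| `cpetwave.classify` | linear / polynomial / RBF soft-margin SVMs, one-vs-one ECOC with hinge-loss decoding, JSON persistence |
| `cpetwave.evaluate` | repeated k-fold CV, confusion matrices (rows = predicted, columns = true), per-label one-vs-rest reduction, macro averages, model ranking |
| `cpetwave.synthetic` | seeded synthetic cohorts with rest/ramp/recovery phase structure and a class-separation knob `delta` |
| `cpetwave.cli` | `cpetwave synth / features / crossval / rank` |

## CLI quick start

```sh
# 45-subject synthetic cohort (15 HF, 15 MS, 15 H), well separated
cpetwave synth --n-per-class 15 --classes HF,MS,H --delta 2 --seed 1 --out cohort/

# three-class wavelet features, 45 x 40
cpetwave features --manifest cohort/manifest.csv --layout MW3 --out mw3.csv

# all six three-class models, 5x5-fold CV, report JSONs + ranking CSV
cpetwave crossval --manifest cohort/manifest.csv \
    --layouts MW3,MW5 --kernels LIN,POL,RBF --k 5 --repeats 5 --seed 1 \
    --out reports/

# combine report JSONs into one ranking table
cpetwave rank reports/SVM-*.json --out ranking.csv
```

Model names follow `SVM-<KERNEL>-<LAYOUT>` (e.g. `SVM-POL-BW5`,
`SVM-LIN-MW3`).  A YAML config file (`--config`) supplies `k` / `repeats`
/ `seed` defaults; explicit CLI flags win over the config file.

## Real data

The optional real-data tests (`TestCriterion6RealDataReproduction`) expect
`CPETWAVE_REAL_DATA` to point at a directory with a canonical-dialect
`manifest.csv` listing the 45 study subjects (HF block, MS block, H block).
Harmonize the source files first: the MS/HF repository dialect
(`GITHUB_MSHF`, headers like `HR(beats/min)`) and the treadmill
healthy-subject dialect (`PHYSIONET_H`, bare headers, VO2/VCO2 in mL/min)
are both available as built-in column maps in `cpetwave.io`.
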