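# pcgkit

A desk-scale toolkit for **phonocardiogram (PCG) screening**: deciding from a
heart-sound recording whether it is *normal* or *abnormal*. It re-creates the
decision-making half of a smart-stethoscope system as testable Python — from
signal synthesis and conditioning, through S1-anchored heart-cycle
segmentation and a 27-feature representation, to cost-sensitive
nearest-neighbor / ensemble classification — plus a simulator for the analog
acquisition chain so the whole pipeline runs without any external data.

## Who it is for

Researchers and students in biomedical signal processing who want a
reproducible, fully synthetic test bed for heart-sound classification
pipelines, and engineers prototyping screening logic for digital
stethoscopes before touching hardware or clinical data.

## What it computes

**Segmentation.** Heart cycles are cut S1-to-S1. S1 (mitral/tricuspid
closure, 50–60 Hz) is the most dominant peak of the PCG; it is located on a
normalized average Shannon-energy envelope with a refractory rule that
exploits S1's amplitude dominance over S2 (80–90 Hz).

**Features (27 per cycle).** Ten time-domain statistics (mean, median,
*s* with the *n*−1 denominator, mean absolute deviation, 25th/75th
percentiles, IQR, skewness *g₁*, excess kurtosis *k*, Shannon entropy
*H(x)*), four spectral features (normalized spectral entropy *SEN*,
peak frequency *f*max, |X(*f*max)|, and the energy ratio in
*f*max ± Δ*f*), and 13 mel-frequency cepstral coefficients (MFCC) with
pre-emphasis x[n] − 0.95·x[n−1]. A fixed reduced preset keeps 15 of the 27:
kurtosis, *f*max, and all 13 MFCCs.

**Feature weighting.** Regularized neighborhood component analysis (NCA)
learns per-feature weights by maximizing softmax leave-one-out
classification accuracy with an L2 penalty.

**Classification.** Fine KNN (k = 1), weighted KNN (k = 10,
inverse-squared-distance votes) and a random-subspace ensemble
(discriminant or KNN base learners), evaluated by stratified 5-fold
cross-validation after an 80/20 record-level holdout. Misclassification
costs are asymmetric: missing an abnormal heart sound costs 10, a false
alarm costs 1, so the abnormal decision threshold on p(abnormal) is 1/11 —
a screening test trades specificity for sensitivity.

**Metrics.** Sensitivity, specificity, FPR, precision, F-score, accuracy,
error and Matthews correlation coefficient from the pooled confusion matrix
(positive class: abnormal).

**Sensor chain.** The synthetic generator emulates the acquisition
hardware: pre-amplifier gain 11 v/v, 20–600 Hz analog band-limit (Bessel),
and a 10-bit ADC at 3.0 V reference (quantization step 2.93 mV). A battery
estimator implements life = capacity / load current × 0.70.

## Worked example

Generate a balanced synthetic dataset, train a cost-sensitive weighted-KNN
model, and classify a stream:

```bash
$ pcgkit simulate --n-normal 20 --n-abnormal 20 --seed 1 demo/data
wrote 40 records to demo/data (class counts: {'normal': 20, 'abnormal': 20})

$ pcgkit train --seed 1 demo/data/manifest.csv demo/model
{
  "seed": 1,
  "model_kind": "weighted_knn",
  "n_features": 27,
  "n_train_cycles": 289,
  "n_test_cycles": 83,
  "cv_pooled": {
    "sensitivity": 1.0,
    "specificity": 0.986,
    "accuracy": 0.993,
    "mcc": 0.986,
    ...
  },
  "test": { "sensitivity": 1.0, "specificity": 0.714, ... }
}

$ pcgkit classify-stream demo/model.npz demo/data/a0020.wav
t=    0.0s  label=abnormal      votes={'normal': 0, 'abnormal': 9} cycles=9
```

Reading the numbers: 40 records yield 372 detected heart cycles (289 train,
83 held-out). Pooled cross-validated sensitivity is 1.0 — every abnormal
cycle in validation folds was flagged — at 0.986 specificity. On the
held-out records the 10:1 cost keeps sensitivity at 1.0 while specificity
drops to 0.714: the intended screening trade-off, where false alarms are
the price of never missing a murmur. The streaming command emits one
decision per 10 s buffer by majority vote over that buffer's cycles.

The same workflow runs on real 2000 Hz mono WAV recordings with a
`record_id,path,label` CSV manifest (PhysioNet-2016-style layouts are
supported through `pcgkit.io.read_physionet_layout`).

## Layout

```
src/pcgkit/
  io.py          WAV + manifest ingestion, canonical PCGRecord
  synthetic.py   annotated PCG generator, sensor chain, power budget
  preprocess.py  band-pass, spike removal, baseline correction
  segment.py     Shannon-energy envelope, S1 detection, cycle cutting
  features.py    27-feature extractor (time / spectral / MFCC)
  select.py      NCA weighting + 15-feature preset
  classify.py    cost-sensitive KNN & subspace ensemble, CV, tuning
  metrics.py     confusion matrix + 8 screening statistics
  pipeline.py    end-to-end workflows, streaming, model archives
  cli.py         `pcgkit` command-line interface
docs/methods.md  model and design notes
```
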