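# stressmon

Stress-state classification from wearable physiology, at desk scale.

`stressmon` re-implements a smartphone stress-assessment engine as a
Python library and CLI.  The input is two single-channel time series per
subject — an electrocardiogram (ECG) sampled at 250 Hz and a thoracic
electrical bioimpedance (TEB) signal sampled at 100 Hz — and the output is
a per-window decision among activity types (neutral / emotional / mental /
physical), emotional states (neutral / sad / disgust) or mental-load
levels (low / high).  Because the engine was designed to run continuously
on a phone, every design choice is paired with an explicit computational
price, and feature selection optimises accuracy *under a budget*.

## The processing chain

1. **Filterbank** — each channel is split into three bands: a continuous
   (near-DC) component below 0.1 Hz, a respiration band 0.1–0.5 Hz and a
   pulse-bearing branch.  The very narrow filters are realised as
   interpolated FIR (IFIR) structures: a prototype of order `N/SF` is
   zero-stuffed by a stretch factor `SF`, compressing its frequency
   response by `SF` while storing only `N/SF + 1` coefficients.  The
   preceding anti-aliasing low-pass doubles as the image suppressor.
   ECG chain: `N1 = 100`, `N2 = 1150`, `SF = 25`; TEB chain: `N1 = 100`,
   `N2 = 400`, `SF = 10`.
2. **Rate estimation** — a min/max cycle detector (BPM block) turns the
   respiration band into breaths/min and breath-depth traces; a detector
   that thresholds the five-sample differentiation (PPM block) turns the
   pulse branch into beats/min.  Piecewise-constant (hold-last-value)
   interpolation puts everything on a common 50 Hz intermediate-frequency
   (IF) grid, giving eight signals: `ECF, ERT, ERD, EPPM` from ECG and
   `ZCF, ZRT, ZRD, ZPPM` from TEB.
3. **Features** — 14 statistics (mean, std, 25% trimmed mean, median,
   skewness, kurtosis, max, min, quartiles, geometric/harmonic mean, mean
   absolute deviation, and an IIR-tracked long-term baseline) per signal
   over 60 s windows advancing every 10 s: a catalog of
   2 × 4 × 14 = **112 features**.
4. **Cost model** — the total simple operations per second, `Nop`, of any
   feature subset.  Filter stages cost `order × fs` (FIR) or
   `order × fs / SF` (IFIR); detector and parameter costs are fixed
   constants; stages shared between features are counted once, and
   rank-based statistics of one signal share a single sort.
5. **Selection** — a genetic algorithm (population 200, 20 survivors, 10%
   mutation, 100 generations, 5 restarts) minimises the by-subject
   cross-validated MSE of a least-squares linear classifier subject to
   `Nop < Nmax`, with a repair step that randomly removes features from
   over-budget subsets.
6. **Classification & evaluation** — a one-hidden-layer MLP (10
   tan-sigmoid units, linear outputs, Levenberg–Marquardt training, early
   stopping on a held-out 10% of subjects, best of 5 restarts) evaluated
   with leave-one-subject-out cross-validation; errors are reported as
   per-class error probabilities and their unweighted mean.

The original study's 40-subject human database is not public, so the
package ships a first-class synthetic-data module: multi-subject cohorts
whose class-conditional heart rate, respiration rate/depth and signal
levels follow the study's published class averages, with per-subject
offsets drawn once per subject (making subject identity a genuine
confounder, as leave-one-subject-out evaluation assumes).

## Worked example

```sh
stressmon simulate --subjects 4 --classes activity --duration 120 --seed 7 --out demo
stressmon extract --in demo --out demo/features.tsv
stressmon cost ECG.ECF.mean ECG.EPPM.std ECG.EPPM.baseline
```

The `cost` call prints the itemised budget of a three-feature subset:

```json
{
 "stages": {
  "ecg.cf": 11500.0,
  "ecg.decim": 3750.0,
  "ecg.lf": 25000.0,
  "ecg.mf": 25000.0,
  "ecg.ppm": 8800.0
 },
 "parameters": {
  "ECG.ECF.mean": 300.0,
  "ECG.EPPM.std": 1201.0,
  "ECG.EPPM.baseline": 550.0
 },
 "total": 76101.0
}
```

The two `EPPM` features share the MF filter and pulse detector
(25,000 + 8,800 ops/s, paid once); the `ECF` feature needs the
anti-aliasing low-pass, the continuous-band IFIR and the decimator
(25,000 + 11,500 + 3,750).  Evaluating the cohort end to end with a
reduced search (`ga: {population_size: 40, survivors: 10, generations:
10, restarts: 1}`, `mlp: {restarts: 2, max_epochs: 60}`):

```sh
stressmon evaluate --features demo/features.tsv --nmax 80000 --seed 3 \
    --config demo/cfg.yaml --out demo/cv.json
```

```
fold 0: 5 features, 28/28 correct
fold 1: 3 features, 28/28 correct
fold 2: 3 features, 28/28 correct
fold 3: 4 features, 28/28 correct
```

Every fold selects a small subset costing under the 80,000 ops/s budget
(here 70,467–74,968 ops/s) and classifies the held-out subject's 28
windows perfectly — the synthetic activity classes differ strongly in
programmed heart rate (72 vs 130 beats/min for neutral vs physical), so
low error is expected; see `docs/methods.md` for what this does and does
not demonstrate about real recordings.

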