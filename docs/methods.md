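# Methods

This note records the models, conventions and numerical choices behind
`stressmon`, in the spirit of a package's statistical documentation: what
is computed, under which assumptions, and which decisions were genuinely
open.

## Filterbank

Each measurement chain has four linear-phase FIR blocks.  On the ECG
(250 Hz): an anti-aliasing low-pass at 0.5 Hz and a medium-frequency
low-pass at 30 Hz, both of order `N1 = 100`, run **in parallel** on the
raw signal; the anti-aliasing output feeds two interpolated FIR (IFIR)
filters of order `N2 = 1150` with stretch factor `SF = 25` — a
continuous-band low-pass at 0.1 Hz (output FE1) and a respiration
band-pass 0.1–0.5 Hz (output FE2).  FE3 is the 30 Hz branch.  The TEB
chain (100 Hz) mirrors this with `N2 = 400`, `SF = 10`, and its
pulse-bearing branch is a 0.5–5 Hz band-pass bracketing the physiological
pulse range (30–300 beats/min), realised with stretch 2 so that its
spectral images fall near the Nyquist edge where the synthetic and
physiological signals carry negligible energy.

The parallel (rather than cascaded) reading of the first two blocks is a
deliberate choice: a 0.5 Hz low-pass followed by a 30 Hz low-pass would
make the second block vacuous, whereas in parallel the 30 Hz branch
carries the pulse train the beat detector needs.

*Design method.*  Plain FIR low-passes are Hamming-windowed sincs.  IFIR
prototypes are least-squares (`firls`) designs against the stretched band
edges: pass/stop edges at 0.5× and 2× the nominal cutoff for low-passes,
and 0.4×/1.5× (lower) and 0.9×/1.45× (upper) the band edges for
band-passes.  Transition bands are additionally capped at roughly the
prototype's frequency resolution (3.5 fs / taps), because least-squares
designs leave transition bands unconstrained and a transition much wider
than the resolution invites unbounded ringing there.  Pass-band gain is
normalised to unity (at DC, or at the geometric band centre).

An order-1150 filter at 250 Hz has a frequency resolution of roughly
0.7 Hz, so the 0.1 Hz boundary between the continuous and respiration
bands is intrinsically soft at the stated orders: the measured responses
give clean (>10×) FE1/FE2 dominance for tones below 0.05 Hz and in
0.25–0.45 Hz, with a transition region in between.  Tests assert those
measured bands, not an unattainable brick-wall partition.

Filters are applied zero-phase by symmetric edge-reflection convolution,
which compensates each chain's group delay exactly for the linear-phase
designs used; the half-filter-length edge regions are only approximately
valid and are reported as a warm-up length.

Decimation to the 50 Hz intermediate frequency keeps every `fs/50`-th
sample at phase 0 (`floor(n·50/fs)` output samples); band-limiting is the
preceding filter's responsibility.

## Cycle detectors

**BPM block** (respiration, and the TEB pulse branch): tracks alternating
extrema with a hysteresis of 20% of a trailing peak-to-peak estimate
(updated blockwise over 10 s), which makes detection scale-invariant and
suppresses noise-driven double counts.  The per-cycle rate is
60 / (interval between successive maxima); the amplitude is that cycle's
max − min.  For the TEB pulse branch the hysteresis widens to 30% and a
300 ms refractory period merges too-close maxima, since the cardiac
component there is a smooth oscillation rather than a spike.

**PPM block** (ECG pulse branch): differentiates with a five-sample lag
and marks a beat at each upward crossing of an adaptive threshold — half
the trailing 99th percentile of the positive differences over 5 s — with
a 250 ms refractory period.  The 99th percentile sits inside the
beat-rise samples across the whole 60–180 beats/min range (rise samples
are 4–12% of the signal), so the threshold scales with beat slope rather
than noise; at the 95th percentile the threshold collapses onto the noise
floor at low heart rates and over-detects.  None of these constants are
prescribed by the original block descriptions; all are exposed as
function parameters.

Event streams are interpolated to the IF grid by hold-last-value
(zero-order hold), left-closed: a sample coinciding with an event takes
the new value, samples before the first event take the first value.  The
held rate is the instantaneous (per-cycle) rate, not a windowed average.
A detector that finds no cycles yields NaN traces; feature windows
touching them are dropped and the affected signals reported.

## Features

14 parameters per signal over 60 s windows, stride 10 s (a T-second
labelled span yields `floor((T−60)/10)+1` windows).  Conventions chosen
where the definitions admit variants:

* *trimmed mean of 25%*: 25% total, i.e. 12.5% of the sorted samples
  discarded at each end (the dominant numeric-toolbox convention), and
  computed from an explicit full sort to match the shared-sort cost
  accounting;
* *kurtosis*: non-excess (normal → 3), population moments;
* *skewness*: population moments; exactly 0 returned for constant
  windows (the moment ratio is otherwise 0/0);
* *percentiles*: linear interpolation between order statistics;
* *geometric/harmonic mean*: defined only for strictly positive windows,
  NaN otherwise — rate traces are positive by construction, so on clean
  synthetic data no windows are lost;
* *baseline*: first-order IIR low-pass `b[n] = (1−α)b[n−1] + αx[n]`,
  `b[0] = x[0]`, with α defaulting to a 300 s time constant at 50 Hz
  (α ≈ 6.7e-5) — the scale of the ~5 min resting intervals between
  recording stages; the feature is the tracker's value at the window's
  end sample (not a window average).

Windows are labelled by majority over the label intervals; windows whose
majority label covers less than 90% of the span straddle a class
boundary and are dropped.

## Cost model

`Nop` of a subset is the sum of (a) the per-second costs of the union of
required processing stages, (b) per-parameter costs, with the sort shared:
the first rank-based parameter (trimmed mean, median, quartiles) of a
signal pays the 27,580 ops/s sort, further rank parameters of the same
signal pay only their increment (225 for the trimmed mean, 0 for median
and quartiles — inferred from the two distinct printed rank-parameter
costs).  Filter stage costs are *computed* from the structural rules
(`order × fs` for FIR, `order × fs / SF` for IFIR): 25,000 and 11,500
ops/s for the ECG FIR/IFIR stages, 10,000 and 4,000 for TEB.  The
decimation (3,750 / 900), BPM-with-interpolation (9,050 / 2,116) and PPM
(8,800) block costs are adopted as printed constants — their internal
op-counting conventions are not derivable from the block structure — and
the TEB pulse branch is costed in the same IFIR class (4,000) as the
other TEB step-1 filters.  The baseline parameter's 550 ops/s attaches
per selected feature; as a running filter it is independent of window
count, consistent with per-second accounting.  The model is monotone and
subadditive by construction (stage union + shared sorts).

The budget test is strict (`Nop < Nmax`).

## Selection GA

Population 200, survivors 20, mutation probability 10% per individual,
100 generations, 5 restarts (defaults).  Where the procedure is
under-specified, the package fixes: uniform set-crossover (each feature
of the parent union inherited with probability ½, never empty); mutation
as a single member-for-non-member substitution (cardinality-preserving);
parents drawn uniformly from the survivors with replacement; duplicate
subsets perturbed by a single-feature swap with a bounded retry;
over-budget subsets repaired by uniformly random removal.  The elite
individual bypasses dedupe, repair cannot alter an under-budget set, and
survivors always include the elite, so the best fitness is non-increasing
— asserted, along with a zero count of post-repair budget violations, in
the tests.

Fitness is the mean over by-subject folds (one fold per design subject)
of the held-out mean squared error of a least-squares linear classifier
on one-hot targets (mean over samples *and* outputs; for M balanced
classes an uninformative subset scores (1/M)(1−1/M)).  Folds are fixed
across generations and fitness values cached per subset.  The linear
solve uses a ridge term of 1e-8 × the Gram trace scale, keeping
rank-deficient subsets finite without biasing well-posed ones.

## Classifiers

The linear classifier is ordinary least squares to one-hot targets with a
bias column; decision by arg-max, ties toward the lowest class index.

The MLP has one hidden layer of 10 tan-sigmoid units and **linear**
outputs trained to one-hot targets by squared error — consistent with
Levenberg–Marquardt, which is a least-squares method (not softmax /
cross-entropy).  Training is full-batch LM with the standard adaptive
damping schedule (μ × 10 on rejection, ÷ 10 on acceptance); early
stopping monitors a validation set holding out 10% of the *subjects* (at
least one), with patience 6 epochs and a 200-epoch cap (the protocol's
patience and epoch cap are not prescribed; these are the package's
defaults).  The best of 5 random restarts by design-set error is kept.
Features are standardised to train-set mean/variance before either
classifier — raw beats-per-minute scales make batch second-order training
ill-conditioned.

## Synthetic cohorts

The generator's defaults are the study conditions: per-class means for
heart rate, respiration rate, respiration depth and the continuous signal
levels are taken from the published class-conditional averages of the
eight IF signals (e.g. neutral 72.07 vs physical 130.43 beats/min).  The
ECG is a train of 80 ms raised-cosine pulses whose instantaneous rate
follows the schedule (beat times by phase integration), plus additive
respiration-coupled baseline wander at half the programmed depth (so the
band-passed peak-to-peak equals the depth), a class-dependent DC level,
and white Gaussian noise (σ = 0.02 against unit pulse amplitude).  The
TEB is a respiration oscillation plus a smaller cardiac-frequency
oscillation (amplitude 0.1), level and noise (σ = 0.01).  Per-subject
multiplicative offsets on rates and depth are drawn once per subject
(default fractional SD 0.05, clipped at ±3 SD), making subject identity a
confounder.  A small slow "wobble" (1% fractional SD, 5 s knots) keeps
cycles from being perfectly metronomic.  Within-class variances are
generator parameters, not literature values — the source material reports
only class means.

What the generator does **not** emulate: real ECG morphology (P-QRS-T),
motion and electrode artifacts, powerline interference, respiratory
sinus arrhythmia beyond additive wander, or the physiological coupling
between the two channels beyond a shared heart/respiration rate.  Two
consequences deserve emphasis.  First, the synthetic activity classes
are separated mainly by large programmed rate contrasts, so end-to-end
error rates near zero on synthetic cohorts demonstrate that the pipeline
recovers planted structure through subject confounding — they say nothing
about error rates attainable on real recordings, and the published human
error rates (21.23%, 4.77%, 32.33%) are used in this package only to
validate the error-metric arithmetic on the printed confusion tables.
Second, respiration depth is recovered up to the respiration band-pass's
gain at the breathing frequency (about 0.65× near 28 breaths/min at the
stated filter orders); class *ordering* in depth is preserved, absolute
depth is not.

## Scaled problem sizes

The default GA/MLP parameters reproduce the full search protocol; the
test suite and the bundled examples run reduced configurations (e.g. 8
subjects, 120 s per class, population 40–60, 10–25 generations, 1
restart) chosen as the smallest sizes at which the behavioural claims —
planted-feature recovery, budget compliance, elitism, above-chance LOSO
accuracy with a chance-level permuted control — are comfortably stable.
The budget-sweep utility supports the original 20,000–200,000 ops/s grid
in 20,000 steps with any number of repetitions.

## Known limitations

* The narrow-band boundary at 0.1 Hz is soft at the stated filter orders
  (see above); respiration rates above ~30 breaths/min leave the nominal
  respiration band and are increasingly attenuated on the ECG side.
* The TEB pulse branch's IFIR realisation has an image near the Nyquist
  edge (≈48 Hz); it is harmless for the modelled signals but a real
  deployment would add a guard low-pass.
* Detector thresholds (hysteresis fractions, percentile, refractory
  periods) are package defaults, not identified constants; they are
  parameters on every public entry point.
* The LM trainer is full-batch and dense; it is intended for the
  selected-subset input sizes (≤ a few tens of features), not for
  training on the full catalog.
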