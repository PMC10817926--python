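# Methods

## Scope and design

`mlfra` predicts whether a fluid bolus will raise cardiac stroke volume by
≥ 15% (fluid responsiveness, FR) using only features of the arterial blood
pressure (ABP) waveform from the 60 s before the bolus, and benchmarks the
learned classifier against pulse pressure variation (PPV). Because no public
dataset of this kind exists, the package ships a first-class synthetic
hemodynamics simulator; the simulator's planted ground truth is what makes
each downstream stage independently testable.

## The synthetic cohort

**Latent driver.** Each bolus carries a latent *preload reserve* r ∈ [0, 1].
A pig-level anchor is drawn uniformly; per-bolus reserve adds wrapped
Gaussian jitter (SD 0.15) so the marginal stays uniform, then a
piecewise-linear map sets P(r ≥ 0.5) equal to the target FR prevalence
(default 0.5) exactly. The true response is linear, ΔSV% = −5 + 40·r, plus
Gaussian label noise (SD 4%), so FR ⇔ r ⪆ 0.5 and a grey zone
(ΔSV 10–20%) arises naturally around the threshold.

**Observable channels.** r drives the respiratory modulation depth of three
waveform properties — per-beat stroke volume (hence pulse pressure),
dicrotic-notch timing, and the diastolic decay constant — each through its
own pig-level gain (log-normal, σ = 0.8, clipped to [0.3, 2]) times a
bolus-level jitter (log-normal, σ = 0.3). Because every observable channel
reads r through an independent noisy gain, any univariate statistic (PPV
included) is an imperfect proxy, while a multivariate model can pool the
channels. Occasional single-beat stroke-volume surges (Poisson, 3/min,
+10–30%) emulate sigh-breath/ectopy-like events; they perturb the
extreme-value PPV statistic far more than the robust median/SD feature
aggregates. These two mechanisms together produce the regime the package is
designed to probe: PPV discriminates well above chance but the learned model
discriminates better (typically ≈ 0.81–0.84 vs ≈ 0.71–0.77 AUROC across
seeds at the 58-pig scale).

**Beat template.** No published waveform model exists for this setting, so the
beat is the simplest shape exposing every fiducial the detector must find,
rendered foot-to-foot at 1000 Hz:

* a symmetric cosine valley (half-width ≥ 90 ms, depth ≥ 5 mmHg) centred on
  the foot;
* a raised-cosine systolic upstroke (rise time 0.18 of the period);
* a curvature-matched raised-cosine fall to a dicrotic shoulder at
  DBP + 0.45·PP;
* a symmetric notch dip (depth 0.15·PP) whose minimum is the planted notch
  time, at 0.27 of the period after the peak;
* the fall+dip shape mirrored for up to 95 ms past the notch (the dicrotic
  wave), capped so the dicrotic crest stays within the detector's 0.3 s
  refractory of the systolic peak;
* an exponential diastolic decay with time constant τ = resistance ×
  compliance down to the next valley.

The symmetric valley, curvature-matched peak, and mirrored notch
surroundings exist for one reason: the prescribed preprocessing
(Savitzky–Golay, window 19 at 100 Hz ≈ 190 ms) is wide relative to a beat,
and band-limiting displaces extrema that are not locally symmetric. With
this template, detection on the standard preprocessed signal recovers
≥ 95% of planted fiducials within ±10 ms (pooled ≈ 99%). Injury archetypes
(HEM/IRI/EPACC, mixed 13/13/32 per 58 pigs) differ only in parameter ranges
(stroke volume 25–60 ml, heart rate 66–105 bpm, compliance 0.8–1.8 ml/mmHg,
τ 0.8–1.8 s, DBP 48–78 mmHg); heart rates reflect anesthetized animals and
keep at least ~0.6 s of beat for the 190 ms smoothing window to act on.
Additive noise (SD 1 mmHg), a slow sinusoidal drift (2 mmHg, 25 s), and
0.5% per-beat period jitter complete the measurement model. CO and HR
channels are sampled at 100 Hz with their own noise; stroke volume recovered
as median(CO)/median(HR) matches the planted value within 1 ml.

**Seeding.** One master seed; per-pig and per-bolus substreams are derived by
`SeedSequence` spawn keys, so enlarging a cohort never reshuffles earlier
pigs.

**What the simulator does not emulate.** Real ABP morphology variation
(damping, catheter artifacts beyond the simple QC rules), ventilator
mechanics beyond sinusoidal modulation, drug effects, or any pressure–volume
physiology. Passing tests therefore demonstrate that the *pipeline* is
correct and that the *study design* (pig-level splitting, selection,
benchmarking) behaves as specified — not that the classifier would reach any
particular performance on real animals.

## Preprocessing

Downsampling 1000 → 100 Hz uses an order-8 Chebyshev-I low-pass at 0.8× the
target Nyquist, applied zero-phase and normalised to unit DC gain (an
even-order Chebyshev-I otherwise sits −rp dB at DC, which would bias every
pressure by its ripple), followed by slicing. Decimating to the current rate
is the identity; non-integer factors are an error rather than silently
resampled. Smoothing is Savitzky–Golay (window 19, order 2) with polynomial
edge evaluation (no invented samples). Automated QC replaces human artifact
review with explicit rules: pressures within (0, 300) mmHg, no > 2 s
flatline, no windowed pulse-pressure collapse below 5 mmHg.

## Beat detection

Systolic peaks: local maxima with prominence ≥ 25% of the median pulse
amplitude and ≥ 0.3 s spacing. Feet: the pressure minimum between
consecutive peaks. Notch: the deepest pressure local minimum in
[peak + 0.1, peak + 0.5] beat periods, falling back to the maximal-curvature
inflection for damped shapes; beats with failed notch search are kept with
null notch fields so pressure features survive. Foot and extremum pressures
are refined by parabolic interpolation (a least-squares parabola over ±8
samples at the foot), which removes sampling-phase error — without this, the
zero-modulation PPV floor sits near 1% instead of < 0.5%. The quality filter
drops beats with period outside [0.3, 1.5] s, pulse pressure < 5 mmHg, or
period > 1.5× the median (missed-detection guard).

## Features and PPV

25 per-beat base features (registry in `mlfra.features`) aggregated as
median and sample SD (ddof 1) over all quality-filtered beats in the window:
exactly 50 values per bolus. The diastolic decay constant is fitted by the
integral linearisation of y = A·e^(−t/τ) + C (one least-squares solve per
beat, exact on clean exponentials) over the monotone decay run between the
dicrotic crest and the diastolic minimum. Base features with fewer than
three non-null beats yield NaN aggregates which are imputed with
training-cohort medians only — never test statistics. PPV uses the literal
global max/min pulse pressures over the window (not per-respiratory-cycle
averaging); FR is predicted at PPV ≥ 12%, boundary inclusive.

## Splitting

Train/test splits are pig-level halves scored by
|prev_train − 0.5| + |prev_test − 0.5| + 0.25·(injury-mix L1 imbalance).
When the number of distinct half-partitions is at most the candidate budget
(200) they are enumerated exhaustively — so on toy cohorts the chosen plan
is the exact optimum; larger cohorts score 200 random candidates per split
(split i uses seed master+i). With an odd pig count the extra pig goes to
training. CV folds assign training pigs greedily (largest bolus count
first, seeded shuffle for ties) to the fold minimising FR/NR imbalance,
then fold size, then index, under a pig-count cap of ⌈n/k⌉ so fold sizes
stay within one pig of equal. Disjointness is asserted programmatically on
every run.

## Selection, training, evaluation

The KS screen retains features whose FR/NR distributions differ at p < 0.1.
The screen's threshold direction is configurable because the literal
printed rule ("p > 0.1") contradicts its stated purpose of keeping
non-overlapping distributions; the discriminative direction is the default.
Correlation pruning then repeatedly drops, from the most correlated pair
(|r| ≥ 0.9), the member with the larger KS p (ties: later registry order);
if nothing passes the screen the single most discriminative feature is kept
so a selection is never empty. RFE, held-out-fold permutation importance
(10 permutations, AUROC scoring), and nearest-neighbour mutual information
each retain exactly 10 features, ties resolving in registry order.
Consensus keeps features selected in ≥ 50% of all trials.

Hyperparameters are tuned by mean pig-level-fold AUROC over small grids
ordered smallest-capacity-first (ties keep the simpler model); single-class
folds score 0.5 with a warning. The random forest's probability is the raw
tree-vote fraction; classification is probability ≥ 0.5, inclusive.
Evaluation reports trapezoidal AUROC (equal to the Mann–Whitney ranking
probability), step-wise AUPRC, confusion metrics per threshold decile with
undefined cells (e.g. precision with zero positive calls) reported as NaN
rather than 0, fixed-width decile calibration, cross-split summaries as
mean ± 1.96·SD/√n over defined values, and least-squares regressions of
per-split AUROC on grey-zone fraction, injury-model proportions, and the
fraction of features with train/test KS p < 0.1.

## Problem sizes

The default configuration is the study design itself: 58 pigs, 7 boluses
each (~406), 29 splits, k = 5, 116 selection trials. The test suite
exercises the same code paths on smaller seeded cohorts (6–12 pigs) chosen
so each property is still statistically decidable, and runs the full-scale
discrimination check once; `scripts/acceptance.py` runs the full-scale
study end to end with tuned training on the RFE-selected features.

## Known limitations

* The 25-feature registry is this package's own reconstruction of an
  expert-informed feature set; only the 50-count and the median/SD
  construction are externally fixed.
* The beat detector is a reconstruction from its output contract (three
  labeled pressures and timestamps per beat); its constants live in
  `DetectorConfig` and are not calibrated to any real recording.
* Simulator realism is deliberately minimal (see above); absolute AUROC
  values on synthetic cohorts carry no clinical meaning — only their
  ordering and the pipeline's statistical behaviour do.
* PPV is computed in its window-global max/min dialect; monitor
  implementations that average per respiratory cycle will read lower values
  on the same data.
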