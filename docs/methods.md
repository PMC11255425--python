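# Methods

This note records the models, conventions and open design choices behind the
package, in the order data flows through it.

## Acquisition model

A triangular voltage ramp (−0.4 V hold → 1.3 V apex → −0.4 V at 400 V/s) is
applied to every carbon fiber; the sweep lasts 8.5 ms and is followed by a
91.5 ms hold at the 10 Hz recording repetition rate.  One thousand current
samples are digitized per sweep (within-scan sampling rate ≈ 117.6 kHz).
The voltage at sample *i* is evaluated at the midpoint of the *i*-th of
1,000 equal subdivisions of the sweep, which makes the sampled sequence
exactly symmetric about the apex.  The transimpedance gain is 200 nA/V
(1 V/4.99 MΩ = 200.4 nA/V, quoted as 200).

Stimulation trains (30–60 Hz, 15–60 pulses, 90–200 µA) are timestamped by
onset; pulses are assumed to fall in hold periods and are not modeled as
artifacts (see Limitations).

### Raw dialect

The on-disk format the acquisition software's description implies ("int16,
saved in 30 s increments per channel") is under-specified, so the package
defines it precisely: little-endian signed 16-bit counts, one flat file per
30 s segment per channel (`ch<NN>/seg<KKK>.i16`), and a `meta.json` sidecar
holding the count scale, gain, waveform geometry and segmentation.  The
default count scale maps the full int16 range to ±2,000 nA (±10 V at 200
nA/V), i.e. a quantization step of ≈ 0.061 nA.  Scan timestamps are derived
as scan index / repetition rate; the hardware provides no per-scan clock.
Write→read round-trips reproduce currents to within half a step.

## Preprocessing

* **Per-scan low-pass**: 4th-order 2 kHz Butterworth IIR, causal, applied
  along the within-scan axis with step-response initial conditions (a
  constant scan passes unchanged; without the initial-state choice every
  scan would carry a spurious onset transient).  Gain is −3 dB at the
  cutoff and rolls off at −80 dB/decade.
* **Across-time high-pass (drift removal)**: 2nd-order 0.01 Hz Butterworth,
  applied forward and backward (zero phase) to the time series of each of
  the 1,000 potential steps, sampled at the 10 Hz repetition rate.  This
  stage *is* the background correction: the static charging-current
  background and its slow drift are removed, and no separate background
  subtraction is performed.

  Edge handling matters because a 30 s record is only 0.3 cutoff periods
  long.  The series is extended by **odd (antisymmetric) reflection** about
  its endpoints, with pad length one cutoff period (capped at record length
  − 1).  Odd reflection continues the local slope, so a linear drift of
  1 nA/min over 30 s is suppressed to ~2% of its range while a 2 s boxcar
  transient retains ~99% of its peak; even (symmetric) reflection of the
  same length leaves most of the ramp in place, and short pads (a few filter
  orders) leave ~20%.  The padding settings are recorded in the output
  stream's metadata.

Filter order is low-pass first, then drift removal; both filters are linear
so the order affects only edge behavior.

## PCR chemometrics

The training set holds ten labeled, background-corrected reference
voltammograms: five dopamine (labeled by oxidation-peak current, nA), three
acidic-pH and two basic-pH (labeled by pH shift, acidic negative).  The
reference matrix is mean-centered and decomposed by SVD; the smallest number
of components reaching 99.5% cumulative explained variance is retained
(capped at n−1 and the numerical rank).  Scores are regressed onto the
mean-centered label matrix by least squares, and the label mean is added
back at prediction (PCR with intercept).  Two consequences worth stating:

* On noiseless mixtures of the references, the prediction coincides with
  direct least-squares regression onto the reference spectra (verified to
  1e−8 relative), because with exact linear labels the fitted map equals the
  true analyte map on the training span.
* The chemically meaningful zero point is the **all-zero scan** (a
  background-subtracted scan with no analyte signal predicts exactly 0 nA
  dopamine).  The mean reference spectrum itself contains dopamine signal
  and correctly predicts the mean dopamine label, not zero.

The residual Q (squared norm of the centered scan outside the retained
span) is compared with a threshold set at the 95th percentile of training
residuals, floored at 1e−8 of the mean squared centered-spectrum norm so a
noiseless training set does not yield a degenerate zero threshold.  Flagged
scans keep their values; if ≤ 20% of a trace is flagged the flagged samples
are linearly interpolated from their neighbors, otherwise the trace is
marked `high_residual` and left untouched.

Dopamine is predicted in current units (nA) and converted to concentration
afterwards by the calibration factor, matching the stated processing order
(chemometric estimate first, calibration conversion second).  Training
references are passed through the same per-scan low-pass as measurement
scans; the across-time filter acts identically on every potential step and
therefore preserves spectral shape, so it does not need to be applied to
single reference scans.

## Calibration

Each bolus window is sampled at the onset peak (maximum in the first third
of the window), the pre-falloff point (last sample above 90% of the plateau,
taken as the window median), and the sample midway between those two
instants; the three samples are averaged, then the three boluses per
concentration are averaged.  The calibration factor is the slope of the
least-squares line **through the origin** (zero dopamine ⇒ zero faradaic
current); an intercept is available by option.  Factors may be fit per
cohort device (the default reading) or per channel.  Conversion is
`[DA] (nM) = current (nA) / factor (nA/µM) × 1000`.

## Kinetics

* **ES DA** = peak within (onset, onset + 10 s] minus the mean over the
  2 s window ending at onset.  A peak later than 10 s is deliberately
  ignored.  Non-positive release is flagged `no_response`.  The 2 s
  baseline window is this package's convention (a window mean is far less
  noisy than a point value; the source protocol does not specify either).
* **τ** is fit by nonlinear least squares of
  `c(t) = baseline + A·exp(−(t−t_peak)/τ)` from the peak down to the first
  sample at or below baseline + 10% of ES DA.  The asymptote is pinned to
  the independently measured pre-stimulation baseline: freeing it makes the
  three-parameter fit badly conditioned on decay segments shorter than
  ~2τ and (in Monte-Carlo at SNR 10) triples the median τ error.  τ is
  bounded to (0, 60] s and reported in **seconds** — a decay *time*
  constant; larger τ means slower reuptake.  Reports that print τ with
  units s⁻¹ while describing slower reuptake at higher values are read as
  using a time constant with a units typo; all group comparisons are
  sign-invariant to that reading.

Monte-Carlo recovery under the default study conditions: median relative τ
error ≈ 7% over the grid τ ∈ {0.5, 1, 2, 5} s at SNR 10, with the 0.5 s
corner worst (~12%) because only ~12 decay samples exist at 10 Hz.

## Channel QC

Fibers do not all respond every day.  A channel's recording is `below
threshold` when its ES DA peak is less than 3× the baseline noise SD of its
own trace — a stand-in for the acquisition-side functionality tests, which
are not quantified anywhere; the multiplier is configurable.  Surviving
channels enter the outlier rule: mean and sample (n−1) SD over all
contributing channels (candidate included), channels outside ± 2 SD
removed, **single pass** — the rule is deliberately not iterated, and tests
document that re-running it on the kept set can remove more channels.  With
fewer than 3 channels the screen is skipped with a warning.  The scalar
tested is the per-recording ES DA value, the unit of all downstream
analysis.

## Synthetic recordings

Per channel: `scan(t) = background·(1+drift(t)) + [DA](t)/1000·S_ch·T_DA +
pH(t)·T_pH + ε`, with

* `[DA](t)`: impulsive release of `release_per_pulse` (default 20 nM) per
  stimulus pulse with first-order clearance (default τ = 1 s), evaluated in
  closed form; the default 60 Hz/30-pulse train gives stimulated peaks of
  ~470 nM, in the hundreds-of-nM regime chronic striatal recordings show.
* Templates: the dopamine template has an oxidation peak near +0.6 V on the
  rising limb and a reduction trough near −0.2 V on the falling limb
  (unit-normalized so nA = µM × sensitivity); the pH template is a distinct
  broad signature (30 nA per pH unit); the background follows the charging
  current's sign reversal at the apex (300 nA scale).  Template geometry is
  parameterized, not claimed to match any particular device — real
  voltammogram shapes are only ever published as pseudocolor figures.
* Acidic and basic pH references lie along one spectral direction with
  opposite signs.  This keeps the labels an exactly linear function of the
  spectra, which is what makes the PCR-vs-least-squares equivalence an
  exact statement; real acid/base voltammograms differ in shape as well as
  sign.
* Per-channel sensitivity `S_ch` is log-normal with mean 10 nA/µM and
  dispersion set so the cross-fiber CV of apparent ES DA under a single
  cohort calibration factor is 0.27 — the week-1 female value of the
  published cross-fiber variability table, used as the generator's realism
  anchor.  Dead channels get `S_ch = 0`.
* Drift: an exponential charging-settling term (2% of background, 120 s
  time constant) plus a smoothed random walk (step SD 2×10⁻⁵ of background
  per scan, 5 s smoothing).  Additive white noise SD 0.1 nA per sample.
  After preprocessing, the detected-current SD of a default baseline
  recording is ≈ 0.06–0.09 nA, comfortably inside the ≤ 0.4 nA
  electrode-stability criterion a stabilized electrode must meet — the
  generator emulates an electrode that has already passed cycling.
* Identical seeds produce byte-identical raw files.

What the generator does **not** emulate: movement and stimulation
artifacts, electrode fouling/sensitivity decay within a session, basal
(non-stimulated) dopamine transients, correlated (non-white) noise, and
realistic acid/base spectral asymmetry.  Passing tests therefore validate
the pipeline's numerics and logic, not its robustness to every in-vivo
pathology.

### Cohort tables

Chronic designs (groups × 4 weeks × 2 stimulation parameters, 16 fibers per
animal) are generated directly at the fiber level from the same
distributional model: a fixed log-normal fiber multiplier (CV 0.27, held
constant across weeks — the repeated-measures structure), multiplicative
group/week/parameter effects (sensitization = fractional ES DA increase per
week), log-normal trial noise (CV 0.10), and Bernoulli missingness for
below-threshold fiber-days.  Generating thousands of full raw recordings
per statistical replicate would be pointless; a bridge test checks that one
full raw recording processed through the pipeline matches the table model's
distribution.  The animal-level random effect defaults to zero because the
fiber is the unit of analysis (as in the source analysis); setting it
positive lets users study the pseudo-replication caveat — fiber-level tests
are anticonservative when animals differ systematically.

## Statistics

* One-way ANOVA + Tukey HSD (statsmodels).
* Two-way between-subjects ANOVA: OLS with type-II sums of squares.
* Two-way fully-repeated ANOVA: pingouin's implementation with
  Greenhouse–Geisser correction.
* `rm_anova_two_way`: an independent expected-mean-squares implementation
  (A tested against A×S, B against B×S, A×B against A×B×S) with per-effect
  GG ε computed as tr(CVC′)²/(q·tr((CVC′)²)) on orthonormal effect
  contrasts, clipped to [1/q, 1].  It agrees with pingouin to machine
  precision on complete balanced data and is the fast route used in
  simulation studies.
* `mixed_model_weeks`: complete data → the exact repeated-measures route;
  any missingness → REML linear mixed model with a random fiber intercept
  (statsmodels MixedLM) and Wald tests per term (χ²/df reported on the F
  scale with fiber-count-based denominator df — approximate, as in any
  software that marries mixed models with ANOVA-style tables).  Weeks with
  zero observations are dropped with a warning.
* Post-hoc families: Bonferroni, Šídák (p-adjustment of pairwise t tests,
  paired on subjects when a subject column is given, on subject marginal
  means when other within factors exist) and Tukey (studentized-range p on
  the pairwise t statistics).
* Per-animal CV tables: CV = SD/mean over a animal's fibers, mean ± SEM
  over animals per cell; animals with < 2 fibers are excluded.
* Calibration under the null: with no week effect, the complete-data
  repeated-measures route rejects the week effect at close to the nominal
  5% (empirically within [0.03, 0.07] over 1,000 simulated cohorts),
  despite the mildly log-normal response distribution.

Significance is α = 0.05 throughout.

## Problem sizes used in the checks

Desk-scale settings keep every verification fast: 30 s recordings (300
scans × 1,000 samples × 16 channels) for pipeline checks, a 5 min
16-channel baseline for the stability measurement, 100 Monte-Carlo traces
for τ recovery, 50 seeds for the cross-fiber CV distribution, and 1,000
replicates (5 animals × 16 fibers × 4 weeks × 2 parameters each) for the
type-I-error calibration.

## Known limitations

* The raw dialect is this package's formalization; other acquisition
  software will need a reader shim.
* Q-residual screening is conservative and its threshold heuristic; the
  source processing chain described no residual screening at all.
* The mixed-model missing-data route's denominator degrees of freedom are
  approximate (no Satterthwaite/Kenward–Roger correction).
* τ is a single-exponential description of clearance; Michaelis–Menten
  saturation and release-per-pulse deconvolution are out of scope.
* 60 Hz cycling sessions are representable as waveform configurations but
  produce no analyzed output, mirroring the recording protocol.
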