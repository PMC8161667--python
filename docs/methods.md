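# Methods

`erptrains` implements, end to end, the analysis chain of an infant
auditory event-related-potential (ERP) study built on a trains-of-vowels
oddball paradigm, together with a synthetic-data generator that makes
every stage testable without access to real infant EEG (which is rarely
shareable).  This note documents the models, the defaults and their
rationale, the numerical choices, and what the synthetic benchmarks do
and do not establish about real data.

## 1. The paradigm and its simulation

Stimulation consists of *trains* of four 50-ms sounds: three identical
standard vowels (S1, S2, S3) followed by a deviant differing either in
pitch or in vowel category, each with probability 0.5.  The
inter-stimulus interval within a train is jittered around 500 ms
(uniform ±100 ms by default; the jitter distribution is configurable
because only its centre is conventionally reported), giving a 450–650 ms
onset asynchrony; the inter-train interval is uniform on 3000–4000 ms.
A session is capped (default 10 min) and truncated on whole-train
boundaries so the event grammar — every deviant preceded by exactly
three standards — holds unconditionally.

Stimulus audio is never synthesised: the ERP analysis only consumes
condition labels and onsets.  Each condition evokes a region-specific
template built from half-period raised-cosine bumps
`a·sin²(π(t−onset)/width)` — smooth, compactly supported, and
analytically integrable over analysis windows, which makes planted
window means computable in closed form.  Frontal and posterior bumps
carry opposite polarity (the conventional fronto-posterior inversion of
infant auditory components), so the template field is zero-mean across
the montage and survives average re-referencing unchanged.

Default template amplitudes follow the response pattern the analysis is
designed to detect: a frontal negativity to the first standard
(≈ −4 µV), strong repetition suppression (S1−S2 ≈ −5 µV frontal, +5 µV
posterior), deviance responses of similar size (S2−Dev ≈ −5/+5 µV), and
a small late pitch-vs-vowel difference (≈ 1.2 µV, 300–440 ms).  All
bumps end by 440 ms post onset so that, at the shortest asynchrony, no
bump leaks into the next stimulus' baseline window.  Group and age act
as template modifiers (default: NF1 amplitude ×0.75; 10 months ×0.8;
onset shifts supported and zero by default).

**Noise.**  Background EEG is modelled as stationary band-limited noise:
white Gaussian noise brick-wall filtered to 0.1–30 Hz in the frequency
domain and rescaled to a marginal SD of 20 µV per channel.  Ideal
band-limiting is used deliberately: its lag-τ autocorrelation has the
closed form `sin(2πBτ)/(2πBτ)` (≈ 0.976 for B = 30 Hz, τ = 2 ms), which
serves as an analytic oracle for the autocorrelation machinery.  A pink
(1/f-weighted) variant and plain white noise are selectable.  Noise is
independent across channels — a known simplification; real EEG noise is
spatially correlated, so real regional averages gain less from channel
averaging than simulated ones.

**Artifacts** mix blink-like transients (150 µV-scale, ~400 ms,
anterior-weighted raised-cosine time course) and motion-like broadband
bursts on all channels, at a default 3/min.  They exist to exercise the
rejection logic, not to model infant artifact statistics.

**Cohorts** are longitudinal: each subject is simulated at 5 and
10 months.  A master `SeedSequence` spawns one substream per
subject-session, so any session is reproducible in isolation.  A latent
per-subject responsiveness factor scales template amplitudes
(1 + 0.25·z, clipped at 0.1) and feeds the outcome generator, which
draws instrument-like scores (MSEL receptive/expressive raw, CDI word
counts, AOSI total for the NF1 group only, IBQ-R Activity) with a
configurable latent–outcome correlation (default 0.4).  The score means
and SDs are invented but order-of-magnitude realistic for 14-month
assessments; they only matter through z-scores and correlations.

**Montage.**  The default test montage has 16 channels: two per
region × site cell (frontal/posterior × left/central/right) plus four
unassigned central channels.  The unassigned channels matter: with
*every* channel assigned, the average reference forces the posterior
regional mean to be the exact negative of the frontal one, collapsing
the 8-variable correlation matrix to rank 4.  A denser 127-channel
schematic layout (`dense_montage`) is available for interpolation and
I/O realism.

## 2. Preprocessing

The chain is: zero-phase band-pass → segmentation → artifact detection →
bad-channel interpolation → baseline correction → average reference →
truncation and averaging.

* **Filter**: 4th-order Butterworth band-pass 0.1–30 Hz applied
  forward-backward (`sosfiltfilt`), i.e. zero-phase with a squared
  magnitude response.  The realisation is a package choice (the
  convention in the field when unspecified); its measured effect on
  planted 0–500 ms contrast waveforms is below 0.02 µV, which is the
  bound the noiseless recovery tests assert.  One measurable
  consequence: white noise filtered this way has a mean lag-1
  autocorrelation of ≈ 0.989, slightly above the ideal brick-wall value
  0.976, because the squared IIR response is effectively narrower than
  its nominal band.
* **Epochs**: −100 to +800 ms around each sound, inclusive at both ends:
  451 samples at 500 Hz with sample 50 at onset.  Adjacent epochs
  overlap by construction (asynchrony ≈ 550 ms < 800 ms); this is
  intentional and harmless because the analysis span ends at 500 ms.
  Events too close to a recording edge are flagged (`edge`), not fatal.
* **Artifact rule**: a channel is bad within an epoch if its
  peak-to-peak amplitude exceeds 200 µV; an epoch is rejected outright
  if *more than* 25 channels are bad (25 exactly is retained — the
  boundary is strict).  The amplitude criterion replaces the visual
  inspection used with real infant data: a reproducible pipeline needs
  a deterministic rule, and the threshold is configurable.
* **Interpolation**: surviving bad channels are replaced by
  inverse-distance-weighted averages of the good channels (exact for
  constant fields, and for linear fields at symmetry points of the
  montage).  Spherical splines would be preferred on a real geodesic
  net; IDW is the appropriate level of modelling for schematic 2-D
  positions.  Epochs without enough good neighbours are rejected
  (`uninterpolable`).
* **Baseline and reference**: per channel, the −100–0 ms mean is
  subtracted; then, per sample, the across-channel mean.  Both means are
  exactly zero afterwards, and the operation is idempotent — two
  invariants asserted on every synthetic epoch set.
* **Truncation and the 10-trial rule**: condition averages use the first
  120 retained standard trials and the first 65 retained deviant trials
  (longer paradigm versions are truncated so exposure is comparable);
  a condition retaining fewer than 10 trials is excluded *for that
  subject and condition only*.  Retention bookkeeping satisfies
  presented = retained + rejected per condition.

## 3. Features

Channels are collapsed by unweighted mean into region (× site) cells.
Contrasts are sample-wise differences in fixed order — S1 (pass-through),
S1−S2, S2−S3, S2−DevPitch, S2−DevVowel, DevPitch−DevVowel — computed
only when both constituents survived the 10-trial rule.  The analysis
grid is the first 500 ms post onset, half-open: 250 points at the native
2-ms spacing (no resampling).  Window means use eight half-open 50-ms
windows tiling 100–500 ms; with equal widths, the 100–500 ms mean equals
the mean of the eight window means, an identity the tests exploit.  The
component-analysis stage consumes eight variables per subject-session:
the 100–500 ms site-collapsed means of S1, S1−S2, S2−DevPitch and
S2−DevVowel, frontal and posterior separately.

## 4. The Monte-Carlo run-length criterion

Waveforms sampled at 2 ms are so strongly autocorrelated (lag-1 ≈ 0.98)
that pointwise paired t-tests at α = .05 produce long spurious runs of
"significance".  The criterion calibrates run *length* instead of level:

1. estimate the mean lag-1 autocorrelation φ of the observed difference
   waveforms (per-waveform sample correlation, averaged across subjects;
   zero-variance waveforms are excluded with a warning, and an
   all-degenerate input is an error);
2. simulate 1000 null experiments of stationary AR(1) waveforms with
   marginal mean 0, variance 1 and lag-1 correlation φ (innovation
   variance 1−φ², stationary start), matched in subject and timepoint
   counts;
3. in each, record the longest run of consecutive two-tailed one-sample
   t-tests significant at α = .05;
4. the threshold is the 95th percentile (nearest-rank on the integer
   run-length distribution) of those longest runs;
5. observed runs *strictly exceeding* the threshold are reported as
   (onset, offset) intervals in ms — the times of the first and last
   significant sample of the run.

φ is pooled across all analysed datasets by default (one grand value,
matching how a single value is conventionally reported), with a
per-dataset mode available; nulls are simulated separately per group and
age because subject counts differ.  Zero-variance timepoints in the
pointwise tests use the convention p = 0 if the mean difference is
nonzero, p = 1 otherwise — never silently dropped.

Calibration is verified by simulation: over 500 null experiments
(20 subjects × 250 timepoints, φ = 0.98), each thresholded by its own
1000 matched simulations, the family-wise false-positive fraction stays
at or below ~0.05 (measured 0.03 at seed 1).  Onset recovery on planted
effects (d ≥ 1.5, n = 20) is accurate to ±20 ms, with a known mild
inward bias near onset/offset edges: run endpoints require pointwise
significance, which builds up over the effect's rising flank.

## 5. Cohort statistics

**Windowed mixed models.**  Window means are modelled per contrast and
region with fixed factors Age (5, 10 m), Group (TD, NF1), Site (left,
central, right) and Time (8 windows), and a compound-symmetry
within-subject covariance fitted by maximum likelihood.  Compound
symmetry is realised as a per-subject random intercept — the identical
covariance structure, restricted to non-negative within-subject
correlation (the plausible regime for windowed ERP data).  The default
fixed-effects structure is all main effects plus the Age × Group
interaction (the developmental question); the saturated four-way
factorial is available (`full_factorial=True`) but is ill-conditioned
for mixed fits at realistic cell counts.  Omnibus tests per term are
Wald tests converted to F with a residual denominator df
(n_obs − fixed-effect rank); this is a fixed, documented convention —
the exact denominator-df algorithm behind published SPSS-style outputs
is not recoverable and is not asserted.  Partial η² is computed as
qF/(qF + df_den).  Estimated marginal means per Age × Group cell average
the fixed-effect prediction over the other factor levels (covariates at
their mean).  On degenerate noiseless data the ML problem is unbounded;
the fit falls back to the OLS limit and says so (`degenerate=True`).

**Follow-ups.**  Pairwise contrasts of the Age × Group marginal means
(within-group across age, within-age across group; family of 4 in a
2 × 2 design) use Bonferroni control: adjusted p = min(1, 4p), and the
adjusted alpha 0.05/4 is reported as .013 (half-up rounding to three
decimals).

**Components.**  The eight mean-amplitude variables (age points stacked
as separate rows, complete-case) are reduced by principal components of
the correlation matrix; components with eigenvalue > 1 are retained
(strict, with a 1e-10 tie guard so the identity-matrix boundary retains
nothing), then rotated by direct oblimin (γ = 0, oblique) via
statsmodels' rotation machinery.  Factor scores use the regression
method (Z R⁻¹ S with S the structure matrix).  PCA signs are arbitrary,
so each component is oriented to make its dominant variable block load
positively, and the component dominated by the deviant contrasts is
listed first (`deviant_response`, then `standard_response`).  On
synthetic data planted with the two-component structure (deviant vs
standard contrasts, frontal positive / posterior negative) the retained
count is 2 in ≥ 95% of replicates at n = 70, and recovered loadings
exceed 0.9 congruence with the planted pattern.

**Composites and correlations.**  Language composites average two
z-scores referenced to the TD group's mean and SD (MSEL Receptive + CDI
Words Understood for comprehension; Expressive + Words Understands-and-
Says for production); a composite exists only when both constituents do,
and the IBQ-R Activity score is blanked when more than 20% of its items
are missing.  Correlations are Pearson with pairwise-complete deletion,
df = n−2 (minimum three complete pairs); partial correlations use the
first-order closed form with df = n−3 and refuse collinear controls.
The AOSI is simulated for the NF1 group only, so the correlation stage
tolerates group-restricted outcomes by construction.

## 6. Pipeline, formats, problem sizes

The pipeline (library calls or the `erptrains` CLI) runs
simulate → preprocess → features → runtest → stats from one YAML config,
writes every table as UTF-8 CSV/TSV plus a JSON manifest (config
snapshot, seeds, per-stage paths), and can resume from cached feature
tables.  Continuous EEG can be exported as 16-bit EDF (1-s records,
per-channel physical scaling, zero-padded final record); the writer is
round-trip checked against MNE's EDF reader to quantisation accuracy.
Figures show group/age mean waveforms ± SEM with horizontal significance
bars, one per detected interval.

Default test and demo sizes (cohorts of 6–16 subjects, 22–40 trains,
150–1000 null simulations) are chosen so the whole suite and the
benchmark script each run in minutes on a single core; they are study-
shaped but deliberately small.  The statistical benchmarks that need
scale (500 calibration experiments, 200 component replicates, 10⁴
run-length oracles) run at full size.

## 7. What passing tests do and do not show

The synthetic generator produces exactly the structure the analysis
assumes: symbolic conditions with additive templates, stationary
Gaussian band-limited noise, independent channels, compound-symmetric
subject effects, and outcome scores linearly coupled to a single latent
factor.  Passing tests therefore demonstrate that the *methods* are
implemented correctly and are calibrated under their own assumptions —
not that real infant EEG satisfies those assumptions.  In particular:
real noise is non-stationary and spatially correlated; real artifact
statistics are not Poisson bursts; visual artifact rejection differs
from a peak-to-peak rule; a real high-density net needs spherical-spline
interpolation and a measured sensor geometry; and published
mixed-model F statistics depend on a denominator-df algorithm this
package does not claim to reproduce.
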