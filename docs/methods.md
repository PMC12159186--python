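# Methods

This note documents the models, estimators and numerical choices behind
`riftsearch`, and what the synthetic experiments do and do not establish
about real recordings.

## Synthetic experiment model

Each trial's sensor signal is a sum of explicitly planted components:

- **Background noise**: 1/f^α Gaussian noise (α = `noise_exponent`,
  default 1), shaped in the frequency domain and normalised to unit
  standard deviation, plus white sensor noise (std 0.3). Real MEG noise
  additionally contains line noise, cardiac/ocular artifacts and
  non-stationarities that the generator does not model; calibration and
  recovery results here therefore demonstrate correctness of the
  estimators under the assumed noise model, not robustness to artifacts
  (which the emulated pipeline handles in preprocessing stages that are
  out of scope).
- **Tag carriers**: one sinusoid per stimulus colour at the tagging
  frequencies (60 and 67 Hz by default), present only after
  search-display onset (t ≥ 0), with a per-experiment random phase shared
  with the reference channel. The carrier amplitude is
  `gain × snr` where the gain encodes the trial's condition: guided
  target colour `boost_gain` (default 1.3), guided distractor colour
  `suppress_gain` (0.7), unguided stimuli `unguided_gain` (1.0).
  Equal gains yield a null experiment. `snr` is the amplitude of the
  unit-gain carrier relative to the background std at the
  signal-carrying sensors; the suite uses 0.5 for "strong response"
  scenarios (the set-size-32 analogue) and 0.05 for weak ones.
- **Evoked transient**: a damped broadband burst (30–80 Hz filtered
  noise under an exponential envelope, ~0.15 s) at t = 0, emulating the
  early frequency-unspecific onset response. It is amplitude-locked but
  not phase-locked to the reference, so it does not masquerade as a
  tagging response in coherence.
- **Sensors**: 20 synthetic sensors by default, the first 5 carrying the
  tag signal — a desk-scale stand-in for an occipital candidate set; all
  analyses treat sensors symmetrically.

The trial table implements a blocked design (24 blocks × 40 trials by
default, i.e. 960 trials): condition (guided/unguided) and set size
(16/32) constant within a block, half target-present/half absent per
block, the colour↔frequency assignment exactly balanced within each
block, the guided target colour constant within a block and
counterbalanced across blocks, the unguided "target colour" label
randomised per trial (it is carried for target-absent unguided trials
too, so both analysis conventions can be exercised; a filter switch
excludes them). Reaction times follow a shifted lognormal
(`rt = 0.2 + LogNormal(μ, 0.35)`) with μ increased by 0.18 for set size
32 and decreased by 0.138 under guidance — the directions and rough
magnitudes of the behavioural effects being emulated; exact parameters
are free choices. Draws beyond 4 s become no-response trials.

Stimulus layouts place `set_size` items (half each colour) on jittered
lattice cells within the 10° × 10° search grid (screen-centred degrees,
+x right, +y up). Gaze traces are smoothed-noise fixational drift around
a fixation locus plus Poisson microsaccade-like jumps with a 2:1
horizontal:vertical amplitude ratio and occasional blinks;
`colour_bias = 0.5` makes gaze independent of colour, while values
toward 1 move the locus onto a target-colour stimulus (positive control
for the gaze-bias statistic). Gaze shares the sensor sampling rate for
simplicity.

Everything is driven by one `numpy` Generator seeded from
`SimConfig.seed`; identical configs produce bit-identical experiments.

## Coherence estimation

The trial-averaged coherence is a phase-locking-weighted amplitude
ratio: per sample, the modulus of the trial-mean of
`m_meg · m_ref · e^{iΔφ}` divided by the product of the trial-mean
amplitudes. It is *not* magnitude-squared coherence: with a
constant-amplitude reference it is bounded by 1 (triangle inequality),
but the bound can fail if reference amplitude covaries with the sensor
amplitude, so the bound is only asserted under a constant-amplitude
reference. The measure is invariant to positive rescaling of either
signal; its null level scales like n^(−1/2) in the trial count.

Narrow-band analytic signals come from a windowed-sinc FIR (Hamming
window, passband centre ± 3.5 Hz, transition width equal to the
half-width, ~53 dB stopband) applied zero-phase. The two-pass
forward–backward cascade is computed as a single convolution with the
kernel's self-convolution (identical for symmetric FIR, and fast via
overlap-add), after reflection padding; samples within one filter length
of the epoch edges are flagged (`edge_invalid`) and analysis windows are
kept away from them.

Spectra and TFRs (default 50–75 Hz in 1 Hz steps) evaluate the same
estimator against a noise-augmented copy of the reference sinusoid
(white noise, amplitude 0.05), which gives the reference non-zero power
away from the tag frequency so the denominator never vanishes.

Condition time courses are counterbalance-averaged: trials are split by
which frequency tags the role's colour, coherence is computed per split
against the matching reference, and the two series are averaged. The
unguided reference series pools unguided trials and averages the series
computed at both tag frequencies (averaging after coherence computation;
pre-pooling was the other defensible option and is not implemented as
the default because the split-then-average form matches the
counterbalancing of the guided roles).

## Sensor selection

The selection statistic is the bias-corrected z-transformed coherence
difference between a search window (0–0.5 s) and a baseline window
(−0.7 to −0.2 s), with `bias = 1/(2n−2)`. The bias terms cancel in the
numerator, so `Z = (atanh coh_search − atanh coh_bsl)·√(n−1)`; the
implementation evaluates the full printed expression and the tests
assert the identity.

The null distribution randomly swaps the baseline and search segments
within each trial (the two are exchangeable under the null of no
stimulus-locked response); one trial-wise draw per permutation is shared
across sensors, since a trial's segments are swapped for the whole
array. Selection requires the empirical Z to *strictly* exceed the
(1 − α) fraction of the sensor's own null draws (per-sensor null;
α = 0.01 by default, 10,000 permutations by default).

Window coherence is estimated, by default, from one Hanning-tapered
Fourier coefficient per cut segment at the reference frequency
(`method="fourier"`), with coherence over trials from averaged cross-
and auto-spectra. This route processes the two segments in complete
isolation, so the segment-swap null is exact under exchangeability, and
measured type-I error sits at the nominal 1% (≈0.95% over 6000 null
datasets). The alternative `method="hilbert"` reuses the narrow-band
analytic-signal coherence averaged per sample within the window
(`average="samples"`, or a pooled window-wide estimate); because the
±3.5 Hz FIR kernel is ~1 s long, the two windows then share filtered
noise, which under-disperses the swap null slightly (measured ≈1.5% at
nominal 1%) — the route is retained for comparability with the
response-magnitude time courses, with this caveat documented.

## Single-trial GLM

Single-trial responses are Welch magnitude-squared coherences at the tag
bin: the epoch is band-passed 30–80 Hz with a two-pass 4th-order
Butterworth over its full (generously padded) length, the 0.2–0.5 s
interval is cut into 0.1 s Hanning windows stepped by 0.025 s (9
windows), each zero-padded to 512 samples, and coherence is formed from
the averaged cross- and auto-spectra. On the 512-point grid at 1000 Hz
the tag frequencies are off-grid; the nearest bin is used (60 → 60.55 Hz
bin 31, 67 → 66.41 Hz bin 34). No detrending is applied beyond the
taper.

The response vector concatenates every trial's target-colour coherence
followed by every trial's distractor-colour coherence; each trial's two
rows share its time-on-task value (global trial index scaled to [0, 1]).
Guided trials contribute a T row and a D row, unguided trials two U
rows. The T/U/D indicators partition the rows, so an explicit intercept
would make the design rank-deficient — which is why there is none. The
fit uses the Moore–Penrose pseudoinverse; residual variance uses the
unbiased denominator `n_obs − rank(X)`. Where the residual variance is
at round-off level (perfect fit) the t value is flagged undefined (NaN)
rather than returned as ±∞. A behavioural variant regresses one role's
guided-trial responses on (constant, tot, rt).

## Cluster-based permutation tests

Paired t statistics per feature; features exceeding the cluster-forming
threshold (the `cluster_alpha` = 0.05 quantile of the t distribution —
the conventional default, exposed in the settings object) are grouped under
the adjacency relation (1-D temporal contiguity, or a k-nearest-
neighbour sensor graph with k = 4 built from sensor positions); cluster
mass is the sum of t (maxsum). The null is the distribution of the
maximal cluster mass under per-unit condition swaps (sign flips of the
paired differences), and `p = (1 + #{null ≥ observed}) / (n_perm + 1)`,
so attainable p values are bounded below by `1/(n_perm+1)`. One-tailed
tests take their direction from the contrast being tested. The
implementation is cross-checked against an independent cluster-test
implementation in the test suite.

## Gaze statistics

Gaze bias: the trial is cut into 0.1 s bins; each bin's mean (optionally
median) valid gaze position is assigned the colour of the Euclidean-
nearest stimulus; the bias is the fraction of valid bins assigned the
target colour. Blink-contaminated samples are excluded; bins with no
valid samples, and bins whose nearest-stimulus distance ties between
colours, are excluded from numerator and denominator alike. The
statistic is translation-invariant (gaze and layout together) and maps
to `1 − fraction` under a global colour swap when no ties occur.

## DICS source mapping

The cross-spectral density at the analysis frequency is the segment
average of outer products of stacked (sensors + reference) Fourier
coefficients, from Hanning-tapered exact-frequency DFTs of 0–0.5 s
segments; Hermitian symmetry is enforced exactly. The sensor block is
inverted with a truncated-SVD pseudoinverse (components below
`dim × machine-epsilon` of the largest singular value are dropped;
an explicit rank can be given instead), which keeps the inversion stable
for rank-deficient covariances. Per grid point the minimum-variance
filter `w ∝ C⁺l` is normalised to unit Euclidean norm (unit noise gain),
and the source-reference coherence is
`|wᴴc_ref|² / ((wᴴC_ss w)·P_ref)` — magnitude-squared, hence in [0, 1]
for a valid averaged CSD (a magnitude option exists). Grid points with a
zero lead-field column are flagged NaN. The top-percent mask keeps the
`ceil(p% × n_grid)` largest values with ties broken by stable grid
order.

Lead fields are package inputs; the bundled generator
(`make_synthetic_leadfield`) builds a smooth synthetic gain matrix
(planar source grid, sensor ring, inverse-quadratic distance falloff
with mild per-sensor gain variation) — adequate for localisation tests,
not an anatomical forward model. Fixed-orientation scalar dipoles only.

## Problem sizes and determinism

Test and example runs use desk-scale configurations (typically 4–8
blocks of 10–20 trials, 1–10 sensors, 0.6–0.8 s search epochs) chosen so
the full suite completes in well under five minutes while keeping the
planted effects detectable at high power; the calibration runs use the
sizes stated with each quantity (1000 null datasets × 50 trials × 1000
permutations for the selection type-I rate; 1000 trials for the null
gaze bias). All randomness flows through seeded `numpy` Generators:
tests are deterministic, and `scripts/acceptance.py` derives every
stream from its `--seed`.

## Known limitations

- The generator's stationarity, Gaussianity and single sensor class are
  idealisations; passing calibration here does not certify behaviour
  under real artifacts, sensor-type mixtures or head movement.
- Eq.-3 coherence values near saturation (high snr) compress condition
  differences; the GLM route on Welch coherences is the more sensitive
  detector in that regime, which the end-to-end test reflects.
- Group-level inference treats simulated experiments as exchangeable
  participants; no hierarchical/mixed modelling is provided.
- The DICS stage does not model anatomy, coregistration or vector
  dipoles; localisation claims are relative to the supplied lead field.
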