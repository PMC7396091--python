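# Methods

This note documents the models, estimators, parameter defaults and numerical
choices in `lfpnet`, and what the synthetic tests do and do not establish
about real recordings.

## Synthetic recordings

Each animal's multichannel wake recording is built at 512 Hz from explicit
ground truth (`LfpGroundTruth`):

* **Background**: Gaussian noise spectrally shaped to `1/f^beta`
  (`background_exponent`, default beta = 1.0, a typical LFP slope), scaled to
  `background_amplitude` (default 20 uV RMS).
* **Band components**: band-passed Gaussian noise (4th-order Butterworth
  around `center +- bandwidth/2`) normalised to the component RMS; a
  bandwidth of zero yields a pure sinusoid with random phase.  The default
  carries one delta component (2 Hz, bw 1.5, 25 uV).
* **Theta-gamma coupling** (`PacSpec`): a slow cosine at `f_phase`
  (default 7 Hz, 30 uV) whose phase modulates the envelope of a fast carrier
  at `f_amp` (default 57.5 Hz, 15 uV) as `amp_fast * (1 + depth cos(phi))`,
  default depth 0.6.  The construction is closed-form, so envelope and
  coupling recovery can be checked against independent Hilbert-transform
  oracles.
* **Pair mixing**: a lagged, scaled copy of a source channel added to a
  target channel (default OBL -> OBR, gain 0.8, lag 4 samples ~ 7.8 ms),
  giving the inter-bulb pair controlled coherence with a non-zero phase lag
  (hence non-zero imaginary coherency).
* **Line contamination**: a 50 Hz sinusoid (European mains), 10 uV.
* **Motion envelope**: an alternating active/quiet box-car (default 30 s /
  30 s) smoothed with a 1-s moving average plus mild positive noise,
  emulating passive-infrared activity traces in arbitrary units.

**Aged effects** are multiplicative on ground-truth parameters
(`AgedEffects`): gamma carrier amplitude x0.5, delta amplitude x1.5, PAC
depth x0.4, mixing gain x0.5, and post-HFS potentiation x0.62.  Every animal
additionally receives lognormal jitter (sd 0.15 on the log scale) on its
amplitudes so between-animal variance exists; per-animal seeds derive from
the master seed through `numpy.random.SeedSequence.spawn`.

What the generator deliberately does **not** emulate: broadband (noise-like)
gamma, non-stationary oscillation bursts, cross-regional phase coupling
beyond linear mixing, electrode drift, chewing/movement artifacts with
realistic morphology, or state transitions beyond the two-state motion gate.
Passing recovery tests therefore demonstrates estimator correctness on
signals with the assumed structure, not robustness to every pathology of
real LFP.

## Synthetic evoked sweeps

`EvokedGroundTruth` defines a stylised CA1 field response on a 3 kHz grid
(-5 to 45 ms around the stimulus): a fast-decaying positive stimulus
artifact inside the 1-ms blanking period; an fEPSP descending linearly from
onset (2 ms) to its negative peak (6 ms), holding a 2-ms flat bottom, then
recovering exponentially (tau 12 ms); and a population-spike complex at
7 ms — a narrow negative Gaussian notch (sd 0.3 ms) riding inside a wider
positive bump (ratio 0.5, sd 0.6 ms), which produces the two positivities
flanking the spike trough that the tangent PSA measurement requires.
Response magnitude scales with a logistic stimulus-response curve (half-max
4000 mV, steepness 800 mV) times the potentiation factor; at the half-max
test stimulus the default geometry lands inside the inclusion windows
(latency 7 ms, amplitude ~2175 uV, slope ~472 uV/ms).  The young
potentiation profile is `1 + exp(-t/120 min)` after HFS (~190% of baseline
early, ~155% late); the aged multiplier scales the whole post-HFS factor, so
a multiplier of 0.62 yields a ~-38% group difference in normalised values.
Note that the `spike_amplitude` parameter is the notch depth, not the PSA
itself: the chord-to-trough distance of the closed-form waveform (the
quantity the extractor estimates and the tests compare against) is smaller,
because the chord rides the positivity bump.

## Preprocessing

* Powerline removal: zero-phase IIR notch, -3 dB bandwidth 1 Hz (>= 30 dB at
  the line frequency, < 1 dB beyond +-2 Hz).
* Band limiting: zero-phase 4th-order Butterworth (1-256 Hz); forward-
  backward filtering keeps inter-channel phase unbiased for coherency.
* Epochs: 2-s windows on a 1-s stride ("sliding windows"; the stride is a
  package choice).  A window is wake-positive when its mean motion envelope
  is at least 20% of the per-animal maximum (PIR units are arbitrary, so the
  threshold is normalised per animal and configurable).
* Artifact rejection: a window is discarded if any channel exceeds 1000 uV
  absolute, or if its delta-band (1-4 Hz) relative power exceeds 0.6 while
  its motion is below threshold (high-voltage slow waves without
  locomotion).  Both limits are package defaults — acquisition systems
  differ — and rejection only ever tightens labels.

## Spectral and connectivity estimators

Welch PSD: one Hann-tapered periodogram per accepted 2-s epoch (0.5 Hz
resolution), averaged across epochs; overlap is handled at the epoch level.
Relative power divides each bin by the total over the half-open analysis
grid [1, 256) Hz (510 bins), so per-animal spectra sum to one exactly.  Band
edges are half-open `[lo, hi)` so delta/theta/gamma partitions never
double-count a bin.

Cross-spectra use the same epochs and taper, with the convention
`S_AB = <X_A conj(X_B)>`, under which a pure delay of B relative to A gives
`imcoh = sin(omega tau)` and imcoh is antisymmetric under channel swap.  The
25-35 Hz imcoh summary is the **signed** mean (preserving antisymmetry);
an absolute-value variant is available by flag.  Bins with zero autospectrum
are NaN and excluded from summaries.  Coherence needs at least two epochs;
the estimator's positive bias on independent signals (~1/n epochs) is
property-tested.

## Phase-amplitude coupling

Morlet wavelets with 7 cycles at every frequency (a standard balance of
time/frequency resolution over 2-200 Hz), truncated at +-4 Gaussian widths
and normalised to unit gain on a tone, extract phase (at f_L in 2-12 Hz,
step 2) and amplitude (f_H in 10-200 Hz, step 5).  Samples within one
wavelet half-support of any segment edge are excluded, and accepted epochs
are merged into maximal contiguous runs before convolution so concatenation
seams never leak into the estimate.  The modulation index is the
mean-vector length `MI = |<A_H exp(i phi_L)>|`; for `A = 1 + cos(phi)` with
uniform phase coverage it equals 0.5 exactly, which the tests assert.  Read
literally, "the mean absolute value of z(t)" would be the mean envelope and
cannot measure coupling; that reading is kept as the diagnostic
`mean_abs_z`, and the canonical mean-vector-length is used everywhere else.
Raw MI is scale-bearing (linear in amplitude); `normalized=True` divides by
the mean envelope for a scale-free index.  An internal surrogate null
(200 circular time shifts of at least 1 s, seeded) provides thresholds for
sanity checks only — group inference never uses it.  Note that for a
strictly periodic slow rhythm, circular shifts only rotate the coupling
phase; surrogate collapse holds for frequency-drifting (real-world) rhythms,
which is how the property is tested.

## Group statistics

Scalars use the Welch (unequal-variance) two-sample t-test with a 95% CI on
the mean difference — the safer default at n = 7-8 per group; degenerate
zero-variance-equal-means input reports t = 0, p = 1.

TFCE enhances the per-bin t-statistic vector with H = 2, E = 0.5, summing
`extent^E * height^H * dh` over supra-threshold heights, where extent is the
length in bins of the contiguous supra-threshold run.  The integration step
is `dh = max|t| / 100`; 100 steps keeps the discretisation error well below
test tolerances while staying fast inside permutation loops (the kernel is
numba-compiled with a pure-numpy fallback, and both paths are tested against
a brute-force double loop).  Positive and negative parts are enhanced
separately because aging effects go both directions (delta up, gamma down).
Family-wise calibration uses the permutation distribution of the maximum
|TFCE| under group-label exchange: all C(n, n_a) assignments are enumerated
when that count is at most C(16, 8) = 12870 (the study's design size),
otherwise a seeded random subset including the observed labelling.  With a
fixed dh the enhancement is monotone in |t| (property-tested); the
data-derived dh is used everywhere else.

Calibration at desk scale: over 500 null simulations (7 vs 8 animals,
100-bin smooth spectra, 500 permutations each) the family-wise false-positive
rate stays within two Monte-Carlo standard errors of alpha = 0.05, and a
halved gamma amplitude in an 8 + 8 cohort with 60 s of signal per animal is
detected (a significant cluster overlapping 30-80 Hz) in >= 80% of
simulations.

## LTP arm

Features per sweep: negative peak = minimum voltage in the search window
(default 4-15 ms, after the 1.5-ms artifact blanking — the artifact end is a
configurable package choice); latency = time of that minimum; amplitude =
baseline-to-peak; slope = least-squares line over the central 80% of
[blanking end, peak time], trimming 10% at each end (reading "the 80%
interval" as a central trim avoids both the artifact tail and the peak
curvature); PSA = chord across the highest points within 1 ms on each side
of the trough, evaluated at the trough (the tangent method; the 1-ms flank
window reflects how fast the population spike is and makes the measurement
robust to sample-level noise where strict local-maximum detection at 3 kHz
is not).  PSA is only meaningful when a spike is present.

I/O curves require exactly 3 sweeps per intensity at 1000-10000 mV (step
1000); "no response" sweeps contribute zero.  A four-parameter logistic is
fitted by least squares (ceiling bounded below by the largest observed
mean); the test stimulus solves the fitted curve at 50% of the fitted
maximum.  Curves with < 5% dynamic range or poor fits are flagged and carry
no test stimulus.

Time courses average exactly 5 sweeps per 2.5-min timepoint and are
expressed as percent of the pre-HFS baseline.  The baseline is the last
30 min before HFS (12 timepoints at 2.5-min spacing) by default; a
6-timepoint variant is exposed via `baseline_mode="n_points"` because the
two windowings are both defensible readings of the protocol.  Baseline mean
of the normalised series is 100 exactly, and normalisation is idempotent.

Phase statistics summarise each animal by its mean normalised value over the
early (0-30 min) and late (60-90 min) post-HFS windows; the group difference
is reported in percent of the young mean with a Welch test, alongside a
mixed ANOVA (between = group, within = baseline/early/late, classical SS
decomposition, verified against an independent implementation) and Dunnett
contrasts of each phase against baseline within group (scipy's Dunnett test
on per-animal per-timepoint observations).

## Problem sizes

The default study configuration simulates 8 + 8 animals with 120 s of wake
signal per animal — enough for ~60 accepted epochs and stable PAC at the
2 Hz edge of the phase grid — plus the full evoked protocol (30 I/O sweeps
and 240 LTP sweeps per animal).  The calibration simulations use 60 s per
animal and 500 permutations per test.  These sizes are the package's
defaults for synthetic studies; all of them are configuration fields.

## Known limitations

* The gamma carrier is narrowband; real gamma is broadband and bursty, so
  absolute PAC and band-power values are not comparable to animal data —
  only directions and recovery of known parameters are claimed.
* PSA extraction assumes a single dominant spike within ~1 ms of the
  negative peak; multi-spike complexes would need wider flank logic.
* The EDF writer targets the package's own interchange needs (one data
  record per second, per-channel tight physical ranges); it is not a general
  EDF+ implementation, though files read back identically and load in MNE.
* TFCE runs on 1-D frequency grids only (no time-frequency TFCE).
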