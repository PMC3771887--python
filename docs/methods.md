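# Methods

## The design and what the generator emulates

One experiment is 23 subjects × 512 trials: 8 blocks of 64 stimulus–test
pairs, 16 of each pair type (CC, WW, CW, WC) per block in randomized order,
256 scene identifiers each used in exactly two trials of one pair type, with
the response hand alternating between block halves.  Timing metadata default
to 250 ms S1, 500 ms mask (the methods-section value; the 250 ms variant is
configurable) and 800 ms fixation; these do not enter any statistic.

### Behavioral model

Ratings and confidence are 5-point ordinal responses.  Each is generated
from a latent Gaussian cut at −1.5, −0.5, +0.5, +1.5 on the recoded (−2…+2)
scale — a discretized-latent model chosen because it gives directly
controllable condition means on an ordinal scale.  Defaults (latent recoded
means): CC −0.05, WW −0.25, CW +0.30, WC −0.60; within-subject trial SD 1.0;
independent subject × condition random effects with SD 0.15.  These encode
the qualitative structure the analysis assumes: identical pairs drift toward
"closer" (WW reliably, CC weakly — the pattern seen when hundreds of trials
dilute BE), and the mismatch asymmetry |E[CW]| < |E[WC]|.  Confidence latent
means (centered at raw 3): CC 0.40, WW 0.40, CW 0.20, WC 0.90 — highest for
WC.  Response times are log-normal (shape 0.30, multiplicative subject
effect SD 0.10) with means keyed by response category × condition; "same"
responses are fastest (≈1.15–1.48 s) and CW-"closer" slowest (1.91 s).

### ERP model

An epoch is `subject gain × condition template + noise` on 67 channels
(63 scalp in an idealized unit-sphere 10-20 geometry with exact left/right
mirror symmetry, plus 4 EOG) at 500 Hz, −100…898 ms.  Templates are sums of
components, each a Gaussian (optionally flat-topped) time course times a
Gaussian spatial falloff over unit-sphere chord distance from a center
electrode:

| component | latency | peak μV (CC/WW/CW/WC) | center | spatial scale |
|---|---|---|---|---|
| P1 | 120 ms (σ 20) | 3 (all) | Oz | 0.5 |
| N1 | 170 ms (σ 22) | −4 (all) | POz | 0.5 |
| P2 | 250 ms (σ 30) | 3 (all) | CPz | 0.5 |
| P3b | 530 ms (σ 50) | 4 / 4 / 5 / 6 | Pz | 0.5 |
| P3b WC right | 530 ms (σ 50) | 0 / 0 / 0 / 0.6 | CP2 | 0.4 |
| mismatch | 280 ms, flat 265–295 (tails σ 10) | 0 / 0 / 0 / −1.5 | TP7 + P7 | 0.35 |

The mismatch component carries its full −1.5 μV across the whole 265–295 ms
interval (flat top) and at both named electrodes (its spatial profile is the
maximum of the per-center falloffs), so the injected WC−CW difference equals
the configured amplitude at every tested grid cell; a narrow single-center
Gaussian would under-deliver the nominal amplitude at the 10 ms samples and
at the second electrode.  The "P3b WC right" increment right-lateralizes the
WC positivity, which is what makes the type × laterality interaction
non-trivial.  Note that the *analyzed* effect is still smaller than the
configured one: the common average reference subtracts the bump's spatial
mean and the band-pass trims the plateau edges, leaving ≈1.34 μV at TP7/P7
in the difference waves.  With 1 μV subject-level noise this puts the
detection noncentrality near 6.4 against a family-wise critical t near 5,
and the end-to-end raster recovers the injected interval in about 86% of
seeded replicate experiments (measured over 50 runs; the companion P3b ROI
contrast recovers in all of them).

Noise is Gaussian with AR(1) temporal correlation (correlation time 50 ms)
and a squared-exponential spatial kernel over montage distance (length scale
0.4 chord units).  The spatial correlation is what makes the tmax critical
value substantially smaller than a Bonferroni threshold would be — the
property the corrected test exploits.  The per-trial stationary SD defaults
to 7.0 μV, calibrated so that at the reference design (128 trials/condition)
one subject's WC−CW difference wave carries ≈1 μV of noise per cell *after*
preprocessing: trial averaging contributes σ√(2/128) and baseline
correction of temporally correlated noise inflates post-stimulus SD by a
measured factor of ≈1.15 (7.0 × 0.125 × 1.15 ≈ 1.0).  The multiplicative
subject gain has SD 0.10.

`ErpEffectParams.rescaled_for_trials(n)` scales the trial noise by √(n/128),
which leaves all subject-level statistics (effect/noise ratios, t-values,
F-values) invariant; analyses and tests run on 16–32 trials/condition under
this rule purely to keep simulation volume small, and state so where they do.

### What the generator does not emulate

Real EEG's 1/f spectrum and alpha oscillations, non-Gaussian and non-blink
artifacts (muscle, drift, electrode pops), latency jitter across trials and
subjects, condition-correlated trial counts after rejection, volume-
conduction physics, and any coupling between behavioral responses and
single-trial EEG.  Passing tests therefore show that the *statistics* are
correct and calibrated for data with the assumed correlation structure —
not that the pipeline is robust to everything real recordings contain.

## Preprocessing

Order: band-pass → common average reference → baseline → rejection →
averaging → decimation → channel selection; all steps but rejection are
linear, so averaging and decimation commute.

- **Filter**: "24 dB/octave" is realized as a 2nd-order-per-edge Butterworth
  band-pass (0.1–30 Hz) run forward and backward (zero-phase, preserving
  latencies).  Epochs are extended by *even* reflection over their full
  length before filtering: with a 0.1 Hz edge the impulse response is long
  relative to a 1 s epoch and the conventional odd reflection injects
  spurious low-frequency energy (measured output SD 1.40× input on AR(1)
  noise, vs 0.95× with even reflection).  Filtering is per epoch because
  only epoched synthesis exists here; this is configurable.
- **Reference**: mean over all 63 scalp channels at each timepoint; EOG
  untouched.  A1/A2 are recorded and participate in the reference but are
  excluded from the analysis channel set (the "original 61").
- **Rejection**: applied to post-filter, post-baseline values, threshold
  ±75 μV on any EEG or EOG channel; if a condition loses all trials the
  error names it.
- **Decimation**: keep every 5th sample anchored at the sample closest to
  0 ms (times become multiples of 10 ms); no extra anti-alias filter is
  needed because the 30 Hz low-pass already satisfies Nyquist for 100 Hz.
- **Channel subset**: a fixed 34-channel even-coverage grid (the paper-style
  analyses name TP7, P7, P4, F7, CP1, P1, CPz, Pz, CP2, P2; all are
  included).  With the 51 samples of 100–600 ms inclusive this gives the
  1734-comparison family.

## The tmax permutation test

For a paired contrast the per-subject difference waves are exchangeable in
sign under the null, so the reference distribution is generated by
independent whole-wave sign flips (exact for a two-condition within-subject
design).  Implementation notes:

- Sign flips leave each cell's Σd² invariant, so every permutation's t-matrix
  reduces to one matrix product of the ±1 matrix with the subject × cell
  difference matrix; 2500 permutations of the full family cost ~100 ms.
- The observed assignment is row 0 of the sign matrix, making it a member of
  the reference set *computed through the same code path* — this guarantees
  p ≥ 1/n_perm and exact ties at the observed value (a separate scalar
  computation can differ by 1 ulp and silently break the tie).
- t_crit is the ⌈(1−α)·n_perm⌉-th smallest null max |t| (ties resolved
  upward, i.e. conservatively); p(cell) = #{null max |t| ≥ |t(cell)|}/n_perm.
- The significance mask requires both |t| ≥ t_crit and p ≤ α; the second
  clause only matters in degenerate all-tie cases (identical conditions give
  t ≡ 0 = t_crit, which must not flag anything).
- Zero-variance cells get a ±10¹² sentinel t with a warning; the permutation
  ranking handles them.
- Exhaustive mode enumerates all 2ⁿ assignments (used by the oracle-
  equivalence tests); sampled mode refuses n_perm > 2ⁿ and n_perm < 100.

The critical value printed for the real study (±4.7419 at df 22) reflects
that dataset's correlation structure and is not recoverable from synthetic
data; what is checked instead is (a) the analytic mapping t_crit ↔ test-wise
alpha (2·P(T₂₂ > 4.7419) = 9.86·10⁻⁵ ≈ 0.000099) and (b) family-wise error
calibration: across 200 simulated null experiments the non-empty-mask rate
must land in the binomial 95% interval [0.02, 0.09] around 0.05.

## RM-ANOVA, ε, and post-hocs

Classical within-subject sums-of-squares decomposition; each effect is
tested against its own subject × effect interaction.  Greenhouse–Geisser ε
uses Box's formula on the covariance of the effect's orthonormalized
contrasts (interaction: Kronecker product of the two contrast bases) — this
matches R's `car::Anova` exactly, including the interaction ε, where some
Python implementations differ.  Corrected p evaluates F at (ε·df1, ε·df2).
Effect size is partial η² = SS_effect/(SS_effect+SS_error); the choice is
stated in the output because "η²" alone is ambiguous.  Tukey HSD uses the
tested effect's own error MS and df with studentized-range p-values
(q = |Δ|/√(MS/n) on the collapsed per-subject scores); interaction cells are
compared with the interaction error term.  Sums of squares below the float
rounding scale of the data are treated as exact zeros so that an all-equal
table yields F = 0 rather than a ratio of rounding residues.

The P3b window is 500–560 ms (the methods value; a 480–580 ms variant
mentioned elsewhere is configurable), inclusive endpoints — 7 samples at
100 Hz.

## Behavioral diagnostics

Recoding is s = raw − 3 with collapsing {1,2} → "closer", {4,5} → "wider"
(confidence: low/medium/high); recoded input fed back in is rejected as an
input-domain error.  BE on identical pairs is a one-sample t of per-subject
mean s against 0 (negative = "closer" = BE), with Cohen's d = mean/sd of the
per-subject means — the paired/one-sample convention; a reported d of 5.12
alongside t(22) = 3.12 is not reproducible under any standard definition and
is not attempted.  The asymmetry test negates the WC means and compares them
to CW means with a paired t.  The first-block scope uses block 1 (64
trials).  RT ANOVAs exclude subjects with any empty category × condition
cell listwise and report the exclusion count — the mechanism that produces
reduced error dfs (e.g. (2, 28) when only 15 subjects are complete).

## Problem sizes and seeds

Defaults are the study conditions (23 subjects, 128 trials/condition, 2500
permutations).  The test-suite and analysis drivers run the simulation-heavy
stages at 16 trials/condition under the variance-preserving rescaling above,
with 2500 permutations for inference and 500 for the 200-replicate
calibration loop; the effect-recovery check uses 50 seeded end-to-end runs
and the behavioral power check 100 simulated experiments.  A single global
seed derives per-stage substreams via `numpy.random.SeedSequence.spawn`, so
a run's report is byte-identical across repetitions of the same config.

## Known limitations

- The ±75 μV rule is the only artifact defense; no ocular correction (the
  pipeline rejects, not corrects, by design).
- The montage is an idealized sphere; only relative distances matter, and no
  claim is made about true electrode coordinates.
- The permutation test covers paired two-condition contrasts only (the
  design's use case); no cluster statistics or FDR alternatives.
- Ordinal ratings are modeled with a single shared set of cut-points; no
  per-subject response-style variation.
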