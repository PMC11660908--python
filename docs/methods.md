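# Methods

This note documents what `megpipe` computes, the modelling choices behind the
synthetic cohort generator, and the numerical conventions that affect results.

## Analysis model

### Spectral measures

Each epoch (default 4096 samples) is transformed with a raw, untapered FFT
periodogram — no Welch segmenting, no windowing — restricted to the broad band
0.5–48 Hz. The frequency resolution is `fs / n_samples` (0.076 Hz at 312 Hz,
0.081 Hz at 333 Hz). Absolute power in a band is the sum of the bin powers
whose centres fall in the band; relative power divides by the broad-band
total, so the six bands — delta [0.5, 4), theta [4, 8), alpha1 [8, 10),
alpha2 [10, 13), beta [13, 30), gamma [30, 48] — partition unity exactly.
Band intervals are half-open with the gamma upper edge inclusive; this
boundary convention is ours (it makes the partition exact) and matters only
for bins landing exactly on an edge.

Peak frequency is the argmax of power in the extended alpha window 4–13 Hz.
Ties break toward the lowest frequency (deterministic and conservative
toward slowing); a spectrum that is identically zero in the window yields a
missing value, never the window edge. Absolute spectra are used for the
argmax; under the normalisation above the argmax is identical for relative
spectra.

Aggregation is always: mean across epochs first (one value per region per
subject), then mean across regions for whole-brain values. Whole-brain peak
frequency is the mean of the regional epoch-averaged peaks.

### Connectivity

Signals are band-filtered by FFT brick-wall masking per epoch (exact band
occupancy; no filter ringing specification to honour). Edge effects of the
subsequent Hilbert transform are accepted by default — no samples are
discarded — and `edge_trim` optionally drops N samples from each end.
Instantaneous phase and amplitude envelope come from the analytic signal.

**PLI** (theta band) is `|mean_t sign(sin(Δφ(t)))|` with `sign(0) = 0`, so
exactly zero-lag coupling scores 0 and a constant non-zero lag scores 1.
Phase differences whose sine is below 1e-12 are treated as zero-lag: without
this, two channels differing only by a positive scale factor would pick up
±1 signs from floating-point noise.

**AECc** (alpha 8–13 Hz and beta bands) orthogonalizes each pair in both
directions: series j is regressed on series i (ordinary least squares with
intercept, per epoch, in the time domain), the envelope of the residual is
Pearson-correlated with the envelope of series i, the two directional
correlations are averaged, and the mean is mapped to [0, 1] via `(r + 1)/2`,
so 0.5 means no coupling. A direction whose residual variance is below
1e-10 of the original variance (pure zero-lag leakage) is degenerate: its
correlation is set to 0 rather than being estimated from numerical noise,
so pure leakage pairs score 0.5, never spuriously high. The matrix routine
exploits the linearity of the Hilbert transform (analytic signals are
computed once per region; residual envelopes are formed algebraically),
which keeps 80-region epochs fast without changing any value.

Epoch-wise regression (not concatenated-epoch regression) is used for the
orthogonalization; with the generator's stationary epochs the two agree in
expectation, and the choice only matters when coupling drifts across epochs.

The weighted functional degree of region r is the mean of row r of the
epoch-averaged connectivity matrix excluding the diagonal (divide by n−1);
the whole-brain mean is the mean over unordered off-diagonal pairs, which
equals the mean of the degrees.

### Hub disruption index

Per-region degree differences (target − reference) are regressed on the
reference degrees by OLS; the slope is the HDI and its significance is the
standard two-sided slope t-test. A region-label permutation p-value is
available as a robustness alternative. If the target is an affine map
`a·ref + b`, the slope is exactly `a − 1` and the intercept `b`.

Group-level HDI uses group-mean degree profiles; individual HDI compares a
subject to its surrogate reference (per-region mean over the three matched
controls). For control subjects the reference is the mean of their own
three-control group, *including* the subject itself — the literal protocol —
which biases individual control HDIs slightly toward 0; `exclude_self
_reference` removes the subject from its reference. All 80 regions enter
the fit (hippocampi included).

### Statistics

* Whole-brain comparisons: Wilcoxon matched-pairs signed-rank on
  carrier − surrogate differences. Zero differences are dropped, tied
  absolute differences mid-ranked, and z is the tie-corrected normal
  approximation of the *smaller* rank sum (the SPSS convention: z ≤ 0
  regardless of direction — the sign of the effect is carried by the median
  difference). Exhaustive sign-flip enumeration (`exact=True`) is available
  for n ≤ 20.
* Regional comparisons: paired t-scores per region; the null flips the sign
  of each pair's whole difference vector (subject-wise across regions,
  preserving spatial correlation), default 2000 flips. Uncorrected p-values
  use the add-one rule (minimum attainable p = 1/(n_perm+1)); family-wise
  corrected p-values compare each |t| to the permutation distribution of the
  maximum |t| over regions, so corrected ≥ uncorrected always. The
  uncorrected regional p-values come from the permutation null, not from a
  parametric t distribution.
* Spearman correlations use mid-ranks; constant inputs are undefined (NaN).
* FDR: the Benjamini–Krieger–Yekutieli two-stage linear step-up procedure,
  implemented literally (stage-1 BH at q/(1+q) estimates m0; stage-2 BH at
  q·m/m0) and cross-checked in the tests against the independent
  `statsmodels` implementation.
* Kruskal–Wallis H with tie correction; Dunn's pairwise z on mean pooled
  ranks with tie-corrected variance, Holm-adjusted over all pairs by default
  (the multiplicity method is configurable; degrees of freedom are reported
  explicitly as k − 1).
* Outlier screen: Tukey fences at 1.5 × IQR with type-7 (linear
  interpolation) quartiles.
* EYBSO = reference onset age − carrier age (parental, family-mean and
  mutation-mean variants; the parental reference falls back to an affected
  sibling's onset age); negative values mean the estimated onset age has
  passed.

Surrogate controls are formed by averaging *outcome measures* over the three
matched controls — band powers, peak frequency, degrees, whole-brain means —
never raw signals; no raw-signal mixing path exists in the code.

## Synthetic cohort generator

The generator provides ground truth, not biophysics. Each region's epoch is
a sum of:

1. band-limited Gaussian noise per canonical band (FFT-masked white noise,
   unit RMS per unit weight) — exact band occupancy, trivially verifiable;
2. a narrowband peak component: FFT-masked noise in peak ± 0.25 Hz (at least
   one FFT bin wide), with amplitude tied to the weight of the band
   containing the peak frequency. A pure shared-frequency sinusoid was
   rejected: a deterministic tone at one frequency is partially collinear
   across regions and corrupts the pairwise orthogonalization;
3. a 1/f^exponent background (default exponent 1, weight 0.3).

Default band weights (delta 0.7, theta 0.45, alpha1 0.6, alpha2 0.7, beta
0.55, gamma 0.2; peak 9.5 Hz) give an alpha-dominant resting-state-like
relative power profile. Defaults elsewhere mirror the study protocol:
4096-sample epochs at 312.5 Hz, 10 epochs per subject, 80 regions, 11
carriers with 3 age-matched controls each.

Coupling is injected per edge with explicit ground truth:

* **Phase coupling** adds one shared theta-band oscillator to both regions
  of an edge, region j's copy rotated by the edge's fixed non-zero lag
  (default π/4). The injected components hold a constant phase difference,
  so PLI rises monotonically with the edge weight and reaches 1 as intrinsic
  noise vanishes — closed-form targets without any ODE integration.
* **Envelope coupling** modulates independent-phase carriers (one per AECc
  band, 8–13 and 13–30 Hz) with one shared slow envelope (0.3–1.5 Hz
  magnitude). Envelopes correlate; phases stay independent, so expected PLI
  remains at its sampling null.
* **Leakage** is an instantaneous linear mix applied last — precisely the
  zero-lag confound PLI and AECc are constructed to reject, giving a sharp
  property test. The default mix is row-normalized (each channel receives a
  fixed fraction, default 0.25, of a weighted mean of the others) so the
  common-mode level does not grow with region count.
* **Hubs**: a latent "hubness" per region (top quartile high) sets edge
  weights as hubness products, thresholded to 30% density, so degree
  profiles are heterogeneous; hub rows/columns of both graphs are scaled by
  the hub attenuation factor before injection.

The default carrier contrast (`CarrierShift.slowing_contrast()`) is theta
weight ×1.6, alpha2 weight ×0.6, peak −1.2 Hz, hub attenuation 0.4. The
study reports only medians on clinical data, not effect sizes, so these are
free parameters of the generator: they were chosen once so that each
effect's *direction* is reliably recoverable at desk scale, and they make no
claim of matching clinical effect magnitudes.

What the generator does **not** emulate: neural mass dynamics, dipole
forward models, sensor noise, artefacts, non-stationarity across epochs,
spatially structured leakage (the mix is random, not geometry-based), or
realistic degree distributions. Passing tests therefore demonstrate the
*estimators and statistics* behave correctly under known structure, not that
the pipeline's clinical sensitivity on real MEG is reproduced.

## Problem sizes used in tests

The test and verification runs use reduced problem sizes chosen to keep the
suite quick while leaving every effect detectable: direction-of-effect runs
use 5 carriers × 3 controls, 16 regions and 4 epochs of 2048 samples over 20
seeds; family-wise-error calibration uses 200 Gaussian paired null datasets
of 20 regions × 11 pairs at 500 permutations (Gaussian data, because the
calibration exercises the permutation machinery, not the signal generator);
Wilcoxon calibration uses 1000 null samples of 11 pairs. Full-scale defaults
(80 regions, 10 × 4096 samples, 11:33 cohort) remain the package defaults
for real use.

## Numerical conventions and degenerate inputs

* All randomness flows through explicitly passed `numpy.random.Generator`
  streams; subject streams are spawned from the manifest seed, so cohort
  generation is byte-identical across runs.
* Peak-frequency ties break to the lowest bin; all-zero windows are NaN.
* Zero-variance signals are rejected for AECc (a degenerate *residual* is
  handled as described above).
* Constant reference degree profiles make the HDI slope undefined and are
  rejected.
* Sampling rates are always taken from the cohort manifest, never
  hard-coded; 312 Hz and 333 Hz streams coexist in one cohort, and band
  powers (bin-sum fractions) are robust to bin-spacing differences of this
  size. No cross-subject spectral bin alignment is attempted.

## Known limitations

* The FFT brick-wall filter is non-causal and rings at epoch edges; with
  4096-sample epochs the effect on band power and PLI is negligible, but
  `edge_trim` exists for sensitivity checks.
* The individual HDI of controls includes the subject in its own reference
  mean by default (see above).
* The Wilcoxon z is the smaller-rank-sum convention and is therefore never
  positive; direction must be read from the median difference.
* AECc values are mildly depressed below 0.5 when strong common-mode
  leakage is present (orthogonalization over-correction); this mirrors the
  measure's real behaviour and is visible in the generator's leakage tests.
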