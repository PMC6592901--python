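# Methods

This note documents the models, algorithms and numerical choices behind
`sensorydrive`, in the spirit of the methods documentation of statistical
packages: what is computed, under which assumptions, and where the design was
genuinely open.

## Audiogram indices

An audiogram is a set of (frequency, threshold) pairs — the quietest
detectable tone level per frequency.  Indices:

* **Peak sensitivity (PS)**: the measured frequency with minimum threshold.
  When the minimum is shared (within a configurable tolerance `tol_db`,
  default 0 — exact ties only), the arithmetic mean of the tied frequencies
  is returned, so a flat audiogram returns the mean of all its frequencies.
* **Interpolation** between measured tones is linear in threshold against
  log2(frequency).  Audiometric test tones are octave-spaced, and octave
  (log-frequency) interpolation is the field convention; a
  `log_frequency=False` switch gives linear-frequency interpolation for
  sensitivity analyses.  Extrapolation outside the measured range is refused:
  thresholds beyond the tested tones are unknowable.
* **Band mean thresholds** average the measured sample points inside the band
  plus the interpolated thresholds at unmeasured band edges (an endpoint
  below the lowest measured tone is dropped — the 0–20 kHz band effectively
  starts at the lowest tested frequency).  The band mean is a mean over
  points, not an integral: audiogram data are tabulated samples and an
  integral would silently impose a smoothness model.
* **relHFHS** = mean(0–20 kHz) − mean(10–20 kHz).  As a difference of two
  means over the same audiogram it is exactly invariant to a constant offset
  in thresholds, which removes between-study calibration differences.
  Positive values indicate relatively better high-frequency hearing.

Composite audiograms are pointwise cross-species means on a fixed grid;
species whose audiograms do not cover a grid frequency are dropped from that
point and recorded, with per-point species counts reported.

## Spectral slope of calls

The slope summarises the distribution of spectral energy of one call:

1. **Preprocessing.** Polyphase down-sampling to 40 kHz — a 20 kHz Nyquist
   matching the upper edge of the hearing band — with a Kaiser-designed FIR
   anti-alias filter (120 dB stopband, transition band 2% of the target
   Nyquist).  The sharp filter matters: with an ordinary default filter,
   harmonics just above 20 kHz fold back into the 18–20 kHz region at −50 dB
   and visibly flatten measured slopes.  Up-sampling is refused.  A uniform
   gain then sets the mean intensity to 60 dB SPL (reference pressure
   2·10⁻⁵ with digital full scale = 1, the Praat convention), making the
   operation idempotent.
2. **Binned peaks.** One Hann-windowed periodogram of the entire call,
   zero-padded to the next power of two; 100 Hz bins from 0 Hz to Nyquist;
   per bin the maximum amplitude (dB re the spectrum maximum, floored at
   −100 dB) and its frequency.  The DC bin is excluded and floor-valued bins
   are dropped, so silence between harmonics does not enter the regression.
3. **Slope.** OLS of peak amplitude (dB) on peak frequency (kHz).  Units are
   dB/kHz.  The slope is invariant to overall gain; the intercept is not.

All knobs (bin width, floor, target rate and intensity) are function
parameters.  The defaults are the package's fixed analysis configuration.

## The PGLMM and its Gibbs sampler

One row per species: response y (a hearing index or the species-mean
spectral slope), fixed effects X (intercept; habitat dummy-coded with
forest = 0 as reference so the habitat coefficient is the other-minus-forest
contrast, flippable by flag; continuous covariates as given), phylogenetic
effect a, optional i.i.d. grouping effect u (presumed call function), and
residual e:

    y = Xβ + a + Z_u u + e
    a ~ N(0, σ²ₐ A),  u ~ N(0, σ²ᵤ I_q),  e ~ N(0, σ²ₑ I_n)

**A** is the phylogenetic correlation matrix: C_ij is the shared
root-to-MRCA path length of tips i and j (the Brownian-motion covariance up
to a scale), and A_ij = C_ij/√(C_ii·C_jj).  Normalising by the tip depths
rather than a single tree depth guarantees a unit diagonal for
non-ultrametric trees too; for ultrametric trees the two coincide.
Pruning a tree to the analysed species collapses degree-2 nodes and sums
their branch lengths, so patristic distances are preserved exactly.

**Priors.** N(0, 10¹⁰) on each fixed effect and inverse-Gamma with shape and
scale 0.001 on each variance (density ∝ x^(−α−1)e^(−β/x)) — a standard
weakly informative choice for comparative analyses.  Note this prior, while
near-flat on log σ², does shrink the phylogenetic variance slightly toward
zero in moderate samples; the residual variance absorbs the difference (see
Calibration below).

**Sampler.** All full conditionals are closed-form, so plain Gibbs:

* β: Gaussian, precision XᵀX/σ²ₑ + I/10¹⁰;
* a: sampled in the eigenbasis A = QΛQᵀ, where its full-conditional
  precision 1/σ²ₑ + 1/(σ²ₐλ_i) is diagonal — each sweep costs two n×n
  matrix-vector products and no per-iteration factorisation;
* u: Gaussian with diagonal precision (group counts)/σ²ₑ + 1/σ²ᵤ;
* each σ²: inverse-Gamma(α + q/2, β + quadratic form/2), where the
  quadratic form for σ²ₐ is aᵀA⁻¹a = Σᵢ ãᵢ²/λᵢ in the eigenbasis.

Chain c is driven by one `numpy` Generator seeded with `seed + c`; runs are
bit-reproducible.  Samples are retained after the burn-in at every thinning
interval, so retained-per-chain = floor((n_iter − burn_in)/thin); the
long-run configuration (11 M iterations, 100 k burn-in, thin 10 k, 3 chains)
retains 1090 draws per chain.  Three settings tiers are provided:
`long_run` (the full-length configuration), `test_scale` (55 k/5 k/50,
minutes) and `quick` (3.5 k/500/3, ~1000 retained draws in under a second at
n = 200) for simulation studies.  The sampler was validated against (a) the
closed-form conjugate posterior of Bayesian linear regression when the
phylogenetic effect is dropped, and (b) an exact 2-D grid evaluation of the
marginal posterior of (σ²ₐ, σ²ₑ) with β and a integrated out analytically;
both agree to within Monte-Carlo error.

**Summaries.** Posterior means pool all chains.  Intervals are 95% HPD
(shortest interval containing ⌈0.95N⌉ sorted samples); equal-tailed
quantile intervals are available by flag.  For fixed effects,
pMCMC = max(2·min(#>0, #<0)/N, 2/N), with zero-valued samples split evenly
between tails — invariant under positive rescaling and never below its 2/N
floor.  H² = σ²ₐ/(σ²ₐ+σ²ₑ) is computed per retained sample and summarised
like any parameter; the call-function variance σ²ᵤ is deliberately excluded
from the denominator, following the two-component definition of
phylogenetic heritability.

**Diagnostics.**

* Gelman–Rubin PSRF: √(((n−1)/n·W + B/n)/W), W the mean within-chain
  variance, B = n·var(chain means).
* ESS = n/(1 + 2Σρ_k) with FFT-based autocorrelations and Geyer
  initial-positive-sequence truncation (consecutive lag pairs added while
  their sum is positive); `lag1_autocorr` exposes ρ₁.
* Heidelberger–Welch: Cramér–von-Mises statistic of the standardised
  cumulative-sum (Brownian-bridge) process, with the long-run variance
  estimated as the spectral density at zero from an AIC-selected Yule–Walker
  AR fit to the second half of the chain; the leading 10% is discarded
  repeatedly (to at most 50%) until the test passes at α = 0.05.  The CvM
  CDF uses the classical four-term Bessel-function series.

## Synthetic data

The generators produce data with exactly the structure the analyses assume —
by design they are the well-specified case:

* **Trees**: pure-birth (Yule) simulation at unit rate starting from the
  root split, run one extra exponential waiting time after the n-th tip so
  terminal branches do not end at a birth event, then rescaled to unit
  root-to-tip height.  Ultrametric by construction, deterministic per seed.
* **Trait tables**: habitat i.i.d. Bernoulli(p_forest) or, in
  `phylo_threshold` mode, a Brownian trait thresholded at its median so
  habitat itself carries phylogenetic signal; a standard-normal covariate;
  a ~ N(0, σ²ₐA) via Cholesky; seven call-function categories with i.i.d.
  level effects; i.i.d. residual.  Defaults (n = 200, β_habitat = −5,
  β_covariate = 1, σ²ₐ = 3, σ²ₑ = 1, hence H² = 0.75) define the
  package's standard recovery conditions.
* **Audiograms**: threshold(f) = floor + curvature·log2(f/peak)² + noise, a
  U-shape in octaves around the best frequency, on an octave grid from
  0.125 to 64 kHz (defaults floor 10 dB, curvature 4 dB/octave²).
* **Calls**: harmonics of f₀ (default 500 Hz) with amplitudes following a
  straight source spectrum of `source_slope_db_per_khz` in dB vs kHz and
  seeded random phases, filtered through cascaded impulse-invariant
  two-pole resonators (unity DC gain) and peak-normalised to 0.9.  The
  default formant pattern places five resonances at odd multiples of
  1/10 of the generation Nyquist (2.205, 6.615, 11.025, 15.435, 19.845 kHz
  at 44.1 kHz; 600 Hz bandwidths) — the evenly spaced resonance pattern of a
  uniform tube.  Evenly tiled poles give an approximately flat spectral
  envelope, so the recovered slope reflects the source slope; the residual
  error is formant ripple plus the band-edge treatment of the highest
  partials, measured at < 0.1 dB/kHz bias over source slopes in [−8, 0].

What the generators do *not* emulate: measurement noise and study
heterogeneity in audiograms beyond i.i.d. Gaussian perturbation, time-varying
f₀/formant contours, amplitude modulation, background noise and reverberation
in recordings, habitat-dependent sound propagation, and correlated evolution
between habitat and covariates.  Passing tests therefore demonstrate
correctness of the estimators under the assumed model, not robustness to
real-data pathologies.

## Calibration findings and limitations

* With a fixed tree (the analysis setting: the phylogeny is a known input)
  95% HPD coverage over 100 trait-simulation replicates is 91–97% for every
  parameter, the pMCMC < 0.05 rule has type-I error ≈ 5% and power ≈ 100%
  against β_habitat = −5 at n = 200, and the average posterior-mean H² is
  within 0.03 of the true 0.75.
* When the tree itself is redrawn each replicate, coverage for σ²ₑ drops to
  ≈ 88%: posterior means stay unbiased, but the IG(0.001, 0.001) prior's
  mild shrinkage of σ²ₐ (compensated by σ²ₑ) plus tree-to-tree variation in
  how well the two variances separate makes fixed-truth coverage of
  variance-component intervals slightly sub-nominal.  Fixed-effect coverage
  is unaffected.
* Slope extraction assumes the call dominates the recording; no segmentation
  or denoising is performed (inputs are assumed pre-screened).  16-bit PCM
  storage adds a quantization floor that becomes visible for source slopes
  steeper than about −6 dB/kHz; synthetic calls are therefore written as
  32-bit float WAV by default.
* Simulation-study replicate counts (100) and the quick chain tier were
  chosen to keep the full calibration loop in a few CPU-minutes; the
  `test_scale` and `long_run` tiers reproduce the same numbers with more
  retained draws.
* Non-Gaussian responses, multi-response models, within-species repeats and
  tree uncertainty are out of scope.
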