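# Methods

`nanotrace` implements the data-reduction chain of a single-particle ICP-MS
(SP-ICP-MS) survey of metal-bearing nanoparticles in biological tissue, from
raw time-resolved detector counts to censored multi-location survey
statistics, together with a ground-truthed synthetic-data generator that makes
every stage testable without instrument data.

## Signal model

The detector reports one integer count per dwell interval (default
`dwell_time = 100 µs`, `acquisition_time = 45 s`, i.e. 450 000 dwells per
acquisition). Dissolved analyte and instrument background produce
Poisson-distributed counts with a slowly varying rate λ(t); a nanoparticle
that survives nebulization arrives as an ion cloud spanning a few dwells and
adds a transient burst of counts on top of the background.

The simulator realizes exactly this model:

* background: per-dwell rate `baseline_mean` plus an optional sinusoidal
  drift; one Poisson draw per dwell;
* particle arrivals: a homogeneous Poisson process with expectation
  `C_num · q · t_acq · η` (number concentration × uptake flow × acquisition
  time × transport efficiency). Coincident (overlapping) events are allowed
  and recorded in the ground truth;
* particle masses: diameters are lognormal (median diameter, geometric SD)
  and converted to element mass through the spherical-particle relation
  `m = f · (π/6) d³ ρ` with compound density ρ and element mass fraction f;
* per-event counts: total counts `S = m · b / (η · q · t_dwell)` (inverse of
  the quantification formula below) spread over a 3–7-dwell transient with
  triangular weights, then Poisson-realized together with the background.

The 3–7-dwell transient span is a configurable placeholder: at 100 µs dwell a
single ion cloud (~0.3–0.7 ms) spans several dwells, which is what makes
maximum-peak discrimination meaningful, but the true span distribution of a
given instrument must be measured, not assumed.

`deterministic=True` writes expected intensities instead of Poisson draws;
the noiseless chain then inverts exactly, which the unit tests exploit.

## Detection

1. **Baseline.** A centered rolling median (default window 1001 dwells
   ≈ 0.1 s: long against transients, short against drift) approximates the
   background trajectory. Edge windows shrink symmetrically, so the estimate
   is defined and centered at every dwell.
2. **Thresholding rate.** The Poisson rate used for thresholding is *not* the
   median itself: the median of Poisson counts is 0 whenever the rate is
   below ln 2 ≈ 0.69, which would collapse the threshold to 1 count and flood
   the detector with single-count false positives on clean, low-background
   channels. Instead the rate is a winsorized rolling mean over the same
   window — counts clipped at `median + 5·sqrt(median + 1)`, far enough into
   the Poisson tail to leave pure noise unbiased while capping the leverage
   of particle transients inside the window.
3. **Threshold.** For a false-positive budget of `fp_rate` spurious events
   per minute (default 1/min), the intensity threshold at local rate λ̂ is the
   smallest integer T with `P(X ≥ T | Poisson(λ̂)) ≤ fp_rate · t_dwell / 60`,
   i.e. at most `fp_rate` expected threshold exceedances per minute of
   dwells. λ̂ enters the tail probability as a real number; no rounding.
4. **Segmentation.** Candidate peaks are maximal runs of dwells strictly
   above the rolling-median baseline; runs separated by ≤ `gap_merge` dwells
   (default 2) are merged, which heals single-dwell dropouts inside a
   transient. A candidate becomes a particle event iff its maximum raw count
   reaches the threshold at its peak position.
5. **Integration.** `S_p = Σ max(counts − baseline, 0)` over the event span;
   the per-dwell clip prevents noise troughs inside an event from
   contributing negatively.

Measured behaviour on simulated particle-free noise (λ = 1 count/dwell,
10 minutes): 1.0 detected events per minute against the 1/min design budget.

## Calibration and quantification

* **Ionic response.** Ordinary least squares of mean counts per dwell against
  dissolved-standard concentration (0/20/200 µg/L, start- and end-of-day
  standards pooled) gives slope `b` (counts/dwell per µg/L) and intercept.
* **Transport efficiency.** Calibrated with a reference nanoparticle
  suspension of known size and mass concentration (60 nm Au at 1250 ng/L in
  the original campaign; a 60 nm Au sphere weighs 2.185 fg, so 1250 ng/L is
  5.72e8 particles/L). Two estimators:
  - *frequency*: `η = N_detected / (C_num,ref · q · t_acq)`;
  - *mass*: `η = m_ref · b / (S̄_p · q · t_dwell)` from the mean reference
    event integral.
  The frequency method is the default; the mass method serves as a
  cross-check (they agree within a few percent on simulated references).
  Both are biased low by event pile-up: at 1250 ng/L, η = 0.05 and 45 s of
  100 µs dwells, roughly 10% of dwell time is occupied and ~5% of events
  merge. Dilute references (≲2% occupancy) keep the bias below the
  statistical noise, matching the usual practice of diluting until pile-up is
  negligible. Replicate reference runs (e.g. day-bracketing measurements)
  should be pooled.
* **Event mass and size.** `m_p = S_p · η · q · t_dwell / b` (all masses in
  grams internally; µg↔g conversion happens at this one boundary), and the
  mass-equivalent spherical diameter `d = (6 (m_p/f) / (π ρ))^{1/3}` under an
  assumed composition — reported sizes are only as good as that assumption.
* **Concentrations.** Number concentration per litre of digest is
  `n_events / (η · q · t_acq)`; division by the dilution factor (grams of
  tissue per litre of digest, default 1 g/L) gives particles per gram of wet
  tissue; mass concentration analogously with `Σ m_p`.
* **Blanks and limits.** The mean of matching procedural blanks is
  subtracted, flooring at zero with a flag. Per day, the concentration LOD is
  blank mean + 3 SD (LOQ: + 10 SD); final concentration limits are means
  across days, while the mass-per-particle LOD converts each day's intensity
  threshold to mass and takes the *maximum* across days so false-negative
  rates stay comparable. Days with fewer than two blanks are skipped with a
  warning. The 3σ/10σ concentration formulas mirror the total-element
  convention; whether LOQ used 10σ in the original campaign is not stated,
  so the choice is documented here rather than asserted.

## Total element content

Full-digestion intensities convert through the same ionic calibration:
dry-weight concentration `(I − a)/b · final_mass / digest_mass`, multiplied
by the dry-weight fraction to a wet-weight basis (LODs are computed on the
dry basis and back-calculated the same way). The detection limit is 3× the
sample (n−1) standard deviation of the procedural blanks — twelve by
default, six for silver. Particle fractions
(`100 · particulate / total`) and per-element particle–total R² (squared
Pearson correlation) exclude censored values; any censored operand censors
the derived quantity.

## Survey statistics

Locations carry triplicate parallels; all summaries work on location means.
Per element: mean, min–max over the uncensored location means, and `%>Ld`,
the percentage of locations whose mean exceeds the detection limit.

Multivariate analyses (PCA, Ward clustering) standardize per-location mean
number concentrations to z-scores after dropping elements censored in more
than half the locations (no imputation by default; LOD/√2 substitution is
available but off). The default working scale is log10: environmental
concentrations here are lognormal over an order of magnitude or more, and on
the raw scale one or two hotspot locations dominate each column's variance,
obliterating group structure. `summarize` and censoring always stay on the
raw scale.

* **PCA** is the eigendecomposition of the standardized matrix's covariance
  (all components kept, so explained-variance fractions sum to 1 and loadings
  are orthonormal). Group centroids get 95% confidence ellipses from the
  within-group score covariance scaled by 1/n, with the χ²(2) quantile — a
  bivariate-normal confidence region of the *mean*, not a data ellipse.
* **Ward clustering** uses the minimal within-cluster sum-of-squares-increase
  criterion on Euclidean distances between the standardized rows. Heights are
  reported on the square-root scale (two singletons merge at their Euclidean
  distance, `sqrt(2 ΔSSQ)`); the two common conventions differ in heights but
  never in topology. The implementation is scipy's Ward linkage, verified in
  the tests against exhaustive enumeration of minimal-SSQ merges on small
  instances.

## What the synthetic survey does and does not emulate

The generator produces lognormal per-element location concentrations
(default GSD 3 across locations, 1.2 between parallels), location classes in
the surveyed proportions (47 farm : 18 anthropogenic : 4 natural of 69),
seasons from uniform sampling months, and censoring at a configurable
quantile of the effect-free distribution. Class effects act through a graded
per-location impact intensity (`effect^w`, `w ~ LN(0, ln 2)`) shared across
all elements the class elevates: hotspots differ in degree, and elements
from a shared source co-vary within a location. Without that shared-source
structure a single-element multiplicative effect is unrecoverable by PCA
after z-scoring — the variance advantage is normalized away and the signal
disperses across near-degenerate components — so a green PCA recovery test
establishes recovery of a co-varying contamination axis, not of an isolated
element shift. The generator does not emulate inter-element natural
correlations, spatial autocorrelation along the coastline, shell-length
covariance, or detector artifacts (dead time, dual counting modes, flicker
noise).

## Numerical choices and degenerate inputs

* Thresholds are exact integer solutions of the Poisson tail condition
  (scipy quantile, then nudged to the boundary); thresholds are
  non-decreasing in the rate, which the detector exploits to prefilter
  candidates at the minimum rate.
* Transport efficiencies an epsilon above 1 (≤ 1 + 1e-9) are clamped to 1;
  larger values are rejected as unphysical.
* Blank subtraction floors at zero and flags; zero detected reference
  particles raise a distinct `NoParticlesError` rather than returning a
  bogus calibration.
* Zero-variance or fully censored columns are dropped (with a warning)
  before standardization; duplicate row labels are rejected in clustering;
  rank-limited PCA (more elements than locations) is allowed but flagged.
* Event tables round-trip losslessly through CSV (`%.17g`,
  `float_precision="round_trip"`).

## Known limitations

* No deconvolution of coincident particle events; number concentrations are
  biased low at high particle loads (dilution is the remedy).
* No dissolved-fraction quantification from the trace baseline, and no upper
  size limit modelling (incomplete ionization of large particles).
* The season assignment (DJF/MAM/JJA/SON from the sampling month) and the
  survey generator's default effect sizes are package choices, stated here
  because no external convention fixes them.
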