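# Methods

This document specifies the algorithms, parameter conventions and numerical
choices implemented in `eihurst`. Units are stated with every quantity.

## 1. Fractal simulation (`eihurst.fractal`)

Fractional Gaussian noise (fGn) with Hurst exponent H ∈ (0, 1), standard
deviation σ > 0 and length N ≥ 8 is simulated *exactly* by circulant embedding
(Davies–Harte). The target autocovariance is

    γ(k) = (σ²/2) (|k−1|^{2H} − 2|k|^{2H} + (k+1)^{2H}).

The first row of the circulant embedding has length m, the smallest power of
two ≥ 2(N−1); its eigenvalues are obtained by FFT. If any eigenvalue is
negative beyond numerical round-off (relative tolerance 1e-8 of the largest
eigenvalue), the embedding is invalid and the simulator raises an error
advising to double the embedding grid — eigenvalues are never clipped, which
would silently bias the covariance. Sample paths are synthesised from
Hermitian-symmetric complex Gaussian weights so that each returned series has
exactly the target covariance. fBm is the cumulative sum of fGn with the same
H. Batch simulation shares one eigenvalue computation across series.

## 2. Spectral Hurst estimation (`eihurst.hurst`)

The power spectral density is estimated with Welch's method
(`scipy.signal.welch`): Hann window, constant detrending, one-sided density
scaling. For a series of N samples and `n_segments` requested segments at
`overlap_fraction` overlap (defaults 8 and 0.5), the segment length is
L = ⌊2N/(n_segments+1)⌋ and the overlap ⌊L·overlap_fraction⌋. The spectral
index β is minus the OLS slope of log₁₀ power against log₁₀ frequency over all
bins with f > 0 and power > 0 (≥ 3 bins required), and

    H = (1 + β)/2.

Classification follows the extended-Hurst convention: H ∈ (0, 1) → fGn,
H ∈ [1, 2) → fBm (H = 1 assigned to fBm), otherwise out-of-range. Constant
series and series too short for the requested segmentation raise errors that
name the minimum usable length.

`hurst_map` applies the estimator voxelwise to a 4-D volume (≥ 64 frames). The
Welch PSDs of all candidate voxels are computed in one vectorised call and the
log–log slope by a centred closed-form OLS; voxels with non-positive power
bins fall back to a per-voxel fit. Invalid voxels (constant, non-finite, or
failed fits) carry the sentinel value 0 with `valid=False`. `roi_mean_hurst`
averages H over the intersection of a tissue mask and the MRS-voxel mask,
using valid voxels only, and errors on empty or all-invalid intersections.
Maps save to NIfTI with a JSON sidecar recording the estimation parameters.

## 3. Multi-echo T2\* (`eihurst.multiecho`)

For echo signals s_i at echo times TE_i (ms), the monoexponential model
s_i = S₀·exp(−TE_i/T2\*) is fitted per voxel on the time-averaged signal.
Non-positive echoes are dropped; fewer than two reliable echoes is an error.
The exact log-linear solution initialises a Levenberg-style refinement
(`scipy.optimize.least_squares`), skipped when the log-linear fit is already
numerically exact (SSE < 1e-14·Σs²). T2\* is clamped to the physiological
range (1, 500) ms. Optimal combination weights the echoes by

    w_i ∝ TE_i · exp(−TE_i / T2*),   Σ w_i = 1,

the matched-filter weighting that maximises BOLD contrast-to-noise under the
monoexponential decay model; voxels without a valid T2\* use the unweighted
echo mean.

## 4. Quality control (`eihurst.qc`)

Framewise displacement at frame t (mm) is the sum of absolute backward
differences of the three translations (mm) plus the head radius (50 mm) times
the sum of absolute differences of the three rotations (rad); the first frame
is 0 and the summary is the mean over frames 2…N. Subjects are excluded when
mean FD strictly exceeds 0.15 mm or when either spectroscopy linewidth (FWHM in Hz,
reported in the cohort table per sequence) strictly exceeds 10; FD
exclusions take precedence in the reported reason. Dice overlap of two masks
is 2|A∩B|/(|A|+|B|), defined as 1 when both are empty. The consensus MRS mask
keeps voxels present in a strict majority of subjects.

## 5. Cohort statistics (`eihurst.cohort`)

The E:I proxy is the ratio of glutamate+glutamine to GABA concentrations
(mM/mM, dimensionless). Condition contrasts use the paired t-test (movie −
rest by default) and associations the Pearson correlation, both with exact
closed-form small-sample p-values; degenerate inputs (zero-variance
differences, constant vectors) raise.

The core model is a random-intercept linear mixed model fitted by REML
(`statsmodels.MixedLM`):

    H ~ 1 + EI + Condition[rest] + meanFD + FWHM_sLASER + FWHM_MEGA
          + Δf_sLASER + Δf_MEGA + (1 | subject)

with movie as the condition reference level. Wald t statistics use

    df = n_obs − n_fixed − n_subjects + 1,

a between–within style allocation appropriate for two observations per
subject; p-values and 95% CIs come from the t distribution on that df. The
optimiser falls back through lbfgs → powell → nelder-mead when a boundary fit
makes a step numerically singular; an informative error reports the trace if
all fail. Rank-deficient designs are rejected with the collinear columns
named. Fit quality is summarised by Nakagawa marginal/conditional R²
(fixed-effects variance computed with ddof = 1) and predictor VIFs (+∞, with a
warning, under perfect collinearity).

Power is estimated by simulate-and-refit: the generative cohort specification
is replicated with the E:I slope set to the candidate effect size, each
replicate refitted, and power is the fraction of replicates with p < α for
the E:I term (default α = 0.05, 1000 replicates), with an exact
Clopper–Pearson 95% CI on that fraction.

A note on REML: fixed-effect estimates are *not* exactly invariant to balanced
duplication of the data — the REML determinant correction does not scale with
n, shifting the variance-ratio estimate and hence the GLS coefficients at
O(1/n) (≈1e-3 at n = 12 → 24 subjects). When the generative random-intercept
variance is zero, the REML estimate hits the boundary (and the fit equals OLS
exactly) only about half the time; otherwise a small interior variance is the
genuine REML optimum. The test suite checks both behaviours as such.

## 6. Synthetic generation (`eihurst.synthgen`)

`CohortSpec` defines the generative cohort model. Metabolite concentrations
(mM) are truncated-normal draws around condition-specific means with a shared
within-subject component (fraction 0.5 of the variance, giving a
within-subject correlation of ≈ 0.25 across conditions) while preserving the
marginal SDs. The Hurst outcome is

    H = 1.05 − 0.07·1[rest] + β_EI·EI + u_subject + ε,

u ~ N(0, 0.10²), ε ~ N(0, 0.06²), β_EI = 0 by default (no true E:I effect
unless requested). The intercept and condition effect place the condition
means near 0.98 (rest) and 1.05 (movie); the variance components give a
plausible intra-class correlation of ≈ 0.74. QC covariates are uniform draws:
mean FD ∈ (0.05, 0.20) mm — deliberately straddling the 0.15 mm threshold so
exclusions are exercised — FWHM ∈ (6, 11) Hz and frequency shift ∈ (−2, 2) Hz
per sequence.

`PhantomSpec` defines 4-D multi-echo phantoms: a 16³ grid (a package-chosen
size that keeps runtimes in seconds while leaving ≥ 4-voxel tissue slabs) with
CSF/WM/GM slabs along x, tissue Hurst exponents 0.5/0.7/0.9, tissue T2\* of
200/45/50 ms, echo times 12.2/35.352/58.504 ms, 480 frames at 1.5 s, baseline
signal 100 with fGn fluctuations of amplitude 5 and white measurement noise
SD 0.5. The MRS voxel is a 6³ cube centred on the GM slab with ±1 voxel
placement jitter; the base corner is clamped so the jittered cube stays
in-grid whenever geometrically feasible, and infeasible configurations raise.
Motion traces are small random walks (0.02 mm steps; rotations scaled by
1/50), yielding mean FD near 0.1 mm. `write_bids_layout` materialises a
BIDS-like directory of NIfTI echoes and motion TSVs at runtime.

## 7. Pipeline (`eihurst.pipeline`)

`run_pipeline(RunConfig)` chains: cohort-table generation → per-subject,
per-condition phantom simulation (the GM Hurst target shifted by the cohort's
rest effect plus a per-subject offset of SD 0.02, clipped to (0.05, 0.95)) →
T2\* fitting and optimal combination → voxelwise Hurst map → GM∩MRS ROI mean →
framewise displacement → consensus-mask Dice → table assembly (imaging-derived
H and FD replace the generative draws; metabolites and spectral QC come from
the table) → exclusions → paired tests, correlations and the mixed model →
optional power stage. All randomness derives from one seed through
`SeedSequence` substreams, so runs are exactly reproducible. A model stage
with too few retained subjects is reported as insufficient data instead of
aborting. With `output_root` set, the pipeline writes `report.json` and the
assembled `cohort.tsv`.

## Limitations

- The generators are calibration instruments, not biophysical models: no
  haemodynamic response, physiological noise, spatial autocorrelation beyond
  tissue slabs, or field-map artefacts.
- The spectral estimator fits one global slope; no multifractal or
  scale-range-restricted variants are provided.
- The mixed model supports exactly the study design (random intercept, two
  conditions per subject); crossed or nested random effects are out of scope.
- T2\* fitting assumes monoexponential decay and ignores S₀ fluctuations
  between echoes within a frame.
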