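# Methods

This note documents the models, numerical choices, and known limitations of
`effconn`. It covers what each stage computes, which parameters matter and
why their defaults are what they are, what the synthetic-data generator does
and does not emulate, and where the design was genuinely open.

## Generative model and the synthetic study

Each subject-session is a stable VAR(p) process
`x_t = sum_k A_k x_{t-k} + e_t` with Gaussian innovations that are
independent across nodes (diagonal Σ). The diagonal Σ choice is deliberate:
GPDC weights edges by per-node innovation standard deviations, and a
node-independent noise model keeps those weights interpretable. Stability is
enforced as spectral radius of the companion matrix < 1; unstable graphs are
rejected with the measured radius in the error message.

The default study mirrors a two-group, two-session clinical design:

| parameter | default | rationale |
|---|---|---|
| groups | 21 patients / 19 controls | typical small clinical cohort |
| sessions | before / after | pre/post intervention |
| timepoints | 200 per session (TR = 2 s, ~6.7 min) | common resting-run length |
| network graph | 6 nodes (SMN, ECN, SN, VN, RFPN, DMN), VAR(1) | six canonical resting networks |
| self-coupling | 0.6 | concentrates spectral power below ~0.1 Hz at TR 2 s |
| designated edge | SMN → DMN, weight 0.35 | the edge whose group/session structure is planted |
| patient deficit | ×0.3 at baseline | clearly detectable at n ≈ 20; no published effect size exists for this contrast, so this is a calibration choice |
| training gain | ×3.0 in patients post | restores the edge to 0.9× base |
| subject factor | lognormal, σ = 0.2, persistent across sessions | between-subject strength variation that the clinical link rides on |
| clinical link | score = intercept + slope × true band-averaged GPDC + noise | RP: 20 + 150·s (SD 10); BP: 40 + 100·s (SD 10), on a 0–100 scale |
| motion outliers | 5% of frames, one contiguous burst | a single movement event; FD/DVARS pushed past 0.5 mm / 1.5 |
| burn-in | 500 samples | removes initial-condition transients |

Hemodynamic convolution (canonical double-gamma HRF, peak 6 s, undershoot
16 s at 1/6 amplitude) and voxel rendering (Gaussian blob maps on a
12×14×12 grid plus white noise) are available but off by default: the
causality stages operate on network time courses, and hemodynamic smoothing
deliberately confounds VAR recovery, so it is opt-in for tests that study it.

What the generator does **not** emulate: scanner drift and physiological
noise spectra, spatially correlated noise, motion-induced spatial
displacement, hemodynamic variability across regions, non-Gaussian
innovations, and inter-subject anatomical variability. Passing tests
therefore demonstrate correctness of the estimators and calibration of the
inference under the stated model — not robustness to every artifact of real
fMRI.

## Preprocessing

- **Band-pass 0.01–0.1 Hz**: zero-phase forward–backward Butterworth of
  order 4 (`scipy.signal.sosfiltfilt`), the standard realization in
  resting-state pipelines. Output is demeaned (finite-record edge effects
  leave a tiny residual mean). Repeated filtering is only idempotent for
  passband content: a second pass re-attenuates transition-band energy, so
  for broadband input the twice-vs-once difference can reach tens of percent
  of signal SD. Bands at or above Nyquist are rejected with the Nyquist
  frequency named.
- **CompCor**: top-k (default 5, common aCompCor practice) principal
  component time courses of the variance-normalized noise-compartment
  series; unit variance, mutually orthogonal.
- **Confound regression**: per-channel least-squares residualization on
  [intercept, regressors]; collinear columns are dropped with a warning.
- **Motion censoring**: a frame is an outlier iff FD > 0.5 mm or
  standardized DVARS > 1.5, both strict inequalities ("exceeds" a
  threshold). Frames are flagged, not deleted: the VAR stage fits on the
  longest contiguous uncensored run, because autoregression needs contiguous
  samples. Sessions whose run is shorter than 10·p·N samples are excluded
  with a logged reason.

Pipeline order is ICA → band-pass → GCA; the filter is applied to network
time courses, not voxel data, and the order is exposed in configuration.

## MVAR, AIC, GPDC

- **Estimation**: per-equation OLS on lagged regressors plus intercept;
  residual covariance uses the small-sample divisor T − p − Np − 1. Channels
  are z-scored before fitting by default so the σ̂ weighting in GPDC is
  comparable across networks. A singular Gram matrix triggers a ridge
  fallback with jitter 1e-8, logged.
- **Order selection**: AIC(p) = ln det Σ̂_p + 2pN²/T_eff (the multivariate
  form), all candidates fitted on the common sample window implied by p_max;
  ties break to the smallest order. The pipeline default caps the search at
  p_max = 2: with 200 frames, six channels, and the 10·p·N run rule, higher
  orders are not identifiable — band-passed series otherwise drive AIC to
  whatever cap is set, since filtering installs long autoregressive memory.
- **GPDC**: computed directly from Ā(f) = I − Σ_k A_k e^(−i2πfk) on a grid
  of 129 evenly spaced frequencies on [0, Nyquist] — fine enough that
  band-averaging error is negligible for smooth spectra. Direction
  convention everywhere, including file headers: `values[i, j]` is source j
  (column) → target i (row). Edge strength is the inclusive mean of
  |π_ij(f)| over grid points in [0.01, 0.1] Hz (band-averaging rather than a
  single-frequency readout; the band is configurable).
- **Surrogate detection**: per-subject edge detection compares observed
  band-averaged GPDC with phase-randomized surrogates (independent phases
  per channel, amplitude spectra preserved, Nyquist bin kept real). The
  p-value (1 + #surrogates ≥ observed)/(1 + n_surrogates) is exact under
  exchangeability; 99 surrogates at α = 0.05 give a 5% null rate. This
  procedure is this package's explicit, documented choice for "where
  causality is found" per subject; published pipelines often leave that
  primitive unspecified.

## Group ICA

Component count comes from the classical MDL eigenvalue criterion
(arithmetic/geometric mean likelihood plus a q(2m−q)·ln(T)/2 penalty) on the
plain sample covariance with the i.i.d. assumption; non-positive eigenvalues
are floored at 1e-12 with a warning. MDL behaves well when observations
(voxels) comfortably exceed channels (timepoints); heavily rank-deficient
regimes push it toward overestimation.

Subject data are voxel-mean-centered and scaled by one global SD per subject
(voxel-wise unit variance would inflate pure-noise voxels to signal scale),
temporally concatenated, PCA-reduced, and unmixed with FastICA. Stability
is handled by multi-restart best-run selection — the restart with the
highest mean best-match |r| against all other restarts wins — a desk-scale
substitute for full bootstrap-based stability analysis, which is out of
scope. Back-reconstruction is dual regression (maps → time courses →
subject maps), chosen over GICA-style back-projection for its simplicity
and well-characterized behavior. Maps are z-scored by their own mean/SD so
template goodness-of-fit scores are comparable.

Network labeling: goodness of fit = mean map value inside a binary template
minus mean outside; assignment is greedy by descending score with each
component used once and ties broken toward the lower component index. A
non-positive best score is flagged as dubious. Templates are required
inputs; the package ships only synthetic ones.

## Voxelwise map statistics

The repeated-measures analysis is decomposed into its two estimable
contrasts: a paired t of (after − before) across subjects (condition
effect) and a pooled-variance two-sample t on per-subject differences,
patients minus controls (interaction effect). Zero-variance voxels get
t = 0 and are masked. Cluster inference is nonparametric: voxels above the
two-tailed t quantile at p = 0.005 form clusters under 26-connectivity;
the null distribution of the maximal cluster extent comes from sign
flipping (condition) or group-label permutation (interaction); corrected
p = (1 + #null ≥ observed)/(1 + n_perm), significant below 0.05. Extent
(voxel count) is the cluster statistic and the threshold is two-tailed
because both directions of change are of interest. Sign-flip permutations
exploit the invariance of per-subject sums of squares, so all permuted t
maps are computed in one matrix product.

## Edge statistics and correlation

Self-edges are excluded everywhere (GPDC self-terms reflect autoregression,
not inter-network influence). Each test family — one-sample per cell,
between-group per session, paired per group — is FDR-corrected with
Benjamini–Hochberg across its N(N−1) directed off-diagonal edges. Two-sample
tests default to pooled variance (Student) with Welch available by flag.
All tests are two-tailed. Zero-variance edges with nonzero mean are treated
as degenerate certainty (p = smallest positive float); with zero mean as a
perfect null (p = 1); both logged.

Clinical correlation is Pearson with the exact t-based p (df = n − 2),
reported with r² and the fitted line. "Levels" mode correlates one
group × session cell; "differences" mode correlates per-subject
(after − before) changes in both variables. One-sample GPDC tests against
zero are never null (GPDC ≥ 0), so null-calibration checks of that family
use symmetric zero-mean synthetic edge values instead.

## Problem sizes used in the checks

The automated checks run at deliberately desk-scale sizes chosen to give
stable Monte-Carlo estimates: 50 replicate studies for pattern recovery and
FDR calibration, 200 null simulations × 500 permutations for cluster FWER,
100 seeds for AIC order recovery, 50 subjects × 99 surrogates for detection
calibration, 1000 simulations for correlation null rates, and six subjects
on a 12×14×12 grid for ICA recovery. Monte-Carlo tolerances are two
standard errors of the corresponding binomial rate.

## Known limitations

- GPDC quantifies directed influence within the fitted VAR; it cannot
  distinguish direct from relayed influence through an unmodeled
  intermediary, and hemodynamic deconvolution is not attempted.
- Band-pass filtering before VAR fitting installs long memory; fitted
  coefficients then describe the filtered process, and order selection
  saturates at the cap. Comparisons remain valid because all groups and
  sessions pass through the identical filter.
- The permutation cluster test is slightly conservative at these grid sizes
  (discrete extents, the +1 p-value convention).
- The one-sample edge test is a test of GPDC ≠ 0 and is expected to reject
  broadly; it mirrors the descriptive single-group maps of this study
  design rather than a substantive null hypothesis.
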