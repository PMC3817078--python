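# Methods

## The statistic

Regional homogeneity (ReHo) quantifies how synchronized a voxel's BOLD time
course is with its immediate neighborhood.  For a cluster of k voxel time
series of length n, rank each series over time (midranks on ties) and let
R_i be the rank sum of time point i across the k series.  Kendall's
coefficient of concordance is

    W = Σ_i (R_i − R̄)² / [ (1/12) k² (n³ − n) ],     R̄ = (n + 1) k / 2,

which is 1 under perfect concordance and has expectation 1/k under
independence (exactly, for any tie-free independent series — the row-sum
variance of a single ranking is a constant).  The default cluster is a voxel
plus its 26 face/edge/corner neighbors (k = 27); 7- and 19-voxel variants
are available.  No tie-correction term enters the denominator; ties are
handled by midranks upstream, accepting a slight downward bias of W under
ties.

At mask boundaries the cluster shrinks to its in-mask subset and the actual
series count is used (and recorded per voxel as `k_used`).  The alternative
— zeroing every boundary voxel — discards cortex at mask edges; the shrink
policy keeps it, at the cost of a boundary elevation of the null level
(E[W] = 1/k rises as k falls).  Normalization divides each in-mask W by the
mask-mean W over voxels with `k_used ≥ 2` (degenerate zeros must not deflate
the mean), after which maps are smoothed with a separable Gaussian kernel,
σ_axis = FWHM / (2√(2 ln 2)) / voxel_size.  Smoothing uses edge replication:
zero padding bleeds mass out of small grids and violates mean preservation
at the percent level.

## Temporal preprocessing

Fixed order: discard the first `n_discard` volumes (default 10; a 240-volume
run enters the statistic with n = 230), per-voxel linear detrend, then an
ideal rectangular band-pass that keeps DFT bins with low ≤ f ≤ high
(inclusive edges; defaults 0.01–0.08 Hz) and zeroes all others, including DC
when low > 0.  The filter is linear, idempotent and power-non-increasing.
Note that an off-bin stopband component is attenuated, not annihilated:
spectral leakage into the kept band can retain a nontrivial fraction of a
very-low-frequency sinusoid's RMS (e.g. ~17% for 0.005 Hz at n = 230,
TR = 2 s); only on-bin components are removed exactly.

Head-motion screening consumes tabulated per-subject maxima and excludes a
subject when translation exceeds `motion_limit_mm` (default 1.0 mm) **or**
rotation exceeds `motion_limit_deg` (default 1.0°); the boundary itself is
retained (strict inequality).  The package does not estimate motion.

## Group inference

Per voxel, OLS of y = b₀ + b₁·group + covariates (patient = 1, control = 0;
covariates mean-centered; defaults: motion shift and rotation).  The
statistic is t = b₁ / se(b₁).  Degrees of freedom are N − rank(X) — equal to
N − 2 − p for any non-degenerate design — so a degenerate covariate column
(e.g. identically zero) changes neither t nor df; designs are rejected only
when the group column itself is collinear with the intercept/covariates.
Testing is two-sided throughout.  Voxels with |t| above the two-tailed
critical value at `voxel_p` (default 0.01) are labeled into connected
components separately per sign (default connectivity 18; 6 and 26
available), so clusters of opposite sign never merge.

## Monte-Carlo cluster-extent correction

Each simulation fills the mask bounding box (padded by the kernel radius)
with i.i.d. standard normal noise, smooths it at the chosen FWHM, restricts
to the mask, re-standardizes to unit variance within the mask (smoothing
shrinks variance and would otherwise bias the voxel threshold), thresholds
two-sided at the Gaussian quantile for `voxel_p`, and records the maximum
cluster extent across both signs.  The corrected minimum extent at level α
is the smallest c with P̂(max extent ≥ c) ≤ α; below the simulation
resolution 1/n_sims the threshold is the observed maximum + 1, with a
warning.  Results are deterministic for a fixed seed.

**Which FWHM to simulate.**  Two modes exist.  `smoothness: nominal`
(default) uses the configured analysis kernel, mirroring how such
corrections are conventionally parameterized.  `smoothness: estimated`
measures the per-axis smoothness of the within-group residual maps from
their lag-1 spatial autocorrelation under a Gaussian-shaped ACF, converted
to the kernel-equivalent FWHM (σ_kernel = σ_ACF/√2, since smoothing white
noise with kernel σ yields an ACF with σ√2).  ReHo maps carry intrinsic
smoothness beyond the applied kernel — overlapping 27-voxel neighborhoods
correlate adjacent W values, and the measured total is ~10.4 mm for an 8-mm
kernel on the default synthetic cohort — so the nominal mode under-sizes the
extent threshold and inflates cluster-level FWER.  The end-to-end validation
studies and the reproduction script therefore run with `estimated`; it is
the recommended setting whenever the statistic image is smoother than its
applied kernel.

## ROI statistics

Cluster-level analyses on the surviving clusters: per-subject mean ReHo over
each cluster; Pearson correlations (two-tailed p via the t transform,
n − 2 df) between ROI means and behavioral variables, gated by Bonferroni at
α / family with family = number of ROIs per variable; the gray-matter index
(ROI GM volume / whole-brain GM volume, continuous probability maps summed
× voxel volume, optional binarization at 0.5); an exact-df ANCOVA F for the
group term in y ~ 1 + group + gm_index with (1, N − 3) df (degenerate fits
— constant y, covariate explaining y exactly — report F = 0); partial
correlations as residual correlations after regressing both variables on
[1, z], p with n − 3 df (a variable exactly explained by z reports r = 0);
and a mean-signal map averaging one raw volume (default the twentieth,
index 19) across subjects as a signal-coverage sanity check.

## The synthetic cohort

The generator emulates a two-group resting-state case-control study and is
the package's ground-truth instrument.  Within a region of coupling ρ every
voxel's series is √ρ·s(t) + √(1−ρ)·ε_j(t) with s, ε white unit Gaussians,
so any voxel pair correlates at ρ and a k-cluster's expected W has the
closed form ((k−1)·r_s + 1)/k with r_s = (6/π)·asin(ρ/2).  A random-slope
linear drift and a 0.15 Hz sinusoid are added per subject; detrending and
the band-pass remove both exactly.  Defaults (the simulated study
conditions): 2×30 subjects, 24³ grid at 3 mm, 240 volumes, TR 2 s; two
planted 4³-voxel deficit ROIs (~1% of the volume — the scale of a focal
deficit against whole-brain gray matter) at ρ = 0.35 in controls vs 0.22 in
patients over a 0.10 background, with subject-level coherence jitter
(SD 0.06).  These values land the recovered peak |t| in the single digits,
the regime of a strong but realistic group difference.

Behavioral scores are linear in each subject's realized ROI coherence plus
noise calibrated to a target correlation, then mapped to the instrument's
scale (impulsivity subscales and total on their integer ranges; the total is
floored at the largest subscale).  Default planted correlations: total
impulsivity vs the first ROI −0.46, attentional subscale vs the second
−0.58, duration of use −0.41 and age of first use +0.42 (patients); motor
and non-planning subscales are unplanted noise.  Gray-matter probability
maps get a multiplicative patient deficit (default 15%) in exactly one ROI,
with a 0.10 within-group SD so the GM group separation sits near t ≈ −5 at
n = 2×30.  With `gm_mediates: true` the same per-subject GM factor drives
the coherence deficit, making the functional group difference fully
structure-mediated — the scenario in which GM-covariate control should
collapse the group F.  Head motion enters only as tabulated summaries
(|N(0.123, 0.016)| mm, |N(0.0017, 0.0006)|°).

What the generator does **not** emulate: hemodynamic response shapes,
physiological noise spectra, image-level motion corruption, spatial
inhomogeneity of noise, or anatomical geometry.  Passing validation
therefore demonstrates the statistical machinery is correct and calibrated
under the stated coherence model — not robustness to the full complexity of
real fMRI.

A note on normalization at desk scale: dividing by the whole-brain mean W
couples focal deficits to the background.  If the planted deficit occupies
an unrealistically large fraction of the volume (a few percent) with a large
ΔW, the patients' global mean drops enough that background voxels acquire a
diffuse spurious *positive* group difference.  At the realistic default
scale (~1% of volume) the shift is far below the between-subject noise
floor.  This is a genuine property of mean-normalized statistics, worth
remembering when interpreting small-field-of-view analyses.

## Validation studies and problem sizes

The self-validation suite (also run by `scripts/acceptance.py`) uses
desk-scale problem sizes chosen for a single CPU: null W calibration on a
20³ grid at n = 230 over 6 replicates; FWER of the extent correction over
200 null cohorts (20³ grid, 2×12 subjects, 6-mm smoothing) against one
shared 1000-simulation null distribution (the threshold depends only on
mask, FWHM and voxel p, so per-cohort re-simulation adds noise but no
information), with per-subject null maps drawn as smoothed Gaussian noise so
the t-map has exactly the smoothness the null assumes; and planted-truth
recovery over 10 replicate default cohorts with 300-simulation thresholds.
For the stray-cluster check, "planted tissue" is the ROI dilated by 3 voxels:
the 8-mm kernel legitimately spreads a planted effect about one FWHM past
the ROI boundary, so halo voxels carry genuine signal.

## Known limitations

- The ideal band-pass assumes stationarity and leaks off-bin stopband
  components (see above); no windowing is applied.
- The extent correction assumes Gaussian-shaped spatial ACF; heavy-tailed
  or anisotropic smoothness beyond the per-axis estimate is not modeled.
- The smoothness estimator needs several subjects for a stable residual
  pool; with very few maps the estimate is noisy.
- Spatial normalization, segmentation and motion estimation are out of
  scope: images are consumed in their native grid, GM maps and motion
  summaries are inputs.
- Under heavy ties (quantized data) W is biased downward relative to a
  tie-corrected statistic, by construction.
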