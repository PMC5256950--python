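# Methods

`nanoflim` re-implements, as a tested library, the quantitative analyses
used to characterise plasma-membrane receptor nanoclusters in live plant
roots: nanocluster detection in surface-illumination (TIRF/VAEM) images,
receptors-per-cluster estimation, per-pixel TCSPC lifetime fitting with
FRET and interacting-pixel statistics, FRAP mobility analysis, and
photobleaching step counting.  Every stage has a matched synthetic-data
generator so parameter recovery can be verified against ground truth.

## Membrane image model and cluster detection

The generator places nanocluster centres by a homogeneous spatial Poisson
process (default 0.55 clusters/µm², the density measured for a
near-endogenous receptor line after ligand depletion) on a 130 nm pixel
grid.  Each cluster holds a fixed number of receptors (default 6), each
contributing a 2-D Gaussian PSF of σ = 110 nm ≈ 0.21·λ_em/NA for GFP
emission at NA 1.49, integrated exactly over pixels via error functions.
Receptors carry an optional maturation probability (default 1; unmatured
fluorophores are dark).  Poisson shot noise, linear camera gain and
Gaussian read noise are applied per frame; the emCCD excess-noise factor is
omitted because detection is threshold-driven, not noise-model-critical.
Clusters have no spatial extent beyond the PSF — the observed 300–500 nm
diameters are upper bounds set by diffraction, and a static snapshot
suffices (no endocytosis dynamics, no cell-wall autofluorescence).

Detection follows the standard particle-analysis chain: rolling-ball
background subtraction (radius 50 px), subtraction of a 2 µm (σ) Gaussian
blur (a band-pass that flattens residual background; negatives are clipped
before thresholding), a fixed threshold of 80 a.u. on the camera intensity
scale, and 8-connected component labelling with a 2 px minimum area that
removes single stray pixels.  Whether rolling ball precedes or replaces
the blur-subtract step is not uniquely determined by the original
workflow; here rolling ball runs first and either step can be disabled.
Analysis can be restricted to a user-supplied ROI polygon (cells were
outlined manually in the original workflow; no automatic segmentation is
attempted).  Densities are clusters per µm² of analysed ROI; the
receptors-per-cluster estimate is the ratio of receptor surface density to
nanocluster density, rounded to the nearest integer, with first-order SEM
propagation.

Two caveats that the tests make explicit: (i) clusters closer than roughly
the spot diameter merge into one component, so the detected density
underestimates the true density by ≈13 % at 0.55/µm² (and more at higher
density).  This bias is intrinsic to diffraction-limited particle counting
— the published densities carry it too — so the recovery test checks the
true density only to ±25 %, while a paired-simulation property verifies
that noise adds no bias beyond the merging itself (detection on a noisy
frame matches detection on the noiseless expected image).  (ii) The
threshold monotonicity property (raising the threshold never increases the
count) holds for isolated unimodal spots; overlapping spots can split at
high thresholds.

## TCSPC decay model, fitting and filters

Pixels are photon-arrival histograms with 256 channels spanning one
repetition period of a 40 MHz pulsed laser (channel width 25 ns/256 ≈
97.7 ps).  The generator labels a fraction `f_interacting` of pixels as
FRET pixels (donor quenched to τ_DA, default below), draws per-pixel
photon totals from a Poisson around the mean (default 3000), samples
arrival times as exponential(τ) plus Gaussian IRF jitter (default FWHM
300 ps, centred on channel 10), wraps them at the period, and histograms.
A background fraction (default 2 %) arrives uniformly in time.  Photon
conservation is exact: each pixel's channel sum equals its drawn total.

The fitted model is the same physical process: one or two exponentials
convolved with the IRF and wrapped at the period.  For the parametric
Gaussian IRF the convolution is the exponentially modified Gaussian, and
channel contents are computed exactly as differences of its closed-form
CDF (wrap handled by summing four periods), so the fit model is the exact
expectation of the generative process.  A measured IRF histogram is
supported through circular convolution on a 4× oversampled grid, which
keeps the discretization bias of the convolution below the statistical
precision of a per-pixel fit.

Fitting maximises the Poisson likelihood (the correct TCSPC noise model);
the per-pixel amplitude is profiled out by the total-count constraint,
which is the Poisson maximum-likelihood solution, leaving lifetime(s) and
the flat-background fraction as free parameters (an optional free IRF
shift is available; it defaults to 0 because the synthetic IRF is exactly
known).  A Neyman weighted-least-squares objective is available for parity
with the commercial software the field commonly uses.  Model selection is
conservative: the bi-exponential model is fitted only when the mono fit's
reduced χ² reaches 2, and kept only if it improves χ²; the per-pixel
lifetime of a bi fit is the amplitude-weighted mean.

Reduced χ² is reported in two conventions.  The Neyman statistic (weights
1/max(n,1)) matches the original analysis software and drives the
acceptance filter (χ² < 2), but at ~3000 photons over 256 channels more
than half the channels have expectation below one photon and the Neyman
statistic averages ≈0.7 — biased low, hence conservative as a filter.  The
Pearson statistic (weights 1/model) has unit expectation for Poisson data
at any count level and is the one whose calibration (mean 1.0 ± 0.1) the
test suite checks.

Quality filters reproduce the published acceptance rules: ≥1200 photons,
reduced χ² strictly below 2, amplitude-weighted lifetime within
1500–2500 ps inclusive.  Image means and SEMs are computed over accepted
pixels only.  FRET efficiency is E = 1 − τ_DA/τ_D; the interacting-pixel
statistic (IPS) is the percentage of pixels below the lifetime threshold
τ_D(1 − E_thr) with E_thr = 0.13.  The IPS denominator is ambiguous in
common usage ("percentage of the total number of pixels"); it defaults to
accepted pixels and can be switched to all fitted pixels.  Per-cluster
lifetime distributions take connected components of pixels above 2000
photons and average the accepted lifetimes within each.

The default FRET lifetime of the generator deserves a note.  The published
mean lifetime of a double-labelled image (≈2227 ps against a 2402 ps
donor) is an average over all accepted pixels, ~85 % of which are
unquenched; it is *not* the lifetime of the interacting subpopulation and
lies above the 13 % IPS threshold (2090 ps).  A pixel population placed at
2227 ps would therefore never be classified as interacting, and the
mixture-consistent value ((2227 − 0.85·2402)/0.15 ≈ 1235 ps) falls outside
the 1500–2500 ps acceptance window.  The generator instead defaults to a
FRET efficiency of 0.25 for interacting pixels (τ_DA ≈ 1801 ps), a typical
GFP→mCherry quench that sits well below the classification threshold and
well inside the acceptance window, so a simulated 15 % interacting
fraction is recovered as IPS ≈ 15 %.

Measured estimator quality (in the test suite): lifetime bias < 1 % at
10⁴ photons and < 5 % at 1200 photons; a 64×64 donor-only image at 3000
photons/pixel fits back to the true 2402 ps within a few ps (the
1500–2500 ps window clips ~2 % of the upper tail, shifting the mean by
about −3 ps); ≥95 % of donor-only pixels pass all filters.

## FRAP model and estimation

The generator produces bleach-, reference- and background-ROI traces: the
bleach ROI follows F(t) = F_pre·[(1 − depth) + depth·Mf·R(t)]·S(t) with a
single-exponential recovery R(t) = 1 − exp(−t/τ_rec) whose half time obeys
the circular-spot relation τ_half = 0.224·w²/D, and S(t) = exp(−k_scan·t)
the scan-bleaching decay that also attenuates the reference ROI.  Defaults
emulate a largely immobile receptor in meristem tissue: Mf = 0.28,
D = 0.003 µm²/s, w = 1 µm, bleach depth 0.7, k_scan = 0.001/s, 2 % Gaussian
noise, five pre-bleach scans and 499 s of recovery at 1 s intervals.  The
exponential-recovery parameterization (not a full reaction–diffusion PDE,
and none of the uniform-disk or reaction-dominant models) was chosen to
match the estimation model so that parameter recovery is well posed; w is
a required user input because it is never identifiable from a single
trace.

Normalization subtracts background, divides by the reference ROI
(cancelling scan bleaching; an exponential fitted to the reference is
available as a smoother alternative), and rescales so the pre-bleach mean
— of all pre-bleach frames, for noise robustness — is 1 and the first
post-bleach sample is 0.  The recovery fit estimates A and τ_rec in
A·(1 − e^(−t/τ)) + B with a free offset B: anchoring the scale to the
single noisy first post-bleach sample perturbs the normalized curve by a
joint scale factor (1+δ) and offset −δ, so B estimates −δ and
Mf = A·(1+B) removes the anchor's scale error to first order.  On
noiseless traces B = 0 and the estimator reduces to the plain exponential
fit; at the default noise level it cuts the sd of the recovered mobile
fraction from 1.8 to 0.7 percentage points (300-seed simulation).
D = 0.224·w²/τ_half with τ_half = τ_rec·ln 2; D scales exactly as w² for a
given trace.  A 1-D Gaussian-plus-offset fit of intensity across the
anticlinal cell wall quantifies membrane replenishment as the ratio of
pre/post-bleach amplitudes.

## Photobleaching step counting

Traces are segmented into piecewise-constant levels by minimising
SSE + β·(segments − 1) *exactly*, with an O(T²) optimal-partitioning
dynamic program — exact optimisation (rather than greedy binary
segmentation) makes the segmentation provably equal to exhaustive
enumeration over all change-point placements, which the test suite checks
on small traces.  β defaults to 3·σ̂²·log T with σ̂ the
median-absolute-difference noise estimate; downward level changes of at
least 3·σ̂ count as bleaching steps, upward changes (blinking) are
reported but excluded.  Because two fluorophores occasionally bleach in
the same frame, the fluorophore count divides each step by the smallest
significant step (the single-fluorophore unit) and rounds: a double-height
step counts as two.  Both the penalty and the minimum step scale with the
data, so counts are invariant under affine intensity rescaling.  At the
default simulation conditions (6 fluorophores, noise sd 0.2× the step
height) the true count is recovered in 96/100 seeds.

## What the generators do not emulate

Synthetic membranes are static, flat and background-uniform: no cell-wall
autofluorescence, no endosome motion, no illumination-angle geometry, no
emCCD excess noise.  Decay cubes have exactly two lifetime species and a
time-uniform background; real pixels mix species within the focal volume.
FRAP traces follow the single-exponential model by construction, so the
recovery tests demonstrate estimator correctness under the model, not the
adequacy of that model for real membranes.  Passing tests therefore
validate the estimators and their implementation — not the biology.

## Problem sizes and reproducibility

The acceptance script (`scripts/acceptance.py`) uses 64×64 (donor-only)
and 128×128 (double-labelled) decay cubes at 3000 photons/pixel and nine
256×256 membrane images; the test suite uses smaller grids (24×24, 48×48)
chosen so that each check retains the statistical power it needs.  All
generators take integer seeds and are bit-for-bit reproducible; the
pipeline runner echoes config, seed and package version into its JSON
report, and an identical config + seed reproduces the report byte for
byte.
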