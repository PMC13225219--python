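# Methods

`flico` quantifies two-channel confocal experiments on *Drosophila*
Filamin (Cheerio) and the kinase Drak: pixel-level colocalization of the two
fluorophores, the shape dynamics of contractile actomyosin rings during
cellularization, cortical/depth intensity courses, and genotype effects on
muscle attachment-site length. This note records the models, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Colocalization

Per-channel global thresholds are estimated from single-fluorophore control
images acquired with the same settings: the threshold is the pooled pixel
mean of all masked control pixels plus `k` pooled standard deviations
(default `k = 3`). Weighting per-image means by masked pixel count makes the
"weighted mean" identical to the pooled pixel mean; if control images have
equal masked areas the distinction vanishes. For Gaussian background this
rule leaves ≈ 0.135 % of control pixels above threshold.

Within an ROI, with thresholds `t_A`, `t_B` and strict "above" (`>`, ties
excluded, fixed for reproducibility):

- `M1 = Σ A_i [A_i>t_A ∧ B_i>t_B] / Σ A_i [A_i>t_A]`, `M2` symmetric —
  intensity-weighted co-occurrence;
- `tPCC` — Pearson correlation of `(A_i, B_i)` over pixels above threshold
  in **both** channels; undefined (missing) when fewer than two such pixels
  exist or either channel is constant on them.

Images aggregate to samples by frequency-weighted means and SDs
(`Σw(x−x̄)²/(Σw−1)`), the weights being the informative-pixel counts: `n_A`
for M1, `n_B` for M2, `n_AB` for tPCC. Population inference is a one-sample
two-sided t-test and 95 % t-interval over the sample means — on the raw scale
for M1/M2 (intervals deliberately unclipped, so an upper bound above 1 is
possible), and on the Fisher-z scale for tPCC with estimates back-transformed
by `tanh`, which keeps the interval inside (−1, 1) and makes it asymmetric
around the point estimate. Sample means at `|r| = 1` (possible on synthetic
data) are clamped to `1 − 10⁻⁶` with a warning. The permutation null
(`randomize_channel`) permutes ROI pixels of one channel, preserving the
intensity multiset; the resulting tPCC distribution is centred at zero.

## ROI construction

The analyzable region is segmented from the Filamin channel only: subtract a
scalar background value (e.g. the control-image mean; the rolling-ball
estimate is reserved for the spot branch, matching the macro's wording),
mean-filter with a radius-4 px disc (exact disc `dy²+dx² ≤ r²`; this differs
from ImageJ's kernel by at most a 1-px rim), Otsu-threshold a 256-bin
histogram of the min–max-rescaled image, and keep the above-threshold pixels
— the bright boundary network; nuclear voids fall below. Manual exclusion
masks (PNG, 0/255) and per-channel spot masks are then removed. An
all-background image yields an empty-flagged result rather than an error.

Spot masks: rolling-ball background subtraction (radius 50 px, classical
ball; a paraboloid kernel is available behind a flag), difference between the
background-removed image and its radius-3 mean-filtered copy, Kapur
maximum-entropy threshold on the difference, one binary dilation with a 3×3
square. Because an entropy split always exists, a detection whose footprint
exceeds `max_spot_fraction` (default 5 %) of the image is treated as
"no spots present" and discarded — genuine autofluorescent spots are sparse.

Otsu, MaxEntropy and Huang thresholds are computed on 256-bin histograms of
min–max-rescaled intensities (mirroring ImageJ AutoThreshold on 16-bit
data), so all three are shift-equivariant to within one bin width.

## Ring morphometry

Per frame: optional classical denoising (none/Gaussian/median; the flag
replaces trained-model denoising, which circularity of synthetic rings does
not require), Huang threshold, largest connected component, then the
sub-pixel contour of the component's single hole — the **inner edge** of the
ring — at the 0.5 iso-level. The contour is resampled to 384 equally spaced
vertices and low-pass filtered in Fourier-descriptor space, keeping
`max(2, round(8 % of n))` frequency pairs. 384 vertices (≈ 31 pairs kept)
matches the native contour density of a ring with ~250 px perimeter; with
128 vertices only 10 pairs survive and polygon corners round by +0.02–0.04
circularity, which would swamp the rasterization error. Measured errors
against closed forms: square +0.013, hexagon +0.008, 256-gon −0.003. An
absolute-count descriptor mode is available (`absolute_descriptors`), since
"8 descriptors" and "8 % of descriptors" are both defensible readings of the
plugin setting.

Circularity is ImageJ's `4πA/P²` (shoelace area, vertex-chain perimeter);
it is scale- and rotation-invariant and ≤ 1 up to numerical tolerance.
Frame times are minutes since a user-supplied zero frame (the first frame
after the 14th nuclear division; detecting that division is out of scope).
Trajectories whose final area exceeds `(1 − min_contraction_frac)` × initial
area are flagged excluded ("no contraction"); `min_contraction_frac`
defaults to 0.2, a choice the source protocol leaves unquantified.

The group trend is a penalized cubic B-spline smooth of circularity on time
(10 basis functions) plus a zero-mean Gaussian random intercept per sample,
fitted per genotype. Both variance ratios (spline wiggle and sample
intercept) are chosen by restricted maximum likelihood via the standard
splines-as-mixed-models reparameterization; the difference penalty is
first-order, so an infinite penalty collapses the smooth to the weighted
mean. The fit is per-sample points rather than per-timepoint averages —
averaging first would make the random intercept unidentifiable; pre-averaged
data can still be passed if desired.

## Intensity profiles

Cortical recruitment: per timepoint, the mean of the first 7 z-slices from
the embryo edge (the edge offset is a per-sample parameter), minus the
matched control mean at the same timepoint, then min–max normalized per
sample. A constant corrected series normalizes to all zeros with a flag.
Depth profiles are per-plane ROI means (depth = plane × z-step); profile
pairs are aligned by shifting the reference (Filamin) channel's peak to
depth 0, linearly interpolated onto the native-step grid, and averaged. A
reference profile whose maximum sits on the boundary has no interior peak
and is rejected. Displacement series subtract the first junction
x-coordinate; samples are time-aligned on the junction minimum with a
configurable origin (default 24 h APF). Local regression is classical
tricube LOESS (default span 0.75, degree 2) evaluated on a uniform grid.

## Attachment-site model

Lengths are modelled as Gamma with common shape α and log-link mean
`μ = exp(Xβ + u_sample + u_image)`; genotype enters in treatment coding with
wild type as reference and the double mutant as a fourth level, and the
random intercepts are nested (image within sample). The marginal likelihood
is Laplace-approximated; because genotype is constant within a sample the
linear predictor is constant within an image, so each image contributes only
(count, Σy, Σ log y) and the per-sample mode is found by Newton steps on an
arrow-structured Hessian solved in closed form — a fit takes well under a
second, making simulation studies cheap. Convergence is BFGS with a
derivative-free polish; SEs come from the numerical observed information,
with boundary variance components conditioned out.

By default the variance components maximize a Cox–Reid adjusted profile
likelihood (an REML analogue): the objective carries `−½ log|X'V⁻¹X|`,
computed from the closed-form expected information. Plain ML
(`reml=False`) underestimates the sample variance by ≈ (k−g)/k with k
samples and g genotypes, which propagates to anticonservative Wald tests at
this design scale (14 flies/genotype).

The three prespecified contrasts are `β_closed`, `β_ko` and the epistasis
combination `β_double − β_closed − β_ko`; each is a two-sided Wald z-test
with model-based SE, Bonferroni-corrected with m = 3 (the prespecified set,
not all pairs). Western-blot fold-change ratios are per-lane
`(phospho / mean reference phospho) / (total / mean reference total)`.

## Synthetic data: what it does and does not emulate

The colocalization field emulates a cellularizing embryo surface: Voronoi
cell-boundary bands around dark elliptical nuclei (both fluorophores absent
inside nuclei), compact autofluorescent spots at identical coordinates in
both channels, and additive Gaussian noise on a constant background
(Poisson shot noise behind a flag; Gaussian suffices to exercise the
thresholding logic). Channel B's structural intensity is the mixture
`gain · amp · (f·N + (1−f)·U)` on the shared network support, where `N` is
channel A's band profile and `U` is independent per-pixel intensity: the
planted fraction `f` moves tPCC smoothly from ≈ 0 to ≈ 1 while spatial
co-occurrence (hence M1/M2) stays high — the qualitative regime the real
embryo data showed (near-total overlap, moderate correlation). A separate,
spatially disjoint channel-B-only network is available through
`independent_signal_level`. Defaults: 256×256 px, 25 nuclei of radius
12 ± 2 px, 4 px boundary bands of amplitude 120, 6 spots of amplitude 400,
background 20 ± 3.

The ring series renders an exact polygon — blended radially from a regular
hexagon toward its circumscribed circle to hit a target circularity, scaled
to a target area — as an anti-aliased band, so truth circularity is the
analytic `4πA/P²` of the polygon itself; the blend includes the polygon's
own vertex angles so the starting frame is exactly the hexagon (0.9069).
The attachment generator is the generative twin of the GLMM above. The
intensity-series generator plants a recruitment curve in the cortical band
of small z-stacks with matched background-only controls.

Not emulated: optical PSF and diffraction, photobleaching, shot-noise
correlations between channels, irregular (non-convex) nuclei, drift or
registration error, and 3-D furrow geometry. Passing tests therefore show
the estimators are correct and calibrated under the stated noise model, not
that the thresholding or segmentation is robust to every real-microscope
artifact.

## Problem sizes used in the checks

The packaged checks run the shape oracle on 128×128 renders; colocalization
recovery over planted fractions {0, 0.25, 0.5, 0.75, 1} with 20 fields each;
100 ROI permutations for the shuffle null; 10⁵ control pixels for threshold
calibration; 500 replicates of 9 samples for Fisher-z interval coverage; and
200 simulated studies at the design scale (4 genotypes × 14 flies × 2 images
× 10 sites) for GLMM bias, coverage and the epistasis type-I rate. These
sizes keep every Monte Carlo standard error well inside the corresponding
tolerance band.
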