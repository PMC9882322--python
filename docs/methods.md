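# Methods

This note documents the models and procedures implemented in `nucleoquant`,
the defaults that matter, and what the synthetic benchmarks do and do not
establish about real data.

## AFM tracing and volume stoichiometry

**Segmentation.** Background height h_b is the median of pixels below an
exclusion threshold (default 0.5 nm); the median is insensitive to the small
fraction of molecule-edge pixels that leak below it, and a flat background
with Gaussian noise σ = 0.1 nm is recovered to within 0.02 nm at ≥10⁴
background pixels. Molecules are 8-connected components with
h_p − h_b ≥ 0.3 nm (default), filtered at 30 px minimum area. The 0.3 nm
threshold sits at ~60% of the apparent ridge height of dsDNA and ~6σ above
the default noise floor.

**Skeleton decomposition.** Masks are thinned with a standard topological
skeletonization; the skeleton's pixel graph uses 8-connectivity with
redundant diagonal edges removed (a diagonal whose two pixels share an
orthogonal neighbor). Spurs shorter than 5 px that terminate at a junction
are pruned iteratively; free-standing paths are never pruned. Branch pixels
(≥3 neighbors) that touch are merged into one junction, and segments are
the maximal junction-free paths; a pure cycle yields one closed segment and
no endpoints. A molecule's contour length is by default the sum of its
segment lengths (configurable to the longest segment, since branched
molecules admit either convention).

**Contour length.** Ordered paths are measured with chain-code weights:
rx per horizontal step, ry per vertical, √(rx²+ry²) per diagonal. This
estimator is exact on axis-aligned and 45° paths and carries a known
orientation-dependent positive bias (up to ~8% for straight lines near
22.5°, ~5.5% averaged over orientations) on smooth curves; on synthetic
worm-like chains at 1 nm/pixel the median absolute error is ~7–8%, within
the 10% accuracy budget the tests assert. No sub-pixel spline refinement is
attempted.

**Volume.** V = rx·ry·Σ(h_p − h_b) over the region enclosed by the
molecule's outer boundary (holes filled), with negative excess clipped at
zero so noise cannot produce negative volume. The implementation agrees
exactly with per-pixel brute-force summation and recovers the analytic
volume 2πσ²A of a Gaussian bump to <1%.

**Stoichiometry.** The reference volume of one complex is
V_p = M/(ρ·N_A) with ρ = 1.44 g/cm³, a standard average protein density
(17,970 Da gives 20.7 nm³). The mass is always a configuration input; no
construct mass is hard-coded. The bound count per site is
n = V_d/(V_p·N_p), where V_d is the mean volume difference between bound
and bare molecules and N_p the mean detected particles per molecule; the
quantity is invariant under common rescaling of V_d and V_p. Particles are
detected as 8-connected clusters with height excess ≥1.2 nm (default) and
classified "end" when their excess-weighted centroid lies within 10 nm of
a skeleton endpoint.

## Condensate morphometry

Core and whole-condensate masks come from two intensity thresholds. By
default the whole threshold is Otsu on log-intensity of the full channel
(background vs signal) and the core threshold is a second Otsu pass on
log-intensity restricted to whole-mask pixels (halo vs core). A fixed
multiple of the whole threshold — valid only when the core/halo intensity
ratio happens to bracket it — and absolute values are available as
overrides. The core radius is r = √(A/π) from the thresholded core area.
Halo thickness is measured on 36 rays (10° steps) from the
intensity-weighted core centroid; per ray, thickness is the distance from
the last core-mask crossing to the last whole-mask crossing, so pinholes
and non-convex lobes do not truncate it. Rays that reach the image border
while still inside the whole mask are excluded from the mean. Both
channels are quantified; the summary medians are taken from the protein
channel, since the two channels give closely similar radii on registered
images.

## Dissociation kinetics

ROI traces are the arithmetic mean of pixel counts in a fixed rectangle
per frame (non-finite pixels excluded and the frame flagged), normalized
to the first frame. Dissociation is fitted as I(t) = A·e^(−kt) by
nonlinear least squares with k ≥ 0, amplitude free, and no additive
baseline by default (traces are background-subtracted upstream); a
baseline term can be enabled. Initialization uses a log-linear slope, and
the fit agrees with a dense 1D grid search to <1%. The estimator is
unbiased to well within 10% at k = 0.034 s⁻¹ with 2 s frames, 60 frames
and 5% multiplicative noise. Waiting times use an automated
threshold-with-persistence rule (default 2 consecutive frames above
threshold) as a declared stand-in for manual event picking.

## EMSA binding curves

Fraction bound is 1 − free/reference, clipped to [0, 1]. C₅₀ is read off
by linear interpolation between the first pair of titration points that
bracket 0.5 from below; an exactly attained 0.5 returns that
concentration, multiple crossings use the first and warn, and a titration
that never brackets 0.5 reports the maximum fraction attained
("unsaturated") instead of a number. Replicates aggregate as: one value —
reported as-is with spread undefined; two — mean ± half the absolute
difference (labeled "range", so each replicate lies at mean ± spread);
three or more — mean ± sample SD. Hill-equation or quadratic K_d fitting
is deliberately out of scope: with unknown bound stoichiometry and
binding-site count, C₅₀ is a comparative quantity only.

## Synthetic data

The generators emulate the study conditions the analysis was designed for,
and their defaults are those conditions: 1000-bp linear DNA (rise
0.383 nm/bp by default, so 383 nm expected contour; the canonical 0.34
nm/bp is available since the appropriate rise depends on deposition and
hydration), persistence length 50 nm, ~1 nm/pixel height maps, particle
counts truncated-Poisson with mean 2.2, per-particle volume
V_d/N_p = 137.7 nm³, condensate core radius 940 nm and halo 657 nm at
100 nm/pixel, decay rate 0.034 s⁻¹ sampled at 2 s for 60 frames with 5%
multiplicative noise, and binding curves crossing 0.5 at C₅₀ = 90 nM.

Chains are surface-equilibrated 2D worm-like chains: steps of length ds
with Gaussian turning angles of variance ds/l_p, giving tangent
correlation e^(−s/2l_p) and the closed-form second moment
⟨R²⟩ = 2ξL − 2ξ²(1 − e^(−L/ξ)) with ξ = 2l_p, which Monte-Carlo sampling
matches within 2 SE at 10⁴ chains. The AFM forward model deposits the DNA
ridge by arc-length resampling with bilinear splatting (constant mass per
unit arc length, so apparent ridge height is independent of local
direction — naive per-pixel rasterization renders diagonal stretches
fainter and fragments the segmentation), deposits each particle's full
volume onto its four nearest pixels, convolves with an isotropic Gaussian
of width 2 nm as a minimal tip-broadening model, and adds Gaussian height
noise (σ = 0.05 nm). The pre-convolution ridge amplitude (2.5 nm·nm
cross-section) is chosen so the post-convolution apparent height is
~0.5 nm, typical of surface-dried dsDNA in tapping mode. Convolution
conserves integrated volume, so an isolated rendered particle integrates
to its manifest volume within 1% with noise off.

What the synthetic benchmarks do *not* show: real AFM tips are not
Gaussian and produce geometry-dependent dilation; real DNA deposition is
between 2D-equilibrated and projected-3D; real condensates are irregular,
can touch, and have graded rather than two-level intensity profiles; real
photon noise is not purely multiplicative. Passing the recovery tests
demonstrates the estimators are correct and unbiased under the stated
forward models, not that those models capture every property of the
instruments.

## Numerical and design choices

- One seeded generator per scene; per-object sub-streams derived
  deterministically via `SeedSequence` spawn keys, so identical seeds give
  bit-identical scenes and individual objects can be regenerated.
- 8-connectivity throughout (masks, skeletons, particle clusters);
  diagonal steps weighted √2.
- Chains in simulated multi-object scenes are laid out one per grid cell
  (resampled until the bounding box fits), which guarantees non-touching
  objects; component counts then equal manifest counts by construction.
- Degenerate molecules (empty skeleton after pruning) are flagged, not
  raised.
- Problem sizes in the test suite (e.g. 50 single-chain scenes for the
  tracing benchmark, 10⁴ chains for the moment check, 60–200 traces for
  fit-bias checks) were chosen as the smallest sizes at which the asserted
  statistical bounds are comfortably stable.

## Known limitations

- No tip deconvolution or sub-pixel contour refinement; the ~+6% chain-code
  bias is documented rather than corrected, matching the measurement
  procedure the package reproduces.
- Touching condensates are not split; each connected component is one
  condensate.
- The kymograph-style line tracking and force-channel analyses of
  optical-trap experiments are out of scope.
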