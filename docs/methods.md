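# Methods

## Model

All optical estimates rest on the gap-fraction model for a horizontally
homogeneous canopy,

P(θ) = exp(−G(θ) · Ω(θ) · PAI / cos θ),

where P(θ) is the probability that a ray at zenith angle θ reaches the
sensor unobstructed, G is the projection coefficient of unit plant area
(0.5 for a spherical leaf-angle distribution) and Ω the clumping index.
The inversion used here is Miller's integral,

PAI = 2 ∫₀^{π/2} −ln P(θ) cos θ sin θ dθ,

which integrates G out entirely: no leaf-angle assumption enters the
inversion itself. Plant area index (PAI) rather than leaf area index is
reported throughout — woody elements are not separated, and stand-level
clumping is not corrected. Shoot-level clumping is optionally corrected by
dividing PAI by 4·STAR, the silhouette-to-total-area ratio of shoots
(defaults offered: 0.147 for pine, 0.161 for spruce; no correction for
birch).

## Processing chain and its parameters

**Reprojection.** The equirectangular panorama must satisfy width = 2 ×
height with row 0 at the zenith; stitching dialects that put the nadir
first are not auto-detected, the convention is enforced. Each pixel of the
output disc at normalized radius r and image azimuth φ (up = north,
clockwise = east) samples the panorama at zenith θ = f⁻¹(r) and azimuth
φ + offset. The lens function f defaults to linear (equidistant,
r/R = θ/90°); polynomial lenses are inverted by monotone bisection to
1e-10. Output size defaults to 4000 px (radius 2000 px), matching typical
field processing. Interpolation defaults to bilinear for photographs;
nearest-neighbor is available and is what the synthetic harness uses (see
below). Pixels outside the inscribed circle carry a fill value of 0 and an
explicit mask; all downstream statistics use the mask.

**Segmentation.** Stored images are treated as gamma-encoded; channels are
linearized as (v/255)^γ with γ = 2.2 by default and averaged with equal
weight (`rgb_mean`; single-band modes are available — the blue band is
also used by the exposure metric). The automatic threshold is the
Ridler–Calvard/isodata fixed point t = (mean below + mean above)/2,
started from the global mean, iterated to 1e-4 on the [0, 1] scale (max
100 iterations). A constant image raises a degenerate-histogram error so
the caller can fall back to a manual threshold. The fixed point is checked
in the tests against an exhaustive 256-candidate scan and against an
independent isodata implementation.

**Gap fractions and PAI.** The disc is partitioned into five contiguous
15° annuli starting at θ = 0 (75° total); the 75–90° ring is imaged but
excluded. P_i is the sky-pixel fraction of annulus i; the Miller integral
is discretized at annulus midpoints with one gap fraction per ring (log of
the ring mean, not mean of logs; sub-ring averaging in the Lang–Xiang
style is out of scope). Because only 0–75° is observed, the sum is divided
by C = 1 − cos θ_max. This rescaling is exact in the continuum whenever
−ln P ∝ 1/cos θ (spherical G), and the residual midpoint-rule error is
0.29% at 5×15° and 0.0013% at 1° rings — the convergence tests pin both.
Saturated annuli are floored at one pixel's worth of gap (1/pixel count)
before the log; an explicit `p_floor` overrides this.

**Vertical profiles.** Replicates per height (typically 3) are averaged
arithmetically; PAI is averaged, not gap fraction — with three replicates
either convention is defensible and the mean-of-PAI choice keeps each
replicate a complete, independently thresholded measurement. The spread
statistic per height is (max − min)/mean·100. PAD per layer is the finite
difference of consecutive mean PAIs. Negative layers are kept by default:
they are a truthful signal of drift or exposure change between heights,
and clipping (available behind a flag, recorded in the result) breaks the
telescoping identity Σ PAD·Δz = PAI(bottom) − PAI(top) that otherwise
holds exactly.

**ALS proxy.** Points within a closed 10 m horizontal radius of the
profile location are kept; z is assumed height-normalized on input.
Points below the 1.5 m ground cut are ground returns: they count in N_t
but never in N_c. Transmission T(z) = 1 − N_c(z)/N_t is evaluated at 50
equally spaced levels spanning [ground cut, cloud top] (≈0.5 m spacing in
a 25 m canopy); each point counts once, echo-number weighting is not
modelled. PAI(z) = −ln T(z)/k with T floored at 1/N_t. The extinction
coefficient k is fitted by OLS of −ln T on the photographic PAI at
height-matched levels (nearest level, max gap one level spacing, since a
2 m flight grid never aligns exactly with 0.5 m levels); the regression is
through the origin because Beer's law forces PAI = 0 at T = 1, with an
intercept variant behind a flag. Profile comparison averages the finer
ALS PAD layers inside each photographic layer and reports the residual
sum of squares and the height of the largest residual.

**Statistics.** Regression SE = √(SSR/(N−2)) and RSE = SE/ȳ·100 require
N ≥ 3. In the two-camera comparison the ground (DHP) values are the
response and the drone values the predictor. Welch's t-test is computed
from group summaries with Welch–Satterthwaite degrees of freedom and
exact t-distribution tails (no normal approximation); recomputing the
published stitching-error table (n = 30 per group, from "50% of 60 images
clear of errors") reproduces its two-tailed p-values 0.964 and 0.765
within the rounding of the printed inputs.

## Synthetic ground truth

The generator emulates exactly the geometry the estimators assume: slab
canopies (non-overlapping layers of uniform PAD) under Beer's-law
attenuation with G = 0.5, so P(θ) = exp(−G·PAI_above/cos θ) in closed
form. Panoramas are rendered by per-pixel Bernoulli dithering of P(θ(row))
with well-separated sky/plant intensities (230/20; optional Gaussian
noise), which makes the expected gap fraction of any zenith band exactly
the band mean of P — crown geometry, penumbra and radiative transfer are
deliberately absent. LiDAR pulses descend vertically (scan-angle spread is
not modelled); interception heights invert the survival curve
exp(−k·PAI_above(z)) analytically, survivors become ground returns at
0.5 m. All generators are deterministic under a seed, with replicate
sub-seeds drawn from a `SeedSequence`.

One consequence drives a default: bilinear resampling of a Bernoulli
field concentrates gray values around the local mean, so thresholding
returns the majority class instead of preserving the mean — gap fractions
collapse toward 0 or 1. The synthetic harness therefore reprojects with
nearest-neighbor sampling, which preserves the per-pixel statistics and
the closed-form expectations; for real photographs, where vegetation is
spatially coherent, bilinear remains the default. Passing tests on this
generator validate the geometry, the thresholding fixed point and the
inversion arithmetic; they do not exercise stitching artifacts, exposure
drift, mixed pixels at crown edges, or non-random foliage dispersion,
which dominate error budgets on real imagery.

## Problem sizes and numerical choices

End-to-end validation renders three replicates at four heights with
1000-px-high panoramas reprojected to 2000 px — large enough that
binomial noise per annulus is well under the tolerances checked (PAI at
ground within 5% of truth, PAD per layer within 10%) while a full run
completes in well under a minute. LiDAR recovery uses 50 000 pulses, at
which the fitted k lands within 10% (observed ≈0.2%) of truth. Bisection
for lens inversion runs 60 halvings (≪1e-10 relative). Ties at the
threshold classify as sky (`>=`); the annulus partition uses half-open
[θ_lo, θ_hi) intervals so every inside pixel lands in exactly one ring.

## Known limitations

No stitching of raw frames, no lens-calibration estimation, no
local-contrast (edge-based) binarization, no woody/green separation, no
stand-level clumping, no echo-number weighting or scan-angle correction,
no LAS/LAZ reader (point clouds are whitespace XYZ text or synthetic).
Negative PAD layers propagate into the ALS comparison unless clipping is
requested.
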