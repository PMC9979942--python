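# Methods

This note records the model `stillsx` implements, the numerical choices
behind it, what the synthetic data emulate, and the limits of what the
tests demonstrate.

## Conventions

Reciprocal space is measured in nm⁻¹ with the wavenumber convention
`ν = 1/λ` (no 2π). The lab frame is right-handed with the beam along +z
by default. Detector panels map fast-scan/slow-scan pixel indices to lab
space through a 3×2 basis matrix and a corner offset; pixel centers sit
at half-integer offsets from the 0-based indices. All weights on
Gaussian kernels are unitless multipliers; physical units (photons,
counts) are attached by the calling layer.

## The kernel algebra

Every distribution is a weighted 3-D Gaussian `w·φ(x; μ, Σ)`. The
identities used throughout: products are Gaussians with summed
precisions and a `φ(μₐ; μᵦ, Σₐ+Σᵦ)` overlap weight; convolutions add
means and covariances; the incoherent overlap `∫ρₐρᵦ` equals the product
weight; the coherent overlap integrates amplitudes `√(wφ)` first and
squares, which for single kernels rescales the incoherent result by
`(8π)^{3/2}√(det Σₐ det Σᵦ / det(Σₐ+Σᵦ))`. Rank-deficient covariances
are legal operands for convolution and projection (the beam's wavelength
spread is rank 1) but are rejected, with the null direction named, where
a pointwise density is required.

Matrix square roots use the symmetric eigendecomposition with
eigenvalues clipped at zero below `−10⁻¹²·trace`, so numerical noise
cannot produce complex roots. `correlated_difference_cov` implements the
correlation-1 rule `(√Σ_out − √Σ_in)(·)ᵀ`, exact whenever the two
covariances commute.

## Illumination

`cov_kin = ν₀²[σ_div²(I − w w ᵀ) + b² w w ᵀ]`: an isotropic divergence
ring transverse to the beam plus radial wavelength broadening, assumed
independent. For the difference `Δk = k_out − k_in` the two wavelength
spreads are driven by the *same* scalar wavenumber deviate (diffraction
preserves wavelength), so their correlated difference is the difference
of the rank-1 square-root factors:

    cov_bw = σ_ν² (w_out − w_in)(w_out − w_in)ᵀ ,  σ_ν = ν₀·bandwidth,

which reproduces the shear geometry of the Ewald construction — the
component of Δk along `w_in` is `ν(cos 2θ − 1)` — and matches
shared-wavelength Monte Carlo sampling exactly at every scattering
angle. (A symmetric-sqrtm difference of the two full covariance matrices
is only correct when they commute, i.e. in the forward direction.) The
divergence part is independent and adds by covariance addition. The
polarization correction is the standard partially-polarized Thomson
factor `C = p[1−(w·n)²] + (1−p)[1+(w·w_in)²]/2`, applied for the actual
outgoing direction but with a single beam direction (the mean), which is
adequate at the sub-milliradian divergences modelled here.

## Crystal

Peaks sit at `x = R h`. Isotropic mosaicity is parameterized as a random
rotation vector with independent `N(0, σ_m²)` components about three
orthogonal axes; its small-angle second moment is the tangential
covariance `σ_m²(|x|²I − xxᵀ)`, valid for `σ_m ≪ 1` (verified against
rotation sampling to 2% at σ_m = 5 mrad). Scalar strain contributes
radially, `σ_s² xxᵀ`. The intrinsic peak shape is a free PSD covariance;
for a cubic crystallite of edge `L` the helper `cube_shape_cov` matches
the FWHM of the central `sinc²` lobe, `σ = 0.376/L`, with the constant
exposed because a Gaussian stand-in for a `sinc²` is a modelling choice.
The `1/(x ln²x)`-tailed shape transform is the place where the
Gaussian approximation is weakest; convolution with bandwidth, mosaicity
and strain smooths it in practice.

A reflection is *excited* when its Mahalanobis distance to the Ewald
sphere, `|δ|/σ_tot` with `δ = ν₀ − |ν₀w_in + x|`, is below a cutoff.
The region-growing search walks the integer lattice with 26-neighbour
connectivity from seeds on the resolution-limited Ewald cap, expanding
through any cell whose unit cube could intersect the condition (the
per-cell test inflates the band by twice the cell circumradius, so the
traversal is conservative). The final membership test is identical to
exhaustive enumeration and the two are set-equal on every random
configuration tested (160 draws over orientation, bandwidth, cutoff).

## Pixel-wise prediction

Per pixel and reflection the expected photon count is the incoherent
overlap of the Δk kernel (convolved with the detector point spread) and
the peak kernel, scaled by `J₀·C·|F|²·a·exp(−B|x|²/2)` and the pixel
solid angle. Readings of integrating detectors are photon-energy
weighted: `reading = g·ν̄·photons`, with the per-pixel wavenumber
statistics computed as the exact Gaussian posterior of ν given arrival
at the pixel (prior `N(ν₀, σ_ν²)`, likelihood the divergence-margina-
lized peak overlap of `ν(w−w_in)`). This is algebraically the "project
the joint kernel on the beam and rescale by `1/(1−cos 2θ)`" rule but
remains well defined in the monochromatic limit (ν̄ → ν₀, var → 0).

The detector point spread is Gaussian with σ of half a pixel extent per
axis, in direction space, scaled by ν₀² into reciprocal space. The
constant ½ is the minimax optimizer of the divergence between the exact
pixel-integrated probabilities (error-function form) and the
variance-inflated density sampled at pixel centers, maximized over
sub-pixel offsets and peak widths; the worst case is a peak much
narrower than a pixel just inside a pixel edge. The center-sampled
estimate is deliberately *not* renormalized in the study — conserving
total flux while misplacing it must cost divergence — and the numerical
optimum is 0.485–0.49 pixel extents depending on grid resolution.
Oversampling by an integer factor `s` evaluates `s²` subpixel centers
with the spread shrunk to `1/(2s)` and averages; frame totals with and
without analytic smoothing agree to ≤0.1% once spots span a few pixels.

The per-pixel reading variance is compound Poisson plus a systematic
term: `α·g²·Σ(photons·E[ν²]) + β·reading²`; background readings are
treated as photons at ν₀. The measurement likelihood is a Gaussian
(variance inflated by the discretization constant ¼ count²) mixed with a
super-heavy-tailed outlier density `∝ 1/((|x/s|+2)·ln²(|x/s|+2))`, an
analytically normalized smoothed universal-prior-style density whose
`1/(x ln²x)` decay keeps dead and hot pixels at finite log-likelihood.

Pattern refinement maximizes the summed pixel likelihood over cell (9),
shape Cholesky (6, log diagonal), log mosaicity, log strain, log scale,
B and the two error-model parameters, with exact forward-mode gradients.
Optimization is staged — smooth parameters first with the cell frozen,
then everything with cell steps bounded — because moving a peak by more
than its width swaps which pixels it explains, producing the local
minima that make still-pattern refinement notoriously basin-sensitive.
Only local refinement from an indexing-quality start is promised. Note
that for a noiseless self-generated image the maximum-likelihood point
is *not* exactly the generating parameter set (the −½log var term
rewards smaller predicted variance), and mosaicity, strain, shape and B
are nearly degenerate on a single frame; the self-consistency test
therefore asserts sub-0.1% recovery for the well-determined block (cell,
scale) with the degenerate block held fixed.

## Integrated intensities and partiality

The reflection's angular flux integral is collapsed by integrating the
3-D overlap across the tangent plane at the optimal outgoing direction
`w_max`: in the flat-slab limit

    factor = (1/ν₀²) · φ₁(δ; 0, σ_tot²),
    σ_tot² = w_maxᵀ(Σ_Δk + Σ_peak)w_max ,

the 1-D overlap between the projected peak and the planar distribution
of Ewald spheres (slab width `d = √(w_maxᵀ Σ_Δk w_max)`). The default
evaluation replaces the flat-slab curvature with the exact angular
Hessian of the log flux density at `w_max` (a Laplace evaluation,
`j_max·2π/√det H`), which keeps Ewald-sphere curvature to second order;
the two agree to ≪1% at synchrotron bandwidths while the Laplace form
stays within 0.15% of dense spherical quadrature up to 5% FWHM bandwidth
and 0.5° mosaicity, where the flat slab drifts to ~2.4%. `w_max` itself
is found by Nelder–Mead plus Newton polish from the closest-approach
direction `(ν₀w_in + x)/|·|`, with stationarity verified through the
curvature-scaled Newton step (< 10⁻⁹ rad).

Partiality is the factor divided by its maximum over rigid
reorientations. The maximizing orientation centers the peak in the slab
along the geodesic, leaving the covariance magnitudes essentially
unchanged, so `p = exp(−δ²/2σ_tot²)` in closed form. Reflections outside
the limiting sphere (`|x| > 2ν₀`) are flagged unreachable with p = 0.
Over uniform random orientations the partiality histogram piles up at 0
(most reflections unobservable) with a faint secondary pile-up at 1
(the flat top of the profile), which the tests check qualitatively.

## Merging

Observations enter as `(crystal, h k l, I, σ_counting)` rows. Each is
predicted as `coef · I_asu` where `coef` collects flux, polarization,
per-crystal scale and B, the intensity factor and the expected
wavenumber; `I_asu` is the merged intensity of the symmetry-unique
reflection (Laue class −1 by default, i.e. Friedel pairs merged; class 1
available). The likelihood per observation is
`(1−ε)·N(I; pred, α σ_c² + β pred²) + ε·Cauchy(I; 0, γ)` — the variance
is the two-parameter counting-plus-systematic form with the counting
sigma supplied by integration and the quadratic term on the *predicted*
intensity, and the Cauchy scale γ is fitted once from the global
intensity histogram unless configured (its value is data-set specific).
ε defaults to 1/16.

Optimization alternates blocks, each accepted only if it improves the
total likelihood (so the trace is non-decreasing by construction):

1. **Intensities**: per unique reflection, a coarse log-grid scan plus
   bounded 1-D refinement. The scan matters: the mixture profile can
   have a narrow Gaussian dip inside a flat outlier-dominated plateau
   that a bare bracketing search walks past.
2. **Error model** (α, β) globally, Nelder–Mead on the log scale.
3. **Per-crystal parameters** (19 each) by L-BFGS-B with exact
   forward-mode gradients, diagonally preconditioned (the likelihood is
   ~10⁷ times stiffer in cell entries than in log-disorder parameters)
   and staged as in pattern refinement. Crystal refinement starts only
   after two warm-up passes of (1)–(2): fitting geometry against raw
   least-squares intensities collapses the disorder parameters into a
   wrong self-consistent optimum.

The multiplicative gauge (all intensities up, all crystal scales down)
is fixed by renormalizing the mean crystal scale to 1 after each pass,
an exactly likelihood-neutral transformation applied only while the
scales are free. With ε = 0, β = 0 and fixed crystals the merged
intensities reduce to the precision-weighted least-squares solution,
which the tests verify against the closed form.

Each merged intensity carries a Gaussian-information standard error
`1/√(Σ coef²/V)`. Reflections observed only deep in the overprediction
tail (partiality ~10⁻⁷) have enormous sigmas and essentially arbitrary
ML intensities — their observations constrain the *crystal* parameters,
not their own intensity. Quality metrics are therefore computed over
adequately measured reflections, defined as merged sigma below 10% of
the mean true intensity (≈96% of unique reflections in the recovery
study).

## Synthetic data

The generator emulates an indexed-stills experiment at the
integrated-intensity level: 10 nm cubic cells under uniform random
orientations with 0.05% metric jitter; acentric-Wilson (exponential)
true intensities with mean 1000; per-crystal log-normal scales
(σ = 0.2) and small positive B factors; 0.13 nm photons with 0.1% rms
bandwidth (SASE-like) and 0.1 mrad divergence; mosaicity 1 mrad, strain
10⁻³, isotropic peak shape σ = 2×10⁻³ nm⁻¹; observations to 1 nm
resolution at a 6σ excitation cutoff (overprediction — most added
observations are weak or negative and are retained); counting sigmas
`√(floor² + pred)` with a 2-count floor; noise variance
`α σ_c² + β pred²` with α = 1, β = 2.5×10⁻³ (5% systematic); outliers
replaced by Cauchy draws at rate 1/16. Identical seeds give bit-identical
tables. Toy images come from the full pixel-prediction path plus flat
background.

What the generator does **not** emulate: image-level integration (the
error model stands in for integration noise except in toy images),
non-Gaussian shape-transform tails, detector gaps/saturation/shadowing,
indexing ambiguities, correlated wavelength–angle source structure, or
anisotropic mosaicity. Passing recovery tests therefore demonstrate that
the estimator inverts its own forward model under realistic noise and
outliers — necessary, not sufficient, for real-beamline data.

## Problem sizes and validation scales

The recovery study runs 200 crystals (~16,000 observations over ~2,100
unique reflections, mean redundancy ~7.7), initialized with cells
perturbed by 0.1% and disorder parameters off by +50%/−40%, and merges
with up to 14 outer passes (tolerance 10⁻⁴ relative). It recovers
merged intensities at truth correlation ≈0.99, median mosaicity within
~4%, per-crystal scale correlation ≈0.99, and beats the Monte-Carlo
average (≈0.71 on the same reflections) decisively. Quadrature
cross-checks use 50 random kernel pairs (overlap integrals, agreement to
~10⁻¹⁴) and 20 random reflections spanning 0–5% FWHM bandwidth and
0–0.5° mosaicity (intensity factor, ≤0.2%). Monte-Carlo oracles use 10⁶
samples; gradient checks compare forward-mode derivatives with central
differences at curvature-appropriate steps for every free parameter.
Module tests use smaller instances of the same constructions (e.g. 160
random configurations for the excited-set equality, 2×10⁴-row table
round trips).

## Known limitations

* Only local refinement: neither pattern fitting nor merging attempts a
  global search over the crinkly cell landscape; starts must come from
  indexing.
* The planar-slab/Laplace intensity factor assumes reflections subtend
  small angles; it degrades for peaks wider than ~0.3 rad (warned).
* The asu reduction covers Laue classes 1 and −1; higher symmetries must
  be supplied by pre-mapping indices.
* Partial coherence is not modelled: integrals are fully incoherent by
  default with a fully coherent alternative, no interpolation between.
* Pixel-wise refinement is exercised on single patterns only, not whole
  data sets.
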