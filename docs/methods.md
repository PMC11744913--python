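# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `myelotrace`, in the order the pipeline runs them.

## Geometry and angle conventions

Volumes are `(z, y, x)` arrays with physical voxel size (x, y, z) =
(0.54, 0.54, 4.0) µm by default, matching commercial light-sheet
acquisition of cleared tissue.  In-plane analysis treats each z plane as
an independent 2D image; the strong z anisotropy makes 3D orientation
tensors unreliable, so none are computed.

Orientations are **axial**: a fibre has no head or tail, so angles live
in [0°, 180°).  The visual convention is counter-clockwise from +x with
the pia "up" (towards low row indices): a radial fibre (running from pia
to white matter) reads 90°, a fibre parallel to a flat surface reads 0°.
All circular statistics double the angles onto the full circle, operate
there, and halve back; this is required for coherent circular statistics
on axial data and is used consistently by the generator and the
regression module.

## Cell detection (Gabor spherical shell)

The kernel K(x,y,z) = 1/(2πσr₀)·exp(−π((r′−r₀)/σ)²)·exp(i(2πf₀(r′−r₀)+φ))
is evaluated on an odd grid, cubic in XY and compressed along z by a
factor (default 2).  r′ is the Euclidean radius with the z coordinate
stretched by that factor.  Defaults r₀ = 22 px, σ = 12 px, f₀ = 0.1
cycles/px, φ = 3.7 rad.  The prefactor is a pure amplitude scale and is
adopted as written; detection uses relative maxima, so it cannot change
results.

*Support*: the grid is truncated at r′ = r₀ + 3σ.  The envelope is
exp(−π((r−r₀)/σ)²), already < 4·10⁻⁶ at 2σ and < 10⁻¹² at 3σ, so a wider
box only adds cost.

*Detection*: FFT convolution of the real part ("same" extent, zero
padding), then 3D local maxima with an anisotropic minimum-separation
footprint (default: kernel radius in XY, converted per axis) and a
relative height threshold (default 0.3 of the global response maximum).
Detections within a kernel half-width of a border are flagged
`near_border` rather than dropped.  For shell-like objects matched to the
kernel, the response of a true centre is well separated from ring
side-lobes: on noiseless matched shells the main-lobe peaks sit at ≳0.65
of the global maximum and side-lobes at ≲0.40, so any relative threshold
in between (the oracle tests use 0.5) separates them exactly.  The
imaginary part is built and carried for completeness (phase/energy
detection) but the default pipeline convolves only the real part.

*Scoring*: greedy one-to-one nearest matching within a radius (default
5 µm ≈ soma radius).  Accuracy = matched/truth, FP = unmatched
detections/detections, FN = unmatched truth/truth.

## Neighbourhood statistics

For each reference cell at least d from every volume edge (d = 54 µm), a
cube of edge d centred on it is binned isotropically (1 µm default; z
positions enter at their physical coordinates, i.e. nearest-µm assignment
of 4 µm-spaced planes).  The reference cell itself is excluded (it would
only add a delta at the origin).  The averaged field uses reference cells
5, 10, 15, … (stride 5).  The radial profile uses the inscribed-sphere
radius d/2 = 27 µm and divides each distance bin by the number of *image
voxels* (on the true anisotropic lattice) whose centre falls in that
radial shell, so a spatially random point field yields a flat profile —
this is verified as a Monte-Carlo property test.  Density is
count/analysed volume in cells/mm³, paired per animal for L/R comparison.

Grids are physically isotropic in µm rather than voxel-aligned; the
alternative (voxel-aligned bins) would entangle the 4 µm z spacing with
the 6 µm biology under study.

## Orientation analysis

Per plane: median filter (3×3), Sato tubeness (bright ridges, σ ∈ {1, 2}
px — the scale of a resolvable fibre bundle at this sampling), min-max
normalisation.  The structure tensor J is the plain mean over a window of
the central-difference gradient products; windows are 24 × 24 px and tile
the plane **without overlap**, keeping records statistically independent
for the regression.  Storing one record per pixel of a sliding window is
the denser alternative; it multiplies n without adding independent
information.

φ = ½·atan2(2J₁₂, J₂₂−J₁₁) is the two-argument form of the half-angle
formula; it resolves the quadrant ambiguity and directly returns the
ridge (structure) direction in the convention above — gradients of a
vertical fibre vary along x, giving φ = 90°.  E = tr J; C is computed in
closed form as √((J₁₁−J₂₂)² + 4J₁₂²)/E (identical to the eigenvalue
contrast, verified against direct eigendecomposition), with C = 0 when
E = 0.  The gate retains windows with E·C at or above a threshold;
because absolute energy depends on staining and normalisation, the
default is the 0.6 quantile of E·C within the plane, with an absolute
override.

*Surface fit*: the autofluorescence plane is Otsu-thresholded; the top
tissue boundary per column is located with sub-pixel interpolation of the
threshold crossing and least-squares fitted with row = a·x² + b·x + c.
The signed distance to the rasterised curve (Euclidean distance
transform, positive below the surface) is smoothed (σ = 2 px) and its
gradient gives the local inward normal; the tangent is the normal + 90°.
On noiseless renders the coefficients round-trip well within 1%.

*Correction and layers*: φ_corrected = (φ − local tangent) mod 180°.  The
layer is assigned from the window centre's depth below the surface
against configured boundaries; a depth exactly on a boundary goes to the
deeper layer.  Layer boundaries are configuration, not inference: expert
annotation is dataset-specific.  Defaults, as fractions of cortical
depth, are L1 0–0.10, L2/3 0.10–0.35, L4 0.35–0.50, L5 0.50–0.75, L6
0.75–1.0 (mouse-cortex-plausible).  L6 is excluded from analysis (poor
staining contrast at depth), as are windows above the surface or below
the deepest boundary.

## Projected-normal circular GLM

Doubled angles 2θᵢ are modelled as directions of latent yᵢ ~ N₂(B'xᵢ, I);
the identity covariance is the standard identifiability constraint.
Covariates are categorical and enter additively (side; side + layer),
dummy-coded against the alphabetically first level.  Coefficients carry
diffuse N(0, 10⁴) priors.

*Sampler*: Gibbs.  The latent length rᵢ has full conditional
p(r) ∝ r·exp(−½(r−bᵢ)²) on r > 0 with bᵢ = uᵢ'μᵢ; it is updated with an
exact slice step (auxiliary uniform under the Gaussian factor, then r²
uniform on the resulting interval).  B is then drawn from its conjugate
matrix-normal conditional via a Cholesky factor computed once.
Observations are sorted into a canonical order before sampling, making
the fit exactly invariant to permutations of the input records.  Defaults:
2 chains × 5000 iterations, 1000 burn-in, no thinning; a minimum
effective sample size (Geyer initial-monotone estimator) below 100
triggers a warning.

*Summaries*: per design cell, the per-draw direction of the cell's linear
predictor is recorded; the posterior mean direction is the circular mean
of those draws, halved back to [0°, 180°).  The 95% HPD is the shortest
circular interval containing 95% of the draws (rotate to the circular
mean, scan sorted draws, rotate back); an interval spanning more than
half the circle is flagged as likely multimodal.  "Distinct effect"
decisions use circular interval intersection (`hpd_overlap`).

*DIC*: Spiegelhalter form, DIC = D̄ + p_D with p_D = D̄ − D(B̄), using the
closed-form marginal projected-normal angle density
f(θ|μ) = (1/2π)·e^(−½|μ|²)·(1 + b√(2π)·e^(b²/2)·Φ(b)), b = u'μ, with an
asymptotic branch for large b.  The density is validated by numerical
integration to 1.  The alternative p_V (half the posterior variance of
the deviance) is not implemented.

*Bootstrap*: datasets with millions of records exceed what one model
instance should carry; `bootstrap_fit` draws equal-size subsamples per
design cell without replacement (default 5000 per cell), checks each
subsample's angular distribution against the full data with a two-sample
Kuiper test (rotation-invariant; α = 0.01, warning on failure),
fits each of the default 25 repetitions with an independent sub-seed, and
reports the circular mean and spread of the posterior means across
repetitions.

## Synthetic data: what it emulates, and what it does not

The generators are the package's stand-in for microscopy data and define
the conditions under which the pipeline is validated:

- **Somata**: microcolumns along the depth axis, 6 µm intra-column
  spacing, 20 µm column pitch, 0.5 µm isotropic positional jitter; each
  soma a hollow shell (bright rim, dimmer core at 0.3 amplitude) with z
  extent compressed by the voxel anisotropy.  The rim radius defaults to
  5 µm and, for detection oracles, is placed at the argmax of the kernel's
  radial profile (`shell_match_radius_px`) — for the default kernel
  parameters that is ≈ 25.7 px, not r₀, because the carrier cosine is
  negative at r₀ with φ = 3.7.  Noise is Poisson shot noise on a constant
  background (10 counts) plus Gaussian read noise (σ = 1); `snr` scales
  the rim peak in background-noise standard deviations, default 10, at
  which detection accuracy exceeds 95%.
- **Fibres**: per-layer anti-aliased in-plane segments whose angle
  relative to the *local surface tangent* is wrapped-normal with the
  layer's mean and sd, under a per-plane quadratic surface; tangent-
  relative truth is therefore curvature-invariant by construction.  L1
  defaults to 0° (parallel to the surface), deeper layers to ~90°
  (radial).
- **Surface**: anti-aliased intensity step across row = a·x² + b·x + c.
- **Direct orientation sampling**: per stratum, angles are drawn from the
  projected normal itself with mean vector κ·(cos 2µ, sin 2µ); κ sets the
  concentration (angular sd ≈ 1/(2κ) rad).  The bundled study designs use
  κ = 10 for the pooled and per-sex models.  For the side+layer model the
  per-cell concentrations are the lengths of the exact additive latent
  parameterisation of the six cell means (8 parameters, 6 direction
  constraints; the two free degrees of freedom are anchored by the L2/3
  dispersions, κ = 7/HPD-width).  Two consequences: the generating
  process is a member of the fitted model family, so recovery is free of
  representation bias, and L2/3 is the most dispersed stratum —
  layer-dependent dispersion is what lets an additive latent model
  express layer-dependent hemispheric differences at all (with equal
  concentrations it mathematically equalises them).

Not emulated: light-sheet PSF and stripe artefacts, depth-dependent
attenuation, staining chemistry, mosaic stitching, or tonotopic gradients.
Passing tests therefore demonstrate correctness of the measurement and
inference chain under the stated geometric and statistical assumptions,
not robustness to raw-microscopy artefacts.

## Problem sizes and numerical choices

The validation suite runs desk-scale problems chosen as the smallest
sizes at which each effect is resolved with comfortable margin:
recovery simulations use 10,000 angles per design cell averaged over 5
sub-seeds (Monte-Carlo error of a group mean ≈ 0.03°, an order below the
smallest effect of interest); image-route cohorts use 4 samples × 2
hemispheres × 2 planes of 480² px; detection oracles use ≈ 50-cell
lattices.  Test fits shorten chains (e.g. 2 × 1500) where the quantity
under test is a posterior mean direction, which converges much faster
than tail quantities; the reproduction script `scripts/acceptance.py`
uses the full 2 × 5000 defaults.  Tolerances mirror the resolution of
each instrument: 1 voxel for centres, ~1° for angles from 24 px windows
(discretisation bias of central differences at 12 px stripe period is
≤ 0.5°), 1% for surface coefficients.

Degenerate inputs are defined, not special-cased: constant planes
normalise to zero with a warning; E = 0 forces C = 0; empty design cells
and empty ground truth raise with the offending cell named; a boundary
tie goes to the deeper layer.

## Known limitations

- No hierarchical (per-animal random-effect) circular model; pooled and
  per-sample fits only.
- No continuous covariates (e.g. tonotopic position).
- The regression's latent covariance is fixed to I; heteroscedastic
  extensions would require a different identifiability argument.
- Orientation is measured per window at pixel level; thick fibres weigh
  more than thin ones.  Segment-level statistics would need single-fibre
  segmentation, which this resolution does not support.
- The 2D analysis ignores through-plane fibre inclination entirely.
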