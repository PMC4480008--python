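# Methods

## Model

Brain tissue is a homogeneous background medium (n_medium = 1.34) containing
discrete, identical, independently scattering spheres representing cell
nuclei (n_nucleus = 1.35, diameter 4.0 μm by default). Light is a bundle of
rays launched on the skin plane (z = 0): positions from a 2-D Gaussian whose
1/e² radius equals the geometric footprint of the focusing cone
(focal_depth · tan(asin(NA/n_medium)), NA = 0.8), directions pointing
exactly at the focal point. Between events rays travel in straight lines;
free paths are exponential with mean 1/μ_s; each event rotates the direction
by a polar angle drawn from the single-sphere phase function with uniform
azimuth. Scattering is elastic and absorption-free: weights never change,
and the energy ledger (launched = forward-exit + backward-exit + capped)
closes to 10⁻⁹ in the tests.

Single-sphere optics come from the Lorenz–Mie series (unpolarized scalar
treatment, phase function ∝ (|S₁|²+|S₂|²)/2), truncated at the Wiscombe
length N = ⌈x + 4x^⅓ + 2⌉ and evaluated through SciPy's spherical Bessel
routines. The phase function is tabulated on 3600 uniform nodes on [0, π] —
enough to resolve the ~0.1 rad forward lobe of a 4 μm sphere at 488 nm — and
sampled by inverse interpolation of the trapezoidal CDF. An index-matched
sphere has zero cross-section; sampling an angle from it is an error by
design, since no event can occur.

For the reference nucleus: size parameter x ≈ 34.5, relative index
m ≈ 1.0075, σ_s ≈ 1.649 μm², g ≈ 0.9965. PVL preset (volume fraction 0.45):
μ_s ≈ 0.0222 μm⁻¹, mean free path ≈ 45 μm.

Because the transport is ray optics, diffraction is restored afterwards:
the accumulated fluence is convolved with the ideal beam waist, a Gaussian
of 0.13 μm transverse × 0.29 μm axial FWHM (the measured diffraction-limited
spot of the instrument this model emulates). Transverse convolution of the
azimuthally symmetric profiles is done exactly through the Hankel form of
the 2-D Gaussian (scaled Bessel I₀, numerically stable); axial convolution
is an ordinary 1-D convolution.

## Fluence recording and width estimators

Crossings are recorded on planes spanning the focus ± 6 μm at 0.02 μm
spacing, binned radially with non-uniform edges: 1.25 nm innermost bins,
5 nm steps to 0.1 μm, 20 nm to 1 μm, 0.1 μm to 12 μm.

* Transverse profile: azimuthal fluence at the focal plane, Hankel-convolved
  with the transverse waist, mirrored onto a signed axis through the peak.
* Axial profile: fluence inside a thin on-axis cylinder versus z, convolved
  with the axial waist.

The cylinder radius matters: the geometric cone contributes 1/Δz² axial
tails whose mass scales with the cylinder radius squared, biasing the
ballistic axial FWHM upward (+3% at r₀ = 5 nm, +0.4% at r₀ = 1.25 nm,
verified against the closed-form cone profile). The default is therefore
r₀ = 1.25 nm, the innermost bin. In the ballistic limit the estimators
return the ideal spot by construction (0.130 × 0.291 μm measured).

Threshold widths (50% and 10% of peak) are the full extent of the connected
region through the peak, with interpolated crossings. Two conventions are
computed: **local** (threshold relative to the profile's own peak — the
documented primary convention; at 50% it equals the FWHM by definition) and
**unscattered-referenced** (threshold relative to a supplied ballistic peak).
The second convention collapses at depth — the scattered peak is only
~0.07–0.11 of the ballistic reference, so the referenced threshold exceeds
the whole profile and the width is empty — which is why the local convention
is the one reported.

## Backscatter imaging

Every ray crossing a recording plane (1 μm spacing, focus ± 100 μm; 201
planes at 100 μm focus) is reflected specularly (z-direction mirrored) with
a per-plane amplitude `plane_reflectivity / n_planes` (default
10⁻⁴ / n_planes in arbitrary units; the physical per-plane reflectivity is
unknown and only relative scales matter) and transported back to the skin
with the same parameters. At z = 0, rays inside the collection cone
(sin θ ≤ NA/n_medium) are projected along their straight line to the focused
plane and deposited there: rays from a common out-of-focus point spread into
the geometric defocus disc of radius |Δz|·tan θ, so defocus blur emerges
per-ray rather than being applied as an explicit kernel — equivalent in the
mean to a per-record defocus kernel and consistent with the Monte Carlo
noise. The deposited image is convolved with the transverse waist, and
radial profiles are taken about the image centroid (searched within 2 μm of
the axis, robust to Monte Carlo jitter).

Skin reflection never enters the tissue volume (its in-tissue effect is a
uniform attenuation); it is an additive camera-side term: the beam footprint
on the skin, reflected and projected, is a Gaussian whose σ grows linearly
with focal depth and whose peak falls as 1/depth². The default
skin_reflectivity = 0.03 places the skin/brain crossover near 15–20 μm
depth, after which the total backscatter decreases smoothly and
monotonically — the model's curve has no sawtooth because the medium is
homogeneous at the ray level; the experimental sawtooth caused by individual
nuclei is outside this model's scope.

The nuclear refractive index can be calibrated by grid search against a
reference backscatter profile (unit-peak sum-of-squares discrepancy, common
random numbers across the grid). On self-generated references the objective
is V-shaped and recovers the generating index exactly
(`analysis/04_calibrate_refractive_index.py`).

## Synthetic confocal stacks

The DAPI-stack generator emulates the measurements that parameterise the
tissue model without any acquired data. Nuclei are axis-aligned ellipsoids
(default mean axes 4.84 × 5.68 × 2.6 μm with 10% size jitter) placed by
random sequential addition with voxel-exact overlap rejection; because plain
sequential addition of these shapes jams near fraction 0.28, candidates
shrink stepwise (floor 50%) after long runs of rejections, emulating nuclear
crowding and letting scenes reach the target fraction to <1%. The scene is
rasterized at 0.1 × 0.1 × 0.2 μm voxels (confocal z-interval 0.2 μm),
blurred with a Gaussian PSF surrogate (σ = 0.15 μm), and sampled with
Poisson photon noise (scale 200 counts) plus Gaussian read noise (σ = 2) on
a constant background (5 counts) — a realistic, moderately bright confocal
regime.

Morphometry follows the measurement procedures the tissue parameters rest
on: volume fraction by slice-wise pixel counting above a threshold (Otsu on
the full stack by default, with a contrast guard — splitting pure noise
yields a class contrast of ~3 background σ, so a 6 σ minimum contrast is
required before the threshold is trusted; a manual threshold can be
supplied), and per-nucleus diameters with X/Y as the maximal extent of each
connected component and Z as (slices containing the component) × 0.2 μm.
What the passing tests show: on synthetic scenes the fraction estimate lands
within a few percent of the voxel ground truth and Z diameters within one
slice for isolated nuclei. What they do not show: robustness to real
chromatin texture, anisotropic PSFs, touching-nucleus segmentation errors,
or the subjectivity of a manual ImageJ threshold — the generator's nuclei
are clean ellipsoids.

## Problem sizes and numerical choices

Default analysis sizes (chosen so the full suite and the acceptance run
complete comfortably on one CPU): 10⁵ rays for the ballistic reference,
3 seeds × 10⁶ rays for the scattered focal volume at 100 μm, 2.5–5 × 10³
rays per depth for backscatter scans (the imaging quantities are ratios of
smooth curves and converge much faster than the nanometre-scale widths).
The event cap is 10⁴ (never reached in practice for g ≈ 0.997 media at
these scales; breaches are counted and reported). One seeded generator
drives launch and transport in fixed order, so identical seeds give
bit-identical crossing records.

## Calibration of the PVL volume fraction, and a known limitation

The nuclear volume fractions of the PVL and neuropil have no published
values to adopt; the presets (0.45 and 0.02) are anatomically motivated
placeholders. A one-off calibration scans f ∈ [0.2, 0.55] against the
reported focal widths at 100 μm (0.16 μm transverse × 0.39 μm axial). The
objective is flat: across the entire admissible range the simulated widths
change by under 1% (`analysis/03_calibrate_volume_fraction.py`), so the
preset keeps 0.45.

That flatness is the model's central limitation. With σ_s ≈ 1.65 μm² the
mean free path is ≥ 37 μm for any admissible fraction, leaving ≥ 6% of rays
unscattered at 100 μm; and the forward lobe (≈ 0.1 rad) converts scattered
rays into a halo micrometres wide whose on-axis density is only ~1–2% of the
surviving ballistic core. The measured widths are therefore pinned near the
ideal-spot values (0.132 × 0.291 μm at 100 μm in the PVL) instead of the
reported 0.16 × 0.39 μm: within this model — nucleus-only, elastic,
position-and-direction ray scattering with diffraction restored by
convolution — no admissible nuclear density reproduces the reported
broadening, which presumably involves scatterer populations or wave-optical
effects outside the model. The acceptance suite reports these comparisons
honestly rather than adjusting the model to meet them. Two further caveats
are documented rather than resolved: the independent-scatterer
approximation is retained even at f = 0.45 (correlated packing would reduce
the effective μ_s), and the reported ideal-spot FWHMs we adopt as the
diffraction kernel (0.13/0.29 μm) are themselves below the textbook
diffraction limit for NA 0.8 at 488 nm, so they are treated as instrument
constants of the emulated setup, not derived quantities.
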