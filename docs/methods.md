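# Methods

## Scope

`protonlet` analyses voxel grids of proton physical dose [Gy] and
dose-averaged LET [keV/μm]: it combines per-beam LET maps into a composite,
thresholds them by dose, converts dose to variable-RBE-weighted dose with
the McNamara linear-quadratic model, and extracts structure-level
comparison metrics. It does not transport particles: the built-in
simulator is an analytical stand-in that produces grids with the *shape*
of Monte-Carlo output so the analysis chain can be exercised, tested and
demonstrated without patient data.

## LET mixing and thresholding

For beams b with dose d_b and LET L_b in a voxel, the composite
dose-averaged LET is Σ d_b L_b / Σ d_b. Voxels with no dose from any beam
have no defined LET and carry a NaN sentinel. LET-derived quantities are
only evaluated where the composite physical dose is at least a fraction
(default 5%) of the plan's maximum dose; below that, scored LET is
dominated by a handful of stray particles and is clinically irrelevant.
Two conventions had to be fixed here and are configuration, not physics:

* the 5% threshold is anchored to the **composite** (all-beam) maximum,
  not per-beam maxima, because thresholding happens after combination;
* the reference maximum is taken **within the body contour** when one is
  available, so a hot spot in immobilisation gear cannot shift the cutoff.

Excluded voxels propagate as "not in the evaluable volume": they are
omitted from every LET/vRBE statistic but keep their physical dose for
dose-only metrics.

## RBE model

The McNamara model with coefficients 0.99064, 0.35605, 1.1012 and
0.0038703 (RBEmax = c1 + c2·LET/(α/β); RBEmin = c3 − c4·√(α/β)·LET) is
evaluated per voxel at d = (voxel total dose)/(number of fractions),
i.e. uniform fractionation; the coefficients are overridable in the study
config. Numerical choices:

* RBEmin is floored at 0. Beyond ~280 keV/μm·√Gy the fitted linear form
  would go negative and feed a growing d² term back into the square root;
  clamping is the conservative extrapolation and only matters far outside
  the model's fitted range.
* d ≤ 0 is a domain error rather than a limit evaluation. Zero-dose voxels
  must be excluded upstream (the dose threshold does this), which keeps the
  1/d singularity out of the vectorised path.
* Setting RBEmax = RBEmin = c makes the discriminant a perfect square and
  the model returns c exactly (to floating-point rounding); with c = 1.1
  this is the degenerate fixed-RBE setting and the pipeline's strongest
  self-check, since every Δdose output must then vanish.

α/β is a single value per run (default 2 Gy, the conventional choice for
late-responding normal tissue; 3 and 10 Gy are run alongside for
sensitivity). Whether a different α/β should apply inside the target is an
open modelling question; the pipeline reports per-structure metrics for
each configured α/β rather than mixing values within one run.

## Comparison metrics

* **D(v cc)** sorts structure voxels descending, accumulates voxel volumes
  and linearly interpolates to the requested hot volume (0.1 cc default).
  The interpolation convention is a choice; a voxel-quantized variant is
  available behind a flag. A structure smaller than the hot volume raises
  a "structure too small" signal which the study records as a missing
  value — the default phantom deliberately contains a sub-0.1 cc
  coronary-artery-like structure to exercise this path.
* **DVHs** are cumulative, in % of the structure's evaluable volume, on a
  fixed axis (0 to 1.5 × prescription by default) so curves from different
  α/β runs are directly comparable.
* **Δdose maps** are voxel-wise vRBE-weighted minus fixed-1.1-weighted
  dose, with sentinels wherever the vRBE dose is undefined; Δdose ≥ 3
  Gy(RBE) volumes are reported both whole-grid and per structure. Nothing
  is clipped; display ranges are presentation only.
* **Overlap** is the volume with dose ≥ 80% of the (body-anchored) maximum
  AND LET ≥ 6 keV/μm, with the list of structures it intersects.
* **Coverage** is D98% ≥ 95% of prescription on the nominal physical dose.
* All volumes are voxel count × voxel volume, exactly; no sub-voxel
  geometry is attempted.

## The synthetic phantom and beams

The phantom is uniform water inside an elliptical body cross-section
(2 mm isotropic grid, 160×120×48 voxels by default) with ellipsoidal /
cylindrical structures in a mediastinal arrangement: an anterior CTV, the
heart directly posterior with a left-atrium-like substructure abutting the
CTV's posterior surface, lungs laterally, spinal cord and esophagus
posteriorly. Depth along a beam is the geometric path length from the body
surface (no heterogeneities, no HU calibration). Plans normalise the
composite CTV **median** dose to the 19.8 Gy / 11-fraction prescription —
TPS normalisation conventions vary and the median is insensitive to edge
voxels; the statistic is flagged in the config.

Depth dose is a pseudo-Bortfeld curve: a 1/(R−z)^0.23 power-law plateau
blended into a Gaussian peak at the residual range R, with a Gaussian
distal falloff of the straggling sigma (3 mm default). Depth LET is
anchored to a plateau value (1.2 keV/μm) at the surface, rises as
let_scale/(R−z+softening), is capped at 15 keV/μm and held at the cap
through the distal falloff. These four-parameter forms reproduce the
features the analysis is sensitive to — flat-ish plateau, sharp peak,
distal LET spike — with every parameter interpretable and testable.

Spread-out Bragg peaks come from non-negative least squares on the layer
weights against a flat target over the CTV depth interval (±3 mm range
margin, 3 mm layer spacing, ≤3% ripple; infeasible flatness warns and
returns the best fit). The lateral profile is a box aperture around the
projected CTV (12 mm margin) convolved with a 5 mm-sigma Gaussian
penumbra, cut off at the aperture plus three sigmas. Beam angles are axial
only (no couch kicks); rays are binned laterally at the in-plane grid
spacing, so oblique beams carry up to half-voxel depth quantisation —
irrelevant at the 2 mm grid but visible in bit-level comparisons.

Energy layers within a beam are combined with the same dose-weighted
mixing operation used across beams, so generation and analysis cannot
drift apart.

Generation is fully deterministic given the config; the seed is reserved
for optional phantom noise and is recorded in the outputs so every table
is reproducible byte for byte.

## What the synthetic study does and does not show

The default study (1F anterior; 2F ±10°; 2F-wide ±30°; 3F ±10° + 180°)
reproduces the qualitative geometry of concern: anterior beams stop in or
near the heart, so near-maximum heart/left-atrium LET is high for
anterior-only plans and drops when a posterior field dilutes the mix, and
vRBE-weighted near-maximum OAR doses exceed fixed-1.1 doses wherever the
mixed LET is high. Magnitudes are properties of the synthetic geometry,
not of any patient: the heart here *abuts* the target, so near-prescription
dose coincides with capped distal-edge LET and Δdose values run far above
what typical patient anatomies show; likewise the ≥80%-dose ∧ ≥6 keV/μm
overlap is tens of cc where patient studies report fractions of a cc,
because a single-field SOBP's distal edge sits inside the full-dose region
by construction. Passing the directional tests therefore validates the
machinery and the direction of the physics, not clinical magnitudes.
Other real-data features the simulator does not emulate: tissue
heterogeneity and range uncertainty (no robustness scenarios), scattering
tails and nuclear halo, TPS optimisation (fields are uniformly weighted),
and Monte-Carlo statistical noise.

## Problem sizes and tolerances

The default study runs four plans (eight beams) on a ~9.2×10⁵-voxel grid
in well under a minute on one core; unit tests use a 4 mm variant of the
same geometry. Oracle-equivalence tests compare vectorised metrics to
pure-Python loop implementations at 1e-9 relative on ≳100 random grids;
the degenerate fixed-RBE identity is asserted at 1e-12 relative, and
pipeline Δdose tables under degenerate coefficients at 1e-9 Gy(RBE)
absolute (floating-point square roots prevent exact zeros). DICOM RT Dose
round trips are checked to 1e-4 of the grid maximum, far above the actual
~1e-9 quantisation of the signed 32-bit encoding.
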