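# Methods

This note documents the models implemented in `tractprox`, the defaults
and why they were chosen, and what the synthetic data do and do not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate frame

All world coordinates are RAS millimetres in an AC-PC-aligned frame with
the intercommissural plane at z = 0; "4 mm ventral to the
intercommissural line" is therefore the plane z = −4, and it falls on a
voxel-center plane of the default grid. The pipeline assumes all inputs
(DWI, masks, electrode coordinates) already share one world frame;
registration is out of scope.

## Synthetic diffusion phantom

The phantom emulates the acquisition the analysis is designed for: one
b = 0 volume plus 30 diffusion-weighted volumes at b = 1000 s/mm², 2 mm
isotropic voxels, on a 24×18×30 grid. The 30 gradient directions are a
fixed electrostatic-repulsion table frozen in `gradients.py`
(reproducibility over optimality; minimum inter-axis angle 25.6°).

Each hemisphere contains one curved "DRT-like" bundle: a tube of radius
3.5 mm around a cubic-spline centerline running dentate → midline
decussation → red-nucleus level → past the STN at z = −4 → thalamus →
precentral end. Voxels whose centers fall inside the tube carry a prolate
tensor aligned with the local centerline tangent
(λ = (1.7, 0.3, 0.3)·10⁻³ mm²/s, FA ≈ 0.80); everything else is
isotropic at 0.8·10⁻³ mm²/s. There is deliberately no partial-volume
blending at the tube boundary: this keeps the tensor-fit oracle exact
(noiseless signal → fit recovers the generating tensor to numerical
precision).

**Decussation geometry.** A single-tensor voxel cannot represent two
crossing fiber populations, and a tracker whose local model is one axis
per location cannot traverse a symmetric X-crossing (the axis field at
the crossing is either biased toward one bundle or degenerates to the
bisector, which destroys the lateral momentum a streamline needs to
continue into the correct branch; both failure modes were observed
directly when a shared-voxel crossing was prototyped). The phantom
therefore lets the two bundles decussate at slightly different
anterior-posterior positions: the left bundle is the x-mirror of the
right one with a parabolic anterior shift (peak 9.5 mm, support
|x| < 4.5 mm of the mirrored centerline), so both bundles cross the
midline but their tubes pass adjacent to each other. The shift vanishes
where the bundles are lateral (the STN plane, the seed and dentate ends),
which keeps the electrode-level geometry mirror-symmetric; the left
red-nucleus ROI is placed on the left bundle's own (shifted) course. One
stray voxel of tube contact can remain where the descending limbs pass
diagonally; it is assigned to the nearer centerline. Real decussations
are genuinely harder than this; see Limitations.

ROIs are generated with the phantom: a precentral seed box at the
superior bundle end, red-nucleus boxes on each bundle at the midbrain
level, wide dentate boxes at the inferior ends (deliberately generous,
mirroring the coarse dentate segmentations typical of clinical data), and
an STN ellipsoid centered (±12, −4, −4) with semi-axes (3, 4, 3) mm —
anterolateral to the tract on the z = −4 plane, so the STN border lines
are well defined and the tract does not cross them in the noiseless
limit.

Noise is Rician: S = √((S₀ₛᵢ𝓰 + ε₁)² + ε₂²) with ε ~ N(0, σ²),
σ = S0/SNR, the standard magnitude-MRI model. Default SNR 20.

## Synthetic cohort

The cohort reproduces the enrolment structure the analysis assumes: 36
patients, all implanted bilaterally, 12 with strictly unilateral tremor,
so 60 of 72 hemispheres carry contralateral resting tremor and enter the
imaging analysis. Baseline items are drawn so every patient passes the
enrolment screen (some resting-tremor item ≥ 2 of 4). Electrodes have
four point contacts at 1.5 mm center-to-center spacing (1.0 mm contact
length + the 0.5 mm inter-contact gap) on a fixed oblique trajectory;
~85 % of hemispheres are monopolar, the rest bipolar or double-monopolar
(midpoint reference, flagged). The active-contact reference point is
placed on the z = −4 plane along the bundle→STN ray at a true distance
sampled uniformly from 0.2–4.4 mm of the tube surface, solved by
bisection on the analytic distance so the stored ground-truth distance is
exact.

Improvement follows a logistic distance-response curve,
E[fraction] = m / (1 + exp((d − d₀)/s)) with m = 100 %, d₀ = 2.4 mm,
s = 0.55 mm: stimulation essentially on the tract removes tremor,
stimulation far from it leaves tremor unchanged, and roughly three
quarters of hemispheres respond. Post scores are integer item sums with
additive Gaussian noise (σ = 0.6 items), clipped to the scale, so zero
and negative improvements occur. These values were chosen once so the
generated cohort reproduces the ordering and rough magnitude of a
realistic responder/non-responder distance split at the phantom's
measurement resolution; they are the study conditions of the test suite,
not fitted quantities. Under `null_model=True` the improvement is driven
by an independently resampled distance, cutting the link while keeping
both marginals — the type-I-error condition. A "linear" effect model
(`clip(1 − d/2d₀)`) is available for sensitivity checks.

Follow-up visits are at 1–7 months, one or two per patient; the analysis
takes the latest visit by default (configurable to earliest), since the
outcome of interest is established stimulation response rather than
early micro-lesional effects.

## Tensor fit

Plain unweighted log-linear least squares of
ln(S₀/Sᵢ) = b gᵢᵀ D gᵢ per masked voxel, S0 taken as the mean of all
b < 50 s/mm² volumes. No weighting and no outlier rejection: the
estimator is exact on noiseless data (giving the test suite a closed-form
round-trip oracle) and adequate at phantom SNRs. Voxels with any
non-positive signal or a non-finite solution are flagged invalid rather
than fatal; negative fitted eigenvalues are clamped to zero and the voxel
stays valid only while λ₁ > 0 (rare at SNR 20, avoids NaN propagation).

## Probabilistic tracking

The local direction model is an axial angular-Gaussian about the
principal eigenvector of the component-wise trilinearly interpolated
tensor: polar angle |N(0, σ)| with σ(FA) = σ_max(1 − FA), σ_max = 40°
default, azimuth uniform. This is the simplest dispersion law that is
monotone in FA; it is isolated in one routine and swappable. With
σ_max = 0 the tracker reduces to deterministic (FACT-like) tracking and
reproduces straight lines on uniform fields exactly — the deterministic
oracle in the test suite.

Streamlines propagate bidirectionally from start positions jittered
uniformly inside each seed voxel: Euler steps of 0.5 mm, termination on
interpolated FA < 0.15, on leaving the grid, on a per-step turn above
45°, or at half of the 250 mm length cap per half-track. Invalid voxels
hold zero tensors, so interpolation near them pulls FA below the stop
threshold and tracking terminates without a separate mask test. A
streamline is accepted iff it has at least one point inside every
waypoint mask, in any order; accepted streamlines increment each
traversed voxel at most once (the hit map counts supporting streamlines,
so revisits do not double-count).

Default 100 starts per seed voxel (the protocol this emulates used
100,000; any value can be configured — the scaled-down default is a
desk-scale choice, and the acceptance checks run at 50). Randomness is
organized in per-streamline counter-derived substreams keyed by (seed,
seed-voxel index, start index): results are bit-reproducible and
independent of seed-voxel iteration order, and the lockstep vectorized
propagation is exactly equivalent to tracking streamlines one at a time.

## Boundary standardization and distance

The manual procedure being formalized raises display contrast until the
tract signal no longer crosses lines drawn along the medial and posterior
STN borders on the z = −4 plane. Thresholding the hit map at an integer
τ is the only monotone, automatable equivalent: τ\* is the smallest τ ≥ 1
such that no voxel with count ≥ τ on that plane lies strictly inside the
open STN-side half-plane of either border line (medial line through the
most medial STN voxel center, running anterior-posterior; posterior line
through the most posterior, running medial-lateral; laterality from the
STN centroid). Because violating voxels are fixed, τ\* is simply one more
than their largest count, which an exhaustive-sweep oracle confirms in
the tests. On which side the tract signal was trimmed is a convention
here, not a reconstruction: the open half-plane containing the STN.

Distance is measured from the active-contact reference point to
face-connectivity boundary voxel centers of the binarized tract, in the
plane perpendicular to the electrode axis (axis taken from the contact
geometry): minimum in-plane norm over boundary centers within a slab of
half-thickness h around the plane. h defaults to half a voxel of the
grid (1 mm at the phantom's 2 mm resolution) — with a tilted axis a
thinner slab misses every boundary center of the contact's own image
plane; an empty slab widens stepwise to a 3 mm cap and flags the record,
beyond which the distance is missing and the hemisphere is excluded
downstream. A reference point inside the mask scores 0. Measuring to
boundary voxel centers (not an interpolated surface) bounds the
discretization error by half a voxel diagonal (≈1.73 mm at 2 mm voxels)
and in practice adds a small positive offset relative to the continuous
surface; the error bound is stated with the outputs.

## Tremor scoring

Five resting-tremor items (right/left arm, right/left leg, lips/jaw),
0–4 each, are the only decomposition consistent with a global maximum of
20 and a per-side limb maximum of 8; percentages divide by those maxima.
Improvement is the pre-minus-post percentage difference; zero or negative
change is "no improvement". A hemisphere is analyzed only if the
contralateral limb item sum was positive at baseline. The
tremor-subtracted UPDRS-III score (total minus resting-tremor sum) is
available for the motor-outcome comparison that controls for tremor
itself.

## Statistics

All p values are two-sided. Mann-Whitney uses midranks; the p value is
exact by enumeration of group assignments when n₁+n₂ ≤ 12 with no ties,
otherwise the normal approximation with tie and continuity corrections
(via scipy). Wilcoxon drops zero differences (Wilcoxon's original rule —
this changes n and is recorded), midranks |d|, and enumerates the 2ⁿ sign
patterns exactly up to n = 12. Spearman is the Pearson correlation of
midranks with Rs² reported; exact permutation p up to n = 8, otherwise
the t approximation. The normality-gated comparison applies Shapiro-Wilk
at α = 0.05 per group and routes to Welch's t test only if both pass,
recording the route taken. Group summaries use linear-interpolation
(type-7) percentiles; the sd of a single observation is reported as NaN.
No multiple-testing correction is applied, and hemispheres are treated as
independent observations — both deliberate mirrors of the analysis this
package reproduces, not statistical recommendations.

## Problem sizes and runtime

The default test run uses the 24×18×30 phantom at SNR 20, 50 starts per
seed voxel (≈900 streamlines per hemisphere), 60-hemisphere cohorts, 100
pipeline replicates for the recovery check and 1000 statistics-only
replicates for the type-I-error check; the full suite completes in
minutes on one CPU. These sizes are the package's chosen operating point
for verifiable-by-default testing; all of them scale up by configuration.

## Limitations

- The phantom contains no eddy-current, susceptibility, or motion
  artifacts (the preprocessing that removes them in real data is out of
  scope), no multi-compartment voxels, and its decussation is geometric
  avoidance rather than a true fiber crossing — passing tests demonstrate
  the pipeline's correctness on well-posed single-tensor geometry, not
  robustness to crossing-fiber ambiguity in real midbrain data.
- Contacts are points; segmented (directional) electrodes and
  volume-of-activated-tissue models are not represented.
- The distance estimate carries a voxelization offset of up to half a
  voxel diagonal toward larger values; comparisons between groups are
  unaffected, absolute distances should be read with that bound.
- The synthetic cohort's effect-model parameters set the *conditions*
  under which recovery is tested; they do not calibrate the method to any
  particular dataset.
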