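# Methods

## Coordinate and beam conventions

All volumes live on regular axis-aligned voxel grids in the DICOM patient
frame (LPS, millimetres), with 0-based indices in axis order
(x, y, z) = (column, row, slice).  Gantry angles follow IEC 61217: 0° puts
the source anterior to a supine patient (−y), angles increase clockwise
viewed from the foot of the couch, so 90° is the patient's left (+x).
Beams are coplanar (axial plane through the isocenter); nonzero couch
angles are read but only flagged.  CT, structures, plan and dose of one
case are assumed to share a DICOM frame of reference, so alignment is the
identity transform on patient coordinates; a registration algorithm is
deliberately out of scope and a frame mismatch is treated as an input
error.

## Geometric beam mask

Each beam is modeled as a point source at SAD (default 1000 mm, the
clinical linac standard; not otherwise constrained by the protocol, so it
is a parameter).  The beam's-eye-view aperture is the convex hull of the
perspective projection of all PTV voxel centers from the source onto the
plane through the isocenter perpendicular to the beam axis.  The hull's
boundary rays graze the PTV point cloud, which realizes "tangent to the
PTV through the isocenter"; the convex hull (rather than a possibly
concave outline) is the minimal aperture all of whose boundary rays are
tangent to the target.  A voxel belongs to the beam iff the ray from the
source through its center crosses the isocenter plane inside the polygon
— a full 3D divergent cone, since a point source diverges cranio-caudally
as well as in-plane (a per-slice 2D fan is the rejected alternative).
Boundary hits count as inside (deterministic tie-break).  Per-beam binary
masks are summed and linearly rescaled so the maximum voxel equals the
plan's prescription (default 50.4 Gy); the integer overlap counts are kept
alongside.  By construction every PTV voxel projects inside every
aperture, so the pre-rescale maximum equals the beam count and rescaled
PTV voxels carry exactly the prescription.  The mask is not clipped to the
body by default (clipping is an option), since the beam path itself is not
body-limited.

Degenerate targets (single-voxel or collinear PTVs) would give a zero-area
hull; the aperture then falls back to the projected voxel-corner
footprint.

## Synthetic phantoms and the analytic dose engine

The phantom emulates a pelvic planning CT: an elliptical body (semi-axes
70 × 55 mm in-plane), a central spherical PTV (radius 16–24 mm across the
catalog), bladder anterior, rectum and spinal cord posterior, femoral
heads lateral, each with tissue-plausible HU means plus Gaussian noise
(SD 15 HU).  The body outline is shifted 6 mm posterior of the isocenter,
making the pelvis anterior–posterior asymmetric (a thinner anterior
wall).  This matters: prone positioning is modeled by flipping the
phantom anterior↔posterior and left↔right in the fixed gantry frame, and
without the A–P asymmetry a flipped phantom would present beams with
identical radiological depths, leaving patient position without physical
consequence.  Any ROI escaping the body under requested geometry is a
hard error.

Ground-truth dose is analytic, not clinical: per beam, dose along each
source ray is `weight · exp(−μ · depth-in-body) · profile`, where depth is
the exact ray–ellipsoid path length inside the body, μ = 0.005 mm⁻¹
(roughly water at megavoltage energies), and the profile is 1 inside the
BEV aperture with a linear rolloff to 0 over a 5 mm penumbra.  Beams are
summed and globally scaled so the PTV mean equals the prescription
exactly.  The engine's only job is to make dose a deterministic,
beam-setting-dependent function of anatomy so that beam-setting effects
are learnable; it has no scatter, no heterogeneity corrections, no MLC
modulation, and no claim to clinical accuracy.

The default catalog mirrors the emulated clinical mix: 46 fixed-angle
supine 7-beam plans (the homogeneous stratum, angles
0/50/100/150/210/260/310°), 167 jittered-angle supine 7-beam, 21 nine-beam
and 45 prone plans in the training pool, plus 9/12/13 held-out test cases
for the three experiment families.  All stratum sizes scale by one factor
(ceiling-rounded) for desk-scale runs.  Jittered plans perturb equispaced
base angles by a seeded uniform offset within ±15°; the ±15° width is this
package's choice (the angle spread of a non-homogeneous clinical catalog
is not otherwise specified) and is a parameter.  Every generator is
deterministic under its seed.

## Data preparation

CT volumes are standardized to mean 0 / variance 1 (population variance,
whole 3D matrix; body-only statistics were rejected to keep the transform
a fixed function of the stored volume).  Contours are rasterized per slice
with a voxel-center-inside scanline fill under the even-odd rule (nested
contours punch holes; self-intersections resolve deterministically with a
warning).  Resampling onto the dose grid (default 2.5 mm) is trilinear for
intensities and nearest-neighbor for labels, with edge-value extension;
standardization happens after resampling (the alternative order is a
one-line change).  Assembled samples stack channels in the fixed order
[CT, bladder, body, femoral_head_l, femoral_head_r, ptv, rectum,
spinal_cord] with the beam mask appended last when used.  The beam-mask
channel is fed in Gy as rescaled, not re-standardized: the rescale to the
prescription already places it on the scale of the dose targets.

## DVH indices and δ errors

DVHs are exact sort-based curves (no dose binning): V(d) is the fraction
of masked voxels with dose ≥ d.  Dp is an order statistic — the largest
voxel dose received by at least p% of the structure — rather than an
interpolated value, so every index is reproducible from voxel doses alone
and checkable against exhaustive counting.  Dmax/Dmean are the masked
maximum and mean; V30 is reported as percent of structure volume.  The 14
evaluation indices comprise five PTV indices, three each for bladder and
rectum, and Dmax of the spinal cord and of each femoral head separately
(the only reading that totals 14).  δ errors divide the absolute
index difference by the prescription (so V30 differences, in percentage
points, are likewise expressed relative to prescription).  Aggregates are
reported per structure and overall; the "% of best prediction" averages
each index over test cases first, then credits the model(s) with the
smallest mean — ties credit all tied models, which keeps the score
deterministic.

## Dose-prediction model

No deep-learning framework is part of this package's dependency set; the
predictor is a compact, fully deterministic numpy network.  Each voxel is
described by its input channels, Gaussian-smoothed copies of every
channel at two scales (σ = 2 and 6 voxels; local and regional context),
and its room-frame coordinates normalized to [−1, 1].  The coordinate
features matter scientifically: they give the model the fixed-gantry-frame
spatial awareness a convolutional network has, so learned dose patterns
are tied to room position and anatomy presented in an unfamiliar
orientation (a prone patient after supine-only training) is genuinely out
of distribution.  Features pass through a small fully connected ReLU
network (default 32×32) trained with Adam on voxelwise mean absolute
error.

Training draws a seeded, stratified voxel subsample per case (quarters
from the PTV, the OAR union, the body, and the whole volume) and runs a
fixed number of optimizer steps per epoch regardless of training-set
size, so designs with different case counts receive the same optimization
budget — the analogue of training each model to its own convergence.
Fine-tuning continues from a saved bundle's weights and frozen feature
scaler (zero epochs returns an identical copy); the suite's default
fine-tuning budget is half the from-scratch epochs.  Everything is
bit-reproducible under (seed, config) in a fixed environment, and bundles
round-trip losslessly through npz + JSON.

## Experiment designs

Fifteen built-in designs cover four families: (1) full catalog vs
homogeneous subset vs full-then-fine-tune, tested on fixed-angle supine
cases; (2) the 2×2 of {homogeneous 46, mixed-angle 213} × {with, without
beam mask}; (3) beam-number homogeneity tested on 9-beam cases; (4)
position homogeneity tested on prone cases.  The suite runner trains
designs on demand (a fine-tuned design pulls in its base), verifies
train/test case-id disjointness, and reports per-(design, seed) mean ± SD
δ plus best-model fractions per test stratum.

Desk-scale problem sizes used by the tests and the acceptance script:
32×32×16 grids at 5 mm, catalog scale 0.1 (30 training cases), 20 epochs
× 50 steps, three model seeds — chosen so a full directional comparison
completes in minutes on one CPU while leaving the directional effects
resolvable.  The directional findings (beam mask helps under mixed
angles; fine-tuning the full-catalog model on the homogeneous subset
helps; cross-position generalization degrades) are asserted as
majority-of-seeds properties, not fixed margins.  At this scale the
fine-tuning comparison (1-3 vs 1-1) is the noisiest of the three: its
margin is small relative to seed-to-seed variation, and individual
catalog seeds can invert it even though the majority direction holds.

## Known limitations

- The dose engine is a geometric caricature; absolute δ values carry no
  clinical meaning, only comparisons between designs run under identical
  conditions.
- Phantom anatomy is convex, piecewise-constant and left-right symmetric;
  none of the texture, organ deformation or contouring variability of
  real data is emulated.  Passing tests demonstrate the machinery and the
  direction of data-selection effects under controlled conditions, not
  clinical performance.
- The voxelwise predictor has no receptive-field hierarchy; it stands in
  for a volumetric CNN only to the extent the experiments need a
  trainable, deterministic dose regressor.
- DICOM support covers identity-orientation axial series with a shared
  frame of reference; writing clinical DICOM is out of scope.
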