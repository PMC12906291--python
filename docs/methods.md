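# Methods

`bonereg` registers a 2D histological section of an osteotomized long bone
(an SHG collagen image, optionally with a co-acquired Osterix channel) into
a 3D μCT volume, corrects the sectioning distortion elastically, scores the
fit, and measures nearest distances between signal channels. Everything is
testable without animal data through a synthetic phantom with known ground
truth. This note records the models, the parameters that matter, and the
design choices made where the problem left the design open.

## Coordinate conventions

Volumes are indexed `(z, y, x)`, 2D images `(row, col)`; indices are
0-based, and the world coordinate of an index is `origin + index * spacing`
(μm), with world vectors stored in the same component order as the array
axes. A cutting plane is a world point (mapped to the section's centre
pixel) plus an orthonormal in-plane frame: `axis_u` along columns, `axis_v`
along rows, `normal = axis_u x axis_v` (cross products use the stored
component order throughout — the conventions are self-consistent as long as
one helper computes them, which is the case).

## The synthetic phantom

The phantom emulates a mouse-femur osteotomy at desk scale:

* **Volume**: 128^3 voxels at 10.5 μm (the μCT resolution of the imagined
  acquisition), containing a hollow diaphysis along x: an elliptical
  cortical shell (outer y semi-axis 420 μm, ellipticity 1.25, cortex
  intensity 1.0, marrow 0.15), a 0.7 mm transverse osteotomy gap, a
  longitudinal ridge on the outer surface (linea aspera analogue, 70 μm
  high at azimuth 30°), an endosteal surface whose centre is shifted by
  (100, 70) μm in (z, y) (uneven cortical thickness), and two fixator
  pin holes (radius 70 μm, drilled along y at ±490 μm from the gap
  centre, 60 μm off the bone axis). Partial-volume blur of 1 voxel and
  Gaussian noise (sd 0.05) are added.
* **Why the asymmetries are load-bearing**: a circularly symmetric tube is
  *unidentifiable* — every rotation of a cutting plane about the bone axis
  cuts an identical section, so no algorithm could recover "the" plane.
  The ellipse, the ridge, the shifted endosteal centre and especially the
  pin holes (whose notch widths vary steeply with local cut depth) are the
  features that make the pose observable, exactly as anatomy and surgical
  hardware do in the real data.
* **Section**: the ground-truth plane is a longitudinal cut 120 μm off the
  bone axis, tilted `plane_tilt` degrees from the volume z axis at a
  seeded azimuth. The SHG analogue samples the analytic geometry at 1/8 of
  the volume spacing (1.3 μm; the study's modality gap is 10.5 μm μCT vs
  0.6 μm SHG), textures the cortex with band-limited noise elongated along
  the bone (fibrous collagen; intensities deliberately differ from μCT so
  registration cannot match raw intensity), warps it with a smooth random
  sectioning distortion (2–4 Gaussian bumps plus a weak global shear,
  rescaled to RMS `warp_amplitude`, default 2 fine pixels), and stacks it
  with depth-dependent defocus (Gaussian blur 1.2 px per slice from the
  focal index, attenuated 25 % per slice for confocal pinhole rejection).
* **OSX analogue**: punctate Gaussian blobs planted at a controlled
  distance (default 20 μm) from the cortex surface and warped identically.
* All randomness derives from one seed through independent `SeedSequence`
  streams, so the noise level never moves the ground truth.

The phantom emulates geometry, modality contrast, distortion and defocus;
it does **not** emulate trabecular bone, woven callus, staining variability
or imaging artefacts, so green tests demonstrate correctness of the
algorithms under controlled conditions, not performance on arbitrary real
data.

## Slice-to-volume search

1. **Templates.** The max-projected section is downsampled to the volume
   resolution, Otsu-segmented and morphologically closed; components at
   least 5 % of the largest are kept (gap and pin holes fragment the two
   cortices). 360 boundary landmarks are sampled uniformly by arc length
   with subpixel gradient orientations, and an R-table (5° bins, offsets
   to the landmark centroid) is built. The volume is reduced to an edge
   cloud: voxels above the 95th percentile of gradient magnitude (capped
   at 2500 strongest), with unit gradient directions.
2. **GHT.** Candidate orientations combine a Fibonacci grid of normals in
   a ±25–30° cone about the nominal section normal with uniformly stepped
   in-plane rotations. For each orientation, edge points whose gradients
   lie within 30° of the plane cast R-table votes *at their own depth
   along the normal*, so one 3D accumulator localizes the in-plane
   reference point and the plane offset simultaneously. Votes are
   trilinearly splatted (cells 1.5 downsampled voxels) to avoid peak
   fragmentation, and all in-plane rotations of one normal share a single
   weighted bincount.
3. **Verification.** Long straight cortical edges blunt the vote counts
   (aperture problem), and a peak's cell is only grid-accurate, so the top
   ~250 peaks are re-scored: each extracted slice mask is aligned to the
   section mask by FFT cross-correlation (plus a depth sweep along the
   normal for the leading 40) and scored by Dice.
4. **Refinement.** The best few candidates get (a) a coarse grid
   refinement over tilt/rotation/depth with closed-form translation at
   every node and a Powell polish of the soft-mask NCC, then (b)
   deterministic coordinate scans (tilt pairs, depth, in-plane rotation,
   plus an in-plane *shear nuisance* applied to the section mask that
   absorbs the coherent component of sectioning distortion) at half-voxel
   and then capped near-native resolution. The final winner is chosen by
   native-resolution mask Dice — competing near-miss basins are separated
   by only a few thousandths of Dice, so selection must happen at the
   sharpest scale. This bounded local search replaces the original
   workflow's manual rotation step.

Scale is never searched: both modalities carry calibrated spacing.

## Elastic correction and Jacobian

The extracted μCT slice (moving) is registered to the section (fixed) with
a B-spline free-form deformation through SimpleITK's registration
framework: NCC on 2 px Gaussian-blurred images (Mattes mutual information
available as `mattes_mi`), dense sampling (deterministic), LBFGSB, 3
shrink levels, one control grid of spacing width/8. Control-point
displacements are box-bounded to 0.4× the control spacing, which
guarantees an invertible transform (positive Jacobian) even in signal-free
background; this replaces an explicit bending-energy penalty, which the
framework does not expose. The displacement field lives on the fixed grid
(`registered(x) = moving(x + u(x))`), so on the phantom it estimates the
planted distortion directly; `jacobian_determinant` evaluates
`det(I + ∇u)` by central differences in physical units.

## Split metrics

The osteotomy gap contains tissue the two modalities render differently,
so Dice and SSIM are evaluated on the proximal and distal fragments only
and averaged: `DSC = (DSC_proximal + DSC_distal)/2`, likewise SSIM. The
gap is localized from the foreground density profile along the principal
axis of the union mask: the longest interior low-density run (below 25 %
of the profile maximum), dilated by 10 % of its width; a connected mask
falls back to a flagged midpoint split. Dice and SSIM use segmented
images (masks cast to float with dynamic range 1, uniform 7 px window,
K1 = 0.01, K2 = 0.03); Jacobian summaries come from the raw-image
deformation field. Empty-region Dice is 1 when both masks are empty and 0
when one is.

## Proximity analysis

Per channel, the best-focused stack slice is the variance-of-Laplacian
argmax (ties to the lowest index). Positive signal is the strict Otsu
threshold of a 256-bin histogram, with the threshold placed at the upper
edge of the last background bin so the partition matches the
variance-optimal one exactly. For every positive query pixel the minimum
Euclidean distance (μm) to the positive target pixels is computed by
streaming query rows in blocks against one KD-tree over *all* target
pixels — the block size is purely a memory knob and never changes the
result. A `within_block_only` variant reproduces the literal per-block
reading (which biases distances upward near block borders) for
comparison. Distance distributions are compared with the two-sided
Mann–Whitney rank-sum test (exact for small samples), starred at
.05/.01/.0001.

## Problem sizes and numerical choices

The default phantom (128^3 voxels, 768×1024 section) runs the full
pipeline in a few minutes on one core; the plane-recovery study uses a
reduced search grid (6° orientation cone step, 15° in-plane step) over the
full-resolution phantom, about half a minute per case. Deliberate
tie-breaks: GHT peaks by votes, then smaller tilt, then orientation index;
focus ties to the first slice; component ranking by area. Degenerate
inputs (constant images, empty masks, planes outside the volume) raise
informative errors or return flagged fallbacks as documented per function.

## Known limitations

* The recovered in-plane pose has a near-180° ambiguity when the section
  is almost 2-fold symmetric; the phantom's asymmetric cortical thickness
  resolves it, and heavily symmetric real sections would need an operator
  hint.
* Verification and refinement assume the cortices dominate the section's
  segmentation; sections whose gap tissue is as bright as cortex would
  need the segmentation parameters revisited.
* The elastic stage corrects smooth distortions up to roughly the control
  spacing; tears and folds are out of scope.
* Recovery tolerances were validated on the phantom's geometry; data with
  far less azimuthal structure (e.g. intact bones without hardware) are
  intrinsically harder, see the identifiability note above.
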