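# bonereg

Slice-to-volume registration of 2D bone histology into 3D micro-CT, with
split overlap metrics and nearest-distance co-localization analysis.

## The problem

Bone healing studies image the same sample with modalities that see
different tissues: micro-CT (μCT) shows the mineral phase (hydroxyapatite)
in 3D, while histological sections — second-harmonic-generation (SHG)
imaging for fibrillar collagen and immunostaining for Osterix (OSX), an
osteoblast marker — show soft-tissue structure in 2D at much higher
resolution. Relating them requires finding, inside the μCT volume, the
exact oblique plane along which the physical section was cut, and then
correcting the smooth distortion that sectioning inflicts on the tissue.
`bonereg` automates that workflow for osteotomized long bones, whose two
bright cortices (split by the fracture gap into proximal and distal
fragments) are the structure shared by both modalities.

## What it does

1. **Plane search (generalized Hough transform).** The section's cortex
   outline becomes a template: boundary landmarks with gradient angles,
   packed into an R-table. The volume becomes a 3D edge cloud. For every
   candidate plane orientation, edge points with in-plane gradients cast
   R-table votes at their own depth, so a single 3D accumulator localizes
   both the in-plane position and the plane offset. Top peaks are verified
   by mask overlap and refined by a bounded local search over plane tilt,
   depth and in-plane pose.
2. **Elastic correction.** The extracted μCT slice is registered 2D-2D to
   the section with a B-spline free-form deformation (SimpleITK backend),
   yielding a dense displacement field.
3. **Evaluation.** Overlap is scored on segmented images with the gap
   omitted:

       DSC  = (DSC_proximal  + DSC_distal)  / 2
       SSIM = (SSIM_proximal + SSIM_distal) / 2

   and the deformation field's Jacobian determinant `det(I + ∇u)`
   summarizes sectioning distortion (1 = none, <1 compression,
   >1 expansion).
4. **Proximity analysis.** Per channel, the best-focused Z-stack slice
   (variance of Laplacian) is Otsu-thresholded; for every positive pixel
   of one channel the minimum Euclidean distance (μm) to the positive
   pixels of another is computed blockwise (block size is a pure memory
   knob), and distance distributions are compared with the Wilcoxon
   rank-sum test.

Because the original animal data are not redistributable, the package
ships a first-class synthetic phantom (`bonereg.phantom`): an osteotomized
elliptical diaphysis with a ridge, uneven cortical thickness and fixator
pin holes, a known ground-truth cutting plane, a planted sectioning
distortion and defocus Z-stacks — enough structure to make the cutting
plane identifiable and every stage testable against ground truth.

## Worked example

```python
import numpy as np
from bonereg import (PhantomSpec, make_phantom, max_projection,
                     find_cutting_plane)

spec = PhantomSpec(plane_tilt=10.0, seed=0)      # 128^3 μCT at 10.5 μm
bundle = make_phantom(spec)
section = max_projection(bundle.shg_stack)        # 768x1024 at 1.3 μm

plane, affine, info = find_cutting_plane(bundle.volume, section,
                                         orientation_step=6.0, psi_step=15.0,
                                         cone_deg=25.0)
truth = bundle.true_plane
angle = np.degrees(np.arccos(abs(plane.normal @ truth.normal)))
offset = abs((plane.center - truth.center) @ truth.normal)
print(f"normal error {angle:.2f} deg, offset {offset:.1f} um,"
      f" mask Dice {info['final_dice']:.3f}")
```

prints (seed 0):

```
normal error 0.26 deg, offset 1.9 um, mask Dice 0.962
```

i.e. the cutting plane of the synthetic section is recovered to about a
quarter of a degree and a fifth of a voxel, and the extracted μCT slice's
cortex mask overlaps the section's at Dice 0.96.

The full pipeline (simulate → register → elastic → metrics → proximity)
runs from one YAML config:

```bash
bonereg simulate --out phantom/ --seed 0 --tilt 10
bonereg run --config config.yaml --out results/
```

writing the found plane (JSON), extracted and warped slices (TIFF), the
deformation field (NRRD), metrics (CSV) and per-pixel distances (CSV).
Re-running a config reproduces every numeric artifact bit for bit.

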