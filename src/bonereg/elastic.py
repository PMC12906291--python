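"""2D-2D deformable registration and Jacobian-determinant evaluation.

The sectioning distortion of a histological cut is corrected by a B-spline
free-form deformation registered between the extracted μCT slice and the
section image. The optimization (coarse-to-fine, LBFGSB, dense sampling —
hence deterministic) is delegated to SimpleITK's registration framework;
the default similarity is normalized cross-correlation on Gaussian-blurred
images, with Mattes mutual information as the cross-modality option.
Regularization is implicit: a coarse control-point grid keeps the
deformation smooth, and control-point displacements are box-bounded to
0.4x the control spacing, which guarantees an invertible (positive-
Jacobian) transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .imagecore import DeformationField, SectionImage

__all__ = ["BSplineGrid", "elastic_register", "apply_field", "jacobian_determinant"]


@dataclass
class BSplineGrid:
    """B-spline transform configuration.

    ``control_spacing`` is the physical distance between control points at
    the *finest* level (μm); ``None`` derives it as image_width / 8.
    ``levels`` multi-resolution levels halve the image and double the
    control spacing per coarser level.
    """

    control_spacing: float = None
    levels: int = 3
    iterations: int = 40
    blur_sigma_px: float = 2.0

    def __post_init__(self):
        if self.control_spacing is not None and self.control_spacing <= 0:
            raise ValueError("control_spacing must be > 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


def _to_sitk(img: SectionImage):
    im = sitk.GetImageFromArray(np.asarray(img.data, np.float64))
    im.SetSpacing((float(img.spacing[1]), float(img.spacing[0])))  # (x=col, y=row)
    return im


def elastic_register(fixed: SectionImage, moving: SectionImage,
                     grid: BSplineGrid = None, metric: str = "ncc"):
    """Register ``moving`` onto ``fixed`` with a multi-level B-spline FFD.

    Returns ``(DeformationField, warped_moving)``. The displacement field
    lives on the fixed grid: pixel ``x`` of the registered image was sampled
    from ``x + u(x)`` in the moving image, so on the phantom it directly
    estimates the planted sectioning distortion. Deterministic for a fixed
    config (dense metric sampling, single-threaded execution).
    """
    if fixed.shape != moving.shape or fixed.spacing != moving.spacing:
        raise ValueError("fixed and moving must share shape and spacing "
                         "(resize_to_section first)")
    if grid is None:
        grid = BSplineGrid()
    control = grid.control_spacing
    if control is None:
        control = fixed.shape[1] * fixed.spacing[1] / 8.0

    fdat = np.asarray(fixed.data, float)
    mdat = np.asarray(moving.data, float)
    if grid.blur_sigma_px > 0 and metric == "ncc":
        fdat = ndimage.gaussian_filter(fdat, grid.blur_sigma_px)
        mdat = ndimage.gaussian_filter(mdat, grid.blur_sigma_px)
    f_im = _to_sitk(SectionImage(fdat, fixed.spacing))
    m_im = _to_sitk(SectionImage(mdat, moving.spacing))

    extent = np.array([fixed.shape[1] * fixed.spacing[1],
                       fixed.shape[0] * fixed.spacing[0]])  # (x, y)
    levels = int(grid.levels)
    # one control mesh for all levels: LBFGSB requires a constant parameter
    # count, so coarse levels regularize through image smoothing instead of
    # a coarser grid
    mesh = np.maximum(1, np.round(extent / control).astype(int))
    tx = sitk.BSplineTransformInitializer(f_im, [int(mesh[0]), int(mesh[1])])

    reg = sitk.ImageRegistrationMethod()
    if metric == "ncc":
        reg.SetMetricAsCorrelation()
    elif metric == "mattes_mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    # bound control-point displacements to 0.4x the control spacing: a
    # B-spline FFD below that bound is guaranteed invertible, so the
    # Jacobian determinant stays positive even where the images carry no
    # signal to constrain the optimization
    bound = 0.4 * control
    reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-7,
                             numberOfIterations=int(grid.iterations),
                             maximumNumberOfCorrections=5,
                             maximumNumberOfFunctionEvaluations=2000,
                             costFunctionConvergenceFactor=1e7,
                             lowerBound=-bound, upperBound=bound)
    shrink = [2 ** (levels - 1 - i) for i in range(levels)]
    smooth = [max(0.0, s / 2.0) for s in shrink]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(smooth)
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetNumberOfWorkUnits(1)
    try:
        reg.Execute(f_im, m_im)
    except RuntimeError as exc:
        raise RuntimeError(f"elastic registration failed: {exc}") from exc
    if not np.isfinite(reg.GetMetricValue()):
        raise RuntimeError("elastic registration produced a non-finite metric "
                           "(empty image overlap?)")

    ref = _to_sitk(fixed)
    disp_im = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, ref.GetSize(), ref.GetOrigin(),
        ref.GetSpacing(), ref.GetDirection())
    disp_xy = sitk.GetArrayFromImage(disp_im)  # (rows, cols, (dx, dy))
    displacement = np.stack([disp_xy[..., 1], disp_xy[..., 0]], axis=-1)  # (dr, dc)
    field = DeformationField(displacement=displacement, spacing=fixed.spacing)

    warped = sitk.Resample(_to_sitk(moving), ref, tx, sitk.sitkLinear, 0.0)
    warped_img = SectionImage(data=sitk.GetArrayFromImage(warped),
                              spacing=fixed.spacing)
    return field, warped_img


def apply_field(field: DeformationField, img: SectionImage) -> SectionImage:
    """Resample ``img`` through the field: out(x) = img(x + u(x))."""
    if img.shape != field.shape:
        raise ValueError("image and field shapes differ")
    rows, cols = img.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr + field.displacement[..., 0] / field.spacing[0],
                       cc + field.displacement[..., 1] / field.spacing[1]])
    out = ndimage.map_coordinates(np.asarray(img.data, float), coords, order=1,
                                  mode="constant", cval=0.0)
    return SectionImage(data=out, spacing=img.spacing)


def jacobian_determinant(field: DeformationField) -> np.ndarray:
    """Per-pixel det(I + ∇u) of the displacement map, gradients by central
    differences in physical units (one-sided at the borders).

    1 means no local area change, < 1 compression, > 1 expansion.
    """
    u = field.displacement
    dr, dc = field.spacing
    dur_dr, dur_dc = np.gradient(u[..., 0], dr, dc)
    duc_dr, duc_dc = np.gradient(u[..., 1], dr, dc)
    return (1.0 + dur_dr) * (1.0 + duc_dc) - dur_dc * duc_dr
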