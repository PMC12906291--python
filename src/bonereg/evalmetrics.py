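"""Registration-quality metrics: split Dice, split SSIM and Jacobian
summaries.

Because the osteotomy gap contains tissue that the two modalities render
very differently, overlap scores are evaluated only on the proximal and
distal cortical fragments: the image is split along the bone axis, the gap
band is omitted, and the final score is the arithmetic mean of the two
region scores:

    DSC  = (DSC_proximal  + DSC_distal)  / 2
    SSIM = (SSIM_proximal + SSIM_distal) / 2

Dice and SSIM are computed on *segmented* images; the deformation-field
Jacobian, which quantifies sectioning distortion, is computed from the
registration of the raw images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .elastic import jacobian_determinant
from .imagecore import BinaryMask, DeformationField, RegistrationMetrics, SectionImage

__all__ = ["SplitRegions", "split_regions", "dice_split", "ssim_split",
           "metrics_report"]


@dataclass
class SplitRegions:
    """Partition of the section into proximal / gap / distal bands along the
    estimated bone axis. The three masks are pairwise disjoint and cover the
    image; ``fallback`` flags a midpoint split used when no gap was found."""

    proximal_mask: BinaryMask
    distal_mask: BinaryMask
    gap_mask: BinaryMask
    fallback: bool = False

    def __post_init__(self):
        p, d, g = (m.data for m in (self.proximal_mask, self.distal_mask, self.gap_mask))
        if (p & d).any() or (p & g).any() or (d & g).any():
            raise ValueError("split regions must be pairwise disjoint")


def split_regions(mask_fixed: BinaryMask, mask_moving: BinaryMask,
                  low_frac: float = 0.25, margin_frac: float = 0.1) -> SplitRegions:
    """Locate the osteotomy gap and split the image along the bone axis.

    The bone axis is the principal axis of the union of the two masks; the
    foreground density profile along that axis is scanned for its longest
    interior low-density run (below ``low_frac`` of the profile maximum),
    which — dilated by ``margin_frac`` of its own width — becomes the gap
    band. Everything on the lower-projection side is labelled proximal.
    Falls back to a zero-width midpoint split (``fallback=True``) when no
    low run exists.
    """
    if mask_fixed.shape != mask_moving.shape:
        raise ValueError("masks must share shape")
    union = mask_fixed.data | mask_moving.data
    spacing = np.asarray(mask_fixed.spacing)
    coords = np.argwhere(union) * spacing
    if coords.shape[0] == 0:
        raise ValueError("both masks are empty")
    mean = coords.mean(axis=0)
    cov = np.cov((coords - mean).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis  # deterministic sign

    rr, cc = np.meshgrid(np.arange(union.shape[0]) * spacing[0],
                         np.arange(union.shape[1]) * spacing[1], indexing="ij")
    proj = rr * axis[0] + cc * axis[1]
    fg_proj = (coords @ axis)
    step = float(min(spacing))
    t0, t1 = fg_proj.min(), fg_proj.max()
    nbins = max(8, int(np.ceil((t1 - t0) / step)))
    hist, edges = np.histogram(fg_proj, bins=nbins, range=(t0, t1))
    dens = np.convolve(hist.astype(float), np.ones(3) / 3.0, mode="same")
    thr = low_frac * dens.max()
    low = dens < thr

    # longest interior low run (bone on both sides)
    best = None
    i = 0
    while i < nbins:
        if low[i]:
            j = i
            while j < nbins and low[j]:
                j += 1
            if i > 0 and j < nbins:  # interior only
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
            i = j
        else:
            i += 1

    if best is None:
        mid = 0.5 * (t0 + t1)
        gap_lo = gap_hi = mid
        fallback = True
    else:
        gap_lo, gap_hi = edges[best[0]], edges[best[1]]
        margin = margin_frac * (gap_hi - gap_lo)
        gap_lo -= margin
        gap_hi += margin
        fallback = False

    prox = proj < gap_lo
    dist = proj > gap_hi
    gap = ~(prox | dist)
    sp = tuple(mask_fixed.spacing)
    return SplitRegions(proximal_mask=BinaryMask(prox, sp),
                        distal_mask=BinaryMask(dist, sp),
                        gap_mask=BinaryMask(gap, sp), fallback=fallback)


def _dice(a, b):
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("both masks empty in a region; Dice defined as 1.0",
                      stacklevel=3)
        return 1.0
    return 2.0 * float((a & b).sum()) / (na + nb)


def dice_split(seg_a: BinaryMask, seg_b: BinaryMask, regions: SplitRegions):
    """Per-region Dice (proximal, distal) and their mean."""
    if seg_a.shape != seg_b.shape:
        raise ValueError("masks must share shape")
    a, b = seg_a.data, seg_b.data
    dp = _dice(a & regions.proximal_mask.data, b & regions.proximal_mask.data)
    dd = _dice(a & regions.distal_mask.data, b & regions.distal_mask.data)
    return dp, dd, (dp + dd) / 2.0


def _region_ssim(a, b, region, window):
    rows = np.any(region, axis=1)
    cols = np.any(region, axis=0)
    if not rows.any():
        return 1.0
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    pa = a[r0:r1 + 1, c0:c1 + 1]
    pb = b[r0:r1 + 1, c0:c1 + 1]
    win = min(window, min(pa.shape))
    if win % 2 == 0:
        win -= 1
    if win < window:
        warnings.warn(f"region smaller than the SSIM window; shrunk to {win}",
                      stacklevel=3)
    if win < 3:
        return 1.0 if np.array_equal(pa, pb) else 0.0
    rng = max(pa.max(), pb.max()) - min(pa.min(), pb.min())
    if rng == 0:
        return 1.0  # equal constant regions: SSIM limit convention
    return float(structural_similarity(pa, pb, win_size=win, data_range=rng,
                                       gaussian_weights=False))


def ssim_split(seg_a, seg_b, regions: SplitRegions, window: int = 7):
    """Per-region SSIM over each region's bounding box and their mean.

    Accepts masks or images; binary masks are cast to float with a declared
    dynamic range of 1. Uniform window, K1=0.01, K2=0.03.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    a = np.asarray(seg_a.data, float)
    b = np.asarray(seg_b.data, float)
    if a.shape != b.shape:
        raise ValueError("inputs must share shape")
    sp = _region_ssim(a, b, regions.proximal_mask.data, window)
    sd = _region_ssim(a, b, regions.distal_mask.data, window)
    return sp, sd, (sp + sd) / 2.0


def metrics_report(fixed: SectionImage, moving_raw: SectionImage,
                   seg_fixed: BinaryMask, seg_moving: BinaryMask,
                   field: DeformationField, window: int = 7,
                   regions: SplitRegions = None) -> RegistrationMetrics:
    """Assemble the full metric set of one registration.

    Dice and SSIM come from the segmented images via the proximal/distal
    split (gap omitted); Jacobian summaries come from the deformation field
    of the raw-image registration.
    """
    if seg_fixed.shape != seg_moving.shape or fixed.shape != moving_raw.shape:
        raise ValueError("inconsistent shapes")
    if regions is None:
        regions = split_regions(seg_fixed, seg_moving)
    dp, dd, dsc = dice_split(seg_fixed, seg_moving, regions)
    sp, sd, ssim = ssim_split(seg_fixed, seg_moving, regions, window=window)
    jac = jacobian_determinant(field)
    return RegistrationMetrics(
        dsc_proximal=dp, dsc_distal=dd, dsc=dsc,
        ssim_proximal=sp, ssim_distal=sd, ssim=ssim,
        jacobian_min=float(jac.min()), jacobian_mean=float(jac.mean()),
        jacobian_max=float(jac.max()))
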