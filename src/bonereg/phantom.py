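"""Synthetic long-bone phantom: μCT-like volume, ground-truth cutting plane,
distorted SHG/OSX-like sections and Z-stacks.

The phantom emulates an osteotomized long-bone diaphysis: a hollow cylinder
of bright "mineralized" cortex (bone axis along the volume's x axis)
interrupted by a dark transverse osteotomy gap. The ground-truth histological
cutting plane is a *longitudinal* cut — its normal is tilted a few degrees
away from the volume z axis — so the section shows two cortical bands split
by the gap into proximal and distal fragments, exactly the geometry the
split-metrics and proximity modules expect.

The SHG-like section is the analytic cortex geometry on the true plane,
re-textured with band-limited fibrous noise (collagen analogue, intensities
deliberately unlike the μCT values), warped by a smooth random "sectioning"
distortion, and embedded in a Z-stack with depth-dependent defocus blur.
The OSX-like channel places punctate blobs at a controlled offset distance
from the cortex surface, which the proximity module must recover.

All randomness is derived from one integer seed through independent
``SeedSequence`` streams (plane pose / texture / warp / blobs / noise), so
the ground-truth plane and warp are unchanged by the noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .imagecore import (BinaryMask, CuttingPlane, DeformationField, SectionImage,
                        VolumeImage, ZStack, cross)

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom"]

CORTEX_INTENSITY = 1.0
MARROW_INTENSITY = 0.15


@dataclass
class PhantomSpec:
    """Parameters of the synthetic osteotomy phantom.

    Defaults mirror the printed acquisition geometry scaled to desk size:
    a 128^3 volume at 10.5 μm voxels (≈1.34 mm cube), a 0.7 mm transverse
    gap, and a section sampled at 1/8 of the volume spacing to preserve the
    coarse-volume / fine-section resolution mismatch.
    """

    shape: tuple = (128, 128, 128)
    vol_spacing: float = 10.5          # μm, isotropic
    cortex_outer_radius: float = 420.0  # μm, y semi-axis of the outer shell
    cortex_inner_radius: float = 300.0  # μm, y semi-axis of the endosteal surface
    ellipticity: float = 1.25           # y/z semi-axis ratio of the cross-section
    inner_center_shift: float = 70.0    # μm, endosteal centre offset (+y): uneven
                                        # cortical thickness, as in a real femur
    inner_center_shift_z: float = 100.0  # μm, endosteal centre offset (+z): breaks
                                        # the +z/-z mirror ambiguity of the cut
    plane_axis_offset: float = 120.0    # μm, distance of the cut from the bone axis
    ridge_amplitude: float = 70.0       # μm, height of the longitudinal ridge
                                        # (linea aspera analogue) on the outer shell
    ridge_azimuth: float = 30.0         # deg, ridge azimuth in the (y, z) section
    ridge_width: float = 20.0           # deg, angular half-width of the ridge
    gap_width: float = 700.0            # μm, transverse osteotomy
    pin_radius: float = 70.0           # μm, fixator pin-hole radius
    pin_offset_x: float = 490.0         # μm, pin-hole centres at +/- this along the bone
    pin_offset_z: float = 60.0          # μm, pin axis offset from the bone axis (z)
    plane_tilt: float = 10.0            # deg between plane normal and volume z axis
    warp_amplitude: float = 2.625       # μm RMS of the planted sectioning distortion
    noise_sd: float = 0.05              # intensity units (cortex = 1.0)
    seed: int = 0
    section_downscale: int = 8          # fine pixel = vol_spacing / section_downscale
    n_slices: int = 7                   # Z-stack depth
    z_spacing: float = 2.0              # μm between stack slices
    defocus_per_slice: float = 1.2      # px of Gaussian blur per slice away from focus
    defocus_attenuation: float = 0.25   # per-slice intensity loss away from focus
                                        # (confocal pinhole rejection)
    osx_offset: float = 20.0            # μm blob distance from the cortex surface
    n_blobs: int = 120
    blob_sigma: float = 3.0             # μm

    def __post_init__(self):
        if self.cortex_inner_radius >= self.cortex_outer_radius:
            raise ValueError("inner radius must be < outer radius")
        if self.gap_width < 0:
            raise ValueError("gap_width must be >= 0")
        if self.section_downscale < 1:
            raise ValueError("section_downscale must be >= 1")

    @property
    def section_spacing(self) -> float:
        return self.vol_spacing / self.section_downscale

    @property
    def section_shape(self) -> tuple:
        rows = int(round(0.75 * self.shape[1] * self.section_downscale))
        cols = int(self.shape[2] * self.section_downscale)
        return rows, cols

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self)) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class PhantomBundle:
    volume: VolumeImage
    true_plane: CuttingPlane
    shg_stack: ZStack
    osx_stack: ZStack
    true_warp: DeformationField
    true_section_mask: BinaryMask
    focus_index: int


def _plane_from_spec(spec, rng):
    """Ground-truth longitudinal cutting plane: normal tilted ``plane_tilt``
    degrees from z in a seeded azimuth; columns follow the bone (x) axis."""
    shape = np.asarray(spec.shape)
    center = (shape - 1) / 2.0 * spec.vol_spacing
    t = np.deg2rad(spec.plane_tilt)
    phi = rng.uniform(0, 2 * np.pi)
    # (z, y, x) components
    n = np.array([np.cos(t), np.sin(t) * np.cos(phi), np.sin(t) * np.sin(phi)])
    x_hat = np.array([0.0, 0.0, 1.0])
    u = x_hat - (x_hat @ n) * n
    u = u / np.linalg.norm(u)
    v = cross(n, u)
    v /= np.linalg.norm(v)
    offset = spec.plane_axis_offset + rng.uniform(-0.5, 0.5) * spec.vol_spacing
    return CuttingPlane(center=center + offset * n, axis_u=u, axis_v=v)


def _plane_points(plane, shape, spacing):
    """World coordinates (H, W, 3) of the section's pixel centres."""
    rows, cols = shape
    r = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    c = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    rr, cc = np.meshgrid(r, c, indexing="ij")
    return (plane.center[None, None, :]
            + cc[..., None] * plane.axis_u[None, None, :]
            + rr[..., None] * plane.axis_v[None, None, :])


def _geometry_masks(points, spec, vol_center):
    """Analytic cortex / marrow membership of world points.

    The cross-section is an ellipse (y semi-axis = radius, z semi-axis =
    radius / ellipticity) whose endosteal surface is shifted along +y; this
    breaks the azimuthal symmetry that would otherwise make the cutting
    plane unidentifiable (every rotation of a plane about a circular tube's
    axis cuts an identical section).
    """
    dz = (points[..., 0] - vol_center[0]) * spec.ellipticity
    dy = points[..., 1] - vol_center[1]
    dx = points[..., 2] - vol_center[2]
    in_gap = np.abs(dx) < spec.gap_width / 2.0
    # longitudinal ridge (linea aspera analogue): a Gaussian bump in the
    # outer radius at a fixed azimuth; together with the shifted endosteal
    # centre it pins the rotational pose of the cut about the bone axis
    theta = np.arctan2(dz, dy)
    dtheta = np.angle(np.exp(1j * (theta - np.deg2rad(spec.ridge_azimuth))))
    r_out = spec.cortex_outer_radius + spec.ridge_amplitude * np.exp(
        -0.5 * (dtheta / np.deg2rad(spec.ridge_width)) ** 2)
    outer = np.hypot(dz, dy) <= r_out
    inner = np.hypot(dz - spec.inner_center_shift_z * spec.ellipticity,
                     dy - spec.inner_center_shift) < spec.cortex_inner_radius
    shell = outer & ~inner
    marrow = inner
    # fixator pin holes: cylinders along y near each fragment. A cut plane
    # sees them as notches whose chord width varies steeply with the local
    # cut depth, anchoring the rotational pose about the bone axis that the
    # smooth shell constrains only weakly.
    dz_phys = points[..., 0] - vol_center[0]
    if spec.pin_radius > 0:
        for xh in (-spec.pin_offset_x, spec.pin_offset_x):
            pin = np.hypot(dz_phys - spec.pin_offset_z, dx - xh) < spec.pin_radius
            shell = shell & ~pin
            marrow = marrow & ~pin
    return shell & ~in_gap, marrow & ~in_gap


def _fibrous_texture(shape, rng, sigma_rc=(1.2, 6.0)):
    """Band-limited noise elongated along the bone (column) direction,
    min-max normalized to [0, 1]."""
    tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_rc)
    lo, hi = tex.min(), tex.max()
    return (tex - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _sectioning_warp(shape, spacing, amplitude, rng):
    """Smooth invertible distortion: 2-4 Gaussian bumps plus a weak global
    shear, rescaled so the whole-field RMS magnitude equals ``amplitude``."""
    rows, cols = shape
    w = np.zeros((rows, cols, 2))
    rr = (np.arange(rows) - rows / 2.0)[:, None] * spacing
    cc = (np.arange(cols) - cols / 2.0)[None, :] * spacing
    n_bumps = int(rng.integers(2, 5))
    for _ in range(n_bumps):
        cr = rng.uniform(-rows / 2, rows / 2) * spacing
        ccn = rng.uniform(-cols / 2, cols / 2) * spacing
        sig = rng.uniform(150.0, 300.0)
        amp = rng.uniform(0.5, 1.0)
        theta = rng.uniform(0, 2 * np.pi)
        bump = amp * np.exp(-((rr - cr) ** 2 + (cc - ccn) ** 2) / (2 * sig ** 2))
        w[..., 0] += bump * np.sin(theta)
        w[..., 1] += bump * np.cos(theta)
    shear = rng.uniform(-0.004, 0.004)
    w[..., 1] += shear * rr  # column shift proportional to row position
    rms = np.sqrt(np.mean(np.sum(w ** 2, axis=-1)))
    if rms > 0 and amplitude > 0:
        w *= amplitude / rms
    else:
        w[:] = 0.0
    return w


def _apply_warp(image, warp, spacing):
    """Distorted(x) = image(x + warp(x)); warp in μm, image pixels."""
    rows, cols = image.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr + warp[..., 0] / spacing[0],
                       cc + warp[..., 1] / spacing[1]])
    return ndimage.map_coordinates(image, coords, order=1, mode="nearest")


def _make_stack(sharp, spacing, z_spacing, n_slices, focus_index,
                defocus_per_slice, attenuation, noise_sd, rng):
    slices = []
    for k in range(n_slices):
        d = abs(k - focus_index)
        sig = defocus_per_slice * d
        img = ndimage.gaussian_filter(sharp, sig) if sig > 0 else sharp.copy()
        img = img / (1.0 + attenuation * d)
        if noise_sd > 0:
            img = img + rng.normal(0.0, 0.3 * noise_sd, img.shape)
        slices.append(SectionImage(data=img, spacing=spacing))
    return ZStack(slices=slices, z_spacing=z_spacing)


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate the full synthetic bundle for one seed.

    Identical specs produce bit-identical bundles; the noise stream is
    independent of the plane/warp streams so changing ``noise_sd`` never
    moves the ground truth.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_plane, rng_tex, rng_warp, rng_blob, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # --- volume -----------------------------------------------------------
    shape = spec.shape
    sp = spec.vol_spacing
    zz, yy, xx = np.meshgrid(*(np.arange(n) * sp for n in shape), indexing="ij")
    vol_center = (np.asarray(shape) - 1) / 2.0 * sp
    pts = np.stack([zz, yy, xx], axis=-1)
    shell3d, marrow3d = _geometry_masks(pts, spec, vol_center)
    vol = np.zeros(shape)
    vol[shell3d] = CORTEX_INTENSITY
    vol[marrow3d] = MARROW_INTENSITY
    vol = ndimage.gaussian_filter(vol, 1.0)
    if spec.noise_sd > 0:
        vol = vol + rng_noise.normal(0.0, spec.noise_sd, shape)
    volume = VolumeImage(data=vol.astype(np.float32), spacing=(sp, sp, sp))

    # --- ground-truth plane and analytic section --------------------------
    plane = _plane_from_spec(spec, rng_plane)
    sec_shape = spec.section_shape
    sec_sp = spec.section_spacing
    points = _plane_points(plane, sec_shape, sec_sp)
    cortex, marrow2d = _geometry_masks(points, spec, vol_center)
    if not (cortex & (points[..., 2] < vol_center[2])).any() or \
       not (cortex & (points[..., 2] > vol_center[2])).any():
        raise ValueError("cutting plane misses the cortical tube on one side; "
                         "adjust plane_tilt or radii")
    true_section_mask = BinaryMask(data=cortex, spacing=(sec_sp, sec_sp))

    # --- SHG-like section: fibrous texture on the cortex ------------------
    tex = _fibrous_texture(sec_shape, rng_tex)
    tex2 = _fibrous_texture(sec_shape, rng_tex, sigma_rc=(2.0, 2.0))
    shg = np.full(sec_shape, 0.02)
    shg[marrow2d] = 0.02 + 0.06 * tex2[marrow2d]
    shg[cortex] = 0.65 + 0.35 * tex[cortex]

    # --- planted sectioning distortion -------------------------------------
    warp = _sectioning_warp(sec_shape, sec_sp, spec.warp_amplitude, rng_warp)
    true_warp = DeformationField(displacement=warp, spacing=(sec_sp, sec_sp))
    shg_d = _apply_warp(shg, warp, (sec_sp, sec_sp))

    # --- OSX-like channel: blobs offset from the cortex surface -----------
    dist = ndimage.distance_transform_edt(~cortex, sampling=(sec_sp, sec_sp))
    band = np.abs(dist - spec.osx_offset) <= 0.5 * sec_sp
    band[:8, :] = band[-8:, :] = False
    band[:, :8] = band[:, -8:] = False
    idx = np.flatnonzero(band)
    osx = np.zeros(sec_shape)
    if idx.size:
        take = min(spec.n_blobs, idx.size)
        chosen = rng_blob.choice(idx, size=take, replace=False)
        seeds = np.zeros(sec_shape)
        seeds.flat[chosen] = 1.0
        sig_px = spec.blob_sigma / sec_sp
        osx = ndimage.gaussian_filter(seeds, sig_px)
        if osx.max() > 0:
            osx /= osx.max()
    osx = 0.02 + 0.98 * osx
    osx_d = _apply_warp(osx, warp, (sec_sp, sec_sp))

    # --- Z-stacks with depth-dependent defocus ----------------------------
    focus_index = int(rng_plane.integers(1, max(2, spec.n_slices - 1)))
    shg_stack = _make_stack(shg_d, (sec_sp, sec_sp), spec.z_spacing, spec.n_slices,
                            focus_index, spec.defocus_per_slice,
                            spec.defocus_attenuation, spec.noise_sd, rng_noise)
    osx_stack = _make_stack(osx_d, (sec_sp, sec_sp), spec.z_spacing, spec.n_slices,
                            focus_index, spec.defocus_per_slice,
                            spec.defocus_attenuation, spec.noise_sd, rng_noise)

    return PhantomBundle(volume=volume, true_plane=plane, shg_stack=shg_stack,
                         osx_stack=osx_stack, true_warp=true_warp,
                         true_section_mask=true_section_mask, focus_index=focus_index)
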