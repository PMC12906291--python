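"""Shared domain types, coordinate conventions and file I/O.

Conventions used throughout the package
---------------------------------------
* Volumes are indexed ``(z, y, x)``; 2D images are indexed ``(row, col)``.
* Voxel/pixel indices are 0-based. The world coordinate (in micrometres) of
  voxel index ``i`` is ``origin + i * spacing``, with world vectors stored in
  the same component order as the array axes (``(z, y, x)`` for volumes,
  ``(row, col)`` for 2D physical vectors).
* Cross products of world vectors use :func:`cross`, i.e. ``numpy.cross`` on
  the stored component order. All orthonormal-frame invariants in this
  package are expressed with respect to that one convention.

Volumes are read and written as NRRD / MetaImage (via SimpleITK, whose
header spacing is authoritative) or as multi-page TIFF with a JSON spacing
sidecar, since TIFF carries no reliable physical spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import tifffile
from scipy import ndimage

__all__ = [
    "VolumeImage",
    "SectionImage",
    "ZStack",
    "BinaryMask",
    "CuttingPlane",
    "AffineTransform2D",
    "DeformationField",
    "RegistrationMetrics",
    "cross",
    "read_volume",
    "write_volume",
    "read_section",
    "write_section",
    "read_zstack",
    "write_zstack",
    "max_projection",
    "downsample",
]

_SITK_SUFFIXES = {".nrrd", ".mha", ".mhd"}
_TIFF_SUFFIXES = {".tif", ".tiff"}

METRICS_CSV_HEADER = (
    "dsc_proximal,dsc_distal,dsc,ssim_proximal,ssim_distal,ssim,"
    "jacobian_min,jacobian_mean,jacobian_max"
)


def cross(a, b):
    """Cross product of two world vectors in the package's component order."""
    return np.cross(np.asarray(a, float), np.asarray(b, float))


def _as_spacing(spacing, ndim):
    s = np.atleast_1d(np.asarray(spacing, dtype=float))
    if s.size == 1:
        s = np.full(ndim, float(s[0]))
    if s.size != ndim:
        raise ValueError(f"spacing must have {ndim} components, got {s.size}")
    if not np.all(s > 0):
        raise ValueError(f"spacing components must be > 0, got {tuple(s)}")
    return tuple(float(v) for v in s)


@dataclass
class VolumeImage:
    """3D scalar grid with anisotropic voxel spacing (micrometres).

    ``data`` is indexed ``(z, y, x)``; ``spacing`` and ``origin`` follow the
    same component order. World coordinate of voxel ``(k, j, i)`` is
    ``origin + (k, j, i) * spacing``.
    """

    data: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VolumeImage.data must be 3D")
        if min(self.data.shape) < 2:
            raise ValueError("VolumeImage needs >= 2 voxels per axis")
        self.spacing = _as_spacing(self.spacing, 3)
        self.origin = tuple(float(v) for v in np.asarray(self.origin, float))

    @property
    def shape(self):
        return self.data.shape

    def world_extent(self):
        """(lower, upper) world corners of the voxel-centre grid (μm)."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def index_to_world(self, index):
        return np.asarray(self.origin) + np.asarray(index, float) * np.asarray(self.spacing)


@dataclass
class SectionImage:
    """2D scalar grid with pixel spacing (μm). Carries no world pose."""

    data: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("SectionImage.data must be 2D")
        self.spacing = _as_spacing(self.spacing, 2)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class ZStack:
    """Ordered stack of sections sharing one pixel spacing."""

    slices: list
    z_spacing: float

    def __post_init__(self):
        if len(self.slices) < 1:
            raise ValueError("ZStack needs >= 1 slice")
        shape = self.slices[0].shape
        spacing = self.slices[0].spacing
        for s in self.slices:
            if s.shape != shape or s.spacing != spacing:
                raise ValueError("all ZStack slices must share shape and spacing")
        self.z_spacing = float(self.z_spacing)
        if self.z_spacing <= 0:
            raise ValueError("z_spacing must be > 0")

    def __len__(self):
        return len(self.slices)

    @property
    def spacing(self):
        return self.slices[0].spacing

    @property
    def shape(self):
        return self.slices[0].shape

    def as_array(self):
        return np.stack([s.data for s in self.slices], axis=0)


@dataclass
class BinaryMask:
    """2D boolean grid with pixel spacing (μm)."""

    data: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("BinaryMask.data must be 2D")
        self.spacing = _as_spacing(self.spacing, 2)

    @property
    def shape(self):
        return self.data.shape


_ORTHO_TOL = 1e-9


@dataclass
class CuttingPlane:
    """A 2D slice pose in volume world coordinates.

    ``center`` is the world point mapped to the section's centre pixel;
    ``axis_u`` is the in-plane column direction, ``axis_v`` the row
    direction, and ``normal = cross(axis_u, axis_v)``. All three are unit
    vectors in the package's ``(z, y, x)`` world component order.
    """

    center: np.ndarray
    axis_u: np.ndarray
    axis_v: np.ndarray
    normal: np.ndarray = None

    def __post_init__(self):
        self.center = np.asarray(self.center, float)
        self.axis_u = np.asarray(self.axis_u, float)
        self.axis_v = np.asarray(self.axis_v, float)
        if self.normal is None:
            self.normal = cross(self.axis_u, self.axis_v)
        self.normal = np.asarray(self.normal, float)
        for name, v in (("axis_u", self.axis_u), ("axis_v", self.axis_v), ("normal", self.normal)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a unit vector")
        if abs(float(self.axis_u @ self.axis_v)) > 1e-6:
            raise ValueError("axis_u and axis_v must be orthogonal")
        if np.linalg.norm(cross(self.axis_u, self.axis_v) - self.normal) > 1e-6:
            raise ValueError("normal must equal cross(axis_u, axis_v)")

    @classmethod
    def from_normal(cls, center, normal, up_hint=(0.0, 0.0, 1.0)):
        """Build an orthonormal frame for ``normal``; ``axis_u`` is the
        projection of ``up_hint`` into the plane (falls back deterministically
        when the hint is parallel to the normal)."""
        n = np.asarray(normal, float)
        n = n / np.linalg.norm(n)
        u = np.asarray(up_hint, float)
        u = u - (u @ n) * n
        if np.linalg.norm(u) < 1e-8:
            for cand in np.eye(3):
                u = cand - (cand @ n) * n
                if np.linalg.norm(u) > 1e-8:
                    break
        u = u / np.linalg.norm(u)
        v = cross(n, u)
        v = v / np.linalg.norm(v)
        return cls(center=np.asarray(center, float), axis_u=u, axis_v=v, normal=n)

    def rotated_inplane(self, psi):
        """Frame rotated by ``psi`` radians about the normal (same plane)."""
        c, s = np.cos(psi), np.sin(psi)
        u = c * self.axis_u + s * self.axis_v
        v = -s * self.axis_u + c * self.axis_v
        return CuttingPlane(center=self.center.copy(), axis_u=u, axis_v=v)

    def to_json(self, path):
        payload = {
            "center_um": list(map(float, self.center)),
            "axis_u": list(map(float, self.axis_u)),
            "axis_v": list(map(float, self.axis_v)),
            "normal": list(map(float, self.normal)),
            "axis_order": "zyx",
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(center=d["center_um"], axis_u=d["axis_u"], axis_v=d["axis_v"],
                   normal=d.get("normal"))


@dataclass
class AffineTransform2D:
    """2D affine map ``y = matrix @ x + translation`` in physical (row, col) μm."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float).reshape(2, 2)
        self.translation = np.asarray(self.translation, float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("AffineTransform2D matrix must be invertible")

    def apply(self, points):
        pts = np.asarray(points, float)
        return pts @ self.matrix.T + self.translation

    def inverse(self):
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(matrix=inv, translation=-inv @ self.translation)

    def to_json(self, path):
        payload = {
            "matrix": self.matrix.tolist(),
            "translation_um": self.translation.tolist(),
            "convention": "y = matrix @ x + translation, (row, col) um",
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(matrix=np.asarray(d["matrix"]), translation=np.asarray(d["translation_um"]))


@dataclass
class DeformationField:
    """Dense per-pixel 2D displacement (μm), channels last: (row, col).

    ``displacement[r, c]`` is the physical displacement attached to pixel
    ``(r, c)`` of the registered (fixed-grid) image; applying the field
    resamples the source image at ``x + displacement(x)``.
    """

    displacement: np.ndarray
    spacing: tuple

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        if self.displacement.ndim != 3 or self.displacement.shape[-1] != 2:
            raise ValueError("displacement must have shape (H, W, 2)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement must be finite everywhere")
        self.spacing = _as_spacing(self.spacing, 2)

    @property
    def shape(self):
        return self.displacement.shape[:2]

    def to_file(self, path):
        """Write as a 2-channel volume (NRRD/MHA via SimpleITK)."""
        img = sitk.GetImageFromArray(self.displacement.astype(np.float64), isVector=True)
        img.SetSpacing((self.spacing[1], self.spacing[0]))
        sitk.WriteImage(img, str(path))

    @classmethod
    def from_file(cls, path):
        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)
        sp = img.GetSpacing()
        return cls(displacement=arr, spacing=(sp[1], sp[0]))


@dataclass
class RegistrationMetrics:
    """Split Dice / split SSIM / Jacobian summaries of one registration."""

    dsc_proximal: float
    dsc_distal: float
    dsc: float
    ssim_proximal: float
    ssim_distal: float
    ssim: float
    jacobian_min: float
    jacobian_mean: float
    jacobian_max: float

    def __post_init__(self):
        if abs(self.dsc - (self.dsc_proximal + self.dsc_distal) / 2) > 1e-9:
            raise ValueError("dsc must be the mean of the proximal and distal scores")
        if abs(self.ssim - (self.ssim_proximal + self.ssim_distal) / 2) > 1e-9:
            raise ValueError("ssim must be the mean of the proximal and distal scores")
        if not (self.jacobian_min <= self.jacobian_mean <= self.jacobian_max):
            raise ValueError("jacobian summaries must satisfy min <= mean <= max")

    def to_csv(self, path):
        vals = [self.dsc_proximal, self.dsc_distal, self.dsc,
                self.ssim_proximal, self.ssim_distal, self.ssim,
                self.jacobian_min, self.jacobian_mean, self.jacobian_max]
        Path(path).write_text(
            METRICS_CSV_HEADER + "\n" + ",".join(repr(float(v)) for v in vals) + "\n")

    @classmethod
    def from_csv(cls, path):
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].split(",")
        values = dict(zip(header, (float(v) for v in lines[1].split(","))))
        return cls(**values)


# ---------------------------------------------------------------------------
# file I/O


def _sidecar_path(path):
    return Path(str(path) + ".spacing.json")


def _read_sidecar(path, ndim):
    sc = _sidecar_path(path)
    if not sc.exists():
        return None
    d = json.loads(sc.read_text())
    return d


def _write_sidecar(path, spacing, z_spacing=None):
    d = {"spacing_um": list(map(float, spacing))}
    if z_spacing is not None:
        d["z_spacing_um"] = float(z_spacing)
    _sidecar_path(path).write_text(json.dumps(d) + "\n")


def read_volume(path, spacing=None):
    """Read a 3D volume from NRRD/MetaImage (header spacing authoritative) or
    multi-page TIFF (spacing from a ``<file>.spacing.json`` sidecar or the
    ``spacing`` argument).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _SITK_SUFFIXES:
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:
            raise IOError(f"could not read volume {path}: {exc}") from exc
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        sp = img.GetSpacing()[::-1]
        org = img.GetOrigin()[::-1]
        return VolumeImage(data=data, spacing=sp, origin=org)
    if suffix in _TIFF_SUFFIXES:
        try:
            data = tifffile.imread(str(path))
        except Exception as exc:
            raise IOError(f"could not read volume {path}: {exc}") from exc
        if data.ndim != 3:
            raise IOError(f"{path} is not a multi-page TIFF stack")
        if spacing is None:
            sc = _read_sidecar(path, 3)
            if sc is None:
                raise ValueError(
                    f"TIFF volume {path} needs a spacing sidecar "
                    f"({_sidecar_path(path).name}) or an explicit spacing")
            spacing = sc["spacing_um"]
        return VolumeImage(data=data, spacing=spacing)
    raise IOError(f"unsupported volume format: {path}")


def write_volume(vol, path):
    """Write a volume; NRRD/MetaImage carry spacing in the header, TIFF gets
    a JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _SITK_SUFFIXES:
        img = sitk.GetImageFromArray(vol.data)
        img.SetSpacing(tuple(vol.spacing[::-1]))
        img.SetOrigin(tuple(vol.origin[::-1]))
        try:
            sitk.WriteImage(img, str(path))
        except RuntimeError as exc:
            raise IOError(f"could not write volume {path}: {exc}") from exc
    elif suffix in _TIFF_SUFFIXES:
        try:
            tifffile.imwrite(str(path), vol.data)
        except Exception as exc:
            raise IOError(f"could not write volume {path}: {exc}") from exc
        _write_sidecar(path, vol.spacing)
    else:
        raise IOError(f"unsupported volume format: {path}")


def read_section(path, spacing=None):
    """Read a single 2D TIFF image; spacing from sidecar or argument."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"section file not found: {path}")
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:
        raise IOError(f"could not read section {path}: {exc}") from exc
    if data.ndim != 2:
        raise IOError(f"{path} is not a single 2D image")
    if spacing is None:
        sc = _read_sidecar(path, 2)
        if sc is None:
            raise ValueError(f"TIFF section {path} needs a spacing sidecar or explicit spacing")
        spacing = sc["spacing_um"]
    return SectionImage(data=data, spacing=spacing)


def write_section(img, path):
    tifffile.imwrite(str(path), img.data)
    _write_sidecar(path, img.spacing)


def read_zstack(path, spacing=None, z_spacing=None):
    """Read a multi-page TIFF as a Z-stack."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"z-stack file not found: {path}")
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    sc = _read_sidecar(path, 2)
    if spacing is None:
        if sc is None:
            raise ValueError(f"TIFF stack {path} needs a spacing sidecar or explicit spacing")
        spacing = sc["spacing_um"]
    if z_spacing is None:
        z_spacing = sc.get("z_spacing_um", 1.0) if sc else 1.0
    return ZStack(slices=[SectionImage(data=sl, spacing=spacing) for sl in data],
                  z_spacing=z_spacing)


def write_zstack(stack, path):
    tifffile.imwrite(str(path), stack.as_array())
    _write_sidecar(path, stack.spacing, z_spacing=stack.z_spacing)


# ---------------------------------------------------------------------------
# basic image operations


def max_projection(stack):
    """Per-pixel maximum across a Z-stack, collapsing it to one section."""
    if len(stack) == 0:
        raise ValueError("cannot project an empty stack")
    return SectionImage(data=stack.as_array().max(axis=0), spacing=stack.spacing)


def downsample(img, factor):
    """Integer decimation with Gaussian anti-aliasing (sigma = factor / 2).

    ``factor`` may be a scalar or per-axis; output spacing is multiplied by
    the factor and the shape becomes ``ceil(shape / factor)``. Factor 1 on an
    axis is the identity (no smoothing on that axis).
    """
    is_volume = isinstance(img, VolumeImage)
    ndim = 3 if is_volume else 2
    f = np.atleast_1d(np.asarray(factor))
    if f.size == 1:
        f = np.full(ndim, f[0])
    if f.size != ndim:
        raise ValueError(f"factor needs {ndim} components")
    if np.any(f < 1) or not np.allclose(f, np.round(f)):
        raise ValueError("downsampling factors must be integers >= 1")
    f = f.astype(int)
    data = img.data
    sigma = [0.5 * fi if fi > 1 else 0.0 for fi in f]
    if any(s > 0 for s in sigma):
        data = ndimage.gaussian_filter(data.astype(float), sigma=sigma, mode="nearest")
    slicer = tuple(slice(None, None, int(fi)) for fi in f)
    out = data[slicer]
    new_spacing = tuple(s * fi for s, fi in zip(img.spacing, f))
    if is_volume:
        return VolumeImage(data=out, spacing=new_spacing, origin=img.origin)
    return SectionImage(data=out, spacing=new_spacing)
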