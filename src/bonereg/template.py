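"""Templates for the generalized Hough transform.

The 2D side: the histological section is Otsu-segmented down to its cortical
fragments, boundary landmarks with local gradient orientations are sampled
along the fragments, and an R-table (quantized gradient angle -> offsets to
the template reference point) is built from them.

The 3D side: the volume is reduced to an edge cloud — voxels of high
gradient magnitude with their unit gradient directions — which the GHT
scans plane by plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .imagecore import BinaryMask, SectionImage, VolumeImage

__all__ = ["Landmark2D", "RTable", "EdgeCloud3D", "segment_cortices",
           "make_landmarks", "build_rtable", "gradient_edges_3d",
           "landmarks_to_json", "landmarks_from_json"]


@dataclass
class Landmark2D:
    """Boundary point of the cortex template, physical (row, col) μm, with
    the orientation of the local image gradient in radians, in [-pi, pi)."""

    position: np.ndarray
    boundary_angle: float

    def __post_init__(self):
        self.position = np.asarray(self.position, float).reshape(2)
        self.boundary_angle = float(self.boundary_angle)
        if not (-np.pi <= self.boundary_angle < np.pi):
            raise ValueError("boundary_angle must lie in [-pi, pi)")


def landmarks_to_json(landmarks, path):
    """Serialize a landmark list as JSON (positions in μm, angles rad)."""
    payload = [{"position_um": lm.position.tolist(),
                "boundary_angle_rad": lm.boundary_angle} for lm in landmarks]
    Path(path).write_text(json.dumps(payload) + "\n")


def landmarks_from_json(path):
    payload = json.loads(Path(path).read_text())
    return [Landmark2D(position=d["position_um"],
                       boundary_angle=d["boundary_angle_rad"]) for d in payload]


@dataclass
class RTable:
    """Generalized-Hough R-table: quantized boundary angle -> offset vectors
    (landmark -> reference point, μm)."""

    bins: dict
    reference_point: np.ndarray
    angle_bin_width: float

    def __post_init__(self):
        self.reference_point = np.asarray(self.reference_point, float).reshape(2)

    @property
    def n_bins(self):
        return int(round(2 * np.pi / self.angle_bin_width))

    def bin_index(self, angle):
        """Quantize an angle (radians) into [0, n_bins)."""
        nb = self.n_bins
        idx = np.floor((np.asarray(angle) + np.pi) / self.angle_bin_width).astype(int)
        return np.mod(idx, nb)

    def to_json(self, path):
        payload = {"reference_point_um": self.reference_point.tolist(),
                   "angle_bin_width_rad": self.angle_bin_width,
                   "bins": {str(b): np.asarray(o).reshape(-1, 2).tolist()
                            for b, o in self.bins.items()}}
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(bins={int(b): [np.asarray(o) for o in offs]
                         for b, offs in d["bins"].items()},
                   reference_point=d["reference_point_um"],
                   angle_bin_width=d["angle_bin_width_rad"])

    def packed(self, spread=0):
        """Offsets flattened into arrays for vectorized voting.

        Returns (offsets, starts, counts): for angle bin b the offsets are
        ``offsets[starts[b]:starts[b]+counts[b]]``. ``spread`` > 0 also
        copies each offset into that many neighbouring bins on each side,
        making the voting tolerant to gradient-angle noise.
        """
        nb = self.n_bins
        per_bin = [[] for _ in range(nb)]
        for b, offs in self.bins.items():
            for o in offs:
                for d in range(-spread, spread + 1):
                    per_bin[(b + d) % nb].append(o)
        counts = np.array([len(p) for p in per_bin], dtype=np.int64)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        if counts.sum() == 0:
            return np.zeros((0, 2)), starts, counts
        offsets = np.concatenate([np.asarray(p, float).reshape(-1, 2) if p else
                                  np.zeros((0, 2)) for p in per_bin])
        return offsets, starts, counts


@dataclass
class EdgeCloud3D:
    """High-gradient voxels of a volume: world points (μm), unit gradient
    directions and gradient magnitudes (intensity / μm)."""

    points: np.ndarray
    gradient_dirs: np.ndarray
    gradient_mags: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.gradient_dirs = np.asarray(self.gradient_dirs, float).reshape(-1, 3)
        self.gradient_mags = np.asarray(self.gradient_mags, float).reshape(-1)
        norms = np.linalg.norm(self.gradient_dirs, axis=1)
        if self.points.shape[0] and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient_dirs must be unit vectors")

    def to_csv(self, path):
        """Write as z,y,x,gz,gy,gx,mag rows (world μm / unit dirs)."""
        header = "z,y,x,gz,gy,gx,mag"
        arr = np.column_stack([self.points, self.gradient_dirs, self.gradient_mags])
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path):
        arr = np.atleast_2d(np.loadtxt(path, delimiter=",", skiprows=1))
        return cls(points=arr[:, :3], gradient_dirs=arr[:, 3:6],
                   gradient_mags=arr[:, 6])


def segment_cortices(img: SectionImage, keep=2, closing_radius: int = 2,
                     min_area_frac: float = 0.05) -> BinaryMask:
    """Otsu-threshold the section, morphologically close it, and keep the
    cortical-fragment components.

    ``keep`` defaults to the two-cortex anatomy. An osteotomy section is
    further fragmented — the gap splits each cortex and fixator pin holes
    split the fragments again — so ``keep=None`` switches to an area rule:
    every component at least ``min_area_frac`` of the largest is kept.
    """
    data = np.asarray(img.data, float)
    if data.max() <= data.min():
        raise ValueError("degenerate intensity range; cannot segment a constant image")
    thr = threshold_otsu(data, nbins=256)
    fg = data > thr
    if closing_radius > 0:
        fg = morphology.binary_closing(fg, morphology.disk(closing_radius))
    labels, n = ndimage.label(fg)
    if n < 2:
        raise ValueError(
            f"found {n} connected component(s) after thresholding; expected >= 2 "
            "cortical fragments — consider overriding the threshold or closing radius")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    if keep is None:
        chosen = np.flatnonzero(areas >= min_area_frac * areas.max()) + 1
    else:
        chosen = np.argsort(areas)[::-1][:keep] + 1
    return BinaryMask(data=np.isin(labels, chosen), spacing=img.spacing)


def make_landmarks(mask: BinaryMask, img: SectionImage, n_landmarks: int = 360,
                   gradient_sigma: float = 1.0) -> list:
    """Sample boundary landmarks approximately uniformly by arc length along
    every component contour of ``mask``; each carries the orientation of the
    (Gaussian-smoothed) image gradient at its location.

    The landmark budget is split across contours proportionally to their
    perimeter and clipped (with a warning) when it exceeds the number of
    boundary pixels.
    """
    if n_landmarks < 8:
        raise ValueError("n_landmarks must be >= 8")
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    contours = measure.find_contours(m.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    boundary_px = int((m & ~ndimage.binary_erosion(m)).sum())
    if n_landmarks > boundary_px:
        warnings.warn(f"n_landmarks={n_landmarks} exceeds {boundary_px} boundary "
                      "pixels; clipping", stacklevel=2)
        n_landmarks = boundary_px

    gr = ndimage.gaussian_filter(np.asarray(img.data, float), gradient_sigma)
    gy, gx = np.gradient(gr, img.spacing[0], img.spacing[1])

    lengths = []
    for c in contours:
        seg = np.diff(c, axis=0) * np.asarray(mask.spacing)
        lengths.append(np.sqrt((seg ** 2).sum(axis=1)).sum())
    lengths = np.asarray(lengths)
    total = lengths.sum()
    # at least one landmark per contour so every fragment contributes
    counts = np.maximum(1, np.round(n_landmarks * lengths / total).astype(int))

    landmarks = []
    rows_max, cols_max = np.array(m.shape) - 1
    for c, k in zip(contours, counts):
        seg = np.diff(c, axis=0) * np.asarray(mask.spacing)
        arc = np.concatenate([[0.0], np.cumsum(np.sqrt((seg ** 2).sum(axis=1)))])
        if arc[-1] == 0:
            continue
        targets = np.linspace(0, arc[-1], k, endpoint=False)
        ridx = np.interp(targets, arc, c[:, 0])
        cidx = np.interp(targets, arc, c[:, 1])
        coords = np.stack([np.clip(ridx, 0, rows_max), np.clip(cidx, 0, cols_max)])
        gyl = ndimage.map_coordinates(gy, coords, order=1)
        gxl = ndimage.map_coordinates(gx, coords, order=1)
        ang = np.arctan2(gyl, gxl)
        ang = np.mod(ang + np.pi, 2 * np.pi) - np.pi
        for rr, cc, a in zip(ridx, cidx, ang):
            landmarks.append(Landmark2D(
                position=(rr * mask.spacing[0], cc * mask.spacing[1]),
                boundary_angle=a))
    return landmarks[:max(n_landmarks, 1)] if len(landmarks) > n_landmarks else landmarks


def build_rtable(landmarks: list, angle_bin_width: float = 2 * np.pi / 72) -> RTable:
    """Standard R-table: the reference point is the landmark centroid and each
    landmark stores offset = reference - position in the bin of its quantized
    boundary angle."""
    if not landmarks:
        raise ValueError("need at least one landmark")
    positions = np.array([lm.position for lm in landmarks])
    ref = positions.mean(axis=0)
    table = RTable(bins={}, reference_point=ref, angle_bin_width=angle_bin_width)
    for lm in landmarks:
        b = int(table.bin_index(lm.boundary_angle))
        table.bins.setdefault(b, []).append(ref - lm.position)
    return table


def gradient_edges_3d(vol: VolumeImage, mag_percentile: float = 95.0,
                      smooth_sigma: float = 1.0, max_points: int = None) -> EdgeCloud3D:
    """Edge cloud of a volume: voxels whose (central-difference, physical-unit)
    gradient magnitude exceeds the given percentile of nonzero magnitudes.

    ``max_points`` optionally keeps only the strongest edges, a speed knob
    for the GHT.
    """
    if not 0 < mag_percentile < 100:
        raise ValueError("mag_percentile must be in (0, 100)")
    data = np.asarray(vol.data, float)
    if data.max() <= data.min():
        raise ValueError("constant volume has no gradient edges")
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma)
    gz, gy, gx = np.gradient(data, *vol.spacing)
    mag = np.sqrt(gz ** 2 + gy ** 2 + gx ** 2)
    nz = mag[mag > 0]
    thr = np.percentile(nz, mag_percentile)
    sel = mag > thr
    idx = np.argwhere(sel)
    mags = mag[sel]
    if max_points is not None and idx.shape[0] > max_points:
        keep = np.argsort(mags)[::-1][:max_points]
        keep.sort()
        idx = idx[keep]
        mags = mags[keep]
    dirs = np.stack([g[tuple(idx.T)] for g in (gz, gy, gx)], axis=1)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    points = np.asarray(vol.origin) + idx * np.asarray(vol.spacing)
    return EdgeCloud3D(points=points, gradient_dirs=dirs, gradient_mags=mags)
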