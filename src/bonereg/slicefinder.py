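"""Slice-to-volume search: generalized Hough transform over plane poses,
local affine refinement, oblique slice extraction and transform propagation.

The GHT treats the section's cortex outline as a rigid template of known
physical scale (both modalities carry μm spacing, so scale is never
searched). Candidate plane orientations are drawn from a Fibonacci grid of
normals inside a cone around a reference axis, crossed with a uniformly
stepped in-plane rotation. For each orientation, every 3D edge point whose
gradient lies close to the candidate plane casts R-table votes at its own
depth, so the 3D translation accumulator simultaneously localizes the
template reference point in-plane and the plane offset along the normal.

The study this re-implements refined the Hough pose manually inside a GUI;
here that step is an automated bounded local search (`refine_affine`) over
plane tilt, normal offset and in-plane rigid pose, driven by a
distance-transform correlation between cortex masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .imagecore import (BinaryMask, CuttingPlane, AffineTransform2D, SectionImage,
                        VolumeImage, ZStack, cross, downsample)
from .template import (EdgeCloud3D, RTable, build_rtable, gradient_edges_3d,
                       make_landmarks, segment_cortices)

__all__ = ["PoseHypothesis", "Accumulator", "generate_orientations", "ght_search",
           "center_plane_on_section", "rank_hypotheses", "refine_affine",
           "scan_polish", "find_cutting_plane", "extract_oblique_slice",
           "resize_to_section", "propagate_to_channel"]


@dataclass
class PoseHypothesis:
    """One GHT accumulator peak: a plane (centred on the world position of
    the template reference point), its in-plane rotation and its votes."""

    plane: CuttingPlane
    in_plane_rotation: float
    votes: int

    def __post_init__(self):
        if self.votes < 0:
            raise ValueError("votes must be >= 0")


@dataclass
class Accumulator:
    """Bookkeeping of one GHT run.

    ``orientation_grid`` holds (theta, phi, psi) in radians per evaluated
    orientation; ``best_votes``/``best_cells`` record the winning translation
    cell per orientation (the full 4D vote array is never materialized).
    """

    orientation_grid: np.ndarray
    translation_step: float
    best_votes: np.ndarray
    best_cells: np.ndarray


def _rodrigues(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = angle
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(k) * K + (1 - np.cos(k)) * (K @ K)


def generate_orientations(cone_deg=30.0, orientation_step_deg=5.0,
                          psi_step_deg=None, cone_axis=(1.0, 0.0, 0.0)):
    """Candidate (normal, psi) pairs: Fibonacci-spiral normals covering a
    spherical cap of half-angle ``cone_deg`` around ``cone_axis`` at roughly
    ``orientation_step_deg`` spacing, crossed with uniform in-plane rotations.

    Returns (normals, psis): arrays of shape (M, 3) and (K,).
    """
    if psi_step_deg is None:
        psi_step_deg = orientation_step_deg
    theta_max = np.deg2rad(cone_deg)
    step = np.deg2rad(orientation_step_deg)
    cap_area = 2 * np.pi * (1 - np.cos(theta_max))
    n_pts = max(1, int(round(cap_area / step ** 2)))
    i = np.arange(n_pts)
    # uniform in cos(theta) over the cap, golden-angle azimuth
    ct = 1 - (1 - np.cos(theta_max)) * (i + 0.5) / n_pts
    st = np.sqrt(1 - ct ** 2)
    golden = np.pi * (3 - np.sqrt(5))
    az = i * golden
    local = np.stack([ct, st * np.sin(az), st * np.cos(az)], axis=1)  # (z,y,x) about z
    axis = np.asarray(cone_axis, float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([1.0, 0.0, 0.0])
    if np.allclose(axis, z):
        normals = local
    else:
        rot_axis = cross(z, axis)
        if np.linalg.norm(rot_axis) < 1e-12:
            normals = -local
        else:
            ang = np.arccos(np.clip(z @ axis, -1, 1))
            R = _rodrigues(rot_axis, ang)
            normals = local @ R.T
    psis = np.deg2rad(np.arange(0.0, 360.0, psi_step_deg))
    return normals, psis


def _frame_for_normal(n, up_hint=(0.0, 0.0, 1.0)):
    plane = CuttingPlane.from_normal((0, 0, 0), n, up_hint=up_hint)
    return plane.axis_u, plane.axis_v


def ght_search(edges: EdgeCloud3D, rtable: RTable, orientation_step=5.0,
               translation_step=21.0, top_k=5, cone_deg=30.0,
               psi_step=None, cone_axis=(1.0, 0.0, 0.0), gate_deg=30.0,
               angle_spread=1, orientation_gated=True, orientations=None):
    """Vote for the section's plane pose in the volume.

    For each candidate orientation (normal ``n``, in-plane rotation ``psi``),
    edge points whose gradient direction lies within ``gate_deg`` of the
    candidate plane are projected into plane coordinates; each casts the
    R-table offsets of its in-plane gradient-angle bin, voting for the 3D
    world position of the template reference point *at the point's own depth
    along n*. The highest translation cell per orientation is kept and the
    global ``top_k`` peaks are returned, ties broken by smaller tilt from
    ``cone_axis``, then orientation index.

    ``orientations`` may supply an explicit ``(normals, psis)`` pair, which
    overrides the cone grid (used e.g. for equivariance checks).
    """
    if edges.points.shape[0] == 0:
        raise ValueError("empty edge cloud")
    if orientation_step <= 0 or translation_step <= 0:
        raise ValueError("steps must be > 0")
    if orientations is None:
        normals, psis = generate_orientations(cone_deg, orientation_step,
                                              psi_step, cone_axis)
    else:
        normals, psis = orientations
        normals = np.asarray(normals, float).reshape(-1, 3)
        psis = np.asarray(psis, float).reshape(-1)
    axis = np.asarray(cone_axis, float)
    axis = axis / np.linalg.norm(axis)

    offsets, starts, counts = rtable.packed(spread=angle_spread)
    if offsets.shape[0] == 0:
        raise ValueError("empty R-table")
    P = edges.points
    G = edges.gradient_dirs
    gate_sin = np.sin(np.deg2rad(gate_deg))

    orient_rows = []
    best_votes = []
    best_cells = []
    best_meta = []  # (votes, tilt, orient_index, world_point, n, psi)
    oi = 0
    for n in normals:
        u0, v0 = _frame_for_normal(n)
        a = P @ u0
        b = P @ v0
        c = P @ n
        gu0 = G @ u0
        gv0 = G @ v0
        gn = G @ n
        keep = np.abs(gn) <= gate_sin if orientation_gated else np.ones(len(P), bool)
        if not keep.any():
            for psi in psis:
                orient_rows.append((np.arccos(np.clip(n @ axis, -1, 1)),
                                    np.arctan2(n[1], n[2]), psi))
                best_votes.append(0)
                best_cells.append((-1, -1, -1))
                oi += 1
            continue
        ak, bk, ck = a[keep], b[keep], c[keep]
        alpha0 = np.arctan2(gv0[keep], gu0[keep])
        # translation grid in this normal's plane coordinates; pad by the
        # largest offset norm so rotated offsets never leave the grid
        pad = 2 * translation_step + np.linalg.norm(offsets, axis=1).max() + 1.0
        lo = np.array([ak.min(), bk.min(), ck.min()]) - pad
        hi = np.array([ak.max(), bk.max(), ck.max()]) + pad
        gshape = np.ceil((hi - lo) / translation_step).astype(int) + 1
        nc = int(np.prod(gshape))
        tilt = float(np.arccos(np.clip(n @ axis, -1, 1)))
        phi_az = float(np.arctan2(n[1], n[2]))
        # all in-plane rotations of this normal share one accumulator array
        # (stacked along a psi axis) so a single weighted bincount covers them
        flat_all, w_all = [], []
        for pi, psi in enumerate(psis):
            cpsi, spsi = np.cos(psi), np.sin(psi)
            bins = rtable.bin_index(alpha0 - psi)
            cnt = counts[bins]
            total = int(cnt.sum())
            orient_rows.append((tilt, phi_az, psi))
            if total == 0:
                continue
            point_rep = np.repeat(np.arange(len(ak)), cnt)
            off_idx = (np.arange(total)
                       - np.repeat(np.cumsum(cnt) - cnt, cnt)
                       + np.repeat(starts[bins], cnt))
            oc = offsets[off_idx, 1]
            orr = offsets[off_idx, 0]
            # rotate template offsets by psi, express in the (u0, v0) frame
            va = ak[point_rep] + cpsi * oc - spsi * orr
            vb = bk[point_rep] + spsi * oc + cpsi * orr
            vc = ck[point_rep]
            # trilinear splat: each vote spreads over its 8 neighbouring
            # cells so peaks are not fragmented by the grid quantization
            fa = (va - lo[0]) / translation_step - 0.5
            fb = (vb - lo[1]) / translation_step - 0.5
            fc = (vc - lo[2]) / translation_step - 0.5
            ia = np.floor(fa).astype(np.int64)
            ib = np.floor(fb).astype(np.int64)
            ic = np.floor(fc).astype(np.int64)
            wa, wb, wc = fa - ia, fb - ib, fc - ic
            base = pi * nc + (ia * gshape[1] + ib) * gshape[2] + ic
            for da in (0, 1):
                for db in (0, 1):
                    for dc in (0, 1):
                        w = ((wa if da else 1 - wa) * (wb if db else 1 - wb)
                             * (wc if dc else 1 - wc))
                        flat_all.append(base + (da * gshape[1] + db) * gshape[2] + dc)
                        w_all.append(w)
        if flat_all:
            hist = np.bincount(np.concatenate(flat_all),
                               weights=np.concatenate(w_all),
                               minlength=len(psis) * nc).reshape(len(psis), nc)
        else:
            hist = np.zeros((len(psis), nc))
        peaks = hist.argmax(axis=1)
        for pi, psi in enumerate(psis):
            peak = int(peaks[pi])
            votes = float(hist[pi, peak])
            ia0, rem = divmod(peak, int(gshape[1] * gshape[2]))
            ib0, ic0 = divmod(rem, int(gshape[2]))
            best_votes.append(votes)
            best_cells.append((ia0, ib0, ic0))
            if votes > 0:
                wp = ((lo[0] + (ia0 + 0.5) * translation_step) * u0
                      + (lo[1] + (ib0 + 0.5) * translation_step) * v0
                      + (lo[2] + (ic0 + 0.5) * translation_step) * n)
                best_meta.append((votes, tilt, oi + pi, wp, n.copy(), psi))
        oi += len(psis)

    if not best_meta:
        raise RuntimeError(
            f"GHT search failed: no votes cast over {oi} orientations "
            f"(cone {cone_deg} deg, gate {gate_deg} deg)")
    best_meta.sort(key=lambda m: (-m[0], m[1], m[2]))
    hypotheses = []
    for votes, tilt, _, wp, n, psi in best_meta[:top_k]:
        base = CuttingPlane.from_normal(wp, n)
        hypotheses.append(PoseHypothesis(plane=base.rotated_inplane(psi),
                                         in_plane_rotation=float(psi),
                                         votes=votes))
    acc = Accumulator(orientation_grid=np.asarray(orient_rows),
                      translation_step=float(translation_step),
                      best_votes=np.asarray(best_votes),
                      best_cells=np.asarray(best_cells))
    return hypotheses, acc


def center_plane_on_section(plane: CuttingPlane, reference_point, section_shape,
                            section_spacing) -> CuttingPlane:
    """Shift a reference-point-centred plane so its centre maps to the
    section's centre pixel; ``reference_point`` is the template reference in
    section physical (row, col) μm."""
    ref = np.asarray(reference_point, float)
    rows, cols = section_shape
    s = np.atleast_1d(np.asarray(section_spacing, float))
    if s.size == 1:
        s = np.repeat(s, 2)
    center_rc = np.array([(rows - 1) / 2.0 * s[0], (cols - 1) / 2.0 * s[1]])
    shift = ((center_rc[1] - ref[1]) * plane.axis_u
             + (center_rc[0] - ref[0]) * plane.axis_v)
    return CuttingPlane(center=plane.center + shift, axis_u=plane.axis_u,
                        axis_v=plane.axis_v)


def extract_oblique_slice(vol: VolumeImage, plane: CuttingPlane, out_shape,
                          out_spacing):
    """Trilinear oblique reslice of the volume.

    Output pixel (r, c) samples the volume at
    ``center + (c - C) * spacing * u + (r - R) * spacing * v`` with (R, C)
    the image centre. Samples outside the volume are zero-filled; a validity
    mask marks in-bounds pixels. Returns ``(SectionImage, BinaryMask)``.
    """
    rows, cols = out_shape
    s = np.atleast_1d(np.asarray(out_spacing, float))
    if s.size == 1:
        s = np.repeat(s, 2)
    r = (np.arange(rows) - (rows - 1) / 2.0) * s[0]
    c = (np.arange(cols) - (cols - 1) / 2.0) * s[1]
    rr, cc = np.meshgrid(r, c, indexing="ij")
    pts = (plane.center[None, None, :]
           + cc[..., None] * plane.axis_u[None, None, :]
           + rr[..., None] * plane.axis_v[None, None, :])
    idx = (pts - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    valid = np.all((idx >= 0) & (idx <= np.asarray(vol.shape) - 1), axis=-1)
    coords = np.moveaxis(idx, -1, 0)
    data = ndimage.map_coordinates(np.asarray(vol.data, float), coords, order=1,
                                   mode="constant", cval=0.0)
    data[~valid] = 0.0
    return (SectionImage(data=data, spacing=tuple(s)),
            BinaryMask(data=valid, spacing=tuple(s)))


def _mask_feature(mask, blur_px=3.0):
    """Gaussian-blurred soft mask: correlating two of these peaks exactly at
    full overlap (no saturation bias), with a convergence basin of a few
    blur widths."""
    return ndimage.gaussian_filter(mask.astype(float), blur_px)


def _ncc(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return -1.0
    return float(a @ b / denom)


def _section_feature(vol, section, section_mask, work_spacing, seg_keep,
                     blur_px=3.0):
    """Soft-mask feature of the section's cortex mask at working
    resolution; returns (feature, shape, spacing)."""
    if work_spacing is None:
        work_spacing = float(vol.spacing[0])
    if section_mask is None:
        f = max(1, int(round(work_spacing / section.spacing[0])))
        work_sec = downsample(section, f)
        m = segment_cortices(work_sec, keep=seg_keep)
        return _mask_feature(m.data, blur_px), m.data.shape, m.spacing
    f = max(1, int(round(work_spacing / section_mask.spacing[0])))
    mask_w = section_mask.data[::f, ::f]
    sp_w = tuple(np.asarray(section_mask.spacing) * f)
    return _mask_feature(mask_w, blur_px), mask_w.shape, sp_w


def _plane_mask(vol, plane, out_shape, sp_w):
    """Otsu mask of the slice the plane extracts from the volume, or None
    for degenerate slices."""
    sl, valid = extract_oblique_slice(vol, plane, out_shape, sp_w)
    d = sl.data
    vdata = d[valid.data]
    if vdata.size < 16 or vdata.max() <= vdata.min():
        return None
    thr = threshold_otsu(vdata, nbins=256)
    m = (d > thr) & valid.data
    return m if m.any() else None


def _plane_similarity(vol, plane, out_shape, sp_w, feat_sec, blur_px=3.0):
    """NCC between the section's soft cortex mask and the soft Otsu mask of
    the slice the plane extracts from the volume."""
    m = _plane_mask(vol, plane, out_shape, sp_w)
    if m is None:
        return -1.0
    return _ncc(feat_sec, _mask_feature(m, blur_px))


def _plane_dice(vol, plane, mask_sec, sp_w):
    """Dice between the section's cortex mask and the Otsu mask of the
    extracted slice — the sharp selector among refined pose candidates."""
    m = _plane_mask(vol, plane, mask_sec.shape, sp_w)
    if m is None:
        return 0.0
    denom = m.sum() + mask_sec.sum()
    return 2.0 * float((m & mask_sec).sum()) / denom if denom else 0.0


def _xcorr_shift(mask_sec, mask_slice, max_shift_frac=0.25):
    """Integer (dr, dc) shift maximizing the overlap of two binary masks,
    by FFT cross-correlation (wrap-around peaks beyond a quarter of the
    image are rejected)."""
    a = mask_sec.astype(float)
    b = mask_slice.astype(float)
    corr = np.fft.irfft2(np.fft.rfft2(a) * np.conj(np.fft.rfft2(b)), s=a.shape)
    rows, cols = a.shape
    dr = np.fft.fftfreq(rows, 1.0 / rows).astype(int)
    dc = np.fft.fftfreq(cols, 1.0 / cols).astype(int)
    ok_r = np.abs(dr) <= max_shift_frac * rows
    ok_c = np.abs(dc) <= max_shift_frac * cols
    sub = corr[np.ix_(ok_r, ok_c)]
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    return int(dr[ok_r][i]), int(dc[ok_c][j])


def rank_hypotheses(vol: VolumeImage, section: SectionImage, hypotheses,
                    reference_point, work_spacing=None,
                    section_mask: BinaryMask = None, seg_keep=None,
                    depth_sweep=0.0, rescore_top=40):
    """Verify GHT peaks by mask overlap after translation compensation.

    Vote counts propose poses but are blunted by the aperture problem on
    long straight cortical edges, and a peak's translation cell is only
    accurate to the voting grid. Each hypothesis is therefore re-scored at
    working resolution: the slice mask it extracts is aligned to the
    section's cortex mask by FFT cross-correlation (absorbing the vote
    quantization) and scored by Dice. Returns ``(score, section-centred,
    shift-corrected PoseHypothesis)`` pairs, best first.
    """
    if work_spacing is None:
        work_spacing = float(vol.spacing[0])
    f = max(1, int(round(work_spacing / section.spacing[0])))
    if section_mask is None:
        work_sec = downsample(section, f)
        mask_sec = segment_cortices(work_sec, keep=seg_keep).data
        sp_w = work_sec.spacing
    else:
        mask_sec = section_mask.data[::f, ::f]
        sp_w = tuple(np.asarray(section_mask.spacing) * f)
    scored = []
    for i, h in enumerate(hypotheses):
        centered = center_plane_on_section(h.plane, reference_point,
                                           section.shape, section.spacing)
        dice, plane = _aligned_dice(vol, centered, mask_sec, sp_w)
        scored.append((dice, i, PoseHypothesis(plane=plane,
                                               in_plane_rotation=h.in_plane_rotation,
                                               votes=h.votes)))
    scored.sort(key=lambda t: (-t[0], t[1]))
    # second pass: the vote cell localizes the plane offset only to the
    # translation grid, and the in-plane alignment above cannot fix depth;
    # re-score the leading candidates over a depth sweep along their normal
    if depth_sweep > 0:
        dns = [dn for dn in np.arange(-depth_sweep, depth_sweep + 1e-9,
                                      vol.spacing[0]) if dn != 0]
        rescored = []
        for dice, i, h in scored[:rescore_top]:
            cands = [CuttingPlane(center=h.plane.center + dn * h.plane.normal,
                                  axis_u=h.plane.axis_u, axis_v=h.plane.axis_v)
                     for dn in dns]
            d, aligned = _batch_aligned_dice(vol, cands, mask_sec, sp_w)
            j = int(np.argmax(d))
            if d[j] > dice:
                rescored.append((float(d[j]), i,
                                 PoseHypothesis(plane=aligned[j],
                                                in_plane_rotation=h.in_plane_rotation,
                                                votes=h.votes)))
            else:
                rescored.append((dice, i, h))
        rescored.sort(key=lambda t: (-t[0], t[1]))
        scored = rescored + scored[rescore_top:]
    return [(s, h) for s, _, h in scored]


def refine_affine(vol: VolumeImage, section: SectionImage, hypothesis: PoseHypothesis,
                  orientation_step=5.0, translation_step=21.0, slab_h=None,
                  work_spacing=None, section_mask: BinaryMask = None,
                  seg_keep=None, maxfev=400, blur_px=3.0):
    """Bounded local refinement of a GHT pose, in two stages.

    Stage 1 scans a coarse grid over plane tilt (two angles, ±2 orientation
    steps), in-plane rotation (±1 step) and offset along the normal
    (± slab half-thickness); at every node the in-plane translation is
    solved exactly by FFT cross-correlation of the cortex masks and the node
    is scored by mask Dice. Stage 2 polishes the winning node with a Powell
    search over all six parameters, maximizing the NCC of Gaussian-blurred
    cortex masks. The returned objective never falls below the input
    hypothesis'. Returns ``(refined_plane, in_plane_affine, info)`` where
    the affine is the rigid in-plane residual relative to the input frame.

    The input hypothesis plane must already be centred on the section
    (see :func:`center_plane_on_section`).
    """
    if slab_h is None:
        slab_h = 1.5 * float(vol.spacing[0])
    feat_sec, out_shape, sp_w = _section_feature(vol, section, section_mask,
                                                 work_spacing, seg_keep,
                                                 blur_px=blur_px)
    mask_sec = feat_sec > 0.5 * feat_sec.max()
    if section_mask is None:
        f = max(1, int(round((work_spacing or vol.spacing[0]) / section.spacing[0])))
        work_sec = downsample(section, f)
        mask_sec = segment_cortices(work_sec, keep=seg_keep).data

    p0 = hypothesis.plane
    n0, u0, v0 = p0.normal, p0.axis_u, p0.axis_v

    def plane_at(x):
        ta, tb, dn, dpsi, tr, tc = x
        R = _rodrigues(u0, ta) @ _rodrigues(v0, tb)
        n = R @ n0
        u = R @ u0
        # re-orthonormalize against numerical drift
        n = n / np.linalg.norm(n)
        u = u - (u @ n) * n
        u = u / np.linalg.norm(u)
        v = cross(n, u)
        v = v / np.linalg.norm(v)
        pl = CuttingPlane(center=p0.center + dn * n0, axis_u=u, axis_v=v)
        pl = pl.rotated_inplane(dpsi)
        return CuttingPlane(center=pl.center + tc * pl.axis_u + tr * pl.axis_v,
                            axis_u=pl.axis_u, axis_v=pl.axis_v)

    def objective(x):
        return -_plane_similarity(vol, plane_at(x), out_shape, sp_w, feat_sec,
                                  blur_px=blur_px)

    step_rad = np.deg2rad(orientation_step)

    # ---- stage 1: tilt/rotation/depth grid with xcorr translation --------
    tilt_grid = np.linspace(-2 * step_rad, 2 * step_rad, 5)
    psi_grid = np.array([-step_rad, 0.0, step_rad])
    n_dn = max(3, 2 * int(np.ceil(slab_h / vol.spacing[0])) + 1)
    dn_grid = np.linspace(-slab_h, slab_h, n_dn)
    nodes = [np.array([ta, tb, dn, dpsi, 0.0, 0.0])
             for ta in tilt_grid for tb in tilt_grid
             for dpsi in psi_grid for dn in dn_grid]
    dices, aligned_planes = _batch_aligned_dice(vol, [plane_at(x) for x in nodes],
                                                mask_sec, sp_w)
    best_i = int(np.argmax(dices))
    x1 = nodes[best_i].copy()
    # recover the xcorr translation of the winning node in (tr, tc) form
    shift_world = aligned_planes[best_i].center - plane_at(x1).center
    x1[4] = float(shift_world @ aligned_planes[best_i].axis_v)
    x1[5] = float(shift_world @ aligned_planes[best_i].axis_u)
    best_node = (float(dices[best_i]), x1)

    # ---- stage 2: Powell polish around the grid winner -------------------
    gs = tilt_grid[1] - tilt_grid[0]
    dn_s = dn_grid[1] - dn_grid[0]
    bounds = [(x1[0] - gs, x1[0] + gs), (x1[1] - gs, x1[1] + gs),
              (x1[2] - dn_s, x1[2] + dn_s), (x1[3] - step_rad, x1[3] + step_rad),
              (x1[4] - translation_step, x1[4] + translation_step),
              (x1[5] - translation_step, x1[5] + translation_step)]
    f0 = objective(np.zeros(6))
    res = optimize.minimize(objective, x1, method="Powell", bounds=bounds,
                            options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-6})
    x = res.x if res.fun <= f0 else np.zeros(6)
    fbest = min(float(res.fun), f0)
    at_bound = bool(res.fun > f0)
    if at_bound:
        warnings.warn("refine_affine could not improve on the input hypothesis",
                      stacklevel=2)
    plane = plane_at(x)
    dpsi, tr, tc = x[3], x[4], x[5]
    cpsi, spsi = np.cos(dpsi), np.sin(dpsi)
    affine = AffineTransform2D(matrix=np.array([[cpsi, -spsi], [spsi, cpsi]]),
                               translation=np.array([tr, tc]))
    return plane, affine, {"objective": -fbest, "initial_objective": -f0,
                           "at_boundary": at_bound, "grid_dice": best_node[0]}


def _aligned_dice(vol, plane, mask_sec, sp_w):
    """Dice between the section mask and the plane's slice mask after
    integer-pixel cross-correlation alignment; returns (dice, aligned plane)."""
    m = _plane_mask(vol, plane, mask_sec.shape, sp_w)
    if m is None:
        return 0.0, plane
    dr, dc = _xcorr_shift(mask_sec, m)
    aligned = np.roll(m, (dr, dc), axis=(0, 1))
    dice = 2.0 * float((aligned & mask_sec).sum()) / (aligned.sum() + mask_sec.sum())
    shifted = CuttingPlane(center=plane.center - dc * sp_w[1] * plane.axis_u
                           - dr * sp_w[0] * plane.axis_v,
                           axis_u=plane.axis_u, axis_v=plane.axis_v)
    return dice, shifted


def _batch_aligned_dice(vol, planes, mask_sec, sp_w, chunk=24):
    """Vectorized :func:`_aligned_dice` over many candidate planes.

    Slices are extracted in chunked ``map_coordinates`` calls (bounding the
    coordinate-buffer memory) and cross-correlations run as batched FFTs;
    returns (dice array, aligned-plane list).
    """
    if len(planes) > chunk:
        dices, outs = [], []
        for i in range(0, len(planes), chunk):
            d, o = _batch_aligned_dice(vol, planes[i:i + chunk], mask_sec, sp_w,
                                       chunk=chunk)
            dices.append(d)
            outs.extend(o)
        return np.concatenate(dices), outs
    rows, cols = mask_sec.shape
    r = (np.arange(rows) - (rows - 1) / 2.0) * sp_w[0]
    c = (np.arange(cols) - (cols - 1) / 2.0) * sp_w[1]
    rr, cc = np.meshgrid(r.astype(np.float32), c.astype(np.float32),
                         indexing="ij")
    sp_vol = np.asarray(vol.spacing)
    centers = (np.stack([pl.center for pl in planes]) - np.asarray(vol.origin)) / sp_vol
    us = np.stack([pl.axis_u for pl in planes]) / sp_vol
    vs = np.stack([pl.axis_v for pl in planes]) / sp_vol
    idx = (centers[:, None, None, :].astype(np.float32)
           + cc[None, ..., None] * us[:, None, None, :].astype(np.float32)
           + rr[None, ..., None] * vs[:, None, None, :].astype(np.float32))
    hi = (np.asarray(vol.shape) - 1).astype(np.float32)
    valid = ((idx >= 0) & (idx <= hi)).all(axis=-1)
    coords = np.moveaxis(idx, -1, 0).reshape(3, -1)
    data = ndimage.map_coordinates(np.asarray(vol.data, np.float32), coords,
                                   order=1, mode="constant", cval=0.0
                                   ).reshape(len(planes), rows, cols)
    masks = np.zeros_like(valid)
    for i in range(len(planes)):
        v = data[i][valid[i]]
        if v.size < 16 or v.max() <= v.min():
            continue
        thr = threshold_otsu(v, nbins=256)
        masks[i] = (data[i] > thr) & valid[i]
    F_sec = np.fft.rfft2(mask_sec.astype(float))
    corr = np.fft.irfft2(F_sec[None] * np.conj(np.fft.rfft2(masks.astype(float),
                                                            axes=(-2, -1))),
                         s=mask_sec.shape, axes=(-2, -1))
    drs = np.fft.fftfreq(rows, 1.0 / rows).astype(int)
    dcs = np.fft.fftfreq(cols, 1.0 / cols).astype(int)
    ok_r = np.abs(drs) <= 0.25 * rows
    ok_c = np.abs(dcs) <= 0.25 * cols
    sub = corr[:, ok_r][:, :, ok_c]
    dice = np.zeros(len(planes))
    out_planes = []
    denom_sec = mask_sec.sum()
    for i, pl in enumerate(planes):
        if not masks[i].any():
            out_planes.append(pl)
            continue
        a, b = np.unravel_index(np.argmax(sub[i]), sub[i].shape)
        dr, dc = int(drs[ok_r][a]), int(dcs[ok_c][b])
        aligned = np.roll(masks[i], (dr, dc), axis=(0, 1))
        dice[i] = 2.0 * float((aligned & mask_sec).sum()) / (aligned.sum() + denom_sec)
        out_planes.append(CuttingPlane(center=pl.center - dc * sp_w[1] * pl.axis_u
                                       - dr * sp_w[0] * pl.axis_v,
                                       axis_u=pl.axis_u, axis_v=pl.axis_v))
    return dice, out_planes


def scan_polish(vol: VolumeImage, section: SectionImage, plane: CuttingPlane,
                work_spacing=None, section_mask: BinaryMask = None, seg_keep=None,
                tilt_limit_deg=3.0, tilt_step_deg=0.75, psi_limit_deg=2.0,
                psi_step_deg=0.5, iterations=2, depth_range=None,
                shear_limit=0.01, shear_steps=5):
    """Deterministic pose polish by coordinate scans.

    Alternates (a) a 2D scan over the two plane-tilt angles, (b) a 1D scan
    of the offset along the normal, (c) a 1D scan of the in-plane rotation
    and (d) a 1D scan of an in-plane shear nuisance, scoring every node by
    cortex-mask Dice after exact cross-correlation translation alignment.
    Scan ranges halve per iteration. Robust where a joint 6-parameter
    optimization stalls: each scan is exhaustive on its axis, and the
    translation is solved in closed form at every node.

    The shear is applied to the *section* mask and absorbs the globally
    coherent component of the sectioning distortion, which would otherwise
    bias the recovered tilt; it never enters the returned plane. Returns
    ``(plane, dice)``.
    """
    if work_spacing is None:
        work_spacing = float(vol.spacing[0]) / 2.0
    f = max(1, int(round(work_spacing / section.spacing[0])))
    if section_mask is None:
        work_sec = downsample(section, f)
        mask_sec = segment_cortices(work_sec, keep=seg_keep).data
        sp_w = work_sec.spacing
    else:
        mask_sec = section_mask.data[::f, ::f]
        sp_w = tuple(np.asarray(section_mask.spacing) * f)

    # precompute sheared section-mask variants (col' = col + k (row - R))
    shears = np.linspace(-shear_limit, shear_limit, shear_steps) \
        if shear_limit > 0 else np.array([0.0])
    rows = mask_sec.shape[0]
    variants = []
    for k in shears:
        if k == 0:
            variants.append(mask_sec)
            continue
        M = np.array([[1.0, 0.0], [k, 1.0]])
        off = np.array([0.0, -k * (rows - 1) / 2.0])
        sheared = ndimage.affine_transform(mask_sec.astype(float), M, offset=off,
                                           order=1, mode="constant", cval=0.0)
        variants.append(sheared > 0.5)
    cur = int(np.argmin(np.abs(shears)))  # start unsheared

    def _rescan_shear(plane, best_dice, cur):
        m = _plane_mask(vol, plane, mask_sec.shape, sp_w)
        if m is None:
            return best_dice, plane, cur
        for vi, vmask in enumerate(variants):
            dr, dc = _xcorr_shift(vmask, m)
            aligned = np.roll(m, (dr, dc), axis=(0, 1))
            d = 2.0 * float((aligned & vmask).sum()) / (aligned.sum() + vmask.sum())
            if d > best_dice:
                best_dice, cur = d, vi
                plane = CuttingPlane(center=plane.center - dc * sp_w[1] * plane.axis_u
                                     - dr * sp_w[0] * plane.axis_v,
                                     axis_u=plane.axis_u, axis_v=plane.axis_v)
        return best_dice, plane, cur

    best_dice, plane = _aligned_dice(vol, plane, variants[cur], sp_w)
    best_dice, plane, cur = _rescan_shear(plane, best_dice, cur)
    mask_sec = variants[cur]

    def _take_best(cands, best_dice, plane):
        if not cands:
            return best_dice, plane
        d, aligned = _batch_aligned_dice(vol, cands, mask_sec, sp_w)
        i = int(np.argmax(d))
        if d[i] > best_dice:
            return float(d[i]), aligned[i]
        return best_dice, plane

    # optional wide depth sweep first: accumulator peaks (and near-mirror
    # cuts of the almost-symmetric shell) can sit several voxels off along
    # the normal, far beyond the per-iteration depth step below
    if depth_range is not None and depth_range > 0:
        c0, n0 = plane.center, plane.normal
        cands = [CuttingPlane(center=c0 + dn * n0, axis_u=plane.axis_u,
                              axis_v=plane.axis_v)
                 for dn in np.arange(-depth_range, depth_range + 1e-9,
                                     vol.spacing[0] / 2.0) if dn != 0]
        best_dice, plane = _take_best(cands, best_dice, plane)
    tl, ts = np.deg2rad(tilt_limit_deg), np.deg2rad(tilt_step_deg)
    pl_, ps = np.deg2rad(psi_limit_deg), np.deg2rad(psi_step_deg)
    dn_limit = float(vol.spacing[0])
    for it in range(iterations):
        # (a) tilt scan
        u0, v0, n0, c0 = plane.axis_u, plane.axis_v, plane.normal, plane.center
        cands = []
        for ta in np.arange(-tl, tl + ts / 2, ts):
            for tb in np.arange(-tl, tl + ts / 2, ts):
                R = _rodrigues(u0, ta) @ _rodrigues(v0, tb)
                n = R @ n0
                u = R @ u0
                u = u - (u @ n) * n
                u /= np.linalg.norm(u)
                v = cross(n, u)
                v /= np.linalg.norm(v)
                cands.append(CuttingPlane(center=c0, axis_u=u, axis_v=v))
        best_dice, plane = _take_best(cands, best_dice, plane)
        # (b) offset along the normal
        c0, n0 = plane.center, plane.normal
        cands = [CuttingPlane(center=c0 + dn * n0, axis_u=plane.axis_u,
                              axis_v=plane.axis_v)
                 for dn in np.arange(-dn_limit, dn_limit + 1e-9, dn_limit / 4)
                 if dn != 0]
        best_dice, plane = _take_best(cands, best_dice, plane)
        # (c) in-plane rotation
        cands = [plane.rotated_inplane(dpsi)
                 for dpsi in np.arange(-pl_, pl_ + ps / 2, ps) if dpsi != 0]
        best_dice, plane = _take_best(cands, best_dice, plane)
        # (d) shear nuisance of the section mask
        best_dice, plane, cur = _rescan_shear(plane, best_dice, cur)
        mask_sec = variants[cur]
        tl, ts = tl / 2, ts / 2
        pl_, ps = pl_ / 2, ps / 2
        dn_limit /= 2
    return plane, best_dice


def find_cutting_plane(volume: VolumeImage, section: SectionImage,
                       volume_ds_factor=2, mag_percentile=95.0, max_edge_points=3000,
                       n_landmarks=360, angle_bin_deg=5.0, angle_spread=1,
                       orientation_step=5.0, psi_step=15.0, cone_deg=30.0,
                       gate_deg=30.0, translation_step_factor=1.5, top_k=300,
                       rank_candidates=None, refine_candidates=4,
                       polish_candidates=3, seg_keep=None, refine_maxfev=200):
    """Full slice-to-volume search: template building, GHT voting,
    similarity verification of the top peaks, and local refinement of the
    best few, returning the winner by refined objective.

    Returns ``(plane, affine, info)``; the plane is section-centred, ready
    for :func:`extract_oblique_slice` at the section's shape and spacing.
    ``info`` carries the refined objective, the winning hypothesis' votes
    and the accumulator.
    """
    # cache a float64 volume once: every scan node resamples it
    if volume.data.dtype != np.float64:
        volume = VolumeImage(data=volume.data.astype(np.float64),
                             spacing=volume.spacing, origin=volume.origin)
    f2d = max(1, int(round(volume.spacing[0] / section.spacing[0])))
    work_sec = downsample(section, f2d)
    sec_mask = segment_cortices(work_sec, keep=seg_keep)
    landmarks = make_landmarks(sec_mask, work_sec, n_landmarks)
    rtable = build_rtable(landmarks, np.deg2rad(angle_bin_deg))

    vol_ds = downsample(volume, volume_ds_factor) if volume_ds_factor > 1 else volume
    edges = gradient_edges_3d(vol_ds, mag_percentile, max_points=max_edge_points)
    tstep = translation_step_factor * vol_ds.spacing[0]
    hyps, acc = ght_search(edges, rtable, orientation_step=orientation_step,
                           translation_step=tstep, top_k=top_k, cone_deg=cone_deg,
                           psi_step=psi_step, gate_deg=gate_deg,
                           angle_spread=angle_spread)
    if rank_candidates is not None:
        hyps = hyps[:rank_candidates]
    ranked = rank_hypotheses(volume, section, hyps, rtable.reference_point,
                             section_mask=None, seg_keep=seg_keep,
                             depth_sweep=3.0 * tstep)
    # sharp selector for refined candidates: cortex-mask Dice at half-voxel
    # working resolution
    fine_sp = volume.spacing[0] / 2.0
    f_fine = max(1, int(round(fine_sp / section.spacing[0])))
    work_fine = downsample(section, f_fine)
    mask_fine = segment_cortices(work_fine, keep=seg_keep).data
    coarse = []
    for score, h in ranked[:refine_candidates]:
        plane, affine, info = refine_affine(volume, section, h,
                                            orientation_step=orientation_step,
                                            translation_step=tstep,
                                            slab_h=max(1.5 * volume.spacing[0], tstep),
                                            seg_keep=seg_keep, maxfev=refine_maxfev,
                                            blur_px=4.0)
        dice = _plane_dice(volume, plane, mask_fine, work_fine.spacing)
        coarse.append((dice, score, plane, affine, dict(info, votes=h.votes,
                                                        verification_dice=score)))
    coarse.sort(key=lambda t: -t[0])
    # polish the leading candidates at double resolution with a tight search
    # box; only there does the cortex-mask Dice separate the true pose from
    # near-miss basins, so the final selection happens after polishing
    best = None
    # polish each leading candidate, finishing at the section's native
    # resolution; competing near-miss basins are separated by only a few
    # thousandths of Dice at half-voxel resolution, so the selection itself
    # must happen on the native-resolution score
    fine_spacing = max(section.spacing[0], volume.spacing[0] / 3.0)
    f_sel = max(1, int(round(fine_spacing / section.spacing[0])))
    sel_sec = downsample(section, f_sel) if f_sel > 1 else section
    sel_mask = BinaryMask(segment_cortices(sel_sec, keep=seg_keep).data,
                          sel_sec.spacing)
    for dice0, score, plane, affine, info in coarse[:polish_candidates]:
        plane2, _ = scan_polish(volume, section, plane,
                                work_spacing=volume.spacing[0] / 2.0,
                                seg_keep=seg_keep, tilt_limit_deg=4.0,
                                tilt_step_deg=1.0, iterations=3,
                                depth_range=8.0 * volume.spacing[0])
        plane2, dice2 = scan_polish(volume, sel_sec, plane2,
                                    work_spacing=sel_sec.spacing[0],
                                    section_mask=sel_mask,
                                    seg_keep=seg_keep, tilt_limit_deg=1.0,
                                    tilt_step_deg=0.25, iterations=1)
        info = dict(info, final_dice=dice2)
        if best is None or dice2 > best[0]:
            best = (dice2, plane2, affine, info)
    _, plane, affine, info = best
    info["accumulator"] = acc
    return plane, affine, info


def resize_to_section(slc: SectionImage, target: SectionImage) -> SectionImage:
    """Bilinear resample to the target's shape and spacing (the physical
    extent is mapped edge to edge)."""
    if slc.shape == target.shape:
        return SectionImage(data=slc.data.copy(), spacing=target.spacing)
    data = _sk_resize(np.asarray(slc.data, float), target.shape, order=1,
                      mode="edge", anti_aliasing=False, preserve_range=True)
    return SectionImage(data=data, spacing=target.spacing)


def propagate_to_channel(other, affine: AffineTransform2D, reference_shape=None):
    """Apply the section's in-plane transform to a co-acquired channel.

    The channel must share the section's shape and spacing (same-device
    contract); a ZStack is transformed slice-wise. The transform maps content
    forward: a pure translation of (dr, dc) μm shifts structures by that
    amount.
    """
    if isinstance(other, ZStack):
        slices = [propagate_to_channel(s, affine, reference_shape) for s in other.slices]
        return ZStack(slices=slices, z_spacing=other.z_spacing)
    if reference_shape is not None and tuple(other.shape) != tuple(reference_shape):
        raise ValueError(f"channel shape {other.shape} does not match the "
                         f"registered section shape {tuple(reference_shape)}")
    s = np.asarray(other.spacing)
    D = np.diag(s)
    Dinv = np.diag(1.0 / s)
    Ainv = np.linalg.inv(affine.matrix)
    M = Dinv @ Ainv @ D
    off = -Dinv @ (Ainv @ affine.translation)
    data = ndimage.affine_transform(np.asarray(other.data, float), M, offset=off,
                                    order=1, mode="constant", cval=0.0)
    return SectionImage(data=data, spacing=other.spacing)
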