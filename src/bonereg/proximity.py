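"""Co-localization by nearest distances between signal channels.

For each channel the best-focused slice of its Z-stack is selected by the
variance-of-Laplacian criterion, positive signal is segmented with Otsu's
threshold, and for every positive pixel of a query channel the minimum
Euclidean distance (μm) to the positive pixels of a target channel is
computed. Distance vectors are compared between groups with the two-sided
Wilcoxon rank-sum (Mann–Whitney) test.

Memory is bounded by streaming query pixels in row blocks against one
KD-tree built over *all* target pixels, so the block size is a pure memory
knob and never changes the result. A literal within-block variant (each
block searched only against its own target pixels, which biases distances
upward near block borders) is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from skimage.filters import threshold_otsu

from .imagecore import BinaryMask, SectionImage, ZStack
from .evalmetrics import SplitRegions

__all__ = ["DistanceSamples", "best_focus_index", "positive_mask",
           "min_distances", "gap_restrict", "compare_groups",
           "significance_stars"]


@dataclass
class DistanceSamples:
    """Minimum distances (μm), one per positive pixel of the query channel,
    in row-major query order; ``rows``/``cols`` give each sample's pixel."""

    distances: np.ndarray
    query_channel: str = "query"
    target_channel: str = "target"
    rows: np.ndarray = None
    cols: np.ndarray = None

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float).reshape(-1)
        if (self.distances < 0).any():
            raise ValueError("distances must be >= 0")

    @property
    def n_query(self):
        return self.distances.size

    def summary(self):
        d = self.distances
        if d.size == 0:
            return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
        return {"n": int(d.size), "median": float(np.median(d)),
                "q1": float(np.percentile(d, 25)), "q3": float(np.percentile(d, 75))}


def best_focus_index(stack: ZStack) -> int:
    """Index of the best-focused slice: argmax of the variance of the
    Laplacian-filtered slice; ties go to the smallest index."""
    scores = [float(np.var(ndimage.laplace(np.asarray(s.data, float))))
              for s in stack.slices]
    return int(np.argmax(scores))


def positive_mask(img: SectionImage) -> BinaryMask:
    """Pixels strictly above the Otsu threshold (256-bin histogram).

    The threshold is placed at the upper edge of Otsu's last background bin
    (``threshold_otsu`` returns that bin's centre, which would misclassify
    in-bin values above the centre relative to the variance-optimal
    partition of the histogram).
    """
    data = np.asarray(img.data, float)
    if data.max() <= data.min():
        raise ValueError("degenerate intensity range; cannot threshold a constant image")
    thr = threshold_otsu(data, nbins=256)
    edges = np.histogram_bin_edges(data, bins=256)
    i = min(np.searchsorted(edges, thr, side="right"), len(edges) - 1)
    thr = np.nextafter(edges[i], edges[i - 1])
    return BinaryMask(data=data > thr, spacing=img.spacing)


def min_distances(query: BinaryMask, target: BinaryMask, block_rows: int = 256,
                  query_channel: str = "query", target_channel: str = "target",
                  within_block_only: bool = False, pixel_units: bool = False) -> DistanceSamples:
    """Per-query-pixel minimum Euclidean distance to the target mask.

    Distances are physical (μm) by default, or in pixels with
    ``pixel_units=True``. The default strategy indexes *all* target pixels
    once and streams query rows in blocks of ``block_rows``; results are
    bit-identical for every block size. ``within_block_only=True`` restricts
    each block's search to the target pixels of the same row block
    (comparison mode; blocks without target pixels yield inf distances).
    """
    if query.shape != target.shape:
        raise ValueError("masks must share shape")
    if block_rows < 1:
        raise ValueError("block_rows must be >= 1")
    sp = np.ones(2) if pixel_units else np.asarray(query.spacing, float)
    tpix = np.argwhere(target.data)
    if tpix.shape[0] == 0:
        raise ValueError("target mask is empty")
    dists, rows_all, cols_all = [], [], []
    tree = None if within_block_only else cKDTree(tpix * sp)
    nrows = query.shape[0]
    for r0 in range(0, nrows, block_rows):
        r1 = min(r0 + block_rows, nrows)
        qpix = np.argwhere(query.data[r0:r1])
        if qpix.shape[0] == 0:
            continue
        qpix[:, 0] += r0
        if within_block_only:
            tblk = tpix[(tpix[:, 0] >= r0) & (tpix[:, 0] < r1)]
            if tblk.shape[0] == 0:
                d = np.full(qpix.shape[0], np.inf)
            else:
                d, _ = cKDTree(tblk * sp).query(qpix * sp)
        else:
            d, _ = tree.query(qpix * sp)
        dists.append(d)
        rows_all.append(qpix[:, 0])
        cols_all.append(qpix[:, 1])
    if dists:
        distances = np.concatenate(dists)
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
    else:
        distances = np.zeros(0)
        rows = cols = np.zeros(0, int)
    return DistanceSamples(distances=distances, query_channel=query_channel,
                           target_channel=target_channel, rows=rows, cols=cols)


def gap_restrict(mask: BinaryMask, regions: SplitRegions) -> BinaryMask:
    """Restrict a signal mask to the osteotomy-gap band."""
    if mask.shape != regions.gap_mask.shape:
        raise ValueError("mask and regions must share shape")
    return BinaryMask(data=mask.data & regions.gap_mask.data, spacing=mask.spacing)


def compare_groups(a: DistanceSamples, b: DistanceSamples):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison of two distance
    distributions. Returns ``(statistic, p_value)``; degenerate all-tied
    input yields p = 1 with a warning."""
    xa = np.asarray(a.distances if isinstance(a, DistanceSamples) else a, float)
    xb = np.asarray(b.distances if isinstance(b, DistanceSamples) else b, float)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([xa, xb])).size == 1:
        warnings.warn("all observations tied; p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    res = mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Significance labels at the .05 / .01 / .0001 thresholds."""
    if p < 1e-4:
        return "****"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
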