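"""Focus selection, Otsu positive masks, minimum distances, rank-sum test."""

import itertools

import numpy as np
import pytest
from scipy.spatial import distance_matrix

from bonereg import (BinaryMask, SectionImage, ZStack, best_focus_index,
                     compare_groups, gap_restrict, min_distances, positive_mask,
                     significance_stars)
from bonereg.proximity import DistanceSamples


def _mask(data, spacing=(1.0, 1.0)):
    return BinaryMask(np.asarray(data, bool), spacing)


class TestBestFocus:
    def test_single_slice(self):
        img = SectionImage(np.random.default_rng(0).random((16, 16)), (1, 1))
        assert best_focus_index(ZStack([img], z_spacing=1.0)) == 0

    def test_identical_slices_tie_to_first(self):
        img = SectionImage(np.random.default_rng(1).random((16, 16)), (1, 1))
        stack = ZStack([img, SectionImage(img.data.copy(), (1, 1))], z_spacing=1.0)
        assert best_focus_index(stack) == 0

    def test_phantom_focus_recovered(self, bundle_warped):
        _, b = bundle_warped
        assert best_focus_index(b.shg_stack) == b.focus_index
        assert best_focus_index(b.osx_stack) == b.focus_index


class TestPositiveMask:
    def test_two_level_image_matches_exhaustive_otsu_oracle(self):
        rng = np.random.default_rng(2)
        data = np.where(rng.random((40, 40)) < 0.3, 10.0, 200.0)
        # oracle: exhaustive inter-class variance maximization over 256 bins
        img = data
        lo, hi = img.min(), img.max()
        edges = np.linspace(lo, hi, 257)
        centers = (edges[:-1] + edges[1:]) / 2
        best_t, best_v = None, -1
        for t in centers:
            below, above = img[img <= t], img[img > t]
            if below.size == 0 or above.size == 0:
                continue
            w0, w1 = below.size, above.size
            v = w0 * w1 * (below.mean() - above.mean()) ** 2
            if v > best_v:
                best_v, best_t = v, t
        oracle = img > best_t
        got = positive_mask(SectionImage(data, (1, 1)))
        np.testing.assert_array_equal(got.data, oracle)
        assert got.data.sum() == (data == 200.0).sum()

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            positive_mask(SectionImage(np.ones((8, 8)), (1, 1)))

    def test_shift_invariance_on_two_level_image(self):
        rng = np.random.default_rng(3)
        data = np.where(rng.random((30, 30)) < 0.5, 1.0, 5.0)
        a = positive_mask(SectionImage(data, (1, 1)))
        b = positive_mask(SectionImage(data + 17.0, (1, 1)))
        np.testing.assert_array_equal(a.data, b.data)


class TestMinDistances:
    def test_self_distances_are_zero(self):
        rng = np.random.default_rng(4)
        m = _mask(rng.random((20, 20)) < 0.2)
        s = min_distances(m, m)
        assert s.n_query == int(m.data.sum())
        np.testing.assert_array_equal(s.distances, 0.0)

    def test_three_four_five_triangle(self):
        q = np.zeros((8, 8), bool); q[0, 0] = True
        t = np.zeros((8, 8), bool); t[3, 4] = True
        s = min_distances(_mask(q), _mask(t))
        np.testing.assert_allclose(s.distances, [5.0])

    def test_physical_units_respect_spacing(self):
        q = np.zeros((4, 4), bool); q[0, 0] = True
        t = np.zeros((4, 4), bool); t[0, 2] = True
        s = min_distances(_mask(q, (2.0, 3.5)), _mask(t, (2.0, 3.5)))
        np.testing.assert_allclose(s.distances, [7.0])

    @pytest.mark.parametrize("block_rows", [1, 7, 64])
    def test_blockwise_equals_all_pairs_brute_force(self, block_rows):
        rng = np.random.default_rng(5)
        q = _mask(rng.random((64, 64)) < 0.05)
        t = _mask(rng.random((64, 64)) < 0.05)
        s = min_distances(q, t, block_rows=block_rows)
        qpix = np.argwhere(q.data).astype(float)
        tpix = np.argwhere(t.data).astype(float)
        oracle = distance_matrix(qpix, tpix).min(axis=1)
        np.testing.assert_array_equal(s.distances, oracle)

    def test_block_size_never_changes_results(self):
        rng = np.random.default_rng(6)
        q = _mask(rng.random((64, 64)) < 0.1)
        t = _mask(rng.random((64, 64)) < 0.1)
        ref = min_distances(q, t, block_rows=64).distances
        for br in (1, 7, 13):
            np.testing.assert_array_equal(min_distances(q, t, block_rows=br).distances,
                                          ref)

    def test_empty_target_rejected_empty_query_ok(self):
        q = _mask(np.ones((4, 4)))
        empty = _mask(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            min_distances(q, empty)
        s = min_distances(empty, q)
        assert s.n_query == 0

    def test_within_block_only_biases_upward(self):
        """The literal per-block variant can only overestimate distances."""
        rng = np.random.default_rng(7)
        q = _mask(rng.random((64, 64)) < 0.1)
        t = _mask(rng.random((64, 64)) < 0.1)
        full = min_distances(q, t, block_rows=16).distances
        literal = min_distances(q, t, block_rows=16, within_block_only=True).distances
        assert (literal >= full - 1e-12).all()
        assert literal.sum() > full.sum()


class TestGapRestrict:
    def test_whole_image_gap_is_noop_empty_gap_empties(self):
        from bonereg.evalmetrics import SplitRegions
        m = _mask(np.random.default_rng(8).random((10, 10)) < 0.4)
        full = SplitRegions(_mask(np.zeros((10, 10))), _mask(np.zeros((10, 10))),
                            _mask(np.ones((10, 10))))
        np.testing.assert_array_equal(gap_restrict(m, full).data, m.data)
        prox = np.zeros((10, 10), bool); prox[:, :5] = True
        dist = ~prox
        none = SplitRegions(_mask(prox), _mask(dist), _mask(np.zeros((10, 10))))
        assert gap_restrict(m, none).data.sum() == 0

    def test_phantom_restriction_contained_in_gap_band(self, bundle_warped):
        from bonereg import split_regions
        _, b = bundle_warped
        mask = b.true_section_mask
        regions = split_regions(mask, mask)
        osx = positive_mask(b.osx_stack.slices[b.focus_index])
        restricted = gap_restrict(osx, regions)
        assert (restricted.data & ~regions.gap_mask.data).sum() == 0


class TestCompareGroups:
    def test_identical_samples_not_significant(self):
        a = DistanceSamples(np.arange(50, dtype=float))
        stat, p = compare_groups(a, a)
        assert p > 0.9

    def test_shifted_samples_highly_significant(self):
        rng = np.random.default_rng(9)
        a = DistanceSamples(rng.gamma(2.0, 5.0, 200))
        b = DistanceSamples(a.distances + 10.0)
        _, p = compare_groups(a, b)
        assert p < 1e-4

    def test_tiny_samples_match_exact_permutation_enumeration(self):
        """{1,2} vs {3,4}: enumerate all C(4,2) label assignments and count
        rank sums at least as extreme (two-sided)."""
        a, b = [1.0, 2.0], [3.0, 4.0]
        pooled = a + b
        obs = sum(sorted(pooled).index(x) + 1 for x in a)
        n = len(a)
        ranks = []
        for comb in itertools.combinations(range(4), n):
            ranks.append(sum(sorted(pooled).index(pooled[i]) + 1 for i in comb))
        mu = np.mean(ranks)
        extreme = sum(1 for r in ranks if abs(r - mu) >= abs(obs - mu) - 1e-12)
        p_exact = extreme / len(ranks)
        _, p = compare_groups(DistanceSamples(a), DistanceSamples(b))
        assert p == pytest.approx(p_exact, abs=1e-12)

    def test_all_tied_degenerate(self):
        a = DistanceSamples(np.full(5, 2.0))
        with pytest.warns(UserWarning):
            stat, p = compare_groups(a, a)
        assert p == 1.0

    def test_star_labels(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-5) == "****"


def test_planted_blob_offset_recovered(bundle_plain):
    """Median OSX-to-mineral minimum distance equals the planted offset
    within one fine pixel."""
    spec, b = bundle_plain
    osx = positive_mask(b.osx_stack.slices[b.focus_index])
    target = BinaryMask(b.true_section_mask.data, b.true_section_mask.spacing)
    s = min_distances(osx, target)
    med = np.median(s.distances)
    assert abs(med - spec.osx_offset) <= spec.section_spacing
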