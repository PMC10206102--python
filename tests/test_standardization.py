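"""Per-pixel histogram specification: histograms, CDF matching, LUTs."""

import numpy as np
import pytest

from galofrec import (accumulate_pixel_histograms, apply_lut_set,
                      build_lut_set, match_cdf, pooled_reference_histogram)
from galofrec.standardization import LUTSet, PixelHistogramStack, ReferenceDistribution


def brute_force_tally(stack):
    n, h, w, c = stack.shape
    counts = np.zeros((h, w, c, 256), dtype=np.int64)
    for frame in stack:
        for y in range(h):
            for x in range(w):
                for ch in range(c):
                    counts[y, x, ch, frame[y, x, ch]] += 1
    return counts


def random_cdf(rng):
    pmf = rng.random(256)
    pmf[rng.random(256) < 0.7] = 0.0  # sparse support, like real histograms
    pmf[rng.integers(256)] += 1.0
    pmf /= pmf.sum()
    return pmf.cumsum()


class TestAccumulate:
    def test_constant_stack(self):
        stack = np.full((3, 4, 4, 3), 7, dtype=np.uint8)
        histos = accumulate_pixel_histograms(stack)
        assert (histos.counts[..., 7] == 3).all()
        assert histos.counts.sum() == 3 * 4 * 4 * 3

    def test_extremes(self):
        stack = np.stack([np.zeros((2, 2, 3), np.uint8),
                          np.full((2, 2, 3), 255, np.uint8)])
        histos = accumulate_pixel_histograms(stack)
        assert (histos.counts[..., 0] == 1).all()
        assert (histos.counts[..., 255] == 1).all()

    def test_matches_brute_force_tally_bit_exactly(self, rng):
        stack = rng.integers(0, 256, (8, 6, 5, 3)).astype(np.uint8)
        histos = accumulate_pixel_histograms(stack)
        assert np.array_equal(histos.counts, brute_force_tally(stack))
        assert histos.n_frames == 8


class TestPooledReference:
    def test_point_mass(self):
        refs = np.full((4, 8, 8, 3), 100, dtype=np.uint8)
        dist = pooled_reference_histogram(refs)
        assert (dist.pmf[:, 100] == 1.0).all()
        assert (dist.cdf[:, :100] == 0.0).all()
        assert (dist.cdf[:, 100:] == 1.0).all()

    def test_two_point_mixture(self):
        refs = np.stack([np.zeros((4, 4, 3), np.uint8),
                         np.full((4, 4, 3), 255, np.uint8)])
        dist = pooled_reference_histogram(refs)
        assert np.allclose(dist.pmf[:, 0], 0.5)
        assert np.allclose(dist.pmf[:, 255], 0.5)

    def test_matches_pooled_tally(self, rng):
        refs = rng.integers(0, 256, (5, 6, 6, 3)).astype(np.uint8)
        dist = pooled_reference_histogram(refs)
        for ch in range(3):
            tally = np.bincount(refs[..., ch].ravel(), minlength=256)
            assert np.allclose(dist.pmf[ch], tally / tally.sum())


class TestMatchCdf:
    def test_identical_strictly_increasing_cdfs_give_identity(self, rng):
        pmf = rng.random(256) + 0.01
        cdf = (pmf / pmf.sum()).cumsum()
        assert np.array_equal(match_cdf(cdf, cdf), np.arange(256))

    def test_point_mass_reference_maps_everything_to_it(self, rng):
        ref = np.concatenate([np.zeros(100), np.ones(156)])
        pmf = rng.random(256) + 0.01  # every level observed at least once
        pix = (pmf / pmf.sum()).cumsum()
        assert (match_cdf(pix, ref) == 100).all()

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_exhaustive_search(self, rng, trial):
        pix, ref = random_cdf(rng), random_cdf(rng)
        lut = match_cdf(pix, ref)
        # independent 256x256 brute-force oracle (targets clamped to the top
        # of the reference CDF, as the documented contract states)
        expected = np.array([
            min(v for v in range(256) if ref[v] >= min(pix[u], ref[255]))
            for u in range(256)])
        assert np.array_equal(lut, expected)
        assert (np.diff(lut.astype(int)) >= 0).all()


class TestBuildLutSet:
    def _uniform_reference(self):
        pmf = np.full((3, 256), 1 / 256)
        return ReferenceDistribution(pmf=pmf, cdf=pmf.cumsum(axis=1))

    def test_low_max_pixel_is_defective(self):
        stack = np.full((20, 2, 2, 3), 5, dtype=np.uint8)
        luts = build_lut_set(accumulate_pixel_histograms(stack),
                             self._uniform_reference())
        assert luts.defective.all()
        assert (luts.lut == 0).all()

    def test_low_std_pixel_is_defective(self):
        # alternating 100/101: max fine but population STD 0.5 < 2
        stack = np.empty((20, 1, 1, 3), dtype=np.uint8)
        stack[::2] = 100
        stack[1::2] = 101
        luts = build_lut_set(accumulate_pixel_histograms(stack),
                             self._uniform_reference())
        assert luts.defective.all()

    def test_defect_rules_are_per_channel(self):
        stack = np.zeros((30, 1, 1, 3), dtype=np.uint8)
        stack[..., 0] = np.linspace(0, 255, 30, dtype=np.uint8)[:, None, None]
        stack[..., 1] = 5    # low max
        stack[..., 2] = 200  # zero STD
        luts = build_lut_set(accumulate_pixel_histograms(stack),
                             self._uniform_reference())
        assert not luts.defective[0, 0, 0]
        assert luts.defective[0, 0, 1]
        assert luts.defective[0, 0, 2]

    def test_uniform_pixel_against_uniform_reference_is_near_identity(self):
        frames = np.arange(256, dtype=np.uint8)
        stack = np.tile(frames[:, None, None, None], (1, 1, 1, 3))
        luts = build_lut_set(accumulate_pixel_histograms(stack),
                             self._uniform_reference())
        assert not luts.defective.any()
        deviation = np.abs(luts.lut.astype(int) - np.arange(256))
        assert deviation.max() <= 1

    def test_nondefective_luts_monotone_on_random_stack(self, rng):
        stack = rng.integers(0, 256, (50, 5, 5, 3)).astype(np.uint8)
        refs = rng.integers(0, 256, (10, 5, 5, 3)).astype(np.uint8)
        luts = build_lut_set(accumulate_pixel_histograms(stack),
                             pooled_reference_histogram(refs))
        ok = ~luts.defective
        assert (np.diff(luts.lut[ok].astype(int), axis=-1) >= 0).all()

    def test_mapped_cdf_tracks_reference_cdf(self, rng):
        # after the LUT, each pixel's empirical CDF sits just below the
        # reference CDF, within the largest atom of the pixel's distribution
        n = 400
        stack = rng.integers(0, 256, (n, 4, 4, 3)).astype(np.uint8)
        refs = rng.integers(0, 256, (20, 8, 8, 3)).astype(np.uint8)
        histos = accumulate_pixel_histograms(stack)
        reference = pooled_reference_histogram(refs)
        luts = build_lut_set(histos, reference)
        mapped = np.stack([apply_lut_set(frame, luts) for frame in stack])
        for (y, x, ch) in [(0, 0, 0), (2, 3, 1), (3, 1, 2)]:
            if luts.defective[y, x, ch]:
                continue
            counts = np.bincount(mapped[:, y, x, ch], minlength=256)
            mapped_cdf = counts.cumsum() / n
            max_atom = histos.counts[y, x, ch].max() / n
            gap = reference.cdf[ch] - mapped_cdf
            assert gap.min() >= -1e-9
            assert gap.max() < max_atom + 1e-9


class TestApplyLutSet:
    def test_identity_luts(self, rng):
        img = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
        lut = np.broadcast_to(np.arange(256, dtype=np.uint8),
                              (4, 4, 3, 256)).copy()
        luts = LUTSet(lut=lut, defective=np.zeros((4, 4, 3), bool))
        assert np.array_equal(apply_lut_set(img, luts), img)

    def test_all_defective_gives_zero_image(self, rng):
        img = rng.integers(0, 256, (4, 4, 3)).astype(np.uint8)
        luts = LUTSet(lut=np.zeros((4, 4, 3, 256), np.uint8),
                      defective=np.ones((4, 4, 3), bool))
        assert (apply_lut_set(img, luts) == 0).all()

    def test_matches_elementwise_loop(self, rng):
        img = rng.integers(0, 256, (5, 6, 3)).astype(np.uint8)
        lut = rng.integers(0, 256, (5, 6, 3, 256)).astype(np.uint8)
        luts = LUTSet(lut=lut, defective=np.zeros((5, 6, 3), bool))
        out = apply_lut_set(img, luts)
        for y in range(5):
            for x in range(6):
                for ch in range(3):
                    assert out[y, x, ch] == lut[y, x, ch, img[y, x, ch]]

    def test_size_mismatch_raises(self, rng):
        luts = LUTSet(lut=np.zeros((4, 4, 3, 256), np.uint8),
                      defective=np.zeros((4, 4, 3), bool))
        with pytest.raises(ValueError):
            apply_lut_set(np.zeros((5, 5, 3), np.uint8), luts)
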