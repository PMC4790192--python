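from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from fishbeat.io_acquisition import split_channel
from fishbeat.segmentation import (
    _largest_component,
    area_chronology,
    binarize,
    enclosed_area,
    find_seed_point,
    histogram_threshold,
    morphological_filter,
    trace_boundary,
)
from fishbeat.synthgen import generate_embryo


def exhaustive_best_threshold(frame, labels):
    """Oracle: scan all 256 thresholds, minimize misclassification."""
    best_t, best_err = 0, np.inf
    for t in range(256):
        err = np.count_nonzero((frame > t) != labels)
        if err < best_err:
            best_t, best_err = t, err
    return best_t, best_err


class TestHistogramThreshold:
    def test_two_delta_histogram_separates_exactly(self):
        rng = np.random.default_rng(0)
        frame = np.where(rng.random((40, 40)) < 0.5, 20, 220).astype(np.uint8)
        t = histogram_threshold(frame)
        assert 20 < t < 220
        mask = binarize(frame, t)
        np.testing.assert_array_equal(mask, frame == 220)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError, match="no bimodal structure"):
            histogram_threshold(np.full((16, 16), 128, np.uint8))

    def test_gaussian_bimodal_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        labels = rng.random((64, 64)) < 0.5
        frame = np.where(
            labels, rng.normal(200, 12, (64, 64)), rng.normal(40, 8, (64, 64))
        )
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
        t = histogram_threshold(frame)
        assert 64 <= t <= 176
        err = np.count_nonzero(binarize(frame, t) != labels)
        assert err / labels.size < 0.01
        _, oracle_err = exhaustive_best_threshold(frame, labels)
        # the histogram valley must be nearly as good as the optimal cut
        assert err <= oracle_err + 0.01 * labels.size

    def test_intensity_rescaling_invariance(self):
        # halving all intensities moves the valley but not the partition
        rng = np.random.default_rng(2)
        frame = np.where(rng.random((32, 32)) < 0.4, 200, 16).astype(np.uint8)
        half = (frame // 2).astype(np.uint8)
        m1 = binarize(frame, histogram_threshold(frame))
        m2 = binarize(half, histogram_threshold(half))
        np.testing.assert_array_equal(m1, m2)


class TestBinarize:
    def test_strict_inequality(self):
        frame = np.array([[50, 51]], np.uint8)
        mask = binarize(frame, 50)
        assert not mask[0, 0] and mask[0, 1]

    def test_threshold_255_empty(self):
        assert not binarize(np.full((8, 8), 255, np.uint8), 255).any()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 255), st.integers(0, 2**31 - 1))
    def test_counting_oracle_random_frames(self, threshold, seed):
        frame = np.random.default_rng(seed).integers(0, 256, (16, 16)).astype(np.uint8)
        mask = binarize(frame, threshold)
        brute = sum(
            1 for v in frame.ravel() if v > threshold
        )
        assert int(mask.sum()) == brute


class TestMorphologicalFilter:
    def test_closing_fills_single_pixel_hole(self):
        m = np.zeros((12, 12), bool)
        m[2:10, 2:10] = True
        m[5, 6] = False
        out = morphological_filter(m)
        assert int(out.sum()) == 64

    def test_isolated_pixel_lost(self):
        m = np.zeros((9, 9), bool)
        m[4, 4] = True
        with pytest.raises(ValueError, match="object lost in morphology"):
            morphological_filter(m)

    def test_speckle_removed_vs_clean_disk(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 144
        rng = np.random.default_rng(3)
        noisy = disk | (rng.random((40, 40)) < 0.02)
        clean = morphological_filter(disk)
        filtered = morphological_filter(noisy)
        agreement = np.mean(filtered == clean)
        assert agreement >= 0.99


class TestSeedPoint:
    def test_single_pixel(self):
        m = np.zeros((8, 8), bool)
        m[3, 7] = True
        assert find_seed_point(m) == (3, 7)

    def test_rectangle_scan_order(self):
        m = np.zeros((8, 12), bool)
        m[2:6, 4:10] = True
        assert find_seed_point(m) == (2, 4)

    def test_seed_lands_on_largest_component(self):
        m = np.zeros((20, 20), bool)
        m[1:3, 1:3] = True  # small blob, encountered first in scan order
        m[8:16, 8:16] = True  # large blob
        labels, _ = ndimage.label(m, structure=np.ones((3, 3)))
        seed = find_seed_point(m)
        sizes = np.bincount(labels.ravel())
        assert labels[seed] == np.argmax(sizes[1:]) + 1
        assert seed == (8, 8)


class TestTraceAndArea:
    def test_single_pixel_contour(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        c = trace_boundary(m, (2, 2))
        assert c.points == [(2, 2)]
        assert enclosed_area(c, m.shape) == 1

    def test_filled_square_border(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        c = trace_boundary(m, find_seed_point(m))
        assert len(set(c.points)) == 12  # the 4x4 square's border pixels
        assert enclosed_area(c, m.shape) == 16

    def test_filled_10x10_square_area(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        c = trace_boundary(m, find_seed_point(m))
        assert enclosed_area(c, m.shape) == 100

    def test_disk_contour_equals_4adjacency_oracle(self):
        yy, xx = np.mgrid[0:26, 0:26]
        disk = (yy - 13) ** 2 + (xx - 13) ** 2 <= 100
        c = trace_boundary(disk, find_seed_point(disk))
        oracle = set()
        h, w = disk.shape
        for r, col in zip(*np.nonzero(disk)):
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, col + dc
                if rr < 0 or rr >= h or cc < 0 or cc >= w or not disk[rr, cc]:
                    oracle.add((r, col))
                    break
        assert set(c.points) == oracle

    def test_disk_area_matches_continuum_and_floodfill(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        c = trace_boundary(disk, find_seed_point(disk))
        area = enclosed_area(c, disk.shape)
        assert abs(area - np.pi * 15**2) / (np.pi * 15**2) < 0.03
        assert area == int(ndimage.binary_fill_holes(disk).sum())

    def test_seed_off_boundary_rejected(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        with pytest.raises(ValueError, match="boundary"):
            trace_boundary(m, (4, 4))

    def test_traced_area_equals_floodfill_on_random_masks(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            m = ndimage.binary_dilation(
                rng.random((16, 16)) < 0.12, np.ones((2, 2))
            )
            if not m.any():
                continue
            comp = _largest_component(m)
            c = trace_boundary(comp, find_seed_point(m))
            assert enclosed_area(c, comp.shape) == int(
                ndimage.binary_fill_holes(comp).sum()
            )
            checked += 1


class TestAreaChronology:
    def test_noiseless_pulsating_disk_tracks_ground_truth(self, noiseless_config):
        stack, gt = generate_embryo(noiseless_config)
        series = area_chronology(split_channel(stack, "green"), stack.meta)
        r = np.corrcoef(series.values, gt.area)[0, 1]
        assert r >= 0.98

    def test_static_heart_low_variation(self, small_config):
        cfg = replace(small_config, radius_amplitude=0.0)
        stack, _ = generate_embryo(cfg)
        series = area_chronology(split_channel(stack, "green"), stack.meta)
        cv = series.values.std() / series.values.mean()
        assert cv < 0.02

    def test_all_dark_stack_is_unreliable(self, small_config):
        frames = np.zeros((64, 32, 32), np.uint8)
        from fishbeat.io_acquisition import AcquisitionMeta

        meta = AcquisitionMeta(0.015, 64, 32, 32)
        with pytest.raises(ValueError, match="unreliable area series"):
            area_chronology(frames, meta)

    def test_failed_frames_interpolated_and_flagged(self, noiseless_config):
        stack, _ = generate_embryo(noiseless_config)
        green = split_channel(stack, "green")
        green[10] = 0  # one dead frame, below the failure budget
        series = area_chronology(green, stack.meta)
        assert series.quality_flags[10]
        expected = 0.5 * (series.values[9] + series.values[11])
        assert series.values[10] == pytest.approx(expected)
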