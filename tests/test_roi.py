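import logging

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import label
from skimage.morphology import disk

from periseg.phantom import TISSUE_CLASSES
from periseg.roi import (
    ROIParams,
    apply_mask,
    extract_roi,
    iterative_threshold,
    largest_component,
    morphology_chain,
)
from periseg.types import CTSlice


def _dilate(m, se):
    return ndimage.binary_dilation(m, se)


def _erode(m, se):
    return ndimage.binary_erosion(m, se, border_value=0)


def _fill(m):
    # background flood fill from the border: holes are what it cannot reach
    inv = ~m
    reach = np.zeros_like(m)
    border = np.zeros_like(m)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    seeds = inv & border
    lbl = label(inv, connectivity=1)
    reachable_labels = set(np.unique(lbl[seeds])) - {0}
    holes = inv & ~np.isin(lbl, sorted(reachable_labels))
    return m | holes


def five_step_oracle(mask, radius):
    """The chain recomposed from erosion/dilation primitives only."""
    se = disk(radius)
    m = _dilate(mask, se)
    m = _erode(m, se)
    m = _fill(m)
    m = _dilate(_erode(m, se), se)  # opening
    m = _erode(_dilate(m, se), se)  # closing
    return m


class TestIterativeThreshold:
    def test_two_level_image(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 100.0
        res = iterative_threshold(CTSlice(px, (1, 1)))
        # T0 = 50, class means 0 and 100 -> fixed point immediately
        assert res.threshold_hu == pytest.approx(50.0)
        assert res.converged
        assert res.n_iterations == 1

    def test_constant_image_degenerate(self):
        res = iterative_threshold(CTSlice(np.full((5, 5), -77.0), (1, 1)))
        assert res.threshold_hu == pytest.approx(-77.0)
        assert res.n_iterations == 1
        assert res.degenerate

    def test_bimodal_fixed_point(self, rng):
        vals = np.concatenate(
            [rng.normal(-500, 30, 2000), rng.normal(50, 30, 2000)]
        ).reshape(40, 100)
        res = iterative_threshold(CTSlice(vals, (1, 1)), tolerance=0.5)
        t = res.threshold_hu
        assert -500 < t < 50
        # recompute the two class means directly at the returned T
        m_low = vals[vals <= t].mean()
        m_high = vals[vals > t].mean()
        assert abs(t - (m_low + m_high) / 2) < 0.5

    def test_terminates_within_max_iter(self, rng):
        for seed in range(5):
            vals = np.random.default_rng(seed).random((32, 32)) * 2000 - 1000
            res = iterative_threshold(CTSlice(vals, (1, 1)), max_iter=100)
            assert res.n_iterations <= 100
            assert vals.min() <= res.threshold_hu <= vals.max()

    def test_history_tracks_iterations(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 100.0
        res = iterative_threshold(CTSlice(px, (1, 1)))
        assert res.history[0] == pytest.approx(50.0)
        assert len(res.history) == res.n_iterations + 1

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            iterative_threshold(CTSlice(np.ones((4, 4)), (1, 1)), tolerance=0.0)


class TestMorphologyChain:
    def test_hole_filled(self):
        m = np.zeros((21, 21), bool)
        m[3:18, 3:18] = True
        m[9:12, 9:12] = False  # 3 px interior hole
        out = morphology_chain(m, se_radius_px=2)
        # oracle: flood fill from the border finds no interior background
        filled = ndimage.binary_fill_holes(out)
        assert np.array_equal(out, filled)
        assert out[10, 10]

    def test_empty_passes_through(self):
        m = np.zeros((9, 9), bool)
        assert not morphology_chain(m, 1).any()

    def test_isolated_pixel_removed(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        out = morphology_chain(m, se_radius_px=1)
        assert np.array_equal(out, five_step_oracle(m, 1))
        assert not out.any()

    def test_matches_five_step_oracle_random(self, rng):
        m = rng.random((24, 24)) > 0.55
        assert np.array_equal(morphology_chain(m, 2), five_step_oracle(m, 2))

    def test_opening_anti_extensive_closing_extensive(self, rng):
        # keep foreground clear of the border: outside the image counts as
        # background, which breaks extensivity only for border-touching blobs
        m = np.zeros((40, 40), bool)
        m[5:35, 5:35] = rng.random((30, 30)) > 0.4
        se = disk(2)
        opened = ndimage.binary_opening(m, se)
        closed = ndimage.binary_closing(m, se)
        assert not np.any(opened & ~m)  # opened subset of input
        assert not np.any(m & ~closed)  # input subset of closed

    def test_opening_closing_idempotent(self, rng):
        m = rng.random((30, 30)) > 0.4
        se = disk(2)
        opened = ndimage.binary_opening(m, se)
        closed = ndimage.binary_closing(m, se)
        assert np.array_equal(ndimage.binary_opening(opened, se), opened)
        assert np.array_equal(ndimage.binary_closing(closed, se), closed)

    def test_hole_filling_never_removes_foreground(self, rng):
        m = rng.random((20, 20)) > 0.5
        filled = ndimage.binary_fill_holes(m)
        assert not np.any(m & ~filled)


class TestApplyMask:
    def test_identity_mask(self, ramp_slice):
        out = apply_mask(ramp_slice, np.ones(ramp_slice.shape, bool))
        assert np.array_equal(out.pixels, ramp_slice.pixels)

    def test_all_false_gives_fill(self, ramp_slice):
        out = apply_mask(ramp_slice, np.zeros(ramp_slice.shape, bool), fill_hu=-5.0)
        assert np.all(out.pixels == -5.0)

    def test_checkerboard_select_oracle(self, ramp_slice):
        mask = np.indices(ramp_slice.shape).sum(axis=0) % 2 == 0
        out = apply_mask(ramp_slice, mask, fill_hu=-1024.0)
        for i in range(8):
            for j in range(8):
                expected = ramp_slice.pixels[i, j] if mask[i, j] else -1024.0
                assert out.pixels[i, j] == expected

    def test_shape_mismatch(self, ramp_slice):
        with pytest.raises(ValueError):
            apply_mask(ramp_slice, np.ones((3, 3), bool))


class TestExtractRoi:
    def test_phantom_single_component_no_holes(self, lesion_phantom):
        ct, _ = lesion_phantom
        res = extract_roi(ct)
        assert label(res.roi_mask, connectivity=2).max() == 1
        assert np.array_equal(
            res.roi_mask, ndimage.binary_fill_holes(res.roi_mask)
        )

    def test_air_only_image_empty_roi(self, caplog):
        ct = CTSlice(np.full((64, 64), -1000.0), (1, 1))
        with caplog.at_level(logging.WARNING, logger="periseg.roi"):
            res = extract_roi(ct)
        assert not res.roi_mask.any()
        assert any("empty ROI" in r.message for r in caplog.records)
        assert np.all(res.masked_slice.pixels == -1024.0)

    def test_covers_body_on_noiseless_phantom(self):
        from periseg.phantom import PhantomConfig, generate_phantom

        ct, gt = generate_phantom(
            PhantomConfig(seed=7, noise_sd_hu=0.0, blur_sigma_px=0.0)
        )
        res = extract_roi(ct)
        body = gt.tissue_map != TISSUE_CLASSES["background"]
        covered = np.count_nonzero(res.roi_mask & body) / np.count_nonzero(body)
        assert covered >= 0.99

    def test_masked_slice_contract(self, lesion_phantom):
        ct, _ = lesion_phantom
        res = extract_roi(ct, ROIParams(fill_hu=-1024.0))
        inside = res.roi_mask
        assert np.array_equal(res.masked_slice.pixels[inside], ct.pixels[inside])
        assert np.all(res.masked_slice.pixels[~inside] == -1024.0)


class TestLargestComponent:
    def test_keeps_biggest(self):
        m = np.zeros((10, 10), bool)
        m[:2, :2] = True
        m[5:9, 5:9] = True
        out = largest_component(m)
        assert out.sum() == 16
        assert out[6, 6] and not out[0, 0]

    def test_empty_in_empty_out(self):
        m = np.zeros((5, 5), bool)
        assert not largest_component(m).any()
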