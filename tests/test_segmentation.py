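"""Segmentation stages against brute-force and generator-truth oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest

from rbcagg import (
    ImageFrame,
    SceneSpec,
    SingleCellAreaError,
    binarize,
    clean_mask,
    estimate_single_cell_area,
    generate_scene,
    label_components,
    normalize_contrast,
    correct_illumination,
    otsu_threshold_exhaustive,
    segment_frame,
    RunConfig,
)
from rbcagg.synthetic import truth_mask_from


def _frame(arr):
    return ImageFrame(pixels=np.asarray(arr, dtype=np.uint8))


# --------------------------------------------------------------------------
# Contrast
# --------------------------------------------------------------------------

class TestNormalizeContrast:
    def test_constant_image_unchanged_with_warning(self):
        f = _frame(np.full((10, 10), 77))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            out = normalize_contrast(f)
        assert np.array_equal(out.pixels, f.pixels)
        assert len(caught) == 1

    def test_two_level_image_stretches_to_full_range(self):
        img = np.full((10, 10), 50)
        img[5:] = 200
        out = normalize_contrast(_frame(img), 0.0, 100.0)
        assert set(np.unique(out.pixels)) == {0, 255}

    def test_idempotent_up_to_quantization(self):
        rng = np.random.default_rng(0)
        f = _frame(rng.integers(30, 220, size=(50, 50)))
        once = normalize_contrast(f, 0.0, 100.0)
        twice = normalize_contrast(once, 0.0, 100.0)
        assert np.abs(once.pixels.astype(int) - twice.pixels.astype(int)).max() <= 1

    def test_invalid_percentiles_rejected(self):
        with pytest.raises(ValueError):
            normalize_contrast(_frame(np.zeros((4, 4))), 40.0, 20.0)

    def test_gradient_scene_recovered_after_conditioning(self):
        """Otsu after flattening recovers ≥99% of the truth mask (Jaccard)."""
        spec = SceneSpec(
            field_width_px=400, field_height_px=200, areal_density=0.10,
            illumination_gradient=0.3, seed=11,
        )
        frame, truth = generate_scene(spec)
        tm = truth_mask_from(truth, spec)
        cfg = RunConfig(median_size=0, fill_holes=False, min_speck_area_px=0)
        seg = segment_frame(frame, cfg)
        inter = (seg.foreground_mask & tm).sum()
        union = (seg.foreground_mask | tm).sum()
        assert inter / union >= 0.99


# --------------------------------------------------------------------------
# Binarization
# --------------------------------------------------------------------------

class TestBinarize:
    def test_bimodal_threshold_separates_the_modes(self):
        """Any cut in [60, 180) maximizes between-class variance for a
        two-level histogram; the chosen threshold must attain that maximum
        and split the image exactly at the modes."""
        img = np.concatenate([np.full(500, 60), np.full(500, 180)]).reshape(20, 50)
        res = binarize(_frame(img))
        assert 60 <= res.threshold < 180
        assert res.threshold == otsu_threshold_exhaustive(img)
        assert res.mask.sum() == 500  # the dark mode exactly

    def test_constant_image_flagged_empty(self):
        res = binarize(_frame(np.full((10, 10), 128)))
        assert res.empty_foreground
        assert not res.mask.any()

    def test_clean_scene_mask_equals_truth(self, small_spec, small_scene):
        frame, truth = small_scene
        res = binarize(frame)
        assert np.array_equal(res.mask, truth_mask_from(truth, small_spec))

    def test_polarity_override(self):
        img = np.concatenate([np.full(100, 40), np.full(900, 200)]).reshape(20, 50)
        bright = binarize(_frame(img), polarity="bright")
        assert bright.mask.sum() == 900  # the bright side, even though majority

    def test_fixed_threshold_requires_value_in_range(self):
        f = _frame(np.tile(np.array([10, 240]), (8, 8)))
        with pytest.raises(ValueError):
            binarize(f, method="fixed")
        with pytest.raises(ValueError):
            binarize(f, method="fixed", fixed_threshold=999)


def test_otsu_matches_exhaustive_search_on_random_histograms():
    """Between-class variance at the library threshold equals the exhaustive max."""
    rng = np.random.default_rng(12345)
    from skimage.filters import threshold_otsu

    def between_class_variance(img, t):
        lo = img[img <= t]
        hi = img[img > t]
        if lo.size == 0 or hi.size == 0:
            return -1.0
        w0, w1 = lo.size / img.size, hi.size / img.size
        return w0 * w1 * (lo.mean() - hi.mean()) ** 2

    for _ in range(100):
        modes = rng.integers(1, 4)
        parts = [
            rng.normal(rng.uniform(30, 220), rng.uniform(2, 40), size=rng.integers(50, 400))
            for _ in range(modes)
        ]
        img = np.clip(np.concatenate(parts), 0, 255).astype(np.uint8)
        t_lib = threshold_otsu(img)
        t_ex = otsu_threshold_exhaustive(img)
        assert between_class_variance(img, t_lib) == pytest.approx(
            between_class_variance(img, t_ex), rel=1e-9
        )


# --------------------------------------------------------------------------
# Mask clean-up
# --------------------------------------------------------------------------

class TestCleanMask:
    def test_speck_removed(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 10] = True
        assert clean_mask(mask, min_speck_area_px=5, fill_holes=False).sum() == 0

    def test_hole_filled_increases_area_by_hole_size(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        mask[9, 9:12] = False  # 3-px interior hole
        out = clean_mask(mask, min_speck_area_px=0, fill_holes=True)
        assert out.sum() == mask.sum() + 3

    def test_idempotent_and_never_adds_outside_holes(self):
        rng = np.random.default_rng(3)
        mask = rng.random((60, 60)) < 0.3
        once = clean_mask(mask, 10, True)
        assert np.array_equal(once, clean_mask(once, 10, True))
        no_fill = clean_mask(mask, 10, False)
        assert not (no_fill & ~mask).any()


# --------------------------------------------------------------------------
# Labeling
# --------------------------------------------------------------------------

def _flood_count(mask, diagonal):
    """Brute-force connected-component count by flood fill."""
    mask = mask.copy()
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if diagonal:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    n = 0
    while mask.any():
        n += 1
        seed = tuple(np.argwhere(mask)[0])
        stack = [seed]
        mask[seed] = False
        while stack:
            y, x = stack.pop()
            for dy, dx in steps:
                p = (y + dy, x + dx)
                if 0 <= p[0] < mask.shape[0] and 0 <= p[1] < mask.shape[1] and mask[p]:
                    mask[p] = False
                    stack.append(p)
    return n


class TestLabelComponents:
    def test_two_separated_discs_two_labels(self):
        mask = np.zeros((30, 60), bool)
        yy, xx = np.mgrid[:30, :60]
        mask |= (yy - 15) ** 2 + (xx - 15) ** 2 <= 36
        mask |= (yy - 15) ** 2 + (xx - 45) ** 2 <= 36
        assert label_components(mask).n_regions == 2

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = mask[5, 5] = True
        for conn, diag in ((8, True), (4, False)):
            seg = label_components(mask, connectivity=conn)
            assert seg.n_regions == _flood_count(mask, diagonal=diag)

    def test_empty_mask_zero_regions(self):
        seg = label_components(np.zeros((5, 5), bool))
        assert seg.n_regions == 0
        assert list(seg.regions.columns)  # schema still present

    def test_area_bookkeeping_is_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            mask = clean_mask(rng.random((80, 80)) < 0.35, 4, False)
            seg = label_components(mask)
            assert seg.regions["area_px"].sum() == mask.sum()
            labels = seg.regions["label"].to_numpy()
            assert np.array_equal(labels, np.arange(1, len(labels) + 1))

    def test_noise_free_scene_reproduces_truth_objects(self, small_spec, small_scene):
        frame, truth = small_scene
        res = binarize(frame)
        seg = label_components(res.mask)
        assert seg.n_regions == len(truth.objects)
        assert sorted(seg.regions["area_px"]) == sorted(o.pixel_area for o in truth.objects)


# --------------------------------------------------------------------------
# Single-cell area
# --------------------------------------------------------------------------

class TestEstimateSingleCellArea:
    def test_identical_discs_close_to_rasterized_disc_area(self):
        """Oracle: area of a rasterized radius-8 disc counted by brute force."""
        r = 8.0
        yy, xx = np.mgrid[:40, :40]
        disc_area = int(((yy + 0.5 - 20) ** 2 + (xx + 0.5 - 20) ** 2 <= r * r).sum())
        assert disc_area == pytest.approx(np.pi * r * r, rel=0.05)
        spec = SceneSpec(
            field_width_px=400, field_height_px=200, areal_density=0.06,
            morphology_weights={"singlet": 1.0, "rouleau": 0.0, "branched": 0.0, "network": 0.0},
            seed=2,
        )
        frame, _ = generate_scene(spec)
        seg = label_components(binarize(frame).mask)
        est = estimate_single_cell_area(seg.regions)
        assert est == pytest.approx(disc_area, rel=0.05)

    def test_prior_override_returned_verbatim(self):
        regions = pd.DataFrame({"area_px": [10.0, 5000.0]})
        assert estimate_single_cell_area(regions, expected_cell_area_px=200) == 200

    def test_all_huge_regions_without_prior_fails(self):
        regions = pd.DataFrame({"area_px": [5000.0]})
        with pytest.raises(SingleCellAreaError):
            estimate_single_cell_area(regions)

    def test_no_regions_without_prior_fails(self):
        with pytest.raises(SingleCellAreaError):
            estimate_single_cell_area(pd.DataFrame({"area_px": []}))


def test_illumination_correction_flattens_gradient():
    spec = SceneSpec(
        field_width_px=400, field_height_px=200, areal_density=0.08,
        illumination_gradient=0.4, seed=6,
    )
    frame, _ = generate_scene(spec)
    flat = correct_illumination(frame)
    # background medians of left and right quarters agree after flattening
    left = np.median(flat.pixels[:, :100][flat.pixels[:, :100] > 80])
    right = np.median(flat.pixels[:, 300:][flat.pixels[:, 300:] > 80])
    assert abs(float(left) - float(right)) <= 5
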