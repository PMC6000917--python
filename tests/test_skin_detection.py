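import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import disk, erosion

from woundseg.color_model import cr_histogram, rgb_to_cr
from woundseg.skin_detection import (
    BACKGROUND,
    FOREGROUND,
    MarkerError,
    SkinParams,
    ThresholdPair,
    build_markers,
    detect_skin,
    dynamic_thresholds,
    predict_skin_proportion,
    recover_dark_wounds,
    remove_background,
    threshold_mask,
    watershed_segment,
    _smoothed_histogram,
)
from .conftest import clutter_free_scene

PARAMS = SkinParams.pre_profile()


def brute_force_proportion(hist, d):
    """Exhaustive scan of every window position (the Eq-1 oracle)."""
    total = hist.sum()
    best = 0.0
    for lo in range(256):
        hi = min(lo + d, 255)
        best = max(best, hist[lo : hi + 1].sum() / total)
    return best


def piecewise_histogram(vertices):
    """Integer histogram linearly interpolated between (cr, count) vertices."""
    counts = np.zeros(256, dtype=np.int64)
    for (x0, y0), (x1, y1) in zip(vertices, vertices[1:]):
        xs = np.arange(x0, x1 + 1)
        counts[x0 : x1 + 1] = np.round(np.interp(xs, [x0, x1], [y0, y1])).astype(int)
    return counts


class TestFastPath:
    def test_constant_cr_is_pure_skin(self):
        hist = np.zeros(256, dtype=int)
        hist[140] = 10_000
        p, window = predict_skin_proportion(hist, PARAMS)
        assert p == 1.0
        assert window[0] <= 140 <= window[1]

    def test_uniform_distribution(self):
        hist = np.full(256, 10, dtype=int)
        p, _ = predict_skin_proportion(hist, PARAMS)
        assert p == pytest.approx(26 / 256)

    def test_two_far_spikes(self):
        hist = np.zeros(256, dtype=int)
        hist[100] = 500
        hist[200] = 500
        p, _ = predict_skin_proportion(hist, PARAMS)
        assert p == pytest.approx(0.5)

    def test_equals_brute_force_on_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            if hist.sum() == 0:
                hist[rng.integers(256)] = 1
            p, _ = predict_skin_proportion(hist, PARAMS)
            assert p == pytest.approx(brute_force_proportion(hist, PARAMS.d))

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            predict_skin_proportion(np.zeros(256, dtype=int), PARAMS)


class TestDynamicThresholds:
    def test_bimodal_valleys_in_search_windows(self):
        # locally symmetric V valleys at 134 and 157 bracketing the skin mode,
        # with enough tail mass that the central-95% width L is generous
        hist = piecewise_histogram(
            [(120, 40), (128, 100), (134, 10), (140, 100), (146, 1400),
             (151, 140), (157, 20), (163, 140), (170, 60), (180, 5)]
        )
        smoothed = _smoothed_histogram(hist, PARAMS.smoothing_window)
        assert smoothed[134] < min(smoothed[133], smoothed[135])
        assert smoothed[157] < min(smoothed[156], smoothed[158])
        # the (134, 157) pair must satisfy both admissibility conditions
        total = hist.sum()
        p_m = hist[134:158].sum() / total
        csum = np.cumsum(hist)
        lo = int(np.searchsorted(csum, 0.025 * total))
        hi = int(np.searchsorted(csum, 0.975 * total))
        assert PARAMS.l_min <= 157 - 134 <= PARAMS.l_max
        assert p_m > (157 - 134) / (hi - lo)
        result = dynamic_thresholds(hist, PARAMS)
        assert result == ThresholdPair(134, 157)
        assert result.gap == 23

    def test_too_wide_valley_pair_rejected(self):
        # only minima are at 131 and 162: gap 31 exceeds l_max=30
        hist = piecewise_histogram(
            [(125, 300), (131, 10), (146, 900), (162, 10), (170, 300)]
        )
        result = dynamic_thresholds(hist, PARAMS)
        assert result != ThresholdPair(131, 162)

    def test_falls_back_to_static_band(self):
        # unimodal histogram far from the skin band: no admissible pair exists
        hist = piecewise_histogram([(40, 10), (60, 500), (80, 10)])
        assert dynamic_thresholds(hist, PARAMS) == ThresholdPair(135, 160)


class TestThresholdMask:
    def test_constant_maps(self):
        t = ThresholdPair(135, 160)
        assert threshold_mask(np.full((5, 5), 140, np.uint8), t).all()
        assert not threshold_mask(np.full((5, 5), 100, np.uint8), t).any()

    def test_checkerboard(self):
        cr = np.where(np.indices((8, 8)).sum(axis=0) % 2 == 0, 130, 150).astype(np.uint8)
        mask = threshold_mask(cr, ThresholdPair(135, 160))
        assert (mask == (cr == 150)).all()

    def test_mask_count_matches_histogram_mass(self, rng):
        cr = rng.integers(0, 256, size=(60, 40)).astype(np.uint8)
        hist = cr_histogram(cr)
        t = ThresholdPair(120, 170)
        assert threshold_mask(cr, t).sum() == hist[120:171].sum()


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestMarkers:
    def test_foreground_is_eroded_filled_mask(self):
        mask = _disk_mask((200, 200), (100, 100), 40)
        mask &= ~_disk_mask((200, 200), (100, 100), 5)  # interior hole
        cr = np.full((200, 200), 145, np.uint8)
        markers = build_markers(mask, cr, PARAMS)
        fg = markers.labels[1:-1, 1:-1] == FOREGROUND
        expected = erosion(ndimage.binary_fill_holes(mask), disk(PARAMS.d1 // 2))
        assert (fg == expected).all()

    def test_two_blobs_joined_into_one_component(self):
        mask = _disk_mask((200, 200), (60, 60), 25) | _disk_mask((200, 200), (150, 150), 25)
        cr = np.full((200, 200), 145, np.uint8)
        markers = build_markers(mask, cr, PARAMS)
        _, n = ndimage.label(markers.labels[1:-1, 1:-1] == FOREGROUND)
        assert n == 1

    def test_frame_joins_background_patches(self):
        # skin band across the middle splits the background into two halves
        mask = np.zeros((200, 200), dtype=bool)
        mask[80:120, :] = True
        cr = np.where(mask, 145, 100).astype(np.uint8)
        markers = build_markers(mask, cr, PARAMS)
        _, n = ndimage.label(markers.labels == BACKGROUND)
        assert n == 1

    def test_erosion_annihilation_reports_parameter(self):
        mask = _disk_mask((100, 100), (50, 50), 3)
        cr = np.full((100, 100), 145, np.uint8)
        with pytest.raises(MarkerError, match="d1"):
            build_markers(mask, cr, PARAMS)

    def test_growing_d1_shrinks_foreground(self):
        mask = _disk_mask((200, 200), (100, 100), 50)
        cr = np.full((200, 200), 145, np.uint8)
        small = build_markers(mask, cr, PARAMS.with_overrides(d1=6))
        large = build_markers(mask, cr, PARAMS.with_overrides(d1=14))
        fg_small = small.labels == FOREGROUND
        fg_large = large.labels == FOREGROUND
        assert (fg_large & ~fg_small).sum() == 0
        assert fg_large.sum() < fg_small.sum()


class TestWatershed:
    def test_fully_marked_input_is_identity(self):
        cr = np.full((50, 50), 140, np.uint8)
        labels = np.full((52, 52), BACKGROUND, np.int8)
        labels[1:26, 1:-1] = FOREGROUND
        from woundseg.skin_detection import MarkerMap

        out = watershed_segment(cr, MarkerMap(labels=labels, frame_value=100.0))
        assert (out == (labels[1:-1, 1:-1] == FOREGROUND)).all()

    def test_two_flat_regions_split_at_their_edge(self):
        cr = np.full((60, 60), 120, np.uint8)
        cr[:, 30:] = 150
        labels = np.full((62, 62), 0, np.int8)
        labels[31, 46] = FOREGROUND
        labels[31, 16] = BACKGROUND
        labels[0, :] = labels[-1, :] = labels[:, 0] = labels[:, -1] = BACKGROUND
        from woundseg.skin_detection import MarkerMap

        out = watershed_segment(cr, MarkerMap(labels=labels, frame_value=120.0))
        # interior pixels away from the 2-px contested edge follow their region
        assert out[5:55, 33:55].all()
        assert not out[5:55, 5:28].any()

    def test_missing_label_rejected(self):
        from woundseg.skin_detection import MarkerMap

        labels = np.full((12, 12), BACKGROUND, np.int8)
        with pytest.raises(MarkerError):
            watershed_segment(np.full((10, 10), 120, np.uint8),
                              MarkerMap(labels=labels, frame_value=100.0))


class TestDarkWoundRecovery:
    def test_category4_scene_recovers_wound(self):
        scene = clutter_free_scene(4, seed=3)
        mask, info = detect_skin(scene.image, PARAMS)
        wound = scene.wound_mask
        assert not info["fast_path"]
        assert (mask & wound).sum() / wound.sum() >= 0.99

    def test_convex_wound_enclosing_mask_unchanged(self):
        mask = _disk_mask((150, 150), (75, 75), 40)
        img = np.full((150, 150, 3), 120, np.uint8)
        cr = rgb_to_cr(img)
        out = recover_dark_wounds(mask, img, cr, PARAMS)
        assert (out == mask).all()

    def test_bright_hull_gap_region_deleted(self):
        # C-shaped skin whose concavity holds a bright (non-black) region
        mask = _disk_mask((200, 200), (100, 100), 60)
        notch = _disk_mask((200, 200), (100, 160), 30)
        mask &= ~notch
        img = np.full((200, 200, 3), (80, 105, 140), np.uint8)
        img[mask] = (188, 152, 124)
        cr = rgb_to_cr(img)
        out = recover_dark_wounds(mask, img, cr, PARAMS)
        # the bright notch must not be annexed into the skin mask
        assert (out & notch & ~mask).sum() < 0.05 * notch.sum()


class TestFullDetector:
    def test_fast_path_returns_image_unchanged(self):
        rng = np.random.default_rng(5)
        img = np.clip(rng.normal((188, 152, 124), 3, (256, 256, 3)), 0, 255).astype(np.uint8)
        mask, info = detect_skin(img, PARAMS)
        assert info["fast_path"]
        assert mask.all()
        assert (remove_background(img, PARAMS) == img).all()

    def test_category1_scene_full_wound_retention(self):
        scene = clutter_free_scene(1, seed=8)
        out = remove_background(scene.image, PARAMS)
        survived = out.any(axis=-1)
        wound = scene.wound_mask
        assert (survived & wound).sum() == wound.sum()

    def test_category3_scene_removes_background(self):
        scene = clutter_free_scene(3, seed=9)
        mask, _ = detect_skin(scene.image, PARAMS)
        bg = scene.labels == 0
        assert (mask & bg).sum() / bg.sum() <= 0.10

    def test_detector_is_deterministic(self):
        scene = clutter_free_scene(2, seed=4, size=(256, 256))
        m1, _ = detect_skin(scene.image, PARAMS)
        m2, _ = detect_skin(scene.image, PARAMS)
        assert (m1 == m2).all()
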