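from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from mammocad import (
    PhantomSpec,
    generate_phantom,
    orient,
    remove_pectoral,
    segment_pipeline,
    srg,
    suppress_artifacts,
)
from mammocad.errors import EmptyImageError, ParameterError


def _flip_oracle(img: np.ndarray, threshold: int = 18) -> bool:
    """Independent orientation rule: more foreground on the right half."""
    fg = img >= threshold
    w = img.shape[1]
    return int(fg[:, w // 2 :].sum()) > int(fg[:, : w // 2].sum())


def _flood_fill_oracle(img: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Brute-force BFS flood fill over pixels equal to the seed intensity."""
    h, w = img.shape
    target = img[seed]
    region = np.zeros((h, w), dtype=bool)
    region[seed] = True
    q = deque([seed])
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not region[rr, cc] and img[rr, cc] == target:
                    region[rr, cc] = True
                    q.append((rr, cc))
    return region


class TestOrient:
    def test_left_sided_phantom_unchanged(self, phantom_default):
        out, flipped = orient(phantom_default.image)
        assert not flipped and np.array_equal(out, phantom_default.image)

    def test_mirrored_phantom_is_flipped_back(self, phantom_default):
        mirrored = phantom_default.image[:, ::-1]
        out, flipped = orient(mirrored)
        assert flipped and np.array_equal(out, phantom_default.image)

    def test_idempotent(self, phantom_default):
        once, _ = orient(phantom_default.image[:, ::-1])
        twice, flipped = orient(once)
        assert not flipped and np.array_equal(once, twice)

    def test_decision_matches_half_count_oracle(self):
        for seed in range(20):
            side = "right" if seed % 2 else "left"
            t = generate_phantom(PhantomSpec(side=side, rng_seed=seed))
            _, flipped = orient(t.image)
            assert flipped == _flip_oracle(t.image)

    def test_empty_image_raises(self):
        with pytest.raises(EmptyImageError):
            orient(np.zeros((16, 16), dtype=np.uint8))


class TestSuppressArtifacts:
    def test_labels_fully_removed_breast_mostly_kept(self, phantom_default):
        t = phantom_default
        out, bmask = suppress_artifacts(t.image)
        assert int(out[t.label_mask].sum()) == 0
        # breast survives up to the opening's boundary erosion
        kept = (bmask.mask & t.breast_mask).sum() / t.breast_mask.sum()
        assert kept > 0.98
        assert not np.any(bmask.mask & t.label_mask)

    def test_never_increases_pixel_values(self, phantom_default):
        out, _ = suppress_artifacts(phantom_default.image)
        assert np.all(out <= phantom_default.image)

    def test_single_component_mask_is_opened_threshold_mask(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[4:28, 4:28] = 100
        out, bmask = suppress_artifacts(img, threshold=18)
        from scipy import ndimage
        from skimage.morphology import disk

        expected = ndimage.binary_opening(img >= 18, structure=disk(1))
        assert np.array_equal(bmask.mask, expected)

    def test_low_background_fully_zeroed(self):
        img = np.full((32, 32), 10, dtype=np.uint8)
        img[8:24, 8:24] = 120
        out, _ = suppress_artifacts(img, threshold=18)
        assert int(out[img == 10].sum()) == 0


class TestSRG:
    def test_homogeneous_triangle_tolerance_zero(self):
        img = np.full((40, 40), 100, dtype=np.uint8)
        rr, cc = np.mgrid[0:40, 0:40]
        tri = (rr / 20 + cc / 20) <= 1
        img[tri] = 200
        region = srg(img, [(2, 2)], tolerance=0)
        assert np.array_equal(region, tri)

    def test_tolerance_saturation_floods_everything(self, phantom_default):
        region = srg(phantom_default.image, [(5, 5)], tolerance=255)
        assert region.all()

    def test_region_contains_all_seeds_and_is_connected(self, phantom_default):
        seeds = [(5, 5), (10, 12)]
        region = srg(phantom_default.image, seeds, tolerance=30)
        for s in seeds:
            assert region[s]
        from scipy import ndimage

        _, n = ndimage.label(region, structure=np.ones((3, 3)))
        assert n == 1

    def test_seed_outside_bounds_raises(self):
        with pytest.raises(ParameterError):
            srg(np.zeros((8, 8), dtype=np.uint8), [(9, 0)], tolerance=1)

    def test_tolerance_zero_equals_flood_fill_oracle(self):
        for seed_val in range(10):
            t = generate_phantom(PhantomSpec(rng_seed=seed_val))
            region = srg(t.image, [(5, 5)], tolerance=0)
            assert np.array_equal(region, _flood_fill_oracle(t.image, (5, 5)))


class TestRemovePectoral:
    def test_dice_against_truth(self, phantom_default):
        t = phantom_default
        suppressed, bmask = suppress_artifacts(t.image)
        result = remove_pectoral(suppressed, bmask, tolerance=32)
        inter = (result.pectoral_mask & t.pectoral_mask).sum()
        dice = 2 * inter / (result.pectoral_mask.sum() + t.pectoral_mask.sum())
        assert not result.failed and dice >= 0.90
        assert result.pectoral_mask[0].any()  # touches the top edge

    def test_degenerate_no_pectoral_blacks_almost_nothing(self):
        t = generate_phantom(PhantomSpec(pectoral_frac=0.0, rng_seed=3))
        suppressed, bmask = suppress_artifacts(t.image)
        result = remove_pectoral(suppressed, bmask, tolerance=32)
        blacked = (suppressed > 0) & (result.image == 0)
        assert blacked.sum() < 0.05 * t.breast_mask.sum()

    def test_masking_identity_outside_pectoral(self, phantom_default):
        suppressed, bmask = suppress_artifacts(phantom_default.image)
        result = remove_pectoral(suppressed, bmask, tolerance=32)
        outside = ~result.pectoral_mask
        assert np.array_equal(result.image[outside], suppressed[outside])


def test_pipeline_runs_on_right_sided_phantom():
    t = generate_phantom(PhantomSpec(side="right", rng_seed=4))
    stages = segment_pipeline(t.image)
    assert stages["flipped"]
    assert int(stages["suppressed"][t.label_mask[:, ::-1]].sum()) == 0
    assert not stages["pectoral"].failed
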