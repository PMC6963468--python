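"""Breast-region segmentation: orientation, artifact suppression, and
pectoral-muscle removal by seeded region growing.

The fixed stage order is orient -> suppress_artifacts -> remove_pectoral.
Orientation mirrors right-sided views so the breast mass sits on the left
half.  Artifact suppression binarizes at a global intensity threshold
(default 18), opens the mask morphologically, and keeps the largest
8-connected component, which discards disconnected radiopaque labels.
Pectoral removal grows a region from an automatically placed seed in the
top-left corner; the pectoral muscle is a roughly homogeneous triangle
touching the top edge, so region growing with an intensity tolerance
recovers it while the noisier parenchyma halts the growth.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .errors import EmptyImageError, ParameterError
from .io import as_gray_image

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity used everywhere
# row-major neighbour enumeration fixes the region-growing frontier order
_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class BreastMask:
    mask: np.ndarray
    side: str = "left"
    flipped: bool = False


@dataclass
class PectoralRemoval:
    image: np.ndarray
    pectoral_mask: np.ndarray
    seed: tuple[int, int]
    failed: bool = False


def orient(image, threshold: int = 18) -> tuple[np.ndarray, bool]:
    """Mirror the image horizontally if the foreground mass sits on the right.

    Returns (oriented image, flipped flag).  Idempotent: orienting an
    already-left-sided image is the identity.
    """
    img = as_gray_image(image)
    fg = img >= threshold
    if not fg.any():
        raise EmptyImageError("no foreground at or above the threshold")
    w = img.shape[1]
    left = int(fg[:, : w // 2].sum())
    right = int(fg[:, w // 2 :].sum())
    if right > left:
        return img[:, ::-1].copy(), True
    return img.copy(), False


def suppress_artifacts(
    image, threshold: int = 18, opening_radius: int | None = None
) -> tuple[np.ndarray, BreastMask]:
    """Zero everything outside the largest thresholded component.

    Binarize at ``threshold``, apply a morphological opening (disk radius
    scaled with image size by default), keep the largest 8-connected
    component as the breast mask, and mask the image with it.  Labels and
    other disconnected bright objects are removed entirely.
    """
    img = as_gray_image(image)
    fg = img >= threshold
    if not fg.any():
        raise EmptyImageError("no foreground at or above the threshold")
    if opening_radius is None:
        opening_radius = max(1, round(min(img.shape) / 200))
    opened = ndimage.binary_opening(fg, structure=disk(opening_radius))
    if not opened.any():  # opening erased everything (tiny images): fall back
        opened = fg
    labels, n = ndimage.label(opened, structure=_EIGHT)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    out = np.where(mask, img, 0).astype(np.uint8)
    return out, BreastMask(mask=mask)


def srg(image, seeds, tolerance: float) -> np.ndarray:
    """Seeded region growing: grow an 8-connected region from ``seeds``.

    A candidate pixel is accepted when its intensity differs from the
    running regional mean by at most ``tolerance``; each pixel is examined
    once, the frontier is processed FIFO with row-major neighbour
    enumeration, so the result is deterministic.  The region always
    contains every seed.
    """
    img = as_gray_image(image)
    h, w = img.shape
    seeds = [(int(r), int(c)) for r, c in seeds]
    if not seeds:
        raise ParameterError("seed set must be nonempty")
    for r, c in seeds:
        if not (0 <= r < h and 0 <= c < w):
            raise ParameterError(f"seed {(r, c)} outside image bounds {img.shape}")

    region = np.zeros((h, w), dtype=bool)
    examined = np.zeros((h, w), dtype=bool)
    total = 0.0
    count = 0
    frontier: deque[tuple[int, int]] = deque()
    for r, c in seeds:
        if not region[r, c]:
            region[r, c] = examined[r, c] = True
            total += float(img[r, c])
            count += 1
            frontier.append((r, c))

    pix = img  # local alias for speed
    while frontier:
        r, c = frontier.popleft()
        for dr, dc in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not examined[rr, cc]:
                examined[rr, cc] = True
                v = float(pix[rr, cc])
                if abs(v - total / count) <= tolerance:
                    region[rr, cc] = True
                    total += v
                    count += 1
                    frontier.append((rr, cc))
    return region


def _place_seed(mask: np.ndarray) -> tuple[int, int]:
    """Topmost-then-leftmost breast pixel inside the top-left 25% x 25%
    window (the pectoral corner after orientation); falls back to a
    whole-image row-major scan if the window is empty."""
    h, w = mask.shape
    window = mask[: max(1, int(np.ceil(0.25 * h))), : max(1, int(np.ceil(0.25 * w)))]
    rows, cols = np.nonzero(window)
    if rows.size == 0:
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            raise EmptyImageError("breast mask is empty")
    order = np.lexsort((cols, rows))  # topmost, then leftmost
    return int(rows[order[0]]), int(cols[order[0]])


def remove_pectoral(
    image, mask: BreastMask, tolerance: float = 32.0, max_frac: float = 0.5
) -> PectoralRemoval:
    """Black out the pectoral muscle grown from an auto-placed corner seed.

    If the grown region exceeds ``max_frac`` of the breast area the
    segmentation is declared failed: a warning is logged, the over-grown
    region is still returned (flagged), and the image is left unmodified.
    """
    img = as_gray_image(image)
    seed = _place_seed(mask.mask)
    region = srg(img, [seed], tolerance)
    breast_area = int(mask.mask.sum())
    if breast_area and region.sum() > max_frac * breast_area:
        logger.warning(
            "pectoral region grew to %.0f%% of the breast (seed %s); "
            "treating as segmentation failure, image left un-blacked",
            100.0 * region.sum() / breast_area,
            seed,
        )
        return PectoralRemoval(image=img.copy(), pectoral_mask=region, seed=seed, failed=True)
    out = img.copy()
    out[region] = 0
    return PectoralRemoval(image=out, pectoral_mask=region, seed=seed, failed=False)


def segment_pipeline(
    image,
    threshold: int = 18,
    tolerance: float = 32.0,
) -> dict:
    """Run orient -> suppress_artifacts -> remove_pectoral; returns all stages."""
    oriented, flipped = orient(image, threshold)
    suppressed, bmask = suppress_artifacts(oriented, threshold)
    bmask.flipped = flipped
    pect = remove_pectoral(suppressed, bmask, tolerance)
    return {
        "oriented": oriented,
        "flipped": flipped,
        "suppressed": suppressed,
        "breast_mask": bmask,
        "pectoral": pect,
        "roi": pect.image,
    }
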