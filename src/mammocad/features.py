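"""Block-statistical texture features.

The image is partitioned into full F x G blocks (default 16 x 16; partial
edge blocks are discarded).  For each block z the statistics are

    Ent_z  = -sum_i pr_i log2 pr_i          (256-level histogram, bits)
    mu_z   = mean of the block pixels
    var_z  = population variance (divisor F*G)
    sd_z   = sqrt(var_z)
    R_z    = max - min
    rms_z  = sqrt(mean of squared pixels)   (default "pixel" mode)

and the per-image feature vector is the arithmetic mean of each statistic
over all Z blocks, in the canonical order (entropy, mean, variance, sd,
range, minimum, maximum, rms).  All eight defaults are invariant under
90-degree rotations of a square image whose side is a multiple of the
block size, because rotation permutes blocks and rotates block contents.

``rms_mode="row_col"`` switches the RMS statistic to the root mean square
of the per-row and per-column block means, a directional variant that is
not rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ParameterError
from .io import CANONICAL_FEATURES, as_gray_image

N_LEVELS = 256


class FeatureVector(NamedTuple):
    entropy: float
    mean: float
    variance: float
    sd: float
    range: float
    minimum: float
    maximum: float
    rms: float


@dataclass
class BlockStats:
    ent: float
    mu: float
    var: float
    sd: float
    range: float
    min: float
    max: float
    rms: float


@dataclass
class BlockGrid:
    blocks: np.ndarray  # (Z, F, G) in raster order
    F: int
    G: int
    grid_shape: tuple[int, int]

    @property
    def Z(self) -> int:
        return self.blocks.shape[0]


def partition(image, F: int = 16, G: int = 16) -> BlockGrid:
    """Split the image into raster-ordered full F x G blocks."""
    img = as_gray_image(image)
    m, n = img.shape
    if m < F or n < G:
        raise ParameterError(f"image {img.shape} smaller than one {F}x{G} block")
    bm, bn = m // F, n // G
    blocks = (
        img[: bm * F, : bn * G]
        .reshape(bm, F, bn, G)
        .swapaxes(1, 2)
        .reshape(bm * bn, F, G)
    )
    return BlockGrid(blocks=blocks, F=F, G=G, grid_shape=(bm, bn))


def block_entropy(block, n_levels: int = N_LEVELS) -> float:
    """Shannon entropy of the block's grey-level histogram, in bits."""
    b = np.asarray(block)
    if b.size == 0:
        raise ParameterError("block must be nonempty")
    counts = np.bincount(b.ravel().astype(np.int64), minlength=n_levels)
    pr = counts[counts > 0] / b.size
    return float(-(pr * np.log2(pr)).sum())


def block_stats(block, rms_mode: str = "pixel") -> BlockStats:
    """All per-block statistics for one block."""
    b = np.asarray(block, dtype=np.float64)
    mu = float(b.mean())
    var = float(b.var())  # population divisor F*G
    if rms_mode == "pixel":
        rms = float(np.sqrt((b**2).mean()))
    elif rms_mode == "row_col":
        line_means = np.concatenate([b.mean(axis=1), b.mean(axis=0)])
        rms = float(np.sqrt((line_means**2).mean()))
    else:
        raise ParameterError("rms_mode must be 'pixel' or 'row_col'")
    return BlockStats(
        ent=block_entropy(block),
        mu=mu,
        var=var,
        sd=float(np.sqrt(var)),
        range=float(b.max() - b.min()),
        min=float(b.min()),
        max=float(b.max()),
        rms=rms,
    )


def extract_features(
    image,
    F: int = 16,
    G: int = 16,
    rms_mode: str = "pixel",
    mask=None,
    mask_blocks: bool = False,
) -> FeatureVector:
    """Per-image feature vector: mean of each block statistic over all blocks.

    With ``mask_blocks=True`` and a breast ``mask``, blocks with zero
    overlap with the mask are excluded from the averages (by default all
    blocks are included).
    """
    grid = partition(image, F, G)
    blocks = grid.blocks.astype(np.float64)

    keep = np.ones(grid.Z, dtype=bool)
    if mask_blocks and mask is not None:
        m = np.asarray(mask, dtype=bool)
        bm, bn = grid.grid_shape
        overlap = (
            m[: bm * F, : bn * G]
            .reshape(bm, F, bn, G)
            .swapaxes(1, 2)
            .reshape(bm * bn, F, G)
            .any(axis=(1, 2))
        )
        if overlap.any():
            keep = overlap
        blocks = blocks[keep]

    mu = blocks.mean(axis=(1, 2))
    var = blocks.var(axis=(1, 2))
    mn = blocks.min(axis=(1, 2))
    mx = blocks.max(axis=(1, 2))
    if rms_mode == "pixel":
        rms = np.sqrt((blocks**2).mean(axis=(1, 2)))
    elif rms_mode == "row_col":
        lines = np.concatenate([blocks.mean(axis=2), blocks.mean(axis=1)], axis=1)
        rms = np.sqrt((lines**2).mean(axis=1))
    else:
        raise ParameterError("rms_mode must be 'pixel' or 'row_col'")
    ints = grid.blocks[keep] if (mask_blocks and mask is not None) else grid.blocks
    ent = np.array([block_entropy(b) for b in ints])

    return FeatureVector(
        entropy=float(ent.mean()),
        mean=float(mu.mean()),
        variance=float(var.mean()),
        sd=float(np.sqrt(var).mean()),
        range=float((mx - mn).mean()),
        minimum=float(mn.mean()),
        maximum=float(mx.mean()),
        rms=float(rms.mean()),
    )


def extract_dataset(images: Sequence, labels: Sequence[int], **kwargs):
    """Feature matrix + labels for a list of images (see LabeledDataset)."""
    from .dataset import LabeledDataset

    if len(images) != len(labels):
        raise ParameterError("images and labels must have equal length")
    X = np.array([list(extract_features(img, **kwargs)) for img in images], dtype=float)
    return LabeledDataset(
        X=X, y=np.asarray(labels, dtype=int), feature_names=list(CANONICAL_FEATURES)
    )
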