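"""Synthetic MLO-view mammogram phantoms with ground-truth masks.

The phantom is the test bed for every downstream stage: it draws a
breast-shaped half-ellipse of clipped Gaussian parenchyma texture against a
dark background, a brighter pectoral triangle filling the top corner on the
breast side (its intensity close to dense tissue, which is exactly why
pectoral removal matters), optional disconnected radiopaque label
rectangles near the opposite edge, and an optional circular mass lesion
that shifts local intensity and texture so the block statistics respond.

Geometry is deliberately simple — no X-ray physics, no CC view — but every
structure comes with an exact binary mask, so segmentation and feature
stages can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import GeometryError, ParameterError


@dataclass(frozen=True)
class LesionSpec:
    """Circular mass lesion: centre (row, col), radius in px, additive
    intensity shift, and additive texture-sd shift inside the disk."""

    center: tuple[int, int] = (160, 72)
    radius: int = 22
    intensity_shift: float = 48.0  # 3 x default parenchyma sd
    texture_sd_shift: float = 14.0


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    side: str = "left"
    breast_mean: float = 100.0
    breast_sd: float = 16.0
    pectoral_mean: float = 150.0
    pectoral_sd: float = 5.0
    pectoral_frac: float = 0.35  # fraction of the top edge under the triangle
    n_labels: int = 2
    lesion: Optional[LesionSpec] = None
    background_level: int = 6
    rng_seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ParameterError("side must be 'left' or 'right'")
        if not (self.background_level < 18 <= self.breast_mean):
            raise ParameterError("need background_level < 18 <= breast_mean")
        if not 0 <= self.pectoral_frac <= 0.6:
            raise ParameterError("pectoral_frac must lie in [0, 0.6]")
        if min(self.size) < 32:
            raise ParameterError("phantom must be at least 32x32")


@dataclass
class PhantomTruth:
    image: np.ndarray
    breast_mask: np.ndarray
    pectoral_mask: np.ndarray
    label_mask: np.ndarray
    lesion_mask: np.ndarray
    class_label: int  # abnormal = 1 iff a lesion is present
    spec: PhantomSpec = field(repr=False, default=None)


def _breast_silhouette(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Left-oriented breast mask (half-ellipse on the chest wall) and the
    pectoral triangle mask at the top-left corner; mirrored for side='right'."""
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w]
    # half-ellipse anchored on the left image edge
    c_r, a, b = 0.55 * h, 0.65 * w, 0.52 * h
    breast = ((cc / a) ** 2 + ((rr - c_r) / b) ** 2) <= 1.0

    pectoral = np.zeros((h, w), dtype=bool)
    if spec.pectoral_frac > 0:
        f_top = spec.pectoral_frac
        f_left = min(0.9, 1.6 * spec.pectoral_frac)
        pectoral = (rr / (f_left * h) + cc / (f_top * w)) <= 1.0
    breast |= pectoral  # pectoral sits inside the breast-side corner

    if spec.side == "right":
        breast = breast[:, ::-1]
        pectoral = pectoral[:, ::-1]
    return breast, pectoral


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom; deterministic for a fixed ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size
    breast, pectoral = _breast_silhouette(spec)

    # background: dim noise strictly below the artifact threshold 18
    img = np.clip(
        spec.background_level + rng.normal(0.0, 3.0, (h, w)), 0, 17
    )

    # parenchyma texture: clipped Gaussian noise (kept >= 24 so thresholding
    # at 18 leaves the breast as one component)
    parenchyma = spec.breast_mean + rng.normal(0.0, spec.breast_sd, (h, w))
    img[breast] = np.clip(parenchyma[breast], 24, 255)

    lesion_mask = np.zeros((h, w), dtype=bool)
    if spec.lesion is not None:
        les = spec.lesion
        rr, cc = np.mgrid[0:h, 0:w]
        lesion_mask = (rr - les.center[0]) ** 2 + (cc - les.center[1]) ** 2 <= les.radius**2
        if not lesion_mask.any():
            raise GeometryError("lesion disk is empty")
        if np.any(lesion_mask & ~(breast & ~pectoral)):
            raise GeometryError("lesion extends outside the breast parenchyma")
        extra_sd = max(0.0, les.texture_sd_shift)
        bump = les.intensity_shift + rng.normal(0.0, extra_sd, int(lesion_mask.sum()))
        img[lesion_mask] = np.clip(img[lesion_mask] + bump, 24, 255)

    if pectoral.any():
        img[pectoral] = np.clip(
            spec.pectoral_mean + rng.normal(0.0, spec.pectoral_sd, int(pectoral.sum())),
            24,
            255,
        )

    # radiopaque labels: bright rectangles near the non-breast edge,
    # guaranteed disconnected from the breast component
    label_mask = np.zeros((h, w), dtype=bool)
    lab_h, lab_w = max(6, h // 20), max(10, w // 14)
    for _ in range(spec.n_labels):
        for _attempt in range(50):
            r0 = int(rng.integers(0, h - lab_h))
            if spec.side == "left":
                c0 = int(rng.integers(int(0.82 * w), w - lab_w))
            else:
                c0 = int(rng.integers(0, int(0.18 * w) - lab_w))
            box = np.zeros((h, w), dtype=bool)
            box[r0 : r0 + lab_h, c0 : c0 + lab_w] = True
            # keep a >=2 px gap from breast and existing labels
            grown = np.zeros((h, w), dtype=bool)
            grown[max(0, r0 - 2) : r0 + lab_h + 2, max(0, c0 - 2) : c0 + lab_w + 2] = True
            if not np.any(grown & (breast | label_mask)):
                label_mask |= box
                break
    if label_mask.any():
        img[label_mask] = np.clip(
            230 + rng.normal(0.0, 5.0, int(label_mask.sum())), 200, 255
        )

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomTruth(
        image=image,
        breast_mask=breast,
        pectoral_mask=pectoral,
        label_mask=label_mask,
        lesion_mask=lesion_mask,
        class_label=int(spec.lesion is not None),
        spec=spec,
    )


def _jitter_spec(base: PhantomSpec, abnormal: bool, rng: np.random.Generator) -> PhantomSpec:
    """Per-phantom parameter jitter around a base spec (mean, pectoral extent,
    lesion placement); texture sd is held fixed so lesion contrast stays
    interpretable in units of sigma."""
    h, w = base.size
    lesion = None
    if abnormal:
        les = base.lesion or LesionSpec(center=(int(0.62 * h), int(0.28 * w)))
        jr = int(rng.integers(-8, 9))
        jc = int(rng.integers(-8, 9))
        lesion = replace(
            les,
            center=(les.center[0] + jr, les.center[1] + jc),
            radius=max(6, les.radius + int(rng.integers(-2, 3))),
        )
    return replace(
        base,
        breast_mean=base.breast_mean + float(rng.uniform(-1, 1)),
        pectoral_frac=(
            0.0
            if base.pectoral_frac == 0
            else float(np.clip(base.pectoral_frac + rng.uniform(-0.01, 0.01), 0.05, 0.6))
        ),
        lesion=lesion,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n_normal: int,
    n_abnormal: int,
    base_spec: PhantomSpec | None = None,
    rng_seed: int = 0,
) -> list[PhantomTruth]:
    """Generate ``n_normal`` lesion-free phantoms followed by ``n_abnormal``
    lesion-bearing ones (labels [0...0, 1...1] in emission order)."""
    if n_normal < 0 or n_abnormal < 0:
        raise ParameterError("cohort counts must be >= 0")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(rng_seed)
    out: list[PhantomTruth] = []
    for _ in range(n_normal):
        out.append(generate_phantom(_jitter_spec(base, abnormal=False, rng=rng)))
    for _ in range(n_abnormal):
        out.append(generate_phantom(_jitter_spec(base, abnormal=True, rng=rng)))
    return out
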