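"""Dataset augmentation by quarter-turn rotations and horizontal flips.

Rotations by multiples of 90 degrees and left-right mirroring are exact
index permutations of the pixel grid, so they enlarge a cohort without
introducing interpolation artefacts.  An AugmentPlan lists the rotations
to emit and whether each rotated copy is also mirrored, giving a
multiplication factor |rotations| x (2 if flip else 1): the standard
plans are x4 (four rotations) and x8 (four rotations, each also flipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .io import as_gray_image

_VALID_ROTATIONS = (0, 90, 180, 270)


@dataclass(frozen=True)
class AugmentPlan:
    rotations: tuple[int, ...] = (0,)
    flip: bool = False

    def __post_init__(self):
        rots = tuple(sorted(set(int(r) for r in self.rotations)))
        if not rots or any(r not in _VALID_ROTATIONS for r in rots):
            raise ParameterError("rotations must be a nonempty subset of {0, 90, 180, 270}")
        object.__setattr__(self, "rotations", rots)

    @property
    def factor(self) -> int:
        return len(self.rotations) * (2 if self.flip else 1)

    @classmethod
    def parse(cls, text: str) -> "AugmentPlan":
        """Parse plan strings like 'rot4+flip', 'rot4', 'rot1'."""
        parts = text.lower().split("+")
        flip = "flip" in parts
        rot = next((p for p in parts if p.startswith("rot")), "rot1")
        n = int(rot[3:])
        if n not in (1, 2, 4):
            raise ParameterError("rotation count must be 1, 2 or 4")
        rots = {1: (0,), 2: (0, 180), 4: (0, 90, 180, 270)}[n]
        return cls(rotations=rots, flip=flip)


#: ROTATE_4_FLIP is the x8 plan; ROTATE_4 the x4 plan; IDENTITY passes through.
ROTATE_4_FLIP = AugmentPlan(rotations=(0, 90, 180, 270), flip=True)
ROTATE_4 = AugmentPlan(rotations=(0, 90, 180, 270))
IDENTITY = AugmentPlan()


def augment_image(image, plan: AugmentPlan) -> list[np.ndarray]:
    """Emit the rotated (and optionally mirrored) copies, ``plan.factor`` in all."""
    img = as_gray_image(image)
    out = []
    for deg in plan.rotations:
        rotated = np.rot90(img, deg // 90).copy()
        out.append(rotated)
        if plan.flip:
            out.append(rotated[:, ::-1].copy())
    return out


def augment_cohort(
    items: Sequence[tuple[np.ndarray, int]],
    plan_by_class: Mapping[int, AugmentPlan],
) -> list[tuple[np.ndarray, int]]:
    """Apply each class's plan to every image of that class, preserving labels."""
    out: list[tuple[np.ndarray, int]] = []
    for image, label in items:
        if label not in plan_by_class:
            raise ParameterError(f"no augmentation plan for class {label!r}")
        for aug in augment_image(image, plan_by_class[label]):
            out.append((aug, label))
    return out


def class_counts(items: Sequence[tuple[np.ndarray, int]]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for _, label in items:
        counts[label] = counts.get(label, 0) + 1
    return counts
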