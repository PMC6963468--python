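"""Reproduce the augmentation counting arithmetic with the x4 and x8 plans.

Rotations by 0/90/180/270 degrees quadruple a class; adding a horizontal
flip of each rotated copy gives a factor of eight.  Applied to the source
counts of the two mammogram datasets this yields the published totals.
"""

import numpy as np

from mammocad import ROTATE_4, ROTATE_4_FLIP, augment_cohort
from mammocad.augment import IDENTITY, class_counts

img = np.random.default_rng(0).integers(0, 256, (8, 8), dtype=np.uint8)


def run(n_normal, n_abnormal, plan_normal, plan_abnormal):
    items = [(img, 0)] * n_normal + [(img, 1)] * n_abnormal
    return class_counts(augment_cohort(items, {0: plan_normal, 1: plan_abnormal}))


dream = run(300, 34, IDENTITY, ROTATE_4_FLIP)
mias = run(120, 93, ROTATE_4, ROTATE_4)
both = run(200, 127, ROTATE_4, ROTATE_4)
print(f"screening challenge: 300 normals kept, 34 abnormals x8 -> {dream[1]}  (total {sum(dream.values())})")
print(f"film database:       120 x4 -> {mias[0]} normals, 93 x4 -> {mias[1]} abnormals (total {sum(mias.values())})")
print(f"combined:            200 x4 -> {both[0]} normals, 127 x4 -> {both[1]} abnormals")
# Expected: 272 / 572, 480 / 372 / 852, 800 / 508 — exact counting identities.
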