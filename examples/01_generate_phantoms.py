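"""Generate a small MLO phantom cohort and inspect its ground truth.

Each phantom is a 256x256 8-bit image: a half-elliptical breast of noisy
parenchyma, a dense pectoral triangle in the top corner, bright label
artifacts near the opposite edge, and (for abnormal cases) a circular
mass lesion.  Every structure comes with an exact binary mask.
"""

from mammocad import LesionSpec, PhantomSpec, generate_cohort, generate_phantom

truth = generate_phantom(PhantomSpec(lesion=LesionSpec(), rng_seed=0))
print(f"image: {truth.image.shape}, class={'abnormal' if truth.class_label else 'normal'}")
for name in ("breast_mask", "pectoral_mask", "label_mask", "lesion_mask"):
    mask = getattr(truth, name)
    print(f"  {name:14s} {int(mask.sum()):6d} px")

cohort = generate_cohort(n_normal=3, n_abnormal=2, rng_seed=7)
print("cohort labels (normals first):", [t.class_label for t in cohort])
# The mask pixel counts are the ground truth that the segmentation stages
# are scored against; the label order is the fixed emission contract.
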