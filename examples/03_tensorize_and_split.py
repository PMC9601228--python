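"""From patches to the training dataset: tensorization, samples-per-class
capping, and the stratified 30/70 split.

Each pixel of a patch whose centered 21 x 21 window fits inside the patch is
a 'dominant pixel' that spawns one 21 x 21 x 10 tensor labeled by that
pixel's class. The SPC cap keeps at most 60 tensors per class from each
patch, and the pooled samples are split 30% training / 70% testing.
"""

from collections import Counter

from mammotensor import PhantomSpec, extract_patches, generate_phantom
from mammotensor import sample_by_class, split_dataset, tensorize_patch
from mammotensor.pipeline import enrich_phantom

image, breast_mask, labels = generate_phantom(PhantomSpec(seed=7))
mci, cropped_labels = enrich_phantom(image, breast_mask, labels)
patches = extract_patches(mci, cropped_labels, sps=64, scan_step=32, max_patches=10)

samples = []
for pid, patch in enumerate(patches):
    samples.append(tensorize_patch(patch, tws=21, tss=2, patch_id=pid))
print(f"tensors per patch : {len(samples[0])} "
      "(= ((64 - 21) // 2 + 1)^2 = 484 dominant pixels)")
flat = [s for group in samples for s in group]
print(f"total tensors     : {len(flat)} from {len(patches)} patches")

capped = sample_by_class(flat, spc=60, rng_seed=0)
print(f"after SPC = 60    : {len(capped)} tensors, class counts "
      f"{dict(Counter(s.class_code for s in capped))}")

ds = split_dataset(capped, train_fraction=0.30, rng_seed=0)
print(f"split             : {len(ds.train_idx)} train / {len(ds.test_idx)} test "
      "(30% / 70%, stratified, training order permuted)")
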