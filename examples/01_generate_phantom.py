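"""Generate one synthetic mammogram phantom and inspect its structures.

The phantom emulates a mammographic projection: a half-elliptical breast
region with smooth parenchymal texture, two bright Gaussian-profile masses
(class 2) and two clusters of tiny calcification speckles (class 1), plus
pixel noise. Labels are per-pixel so every downstream stage can be audited.
"""

import numpy as np

from mammotensor import PhantomSpec, generate_phantom

spec = PhantomSpec(image_size=(192, 192), n_masses=2, n_calc_clusters=2, seed=42)
image, breast_mask, labels = generate_phantom(spec)

print(f"image shape          : {image.shape}, intensities in "
      f"[{image.pixels.min():.3f}, {image.pixels.max():.3f}]")
print(f"breast coverage      : {breast_mask.coverage:.1%} of the frame")
counts = {c: int((labels == c).sum()) for c in (0, 1, 2)}
print(f"label pixel counts   : healthy={counts[0]}, calcification={counts[1]}, "
      f"mass={counts[2]}")
in_mass = image.pixels[labels == 2].mean()
healthy = image.pixels[(labels == 0) & (breast_mask.mask == 1)].mean()
print(f"mass vs tissue mean  : {in_mass:.3f} vs {healthy:.3f} "
      f"(elevation {in_mass - healthy:.3f}, configured contrast {spec.mass_contrast})")
# The elevation exceeding the configured contrast is what makes the masses
# detectable yet non-trivial against the textured, noisy background.
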