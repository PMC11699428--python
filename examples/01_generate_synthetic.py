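"""Generate a ground-truthed noisy test image and inspect its statistics.

Builds the classic two-region benchmark: a 100x100 image whose left half
is drawn from N(50, 20) and right half from N(200, 20), contaminated with
2000 impulse pixels (1000 forced to 0, 1000 to 255).
"""

import numpy as np

from abmff import generate, two_region_spec

spec = two_region_spec(sp_count=2000, seed=0)
clean, noisy, labels = generate(spec)

for name, img in (("clean", clean), ("noisy", noisy)):
    dark = img[labels == 1].astype(float)
    bright = img[labels == 2].astype(float)
    print(f"{name:>5}: dark region mean {dark.mean():6.2f} (std {dark.std():5.2f}) | "
          f"bright region mean {bright.mean():6.2f} (std {bright.std():5.2f})")
altered = int((noisy != clean).sum())
print(f"impulses: {altered} pixels altered, "
      f"{int((noisy == 0).sum())} at 0 / {int((noisy == 255).sum())} at 255")

# The clean means sit near the nominal 50/200; the impulses inflate the
# within-region standard deviations, which is what the homogenization
# stage is there to undo.
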