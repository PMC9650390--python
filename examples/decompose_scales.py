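"""Multi-scale bright/dark decomposition of one image.

Shows the per-scale detail energy, the entropy-based enhancement
weights, and the exact telescoping reconstruction.
"""

import numpy as np

from legff import FusionConfig, decompose, make_mr_like
from legff.fusion import compute_weights

img = make_mr_like(size=128, seed=7).image
cfg = FusionConfig()  # n=5 scales, windows [3,5,7,9,11], disks equal

dec = decompose(img, cfg)
wb = compute_weights(dec.bright_maps, "bright", cfg.entropy_bins)
wd = compute_weights(dec.dark_maps, "dark", cfg.entropy_bins)

print("scale  window  |bright|     |dark|    w_bright  w_dark")
for i in range(cfg.n_scales):
    print(f"{i + 1:>5}  {cfg.window_sizes[i]:>6}  "
          f"{np.abs(dec.bright_maps[i]).sum():9.1f}  {np.abs(dec.dark_maps[i]).sum():9.1f}  "
          f"{wb[i]:8.3f}  {wd[i]:7.3f}")

err = np.abs(dec.reconstruct() - img).max()
print(f"\nreconstruction max abs error: {err:.2e}")
print("The detail layers plus the base rebuild the input exactly; scales "
      "with richer (higher-entropy) detail get weights > 1 when fused.")
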