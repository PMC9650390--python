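"""Fuse a CT-like and an MR-like phantom and score the result.

The CT-like phantom carries the bright skull; the MR-like one carries
soft-tissue texture and lesions.  The fused image should score at least
as high as either source on the detail metrics.
"""

import numpy as np

from legff import fuse_pair, make_ct_like, make_mr_like, metric_report

ct = make_ct_like(size=256, seed=1)
mr = make_mr_like(size=256, seed=2)

fused = fuse_pair(ct.image, mr.image)

print("metric      CT       MR       fused")
for name in ("SF", "AbG", "STD", "E"):
    row = [getattr(metric_report(np.clip(img, 0, 255)), name)
           for img in (ct.image, mr.image, fused)]
    print(f"{name:<10}" + "".join(f"{v:9.3f}" for v in row))

lesions = mr.masks["bright_lesions"]
print(f"\nMR lesion mean in MR source: {mr.image[lesions].mean():.1f}")
print(f"MR lesion mean in fused:     {fused[lesions].mean():.1f}")
print("Higher detail scores (SF/AbG/STD) than either source mean the fused "
      "image kept both modalities' structures; the lesion means show the "
      "MR-only lesions survive fusion.")
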