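# legff — local extreme map guided multi-modal image fusion

`legff` fuses two co-registered 2-D medical images — e.g. a CT and an MR
slice, or a pseudo-color PET/SPECT map and a grayscale MR — into one image
that keeps the salient structures of both. It is aimed at researchers and
tool builders in medical image analysis who need a deterministic,
classical (non-learned) fusion baseline with a tested, scriptable API.

## Method

The core primitive is a guided filter whose guidance is not the image
itself but its **local extreme maps**. For an input *I*, structuring
element *se* (a flat disk of radius *k*) and window size *r*:

    I_f' = guidedfilter(I,    erode(I, se),     r)     # min-map guidance
    I_f  = guidedfilter(I_f', dilate(I_f', se), r)     # max-map guidance

Guiding by the local minimum map strips salient bright structures, and
the second pass under the local maximum map strips dark ones, so the
residual *I − I_f* is a far richer detail signal than a self-guided
filter produces. Splitting it by sign gives bright/dark feature maps:

    F_b = max(I − I_f, 0),   F_d = min(I − I_f, 0)

Iterating the filter with growing windows (*r_i* = 2·*i*+1, *k_i* = *r_i*,
*i* = 1…5 by default) on the previous scale's output yields per-scale
feature maps `F_{b,i}, F_{d,i}` and a base image `I_base = I_f^n`; the
stack telescopes back to *I* exactly.

Two images are fused per scale by `max(F_b^1, F_b^2)` and
`min(F_d^1, F_d^2)`, the per-scale fused maps are summed with
entropy-proportional weights `w_i = e_i / min_j e_j` (the least
informative scale gets weight 1), bases fuse as `max(I_base^1, I_base^2)`,
and the output is `F_b^fuse + F_d^fuse + I_base^fuse`. Color sources are
fused via their BT.601 luminance with chroma passed through untouched.

## Worked example

`python examples/fuse_phantom_pair.py` fuses the built-in CT-like and
MR-like phantoms (256×256, seeded) and prints:

```
metric      CT       MR       fused
SF           31.070    9.085   33.464
AbG           4.510    2.696    5.943
STD          72.945   45.545   79.665
E             3.225    5.162    6.070

MR lesion mean in MR source: 158.6
MR lesion mean in fused:     167.7
```

SF (spatial frequency), AbG (average absolute gradient) and STD measure
retained detail, E is the intensity entropy in bits; the fused image
scores above both sources on every metric, and the lesions that exist
only in the MR source survive fusion. The other examples cover the
color+gray pathway, the per-scale decomposition, and the
guidance-ablation comparison.

A thin CLI wraps the same pipeline:

```bash
legff synth --kind ct --size 256 --seed 1 -o ct.png
legff synth --kind mr --size 256 --seed 2 -o mr.png
legff fuse ct.png mr.png -o fused.png --metrics scores.json
legff metrics fused.png
```

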