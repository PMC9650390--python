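# Methods

## Model

`legff` implements a transform-domain fusion of two co-registered 2-D
images. Each source is decomposed into multi-scale bright/dark detail
layers plus a base image by iterated *local extreme map guided
filtering*, the layers are fused by elementwise max/min rules with
entropy-proportional enhancement, and the result is the sum of the fused
components. The method assumes the inputs are spatially aligned and on a
common 8-bit-like intensity scale; registration, resampling and
denoising are out of scope.

All computation is double precision on the 0–255 scale. 16-bit inputs
are linearly rescaled to 0–255 at load, because the entropy binning
(256 bins) and the metric conventions assume 8-bit dynamic range.
Intermediate feature maps are kept unclipped and signed (dark maps are
negative; weighted sums may exceed 255); only 8-bit export clips to
[0, 255] and rounds half-to-even.

## The filter

One filtering step runs the He-style guided filter twice: first on the
input guided by its morphological erosion (local minimum map), then on
that output guided by the *dilation of the once-filtered image* (local
maximum map) — the max map is deliberately derived from the intermediate
result, not the original input. Erosion/dilation use the closed flat
disk (cell (di, dj) in the footprint iff di²+dj² ≤ k²) with replicated
edges; replication avoids the spurious border extrema that 0/255 padding
would create, and the exact-disk membership rule is pinned by
enumeration tests (some toolboxes default to approximate decompositions).

Guided-filter conventions:

- `r` is the full window side length (an r×r window), so the default
  schedule [3, 5, 7, 9, 11] means 3×3 … 11×11 windows. The alternative
  radius reading would make the windows roughly twice as large; the
  side-length convention is exposed through the config so either can be
  tested.
- Box means near the border divide by the in-bounds pixel count.
- Intensities are divided by 255 before the linear-model fit, so the
  regularizer `gf_epsilon` (default 0.01) lives on the conventional
  0–1 scale. The same ε is used for both passes and all scales.
- Windows of exactly zero guidance variance with ε = 0 use the limit
  convention a = 0, b = window mean; with the default ε > 0 this never
  triggers. Note that with constant guidance the filter output is the
  box mean of the window means (a double box filter), since the
  per-window offset b is itself averaged over all covering windows.

## Multi-scale decomposition and fusion

Scale *i* filters the output of scale *i−1* (scale 1 filters the input)
with window r_i = 2i+1 and disk radius k_i = r_i, i = 1…5 by default —
five scales balance detail coverage against cost. The per-scale
difference splits exactly into a nonnegative bright map and a
nonpositive dark map with disjoint support, so the stack reconstructs
the input to float rounding (~1e−13); the final-scale output is the base.

Fusion rules: per-scale bright maps fuse by elementwise max, dark maps
by elementwise min, bases by elementwise max. The per-scale fused maps
are summed with weights w_i = e_i / min_j e_j, where e_i is the Shannon
entropy (base 2) of the fused map at scale i, dark maps being negated
first. Entropy histograms use 256 equal-width bins over [0, 255] with
values above 255 folded into the top bin; feature maps are real-valued,
so this binning is a pinned, configurable convention. If the minimum
entropy is zero (blank maps, possible on synthetic inputs) the weights
fall back to all ones with a logged warning, preserving the weighted-sum
semantics in the limit. Setting `enhance_weights=False` forces unit
weights, which makes fusing an image with itself return it exactly — the
strongest end-to-end correctness probe, exercised throughout the tests.
The fused sum is kept unclipped internally; export clips to [0, 255]
(rescaling instead would alter the preserved base intensities).

Color pairs follow the luminance protocol: the color source is converted
with the full-range BT.601 YCbCr matrix (pinned in one constant; the
variant with 16–235 headroom is not used because it is not invertible
over the full [0, 255] range), its Y channel is fused with the grayscale
source, and the output RGB is assembled from the fused Y and the
original Cb/Cr. Chroma is bit-identical up to the final RGB conversion,
where gamut clipping can still alter strongly saturated, brightened
pixels.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_scales` | 5 | number of filtering scales |
| `window_sizes` | [3,5,7,9,11] | guided-filter window side lengths (pixels) |
| `disk_radii` | = window sizes | flat-disk radii for the extreme maps (pixels) |
| `gf_epsilon` | 0.01 | guided-filter regularizer on the 0–1 scale |
| `entropy_bins` | 256 | histogram bins for the enhancement weights |
| `enhance_weights` | true | entropy-proportional detail enhancement |

## Synthetic phantoms

The generators emulate the *structure* of multi-modal brain pairs, not
their anatomy: a CT-like image (bright elliptical skull annulus, dark
air, dim soft-tissue interior), an MR-like image (band-limited texture,
bright and dark lesions of 60-level contrast at known loci, faint rim),
and a PET-like pseudo-color activity map (smooth Gaussian blobs with
strongly non-neutral chroma on a neutral background). All randomness
sits behind one seed, and each generator returns ground-truth masks so
tests can assert feature transfer pointwise.

Two deliberate stylizations:

- The CT interior is exactly flat; the mild noise is confined to the
  annulus and the exterior. Because the dark-fusion rule takes the
  elementwise minimum, any texture the CT carried at the MR lesion loci
  would be subtracted from the fused image there; a flat interior gives
  the lesion feature-transfer property an essentially exact bound. The
  guided filter's influence is hard-limited by its windows (per scale
  the output at a pixel depends on inputs within 2(r−1+k) pixels, ~130
  cumulative at the default schedule), so at the default 256×256
  resolution the lesion neighborhoods are effectively outside the
  skull's influence and the transfer deficit is below 1e−6 intensity
  levels. At much smaller sizes the skull sits inside that support
  radius and the bound degrades to fractions of a level.
- The MR rim is markedly darker than the tissue it encloses, as in real
  MR, which makes it a genuine dark feature overlapping the CT skull;
  the min rule therefore subtracts up to a few tens of levels from the
  fused skull. The skull-transfer test uses a correspondingly looser
  pointwise bound (−60 levels, mean ≥ 0.85× the CT value) — the skull
  remains clearly the brightest structure.

Passing tests on these phantoms show the pipeline's algebraic and
feature-transfer properties; they do not certify behavior on real
scanner data (no registration error, bias fields, or modality-specific
noise models are simulated).

## Metrics

SF is the quadrature sum of RMS row/column first differences; AbG is the
mean over interior pixels of sqrt((Δx²+Δy²)/2) with forward differences
— conventions for AbG vary across the literature, so scores are
comparable within this package, not across codebases. STD is the
population standard deviation and E the 256-bin Shannon entropy of the
clipped image. Color images are scored on their Y channel. The report
schema reserves keys for reference-based metrics (PS, QCB, VIFF, Qabf,
QGS, WSSIM, MSSIM) that this package does not compute.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run on phantoms of 32–256
pixels per side — 256×256 matching the resolution the method targets —
and brute-force oracles (sliding-window morphology, per-window
least-squares guided filtering) on 9–16 pixel images, where their
O(HW·r²) cost is negligible. One 256×256 default-config fusion takes
well under a second on a single CPU, and the whole pipeline is
deterministic: identical inputs and options produce byte-identical
outputs.
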