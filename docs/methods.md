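# Methods

`inifield` compresses a microscopy image by *fitting a function to it*:
a small sinusoidal multilayer perceptron is trained to map normalized
pixel coordinates to pixel intensities, and the trained weights — not
the pixels — are what is stored. This note documents the model, the
numerical choices, and what the synthetic test data does and does not
show.

## The model

An image with axes drawn from (T, C, Z, Y, X) is treated as a function
`f: [-1, 1]^D -> R`. Index `i` on an axis of extent `n >= 2` maps to the
coordinate `-1 + 2i/(n-1)`; an axis of extent 1 maps to the midpoint 0.
Intensities are min–max normalized onto [0, 100] using the observed
per-image minimum and maximum (stored in the header so the map can be
inverted at decode time). Normalization is global across all axes,
including channels, which preserves inter-channel brightness relations;
per-channel normalization is a configuration flag.

The network is a SIREN-style MLP. `depth` counts weight layers: the
default depth-7 model is an input layer, five hidden layers and an
affine output head, with the sine activation `h -> sin(omega_l (W h + b))`
after each of the first six layers. Each sine layer carries one
*trainable* frequency scalar `omega_l`, initialized at `omega_0 = 30`.
Initialization follows the standard SIREN scheme — first layer uniform
on `[-1/D, 1/D]`, deeper layers uniform on `±sqrt(6/fan_in)/omega_0`,
biases zero. `depth = 2` is a documented degenerate case: a single
affine map with no sine layers, used in the test suite as a
least-squares oracle for the training loop. The forward pass, backward
pass and the small convolutional feature extractor are implemented
directly in numpy with hand-derived analytic gradients; the test suite
validates every gradient path against central finite differences.

Matrix products with a single output column are evaluated with a
per-row pairwise reduction instead of BLAS, because BLAS gemv results
can differ in the last ulp depending on batch size; this keeps forward
evaluation bit-stable under any batching, which the decoding guarantee
below relies on.

## Sizing: the compression ratio is a guarantee

Given a target ratio `CR`, the byte budget is `floor(raw_bytes / CR)`
where `raw_bytes` is the uncompressed pixel payload (extents × dtype
bytes, independent of the source container). The planner chooses the
largest hidden width whose *exact* serialized file size — 8 bytes of
magic/length, the real JSON header and the weight payload — fits the
budget. The achieved ratio, measured on the written file, is therefore
always at least the target. Width is the only sized dimension; depth is
fixed at 7 unless overridden. Weights are stored as little-endian
float32 by default (float16 behind a header flag, trading precision for
budget).

## Training

Compression runs `steps` iterations of mini-batch gradient descent on
the mean-squared error between predicted and normalized intensities,
computed in the [0, 100] domain. Batches are drawn from a seeded
permutation of the full grid, reshuffled each epoch (default batch
65,536 points, or the full grid if smaller). The default optimizer is
adam (lr 1e-3, betas 0.9/0.999, cosine decay to 1e-5). Two conditioning
details matter:

* **Per-tensor learning-rate multipliers.** The output head's rate is
  multiplied by the intensity half-range (50 for the default [0, 100]
  domain). The hidden sine layers live on the scale
  `sqrt(6/fan_in)/omega_0` (~1e-2) and need small steps, while the head
  must traverse the full intensity range; with a single global rate the
  fit plateaus near the image mean (~24 dB on the nuclei fixture versus
  ~50 dB with the policy, at identical budgets).
* **Determinism.** Everything downstream of the seed is deterministic:
  identical image + configuration + seed produce byte-identical files.
  A non-finite loss aborts with a diagnostic rather than restarting.

The optimizer is pluggable behind a registry (`adam`, `sgd`, plus an
extension hook with the same `(params, grads, state)` signature). The
hook exists because the natural fit for this workflow is a *learned*
optimizer — a network trained to propose updates, removing per-image
learning-rate tuning; pretrained learned-optimizer weights are not
shipped, so the default is the hand-tuned adam policy above.

## Guidance losses

The total training loss is `mse + weight * balance * guidance`, where
`guidance` is dimensionless and `balance` (default 1000) places it on
the squared-intensity scale of the similarity term; `weight = 0`
reproduces the unguided trainer bit-exactly.

**Segmentation guidance** preserves downstream filament segmentation.
The evaluation segmenter (`reference_segment`) is deterministic:
auto-contrast clipping to `[mean - 1.5*std, mean + 10.5*std]`, Gaussian
smoothing (sigma 1), a Sato ridge response at scale 1 thresholded at
0.01, and removal of components whose *skeleton length* is below 20
pixels. Centreline length, not footprint area, is the size criterion:
the ridge filter inflates every object's binary footprint by roughly
the filter scale, so footprint area would let blurred specks survive a
threshold meant for filament length. Because this pipeline is not
differentiable, training uses a smooth surrogate: Gaussian smoothing,
a negative Laplacian-of-Gaussian ridge response, and a sigmoid
threshold with temperature tau (default 0.02); all filters use
zero-padded symmetric kernels so the adjoint in the analytic gradient
is the filter itself. The loss is one minus a soft Jaccard index
(`sum(min)/sum(max)`, exactly 1 at identity, equal to the product form
for binary arguments; two empty masks count as perfect agreement). The
trainer scores the surrogate against the *hard* reference mask of the
original: development probes showed soft-vs-soft matching has no
effect at practical weights, and over-weighted soft targets pull the
reconstruction away from what the reference segmenter responds to.

**Perceptual guidance** suppresses noise when compressing
low-laser-power acquisitions: each step, one patch rendered from the
model and one patch from a *clean reference* image are drawn at
independent seeded uniform locations, passed through a feature network,
and penalized by the layer-weighted squared feature distance
(per-layer mean over spatial positions). The default feature network is
a fixed, seeded three-layer convolutional stack with tanh
nonlinearities — a deterministic stand-in, not a pretrained perceptual
model; any network exposing `features_cached`/`vjp` can be substituted,
including pretrained ones. Patches enter the feature network on a unit
scale (divided by the intensity range).

## Hybrid mode (codec prior)

When fast compression matters, a classic codec takes `split` (default
90%) of the byte budget and the network fits only the residual. The
residual (original minus codec reconstruction, in the normalized
domain) is affinely mapped onto the training range, with the map stored
in the header. At decode time each Z-slice (or T-frame, or the whole
image if neither axis exists) keeps whichever of codec-only /
codec+residual scores better under the decision metric — PSNR by
default, with a callable hook for application-specific scores such as
object counts. Ties keep the codec-only slice. The built-in codec is a
deterministic toy: integer-factor spatial downsampling plus uniform
quantization at 16/8/4/2 bits, choosing the gentlest degradation that
fits its budget. It exists so the hybrid path is self-contained and
reproducible; production codecs (HEVC and friends) plug in behind the
same two-method adapter, with the caveat that their rate control is
approximate, so the adapter contract requires the payload to fit the
budget or fail loudly.

## File format and decoding

An `.inif` file is `"NIF1"`, a little-endian uint32 header length, a
compact JSON header (axes, shape, source dtype, normalization
parameters, architecture, seed, optional guidance/hybrid blocks, and a
fixed-width CRC-32 of the payload) and the raw weight payload in a
fixed order (per layer: weights row-major, then bias; then the
frequency scalars). Round-trips are bit-exact; corrupted, truncated,
mislabeled or future-versioned files fail with distinct errors.

Decoding evaluates the stored network only at requested coordinates:
full grids, single slices (the sliced axis keeps extent 1), strided
previews (anchored at index 0, extent `ceil(n/s)`), explicit index
lists, or boolean masks — possibly disconnected. Outputs are clipped to
the training range, inverse-affine mapped, clipped to the dtype range
and rounded half-to-even. Because the representation is a pure
function and evaluation is batch-invariant, every partial decode equals
the corresponding selection from a full decode bit-exactly; this is
tested across random ROIs of all modes.

## Metrics

PSNR is `10 log10(range^2 / MSE)` with `range` the dtype maximum (255
for u8, 65535 for u16), `+inf` for identical inputs. SSIM uses the
standard Gaussian-weighted 11×11 window (sigma 1.5, k1 0.01, k2 0.03)
via scikit-image, averaged over Y–X planes for higher-dimensional
stacks (the volumetric-window alternative is deliberately not used, so
numbers are comparable across 2D and 3D inputs).

## Synthetic data

The generators are pure functions of their arguments and a seed, and
emulate the image families the compressor targets: DNA-stained nucleus
volumes (non-overlapping ellipsoids with band-limited internal texture
over a dim background, u16), filamentous structures with periodic
striped intensity along the fiber (sarcomere-like), multichannel fields
whose channels share a base structure at a tunable colocalization
weight, and Poisson–Gaussian noise parameterized by an expected photon
count at full scale plus read-noise sigma. They deliberately omit PSF
blur, depth attenuation, spectral bleed-through and registration error;
passing tests on them demonstrates the *mechanics* of the workflow
(budget control, decoding, guidance plumbing, relative quality against
a matched-budget codec) — not reconstruction quality on real
microscopy, which depends on content statistics these phantoms do not
reproduce.

## Test-condition choices

Training-based checks use deliberately small problems so the whole
suite runs on a single CPU core: quality and guidance checks use a
48×48×24 nuclei volume (ratio 16, 3,000 steps) and a 192² filament
image (ratio 64, 2,000 steps) with batch 8,192 and three seeds,
reporting medians; ratio-controllability checks run 500-step fits on a
135×136×160 volume at targets 128/256/512 (the achieved ratio is fixed
by the planner, not by training length). The reproduction script
(`scripts/acceptance.py`) regenerates its volumes from the given seed
and recomputes the achieved ratios from the written files.

## Known limitations

* Lossy by construction; at high ratios fine texture is smoothed.
  Lossless methods should be preferred when downstream analysis cannot
  tolerate the measured loss.
* Compression is iterative optimization: minutes per volume on CPU,
  orders of magnitude slower than a classic codec (the hybrid mode
  exists for exactly this reason).
* The learned-optimizer and pretrained-perceptual-feature variants are
  interfaces, not shipped weights.
* The guidance balance factor is calibrated for the default [0, 100]
  training domain; custom domains may need a different `balance`.
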