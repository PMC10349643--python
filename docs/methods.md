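# Methods

## Problem and approach

Epicardial and intramyocardial adipose tissue appears in catheter-free OCT
B-scans of human hearts as clusters of honeycomb texture: bright
collagen/septal walls around dark lipid-filled lumens. Pixel-level
annotation of such images is expensive; image-level annotation ("this
B-scan contains adipose / it does not") is cheap. This package trains a
pixel-wise adipose segmenter from image-level labels only, in two stages.

**Stage 1 — pseudo-label generation.**

1. A small classifier (three convolutional layers with 32/32/64 channels,
   ReLU, two stride-2 stages so features live at 1/4 resolution, global
   average pooling, one linear layer to two logits) is trained on
   image-level labels with cross entropy and Adam.
2. The class activation map for the adipose class, `M(w) = sum_j mu_j
   f_j(w)` with `f_j` the final-layer feature maps and `mu_j` the adipose
   row of the linear head, is min-max normalized per image, bilinearly
   upsampled to image resolution, and thresholded at 0.15 (inclusive) to
   yield sparse adipose *seeds*. Seeds are produced only for images the
   classifier itself predicts adipose, so no labels are needed at
   inference.
3. CAMs respond to the bright tissue-surface artifact band, so seeds above
   or within a margin (default 10 px) of the detected tissue-background
   surface are removed. The surface detector smooths each column with a
   Gaussian (sigma 3 px along depth), thresholds at the image's Otsu level,
   takes the first crossing per column and median-filters the curve across
   columns (window 15).
4. The image is partitioned into ~K SLIC superpixels (K = 2000 at the
   reference 512x800 B-scan size; rescaled by area for other sizes so the
   superpixel density is preserved). A superpixel containing at least one
   seed is labeled adipose wholesale.
5. Markov spatial regularization: adipose cells cluster, so a superpixel
   flips its label when at least 80% (inclusive) of its adjacent
   superpixels carry the opposite label. Sweeps are synchronous and repeat
   to a fixed point (at most 10; in practice 1-3).

**Stage 2 — segmentation training.** A UNet-style encoder-decoder is
trained on the pseudo labels under

    Loss = alpha1 * CEL + (1 - alpha1) * ASL + alpha2 * DL

where CEL is mean per-pixel cross entropy, ASL (adipose seed loss) is cross
entropy restricted to pseudo-adipose pixels (so the network is free to find
adipose the pseudo labels missed), and DL is two-class soft Dice. alpha1 is
1.0 when fewer than 5% of training images contain adipose and 0.5
otherwise; alpha2 = 0.5.

## Networks without a deep-learning framework

Both networks are implemented on a compact NumPy layer stack
(`adiposeg.nn`) with explicit forward/backward passes: same-padded
convolutions via im2col + BLAS matmul, ReLU, 2x2 max pooling,
nearest-neighbour upsampling, global average pooling, a linear head, and
Adam. Everything runs in float32 on one CPU and is bit-reproducible for a
fixed seed, which makes the paired ablation contracts in the test suite
exact. Gradients of every loss term are analytic and are checked against
central finite differences in the test suite (away from ReLU kinks and the
probability clamp, where the loss is smooth).

## Parameters that matter

| knob | default | units | rationale |
| --- | --- | --- | --- |
| `cam_threshold` | 0.15 | fraction of normalized CAM | reference operating point; inclusive comparison |
| `boundary_margin` | 10 | pixels | covers the surface artifact band plus surface-detection error (MAE < 2 px on phantoms) |
| `superpixel_count` | 2000 | count at 512x800 | balances FP suppression (larger K) against TPR (smaller K); rescaled by area |
| `superpixel_compactness` | 0.1 | – | SLIC trade-off on [0,1] grayscale |
| `superpixel_sigma` | 1.0 | pixels | Gaussian pre-smoothing so superpixel borders follow tissue boundaries, not speckle grains |
| `regularization_quorum` | 0.8 | fraction of adjacent superpixels | inclusive; counts neighbours, not shared-border length |
| `alpha1` | rule | – | 1.0 below a 5% adipose-image ratio, else 0.5 |
| `alpha2` | 0.5 | – | Dice term weight |
| `patch_width`/`patch_stride` | 128 / 112 | pixels | overlapping full-height patches; 16-px overlap; probability maps fused by mean, seed maps by OR |
| localizer | 32/32/64 ch, lr 1e-3, batch 16 | – | Glorot init, Adam, cross entropy |
| segmenter | UNet depth 3, base 8, lr 1e-3 (optional step decay), wd 1e-4 | – | desk-scale size; depth/width configurable |

## The phantom generator

The human cardiac dataset this method targets is not publicly deposited,
so development and testing run on synthetic B-scans that reproduce the
features the method must cope with:

* per-column tissue surface `surface_row + tilt*(c - W/2) +
  wave_amp*sin(2 pi c / W)`;
* mean tissue intensity `background_level * g(r) * exp(-mu * depth)` below
  the surface, with `g` a Gaussian focal-plane gain (sigma = H/8) — with
  speckle off this closed form is exact, which the tests exploit;
* multiplicative gamma speckle with shape `1/s^2` (mean 1, dispersion `s`);
* adipose blobs as ellipses filled with Voronoi honeycomb: jittered
  hexagonal lattice of cell centres (period = `cell_diameter`), walls where
  the two nearest-centre distances differ by < 1.2 px, walls brightened and
  lumens darkened proportionally to the blob's contrast, smoothed with a
  0.6-px Gaussian. Deeper blobs get lower contrast (defocus and
  attenuation).

Randomly sampled specs use an ~11% adipose-image probability by default and
produce a long-run adipose-pixel fraction of a few percent on full-size
images. Fat-cell diameter (6-10 px) and blob radii (26-56 px axially) are
drawn in absolute pixels at the reference digital resolution and clipped to
the image, so a 64x64 phantom behaves like a patch cropped from a full
B-scan — the same anatomy at higher relative area — rather than a
miniaturized heart.

What the phantom does **not** model: physical OCT speckle correlation
(noise is i.i.d. per pixel), catheter or in-vivo motion artifacts,
multi-layer wall anatomy (endocardium/myocardium interfaces), shadowing
under vessels, and real adipose texture statistics, which are not publicly
quantified. Passing phantom tests therefore demonstrates that the
implementation is faithful and that the pipeline's stages interact as
designed, not that clinical-grade accuracy transfers to real scans.

## Numerical and design choices

* CAM normalization is per-image min-max; a constant CAM maps to all
  zeros. Upsampling aligns grid corners, so corner values are exact.
* Threshold comparisons are inclusive (CAM >= 0.15, quorum >= 0.8).
* The probability floor inside logs is 1e-7; ASL over an empty seed set is
  0; a Dice class term with zero denominator counts as perfect agreement.
* Predicted masks are per-pixel argmax with exact ties going to background.
* The surface detector substitutes a documented smoothed-threshold
  first-crossing rule for the original layer-segmentation algorithm, which
  is not specified in enough detail to re-implement; on phantoms its mean
  absolute error is well under the default boundary margin.
* Superpixel adjacency uses 4-connectivity and neighbour *counts* (not
  shared-border length) in the quorum; regularization updates are
  synchronous. Single superpixels with no neighbours never flip.
* Images the classifier predicts non-adipose receive all-zero pseudo
  masks and contribute only background supervision.
* The segmentation learning rate is 1e-3 and weight decay 1e-4; training
  is plain Adam without augmentation or scheduling.
* Grouped cross-validation splits by `sample_id` (heart), never by image.

## Desk-scale evaluation sizes

The self-contained experiments in the test suite and README run at sizes
chosen for a single CPU: 64x64 phantom patches (200 images) for the
end-to-end weakly-vs-fully supervised comparison, 128x128 phantoms for
seed-propagation quality, a depth-3 / base-8 UNet, 150 localizer epochs,
and 100 segmenter epochs with one 0.3x learning-rate decay at epoch 60
(training loss plateaus well before that; the decay damps the late-phase
oscillation of Adam at a plateau). The pipeline itself is
size-agnostic; the reference configuration (512x800 images, 512x128
patches, K = 2000, up to 300/200 epochs) is the default `RunConfig`.

## Known limitations

* The any-seed propagation rule dilates over-wide seed maps: every
  superpixel touched by a spilled seed is labeled adipose in full, so
  pseudo-label precision is bounded by CAM sharpness relative to
  superpixel size. Pseudo labels therefore plateau below fully supervised
  quality, and this is the main gap between weakly and fully supervised
  Dice on phantoms — wider than on real tissue, where annotation ambiguity
  lowers the supervised ceiling far more than it lowers the weak pipeline.
* The alpha1 rule gives *more* weight to CEL when adipose images are
  rarer; it is implemented exactly as specified even though the reverse
  might seem more intuitive.
* Regularization with an 80% quorum removes any isolated single-superpixel
  adipose region — deliberate noise suppression, but it also means a true
  adipose deposit smaller than one superpixel cannot survive unless its
  seeds span two superpixels.
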