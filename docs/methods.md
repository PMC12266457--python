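# Methods

## Problem setting

`burntseg` segments fire-burnt forest in single post-fire, 4-band
(NIR, red, green, blue) surface-reflectance scenes at 3 m pixel size.
Burnt surfaces are dark and strongly NIR-depressed; the difficulty of the
task comes from spectral confusers (water and shadow are also dark and
NIR-low) and from the spatial structure of burns, which range from large
contiguous patches to single-pixel fragments. Analysis is restricted to a
binary forest mask, nominally derived at 10 m and resampled to the scene
grid, so "unburnt" covers intact vegetation plus everything the mask
retains.

## Synthetic scene model

The generator produces a per-pixel class map (vegetation, burnt, water,
shadow, non-forest), renders reflectance from per-class per-band Gaussian
spectra, adds band-independent sensor noise, and clips to [0, 1]
(the clipped fraction is reported on the scene).

* **Geometry.** Burnt patches grow by stochastic frontier expansion —
  starting at a random forest pixel and repeatedly annexing a random
  subset of the 4-connected frontier — producing compact patches with
  irregular edges; a `fragmentation` parameter (default 0.15) diverts
  that share of the burnt budget into independently scattered single-pixel
  fragments. The total budget is `burnt_fraction_target` (default 0.157)
  times the forest pixel count and is hit exactly when geometry permits;
  generation fails explicitly when the target exceeds the burnable area.
  Water bodies and shadow blobs grow the same way; non-forest clearings
  are drawn on the coarse (10 m) grid so the forest mask is blocky.
* **Spectra** (reflectance mean ± sd): vegetation NIR 0.45 ± 0.05 / red
  0.06; burnt NIR 0.12 ± 0.025, dark in all bands; water 0.02–0.04
  everywhere (the deliberate burn confuser); shadow intermediate dark
  (NIR 0.08); non-forest bright (bare-soil-like). Sensor noise sd 0.01.
  These are stipulated, not fitted to any particular sensor or site: no
  quantitative spectral statistics were available to fit, so values were
  chosen once to reproduce the qualitative contrasts that drive the
  segmentation problem (strong NIR burn contrast, water/shadow/burn
  confusability) and are fully configurable.
* **Determinism.** One `numpy.random.Generator` per call, seeded
  explicitly; identical parameters and seed give bit-identical scenes.
* **What it does not emulate:** radiative transfer, topographic
  illumination, mixed pixels, sensor PSF, temporal change, clouds beyond
  dark shadow blobs, spatially correlated noise. Passing tests on these
  scenes demonstrates that the pipeline, architectures, training protocol
  and statistics behave correctly — not that the trained weights transfer
  to real imagery.

`make_forest_mask` block-averages NIR and red onto the coarse grid,
thresholds NDVI = (NIR − red)/(NIR + red) at 0.15 (vegetation ≈ 0.76,
burnt ≈ 0.26, shadow ≈ 0.33 pass; water ≈ 0 and bright bare surfaces
≈ 0.09 fail), and resamples to the scene grid by nearest neighbour, so the
result is constant within each coarse cell.

## Threshold reference mask

The reference ("labelled") burnt mask is derived exactly as an analyst
would produce it from the image itself: per-band min/max over burnt-labelled
samples, then a conjunctive inclusive interval test over all four bands,
intersected with the forest mask. Two conventions are assumptions, made
explicit here: the interval test is **inclusive** on both ends (ranges
derived from data must re-select their own pixels — tested as a closure
property) and **conjunctive** across bands (the conservative reading of
thresholding on all noted ranges). Sample defaults are 200 burnt + 200
unburnt points: an empirical min/max only covers the burnt spectral
distribution once the sample is large, and small samples truncate the
tails, speckling the mask.

## Architectures

Both networks are built on an in-package numpy layer library (3×3 same
convolutions via im2col, 2×2 max-pooling, 2×2 stride-2 transposed
convolutions, inverted dropout, a unidirectional GRU, softmax) with
hand-derived backward passes validated against central-difference
gradients in the test suite (relative error < 1e-4 in float64).

* **UNet:** encoder of `depth` (default 4) blocks, each two 3×3
  convolutions + ReLU (He-normal init), then 2×2 max-pool and 20 %
  dropout; filters double from `base_filters` 16 to a 256-filter
  two-convolution bottleneck; decoder mirrors the encoder with transposed
  convolutions, concatenation of the equal-resolution encoder map
  (shapes asserted at build time), dropout after each concatenation and
  two convolutions; head is a 1×1 convolution to 2 channels + per-pixel
  softmax.
* **UNet-GRU:** same recipe at `base_filters` 64 (encoder 64→512,
  bottleneck 1024). The bottleneck map (h × w × 1024) is flattened
  **row-major** into a sequence of h·w vectors — the canonical reading of
  reshaping a feature map into a sequence; direction and order are not
  otherwise determined — and a 512-unit GRU emits one vector per position
  (full-sequence output, unidirectional), reshaped back to h × w × 512
  before the decoder (512→64). The GRU output feeds the first up-block
  directly, without re-projection.
* Two output channels with softmax (not one with sigmoid) match the
  categorical cross-entropy objective; burnt is channel 1 and argmax ties
  break toward unburnt.
* Dropout is placed after each encoder block and after each decoder
  concatenation, rate 0.2 throughout.

At full scale (256×256×3 input) the bottleneck is 16×16, giving the GRU a
sequence length of 256 with 1024-dimensional steps.

## Training protocol

Adam (lr 1e-4 at full scale), categorical cross-entropy on one-hot masks,
batch size 4. The monitored quantity everywhere is the **burnt-class IoU
of argmax predictions on the validation set** — chosen because it is the
IoU variant that reproduces the tabulated full-scale values (TP/(TP+FP+FN)
on the published confusion counts gives exactly the printed 0.893 / 0.940,
whereas the two-class macro mean does not). Checkpointing keeps the
weights of the best monitored epoch; reduce-on-plateau multiplies the LR
by 0.9 after 10 consecutive non-improving epochs (floor 1e-7), with the
wait counter reset on both improvement and reduction and no minimum delta
(none is specified anywhere; any increase counts). Early stopping uses the
same monitor with patience 15 by default — the protocol names the callback
without parameters, so the value is this package's choice. Epoch budgets
default to 100 (UNet) and 50 (UNet-GRU). Training aborts with a diagnostic
on non-finite loss. Given a seed, runs are bit-reproducible
(single-threaded numpy).

## Evaluation

All scalar metrics derive from pixel confusion counts with burnt positive.
Ratios with zero denominators are NaN, never silently 0. F1 and Dice are
the same algebraic quantity and both are reported; `iou_burnt` is labelled
as the table-compatible IoU and a true macro IoU is reported alongside.
One documented discrepancy: the published GRU-model precision prints as
0.971, while its own confusion counts give 4,911,715/5,054,462 = 0.9718,
which rounds to 0.972 — the suite computes at full precision and asserts
agreement to one unit in the last printed digit. Similarly the printed
full-scale F1 values differ from full-precision recomputation in the third
decimal, so F1 is checked through Dice. One published hectare figure
(598.50 ha for a 655,000-pixel set at 3 m) is inconsistent with its own
pixel count (589.50 ha) and is deliberately not reproduced.

ROC-AUC is computed in rank (concordance) form — the probability that a
random positive outscores a random negative, ties ½ — with the (FPR, TPR)
curve from scikit-learn when requested. Pooled-pixel AUC is used for
curves; per-tile AUC feeds the model comparison, and tiles whose reference
contains a single class are excluded with a report.

Report rounding is half-away-from-zero at display time only; all
computation and CSV output is full precision.

## Statistical comparison

Tile-wise paired comparison of two models: two-sided paired t
(`t = mean(d)·√n / sd(d)`, sample sd, df = n−1) and a two-sided Wilcoxon
signed-rank test. Wilcoxon conventions (the source protocol is silent on
all three): zeros discarded, mid-ranks for tied magnitudes,
`W = min(R⁺, R⁻)`. The exact two-sided p for n ≤ 25 comes from a
dynamic-programming convolution over doubled ranks (so mid-ranks stay
exact), verified in tests against full 2ⁿ sign enumeration; larger n uses
the normal approximation with continuity and tie corrections. Zero
variance or all-zero differences raise an explicit degenerate-result
signal rather than returning a number.

## Scaled-down study conditions

The end-to-end acceptance study runs at desk size: three 256×256 scenes,
64×64 tiles in all four bands, both networks at `base_filters` 8 /
`depth` 3 (bottleneck 64; GRU 32 units over a 64-step sequence), Adam at
5e-3, 30 epochs, batch 4. Choices fixed once for this regime:

* **All four bands as input.** The threshold reference mask is a function
  of all four bands; giving the network the same information makes the
  task well-posed. (Full-scale defaults remain the 3-channel NIR-first
  false-colour stack, configurable.)
* **lr 5e-3** rather than the full-scale 1e-4: the scaled networks have
  ~10³ fewer parameters and see ~200 optimization steps, and 1e-4 leaves
  them far from convergence; 1e-2 was unstable for the GRU variant.
* **Burnt-preferring train split** (`prefer_burnt_train`): training tiles
  are drawn with extra weight on burnt-containing tiles, emulating the
  nearly class-balanced full-scale training set; this substantially
  shortens the initial all-unburnt collapse phase of optimization.

Under these conditions both architectures typically exceed validation
burnt-class IoU 0.8 within 30 epochs (≈1 minute per model on one CPU
core). The trajectory has two phases — collapse to the majority class,
then rapid emergence of the burnt class — and the length of the first
phase varies with the seed; occasional seeds leave one model below the
0.8 mark at epoch 30. The packaged end-to-end test therefore runs at a
fixed seed, which is the stated contract of that check.

## Numerical choices

* float32 weights/activations for training and inference; float64 only in
  gradient-check tests.
* Max-pool backward splits gradient equally among tied maxima.
* Softmax is computed with max subtraction; cross-entropy clips
  probabilities at 1e-12.
* Augmentation: one affine transform per call (flips, rotation uniform in
  ±30°, shifts uniform in ±10 % of the tile, zoom uniform in [0.8, 1.2]),
  bilinear with reflect fill for images, nearest-neighbour on the class
  map for masks (then re-one-hot, so masks stay exactly one-hot). The
  all-zero configuration short-circuits to a bit-exact identity.
* Tile splitting uses largest-remainder apportionment; empty sets are an
  error.
* Raster I/O is plain TIFF with a JSON metadata document (pixel size,
  affine transform, band order, nodata) in the ImageDescription tag;
  a write/read round trip preserves arrays and metadata exactly.

## Known limitations

* The numpy networks are CPU-bound and practical up to roughly 256×256
  inference / 64×64 training tiles; there is no GPU path.
* The GRU sequence order (row-major, unidirectional) is one canonical
  choice; a direction/order study is out of scope.
* Synthetic spectra are stipulated; nothing here validates transfer of
  trained weights to real sensor data.
* Tile-wise significance tests treat tiles as independent; spatial
  autocorrelation between neighbouring tiles is not corrected for.
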