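# Methods

This note records the scientific and numerical choices behind `mammoseg`:
the preprocessing contract, the architecture family and its cost accounting,
the metrics, the training procedure, what the synthetic phantoms emulate,
and the known limitations.

## Preprocessing chain

Raw mammogram exports (8- or 16-bit single-channel PNG/TIFF; DICOM
conversion is upstream of this tool) pass through a fixed order of
operations:

1. **Border crop** — scanned films show bright borders; `floor(0.025·H)`
   rows are removed top and bottom and `floor(0.01·W)` columns per side.
   The asymmetry (2.5 % vs 1 %) avoids clipping breast tissue that touches
   the lateral edge.
2. **Orientation** — all images are brought to a canonical "facing right"
   pose. The criterion is intensity-based: if the mean of the right
   half-columns strictly exceeds the left, the image and all its masks are
   mirrored; an exact tie means no flip. This is a deterministic, testable
   proxy for what is a manual/metadata step in clinical archives.
3. **Range normalisation** — min–max rescale to [0, 255], rounded; a
   constant image maps to all zeros (avoids 0/0). Placed *before* CLAHE so
   that CLAHE always sees an 8-bit histogram; the alternative order is not
   distinguishable from published descriptions of such pipelines, and doing
   normalisation first makes 16-bit and 8-bit inputs follow one code path.
4. **CLAHE** — contrast-limited adaptive histogram equalisation, clip limit
   2.0 on an 8×8 tile grid (the common defaults; both exposed in config).
   Semantics: per-tile 256-bin histogram clipped at
   `clip_limit · tile_area / 256` with uniform redistribution of the
   excess, equalisation LUT per tile, bilinear interpolation between the
   four surrounding tile-centre LUTs, reflect-padding when the grid does
   not divide the image. Applied to images only, never to masks.
5. **Pad to square** — zero fill, centred, odd surplus to the bottom/right.
6. **Resize** — bilinear to 640×640 for images; nearest-neighbour plus
   re-binarisation at 0.5 for masks.

Masks undergo only the geometric subset (crop, flip, pad, resize-as-mask),
so image and mask stay pixel-aligned throughout. Every geometric step is
logged in a `TransformRecord` (crop counts, flip flag, pad offsets, scale,
raw size); the record composes and inverts, and coordinate round-trips are
accurate to within one pixel (the only loss is the resize quantisation).

## Annotations and ROIs

Boxes are derived **per mass, before mask combination**, so two overlapping
masses produce two labels even though their union is one blob. Boxes use an
inclusive integer convention — `(xmin, ymin, xmax, ymax)` are extreme
foreground indices, width `xmax − xmin + 1` — which makes box metrics agree
exactly with pixel enumeration. YOLO label files carry one
`0 cx cy w h` line per box (6-decimal fixed point, normalised to the
frame). ROIs are cut with **zero margin** around the tight box (so ROI and
mask are exactly aligned, and mask foreground touches the non-padded ROI
borders), padded to square and resized to 128×128; a configurable margin
exists but defaults to 0.

## Architecture family

One declarative config generates every member: depth 3 or 4 encoder blocks
with (2, 2, 2, 3) convolutions per block and base filters (64, 128, 256,
512); the decoder mirrors the blocks in reverse, each starting with a 2×2
max-unpool driven by the paired encoder pool's argmax indices; the final
decoder convolution maps to one channel, followed by a sigmoid. This filter
schedule is the unique natural VGG-style choice that simultaneously
reproduces the published parameter counts of all six scratch-trained
variants (SegNet3 ≈ 2.29 M, SegNet4 ≈ 14.09 M, SegDSC3 ≈ 0.271 M,
SegDSC4 ≈ 1.61 M, SegDSC4_90 ≈ 20.5 k, SegDSC4_95 ≈ 6.4 k).

Conventions that the accounting (and the counts above) depend on:

* convolutions carry **no bias**; every convolution is followed by an
  affine normalisation (2 parameters/channel);
* in DSC units, normalisation and ReLU follow the **pointwise** convolution
  only (placing them after the depthwise too would push SegDSC4_90 past
  21 k parameters, off the published 0.020 M cell);
* width multiplier rounding is round-half-up with a floor of one filter;
  the output channel stays 1 regardless of w;
* MAC accounting counts convolution multiplies only
  (`H·W·9·Cin·Cout` standard; `H·W·(9·Cin + Cin·Cout)` DSC), with the
  spatial side halving per encoder block and doubling per decoder block;
  normalisation, activations and pooling are excluded.

Under this MAC-only convention the computed budgets at 128×128 are
SegNet3 4.85 G, SegNet4 7.87 G, SegDSC3 0.592 G, SegDSC4 0.934 G,
SegDSC4_90 0.0148 G, SegDSC4_95 0.0052 G. The first two and SegDSC4_90
match the published table at its printed precision; the published DSC cells
0.62 / 0.96 / 0.007 G differ from the MAC-only numbers in the last printed
digit, consistent with an unstated (and tool-dependent) FLOP convention in
the source benchmark; the closed forms here are exact for what they claim
to count and are verified against hand-computed sums.

The whole family — layers, forward, hand-written backward passes, Adam —
is implemented in numpy (float32, NCHW). Convolutions are evaluated as nine
shifted channel-mixing matmuls, which keeps peak memory at one padded input
copy rather than a full im2col buffer. Checkpoints are `.npz` weight
archives with a JSON architecture descriptor (config echo plus the
accounting report) alongside.

## Metrics

* Box IoU/GIoU use the inclusive-pixel areas, so they equal pixel-set
  enumeration exactly; GIoU subtracts the hull fraction not covered by the
  union and remains informative for disjoint boxes.
* Mask IoU and Dice are hard-mask metrics; probability inputs are
  thresholded at 0.5. Two empty masks score 1.0 (agreement on emptiness);
  empty vs non-empty scores 0.0. Dice = 2·IoU/(1+IoU) holds exactly and is
  asserted over random mask pairs.
* The soft Dice loss uses smoothing ε = 1.0 in numerator and denominator,
  keeping value and gradient finite on empty masks.
* AP matches detections (descending confidence, stable ties) greedily to
  each image's unmatched truth of highest IoU, then integrates the exact
  precision envelope over recall ("all-point" interpolation; a 101-point
  variant is available behind a flag). mAP@50:95 averages thresholds
  0.50–0.95 in steps of 0.05; with the single "mass" class, mAP = AP.
  Evaluation with zero ground-truth boxes is an error (recall undefined).
* The Otsu baseline maximises between-class variance over the 256-bin
  histogram, taking the smallest maximising threshold; the brighter class
  is the predicted mass (masses are hyperintense); constant ROIs yield an
  empty mask.

## Training procedure

Adam at initial learning rate 0.01 for from-scratch models (0.0001 would be
the pre-trained regime), soft Dice loss, batch size 16, epoch cap 160. Two
controllers watch the validation loss: a plateau scheduler multiplies the
rate by 0.6 after 5 epochs without improvement, and early stopping halts
after 25 stagnant epochs; "improvement" is an absolute decrease greater
than 1e-4. With stagnation from epoch 1 the first cut fires at epoch 6 and
the stop at epoch 26. The best-validation weights are restored at the end,
and the history logs loss, validation Dice and the learning rate per epoch.

When no explicit validation set is supplied, 10 % of *cases* (mammogram
ids, never individual ROIs) are held out with a fixed seed, preventing
leakage of ROIs from one mammogram across the split. Augmentation —
rotation ±20°, centre crop up to 10 %, scale 0.9–1.1, horizontal/vertical
flips at p = 0.5, all configurable — applies the identical geometric
transform to image and mask (mask re-binarised) and is driven by one seeded
generator, so full runs reproduce bit-identically. The held-out test split
is never augmented. Validation batches are evaluated un-augmented to keep
the controllers' signal stable. The monitored quantity for both controllers
is the validation loss.

## Synthetic phantoms

The generator emulates the *structure* the pipeline assumes, not mammogram
appearance: dark background (level ~N(10, 3)), a half-elliptical "breast"
anchored at the left or right edge (tissue level ~N(90, 10) with a radial
falloff), optional bright border rows/columns thin enough for the border
crop to remove, a bright corner tag, and 1–3 disjoint elliptical masses.
Masses have a flat core with a Gaussian edge (peak level ~N(180, 10)); the
ground-truth mask is the region above half the peak elevation, so the mass
is a distinct intensity mode with a soft rim. Gaussian pixel noise (σ = 3
by default) is added. Each case's RNG stream derives from (dataset seed,
case index), so any case regenerates independently and byte-identically.

What passing tests on phantoms shows: the geometry of the whole chain is
correct and invertible, the networks can learn a bright-lesion segmentation
task to high Dice at small scale, and Otsu behaves as expected (Dice ≥ 0.9
noiseless, degrading monotonically with noise). What it does not show:
performance on real mammograms — real masses have indistinct margins,
spiculation, overlapping fibroglandular texture and density variation that
the phantoms deliberately do not model. Published-scale results require the
real datasets and GPU-scale training.

The end-to-end learning check trains SegDSC4_90 on 200 phantom ROIs at
64×64 for at most 30 epochs and requires held-out Dice ≥ 0.85 (it reaches
≈ 0.95); ROI size 64 and n = 200 were chosen as the smallest problem that
still exercises the full four-level architecture (64 = 2⁴·4 leaves a 4×4
bottleneck).

## Two-stage inference

The detector is an interface, never a bundled network: implementations read
YOLO-format prediction files, adapt an external command, or derive oracle
boxes from ground-truth masks (testing). Detections below the confidence
cutoff (default 0.25, configurable) are discarded. Each accepted box is cut
as a zero-margin ROI, segmented, thresholded at 0.5, mapped back through
the recorded ROI and preprocessing transforms, and OR-ed into a single
full-resolution mask — the same pixelwise OR used to combine ground-truth
masks, which is the natural choice for overlapping predictions. Predicted
foreground can never fall outside a detection box. On phantoms,
oracle boxes plus an identity segmenter reconstruct the combined truth
within a one-pixel boundary tolerance (the nearest-neighbour resize
quantisation), verified over 50 cases.

## Degenerate inputs and tie-breaks

* Constant image under min–max normalisation → all zeros.
* Orientation tie (equal half means) → no flip.
* Odd padding surplus → extra pixel bottom/right.
* Empty mask to `mask_to_bbox` → error (signals a corrupt annotation).
* Empty detection list → empty mask, not an error.
* Two empty masks → IoU/Dice 1.0; Otsu on a constant ROI → empty mask,
  smallest maximising threshold on plateaus.
* Width-multiplier channel floor of 1 filter.
* Network forward requires the input side divisible by 2^depth, checked at
  pooling time.

## Known limitations

* No artefact/tag inpainting and no pectoral-muscle removal (the former was
  evaluated and rejected in the source study; the latter is out of scope).
* The orientation proxy can misjudge images whose background half is
  brighter than tissue (e.g. inverted-LUT exports).
* The numpy training loop is single-threaded BLAS-bound; it is sized for
  the compressed variants (SegDSC4_85/90/95) and small ROIs, not for
  training SegNet4 at full resolution.
* The detector stage ships as an interface only; detection quality is
  whatever the plugged-in provider delivers.
* Phantoms are structural stand-ins; no claim about real-data performance
  follows from them.
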