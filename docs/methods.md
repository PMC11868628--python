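# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limitations of the package. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The screening model family

All image models share one encoder design: an initial 3×3 convolution to
`base_channels` (16 at the reference scale), then one 3×3 convolution per
2×2 max-pooling stage, with the channel count doubling per stage up to a
cap of 256. At the reference input of 512×512×3 with five stages this
yields the 16×16×256 terminal feature map (16 → 32 → 64 → 128 → 256 → 256:
doubling is capped so the terminal matches the published shape).

**Attention bottleneck.** The bottleneck narrows channels progressively —
halving per step down to the target count (256 → 128 → 64 → 32 → 16 → 8
for the classifier; → 16 for the U-net). Each step is a 3×3 convolution
followed by a per-channel attention gate: global average pooling, a dense
C→C layer, and a sigmoid whose output rescales the channels. Gate biases
are initialized at +2 so the stacked gates start near-open (≈0.88) instead
of multiplicatively shrinking activations by 0.5 per step, which slowed
optimization noticeably in scaled-down training.

**Binary classifier.** Encoder + bottleneck to 16×16×8, flatten (2048),
two FC+dropout blocks, 2-way softmax. The published description fixes the
encoder shapes, the bottleneck output, and the total trainable parameter
count (1,718,770) but not the FC widths or the bottleneck internals.
`scripts/resolve_head_widths.py` enumerates a lattice of bottleneck
designs (narrowing schedule × conv kernel × attention form × attention
placement) crossed with all integer width pairs and keeps exact matches.
The frozen solution — halving schedule, 3×3 narrowing convolutions,
post-conv dense attention gate, head widths (144, 176) — reproduces the
total exactly (982,688 encoder + 415,152 bottleneck + 320,930 head). An
SE-style reduced attention (C→C/r→C) admits no integer solution with both
widths in [8, 1024] under the halving schedule, which is why the plain
dense gate was chosen.

**U-net segmenter.** Four stages at the reference scale (32×32×256
terminal), bottleneck to 16 channels, and a mirrored decoder: nearest-
neighbour ×2 upsampling, concatenation with the pre-pooling encoder
feature, one 3×3 convolution back to the skip's channel count, and a final
1×1 sigmoid convolution to 3 planes (disc, cup, fovea heatmap).

**Multi-task model.** The same U-net plus a classification branch taken
from the bottleneck output — 32×32×16 at the reference scale, the smallest
array in the network — flattened through two FC+dropout blocks to a 2-way
softmax. Whether the branch taps before or after the attention narrowing
is not externally constrained; it taps the narrowed output, which is what
makes the 16-channel branch point shape hold.

**FFCN.** Numeric-feature classifier with hidden widths 16, 32, 64, 128,
64, 32, 16 (the published width list is taken as authoritative over the
prose layer count), dropout (rate 0.2) after every hidden layer, softmax
output. The cupping instance consumes 9 features: disc size index, the
five CDRs, NRRA/DA, and the two circularity indices. The fusion instance
consumes the four binarized sub-model decisions; appending probabilities
or raw disc parameters is left to the caller (the deployed input encoding
is ambiguous in its public description, so binaries — the literal reading
— are the default).

**Training.** Adam (β₁ 0.9, β₂ 0.999). Segmentation uses 1 − soft-Dice
with smoothing ε = 1 in numerator and denominator (stabilizes empty
masks); classification uses categorical cross-entropy. Default learning
rate 1e-3 (3e-4 for the 64-px image classifier runs, which diverge at
1e-3); batch size 8. All training is seeded: one generator drives
shuffling and every dropout layer is reseeded deterministically, so a
fixed seed reproduces the loss history bit-for-bit on one machine.
Five-fold splitting is stratified (class ratio within one item per fold).

**Implementation note.** The models run on a small reverse-mode autodiff
core (`aigs.nn`) written on numpy: im2col convolutions, 2×2 max pooling,
nearest upsampling, channel concatenation, and the activations/losses
above. Gradients of every operation are finite-difference checked in the
test suite. This keeps the package dependency-light and fully
deterministic on CPU; the cost is that realistic 512² training is out of
scope — training-dependent tests run at 64² (see below).

## Operating thresholds

Per-model decision thresholds default to the published optimal operating
points: multi-task classifier 0.5245, cupping FFCN 0.4638, DH classifier
0.4373, mask-assisted DH classifier 0.4004. The RNFLD threshold is not
printed anywhere and defaults to 0.5; the fusion threshold defaults to
0.5. The escalation rule upgrades a fused-negative case to *glaucoma
suspect* when cupping probability > 0.65, RNFLD > 0.8, or DH > 0.75 —
strict inequalities, so setting an escalation threshold to 1.0 disables
that channel exactly. A fused-positive referral is never downgraded, which
is why escalation can only raise sensitivity and lower specificity; the
test suite checks this monotonicity on 1000 synthetic prediction bundles.

## Synthetic phantoms

A phantom is a fully parameterized scene: disc ellipse (center, semi-axes,
rotation), cup ellipse (same rotation, center offset, contained by
construction), fovea center outside the disc, vessel arcades (quadratic
Béziers seeded per scene), optional DH blobs (dark-red soft-edged
ellipses near the disc margin, within 2× the disc diameter) and RNFLD
bands (multiplicative darkening of an arcuate wedge from the disc margin
toward the fovea, contrast 0.05–0.2).

Default cohort geometry emulates a 45° macula-centered photograph: disc
diameter 13–16% of the image side, fovea temporal to the disc at a disc
size index (disc-fovea distance over maximum disc diameter) uniform in
2.45–3.35, disc-fovea angle within ±8°, disc ovality (major/minor) 1.0–
1.25 with a near-vertical major axis. Glaucomatous scenes draw a linear
CDR of 0.65–0.85 against 0.25–0.5 for normals. Laterality mirrors the
geometry (right eye: disc on the right, fovea to its left). Disc size
classes use index cutoffs < 2.4 (large) and > 3.0 (small); the cutoffs are
configuration, not anatomy — no published values exist.

The generator's purpose is geometric ground truth, not photorealism: no
camera color model, no media opacity, no peripapillary atrophy, no myopic
tigroid texture, and vessels that are smooth arcs rather than a vascular
tree. Consequences: segmentation and classification tasks on phantoms are
much easier than on clinical images, so passing training smoke tests
demonstrates that the architectures and training loops learn — not
clinical performance. Conversely the morphometry validation is exact in a
way clinical data cannot be: every ratio has a closed-form value
(ellipse areas πab, extents from the rotated-ellipse bounding box,
perimeters by the complete elliptic integral, sector areas by 4096-ray
polar quadrature).

## Morphometry: numerical choices

- Planes binarize at 0.5; the cup is intersected into the disc, making
  NRRA/DA + ACDR = 1 an arithmetic identity. The largest connected
  component per plane is measured; smaller fragments are dropped.
- Perimeters use the Crofton formula (4 directions): the marching-squares
  arc length overestimates a rasterized ellipse's perimeter by ~5%, which
  cancels in PCDR but not in circularity (4πA/P²).
- Vertical/horizontal/major-axis extents are measured on the moment-fitted
  equivalent ellipse of each component. A raw pixel caliper quantizes to
  whole pixels (±1 px ⇒ ~2% on a 50 px cup); the moment fit is sub-pixel
  (≲0.3% on rasterized ellipses). For non-elliptical components the value
  is the equivalent-ellipse extent.
- Maximum disc diameter (for the disc size index) is the caliper of the
  convex hull of the boundary contour.
- The fovea heatmap grid side is round(0.2 × image side); σ defaults to 8%
  of the image side (unspecified externally; the 20% grid is published).
  Fovea decoding takes the intensity-weighted centroid of the connected
  region ≥ half the global maximum; a peak below 0.2 counts as absent,
  in which case fovea-dependent parameters are NaN and the pipeline
  continues disc-only.
- Sector frame: 0° points from disc center to fovea (temporal); T and N
  are ±45° wedges about 0°/180°; S and I the remaining quadrants; ST/IT
  the 45° wedges at +(45–90]° and −[45–90)° flanking T. The superior side
  is fixed by laterality (image-up for an upright photograph of that eye),
  which keeps all sector ratios covariant under image rotation. No
  published sector-boundary angles exist; these are package conventions.
- Mask PNGs support two dialects — training (cup yellow) and model-output
  (cup green) — that decode to identical planes; unknown colors are
  rejected with a pixel count.

## Preprocessing

CLAHE is applied to the Y channel of a YCbCr decomposition (chroma
untouched), 8×8 tile grid, clip limit 2.0 expressed as a multiple of the
uniform histogram level (converted internally to the normalized convention
of the underlying implementation). The color space and parameters are
package choices; only the use of CLAHE itself is externally fixed. ROI
crops for the DH branch are squares of side 2× the disc diameter (factor
configurable), centered on the circle fitted to the disc contour
(least-squares Kåsa fit), black-padded at image borders, resampled
bilinearly (images) or nearest-neighbour (masks); the `RoiCrop` record
stores the exact affine mapping, and overlays are drawn back in source
coordinates through its inverse.

## Statistics

Percentile bootstrap throughout (B = 2000 default, 95% level); BCa was not
used because the external description names percentile selection.
Youden's threshold breaks ties toward the larger threshold. DeLong's test
uses the structural-components formulation with midranks; zero variance of
the AUC difference (e.g. identical score vectors) returns p = 1 by
convention. Bland-Altman differences are a − b with limits bias ± 1.96 sd.
Correlation comparison picks Pearson only when all four involved columns
pass Shapiro-Wilk (α = 0.05, subsampled to 5000) in their group, Spearman
otherwise; the difference p-value is twice the smaller bootstrap tail
about zero. Histogram FWHM interpolates the half-maximum crossings between
bin centers; constant data reports a single bin whose width is the FWHM.

## Scaled-down validation sizes

The problem sizes used by the heavier suites, chosen to exercise each
claim at desk scale: the morphometry oracle sweep uses 200 phantoms at
1024 px with disc diameter ≥ 200 px (where rasterization error is safely
below the 2% band); segmenter smoke training uses 50 phantoms at 64 px for
30 epochs with a 20-image hold-out; classifier smoke training uses 120
disc-ROI crops at 64 px for 50 epochs with a 40-crop hold-out; the fusion
network trains on class-rebalanced OR-labeled bundles (the 16-row truth
table is 15:1 imbalanced, so the all-negative row is oversampled); DeLong
type-I error uses 5000 null simulations at n = 200; bootstrap CI coverage
uses 400 replicates of binormal scores at n = 400 with B = 400.

## Known limitations

- Phantom realism as above; no claim of clinical performance transfers.
- The bottleneck's internal design and FC widths are one exact solution to
  the published constraints, not a confirmed reconstruction.
- Equivalent-ellipse extents assume roughly convex, blob-like components.
- The numpy backend is single-threaded-deterministic but slow; 512²
  training is intentionally unsupported.
- The escalation rule's recommendation wording in reports is package
  wording; no canonical phrasing exists.
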