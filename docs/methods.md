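# Methods

`myelinquant` quantifies oligodendrocyte ensheathment in nanofiber
cultures: cells are grown on parallel electrospun fibers (~2 µm wide,
axon mimics), stained for nuclei (Hoechst) and membrane/myelin (O4 or
MBP), and imaged as whole-well rasters at 0.5 µm/pixel. The unit of
measurement is the *sheath* (ensheathment): an elongated membrane segment
wrapped along a fiber, scored per cell under four criteria — (1) an
identifiable cell body and nucleus, (2) length > 12 µm and thickness
> 2 µm, (3) continuity with the cell body, (4) each sheath belongs to at
most one cell.

## Heuristic engine

Two streams run on the CLAHE-enhanced membrane channel:

* **Ridge stream.** Sheaths are bright elongated structures; the engine
  scores each pixel from the Hessian eigenvalues at scale
  `ridge_sigma_px` (default 2 px, maximal response at the 4 px ≈ 2 µm
  sheath width). With eigenvalues ordered |λ₁| ≤ |λ₂| the ridge-likeness
  is |λ₂|·(1 − |λ₁|/|λ₂|) for λ₂ < 0, else 0 — strong curvature across
  the ridge, weak along it. The exact eigenvalue combination is a design
  choice of this package and is isolated in `ridge_score` so it can be
  swapped. The binarization threshold is the `1 − sensitivity` quantile
  of the score map. A quantile threshold is scale-free, but it caps the
  segmentable area at the `sensitivity` fraction of the image: set it
  above the expected sheath-pixel fraction (defaults 0.05; dense wells in
  the group-comparison benchmark use 0.10, since their sheath fraction
  approaches 6%).
* **Cell-body stream.** The membrane foreground (Otsu) is opened with a
  disk wider than the sheath half-thickness, so only compact somata
  survive; the distance transform's h-maxima (suppression depth
  `hmax_depth`, default 2 px) seed a watershed of the inverted distance
  map; regions are kept only if they contain a detected nucleus and carry
  that nucleus's label (regions spanning several nuclei are re-split with
  the nuclei as seeds).

Cell bodies are subtracted from the ridge mask and the remaining
connected segments are associated to cells by continuity: a segment
joins the nearest cell whose body (or already-associated sheath) lies
within `association_gap_um` (default 2 µm, one sheath thickness). The
transitive step matters because oligodendrocytes lay several internodes
along one fiber: a distal internode touches its proximal neighbour, not
the soma. Remaining segments are discarded; per-cell sheaths below the
length floor are filtered (see post-processing). No sheath pixel is ever
claimed by two cells.

## Masked-nucleus network

The cell-by-cell network sees one candidate at a time: a crop (default
256 px, 128 px in the scaled-down experiments) centered on a nucleus,
with channels (membrane, binary mask of that nucleus, all-nuclei stain).
Candidates are nuclei whose centroid falls in a membrane blob (closing
then opening of the binarized membrane); unstained cells are skipped.

The network is a reduced UNet: five 5×5 stride-2 convolutions with 10,
20, 30, 40, 50 filters down; five 5×5 fractional-stride (transposed)
convolutions with 50…10 filters up, each preceded by concatenation of
the matching down-arm resolution; a 1×1 softmax head yields two mutually
exclusive classes, thresholded at 0.5. It is implemented directly in
numpy with hand-derived backpropagation: convolutions via im2col/GEMM,
transposed convolutions as the exact adjoint (input-gradient) of a
stride-2 convolution — which guarantees the two arms mirror shapes — and
Adam updates. Gradients are validated against finite differences in the
test suite. ReLU activations and He initialization are used; the
original work does not state its activation or initializer, and nothing
downstream depends on the choice.

### Loss weighting

Per-pixel categorical cross-entropy with two optional emphases:

* **Class weighting** multiplies the loss on sheath pixels by 10,
  countering the extreme class imbalance (sheath pixels are <1% of a
  crop; most candidate crops contain no sheath at all).
* **Spatial weighting** multiplies each pixel's loss by an exponential
  decay in D, the Chebyshev (chessboard) distance to the nearest
  ground-truth sheath pixel, computed on the inverted truth mask. Two
  readings of the offset `b` are implemented: `exponent` mode,
  w = exp(1 − D/f + b), the formula as printed; and `additive_floor`
  mode, w = exp(1 − D/f) + b, matching b's stated purpose of keeping
  weights away from zero. `spatial_weight_map` defaults to the printed
  formula. For *training* the default is the additive floor with
  f = 6 px, b = 1.0: with b = 0 the weight vanishes far from any sheath,
  so false positives in empty regions are never penalized and the
  network's validation JI plateaus around 0.25–0.3 — exactly the failure
  b exists to prevent. At b = 1 the background weight tends to exactly 1
  (plain cross-entropy far from objects) with an e-fold bonus at object
  margins, which in our experiments gives both the early learning
  advantage of weighting and a stable rise in validation JI. f and b are
  never stated numerically in the original work; both are exposed
  configuration.

### Training and monitoring

One "step" is one minibatch update (batch 4, Adam, lr 10⁻³ by default;
optimizer, batch and rate are unstated upstream and configurable here).
Optional augmentation rotates each example by a uniformly random angle.
Every `val_every` steps the log records the training loss, unweighted
validation loss, the mean per-example Jaccard index at threshold 0.5,
and a *pooled* validation JI (sum of intersections over sum of unions
across the validation set). The per-example mean scores an empty-vs-empty
pair as 1, so with realistic imbalance an all-background predictor gets
~0.85 — useless as a learning signal; the pooled JI gives it 0. Best
checkpoints are therefore selected on pooled JI. Training aborts on a
non-finite loss.

## Post-processing

Applied to per-cell masks, in order:

1. **Unfair distribution.** A connected sheath component claimed by two
   or more cells goes wholly to the claimant with the larger total sheath
   area (ties to the lower cell id; result independent of input order).
2. **Sticky removal.** The mask is skeletonized; branch points (≥3
   skeleton neighbours) are removed; each skeletal branch whose extent
   across the fiber axis exceeds its extent along it is deleted;
   branch-point clusters adjacent to ≥2 retained branches are re-inserted
   to restore along-fiber connectivity; finally each mask pixel survives
   iff its nearest skeleton pixel is retained (and within
   `reconstruct_radius_px`, default 6).
3. **Length filtering.** Lengths below `min_length_um` (12 µm) are
   dropped; survivors are re-counted per cell, and cells left with one or
   two sheaths face a `strict_multiplier` × floor (default 3×, the
   lenient end of the stated 3–4× range) — guarding against the
   false-positive bias human non-experts show on sparsely ensheathing
   cells. The pass ordering (filter, re-count, strict pass) is a design
   choice documented by a worked example in the tests: sheaths of
   10/15/40 µm leave only the 40 µm sheath at multiplier 3.

**Length** is the moment-equivalent major axis: with λ_max the largest
eigenvalue of the pixel-coordinate covariance, length = √(12·λ_max + 1)
pixels, scaled by the pixel size. For an N-pixel straight bar this is
exactly N, for one pixel exactly 1, and it is rotation-invariant to
within ~2% discretization error. This is a fixed √3/2 rescale of the
regionprops "ellipse major axis" convention (which returns 1.155·N for a
thin bar); the rescaled version is used consistently on both sides of
every comparison so thresholds keep their physical µm meaning.

## Morphometrics and power scaling

Per cell: sheath count, lengths, mean sheath length (mSLC). Per well:
means ± SEM over ensheathing cells (counts, mSLC) and over pooled
sheaths (log₁₀ lengths — sheath lengths are log-normal, so analysis is
on log lengths; base 10 throughout). Segmentations are compared by
Jaccard index per commonly identified cell (nuclei paired greedily
closest-first within 10 µm, one-to-one) and globally over the union of
per-cell masks; a both-empty pair scores 1.

`min_detectable_difference(n, n_ref, delta_ref)` carries the 1/√n
scaling of the two-sample minimum detectable difference at fixed power
and significance: a reference of 0.01 log units at n = 13,000 maps to
≈0.066 (~0.07) at n = 300. `derive_log_length_sd` inverts the same
normal-approximation power equation for the per-observation dispersion,
giving σ ≈ 0.288; the phantom's default log₁₀-length sd of 0.29 is this
value rounded.

## The phantom generator

Phantoms emulate the culture geometry: vertical fibers every 8 µm;
somata (stained disc, default radius 6 µm) with nuclei (3.5 µm); sheath
bars 2 µm thick centered on fibers, one end inside the soma disc so
continuity holds by construction; additional same-cell internodes chain
along a fiber behind earlier ones with a small (2 µm) gap, as real
oligodendrocytes tile internodes along one axon. Lengths are
log₁₀-normal (mean 1.6, sd 0.29) truncated below at the 12 µm floor;
sheath counts are 1 + Poisson(mean − 1) for ensheathing cells.
Ensheathing probability defaults to 0.15, the approximate fraction of
candidates that ensheathe in real wells (~300 of ~2000). Rendering adds
a flat background, slight Gaussian edge softening, and additive Gaussian
noise; fibers appear only faintly in the brightfield channel (the stains
do not label bare fibers).

Somata are rejection-sampled with a distance floor and, additionally, a
vertical separation between somata that can reach the same fibers, so
one cell's internode chain does not block a neighbour's fiber access;
`crowding > 0` relaxes both constraints and deliberately engineers
sheath overlaps between neighbours, recording each shared segment and
its intended (larger-area) owner so overlap resolution can be scored
exactly.

Two realized-statistics caveats, both visible in the tests: truncation
at 12 µm shrinks the realized log-length sd ~8% below the nominal value
(matching the truncated-normal prediction), and on crowded canvases
placement rejections select against long sheaths — sample-moment checks
therefore use canvases with low fiber occupancy.

What the phantom does **not** emulate: process arbors and branching
morphology, fiber curvature or crossing, staining heterogeneity and
photobleaching, out-of-focus light, 3-D structure. Passing phantom tests
demonstrates the machinery (geometry handling, association logic,
filtering, statistics) — not segmentation accuracy on real micrographs,
which requires real annotated images.

## Problem sizes

The validation suite and the reproduction script run, as this package's
own scale choices: heuristic recovery on 10 phantoms of 1024² px with 20
ensheathing cells each; network experiments on ≥200 training and ~50
validation crops of 128² px, up to 400 steps, with the weighted/
unweighted comparison repeated over 3 seeds (runs stop early once the
pooled validation JI clears 0.45); sample-moment checks on a 500-cell
4096² phantom; group-effect recovery on 2 × 3 wells of 1024² px with 30
cells, comparing a mean of 5 vs 6 sheaths per cell with the ridge
sensitivity at 0.10. Full-scale training (hundreds of thousands of
steps on ~40,000 crops of 256²) is out of scope on a CPU and is not
attempted.

## Known limitations

* The heuristic's continuity gap (2 µm) and its transitive closure are
  interpretations; the original continuity rule is qualitative.
* The quantile-based ridge sensitivity couples the segmented area to the
  image's sheath content; per-experiment adjustment is expected.
* The numpy network trains at small scales only; no GPU path.
* ImageJ ROI support covers polygon ROIs (the tracing tool's output),
  not the full ROI zoo.
* Chained internodes separated by small gaps can merge into one detected
  sheath (and a sheath crossing a cell body can split), so per-cell
  counts carry a method-dependent bias at high sheath density.
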