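# myelinquant

High-throughput quantification of oligodendrocyte ensheathment in
nanofiber cultures.

Oligodendrocytes — the myelinating glia of the central nervous system —
are commonly screened on electrospun parallel nanofibers that mimic
axons: a differentiating cell wraps fibers in elongated membrane sheaths
("ensheathments"), visualized with Hoechst (nuclei) and O4/MBP
(membrane/myelin) staining. Scoring these cultures by hand takes days
per plate and varies between raters. `myelinquant` automates the
analysis of whole-well images (TIFF, ~0.5 µm/pixel) with two engines and
a shared measurement layer:

* a **heuristic engine**: CLAHE enhancement, a Hessian-eigenvalue ridge
  filter for the bright elongated sheaths, watershed cell-body
  estimation validated by nucleus colocalization, cell-body subtraction,
  and continuity-based assignment of each sheath to at most one cell;
* a **masked-nucleus UNet**: per candidate nucleus, a 3-channel crop
  whose middle channel is that nucleus's binary mask prompts the network
  to segment only that cell's sheaths (5×5 kernels, stride 2, filters
  10→50→10 with skip concatenations, softmax head, threshold 0.5),
  trained with per-pixel cross-entropy under class weighting (×10 on
  sheath pixels) and spatial weighting w = exp(1 − D/f + b) with D the
  Chebyshev distance to the nearest sheath pixel;
* **post-processing**: unfair distribution of ambiguously shared
  sheaths to the larger claimant cell, skeleton-based removal of
  cross-fiber "sticky" bridges, and a 12 µm length floor that is three
  times stricter for cells with only one or two sheaths;
* **morphometrics**: sheaths per cell, mean sheath length per cell
  (mSLC), pooled log₁₀ length distributions, per-cell and global Jaccard
  evaluation against references, group comparisons, and the 1/√n
  minimum-detectable-difference scaling for planning sample sizes.

Everything is testable end-to-end without any imaging data through a
**phantom generator** that renders synthetic nanofiber wells with exact
per-cell ground truth (parallel fibers, somata with nuclei, log-normally
distributed sheath bars, engineered overlaps for the crowding operators).

The network is implemented in pure numpy (im2col convolutions,
transposed convolutions as exact conv adjoints, hand-derived
backpropagation verified against finite differences, Adam) and trains at
reduced scale on a CPU.

See `docs/methods.md` for the model details, parameter defaults and
their rationale, and known limitations.

## Worked example

```python
import myelinquant as mq

# a synthetic well: 20 cells, all ensheathing, low noise
spec = mq.PhantomSpec(height_px=1024, width_px=1024, n_cells=20,
                      p_ensheathing=1.0, noise_sd=0.01, seed=0)
image, truth = mq.generate_phantom(spec)

cells = mq.run_heuristic(image)          # heuristic engine, defaults

import myelinquant.benchmarks as bench
report = mq.per_cell_ji(bench.truth_cell_segmentations(truth), cells,
                        pairing_radius_um=10.0, pixel_size_um=0.5)
print(f"detected {report.n_paired}/{report.n_ref} cells, "
      f"median per-cell JI {report.median_ji:.2f}, "
      f"global JI {report.global_ji:.2f}")

print(f"minimum detectable log-length difference at n=300: "
      f"{mq.min_detectable_difference(300, 13000, 0.01):.4f}")
```

prints

```
detected 19/20 cells, median per-cell JI 0.90, global JI 0.89
minimum detectable log-length difference at n=300: 0.0658
```

i.e. on this phantom the heuristic engine finds 19 of the 20 ensheathing
cells, its per-cell sheath masks overlap the ground truth with a median
Jaccard index of 0.90, and a study sampling only 300 sheaths can resolve
group differences no finer than ~0.07 log units (which is why whole-well
screens that collect ~13,000 sheaths can detect 0.01-log effects).

The command line mirrors the library:

```bash
myelinquant phantom --out-dir well0 --seed 0 --n-cells 20 --p-ensheathing 1.0
myelinquant heuristic --image well0/image.tif --channels nuclei=0,membrane=1 --out-dir seg0
myelinquant metrics mdd --n 300 --n-ref 13000 --delta-ref 0.01
```

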