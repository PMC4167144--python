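# ifishquant

Quantification of single-cell genomic and phenotypic heterogeneity from
combined immunofluorescence + FISH (IFISH) tissue images.

Tumour tissue sections stained with a nuclear counterstain (DAPI),
protein markers (e.g. nuclear ER, membrane HER2) and FISH probes (e.g.
the *HER2* locus and a centromere-17 reference) carry both phenotype and
copy-number information for every cell — but only if nuclei, membranes
and spots can be segmented reliably in densely packed, autofluorescent
tissue. `ifishquant` is a scriptable library and batch CLI for exactly
that: it segments all three compartments, measures background-corrected
per-cell intensities and copy numbers, classifies cells, renders spatial
topology maps, and scores segmentations against a gold standard.

## The method

**Nuclear segmentation** is an iterative H-minima watershed. The inverted
DAPI image is flooded inside a foreground mask (Otsu threshold on the sum
of normalised local entropy and intensity) after suppressing regional
minima shallower than a depth *h*. The depth steps down a ladder from 30%
to 10% of the dynamic range; after each sweep a linear discriminant
classifies every fragment from 10 shape features (solidity, area,
perimeter, axis lengths, axis ratio, circularity, area–perimeter ratio,
deviations from the expected nucleus area and perimeter) as *optimal*,
*undersegmented* or *oversegmented*. Optimal fragments are frozen;
the remainder is re-segmented at a shallower depth, which splits merged
clumps. Residual oversegmentation is repaired combinatorially: an
oversegmented fragment *f* with neighbours **g** within radius *r* is
scored against every union *c* = *f* ∪ (subset of **g**) by

    S(c) = Σ_F [ F(c) − (1/n) Σ_i F(c_i) ],   F ∈ {solidity, −|area dev|}

and the best strictly positive union replaces its parts (*c\** = *f* when
no positive score exists).

**Membrane territories** combine a Voronoi partition of the nuclei
(geodesic distance to the nucleus *region*) with a nucleus-seeded
watershed over the membrane channel in which pixels above the 95th
intensity percentile act as barriers — boundaries lock onto bright HER2
rings where present and fall back to Voronoi geometry where staining is
weak or incomplete. Optional Chan-Vese / geodesic active-contour
refinement is available.

**FISH spots** are Laplacian-of-Gaussian blob candidates confirmed by
sharp gradient maxima, filtered by size (default minimum 15 px at 60x)
and intensity, with an optional LDA shape classifier for low-contrast
probes. Copy number per cell is `round(total spot area / 20 px)`,
saturating at the amplified code **22** when the area reaches the ~400 px
countability plateau (one above the highest countable value of 21).

**Per-cell records** link the three compartments and carry raw, globally
background-subtracted and per-nucleus *ring*-adjusted intensities (mean
over an annulus 2–6 px outside each nucleus, absorbing local
autofluorescence), morphology, membrane coefficient of variation
(a completeness proxy), spot area and copy number. Cells are typed by a
one-vs-all linear SVM trained on a user-labelled subset; global
thresholds (e.g. ER ≥ 50 ring-adjusted, HER2 ≥ 300 background-adjusted)
produce marker-positivity classes, and topology maps render the relative
ratio a/(a+b) of two stains in tissue context.

**Evaluation** against a manually segmented gold standard uses
object-level counts — Nt correct, Nunder / Nover under- and
over-segmented, NFP / NFN spurious and missed — with

    P = Nt/(Nt+NFP+Nover),  R = Nt/(Nt+NFN+Nunder),  F = 2PR/(P+R)

plus a perimeter–area-ratio quotient per matched object as a shape
fidelity measure (1 = morphology faithfully reproduced).

A synthetic-scene generator (`ifishquant.synth`) renders packed
elliptical nuclei with controlled touching, complete or broken membrane
rings, isolated and clustered FISH spots, spatially varying background
and Poisson–Gaussian noise, with exported pixel-level ground truth — so
every stage is testable without patient data.

## Worked example

```python
import numpy as np
from ifishquant import (synth, nuclear_seg, membrane_seg, spot_detect,
                        cell_features, io_background, evaluation)

spec = synth.SceneSpec(n_cells=30, height=500, width=500, seed=1,
                       touching_fraction=0.2, spots_per_cell=4)
stack, nuclei_truth, cells_truth, spots_truth, records_truth = \
    synth.generate_scene(spec)

params = nuclear_seg.SegParams.for_magnification(40)
nuclei = nuclear_seg.iterative_segment(stack.dapi, params)
report = evaluation.evaluate(nuclei, nuclei_truth)
print(f"nuclei: {nuclei.max()} detected / {nuclei_truth.max()} planted, "
      f"F = {report['f_score']:.3f}")

membranes = membrane_seg.membrane_segment(stack.channel("HER2"), nuclei)
spots = spot_detect.detect_spots(stack.channel("HER2-FISH"), nuclei)
records = cell_features.map_segments(nuclei, membranes, spots,
                                     spot_channel="HER2-FISH")
er = stack.channel("ER")
bg = io_background.ring_background(er, nuclei)
backgrounds = {"ER": io_background.BackgroundEstimate(
    global_mean=io_background.global_background(er, nuclei == 0),
    per_label=bg.per_label)}
records = cell_features.measure_cells(records, stack, backgrounds,
                                      nuclei=nuclei, membranes=membranes)
copies = [r.copies["HER2-FISH"] for r in records]
print(f"copy number: median {int(np.median(copies))}, "
      f"{sum(c == 4 for c in copies)}/{len(copies)} cells at the planted 4")
first = records[0]
print(f"cell 1: area {first.area:.0f} px, ER raw {first.raw['ER']:.3f}, "
      f"ring-adjusted {first.ring_adj['ER']:.3f}")
```

prints

```
nuclei: 30 detected / 30 planted, F = 1.000
copy number: median 4, 30/30 cells at the planted 4
cell 1: area 1980 px, ER raw 0.549, ring-adjusted 0.450
```

All 30 planted nuclei are recovered (object F-score 1.0), every cell's
planted 4 FISH signals are counted back from detected spot area, and the
ring adjustment strips the planted 0.10 background from the raw ER
intensity, leaving the planted 0.45 nuclear signal.

## Command line

```
ifish-quant run --params params.yaml          # batch pipeline -> bundles
ifish-quant segment-nuclei --image x.tiff --stains DAPI,membrane,spot --out n.tiff
ifish-quant segment-membranes --image x.tiff --stains ... --channel membrane --nuclei n.tiff --out m.tiff
ifish-quant detect-spots --image x.tiff --stains ... --channel spot --nuclei n.tiff --out spots.csv
ifish-quant evaluate --pred n.tiff --gold g.tiff --report report.csv
ifish-quant synth --spec scene.yaml --out scene_dir/
```

`run` consumes a YAML parameter file (input glob, per-channel stains,
magnification, segmentation/spot parameters, threshold rules) and writes
one resumable bundle per image: `nuclei.tiff`, `membranes.tiff`,
`spots.csv`, `cells.csv` and a `manifest.json` recording every parameter
used. Images beyond a pixel budget are processed as overlapping tiles
and stitched with larger-area precedence.

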