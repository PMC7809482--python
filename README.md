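# plateqc

Quantitative quality control for automated cell-culture and
high-throughput/high-content screening (HTS/HCS) platforms that maintain
patient-derived fibroblasts, iPSC, neural progenitors (smNPC), their
dopaminergic-neuron differentiations and midbrain organoids in 6-well,
1-well and 96/384-well formats.

`plateqc` covers the four quantitative layers such a platform runs after
every seeding, split or differentiation, plus a synthetic-scene generator
so every stage is testable against exact ground truth without any
microscope attached.

## What it computes

**Label-free confluency and seeding homogeneity.** A transmitted-light
field shows cells as *texture* on a flat substrate. Per-field coverage is
the fraction of pixels whose local intensity standard deviation (15 px
window) exceeds an automatic threshold of the local-sd map (Otsu split
when the map is bimodal, a robust-MAD rule otherwise), followed by a 3×3
closing and small-object removal. With 38 fields per 6-well well (384 per
1-well plate), the well confluency is

&nbsp;&nbsp;confluency = 100 · mean(per-field coverage),&nbsp;&nbsp;
CV = 100 · sd(per-field coverage) / mean,

the CV scoring how evenly the cells were dispensed. Serial-dilution reads
are checked for consistency by fitting the saturating curve
*y* = *y*<sub>max</sub>(1 − e<sup>−*kx*</sup>) and reporting R².

**Neuronal immunofluorescence segmentation.** The fixed-parameter chain
used to score dopaminergic differentiations in assay plates:

1. nuclei: DoG band-pass (Gaussian windows 10 px/σ2 − 60 px/σ20,
   mirror padding), threshold > 50; touching nuclei split by
   `watershed(imhmin(−bwdist(mask), 1))` with 8-connectivity;
2. one cell ROI per nucleus: the nuclei mask dilated by an exact Euclidean
   disk of radius 10 px, cut along the same watershed ridges;
3. marker masks (TH and Tuj1): fine DoG (11/1 − 11/3) > {3, 2} OR coarse
   DoG (99/3 − 99/11) > {10, 3} OR 3×3-median > {50, 20};
4. a cell is a neuron iff its ROI touches `NeuroMask = THMask | Tuj1Mask`;
   a neuron is TH⁺ iff the ROI mean of the TH channel, after subtracting
   the mean TH intensity outside nuclei, exceeds 20 (all comparisons
   strict).

**Organoid morphometrics.** One organoid per well of an ultra-low-
attachment 96-well plate, imaged in brightfield: Otsu segmentation of the
inverted image (largest component, holes filled), then area
(pixel count · pixel_size²) and Feret's diameter (maximum caliper
distance, convex hull + rotating calipers, equal to the brute-force
pairwise maximum). Per-line batch statistics report mean and sample CV of
both parameters — the size-homogeneity score that decides whether a batch
is screenable.

**Rank statistics and capacity planning.** Mann–Whitney U (exact by
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise), Kruskal–Wallis with tie correction,
Dunn's post-hoc z tests (Bonferroni-adjusted), and the expansion
arithmetic: `floor(plates × yield / (wells × cells_per_well))` assay
plates from a production run, and cells/well from a suspension
concentration and dispense volume.

## Worked example

```bash
# a 38-field 6-well well scan at ~45% confluency with a 20% seeding gradient
plateqc simulate well --plate-format six_well --mean-coverage 0.45 \
    --gradient 0.2 --seed 11 --out-dir wellA1
plateqc confluency --images wellA1 --well-id A1 --out wellA1_qc.csv
```

    A1: confluency 48.9% CV 10.64% over 38 fields

The well mean (48.9%) recovers the generated mean coverage; the 10.6% CV
reflects the injected spatial gradient — a perfectly homogeneous well
scores ~1%.

```bash
# a stained culture: 40 cells, all neurons, 25% dopaminergic
plateqc simulate neuro --n-cells 40 --th-fraction 0.25 --seed 5 --out scene.tif
plateqc neuro --image scene.tif --out cells.csv
```

    {"n_nuclei": 40, "n_neurons": 40, "n_th_positive": 10,
     "neuron_fraction": 1.0, "th_fraction_of_neurons": 0.25}

All 40 nuclei are found, every ROI touches the pan-neuronal mask, and 10
of 40 neurons are called TH⁺ — exactly the generated 25% dopaminergic
fraction.

```bash
plateqc capacity --plates 10 --yield 1.18e7
```

    15 assay plates (384 wells x 20000 cells) from 10 source plates at 1.18e+07 cells/plate

Ten confluent 1-well plates at the mean iPSC yield of 1.18×10⁷ cells
seed 15 full 384-well assay plates at 20,000 cells/well.

The same operations are available as library functions
(`plateqc.detect_coverage`, `plateqc.segment_scene`,
`plateqc.measure_organoid`, `plateqc.kruskal_wallis`, …); see the module
docstrings and `docs/methods.md`.

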