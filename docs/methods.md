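# Methods

This note records the models, conventions and design choices behind
`plateqc`, what the synthetic scenes do and do not emulate, and the known
limitations.

## Label-free coverage detection

The detector assumes cells are visible in transmitted light as local
intensity *texture* while cell-free substrate is flat. The statistic is
the windowed standard deviation (default 15 px, mirror padding, computed
from the first two moments). Thresholding this local-sd map must be
automatic and invariant to adding a constant to all intensities and to
positive rescaling; both requirements are met because every quantity
below is computed from the map itself.

Two regimes are distinguished:

* **Bimodal map** (a genuine mixture of textured and flat regions): the
  Otsu split of the map is used, accepted only when the resulting
  foreground class mean exceeds `k_sd` (default 3) times the background
  class mean — i.e. when the split reflects real texture contrast rather
  than noise quantiles.
* **Unimodal map** (all-flat or all-textured field): the threshold falls
  back to `k_sd × 1.4826 × MAD(map)`. On a constant field the map is
  identically zero and nothing exceeds the (strict) threshold; on a fully
  textured field the MAD measures only sampling spread of the sd
  estimator, the threshold sits far below the texture level, and
  essentially every pixel is foreground.

A pure MAD rule cannot work in the mixed regime when the background has
any noise at all: the MAD of the map then reflects the *spread* of
background sd estimates (a few percent of the background sd for a 15 px
window), so a threshold proportional to it lies far below the background
texture level and everything is detected. The Otsu refinement exists for
exactly that case. The price of scale invariance is that an entirely
cell-free but noisy field is indistinguishable from an entirely covered
one (both are uniform texture at some amplitude); such fields are read as
covered. Plate-level QC is unaffected because wells at the coverages of
interest (≳5%) always present both classes.

The binary map is closed with a 3×3 structuring element and components
smaller than `min_object_px` (default 25 px) are removed. Detection
extends a few pixels beyond true cell boundaries (the window straddles
the edge), a positive bias of 1–2 percentage points at 512×512 with the
default blob geometry; the recovery tests budget ±5 points.

Well summaries use the sample (n−1) standard deviation for the CV, the
convention of the Prism-style analyses the measurements feed. A
zero-mean well flags its CV as undefined (NaN) rather than raising.

## Dilution model

Confluency versus seeded amount is fitted with
`y = ymax (1 − exp(−k x))`, a monotone, bounded two-parameter model that
reproduces the near-saturation shape of real dilution reads and is
approximately linear at small `k·x`. The fit is bounded
(`ymax ∈ (0, 120]`, `k > 0`) trust-region least squares with a
deterministic initializer (`ymax₀ = max(y)`, `k₀` from inverting the
model at the first point), so refitting the same table is bit-stable.
R² = 1 − SS_res/SS_tot, flagged NaN when all reads are equal. Generated
series use `ymax = 95`, `k = 0.3` over levels 1–32 (arbitrary dilution
units) with Gaussian noise of 2 confluency points by default — a range
and noise level at which R² > 0.96 in essentially every realization.

## Segmentation chain conventions

The chain is a faithful re-expression of a fixed-parameter MATLAB
pipeline; the conventions below matter for bit-level reproducibility:

* **Kernels.** `fspecial`-style truncated Gaussians on square windows,
  normalized to sum exactly 1, sampled on a grid centered at
  `(size−1)/2`. The even window sizes (10, 60) are kept as given: the
  anchor sits at index `size // 2`, half a pixel off the sampling center;
  both DoG terms share the convention, so the half-pixel bias cancels in
  the difference. Filtering is correlation with mirror ("symmetric")
  padding, applied separably (exact for an outer-product kernel).
* **Splitting.** Euclidean distance transform of the nuclei mask, negated
  (on a float map the classical complement `1 − d` differs from `−d` by a
  constant, to which h-minima and watershed are invariant), h-minima
  suppression of depth 1 by grayscale reconstruction (3×3 connectivity),
  watershed with 8-connectivity. Label maps are 8-connected components
  with ridge pixels removed.
* **ROIs.** Dilation by the exact Euclidean disk
  `{(dx,dy): dx²+dy² ≤ 100}` (not a decomposed approximation), ridges
  removed, components labelled; a component inherits the label of the
  nucleus it contains and componentless regions are discarded. Ridges
  make a two-nucleus ROI impossible by construction; the code asserts
  this rather than silently merging.
* **Median clause.** 3×3 median with zero padding (the source default).
  Consequence: on a uniformly bright field the four corner windows hold
  five padded zeros, so the corners fall below the global threshold — the
  clause covers the field *except* those four pixels.
* **Classification.** "ROI outside a neuron" is read literally as zero
  overlap with `THMask | Tuj1Mask`; any overlapping pixel keeps the cell
  (a minimum-overlap fraction is available as a config knob). The TH⁺
  statistic is the ROI **mean** of the background-subtracted TH channel
  (the least outlier-sensitive literal choice; `max` and `median` are
  config options). All thresholds are strict `>` comparisons. If nuclei
  cover the whole image the TH background is undefined; the code falls
  back to 0 with a logged warning.

Every stage is verified bit-for-bit against an independent straight-line
re-execution of the chain (`tests/_literal_chain.py`) that builds full
2-D kernels and filters via FFT correlation — a different numerical route
to the same operations.

## Organoid measurements

Segmentation (inverted-intensity Otsu, largest 8-connected component,
hole filling, 500 px minimum) is a surrogate for an unpublished
extraction step; it is validated by recovery against generated truth
masks, not against absolute published sizes. A candidate component must
also be darker than the remaining background by more than twice the
background standard deviation, which rejects the percolating noise
component an object-free frame would otherwise yield.

Feret's diameter uses the pixel-center convention: the maximum Euclidean
distance between centers of boundary pixels, so a single-pixel object has
Feret 0 (the pixel-edge convention, ≈1 px larger, is available as an
option since the original measurement tool is unstated). The rotating-
calipers implementation over the convex hull is property-tested to equal
the brute-force pairwise maximum on every mask tried. Areas are pixel
counts times `pixel_size²`; pixel size is a required input because the
source acquisitions state only scale bars.

## Rank statistics

Mann–Whitney returns `U = min(U_a, U_b)` with midranks. For tie-free
samples with `n_a + n_b ≤ 12` the two-sided p is exact:
`P(min(U_a, U_b) ≤ U_obs)` by full enumeration of all
`C(n_a+n_b, n_a)` label assignments (the panel sizes the statistic is
used at are 3–12, where exactness matters; the switch point is
configurable). Otherwise the normal approximation with tie-corrected
variance and continuity correction `+0.5` is used, capped at 1 — so
identical groups report exactly p = 1. Kruskal–Wallis uses the rank-sum
formula with the `1 − Σ(t³−t)/(N³−N)` tie correction and the chi-square
approximation; all-identical data returns H = 0, p = 1 by convention.
Dunn's z uses the pooled-variance form with the `Σ(t³−t)/(12(N−1))` tie
term; the default adjustment is Bonferroni over all k(k−1)/2 pairs
(conservative and reproducible; raw p values are always reported
alongside). scipy's implementations serve as independent cross-checks in
the test suite, never as the implementation.

Capacity planning floors the plate count (a partial assay plate is
unusable). At the published fibroblast yield (1.67×10⁷ cells/plate) the
arithmetic gives 21 plates, not the 19 quoted alongside it — possibly a
dead-volume allowance; the discrepancy is surfaced, not reconciled.
Cells-per-well rounds half up.

## Synthetic scenes

The generators are pure functions of (parameters, seed) — one explicitly
seeded RNG per call, no global state — and every derived truth quantity
is recomputed from the emitted mask itself (coverage by pixel counting,
Feret by brute-force pairwise distances), so independent re-derivation
matches exactly.

* **Adherent fields**: elliptical blobs carrying zero-mean speckle with
  sd 8× the background noise sd (the contrast regime the variance
  detector assumes; anything ≥5× works), boundary-trimmed/grown to hit
  the requested coverage to the pixel. Not emulated: illumination
  gradients within a field, debris, cell-to-cell contrast variation.
* **Well scans**: a seed-chosen linear coverage ramp across field
  positions with relative amplitude `gradient_strength`, clipped to
  [0,1]. The default 38-field layout is a centered (disk-like) packing on
  a 7×7 grid and the 384-field layout a 16×24 grid; true acquisition
  geometries can be supplied via config since only field *counts* are
  published.
* **Neuro scenes**: nuclei as Gaussian blobs (σ 4 px, peak ≥150 over a
  background ≤10 — comfortably above the DoG>50 operating point), somatic
  disks plus curvilinear Bezier strokes in the pan-neuronal and TH
  channels, channel order TH/nuclei/Tuj1 as acquired (561/405/488 nm).
  Neuron and TH⁺ counts are realized by nearest-integer rounding (ties
  up), so truth fractions are exact. Default center spacing is ≥14 px
  (the hard floor is 8), at which nuclei masks rarely merge — watershed
  splitting is exercised by dedicated touching-blob tests instead.
  Not emulated: overlapping nuclei, out-of-focus light, marker bleed-
  through, intensity-graded marker expression; at neuron fractions < 1 a
  stroke passing a non-neuron's ROI can misclassify it, so recovery
  claims are made for the all-neuron scenes the validation panels show.
* **Organoids**: disk/ellipse/smooth-blob dark objects (≤40% of
  background intensity) with mild shading and noise, one per frame.
* **Scales.** Tests and the acceptance script run scenes at 128–512 px
  and 20–200 replicates — sizes at which every recovery property is
  stable while the whole suite stays fast.

Passing on these scenes demonstrates that the *computation* is correct
and recoverable under the stated contrast assumptions; it does not
calibrate biological accuracy on real acquisitions, which were not
published.
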