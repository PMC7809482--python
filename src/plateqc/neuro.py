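"""Immunofluorescence segmentation for dopaminergic-neuron cultures.

Implements the fixed-parameter pipeline used to quantify midbrain neuron
differentiations in high-content assay plates:

1. nuclei: difference-of-Gaussians band-pass (10 px/sigma 2 minus
   60 px/sigma 20 windows), threshold > 50, then splitting of touching
   nuclei by a watershed of the negated Euclidean distance transform with
   h-minima suppression of depth 1;
2. single-cell ROIs: the nuclei mask dilated by an exact Euclidean disk of
   radius 10 px, cut along the same watershed ridges, one ROI per nucleus;
3. marker masks (TH, Tuj1): OR of a fine DoG (11/1 minus 11/3), a coarse DoG
   (99/3 minus 99/11) and a global threshold on the 3x3 median-filtered
   channel;
4. classification: a cell is a neuron when its ROI touches the neuronal mask
   (TH OR Tuj1); a neuron is TH-positive when the ROI mean of the
   background-subtracted TH channel exceeds 20, background being the mean TH
   intensity outside nuclei.

All thresholds are strict (">") comparisons.  Kernels use the source
convention of truncated windows normalized to unit sum; the even window
sizes (10, 60) place the sampling grid half a pixel off center, which
cancels between the two DoG terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

logger = logging.getLogger("plateqc")


# ---------------------------------------------------------------------------
# kernels and filtering


@dataclass(frozen=True)
class GaussianKernelSpec:
    """A truncated Gaussian on a square window, normalized to sum 1.

    The window may have even edge length; samples are taken on a grid
    centered at ``(size-1)/2`` so even windows are symmetric about a
    half-integer position.
    """

    size: int
    sigma: float

    def kernel1d(self) -> np.ndarray:
        ax = np.arange(self.size, dtype=float) - (self.size - 1) / 2.0
        g = np.exp(-(ax ** 2) / (2.0 * self.sigma ** 2))
        return g / g.sum()

    def kernel2d(self) -> np.ndarray:
        g = self.kernel1d()
        return np.outer(g, g)


def gaussian_filter_trunc(image: np.ndarray, spec: GaussianKernelSpec) -> np.ndarray:
    """Correlate with the truncated normalized Gaussian, mirror padding.

    Separable: applied as two 1-D passes, which is exact for the outer-
    product kernel.  For even window sizes the anchor sits at index
    ``size // 2``.
    """
    g = spec.kernel1d()
    out = ndi.correlate1d(np.asarray(image, float), g, axis=0, mode="reflect")
    return ndi.correlate1d(out, g, axis=1, mode="reflect")


def dog_filter(image: np.ndarray, fine: GaussianKernelSpec | tuple,
               coarse: GaussianKernelSpec | tuple) -> np.ndarray:
    """Difference of Gaussians: fine-blurred minus coarse-blurred image.

    Both kernels sum to one, so constant images map to zero; the output is
    signed.
    """
    fine = GaussianKernelSpec(*fine) if not isinstance(fine, GaussianKernelSpec) else fine
    coarse = GaussianKernelSpec(*coarse) if not isinstance(coarse, GaussianKernelSpec) else coarse
    if not fine.sigma < coarse.sigma:
        raise ValueError(
            f"fine sigma ({fine.sigma}) must be smaller than coarse sigma ({coarse.sigma})"
        )
    return gaussian_filter_trunc(image, fine) - gaussian_filter_trunc(image, coarse)


@dataclass(frozen=True)
class PipelineThresholds:
    """All fixed parameters of the segmentation chain (strict comparisons)."""

    nuc_dog: float = 50.0
    th_fine: float = 3.0
    th_big: float = 10.0
    tuj1_fine: float = 2.0
    tuj1_big: float = 3.0
    th_median_global: float = 50.0
    tuj1_median_global: float = 20.0
    th_positive: float = 20.0
    hmin_depth: float = 1.0
    roi_dilation_radius: int = 10
    #: minimum ROI/neuro-mask overlap fraction to call a neuron; 0 means
    #: any single overlapping pixel counts (the literal boolean-AND reading)
    min_neuron_overlap: float = 0.0
    #: per-ROI statistic compared against ``th_positive``
    th_statistic: str = "mean"

    nuc_fine: tuple[int, float] = (10, 2.0)
    nuc_coarse: tuple[int, float] = (60, 20.0)
    marker_fine_pair: tuple[tuple[int, float], tuple[int, float]] = ((11, 1.0), (11, 3.0))
    marker_big_pair: tuple[tuple[int, float], tuple[int, float]] = ((99, 3.0), (99, 11.0))


DEFAULT_THRESHOLDS = PipelineThresholds()


# ---------------------------------------------------------------------------
# nuclei segmentation and splitting


def _h_minima_suppress(image: np.ndarray, depth: float) -> np.ndarray:
    """Suppress regional minima shallower than ``depth``.

    Implemented by grayscale reconstruction (by dilation) of the negated
    image: equivalent to the classical fill of minima to depth ``h``.
    """
    neg = -np.asarray(image, float)
    rec = reconstruction(neg - depth, neg, method="dilation",
                         footprint=np.ones((3, 3), bool))
    return -rec


def split_stencil(mask: np.ndarray, hmin_depth: float = 1.0) -> np.ndarray:
    """Watershed ridge mask that separates touching objects in ``mask``.

    The landscape is the negated Euclidean distance transform of the mask;
    minima shallower than ``hmin_depth`` are suppressed so shape noise on
    the distance map does not over-segment.  Watershed uses 8-connectivity;
    returned True pixels are ridge (boundary) pixels.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    dist = ndi.distance_transform_edt(mask)
    landscape = _h_minima_suppress(-dist, hmin_depth)
    labels = watershed(landscape, connectivity=2, watershed_line=True)
    return labels == 0


def segment_nuclei(nuc_channel: np.ndarray,
                   thresholds: PipelineThresholds = DEFAULT_THRESHOLDS
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Segment nuclei: DoG band-pass, threshold, watershed splitting.

    Returns ``(nuc_mask, nuc_labels)``; labels are 8-connected components
    of the mask with watershed ridge pixels removed, so touching nuclei
    receive distinct labels.
    """
    nuc = np.asarray(nuc_channel, float)
    if nuc.ndim != 2:
        raise ValueError("nuclei channel must be single-channel (2-D)")
    dog = dog_filter(nuc, thresholds.nuc_fine, thresholds.nuc_coarse)
    nuc_mask = dog > thresholds.nuc_dog
    ridges = split_stencil(nuc_mask, thresholds.hmin_depth)
    labels, n = ndi.label(nuc_mask & ~ridges, structure=np.ones((3, 3), int))
    logger.debug("segment_nuclei: %d nuclei", n)
    return nuc_mask, labels


def euclidean_disk(radius: int) -> np.ndarray:
    """Exact Euclidean disk footprint: offsets with dx^2 + dy^2 <= r^2."""
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy = np.meshgrid(ax, ax, indexing="ij")
    return (dx * dx + dy * dy) <= r * r


def build_cell_rois(nuc_mask: np.ndarray, nuc_labels: np.ndarray,
                    thresholds: PipelineThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Single-cell ROIs: disk-dilated nuclei mask cut along watershed ridges.

    Each connected region of the dilated mask (ridges removed) that contains
    a nucleus becomes that nucleus' ROI and inherits its label; regions
    without a nucleus are discarded.  Ridges guarantee each region holds at
    most one nucleus label; this is asserted.
    """
    nuc_mask = np.asarray(nuc_mask, bool)
    dilated = ndi.binary_dilation(nuc_mask, structure=euclidean_disk(thresholds.roi_dilation_radius))
    ridges = split_stencil(nuc_mask, thresholds.hmin_depth)
    regions, _ = ndi.label(dilated & ~ridges, structure=np.ones((3, 3), int))

    roi_labels = np.zeros_like(nuc_labels)
    inside = nuc_labels > 0
    region_of = regions[inside]
    nucleus_of = nuc_labels[inside]
    # map region id -> nucleus label; a nucleus may lose its ridge pixels but
    # keeps >= 1 interior pixel inside its region
    mapping: dict[int, int] = {}
    for reg, lab in zip(region_of.tolist(), nucleus_of.tolist()):
        if reg == 0:
            continue
        prev = mapping.setdefault(reg, lab)
        if prev != lab:
            raise AssertionError(
                f"ROI region {reg} contains two nucleus labels ({prev}, {lab}); "
                "watershed ridges failed to separate them"
            )
    if mapping:
        lut = np.zeros(regions.max() + 1, dtype=nuc_labels.dtype)
        for reg, lab in mapping.items():
            lut[reg] = lab
        roi_labels = lut[regions]
    return roi_labels


# ---------------------------------------------------------------------------
# marker masks and classification


def median3x3(channel: np.ndarray) -> np.ndarray:
    """3x3 median filter with zero padding at the borders."""
    return ndi.median_filter(np.asarray(channel, float), size=3, mode="constant", cval=0.0)


def segment_marker_mask(channel: np.ndarray,
                        fine_pair: tuple[tuple[int, float], tuple[int, float]],
                        big_pair: tuple[tuple[int, float], tuple[int, float]],
                        local_fine_thr: float, local_big_thr: float,
                        global_thr: float) -> np.ndarray:
    """Marker (TH / Tuj1) mask: fine DoG OR coarse DoG OR global clause.

    The fine DoG picks up neurites, the coarse DoG somata and thick
    processes, and the 3x3-median global threshold bright contiguous
    staining the band-passes flatten out.
    """
    ch = np.asarray(channel, float)
    mask_fine = dog_filter(ch, *fine_pair) > local_fine_thr
    mask_big = dog_filter(ch, *big_pair) > local_big_thr
    mask_global = median3x3(ch) > global_thr
    return mask_fine | mask_big | mask_global


@dataclass
class SegmentationResult:
    """Full output of the single-scene segmentation and classification."""

    nuc_mask: np.ndarray
    nuc_labels: np.ndarray
    roi_labels: np.ndarray
    th_mask: np.ndarray
    tuj1_mask: np.ndarray
    neuro_mask: np.ndarray
    n_nuclei: int
    n_neurons: int
    n_th_positive: int
    neuron_fraction: float  # NaN when n_nuclei == 0
    th_fraction_of_neurons: float  # NaN when n_neurons == 0
    cells: pd.DataFrame = dc_field(repr=False, default_factory=pd.DataFrame)

    def summary(self) -> dict:
        return {
            "n_nuclei": self.n_nuclei,
            "n_neurons": self.n_neurons,
            "n_th_positive": self.n_th_positive,
            "neuron_fraction": self.neuron_fraction,
            "th_fraction_of_neurons": self.th_fraction_of_neurons,
        }


def classify_cells(roi_labels: np.ndarray, nuc_mask: np.ndarray,
                   th_channel: np.ndarray, tuj1_mask: np.ndarray, th_mask: np.ndarray,
                   thresholds: PipelineThresholds = DEFAULT_THRESHOLDS,
                   nuc_labels: np.ndarray | None = None) -> SegmentationResult:
    """Classify each ROI as neuron / TH-positive and summarize fractions.

    A cell is a neuron when its ROI overlaps the neuronal mask
    ``th_mask | tuj1_mask`` (at least one pixel, or a configurable minimum
    fraction).  TH background is the mean TH intensity outside nuclei; a
    neuron is TH-positive when the chosen per-ROI statistic of the
    background-subtracted TH channel is strictly greater than the TH
    threshold (default mean > 20).
    """
    roi_labels = np.asarray(roi_labels)
    th_channel = np.asarray(th_channel, float)
    nuc_mask = np.asarray(nuc_mask, bool)
    shapes = {roi_labels.shape, th_channel.shape, np.asarray(tuj1_mask).shape,
              np.asarray(th_mask).shape, nuc_mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"all grids must share one shape, got {shapes}")
    neuro_mask = np.asarray(th_mask, bool) | np.asarray(tuj1_mask, bool)

    if nuc_labels is None:
        nuc_labels = roi_labels * nuc_mask
    labels = np.unique(nuc_labels)
    labels = labels[labels > 0]
    n_nuclei = int(labels.size)

    outside = ~nuc_mask
    if outside.any():
        background = float(th_channel[outside].mean())
    else:
        background = 0.0
        logger.warning("TH background undefined (nuclei cover the image); using 0")
    th_bgsub = th_channel - background

    nmax = int(max(roi_labels.max(), nuc_labels.max(), 1))
    roi_area = np.bincount(roi_labels.ravel(), minlength=nmax + 1)
    overlap = np.bincount(roi_labels.ravel(), weights=neuro_mask.ravel(),
                          minlength=nmax + 1)

    rows = []
    stat = thresholds.th_statistic
    for lab in labels.tolist():
        area = int(roi_area[lab])
        if area == 0:
            # nucleus whose ROI vanished (fully on ridge pixels); keep as
            # non-neuron with empty ROI
            is_neuron, th_stat = False, float("nan")
        else:
            frac = overlap[lab] / area
            is_neuron = (overlap[lab] >= 1) if thresholds.min_neuron_overlap <= 0 \
                else (frac >= thresholds.min_neuron_overlap)
            vals = th_bgsub[roi_labels == lab]
            if stat == "mean":
                th_stat = float(vals.mean())
            elif stat == "max":
                th_stat = float(vals.max())
            elif stat == "median":
                th_stat = float(np.median(vals))
            else:
                raise ValueError(f"unknown th_statistic {stat!r}")
        is_th = bool(is_neuron and area > 0 and th_stat > thresholds.th_positive)
        ys, xs = np.nonzero(nuc_labels == lab)
        rows.append({
            "cell_id": lab,
            "centroid_x": float(xs.mean()) if xs.size else float("nan"),
            "centroid_y": float(ys.mean()) if ys.size else float("nan"),
            "nucleus_area_px": int(xs.size),
            "roi_area_px": area,
            "is_neuron": bool(is_neuron),
            "th_mean_bgsub": th_stat,
            "is_th_positive": is_th,
        })
    cells = pd.DataFrame(rows, columns=["cell_id", "centroid_x", "centroid_y",
                                        "nucleus_area_px", "roi_area_px",
                                        "is_neuron", "th_mean_bgsub", "is_th_positive"])
    n_neurons = int(cells["is_neuron"].sum()) if len(cells) else 0
    n_th = int(cells["is_th_positive"].sum()) if len(cells) else 0
    return SegmentationResult(
        nuc_mask=nuc_mask,
        nuc_labels=np.asarray(nuc_labels),
        roi_labels=roi_labels,
        th_mask=np.asarray(th_mask, bool),
        tuj1_mask=np.asarray(tuj1_mask, bool),
        neuro_mask=neuro_mask,
        n_nuclei=n_nuclei,
        n_neurons=n_neurons,
        n_th_positive=n_th,
        neuron_fraction=(n_neurons / n_nuclei) if n_nuclei else float("nan"),
        th_fraction_of_neurons=(n_th / n_neurons) if n_neurons else float("nan"),
        cells=cells,
    )


def segment_scene(nuc_channel: np.ndarray, tuj1_channel: np.ndarray,
                  th_channel: np.ndarray,
                  thresholds: PipelineThresholds = DEFAULT_THRESHOLDS) -> SegmentationResult:
    """Run the complete chain on one three-channel scene."""
    nuc_mask, nuc_labels = segment_nuclei(nuc_channel, thresholds)
    roi_labels = build_cell_rois(nuc_mask, nuc_labels, thresholds)
    th_mask = segment_marker_mask(th_channel, thresholds.marker_fine_pair,
                                  thresholds.marker_big_pair,
                                  thresholds.th_fine, thresholds.th_big,
                                  thresholds.th_median_global)
    tuj1_mask = segment_marker_mask(tuj1_channel, thresholds.marker_fine_pair,
                                    thresholds.marker_big_pair,
                                    thresholds.tuj1_fine, thresholds.tuj1_big,
                                    thresholds.tuj1_median_global)
    return classify_cells(roi_labels, nuc_mask, th_channel, tuj1_mask, th_mask,
                          thresholds, nuc_labels=nuc_labels)
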