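"""Organoid morphometrics from brightfield well images.

One organoid is expected per well of an ultra-low-attachment plate.  The
object is dark on a bright background; it is segmented by Otsu thresholding
of the inverted image, keeping the largest connected component and filling
holes.  Two size parameters are measured: area (foreground pixel count x
pixel_size^2) and Feret's diameter (largest caliper distance between
boundary pixel centers, via convex hull + rotating calipers).  Batch
statistics report the per-line mean and sample CV of both parameters, the
screening-suitability score used for organoid production runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage.filters import threshold_otsu

from .io import FieldImage

logger = logging.getLogger("plateqc")

#: components smaller than this many pixels are not considered organoids
MIN_ORGANOID_PX = 500


@dataclass
class OrganoidMeasurement:
    """Size measurements of one organoid (empty when none was found)."""

    mask: np.ndarray | None
    area: float  # µm²
    feret_diameter: float  # µm
    well_id: str = ""
    line_id: str = ""
    flags: str = ""

    @property
    def found(self) -> bool:
        return self.mask is not None


def segment_organoid(image: FieldImage | np.ndarray,
                     min_object_px: int = MIN_ORGANOID_PX) -> np.ndarray | None:
    """Segment the single dark organoid in a brightfield frame.

    Inverted-intensity Otsu threshold, largest 8-connected component, holes
    filled.  Returns ``None`` (flagged "no organoid") when no component
    reaches ``min_object_px`` or the frame has no contrast.
    """
    if isinstance(image, FieldImage):
        if image.n_channels != 1:
            raise ValueError("organoid segmentation expects a single-channel image")
        img = image.channel(0)
    else:
        img = np.asarray(image, float)
        if img.ndim != 2:
            raise ValueError("organoid segmentation expects a 2-D image")
    inv = img.max() - img
    if inv.max() == inv.min():
        return None
    dark = inv > threshold_otsu(inv, nbins=512)
    labels, n = ndi.label(dark, structure=np.ones((3, 3), int))
    if n == 0:
        return None
    sizes = np.bincount(labels.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_object_px:
        logger.info("largest dark component has %d px < %d; no organoid",
                    sizes[largest - 1], min_object_px)
        return None
    mask = ndi.binary_fill_holes(labels == largest)
    # reject noise splits on object-free frames: a real organoid is darker
    # than the background by far more than the background fluctuation
    outside = ~mask
    if outside.any():
        contrast = float(img[outside].mean() - img[mask].mean())
        if contrast <= 2.0 * float(img[outside].std()):
            logger.info("candidate component not darker than background "
                        "(contrast %.1f); no organoid", contrast)
            return None
    return mask


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    inner = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    ys, xs = np.nonzero(mask & ~inner)
    return np.column_stack([ys, xs]).astype(float)


def _rotating_calipers_diameter(points: np.ndarray) -> float:
    """Diameter of a 2-D point set: convex hull + rotating calipers.

    Falls back to direct pairwise search for degenerate (collinear / tiny)
    sets.  Distances are between pixel centers.
    """
    n = len(points)
    if n < 2:
        return 0.0
    if n == 2:
        return float(np.linalg.norm(points[0] - points[1]))
    try:
        hull = ConvexHull(points)
    except QhullError:  # collinear points
        return float(pdist(points).max())
    pts = points[hull.vertices]  # counter-clockwise
    m = len(pts)
    if m == 2:
        return float(np.linalg.norm(pts[0] - pts[1]))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    best = 0.0
    k = 1
    for i in range(m):
        j = (i + 1) % m
        # advance the antipodal point while the supporting triangle grows
        while cross(pts[i], pts[j], pts[(k + 1) % m]) > cross(pts[i], pts[j], pts[k]):
            k = (k + 1) % m
        best = max(best,
                   float(np.linalg.norm(pts[i] - pts[k])),
                   float(np.linalg.norm(pts[j] - pts[k])))
    return best


def feret_diameter(mask: np.ndarray, pixel_size: float = 1.0,
                   convention: str = "center") -> float:
    """Feret's (maximum caliper) diameter of a binary mask in µm.

    ``convention="center"`` measures between pixel centers (a single pixel
    has Feret 0); ``convention="edge"`` adds one pixel, approximating the
    pixel-edge convention of some imaging tools.
    """
    mask = np.asarray(mask, bool)
    pts = _boundary_points(mask)
    if len(pts) == 0:
        return 0.0
    d = _rotating_calipers_diameter(pts)
    if convention == "edge" and mask.any():
        d = d + 1.0
    elif convention not in ("center", "edge"):
        raise ValueError(f"unknown Feret convention {convention!r}")
    return d * pixel_size


def measure_organoid(mask: np.ndarray, pixel_size: float,
                     well_id: str = "", line_id: str = "",
                     feret_convention: str = "center") -> OrganoidMeasurement:
    """Area and Feret's diameter of a segmented organoid mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty organoid mask")
    area = float(mask.sum()) * pixel_size ** 2
    feret = feret_diameter(mask, pixel_size, convention=feret_convention)
    return OrganoidMeasurement(mask=mask, area=area, feret_diameter=feret,
                               well_id=well_id, line_id=line_id)


def empty_measurement(well_id: str = "", line_id: str = "") -> OrganoidMeasurement:
    """Flagged placeholder for a well where no organoid was found."""
    return OrganoidMeasurement(mask=None, area=float("nan"),
                               feret_diameter=float("nan"), well_id=well_id,
                               line_id=line_id, flags="no_organoid")


@dataclass
class LineBatchStats:
    """Per-line size homogeneity: mean and sample CV of area and Feret."""

    line_id: str
    n: int
    mean_area: float
    cv_area: float  # percent; NaN when n < 2
    mean_feret: float
    cv_feret: float


def _cv_percent(values: np.ndarray) -> float:
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return 100.0 * float(values.std(ddof=1)) / float(mean)


def batch_stats(measurements, by: str = "line_id") -> list[LineBatchStats]:
    """Per-group mean and sample CV of organoid area and Feret's diameter.

    ``measurements`` is a sequence of :class:`OrganoidMeasurement` or a
    DataFrame with columns ``area``, ``feret_diameter`` and the grouping
    column.  Pooling batches is done upstream by concatenating their
    measurements under one group id; groups with fewer than two organoids
    get a flagged (NaN) CV.
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements
    else:
        df = pd.DataFrame([{by: getattr(m, by), "area": m.area,
                            "feret_diameter": m.feret_diameter}
                           for m in measurements if m.found])
    out = []
    for gid, sub in df.groupby(by, sort=True):
        area = sub["area"].to_numpy(float)
        feret = sub["feret_diameter"].to_numpy(float)
        out.append(LineBatchStats(
            line_id=str(gid), n=len(sub),
            mean_area=float(area.mean()), cv_area=_cv_percent(area),
            mean_feret=float(feret.mean()), cv_feret=_cv_percent(feret),
        ))
    return out
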