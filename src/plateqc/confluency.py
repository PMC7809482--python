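"""Label-free confluency estimation and well-level seeding-homogeneity QC.

Cells in transmitted-light images are textured while empty substrate is
nearly flat, so per-field coverage is estimated from the local standard
deviation of intensity.  Well confluency is the mean of the per-field
coverages (in percent) and the coefficient of variation (CV) across fields
scores how homogeneously the cells were seeded.  A saturating-exponential
fit to serial-dilution confluency reads checks that the estimate tracks
seeded cell number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .io import FieldImage, WellScan

logger = logging.getLogger("plateqc")


def _local_sd(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed standard deviation, mirror-padded (moment filter)."""
    img = np.asarray(image, float)
    m = ndi.uniform_filter(img, size=window, mode="reflect")
    m2 = ndi.uniform_filter(img * img, size=window, mode="reflect")
    var = np.maximum(m2 - m * m, 0.0)
    return np.sqrt(var)


def detect_coverage(field: FieldImage | np.ndarray, window: int = 15,
                    k_sd: float = 3.0, min_object_px: int = 25) -> float:
    """Fraction of a transmitted-light field covered by cells.

    Foreground pixels are those whose local standard deviation (window x
    window, mirror padding) exceeds an automatic threshold on the local-sd
    map: the Otsu split of the map when it is genuinely bimodal (the
    foreground texture class exceeding the background class by more than
    ``k_sd``-fold), otherwise ``k_sd`` times the robust spread of the map
    (1.4826 x median absolute deviation), which handles the uniform cases —
    a constant field yields coverage 0, a fully textured field ~1.  The
    binary map is closed (3x3) and components smaller than
    ``min_object_px`` are dropped.

    The estimate is invariant to adding a constant to all intensities and
    to positive rescaling, since both the map and the thresholds scale
    accordingly.
    """
    if isinstance(field, FieldImage):
        if field.n_channels != 1:
            raise ValueError("detect_coverage expects a single-channel image")
        image = field.channel(0)
    else:
        image = np.asarray(field, float)
        if image.ndim != 2:
            raise ValueError("detect_coverage expects a single-channel image")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")

    sd = _local_sd(image, window)
    med = float(np.median(sd))
    mad = float(np.median(np.abs(sd - med)))
    robust_spread = 1.4826 * mad

    thr = k_sd * robust_spread
    if sd.max() > sd.min():
        t_otsu = float(threshold_otsu(sd, nbins=512))
        lo, hi = sd[sd <= t_otsu], sd[sd > t_otsu]
        if lo.size and hi.size:
            mu0, mu1 = float(lo.mean()), float(hi.mean())
            if mu1 > k_sd * mu0:  # genuine texture contrast between classes
                thr = t_otsu

    fg = sd > thr
    fg = ndi.binary_closing(fg, structure=np.ones((3, 3), bool))
    if min_object_px > 1 and fg.any():
        # drop components strictly smaller than min_object_px
        fg = remove_small_objects(fg, max_size=min_object_px - 1, connectivity=2)
    return float(fg.mean())


@dataclass
class ConfluencyResult:
    """Well-level confluency summary.

    ``well_mean`` is 100 x mean per-field coverage; ``well_cv`` is the
    sample CV (n-1) of the per-field coverages in percent, NaN (flagged)
    when the mean coverage is zero.
    """

    per_field_coverage: list[float]
    well_mean: float
    well_cv: float
    n_fields: int

    @property
    def cv_defined(self) -> bool:
        return np.isfinite(self.well_cv)


def summarize_coverages(per_field: np.ndarray | list[float]) -> ConfluencyResult:
    """Mean/CV summary of a per-field coverage vector."""
    cov = np.asarray(per_field, float)
    if cov.size == 0:
        raise ValueError("empty coverage vector")
    mean = float(cov.mean())
    if mean == 0:
        cv = float("nan")
        logger.warning("well mean coverage is 0; CV undefined")
    elif cov.size < 2:
        cv = float("nan")
    else:
        cv = 100.0 * float(cov.std(ddof=1)) / mean
    return ConfluencyResult(
        per_field_coverage=[float(c) for c in cov],
        well_mean=100.0 * mean,
        well_cv=cv,
        n_fields=int(cov.size),
    )


def assess_well(scan: WellScan | list, window: int = 15, k_sd: float = 3.0,
                min_object_px: int = 25) -> ConfluencyResult:
    """Apply :func:`detect_coverage` to every field of a well scan.

    Fields are processed in layout order; the result carries the per-field
    coverages plus the well mean (percent) and across-field sample CV.
    """
    fields = scan.fields if isinstance(scan, WellScan) else list(scan)
    if not fields:
        raise ValueError("empty well scan")
    shapes = {f.shape if isinstance(f, FieldImage) else np.asarray(f).shape for f in fields}
    if len(shapes) != 1:
        raise ValueError(f"all fields must share one shape, got {shapes}")
    cov = [detect_coverage(f, window=window, k_sd=k_sd, min_object_px=min_object_px)
           for f in fields]
    return summarize_coverages(cov)


# ---------------------------------------------------------------------------
# serial-dilution linearity


@dataclass
class DilutionFit:
    """Saturating-exponential fit ``y = ymax (1 - exp(-k x))`` to dilution reads."""

    ymax: float
    k: float
    r_squared: float  # NaN when SS_tot == 0 (degenerate, all y equal)

    @property
    def model_params(self) -> tuple[float, float]:
        return (self.ymax, self.k)

    def predict(self, x) -> np.ndarray:
        return dilution_model(np.asarray(x, float), self.ymax, self.k)


def dilution_model(x: np.ndarray, ymax: float, k: float) -> np.ndarray:
    """Monotone saturating confluency response to seeded amount."""
    return ymax * (1.0 - np.exp(-k * np.asarray(x, float)))


def fit_dilution_curve(seeded, confluency) -> DilutionFit:
    """Fit the saturating model to (seeded amount, confluency %) points.

    Bounded least squares with a deterministic initializer: ``ymax0`` is the
    largest observed confluency and ``k0`` comes from inverting the model at
    the first point.  ``r_squared = 1 - SS_res / SS_tot``; when all reads
    are equal SS_tot is zero and R^2 is flagged NaN.
    """
    x = np.asarray(seeded, float)
    y = np.asarray(confluency, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 (seeded, confluency) points")
    if not np.all(np.diff(x) > 0):
        raise ValueError("seeded amounts must be strictly increasing")
    if np.any((y < 0) | (y > 100)):
        raise ValueError("confluency values must lie in [0, 100]")

    ymax0 = max(float(y.max()), 1e-6)
    frac = min(max(y[0] / (ymax0 * 1.001), 1e-6), 1 - 1e-9)
    k0 = -np.log(1.0 - frac) / x[0] if x[0] > 0 else 1.0
    k0 = min(max(k0, 1e-8), 1e6)

    res = least_squares(
        lambda p: dilution_model(x, p[0], p[1]) - y,
        x0=[min(ymax0, 120.0), k0],
        bounds=([1e-9, 1e-9], [120.0, 1e6]),
        method="trf",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    ymax, k = float(res.x[0]), float(res.x[1])
    ss_res = float(np.sum((y - dilution_model(x, ymax, k)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = float("nan")
        logger.warning("degenerate dilution series (all reads equal); R^2 undefined")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return DilutionFit(ymax=ymax, k=k, r_squared=r2)
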