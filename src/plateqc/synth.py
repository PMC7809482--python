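"""Synthetic microscopy scenes with exact ground truth.

Every generator is a pure function of its parameters and an explicit RNG
seed, and emits a truth record whose derived quantities (coverage fraction,
object area, Feret's diameter) are computed from the emitted ground-truth
mask itself, so an independent brute-force pass reproduces them exactly.

Four scene families are produced:

* adherent transmitted-light fields — textured cell regions (zero-mean
  speckle, sd several-fold above the background noise) on a flat substrate,
  hitting a requested coverage fraction to the pixel;
* well scans — one field per layout position with a smooth spatial coverage
  ramp emulating inhomogeneous seeding;
* three-channel neuronal scenes (nuclei / pan-neuronal / TH) with known cell
  centers, neuron identities and TH-positive identities;
* brightfield organoid frames — one dark compact object per well — and
  serial-dilution confluency tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import pdist

from .io import FieldImage, FieldLayout, WellScan, write_image

#: intensity defaults (16-bit-range floats)
BACKGROUND_LEVEL = 500.0
BACKGROUND_SD = 3.0
#: foreground speckle sd as a multiple of the background sd; the
#: variance-based coverage detector assumes a several-fold contrast
SPECKLE_CONTRAST = 8.0


class CapacityError(ValueError):
    """Requested cell count cannot be placed at the minimum spacing."""


@dataclass
class CellSceneTruth:
    """Ground truth emitted alongside every synthetic scene."""

    kind: str  # adherent_field | neuro_scene | organoid | dilution_series
    seed: int
    coverage_true: float | None = None
    n_cells_true: int | None = None
    neuron_ids: tuple[int, ...] = ()
    th_positive_ids: tuple[int, ...] = ()
    organoid_area_true: float | None = None  # µm²
    organoid_feret_true: float | None = None  # µm
    gradient_strength: float = 0.0
    mask: np.ndarray | None = dc_field(default=None, repr=False)
    centers: tuple[tuple[float, float], ...] = ()  # (row, col)
    per_field_coverage: tuple[float, ...] = ()
    params: dict = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "seed": self.seed,
            "coverage_true": self.coverage_true,
            "n_cells_true": self.n_cells_true,
            "neuron_ids": list(self.neuron_ids),
            "th_positive_ids": list(self.th_positive_ids),
            "organoid_area_true": self.organoid_area_true,
            "organoid_feret_true": self.organoid_feret_true,
            "gradient_strength": self.gradient_strength,
            "centers": [list(c) for c in self.centers],
            "per_field_coverage": list(self.per_field_coverage),
            "params": self.params,
        }
        return d


def save_scene(image: FieldImage | np.ndarray, truth: CellSceneTruth,
               path: str | Path) -> None:
    """Write a scene as 16-bit TIFF plus a sidecar ``.truth.json`` file.

    The ground-truth mask, when present, goes to ``<stem>.truth.tif``.
    """
    path = Path(path)
    write_image(image, path)
    path.with_suffix(".truth.json").write_text(
        json.dumps(truth.to_json_dict(), indent=1) + "\n")
    if truth.mask is not None:
        write_image(truth.mask.astype(np.uint16) * 65535, path.with_suffix(".truth.tif"))


# ---------------------------------------------------------------------------
# adherent transmitted-light fields


def _stamp_ellipse(mask: np.ndarray, cy: float, cx: float, a: float, b: float,
                   theta: float) -> None:
    h, w = mask.shape
    r = max(a, b)
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _adjust_to_quota(mask: np.ndarray, target: int, rng: np.random.Generator) -> None:
    """Trim or grow the mask at its boundary until it has exactly ``target``
    foreground pixels, keeping blobs compact."""
    current = int(mask.sum())
    if current > target:
        # remove shallowest (boundary-first) pixels
        depth = ndi.distance_transform_edt(mask)
        ys, xs = np.nonzero(mask)
        order = np.argsort(depth[ys, xs] + rng.random(ys.size) * 1e-3, kind="stable")
        kill = order[: current - target]
        mask[ys[kill], xs[kill]] = False
    elif current < target:
        if current == 0:
            mask[mask.shape[0] // 2, mask.shape[1] // 2] = True
            current = 1
        dist = ndi.distance_transform_edt(~mask)
        ys, xs = np.nonzero(~mask)
        order = np.argsort(dist[ys, xs] + rng.random(ys.size) * 1e-3, kind="stable")
        grow = order[: target - current]
        mask[ys[grow], xs[grow]] = True


def gen_adherent_field(width: int, height: int, coverage: float,
                       clumpiness: float = 1.0, seed: int = 0,
                       pixel_size: float = 1.0,
                       contrast: float = SPECKLE_CONTRAST
                       ) -> tuple[FieldImage, CellSceneTruth]:
    """Transmitted-light-like field at an exact coverage fraction.

    Elliptical textured blobs are placed at random, then the mask boundary
    is trimmed/grown to hit the pixel quota ``round(coverage * W * H)``
    exactly; the truth record carries the achieved fraction.  Foreground
    pixels get zero-mean speckle with sd ``contrast`` times the background
    noise sd, which is the contrast the variance-based coverage detector
    relies on.  Higher ``clumpiness`` gives fewer, larger blobs.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    if width < 32 or height < 32:
        raise ValueError("field must be at least 32 x 32 px")
    if clumpiness <= 0:
        raise ValueError("clumpiness must be > 0")
    rng = np.random.default_rng(seed)
    h, w = int(height), int(width)
    target = int(round(coverage * w * h))
    mask = np.zeros((h, w), dtype=bool)

    if target > 0:
        n_planned = max(1, int(np.ceil(coverage * 8.0 / clumpiness)))
        r0 = np.sqrt(target / (np.pi * n_planned))
        attempts = 0
        while int(mask.sum()) < target and attempts < 20 * n_planned + 20:
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            scale = rng.uniform(0.7, 1.3)
            ratio = rng.uniform(0.6, 1.0)
            a = max(2.0, r0 * scale / np.sqrt(ratio))
            b = max(2.0, r0 * scale * np.sqrt(ratio))
            _stamp_ellipse(mask, cy, cx, a, b, rng.uniform(0, np.pi))
            attempts += 1
        _adjust_to_quota(mask, target, rng)

    image = BACKGROUND_LEVEL + rng.normal(0.0, BACKGROUND_SD, size=(h, w))
    image[mask] += rng.normal(0.0, contrast * BACKGROUND_SD, size=int(mask.sum()))
    image = np.clip(image, 0.0, 65535.0)

    truth = CellSceneTruth(
        kind="adherent_field", seed=int(seed),
        coverage_true=float(mask.sum()) / (w * h),
        mask=mask,
        params={"width": w, "height": h, "coverage": coverage,
                "clumpiness": clumpiness, "contrast": contrast},
    )
    return FieldImage(image, pixel_size=pixel_size), truth


def gen_well_scan(layout: FieldLayout, mean_coverage: float,
                  gradient_strength: float = 0.0, seed: int = 0,
                  width: int = 256, height: int = 256,
                  clumpiness: float = 1.0) -> tuple[WellScan, CellSceneTruth]:
    """One adherent field per layout position with a smooth coverage ramp.

    Per-field target coverages follow a linear spatial gradient of relative
    amplitude ``gradient_strength`` around ``mean_coverage`` along a
    seed-chosen direction, clipped to [0, 1]; ``gradient_strength = 0``
    gives every field the same target.
    """
    if len(layout.field_positions) < 2:
        raise ValueError("layout needs at least 2 fields")
    if not 0.0 <= mean_coverage <= 1.0:
        raise ValueError("mean_coverage must be in [0, 1]")
    if gradient_strength < 0:
        raise ValueError("gradient_strength must be >= 0")
    rng = np.random.default_rng(seed)
    pos = np.asarray(layout.field_positions, float)
    theta = rng.uniform(0, 2 * np.pi)
    proj = pos @ np.array([np.cos(theta), np.sin(theta)])
    span = proj.max() - proj.min()
    ramp = np.zeros(len(pos)) if span == 0 else 2 * (proj - proj.min()) / span - 1
    targets = np.clip(mean_coverage * (1.0 + gradient_strength * ramp), 0.0, 1.0)

    field_seeds = rng.integers(0, 2 ** 31 - 1, size=len(pos))
    fields, achieved = [], []
    for t, s in zip(targets, field_seeds):
        img, tr = gen_adherent_field(width, height, float(t), clumpiness=clumpiness,
                                     seed=int(s))
        fields.append(img)
        achieved.append(tr.coverage_true)

    truth = CellSceneTruth(
        kind="adherent_field", seed=int(seed),
        coverage_true=float(np.mean(achieved)),
        gradient_strength=float(gradient_strength),
        per_field_coverage=tuple(achieved),
        params={"mean_coverage": mean_coverage, "width": width, "height": height},
    )
    return WellScan(layout=layout, fields=fields), truth


# ---------------------------------------------------------------------------
# three-channel neuronal scenes


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _place_centers(rng: np.random.Generator, n: int, width: int, height: int,
                   min_spacing: float, margin: float) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    lo_y, hi_y = margin, height - margin
    lo_x, hi_x = margin, width - margin
    if hi_y <= lo_y or hi_x <= lo_x:
        raise CapacityError(f"field {width}x{height} too small for margin {margin}")
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 2000 * n
    while len(centers) < n:
        if attempts >= max_attempts:
            raise CapacityError(
                f"cannot place {n} cells at spacing >= {min_spacing} px in a "
                f"{width}x{height} field"
            )
        cy, cx = rng.uniform(lo_y, hi_y), rng.uniform(lo_x, hi_x)
        ok = all((cy - y) ** 2 + (cx - x) ** 2 >= min_spacing ** 2 for y, x in centers)
        if ok:
            centers.append((cy, cx))
        attempts += 1
    return np.asarray(centers)


def _add_gaussian_blob(img: np.ndarray, cy: float, cx: float, amp: float,
                       sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2)
                                      / (2 * sigma ** 2))


def _add_disk(img: np.ndarray, cy: float, cx: float, radius: float, amp: float) -> None:
    h, w = img.shape
    r = int(np.ceil(radius)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1][(yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2] += amp


def _add_stroke(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, amp: float,
                rng: np.random.Generator) -> None:
    """Curvilinear neurite stroke: a quadratic Bezier sampled densely and
    stamped ~2 px wide."""
    h, w = img.shape
    mid = (p0 + p1) / 2.0
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    norm = np.linalg.norm(normal)
    if norm > 0:
        mid = mid + normal / norm * rng.uniform(-0.15, 0.15) * np.linalg.norm(p1 - p0)
    n_steps = max(2, int(2 * np.linalg.norm(p1 - p0)))
    t = np.linspace(0, 1, n_steps)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * mid + t ** 2 * p1
    iy = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    ix = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    stroke = np.zeros_like(img, dtype=bool)
    stroke[iy, ix] = True
    stroke = ndi.binary_dilation(stroke, structure=np.ones((2, 2), bool))
    img[stroke] += amp


def gen_neuro_scene(width: int, height: int, n_cells: int,
                    neuron_fraction: float = 1.0,
                    th_fraction_of_neurons: float = 0.25, seed: int = 0,
                    min_spacing: float = 14.0,
                    pixel_size: float = 1.0) -> tuple[FieldImage, CellSceneTruth]:
    """Three-channel fluorescence scene with known per-cell identities.

    Channel order follows the acquisition convention TH (561 nm), nuclei
    (405 nm), Tuj1 (488 nm) -> index 0 = TH, 1 = nuclei, 2 = Tuj1.

    Nuclei are bright Gaussian blobs (peak >= 150 over a background <= 10,
    sigma ~4 px); neurons additionally get a somatic disk plus curvilinear
    strokes in the pan-neuronal channel, and TH-positive neurons the same
    in the TH channel.  Neuron and TH-positive counts are realized by
    deterministic rounding (nearest integer, ties up) so the truth
    fractions are exact.  Cell centers keep at least ``min_spacing`` px
    between each other (>= 8) and 12 px from the borders.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not (0 <= neuron_fraction <= 1 and 0 <= th_fraction_of_neurons <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if min_spacing < 8:
        raise ValueError("min_spacing must be >= 8 px")
    rng = np.random.default_rng(seed)
    h, w = int(height), int(width)

    centers = _place_centers(rng, n_cells, w, h, min_spacing, margin=12.0)
    n_neurons = _round_half_up(neuron_fraction * n_cells)
    ids = np.arange(1, n_cells + 1)
    neuron_ids = np.sort(rng.choice(ids, size=n_neurons, replace=False)) if n_cells else ids[:0]
    n_th = _round_half_up(th_fraction_of_neurons * n_neurons)
    th_ids = np.sort(rng.choice(neuron_ids, size=n_th, replace=False)) if n_neurons else ids[:0]

    nuc = np.full((h, w), 5.0) + rng.normal(0, 1.0, (h, w))
    tuj1 = np.full((h, w), 2.0) + rng.normal(0, 0.5, (h, w))
    th = np.full((h, w), 2.0) + rng.normal(0, 0.5, (h, w))

    amps = rng.uniform(180.0, 240.0, size=n_cells)
    for (cy, cx), amp in zip(centers, amps):
        _add_gaussian_blob(nuc, cy, cx, amp, sigma=4.0)

    neuron_set = set(neuron_ids.tolist())
    th_set = set(th_ids.tolist())
    neuron_centers = {i: centers[i - 1] for i in neuron_set}
    for i in neuron_set:
        cy, cx = neuron_centers[i]
        _add_disk(tuj1, cy, cx, radius=7.0, amp=130.0)
    for i in th_set:
        cy, cx = neuron_centers[i]
        _add_disk(th, cy, cx, radius=8.0, amp=200.0)

    def _nearest_strokes(img, members, amp):
        pts = {i: np.asarray(neuron_centers[i]) for i in members}
        for i in members:
            others = [j for j in members if j != i]
            if not others:
                continue
            j = min(others, key=lambda j: np.sum((pts[j] - pts[i]) ** 2))
            _add_stroke(img, pts[i], pts[j], amp, rng)

    _nearest_strokes(tuj1, sorted(neuron_set), amp=90.0)
    _nearest_strokes(th, sorted(th_set), amp=60.0)

    stack = np.stack([np.clip(th, 0, 65535), np.clip(nuc, 0, 65535),
                      np.clip(tuj1, 0, 65535)])
    truth = CellSceneTruth(
        kind="neuro_scene", seed=int(seed),
        n_cells_true=int(n_cells),
        neuron_ids=tuple(int(i) for i in neuron_ids),
        th_positive_ids=tuple(int(i) for i in th_ids),
        centers=tuple((float(cy), float(cx)) for cy, cx in centers),
        params={"width": w, "height": h, "neuron_fraction": neuron_fraction,
                "th_fraction_of_neurons": th_fraction_of_neurons,
                "min_spacing": min_spacing},
    )
    image = FieldImage(stack, pixel_size=pixel_size,
                       channel_names=("th", "nuclei", "tuj1"))
    return image, truth


# ---------------------------------------------------------------------------
# brightfield organoids


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    inner = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    ys, xs = np.nonzero(mask & ~inner)
    return np.column_stack([ys, xs]).astype(float)


def brute_force_feret(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Max pairwise distance between foreground-boundary pixel centers.

    A mask with a single pixel has Feret 0 (center-to-center convention).
    """
    pts = _boundary_pixels(np.asarray(mask, bool))
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max()) * pixel_size


def gen_organoid_image(shape: str = "disk", size_params=50.0,
                       pixel_size: float = 1.0, seed: int = 0,
                       width: int | None = None, height: int | None = None
                       ) -> tuple[FieldImage, CellSceneTruth]:
    """Brightfield frame with one dark compact organoid on a bright background.

    ``size_params`` is the radius for ``disk``, ``(a, b)`` or
    ``(a, b, theta)`` semi-axes for ``ellipse``, and the base radius for
    ``blob`` (random smooth radial perturbation up to 15%).  The truth
    carries the exact rasterized mask, its pixel count x pixel_size^2 as
    the area, and the brute-force max boundary-pixel-center distance x
    pixel_size as the Feret diameter.
    """
    rng = np.random.default_rng(seed)
    if shape == "disk":
        r_max = float(size_params)
        radius_fn = lambda phi: np.full_like(phi, float(size_params))  # noqa: E731
    elif shape == "ellipse":
        p = tuple(np.atleast_1d(size_params).astype(float))
        a, b = p[0], p[1]
        theta = p[2] if len(p) > 2 else rng.uniform(0, np.pi)
        r_max = max(a, b)

        def radius_fn(phi):
            c, s = np.cos(phi - theta), np.sin(phi - theta)
            return (a * b) / np.sqrt((b * c) ** 2 + (a * s) ** 2)
    elif shape == "blob":
        r0 = float(size_params)
        kmax = 5
        amp = rng.uniform(0.0, 0.15 / (kmax - 1), size=kmax - 1)
        phase = rng.uniform(0, 2 * np.pi, size=kmax - 1)
        r_max = r0 * (1 + amp.sum())

        def radius_fn(phi):
            r = np.full_like(phi, r0, dtype=float)
            for k, (a_k, p_k) in enumerate(zip(amp, phase), start=2):
                r += r0 * a_k * np.cos(k * phi + p_k)
            return r
    else:
        raise ValueError(f"unknown organoid shape {shape!r}")

    margin = 8
    side = int(np.ceil(2 * r_max)) + 2 * margin
    h = int(height) if height else side
    w = int(width) if width else side
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if r_max + 5 > min(cy, cx, h - 1 - cy, w - 1 - cx) + 1:
        raise ValueError(
            f"organoid of extent {r_max:.1f} px does not fit a {w}x{h} frame "
            "with a 5 px margin")

    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    phi = np.arctan2(dy, dx)
    mask = rr <= radius_fn(phi)

    bg = 1000.0
    shading = 1.0 + 0.03 * (xx - cx) / max(w, 1)  # mild lateral shading
    image = bg * shading + rng.normal(0, 8.0, (h, w))
    image[mask] = 0.30 * bg + rng.normal(0, 8.0, int(mask.sum()))
    image = ndi.gaussian_filter(np.clip(image, 0, 65535), sigma=1.0)

    truth = CellSceneTruth(
        kind="organoid", seed=int(seed),
        organoid_area_true=float(mask.sum()) * pixel_size ** 2,
        organoid_feret_true=brute_force_feret(mask, pixel_size),
        mask=mask,
        params={"shape": shape, "pixel_size": pixel_size},
    )
    return FieldImage(image, pixel_size=pixel_size), truth


# ---------------------------------------------------------------------------
# serial dilutions


def gen_dilution_series(levels: Sequence[float], noise_sd: float = 2.0,
                        seed: int = 0, ymax: float = 95.0, k: float = 0.3
                        ) -> tuple[pd.DataFrame, CellSceneTruth]:
    """Confluency reads for a serial dilution of seeded cells.

    Confluency follows the saturating curve ``y = ymax (1 - exp(-k x))``
    plus Gaussian noise of sd ``noise_sd`` confluency points, clipped to
    [0, 100].  ``levels`` are the seeded amounts (strictly increasing,
    at least 4).
    """
    x = np.asarray(levels, float)
    if x.size < 4 or not np.all(np.diff(x) > 0):
        raise ValueError("levels must be strictly increasing with >= 4 entries")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    y = ymax * (1.0 - np.exp(-k * x))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, size=x.size)
    y = np.clip(y, 0.0, 100.0)
    table = pd.DataFrame({"seeded_amount": x, "confluency_pct": y})
    truth = CellSceneTruth(kind="dilution_series", seed=int(seed),
                           params={"ymax": ymax, "k": k, "noise_sd": noise_sd,
                                   "levels": [float(v) for v in x]})
    return table, truth
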