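"""Image and tabular I/O, plate/acquisition layouts, and result serialization.

Images are exchanged as plain TIFF (one page per channel); results as
RFC-4180 CSV or JSON.  Field layouts describe how many microscope fields are
acquired per well and where they sit on the acquisition grid: the platform
this package targets scans 38 fields per well of a 6-well plate and 384
fields for a 1-well plate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("plateqc")

PLATE_FORMATS = ("six_well", "one_well", "ninety_six_well", "three_eighty_four_well")

#: default number of acquisition fields per well for each plate format
DEFAULT_FIELDS_PER_WELL = {
    "six_well": 38,
    "one_well": 384,
    "ninety_six_well": 1,
    "three_eighty_four_well": 1,
}


class FormatError(ValueError):
    """Raised when a file cannot be read as the expected format."""


class ConfigError(ValueError):
    """Raised when a layout or pipeline configuration is invalid."""


@dataclass(frozen=True)
class FieldImage:
    """One acquisition field: a 2-D intensity grid (or a channel stack).

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` for single-channel or ``(C, H, W)`` for multi-channel
        images; intensities are non-negative floats on a 16-bit range.
    pixel_size : float
        Physical pixel edge length in µm/px.
    channel_names : tuple of str, optional
        One name per channel for multi-channel images.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3):
            raise ValueError(f"pixels must be 2-D or (C, H, W) 3-D, got ndim={px.ndim}")
        if px.shape[-1] < 1 or px.shape[-2] < 1:
            raise ValueError("pixel grid must be at least 1x1")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[-2:]

    def channel(self, i: int) -> np.ndarray:
        """Return channel ``i`` as a 2-D array."""
        if self.pixels.ndim == 2:
            if i != 0:
                raise IndexError("single-channel image")
            return self.pixels
        return self.pixels[i]


@dataclass(frozen=True)
class FieldLayout:
    """Positions of the acquisition fields within one well.

    ``field_positions`` are (row, col) grid coordinates, unique, one per
    field.  Six-well wells default to a 38-field centered packing on a 7x7
    grid (round well); 1-well plates to the full 16x24 = 384 grid.
    """

    plate_format: str
    fields_per_well: int
    field_positions: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.plate_format not in PLATE_FORMATS:
            raise ConfigError(
                f"unknown plate_format {self.plate_format!r}; expected one of {PLATE_FORMATS}"
            )
        pos = tuple((int(r), int(c)) for r, c in self.field_positions)
        if len(pos) != self.fields_per_well:
            raise ConfigError(
                f"{len(pos)} positions given but fields_per_well={self.fields_per_well}"
            )
        if len(set(pos)) != len(pos):
            raise ConfigError("duplicate field positions in layout")
        object.__setattr__(self, "field_positions", pos)


@dataclass
class WellScan:
    """Ordered set of field images for one well, following a layout."""

    layout: FieldLayout
    fields: list[FieldImage] = field(default_factory=list)

    def __post_init__(self):
        if len(self.fields) and len(self.fields) != self.layout.fields_per_well:
            raise ValueError(
                f"scan has {len(self.fields)} fields, layout expects "
                f"{self.layout.fields_per_well}"
            )

    def __len__(self) -> int:
        return len(self.fields)


def _centered_grid_positions(n: int, rows: int, cols: int) -> tuple[tuple[int, int], ...]:
    """The ``n`` grid positions nearest the grid center (disk-like packing).

    Ties in radius are broken by (row, col) order so the layout is
    deterministic.  Used for round wells where the corner fields of a
    rectangular scan fall outside the well.
    """
    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    cells.sort(key=lambda rc: ((rc[0] - cr) ** 2 + (rc[1] - cc) ** 2, rc[0], rc[1]))
    return tuple(cells[:n])


def default_layout(plate_format: str, fields_per_well: int | None = None) -> FieldLayout:
    """Build the default field layout for a plate format."""
    if plate_format not in PLATE_FORMATS:
        raise ConfigError(
            f"unknown plate_format {plate_format!r}; expected one of {PLATE_FORMATS}"
        )
    n = DEFAULT_FIELDS_PER_WELL[plate_format] if fields_per_well is None else int(fields_per_well)
    if plate_format == "one_well" and n == 384:
        positions = tuple((r, c) for r in range(16) for c in range(24))
    elif plate_format == "six_well" and n == 38:
        positions = _centered_grid_positions(38, 7, 7)
    else:
        # generic near-square grid, filled center-out
        cols = int(np.ceil(np.sqrt(n)))
        rows = int(np.ceil(n / cols))
        positions = _centered_grid_positions(n, rows, cols)
    return FieldLayout(plate_format, n, positions)


def load_layout(config: Mapping | str | Path) -> FieldLayout:
    """Load and validate a field layout from a mapping or YAML/JSON file.

    The config either names a ``plate_format`` (defaults: six_well -> 38
    fields, one_well -> 384) or gives explicit ``field_positions``, which are
    echoed back unchanged.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    if not isinstance(config, Mapping):
        raise ConfigError("layout config must be a mapping or a path to one")
    positions = config.get("field_positions")
    plate_format = config.get("plate_format")
    if positions is not None:
        pos = tuple((int(r), int(c)) for r, c in positions)
        return FieldLayout(plate_format or "six_well", len(pos), pos)
    if plate_format is None:
        raise ConfigError("layout config needs 'plate_format' or 'field_positions'")
    return default_layout(plate_format, config.get("fields_per_well"))


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return data


def read_image(path: str | Path, pixel_size: float | None = None,
               channel_names: Sequence[str] | None = None) -> FieldImage:
    """Read an 8/16-bit TIFF (1-4 pages = channels) as a :class:`FieldImage`.

    Intensities are preserved losslessly as floats and channel (page) order
    is kept.  ``pixel_size`` must come from configuration when the file
    carries no resolution metadata; it defaults to 1 µm/px.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize to a format error
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (1, 2, 3, 4):
        # RGB(A) stored interleaved -> channels-first
        arr = np.moveaxis(arr, -1, 0)
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported TIFF dimensionality {arr.shape} in {path}")
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return FieldImage(
        arr.astype(float),
        pixel_size=1.0 if pixel_size is None else float(pixel_size),
        channel_names=tuple(channel_names) if channel_names else None,
    )


def write_image(image: FieldImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 16-bit TIFF, one page per channel.

    Intensities are clipped to [0, 65535] and rounded; generators emit
    16-bit-range floats so the round trip is lossless for them.
    """
    arr = image.pixels if isinstance(image, FieldImage) else np.asarray(image, float)
    q = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), q, photometric="minisblack")


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def records_to_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    """Homogeneous records -> DataFrame with stable column order."""
    records = list(records)
    if not records:
        return pd.DataFrame()
    cols = list(records[0].keys())
    for r in records[1:]:
        if list(r.keys()) != cols:
            raise ValueError("records are not homogeneous (column mismatch)")
    return pd.DataFrame.from_records(records, columns=cols)


def write_results(records: Iterable[Mapping] | pd.DataFrame, path: str | Path,
                  format: str | None = None, columns: Sequence[str] | None = None) -> None:
    """Write result records to CSV (RFC-4180) or JSON.

    Floats are serialized with 6 significant digits; column order follows
    the first record.  ``format`` defaults to the file suffix.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    if format not in ("csv", "json"):
        raise ValueError(f"unsupported results format {format!r}")
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if columns is not None:
        df = pd.DataFrame(df, columns=list(columns))
    try:
        if format == "csv":
            df.to_csv(path, index=False, float_format="%.6g", lineterminator="\r\n")
        else:
            recs = df.to_dict(orient="records")
            for r in recs:
                for k, v in r.items():
                    if isinstance(v, float):
                        r[k] = _round_sig(v)
                    elif isinstance(v, (np.integer,)):
                        r[k] = int(v)
            path.write_text(json.dumps(recs, indent=1) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    logger.info("wrote %d records to %s (%s)", len(df), path, format)
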