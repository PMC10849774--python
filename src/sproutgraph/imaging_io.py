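"""Calibrated image I/O: TIFF stacks, z max-projection, and tabular records.

Input images are single-channel 8/16-bit TIFFs, possibly multi-page
(z-slices).  Loading always returns the per-pixel maximum intensity
projection across pages.  Tabular outputs (morphometric records) round-trip
through plain CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .units import DEFAULT_RESOLUTION_UM_PER_PX

#: Default filename pattern used to recover (bead, day) metadata.
DEFAULT_FILENAME_PATTERN = r"bead(?P<bead>\d+)_day(?P<day>\d+)"


class FormatError(ValueError):
    """Raised for unreadable or malformed image files."""


@dataclass
class CalibratedImage:
    """A 2D intensity field with physical calibration and acquisition metadata."""

    pixels: np.ndarray
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX
    bead_id: str | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if self.resolution_um_per_px <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TimeSeries:
    """One observable sampled on an increasing day grid."""

    days: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.values.shape:
            raise ValueError("days and values must be 1D arrays of equal length")
        if self.days.size and np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.days.size

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.days.tolist(), self.values.tolist()))


def max_project(pages: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis; 2D input passes through."""
    pages = np.asarray(pages)
    if pages.ndim == 2:
        return pages
    if pages.ndim != 3:
        raise FormatError(f"expected 2D or 3D grayscale data, got shape {pages.shape}")
    return pages.max(axis=0)


def parse_metadata(path: str | Path, pattern: str = DEFAULT_FILENAME_PATTERN) -> tuple[str | None, int | None]:
    """Extract (bead_id, day) from a filename via a regex with named groups."""
    m = re.search(pattern, Path(path).name)
    if m is None:
        return None, None
    groups = m.groupdict()
    bead = groups.get("bead")
    day = groups.get("day")
    return bead, int(day) if day is not None else None


def load_stack(
    path: str | Path,
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM_PER_PX,
    filename_pattern: str = DEFAULT_FILENAME_PATTERN,
) -> CalibratedImage:
    """Load a single-channel TIFF (1..n pages) and return its z max-projection.

    Raises :class:`FormatError` for unreadable files, multi-channel pages or
    pages of non-uniform shape.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path}: no pages")
    shape0 = pages[0].shape
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"{path}: page {i} is not single-channel (shape {page.shape})")
        if page.shape != shape0:
            raise FormatError(f"{path}: page {i} shape {page.shape} != page 0 shape {shape0}")
    projected = max_project(np.stack(pages)) if len(pages) > 1 else pages[0]
    bead, day = parse_metadata(path, filename_pattern)
    return CalibratedImage(projected.astype(float), resolution_um_per_px, bead_id=bead, day=day)


def write_image(img: CalibratedImage, path: str | Path) -> None:
    """Write an image as 16-bit single-page TIFF (values clipped to uint16)."""
    data = np.clip(np.rint(img.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


# ---------------------------------------------------------------------------
# Morphometric record CSV round trip
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "bead_id",
    "day",
    "condition",
    "A_um2",
    "Ac_um2",
    "L_um",
    "lambda_um",
    "rmax_um",
    "N_tip",
    "N_pb",
    "G",
]


def write_records(records: Sequence[Mapping], path: str | Path, config_hash: str | None = None) -> None:
    """Write morphometric records as CSV, one row per (bead, day).

    ``records`` are mappings (or dataclasses exposing ``to_dict``) with the
    schema of :data:`RECORD_COLUMNS`.  Numerics keep full precision.
    """
    rows = []
    for rec in records:
        d = rec.to_dict() if hasattr(rec, "to_dict") else dict(rec)
        missing = set(RECORD_COLUMNS) - set(d)
        if missing:
            raise ValueError(f"record missing fields: {sorted(missing)}")
        rows.append({k: d[k] for k in RECORD_COLUMNS})
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a records CSV back; raises on schema mismatch."""
    df = pd.read_csv(path, comment="#", dtype={"bead_id": str, "condition": str})
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(f"unexpected record schema {list(df.columns)}")
    return df
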