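"""Reading and writing binary fiber-trace z-stacks and per-segment tables.

A *trace stack* is an ordered series of 2-D binary images, one per confocal
optical section, in which foreground pixels are 1-pixel-wide hand-drawn lines
over elongated muscle cells.  This module owns the physical calibration of a
stack (section count, z spacing, optional in-plane pixel size), the depth
bookkeeping ``total_depth = n_sections * z_spacing``, and the plain-text
export of per-segment orientation results.

Stack geometry travels in a key-value sidecar file rather than in TIFF tags:
tag dialects are unreliable across tracing tools, so when embedded resolution
tags conflict with the sidecar a warning is logged and the sidecar wins.

Coordinate convention throughout the package: ``x`` is the column index
increasing rightward, ``y`` the row index increasing downward, both 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DomainError, FormatError, GeometryError

logger = logging.getLogger("fibermap")

__all__ = [
    "StackGeometry",
    "TraceStack",
    "total_depth",
    "load_trace_stack",
    "save_trace_stack",
    "read_geometry",
    "write_geometry",
    "SEGMENT_TABLE_COLUMNS",
    "write_segment_table",
    "read_segment_table",
    "validate_segment_table",
]


def total_depth(n_sections: int, z_spacing: float) -> float:
    """Total physical depth of a stack in micrometers, to 0.01 um.

    The convention is ``n_sections * z_spacing`` (each section owns one
    spacing's worth of depth), e.g. 46 sections every 1.51 um span 69.46 um.

    Parameters
    ----------
    n_sections : int
        Number of optical sections, >= 1.
    z_spacing : float
        Micrometers between successive sections, > 0.
    """
    if n_sections < 1:
        raise DomainError(f"n_sections must be >= 1, got {n_sections}")
    if not z_spacing > 0:
        raise DomainError(f"z_spacing must be > 0, got {z_spacing}")
    return round(n_sections * z_spacing, 2)


@dataclass(frozen=True)
class StackGeometry:
    """Physical calibration of a trace stack.

    Attributes
    ----------
    n_sections : int
        Number of optical sections (>= 1).
    z_spacing : float
        Micrometers per section (> 0).
    pixel_size_xy : float or None
        Micrometers per pixel in-plane; ``None`` when unknown.
    """

    n_sections: int
    z_spacing: float
    pixel_size_xy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise GeometryError(f"n_sections must be >= 1, got {self.n_sections}")
        if not self.z_spacing > 0:
            raise GeometryError(f"z_spacing must be > 0, got {self.z_spacing}")
        if self.pixel_size_xy is not None and not self.pixel_size_xy > 0:
            raise GeometryError(
                f"pixel_size_xy must be > 0 or None, got {self.pixel_size_xy}"
            )

    @property
    def total_depth(self) -> float:
        """Stack depth in micrometers (``n_sections * z_spacing``, to 0.01 um)."""
        return total_depth(self.n_sections, self.z_spacing)


@dataclass
class TraceStack:
    """An ordered stack of binary trace planes plus its calibration.

    ``planes`` is a ``(n_sections, height, width)`` uint8 array restricted to
    {0, 1}; index 0 is the first optical section.
    """

    planes: np.ndarray
    geometry: StackGeometry
    label: str = ""

    def __post_init__(self) -> None:
        planes = np.asarray(self.planes)
        if planes.ndim != 3:
            raise FormatError(
                f"planes must be a 3-D (z, y, x) array, got shape {planes.shape}"
            )
        if planes.shape[0] != self.geometry.n_sections:
            raise GeometryError(
                f"stack has {planes.shape[0]} planes but geometry declares "
                f"{self.geometry.n_sections} sections"
            )
        if not np.isin(planes, (0, 1)).all():
            raise FormatError("plane values must be restricted to {0, 1}")
        self.planes = planes.astype(np.uint8, copy=False)

    @property
    def n_sections(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every plane."""
        return self.planes.shape[1], self.planes.shape[2]


def _binarize(pages: np.ndarray) -> np.ndarray:
    """Map any nonzero sample (any bit depth) to foreground 1."""
    return (pages != 0).astype(np.uint8)


def load_trace_stack(path: str | Path, geometry: StackGeometry, label: str = "") -> TraceStack:
    """Load a multi-page TIFF of binary trace planes.

    Any nonzero pixel sample becomes foreground 1 (tolerating 8-bit 0/255
    masks); page order is preserved as z order.  The page count must equal
    ``geometry.n_sections``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace stack not found: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        _warn_on_conflicting_resolution_tags(tif, geometry, path)
    if len(pages) != geometry.n_sections:
        raise GeometryError(
            f"{path} has {len(pages)} pages but geometry declares "
            f"{geometry.n_sections} sections"
        )
    for i, page in enumerate(pages):
        if page.ndim != 2:
            raise FormatError(f"page {i} of {path} is not a 2-D image (shape {page.shape})")
    if len({p.shape for p in pages}) > 1:
        raise FormatError(f"pages of {path} do not share a single height x width")
    planes = _binarize(np.stack(pages, axis=0))
    return TraceStack(planes=planes, geometry=geometry, label=label or path.stem)


def _warn_on_conflicting_resolution_tags(
    tif: tifffile.TiffFile, geometry: StackGeometry, path: Path
) -> None:
    """Log a warning when embedded XResolution disagrees with the sidecar.

    The sidecar geometry always wins; TIFF resolution-unit dialects are too
    inconsistent to trust for calibration.
    """
    if geometry.pixel_size_xy is None:
        return
    try:
        tag = tif.pages[0].tags.get("XResolution")
        if tag is None:
            return
        num, den = tag.value
        if num == 0:
            return
        tag_pixel_size = den / num  # units per pixel in the tag's own unit
    except Exception:  # malformed tags are ignored outright
        return
    if not math.isclose(tag_pixel_size, geometry.pixel_size_xy, rel_tol=0.01):
        logger.warning(
            "%s: embedded XResolution implies %.4g per pixel but sidecar says "
            "%.4g um; using the sidecar",
            path,
            tag_pixel_size,
            geometry.pixel_size_xy,
        )


def save_trace_stack(stack: TraceStack, path: str | Path) -> None:
    """Write a stack as an 8-bit multi-page TIFF with values {0, 1}."""
    tifffile.imwrite(Path(path), stack.planes, photometric="minisblack")


# --- geometry sidecar -------------------------------------------------------

_GEOMETRY_KEYS = ("n_sections", "z_spacing_um", "pixel_size_um", "label")


def write_geometry(geometry: StackGeometry, path: str | Path, label: str = "") -> None:
    """Write stack geometry to a ``key = value`` sidecar file."""
    lines = [
        f"n_sections = {geometry.n_sections}",
        f"z_spacing_um = {geometry.z_spacing!r}",
        f"pixel_size_um = {'unknown' if geometry.pixel_size_xy is None else repr(geometry.pixel_size_xy)}",
        f"label = {label}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_geometry(path: str | Path) -> tuple[StackGeometry, str]:
    """Read a geometry sidecar; returns ``(geometry, label)``."""
    fields: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        fields[key.strip()] = value.strip()
    missing = [k for k in ("n_sections", "z_spacing_um") if k not in fields]
    if missing:
        raise FormatError(f"{path}: missing required geometry keys {missing}")
    pixel_size = fields.get("pixel_size_um", "unknown")
    geometry = StackGeometry(
        n_sections=int(fields["n_sections"]),
        z_spacing=float(fields["z_spacing_um"]),
        pixel_size_xy=None if pixel_size in ("unknown", "", "none") else float(pixel_size),
    )
    return geometry, fields.get("label", "")


# --- segment tables ---------------------------------------------------------

SEGMENT_TABLE_COLUMNS = (
    "segment_id",
    "plane_index",
    "pixel_count",
    "centroid_x",
    "centroid_y",
    "mu20",
    "mu02",
    "mu11",
    "angle_deg",
    "bin_index",
)


def validate_segment_table(table: pd.DataFrame, n_bins: Optional[int] = None) -> None:
    """Check segment-table invariants, naming the offending file line.

    Degenerate segments carry NaN ``angle_deg`` and a missing ``bin_index``;
    all other rows need an angle in [0, 180) and, when ``n_bins`` is known,
    a bin index in [0, n_bins).
    """
    if list(table.columns) != list(SEGMENT_TABLE_COLUMNS):
        raise FormatError(
            f"segment table header must be {list(SEGMENT_TABLE_COLUMNS)}, "
            f"got {list(table.columns)}"
        )
    if table["segment_id"].duplicated().any():
        dup = int(table["segment_id"][table["segment_id"].duplicated()].iloc[0])
        raise FormatError(f"duplicate segment_id {dup}")
    for idx, row in table.iterrows():
        line = int(idx) + 2  # header is line 1
        angle = row["angle_deg"]
        if not pd.isna(angle) and not (0.0 <= angle < 180.0):
            raise FormatError(f"line {line}: angle_deg {angle} outside [0, 180)")
        bin_index = row["bin_index"]
        if not pd.isna(bin_index):
            if bin_index < 0 or (n_bins is not None and bin_index >= n_bins):
                raise FormatError(f"line {line}: bin_index {bin_index} out of range")
        if row["plane_index"] < 0:
            raise FormatError(f"line {line}: negative plane_index")


def write_segment_table(orientation_map, path: str | Path) -> None:
    """Write one tab-separated row per segment of an annotated orientation map.

    Numeric fields are written at full ``repr`` precision so that the table
    round-trips losslessly through :func:`read_segment_table`.
    """
    rows = []
    for entry in orientation_map.entries:
        seg, m, ax = entry.segment, entry.moments, entry.axial
        rows.append(
            {
                "segment_id": seg.segment_id,
                "plane_index": seg.plane_index,
                "pixel_count": seg.pixel_count,
                "centroid_x": m.centroid_x,
                "centroid_y": m.centroid_y,
                "mu20": m.mu20,
                "mu02": m.mu02,
                "mu11": m.mu11,
                "angle_deg": np.nan if ax.degenerate else ax.angle_deg,
                "bin_index": pd.NA if ax.degenerate else ax.bin_index,
            }
        )
    table = pd.DataFrame(rows, columns=SEGMENT_TABLE_COLUMNS)
    table["bin_index"] = table["bin_index"].astype("Int64")
    table.to_csv(Path(path), sep="\t", index=False)


def read_segment_table(path: str | Path, n_bins: Optional[int] = None) -> pd.DataFrame:
    """Read a segment table written by :func:`write_segment_table`.

    Returns a DataFrame with the documented columns; raises
    :class:`~fibermap.errors.FormatError` naming the offending line when a
    row violates the table invariants.
    """
    try:
        table = pd.read_csv(
            Path(path),
            sep="\t",
            dtype={
                "segment_id": "int64",
                "plane_index": "int64",
                "pixel_count": "int64",
                "bin_index": "Int64",
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed segment table: {exc}") from exc
    validate_segment_table(table, n_bins=n_bins)
    return table
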