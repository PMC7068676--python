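"""Projections, hue-coded orientation maps, and axial order statistics.

Two visual outputs are produced per stack: a binary maximum projection of
the retained trace pixels, and an RGB projection in which every segment is
painted with the color of its orientation bin from a "rainbow ruler" hue
look-up table.  Quantitatively, a field of axial angles {θ_i} with weights
{w_i} is summarized by the nematic order parameter

    S = |Σ w_i e^{i·2θ_i}| / Σ w_i,          mean axis = ½·arg(Σ w_i e^{i·2θ_i})

(angles doubled because orientations are defined modulo 180°): S = 1 for a
perfectly parallel field, S → 0 for an isotropic one.  Comparing S between
two conditions quantifies "more ordered vs less ordered" without attaching
an inferential p-value.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, DomainError
from .orientation_core import DEFAULT_N_BINS, AnnotatedSegment
from .trace_io import TraceStack

__all__ = [
    "OrientationMap",
    "AngularHistogram",
    "AxialOrderSummary",
    "HueLUT",
    "ComparisonReport",
    "hue_lut",
    "project_binary",
    "render_colored_projection",
    "angular_histogram",
    "axial_order",
    "compare_conditions",
    "lut_ruler",
    "write_projection_png",
    "write_projection_tiff",
    "write_histogram",
]

DEGENERATE_GRAY = (128, 128, 128)


@dataclass
class OrientationMap:
    """All annotated segments of one stack, ready for rendering and stats."""

    label: str
    entries: list[AnnotatedSegment]
    n_bins: int
    image_shape: tuple[int, int]
    n_sections: int

    def __post_init__(self) -> None:
        w = 180.0 / self.n_bins
        for e in self.entries:
            if e.degenerate:
                continue
            if e.bin_index != int(e.angle_deg / w) and e.bin_index != min(
                int(e.angle_deg / w), self.n_bins - 1
            ):
                raise ConfigurationError(
                    f"segment {e.segment.segment_id}: bin {e.bin_index} "
                    f"inconsistent with angle {e.angle_deg}"
                )

    @property
    def non_degenerate(self) -> list[AnnotatedSegment]:
        return [e for e in self.entries if not e.degenerate]

    @property
    def n_segments(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class AngularHistogram:
    """Per-bin counts of non-degenerate segments (or their pixels)."""

    counts: np.ndarray
    weighting: str
    total: int

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[0])

    def occupied_bins(self) -> set[int]:
        return {int(i) for i in np.nonzero(self.counts)[0]}


@dataclass(frozen=True)
class AxialOrderSummary:
    """Nematic order parameter and mean axis of a segment set.

    ``order_parameter`` lies in [0, 1]; ``mean_axis_deg`` is undefined
    (None) when the field is perfectly balanced (S = 0).
    """

    order_parameter: float
    mean_axis_deg: Optional[float]
    n_segments: int
    weighting: str


@dataclass(frozen=True)
class HueLUT:
    """Orientation-bin → RGB map with monotonically varying hue."""

    colors: np.ndarray  # (n_bins, 3) uint8
    start_hue: float
    end_hue: float

    def __post_init__(self) -> None:
        colors = np.asarray(self.colors, dtype=np.uint8)
        if colors.ndim != 2 or colors.shape[1] != 3:
            raise ConfigurationError(f"LUT colors must be (n, 3), got {colors.shape}")
        if len({tuple(c) for c in colors}) != colors.shape[0]:
            raise ConfigurationError("LUT entries must be pairwise distinct")
        object.__setattr__(self, "colors", colors)

    @property
    def n_bins(self) -> int:
        return int(self.colors.shape[0])


def hue_lut(
    n_bins: int = DEFAULT_N_BINS, start_hue: float = 0.0, end_hue: float = 300.0
) -> HueLUT:
    """Rainbow-ruler LUT: HSV hue swept linearly across the bins.

    The default 0° (red) → 300° (magenta) span keeps bin 0 and bin
    ``n_bins - 1`` visually distinct despite the axial wrap at 180°.
    """
    if n_bins < 1:
        raise ConfigurationError(f"n_bins must be >= 1, got {n_bins}")
    hues = np.linspace(start_hue, end_hue, n_bins)
    colors = np.array(
        [
            [round(255 * c) for c in colorsys.hsv_to_rgb((h % 360.0) / 360.0, 1.0, 1.0)]
            for h in hues
        ],
        dtype=np.uint8,
    )
    return HueLUT(colors=colors, start_hue=start_hue, end_hue=end_hue)


def _resolve_z_range(
    z_range: Optional[tuple[int, int]], n_sections: int
) -> tuple[int, int]:
    if z_range is None:
        return 0, n_sections
    lo, hi = z_range
    lo, hi = max(int(lo), 0), min(int(hi), n_sections)
    if hi <= lo:
        raise DomainError(f"empty z_range {z_range} for {n_sections} sections")
    return lo, hi


def project_binary(
    source: Union[TraceStack, OrientationMap],
    z_range: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Per-pixel maximum projection over the selected optical sections.

    ``z_range`` is a half-open ``(start, stop)`` section interval, default
    all sections.  Given a stack, every foreground pixel projects; given an
    orientation map, only retained segment pixels project.
    """
    if isinstance(source, TraceStack):
        lo, hi = _resolve_z_range(z_range, source.n_sections)
        return source.planes[lo:hi].max(axis=0)
    lo, hi = _resolve_z_range(z_range, source.n_sections)
    out = np.zeros(source.image_shape, dtype=np.uint8)
    for e in source.entries:
        if lo <= e.segment.plane_index < hi:
            px = e.segment.pixels
            out[px[:, 1], px[:, 0]] = 1
    return out


def render_colored_projection(
    orientation_map: OrientationMap,
    lut: Optional[HueLUT] = None,
    z_range: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Hue-coded projection: each segment painted with its bin's color.

    Degenerate segments are painted a reserved neutral gray; background is
    black.  Where segments from different planes overlap in projection the
    topmost (largest plane index) wins.
    """
    if lut is None:
        lut = hue_lut(orientation_map.n_bins)
    if lut.n_bins != orientation_map.n_bins:
        raise ConfigurationError(
            f"LUT has {lut.n_bins} entries but map uses {orientation_map.n_bins} bins"
        )
    lo, hi = _resolve_z_range(z_range, orientation_map.n_sections)
    h, w = orientation_map.image_shape
    img = np.zeros((h, w, 3), dtype=np.uint8)
    for e in sorted(orientation_map.entries, key=lambda e: e.segment.plane_index):
        if not (lo <= e.segment.plane_index < hi):
            continue
        color = DEGENERATE_GRAY if e.degenerate else tuple(lut.colors[e.bin_index])
        px = e.segment.pixels
        img[px[:, 1], px[:, 0]] = color
    return img


def angular_histogram(
    orientation_map: OrientationMap, weighting: str = "segment"
) -> AngularHistogram:
    """Bin occupancies of the map's non-degenerate segments.

    ``weighting='segment'`` counts each segment once (the traced unit is the
    whole vector); ``'pixel'`` counts each segment's pixels, giving longer
    fibers proportionally more weight.
    """
    if weighting not in ("segment", "pixel"):
        raise DomainError(f"weighting must be 'segment' or 'pixel', got {weighting!r}")
    counts = np.zeros(orientation_map.n_bins, dtype=np.int64)
    for e in orientation_map.non_degenerate:
        counts[e.bin_index] += 1 if weighting == "segment" else e.segment.pixel_count
    return AngularHistogram(counts=counts, weighting=weighting, total=int(counts.sum()))


def _angles_and_weights(
    source: Union[OrientationMap, Iterable], weighting: str
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(source, OrientationMap):
        entries = source.non_degenerate
        angles = np.array([e.angle_deg for e in entries], dtype=np.float64)
        if weighting == "pixel":
            weights = np.array([e.segment.pixel_count for e in entries], dtype=np.float64)
        else:
            weights = np.ones(len(entries))
        return angles, weights
    angles = np.asarray(list(source), dtype=np.float64)
    return angles, np.ones(angles.shape[0])


def axial_order(
    source: Union[OrientationMap, Sequence[float]], weighting: str = "segment"
) -> AxialOrderSummary:
    """Nematic order parameter S and mean axis of an axial-angle field.

    With doubled angles φ_i = 2θ_i, S = |Σ w e^{iφ}| / Σ w and the mean axis
    is ½·arg(Σ w e^{iφ}) mapped into [0, 180).  Accepts an annotated map
    (degenerate segments excluded) or a plain sequence of angles in degrees.
    """
    if weighting not in ("segment", "pixel"):
        raise DomainError(f"weighting must be 'segment' or 'pixel', got {weighting!r}")
    angles, weights = _angles_and_weights(source, weighting)
    if angles.size == 0:
        raise DomainError("axial_order requires at least one non-degenerate angle")
    phi = np.radians(2.0 * angles)
    resultant = np.sum(weights * np.exp(1j * phi)) / np.sum(weights)
    s = float(np.abs(resultant))
    if s < 1e-12:
        mean_axis = None
        s = 0.0
    else:
        mean_axis = float(np.degrees(np.angle(resultant)) / 2.0) % 180.0
    return AxialOrderSummary(
        order_parameter=min(s, 1.0),
        mean_axis_deg=mean_axis,
        n_segments=int(angles.size),
        weighting=weighting,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side order statistics for two conditions (e.g. control vs mutant)."""

    label_a: str
    label_b: str
    summary_a: AxialOrderSummary
    summary_b: AxialOrderSummary
    histogram_a: AngularHistogram
    histogram_b: AngularHistogram
    delta_order_parameter: float


def compare_conditions(
    map_a: OrientationMap, map_b: OrientationMap, weighting: str = "segment"
) -> ComparisonReport:
    """Compare orientation order between two annotated maps.

    Reports per-map order parameter, mean axis and histograms, and the
    difference S_a − S_b.  No hypothesis test is attached: the comparison
    supports qualitative more/less-ordered statements.
    """
    if map_a.n_bins != map_b.n_bins:
        raise ConfigurationError(
            f"n_bins mismatch: {map_a.n_bins} vs {map_b.n_bins}"
        )
    sa = axial_order(map_a, weighting)
    sb = axial_order(map_b, weighting)
    return ComparisonReport(
        label_a=map_a.label,
        label_b=map_b.label,
        summary_a=sa,
        summary_b=sb,
        histogram_a=angular_histogram(map_a, weighting),
        histogram_b=angular_histogram(map_b, weighting),
        delta_order_parameter=sa.order_parameter - sb.order_parameter,
    )


# --- file outputs -----------------------------------------------------------


def lut_ruler(lut: HueLUT, bin_width_px: int = 8, height_px: int = 16) -> np.ndarray:
    """Render the LUT as a horizontal color-strip legend ("rainbow ruler")."""
    strip = np.repeat(lut.colors[np.newaxis, :, :], height_px, axis=0)
    return np.repeat(strip, bin_width_px, axis=1)


def write_projection_png(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB (or grayscale) projection as an 8-bit PNG."""
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8), extension=".png")


def write_projection_tiff(image: np.ndarray, path: str | Path) -> None:
    """Write a binary projection as a single-page 8-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def write_histogram(hist: AngularHistogram, path: str | Path) -> None:
    """Write an angular histogram as a tab-separated table."""
    width = 180.0 / hist.n_bins
    table = pd.DataFrame(
        {
            "bin_index": np.arange(hist.n_bins),
            "angle_lo_deg": np.arange(hist.n_bins) * width,
            "angle_hi_deg": (np.arange(hist.n_bins) + 1) * width,
            "count": hist.counts,
        }
    )
    table.to_csv(Path(path), sep="\t", index=False)
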