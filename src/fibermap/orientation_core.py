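"""Per-segment axial orientation from second-order central moments.

For a segment with pixel coordinates :math:`(x_i, y_i)` the unweighted
central moments are

.. math::

    \\mu_{20} = \\sum_i (x_i-\\bar x)^2,\\quad
    \\mu_{02} = \\sum_i (y_i-\\bar y)^2,\\quad
    \\mu_{11} = \\sum_i (x_i-\\bar x)(y_i-\\bar y),

and the principal (long) axis makes the angle

.. math::

    \\theta = \\tfrac12\\,\\operatorname{atan2}(2\\mu_{11},\\,
              \\mu_{20}-\\mu_{02})

with the +x direction, measured toward +y (image frame, y down).  Fibers
are axial objects — a fiber at θ and θ+180° is the same orientation — so
angles are reduced modulo 180° into [0°, 180°) and discretized into
``n_bins`` equal half-open bins (default 32, bin width 5.625°).

Segments with no preferred axis (μ20 = μ02 and μ11 = 0, e.g. a symmetric
blob or a single pixel) are flagged degenerate rather than assigned an
arbitrary angle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError
from .segment_decomposition import FiberSegment

logger = logging.getLogger("fibermap")

__all__ = [
    "DEFAULT_N_BINS",
    "CentralMoments",
    "AxialAngle",
    "AnnotatedSegment",
    "central_moments",
    "orientation_angle",
    "normalize_and_bin",
    "annotate_segments",
    "axial_difference_deg",
]

DEFAULT_N_BINS = 32

# relative degeneracy tolerance: moment differences below this times the
# pixel count carry no orientation signal, only rounding noise
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class CentralMoments:
    """Second-order central moments (squared pixels) about the centroid."""

    mu20: float
    mu02: float
    mu11: float
    centroid_x: float
    centroid_y: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.mu20 < 0 or self.mu02 < 0:
            raise DomainError("mu20 and mu02 must be non-negative")
        # Cauchy-Schwarz, with a little slack for accumulated rounding
        bound = math.sqrt(self.mu20 * self.mu02)
        if abs(self.mu11) > bound + 1e-9 * (1.0 + bound):
            raise DomainError(
                f"|mu11|={abs(self.mu11)} exceeds sqrt(mu20*mu02)={bound}"
            )


@dataclass(frozen=True)
class AxialAngle:
    """An axial orientation in [0, 180) with its histogram bin.

    ``degenerate`` marks segments with no preferred axis; such entries carry
    neither an angle nor a bin and are excluded from statistics downstream.
    """

    angle_deg: Optional[float]
    bin_index: Optional[int] = None
    n_bins: Optional[int] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            if self.angle_deg is None or not (0.0 <= self.angle_deg < 180.0):
                raise DomainError(f"angle_deg must lie in [0, 180), got {self.angle_deg}")
            if self.bin_index is not None:
                if self.n_bins is None or not (0 <= self.bin_index < self.n_bins):
                    raise DomainError(
                        f"bin_index {self.bin_index} invalid for n_bins {self.n_bins}"
                    )


def central_moments(pixels: Sequence | np.ndarray) -> CentralMoments:
    """Unweighted second-order central moments of a pixel (or point) set.

    Accepts integer pixel coordinates or real-valued points, shape ``(n, 2)``
    as (x, y).  Each point counts once; the traced vectors carry no
    intensity, so no weighting is applied.
    """
    pts = np.asarray(pixels, dtype=np.float64)
    if pts.size == 0:
        raise DomainError("cannot compute moments of an empty pixel set")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError(f"pixels must be (n, 2), got shape {pts.shape}")
    centroid = pts.mean(axis=0)
    dx = pts[:, 0] - centroid[0]
    dy = pts[:, 1] - centroid[1]
    return CentralMoments(
        mu20=float(np.dot(dx, dx)),
        mu02=float(np.dot(dy, dy)),
        mu11=float(np.dot(dx, dy)),
        centroid_x=float(centroid[0]),
        centroid_y=float(centroid[1]),
        n_pixels=int(pts.shape[0]),
    )


def orientation_angle(m: CentralMoments) -> AxialAngle:
    """Principal-axis angle of a moment set, in degrees in [0, 180).

    Uses the branch-free form θ = ½·atan2(2μ11, μ20−μ02), identical to the
    leading eigenvector of the covariance matrix.  Returns a degenerate flag
    when the segment has fewer than 2 pixels or no preferred axis.
    """
    tol = _DEGENERACY_RTOL * max(m.n_pixels, 1)
    if m.n_pixels < 2 or (abs(m.mu20 - m.mu02) < tol and abs(m.mu11) < tol):
        return AxialAngle(angle_deg=None, degenerate=True)
    theta = 0.5 * math.atan2(2.0 * m.mu11, m.mu20 - m.mu02)
    angle = math.degrees(theta) % 180.0
    if angle >= 180.0:  # guard the floating-point upper edge
        angle = 0.0
    return AxialAngle(angle_deg=angle)


def normalize_and_bin(angle_deg: float, n_bins: int = DEFAULT_N_BINS) -> AxialAngle:
    """Reduce any real angle modulo 180 and assign its half-open bin.

    Bin k covers [k·w, (k+1)·w) with w = 180/n_bins; the upper edge 180°
    wraps to 0° / bin 0, as forced by the axial topology.
    """
    if n_bins < 1:
        raise DomainError(f"n_bins must be >= 1, got {n_bins}")
    if not math.isfinite(angle_deg):
        raise DomainError(f"angle must be finite, got {angle_deg}")
    angle = float(angle_deg) % 180.0
    if angle >= 180.0:
        angle = 0.0
    bin_index = int(angle / (180.0 / n_bins))
    if bin_index >= n_bins:  # floating-point edge just below 180
        bin_index = n_bins - 1
    return AxialAngle(angle_deg=angle, bin_index=bin_index, n_bins=n_bins)


@dataclass(frozen=True)
class AnnotatedSegment:
    """A fiber segment together with its moments and axial orientation."""

    segment: FiberSegment
    moments: CentralMoments
    axial: AxialAngle

    @property
    def degenerate(self) -> bool:
        return self.axial.degenerate

    @property
    def angle_deg(self) -> Optional[float]:
        return self.axial.angle_deg

    @property
    def bin_index(self) -> Optional[int]:
        return self.axial.bin_index


def annotate_segments(
    segments: Sequence[FiberSegment], n_bins: int = DEFAULT_N_BINS
) -> list[AnnotatedSegment]:
    """Attach moments and binned axial angles to every segment.

    Degenerate segments are retained but flagged (and counted in the log);
    downstream histograms and order statistics exclude them.
    """
    entries: list[AnnotatedSegment] = []
    n_degenerate = 0
    for seg in segments:
        m = central_moments(seg.pixels)
        ax = orientation_angle(m)
        if ax.degenerate:
            n_degenerate += 1
        else:
            ax = normalize_and_bin(ax.angle_deg, n_bins)
        entries.append(AnnotatedSegment(segment=seg, moments=m, axial=ax))
    if n_degenerate:
        logger.info("%d of %d segments degenerate (no preferred axis)", n_degenerate, len(segments))
    return entries


def axial_difference_deg(a: float, b: float) -> float:
    """Smallest angular distance between two axial angles, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
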