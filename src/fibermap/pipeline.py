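"""End-to-end orchestration: trace stack in, annotated orientation map out."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .mapping_and_statistics import OrientationMap
from .orientation_core import DEFAULT_N_BINS, annotate_segments
from .segment_decomposition import decompose_stack
from .trace_io import TraceStack

__all__ = ["PipelineParams", "analyze_stack"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable parameters of the orientation pipeline.

    connectivity : 4 or 8
        Pixel neighborhood for branch-point removal and component labeling;
        8 by default, since hand-drawn diagonal strokes are 8-connected.
    min_segment_length : int
        Minimum pixel count for a retained segment (default 5); shorter
        components are junction debris and are dropped.
    thinning : bool
        Morphological skeletonization pre-step for traces thicker than the
        assumed 1-pixel drawn lines (off by default).
    n_bins : int
        Angular bins spanning 0-180 degrees (default 32).
    """

    connectivity: int = 8
    min_segment_length: int = 5
    thinning: bool = False
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ConfigurationError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.min_segment_length < 1:
            raise ConfigurationError("min_segment_length must be >= 1")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")


def analyze_stack(stack: TraceStack, params: PipelineParams | None = None) -> OrientationMap:
    """Run the full per-stack analysis.

    Each plane is branch-pruned and decomposed into fiber segments, every
    segment receives its central moments and binned axial angle, and the
    result is packed into an :class:`OrientationMap` ready for projection,
    rendering and order statistics.
    """
    params = params or PipelineParams()
    segments = decompose_stack(
        stack,
        connectivity=params.connectivity,
        min_segment_length=params.min_segment_length,
        thinning=params.thinning,
    )
    entries = annotate_segments(segments, n_bins=params.n_bins)
    return OrientationMap(
        label=stack.label,
        entries=entries,
        n_bins=params.n_bins,
        image_shape=stack.shape,
        n_sections=stack.n_sections,
    )
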