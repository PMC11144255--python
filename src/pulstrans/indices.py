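"""Pulsatility index (Gosling) and damping factor, with the locus-based root protocol.

``p_pi = (q_max - q_min) / q_mean`` over one cardiac cycle, and
``p_df = p_pi(distal) / p_pi(proximal)`` between two user-chosen loci along a
perfusion path.  Root-level summaries average a proximal locus against one or
more distal loci (e.g. the starts of the M1 and A1 segments against the C3
level of an internal carotid), and global values average the available roots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import FlowTrace, ValidationError, VesselSegment, VascularNetwork

__all__ = [
    "RootIndices",
    "compute_ppi",
    "windowed_ppi",
    "compute_pdf",
    "root_indices",
    "global_indices",
]

Locus = tuple[str, int]  # (segment_id, positional index along the segment)


def compute_ppi(trace: FlowTrace) -> float:
    """Pulsatility index (max - min) / mean of a flow trace."""
    mean = trace.q_mean
    if mean == 0:
        raise ValidationError("pulsatility index undefined for zero-mean flow")
    return (trace.q_max - trace.q_min) / mean


def windowed_ppi(segment: VesselSegment, index: int, half_width: int = 2) -> float:
    """Mean p_pi over a stencil centred on ``index``, truncated at segment ends."""
    n = len(segment)
    if not 0 <= index < n:
        raise IndexError(f"index {index} outside segment of length {n}")
    if half_width < 0:
        raise ValidationError("half_width must be >= 0")
    lo, hi = max(0, index - half_width), min(n, index + half_width + 1)
    vals = [compute_ppi(c.trace) for c in segment.cross_sections[lo:hi]]
    return float(np.mean(vals))


def compute_pdf(p_pi_distal: float, p_pi_proximal: float) -> float:
    """Damping factor: ratio of distal to proximal pulsatility."""
    if p_pi_proximal <= 0:
        raise ValidationError("proximal p_pi must be positive")
    return p_pi_distal / p_pi_proximal


@dataclass(frozen=True)
class RootIndices:
    """Locus-protocol pulsatility summary for one root vessel."""

    root_segment_id: str
    p_pi_proximal: float
    p_pi_distal: float
    p_df: float


def root_indices(
    network: VascularNetwork,
    proximal_locus: Locus,
    distal_loci: Sequence[Locus],
    half_width: int = 2,
) -> RootIndices:
    """Windowed p_pi at the proximal locus, mean over the distal loci, and p_df.

    A single distal locus is allowed (anatomical variants, e.g. a missing A1
    segment, leave only one distal vessel).
    """
    if not distal_loci:
        raise ValidationError("at least one distal locus is required")

    def _at(locus: Locus) -> float:
        sid, idx = locus
        if sid not in network.segments:
            raise ValidationError(f"locus segment {sid!r} not in network")
        return windowed_ppi(network.segments[sid], idx, half_width)

    proximal = _at(proximal_locus)
    distal = float(np.mean([_at(l) for l in distal_loci]))
    return RootIndices(
        root_segment_id=network.root_segment_id,
        p_pi_proximal=proximal,
        p_pi_distal=distal,
        p_df=compute_pdf(distal, proximal),
    )


def global_indices(root_results: Sequence[RootIndices]) -> tuple[float, float]:
    """Global (p_pi, p_df): arithmetic means over the available roots.

    Missing roots are simply omitted from the sequence by the caller.
    """
    results = [r for r in root_results if r is not None]
    if not results:
        raise ValidationError("no root indices available")
    p_pi = float(np.mean([r.p_pi_proximal for r in results]))
    p_df = float(np.mean([r.p_df for r in results]))
    return p_pi, p_df
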