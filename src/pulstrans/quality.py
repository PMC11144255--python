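"""Per-cross-section quality score Q and its four component terms.

Q sums four dimensionless metrics evaluated on a 5-point stencil centred on
the point of interest (truncated at segment ends):

* circularity — stencil mean of r_min/r_max of the segmented cross-section;
* mean-flow conservation — 1 - sigma/mu of the per-point mean flow;
* area conservation — 1 - sigma/mu of the cross-section area;
* waveform conservation — 1 - delta_q/mu of the mean flow, where delta_q is
  the phase-averaged spread (max - min over the stencil) of the flow traces.

A perfectly circular, locally mass-conserving vessel scores the maximum
Q = 4.  Terms are not clamped below zero: badly corrupted stencils can score
arbitrarily low, which is exactly what the downstream Q >= 2.5 cut exploits.
Standard deviations use the population convention (divide by n) since the
stencil is a fixed window, not a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CrossSection, FlowTrace, ValidationError, VesselSegment

__all__ = ["QualityScore", "circularity", "delta_q", "quality"]


@dataclass(frozen=True)
class QualityScore:
    circularity_term: float
    flow_cv_term: float
    area_cv_term: float
    waveform_term: float

    @property
    def q_total(self) -> float:
        return (
            self.circularity_term
            + self.flow_cv_term
            + self.area_cv_term
            + self.waveform_term
        )


def circularity(cross_section: CrossSection) -> float:
    """Ratio of minimum to maximum in-plane radius, in (0, 1]."""
    if cross_section.r_max <= 0 or cross_section.r_min <= 0:
        raise ValidationError("radii must be positive")
    return cross_section.r_min / cross_section.r_max


def delta_q(traces: Sequence[FlowTrace]) -> float:
    """Phase-averaged spread of neighbouring flow traces (mL/s).

    (1/S) * sum_t [max over the stencil of q(., t) - min over the stencil].
    Zero iff all traces agree at every phase.
    """
    if not traces:
        raise ValidationError("empty stencil")
    phases = {t.n_phases for t in traces}
    if len(phases) > 1:
        raise ValidationError(f"traces have mismatched phase counts {sorted(phases)}")
    stack = np.stack([t.values for t in traces])
    return float(np.mean(stack.max(axis=0) - stack.min(axis=0)))


def quality(segment: VesselSegment, index: int, half_width: int = 2) -> QualityScore:
    """Quality score of one cross-section from its local stencil."""
    n = len(segment)
    if not 0 <= index < n:
        raise IndexError(f"index {index} outside segment of length {n}")
    lo, hi = max(0, index - half_width), min(n, index + half_width + 1)
    stencil = segment.cross_sections[lo:hi]

    circ = np.array([circularity(c) for c in stencil])
    q_mean = np.array([c.trace.q_mean for c in stencil])
    area = np.array([c.area for c in stencil])

    mu_q = float(q_mean.mean())
    mu_area = float(area.mean())
    if mu_q <= 0:
        raise ValidationError("stencil mean flow must be positive")
    if mu_area <= 0:
        raise ValidationError("stencil mean area must be positive")

    dq = delta_q([c.trace for c in stencil])
    return QualityScore(
        circularity_term=float(circ.mean()),
        flow_cv_term=1.0 - float(q_mean.std()) / mu_q,
        area_cv_term=1.0 - float(area.std()) / mu_area,
        waveform_term=1.0 - dq / mu_q,
    )
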