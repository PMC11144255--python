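"""Quality-thresholded, quality-weighted linear fit of pulsatility versus distance.

The transmission coefficient p_tc is the slope of the weighted least-squares
line ``p_pi = p_tc * d + beta`` over every high-quality cross-section of a
rooted subvascular tree, with distance d measured along the centreline from
the root inlet.  Samples with quality Q below the threshold (default 2.5)
are discarded; the rest are weighted linearly from 0 at the threshold to 1
at the score ceiling Q_max = 4.

Distances are carried in mm internally; slopes are reported per metre
(p_pi/m), the scale on which root slopes typically span roughly -2 to 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import FitConfig, ValidationError, VascularNetwork
from .indices import compute_ppi
from .quality import quality

__all__ = [
    "PulsatilitySample",
    "TransmissionFit",
    "compute_weight",
    "compute_profiles",
    "collect_samples",
    "fit_transmission",
    "global_ptc",
]

FIT_MODES = ("weighted", "unweighted", "unthresholded")


@dataclass(frozen=True)
class PulsatilitySample:
    """One cross-section's contribution to the transmission fit."""

    segment_id: str
    index: int
    distance_mm: float
    p_pi: float
    q_score: float
    weight: float  # quality weight in [0, 1]; 0 iff q_score <= threshold
    included: bool = True  # q_score >= threshold at collection time


@dataclass(frozen=True)
class TransmissionFit:
    """Weighted linear fit p_pi = p_tc * d + beta for one root."""

    root_segment_id: str
    p_tc: float  # slope, p_pi per metre
    beta: float  # offset, dimensionless
    weighted_r2: float
    n_included: int
    n_excluded: int


def compute_weight(q_score: float, config: FitConfig = FitConfig()) -> float:
    """Linear quality weight: 0 at/below the threshold, 1 at/above Q_max."""
    if q_score <= config.q_threshold:
        return 0.0
    return min(1.0, (q_score - config.q_threshold) / (config.q_max - config.q_threshold))


def compute_profiles(
    network: VascularNetwork, config: FitConfig = FitConfig()
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-point p_pi and Q arrays for every segment in the rooted tree."""
    ppi: dict[str, np.ndarray] = {}
    q: dict[str, np.ndarray] = {}
    for sid in network.rooted_segment_ids():
        seg = network.segments[sid]
        ppi[sid] = np.array([compute_ppi(c.trace) for c in seg.cross_sections])
        q[sid] = np.array(
            [
                quality(seg, i, config.stencil_half_width).q_total
                for i in range(len(seg))
            ]
        )
    return ppi, q


def collect_samples(
    network: VascularNetwork,
    ppi_profile: Mapping[str, np.ndarray],
    quality_profile: Mapping[str, np.ndarray],
    config: FitConfig = FitConfig(),
) -> list[PulsatilitySample]:
    """One sample per rooted cross-section, with distance, p_pi, Q and weight.

    Samples below the quality threshold get weight 0 and are excluded from
    the default (thresholded) fit modes, but are kept in the list so the
    unthresholded sensitivity mode and exclusion counts can use them.
    """
    rooted = network.rooted_segment_ids()
    if not rooted:
        raise ValidationError("network has no rooted segments")
    distances = network.point_distances()
    samples = []
    for sid in rooted:
        d = distances[sid]
        p = np.asarray(ppi_profile[sid], dtype=float)
        qs = np.asarray(quality_profile[sid], dtype=float)
        if not (len(d) == len(p) == len(qs)):
            raise ValidationError(f"profile lengths disagree for segment {sid!r}")
        for i in range(len(d)):
            samples.append(
                PulsatilitySample(
                    segment_id=sid,
                    index=i,
                    distance_mm=float(d[i]),
                    p_pi=float(p[i]),
                    q_score=float(qs[i]),
                    weight=compute_weight(float(qs[i]), config),
                    included=bool(qs[i] >= config.q_threshold),
                )
            )
    return samples


def _fit_weights(
    samples: Sequence[PulsatilitySample], mode: str, config: FitConfig
) -> np.ndarray:
    if mode == "weighted":
        return np.array([s.weight for s in samples])
    if mode == "unweighted":
        return np.array([s.included for s in samples], dtype=float)
    if mode == "unthresholded":
        return np.ones(len(samples))
    raise ValueError(f"unknown fit mode {mode!r}; expected one of {FIT_MODES}")


def fit_transmission(
    samples: Sequence[PulsatilitySample],
    mode: str = "weighted",
    config: FitConfig = FitConfig(),
    root_segment_id: str = "",
) -> TransmissionFit:
    """Closed-form weighted least squares of p_pi against distance.

    Modes: ``weighted`` (quality weights, the default), ``unweighted``
    (weight 1 for every sample passing the Q threshold) and
    ``unthresholded`` (weight 1 for everything) — the latter two exist for
    sensitivity comparisons.

    The weighted R^2 is 1 - SSres_w / SStot_w with the total sum of squares
    taken about the weighted mean of p_pi.
    """
    if not samples:
        raise ValidationError("no samples to fit")
    w = _fit_weights(samples, mode, config)
    if mode == "unthresholded":
        keep = np.ones(len(samples), dtype=bool)
    else:
        keep = np.array([s.included for s in samples], dtype=bool)
    x = np.array([s.distance_mm for s in samples])[keep] / 1000.0  # metres
    y = np.array([s.p_pi for s in samples])[keep]
    w = w[keep]
    n_included = int(keep.sum())
    n_excluded = int(len(samples) - n_included)
    if n_included < 2 or np.unique(x).size < 2:
        raise ValidationError("fit needs >= 2 included samples at distinct distances")
    sw = float(w.sum())
    if sw <= 0:
        raise ValidationError("total weight must be positive")
    sx = float((w * x).sum())
    sy = float((w * y).sum())
    sxx = float((w * x * x).sum())
    sxy = float((w * x * y).sum())
    denom = sw * sxx - sx * sx
    if denom <= 0:
        raise ValidationError("degenerate design: weighted distances are all equal")
    slope = (sw * sxy - sx * sy) / denom
    beta = (sy - slope * sx) / sw
    resid = y - (slope * x + beta)
    ss_res = float((w * resid**2).sum())
    ss_tot = float((w * (y - sy / sw) ** 2).sum())
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res <= 1e-300 else 0.0
    return TransmissionFit(
        root_segment_id=root_segment_id,
        p_tc=slope,
        beta=beta,
        weighted_r2=r2,
        n_included=n_included,
        n_excluded=n_excluded,
    )


def global_ptc(fits: Sequence[TransmissionFit]) -> float:
    """Global transmission: arithmetic mean of the available root slopes."""
    fits = [f for f in fits if f is not None]
    if not fits:
        raise ValidationError("no fits available")
    return float(np.mean([f.p_tc for f in fits]))
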