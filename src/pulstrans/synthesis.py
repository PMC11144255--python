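"""Synthetic vascular trees, flow waveforms, and the distance-shift error experiment.

The generator emulates the situation the fitting pipeline faces in practice:
a branching polyline tree whose pulsatility decreases linearly with
centreline distance from the root (slope and offset configurable), flow
waveforms sampled over S cardiac phases, junction gaps bridged by straight
lines, and two corruption modes —

* zero-mean symmetric *distance shifts* at junctions, emulating kissing/
  crossing mis-connections that stretch or shrink all downstream distances;
* degraded *segment ends* (eccentric radii, jittered traces), emulating the
  poor cross-section segmentation near bifurcations that the quality score
  is designed to catch.

``run_shift_experiment`` reproduces the Monte-Carlo assessment of how those
junction distance errors propagate into the fitted slope: with a ground
truth slope of -1 p_pi/m and symmetric shifts the fitted slope stays
unbiased, with a spread of a few hundredths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import skew

from .core import (
    Connection,
    CrossSection,
    FlowTrace,
    ValidationError,
    VesselSegment,
    VascularNetwork,
)
from .fitting import PulsatilitySample, fit_transmission

__all__ = [
    "SyntheticSpec",
    "SyntheticTree",
    "ShiftExperimentResult",
    "make_tree",
    "make_flow_traces",
    "inject_shift_errors",
    "run_shift_experiment",
    "corrupt_for_quality",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for synthetic trees, waveforms and corruptions.

    The defaults describe a six-generation bifurcating tree with 90 points
    per segment at 1 mm spacing, pulsatility falling at 1 p_pi/m from an
    offset of 0.9, S = 20 cardiac phases, junction gaps of 8 mm and junction
    shift errors drawn uniformly on ±8 mm (the connectivity search scale).
    The gap equals the shift scale so the gap >= 0 clamp never truncates a
    draw and the shift distribution stays exactly symmetric; segments are
    long relative to the shifts so junction distance errors perturb the
    fitted slope without attenuating it.
    """

    depth: int = 6  # generations of branching below the root
    branch_factor: int = 2
    points_per_segment: int = 90
    step_mm: float = 1.0
    gap_mm: float = 8.0  # straight-line junction gap
    true_slope: float = -1.0  # p_pi per metre
    true_offset: float = 0.9  # p_pi at the root inlet
    ppi_noise_sd: float = 0.0
    shift_scale_mm: float = 8.0  # junction shifts ~ Uniform(-scale, scale)
    n_phases: int = 20
    seed: int = 0
    branch_angle_deg: float = 35.0
    curvature_deg_per_step: float = 1.0
    root_radius_mm: float = 2.0
    radius_decay: float = 0.8  # per generation
    root_flow_mls: float = 5.0  # mean flow at the root, split at branches

    def __post_init__(self) -> None:
        if self.true_offset <= 0:
            raise ValidationError("true_offset must be positive")
        if self.step_mm <= 0:
            raise ValidationError("step_mm must be positive")
        if self.shift_scale_mm < 0:
            raise ValidationError("shift scale must be nonnegative")
        if self.depth < 0 or self.branch_factor < 1:
            raise ValidationError("depth >= 0 and branch_factor >= 1 required")
        if self.points_per_segment < 2:
            raise ValidationError("points_per_segment must be >= 2")
        if self.gap_mm < 0:
            raise ValidationError("gap_mm must be nonnegative")
        if self.n_phases < 2:
            raise ValidationError("n_phases must be >= 2")


@dataclass
class SyntheticTree:
    """A generated network plus its ground truth (the generator's bookkeeping)."""

    spec: SyntheticSpec
    network: VascularNetwork
    true_parent: dict[str, str]  # child id -> parent id
    true_distances: dict[str, np.ndarray]  # mm from root inlet, per point
    generation: dict[str, int]
    target_ppi: dict[str, np.ndarray] | None = None  # set by make_flow_traces
    shifts: dict[str, float] | None = None  # set by inject_shift_errors

    @property
    def segment_ids(self) -> list[str]:
        return list(self.network.rooted_segment_ids())

    def n_points(self) -> int:
        return sum(len(self.network.segments[s]) for s in self.segment_ids)


def _rotate(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(angle_rad * axis).apply(vec)


def _perpendicular(vec: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, vec) * vec
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _constant_trace(flow: float, n_phases: int) -> FlowTrace:
    return FlowTrace(np.full(n_phases, flow))


def make_tree(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> SyntheticTree:
    """Generate a branching polyline tree with geometry, radii and placeholder traces.

    Each segment is a gently curved polyline of ``points_per_segment`` points
    at ``step_mm`` spacing; children branch off the parent terminal at
    ``branch_angle_deg`` around evenly spread azimuths and start ``gap_mm``
    beyond it.  Placeholder traces are constant at the generation's mean
    flow (the root flow split at every branch); call
    :func:`make_flow_traces` to encode a pulsatility profile.

    Ground-truth topology and per-point root distances are stored alongside
    the network.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    segments: dict[str, VesselSegment] = {}
    connections: list[Connection] = []
    true_parent: dict[str, str] = {}
    true_dist: dict[str, np.ndarray] = {}
    generation: dict[str, int] = {}

    root_dir = _rotate(
        np.array([0.0, 0.0, 1.0]),
        np.array([1.0, 0.0, 0.0]),
        math.radians(rng.uniform(-10, 10)),
    )
    # (segment_id, start point, initial direction, generation, inlet distance)
    stack = [("S0", np.zeros(3), root_dir, 0, 0.0)]
    counter = 1
    while stack:
        sid, start, direction, gen, inlet_d = stack.pop(0)
        curve_axis = _perpendicular(direction, rng)
        step_angle = math.radians(spec.curvature_deg_per_step)
        pos = start.copy()
        d = direction.copy()
        radius = spec.root_radius_mm * spec.radius_decay**gen
        flow = spec.root_flow_mls / spec.branch_factor**gen
        points = []
        for k in range(spec.points_per_segment):
            points.append(
                CrossSection(
                    segment_id=sid,
                    order_index=k,
                    position=pos.copy(),
                    tangent=d / np.linalg.norm(d),
                    area=math.pi * radius**2,
                    r_min=radius,
                    r_max=radius,
                    trace=_constant_trace(flow, spec.n_phases),
                )
            )
            if k < spec.points_per_segment - 1:
                d = _rotate(d, curve_axis, step_angle)
                pos = pos + spec.step_mm * d / np.linalg.norm(d)
        seg = VesselSegment(sid, points)
        segments[sid] = seg
        true_dist[sid] = inlet_d + seg.cumulative_arclength()
        generation[sid] = gen

        if gen < spec.depth:
            terminal_dir = seg.terminal.tangent
            azimuth0 = rng.uniform(0, 2 * math.pi)
            perp = _perpendicular(terminal_dir, rng)
            theta = math.radians(spec.branch_angle_deg)
            for b in range(spec.branch_factor):
                azimuth = azimuth0 + 2 * math.pi * b / spec.branch_factor
                lateral = _rotate(perp, terminal_dir, azimuth)
                child_dir = math.cos(theta) * terminal_dir + math.sin(theta) * lateral
                child_dir /= np.linalg.norm(child_dir)
                child_id = f"S{counter}"
                counter += 1
                child_start = seg.terminal.position + spec.gap_mm * child_dir
                gap = float(np.linalg.norm(child_start - seg.terminal.position))
                connections.append(Connection(sid, child_id, gap))
                true_parent[child_id] = sid
                child_inlet_d = true_dist[sid][-1] + gap
                stack.append((child_id, child_start, child_dir, gen + 1, child_inlet_d))

    network = VascularNetwork(
        segments=segments, connections=connections, root_segment_id="S0"
    )
    return SyntheticTree(
        spec=spec,
        network=network,
        true_parent=true_parent,
        true_distances=true_dist,
        generation=generation,
    )


def _sin_samples(n_phases: int) -> np.ndarray:
    return np.sin(2 * math.pi * np.arange(n_phases) / n_phases)


def solve_amplitude(target_ppi: float, n_phases: int) -> float:
    """Relative amplitude a such that M*(1 + a*sin) has exactly the target p_pi.

    For the sampled sinusoid, p_pi = a*(smax - smin)/(1 + a*smean) with
    smax/smin/smean the order statistics of the sampled sine; solving for a
    gives a = target / (smax - smin - target*smean).
    """
    if target_ppi <= 0:
        raise ValidationError(f"target p_pi must be positive, got {target_ppi}")
    s = _sin_samples(n_phases)
    denom = s.max() - s.min() - target_ppi * s.mean()
    if denom <= 0:
        raise ValidationError("target p_pi too large for a raised sinusoid")
    a = target_ppi / denom
    if 1.0 + a * s.min() <= 0:
        # would require the waveform to cross zero (p_pi > ~2 for sampled sines)
        raise ValidationError(
            f"target p_pi {target_ppi} needs a negative-flow excursion"
        )
    return a


def make_flow_traces(
    spec: SyntheticSpec,
    tree: SyntheticTree,
    rng: np.random.Generator | None = None,
) -> SyntheticTree:
    """Replace placeholder traces so each point's exact p_pi follows the linear law.

    The target at distance d (mm) is ``true_offset + true_slope * d/1000``
    plus optional Gaussian noise (added to the target *before* the waveform
    amplitude is solved, so the realised p_pi equals the noisy target to
    machine precision).  Traces are raised sinusoids over S phases with the
    generation's mean flow.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    new_segments: dict[str, VesselSegment] = {}
    targets: dict[str, np.ndarray] = {}
    phases = _sin_samples(spec.n_phases)
    for sid in tree.segment_ids:
        seg = tree.network.segments[sid]
        d = tree.true_distances[sid]
        target = spec.true_offset + spec.true_slope * d / 1000.0
        if spec.ppi_noise_sd > 0:
            target = target + rng.normal(0.0, spec.ppi_noise_sd, size=target.shape)
        if np.any(target <= 0):
            raise ValidationError(
                f"target p_pi non-positive on segment {sid!r}; "
                "offset/slope/noise are incompatible with the tree depth"
            )
        flow = spec.root_flow_mls / spec.branch_factor ** tree.generation[sid]
        cs = []
        for i, c in enumerate(seg.cross_sections):
            a = solve_amplitude(float(target[i]), spec.n_phases)
            cs.append(replace(c, trace=FlowTrace(flow * (1.0 + a * phases))))
        new_segments[sid] = VesselSegment(sid, cs)
        targets[sid] = target
    network = VascularNetwork(
        segments=new_segments,
        connections=list(tree.network.connections),
        root_segment_id=tree.network.root_segment_id,
    )
    return SyntheticTree(
        spec=spec,
        network=network,
        true_parent=dict(tree.true_parent),
        true_distances={k: v.copy() for k, v in tree.true_distances.items()},
        generation=dict(tree.generation),
        target_ppi=targets,
        shifts=None if tree.shifts is None else dict(tree.shifts),
    )


def inject_shift_errors(
    tree: SyntheticTree,
    spec: SyntheticSpec | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticTree:
    """Perturb every junction gap by an independent zero-mean symmetric draw.

    Shifts are Uniform(-scale, scale), clamped so gaps stay nonnegative;
    they displace all downstream distances while the stored ground-truth
    distances (and any pulsatility attached to them) stay untouched.
    """
    spec = tree.spec if spec is None else spec
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    shifts: dict[str, float] = {}
    new_connections = []
    for conn in tree.network.connections:
        draw = float(rng.uniform(-spec.shift_scale_mm, spec.shift_scale_mm))
        shift = max(draw, -conn.gap_length)  # keep gap >= 0
        shifts[conn.child_id] = shift
        new_connections.append(
            Connection(conn.parent_id, conn.child_id, conn.gap_length + shift)
        )
    network = VascularNetwork(
        segments=dict(tree.network.segments),
        connections=new_connections,
        root_segment_id=tree.network.root_segment_id,
    )
    return SyntheticTree(
        spec=tree.spec,
        network=network,
        true_parent=dict(tree.true_parent),
        true_distances={k: v.copy() for k, v in tree.true_distances.items()},
        generation=dict(tree.generation),
        target_ppi=None if tree.target_ppi is None else dict(tree.target_ppi),
        shifts=shifts,
    )


@dataclass(frozen=True)
class ShiftExperimentResult:
    """Fitted slopes (p_pi/m) across Monte-Carlo shift-error cases."""

    slopes: np.ndarray
    true_slope: float

    @property
    def mean(self) -> float:
        return float(self.slopes.mean())

    @property
    def sd(self) -> float:
        return float(self.slopes.std(ddof=1))

    @property
    def skewness(self) -> float:
        return float(skew(self.slopes))


def run_shift_experiment(
    spec: SyntheticSpec,
    n_cases: int = 1000,
    rng: np.random.Generator | None = None,
) -> ShiftExperimentResult:
    """Monte-Carlo assessment of junction distance errors on the fitted slope.

    Per case: generate the tree, assign each point its true pulsatility
    ``offset + slope * d_true`` (plus optional noise, directly — no waveform
    synthesis needed here), inject junction shift errors, and fit the line
    with uniform weights against the *corrupted* distances.  Returns the
    sample of fitted slopes.

    The tree geometry is a deterministic function of the spec, so it is
    built once and only the random draws are repeated per case; the
    propagation of shifts to downstream distances is vectorised over points.
    """
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    tree = make_tree(spec)

    sids = tree.segment_ids
    conn = tree.network.connections
    conn_index = {c.child_id: j for j, c in enumerate(conn)}
    gaps = np.array([c.gap_length for c in conn])
    # Path incidence: which junctions lie between the root and each segment.
    incidence = np.zeros((len(sids), len(conn)))
    for i, sid in enumerate(sids):
        node = sid
        while node in tree.true_parent:
            incidence[i, conn_index[node]] = 1.0
            node = tree.true_parent[node]
    seg_of_point = np.concatenate(
        [np.full(len(tree.network.segments[s]), i) for i, s in enumerate(sids)]
    )
    d_true = np.concatenate([tree.true_distances[s] for s in sids])
    y_clean = spec.true_offset + spec.true_slope * d_true / 1000.0

    slopes = np.empty(n_cases)
    for case in range(n_cases):
        draws = rng.uniform(-spec.shift_scale_mm, spec.shift_scale_mm, size=len(conn))
        shifts = np.maximum(draws, -gaps)
        seg_shift = incidence @ shifts
        x = (d_true + seg_shift[seg_of_point]) / 1000.0  # metres
        y = y_clean
        if spec.ppi_noise_sd > 0:
            y = y + rng.normal(0.0, spec.ppi_noise_sd, size=y.shape)
        # Uniform-weight least squares, closed form.
        xm = x.mean()
        ym = y.mean()
        slopes[case] = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
    return ShiftExperimentResult(slopes=slopes, true_slope=spec.true_slope)


def corrupt_for_quality(
    tree: SyntheticTree,
    spec: SyntheticSpec | None = None,
    rng: np.random.Generator | None = None,
    end_fraction: float = 0.15,
    eccentricity: float = 0.35,
    jitter: float = 0.8,
) -> SyntheticTree:
    """Degrade segment ends: eccentric radii and jittered flow traces.

    The first and last ``end_fraction`` of each segment's points get their
    minimum radius multiplied by ``eccentricity`` and independent Gaussian
    jitter with standard deviation ``jitter * |mean flow|`` added to every
    cardiac phase — emulating the failed cross-section segmentation near
    bifurcations.  With ``end_fraction = 0`` (or jitter 0 and eccentricity
    1) the tree is returned point-for-point unchanged.
    """
    spec = tree.spec if spec is None else spec
    rng = np.random.default_rng(spec.seed + 3) if rng is None else rng
    new_segments: dict[str, VesselSegment] = {}
    for sid in tree.segment_ids:
        seg = tree.network.segments[sid]
        n = len(seg)
        n_end = int(math.ceil(end_fraction * n)) if end_fraction > 0 else 0
        cs = []
        for i, c in enumerate(seg.cross_sections):
            if n_end and (i < n_end or i >= n - n_end):
                noise = rng.normal(
                    0.0, jitter * abs(c.trace.q_mean), size=c.trace.n_phases
                )
                cs.append(
                    replace(
                        c,
                        r_min=c.r_min * eccentricity,
                        trace=FlowTrace(c.trace.values + noise),
                    )
                )
            else:
                cs.append(c)
        new_segments[sid] = VesselSegment(sid, cs)
    network = VascularNetwork(
        segments=new_segments,
        connections=list(tree.network.connections),
        root_segment_id=tree.network.root_segment_id,
    )
    return SyntheticTree(
        spec=tree.spec,
        network=network,
        true_parent=dict(tree.true_parent),
        true_distances={k: v.copy() for k, v in tree.true_distances.items()},
        generation=dict(tree.generation),
        target_ppi=None if tree.target_ppi is None else dict(tree.target_ppi),
        shifts=None if tree.shifts is None else dict(tree.shifts),
    )
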