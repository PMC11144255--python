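"""Domain types for centreline cross-section flow analysis.

The central objects are :class:`CrossSection` (one centreline point with its
geometry and cardiac-cycle flow trace), :class:`VesselSegment` (an ordered,
downstream-oriented run of cross-sections) and :class:`VascularNetwork`
(segments plus the directed, root-connected topology with junction gaps).

Conventions
-----------
* All coordinates and lengths are millimetres; flow is mL/s.
* ``order_index`` is 0-based and increases downstream once a segment has been
  oriented with :func:`orient_segment`.
* Flow is signed: positive means flow in the direction of increasing
  ``order_index`` (i.e. along the stored tangents).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "FlowTrace",
    "CrossSection",
    "VesselSegment",
    "Connection",
    "VascularNetwork",
    "FitConfig",
    "orient_segment",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


def _as_float_vector(x, n: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (n,):
        raise ValidationError(f"{name} must be a length-{n} vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} contains non-finite values")
    return v


@dataclass(frozen=True)
class FlowTrace:
    """A cardiac-cycle flow waveform: one value (mL/s) per cardiac phase."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("a flow trace needs at least 2 cardiac phases")
        if not np.all(np.isfinite(v)):
            raise ValidationError("flow trace contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_phases(self) -> int:
        return int(self.values.size)

    @property
    def q_max(self) -> float:
        return float(self.values.max())

    @property
    def q_min(self) -> float:
        return float(self.values.min())

    @property
    def q_mean(self) -> float:
        return float(self.values.mean())

    def scaled(self, factor: float) -> "FlowTrace":
        return FlowTrace(self.values * factor)


@dataclass
class CrossSection:
    """One centreline point: position, tangent, lumen geometry and flow trace."""

    segment_id: str
    order_index: int
    position: np.ndarray  # (3,) mm
    tangent: np.ndarray  # (3,) unit vector
    area: float  # mm^2
    r_min: float  # mm
    r_max: float  # mm
    trace: FlowTrace

    def __post_init__(self) -> None:
        self.position = _as_float_vector(self.position, 3, "position")
        self.tangent = _as_float_vector(self.tangent, 3, "tangent")
        norm = float(np.linalg.norm(self.tangent))
        if abs(norm - 1.0) > 1e-6:
            raise ValidationError(
                f"tangent of ({self.segment_id}, {self.order_index}) is not unit "
                f"length (|t| = {norm:.8f})"
            )
        if not self.area > 0:
            raise ValidationError(f"area must be positive, got {self.area}")
        if not (0 < self.r_min <= self.r_max):
            raise ValidationError(
                f"radii must satisfy 0 < r_min <= r_max, got "
                f"r_min={self.r_min}, r_max={self.r_max}"
            )


@dataclass
class VesselSegment:
    """An ordered run of cross-sections; inlet first, terminal last."""

    segment_id: str
    cross_sections: list[CrossSection]

    def __post_init__(self) -> None:
        cs = list(self.cross_sections)
        if not cs:
            raise ValidationError(f"segment {self.segment_id!r} has no cross-sections")
        for c in cs:
            if c.segment_id != self.segment_id:
                raise ValidationError(
                    f"cross-section labelled {c.segment_id!r} inside segment "
                    f"{self.segment_id!r}"
                )
        orders = [c.order_index for c in cs]
        if any(b <= a for a, b in zip(orders, orders[1:])):
            raise ValidationError(
                f"segment {self.segment_id!r}: order_index must be strictly increasing"
            )
        phases = {c.trace.n_phases for c in cs}
        if len(phases) > 1:
            raise ValidationError(
                f"segment {self.segment_id!r}: inconsistent phase counts {sorted(phases)}"
            )
        self.cross_sections = cs

    def __len__(self) -> int:
        return len(self.cross_sections)

    @property
    def inlet(self) -> CrossSection:
        return self.cross_sections[0]

    @property
    def terminal(self) -> CrossSection:
        return self.cross_sections[-1]

    @property
    def n_phases(self) -> int:
        return self.inlet.trace.n_phases

    def positions(self) -> np.ndarray:
        return np.stack([c.position for c in self.cross_sections])

    def q_mean(self) -> np.ndarray:
        return np.array([c.trace.q_mean for c in self.cross_sections])

    def cumulative_arclength(self) -> np.ndarray:
        """Arc length (mm) from the inlet to each point, summing Euclidean steps."""
        pos = self.positions()
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def total_arclength(self) -> float:
        return float(self.cumulative_arclength()[-1])

    def index_of(self, order_index: int) -> int:
        """Positional index of the cross-section with the given order_index."""
        for i, c in enumerate(self.cross_sections):
            if c.order_index == order_index:
                return i
        raise KeyError(
            f"segment {self.segment_id!r} has no point with order_index {order_index}"
        )


@dataclass(frozen=True)
class Connection:
    """Directed junction: parent terminal -> child inlet, bridged by a straight gap."""

    parent_id: str
    child_id: str
    gap_length: float  # mm

    def __post_init__(self) -> None:
        if self.gap_length < 0:
            raise ValidationError("gap_length must be nonnegative")


@dataclass
class VascularNetwork:
    """Vessel segments plus a rooted, acyclic, one-parent connection topology.

    Segments not reachable from the root may be present (e.g. vessels the
    connection search never reached); they are simply outside the rooted tree.
    """

    segments: dict[str, VesselSegment]
    connections: list[Connection]
    root_segment_id: str

    def __post_init__(self) -> None:
        if not isinstance(self.segments, Mapping):
            self.segments = {s.segment_id: s for s in self.segments}
        else:
            self.segments = dict(self.segments)
        if self.root_segment_id not in self.segments:
            raise ValidationError(f"root segment {self.root_segment_id!r} not present")
        parents: dict[str, str] = {}
        for conn in self.connections:
            if conn.parent_id not in self.segments or conn.child_id not in self.segments:
                raise ValidationError(f"connection {conn} references unknown segment")
            if conn.child_id in parents:
                raise ValidationError(f"segment {conn.child_id!r} has two parents")
            parents[conn.child_id] = conn.parent_id
        if self.root_segment_id in parents:
            raise ValidationError("root segment cannot have a parent")
        # Acyclicity: walk each parent chain; a one-parent digraph is cyclic only
        # if some chain revisits a node.
        for start in parents:
            seen = {start}
            node = start
            while node in parents:
                node = parents[node]
                if node in seen:
                    raise ValidationError("connection topology contains a cycle")
                seen.add(node)
        self._parents = parents

    @property
    def parent_map(self) -> dict[str, str]:
        return dict(self._parents)

    def connection_to(self, child_id: str) -> Connection:
        for conn in self.connections:
            if conn.child_id == child_id:
                return conn
        raise KeyError(f"segment {child_id!r} has no parent connection")

    def children_of(self, segment_id: str) -> list[str]:
        return sorted(c.child_id for c in self.connections if c.parent_id == segment_id)

    def rooted_segment_ids(self) -> list[str]:
        """Segment ids reachable from the root, in BFS order."""
        order = [self.root_segment_id]
        queue = deque(order)
        while queue:
            sid = queue.popleft()
            for child in self.children_of(sid):
                order.append(child)
                queue.append(child)
        return order

    def inlet_distances(self) -> dict[str, float]:
        """Centreline distance (mm) from the root inlet to each rooted segment's inlet."""
        dist = {self.root_segment_id: 0.0}
        queue = deque([self.root_segment_id])
        while queue:
            sid = queue.popleft()
            seg = self.segments[sid]
            for conn in self.connections:
                if conn.parent_id != sid:
                    continue
                dist[conn.child_id] = dist[sid] + seg.total_arclength + conn.gap_length
                queue.append(conn.child_id)
        return dist

    def point_distances(self) -> dict[str, np.ndarray]:
        """Per-segment arrays of centreline distance (mm) from the root inlet."""
        inlet = self.inlet_distances()
        return {
            sid: inlet[sid] + self.segments[sid].cumulative_arclength() for sid in inlet
        }


@dataclass(frozen=True)
class FitConfig:
    """Processing parameters shared across connectivity, quality and fitting.

    q_threshold / q_max
        Quality cut (samples with Q below the cut are discarded) and the score
        ceiling; weights ramp linearly between them.
    search_distance_voxels / voxel_size_mm
        Junction search radius, given in voxels and converted to mm.
    stencil_half_width
        Half-width of the local stencil (2 -> a 5-point window).
    exclude_segment_ids
        Segments that must never be connected (e.g. communicating arteries).
    """

    q_threshold: float = 2.5
    q_max: float = 4.0
    search_distance_voxels: float = 8.0
    voxel_size_mm: float = 1.0
    stencil_half_width: int = 2
    exclude_segment_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.q_threshold < self.q_max:
            raise ValidationError("q_threshold must be below q_max")
        if self.stencil_half_width < 0:
            raise ValidationError("stencil_half_width must be >= 0")
        if self.search_distance_voxels <= 0 or self.voxel_size_mm <= 0:
            raise ValidationError("search distance and voxel size must be positive")
        object.__setattr__(
            self, "exclude_segment_ids", tuple(self.exclude_segment_ids)
        )

    @property
    def search_radius_mm(self) -> float:
        return self.search_distance_voxels * self.voxel_size_mm


def orient_segment(segment: VesselSegment) -> VesselSegment:
    """Orient a segment so flow is positive downstream.

    If the segment-median of the per-point mean flow is negative the point
    order is reversed and tangents and traces are negated; otherwise the
    segment is returned unchanged.  Applying the function twice equals
    applying it once.
    """
    if len(segment) < 2:
        raise ValidationError("orientation needs at least 2 cross-sections")
    med = float(np.median(segment.q_mean()))
    if med > 0:
        return segment
    if med == 0:
        raise ValidationError(
            f"segment {segment.segment_id!r}: median mean flow is zero, "
            "orientation is ambiguous"
        )
    orders = sorted(c.order_index for c in segment.cross_sections)
    flipped = [
        replace(
            c,
            order_index=orders[i],
            tangent=-c.tangent,
            trace=FlowTrace(-c.trace.values),
        )
        for i, c in enumerate(reversed(segment.cross_sections))
    ]
    return VesselSegment(segment.segment_id, flipped)
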