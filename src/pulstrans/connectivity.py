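"""Reconnect unlinked vessel segments into a rooted tree.

Centreline-processing tools export vessels as isolated segments; to measure
distance from a root vessel the segments must be re-linked at bifurcations.
A breadth-first search grows the tree from the root: each frontier terminal
looks for unconnected segment inlets within the search radius, competing
parents for the same inlet (kissing/crossing vessels) are resolved by tangent
alignment, and the newly connected segments form the next frontier.

Distances from the root inlet accumulate Euclidean steps along each
centreline plus the straight-line gap bridged at every traversed junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    Connection,
    CrossSection,
    FitConfig,
    ValidationError,
    VesselSegment,
    VascularNetwork,
)

__all__ = [
    "ConnectionCandidate",
    "find_candidates",
    "resolve_ambiguity",
    "build_tree",
    "path_distance",
]


@dataclass(frozen=True)
class ConnectionCandidate:
    """A possible parent-terminal -> child-inlet link."""

    parent_segment_id: str
    child_segment_id: str
    gap_length: float  # mm, straight-line terminal -> inlet
    alignment: float  # inner product of terminal and inlet tangents, in [-1, 1]

    def __post_init__(self) -> None:
        if self.gap_length < 0:
            raise ValidationError("gap_length must be nonnegative")


def _candidates_from_terminal(
    parent_id: str,
    terminal: CrossSection,
    children: Iterable[VesselSegment],
    radius_mm: float,
) -> list[ConnectionCandidate]:
    out = []
    for seg in children:
        inlet = seg.inlet
        gap = float(np.linalg.norm(inlet.position - terminal.position))
        if gap <= radius_mm:
            out.append(
                ConnectionCandidate(
                    parent_segment_id=parent_id,
                    child_segment_id=seg.segment_id,
                    gap_length=gap,
                    alignment=float(np.dot(terminal.tangent, inlet.tangent)),
                )
            )
    return out


def find_candidates(
    network: VascularNetwork,
    frontier_segment_id: str,
    config: FitConfig = FitConfig(),
) -> list[ConnectionCandidate]:
    """Unconnected segment inlets within the search radius of a frontier terminal.

    A segment is eligible if it has no parent yet, is not the root or the
    frontier itself, and is not in ``config.exclude_segment_ids``.
    """
    if frontier_segment_id not in network.segments:
        raise KeyError(f"unknown segment {frontier_segment_id!r}")
    taken = set(network.parent_map) | {network.root_segment_id, frontier_segment_id}
    taken.update(config.exclude_segment_ids)
    pool = [
        seg for sid, seg in sorted(network.segments.items()) if sid not in taken
    ]
    terminal = network.segments[frontier_segment_id].terminal
    return _candidates_from_terminal(
        frontier_segment_id, terminal, pool, config.search_radius_mm
    )


def resolve_ambiguity(
    candidates: Sequence[ConnectionCandidate],
) -> dict[str, ConnectionCandidate]:
    """Pick one parent per child inlet.

    The candidate with maximal tangent alignment wins; ties break on smaller
    gap, then on lexicographically smaller parent id, making the choice
    deterministic.
    """
    best: dict[str, ConnectionCandidate] = {}
    for cand in sorted(
        candidates,
        key=lambda c: (c.child_segment_id, -c.alignment, c.gap_length, c.parent_segment_id),
    ):
        best.setdefault(cand.child_segment_id, cand)
    return best


def build_tree(
    segments: Sequence[VesselSegment] | Mapping[str, VesselSegment],
    root_segment_id: str,
    config: FitConfig = FitConfig(),
) -> VascularNetwork:
    """Breadth-first reconnection from the root until no new inlets are found.

    Each round gathers candidates from every current frontier terminal,
    resolves competing parents per child, commits the winners and makes them
    the next frontier.  Already-connected segments are never re-connected
    (one parent each, so the result is acyclic) and excluded segments are
    never linked.
    """
    if isinstance(segments, Mapping):
        segs = dict(segments)
    else:
        segs = {s.segment_id: s for s in segments}
    if root_segment_id not in segs:
        raise KeyError(f"root segment {root_segment_id!r} not among segments")
    excluded = set(config.exclude_segment_ids)
    connected = {root_segment_id}
    connections: list[Connection] = []
    frontier = [root_segment_id]
    radius = config.search_radius_mm
    while frontier:
        round_candidates: list[ConnectionCandidate] = []
        for fid in sorted(frontier):
            pool = [
                seg
                for sid, seg in sorted(segs.items())
                if sid not in connected and sid not in excluded
            ]
            round_candidates.extend(
                _candidates_from_terminal(fid, segs[fid].terminal, pool, radius)
            )
        chosen = resolve_ambiguity(round_candidates)
        frontier = []
        for child_id in sorted(chosen):
            cand = chosen[child_id]
            connections.append(
                Connection(cand.parent_segment_id, child_id, cand.gap_length)
            )
            connected.add(child_id)
            frontier.append(child_id)
    return VascularNetwork(
        segments=segs, connections=connections, root_segment_id=root_segment_id
    )


def path_distance(network: VascularNetwork, cross_section: CrossSection) -> float:
    """Centreline distance (mm) from the root inlet to a cross-section.

    Sums Euclidean steps between consecutive centreline points along the
    connected path plus each traversed junction's straight-line gap.
    """
    distances = network.point_distances()
    sid = cross_section.segment_id
    if sid not in distances:
        raise ValidationError(
            f"segment {sid!r} is not connected to root {network.root_segment_id!r}"
        )
    idx = network.segments[sid].index_of(cross_section.order_index)
    return float(distances[sid][idx])
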