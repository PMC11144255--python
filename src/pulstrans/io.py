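"""Tabular I/O: cross-section tables (CSV), connectivity and result reports (JSON).

Cross-section table schema (header row mandatory)::

    segment_id, order_index, x_mm, y_mm, z_mm, tx, ty, tz,
    area_mm2, rmin_mm, rmax_mm, q_00 ... q_{S-1}

with one row per centreline point and flow values in mL/s, one column per
cardiac phase.  Floats are written with 12 significant digits so a
write/read round-trip reproduces values to that precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    Connection,
    CrossSection,
    FlowTrace,
    ValidationError,
    VesselSegment,
    VascularNetwork,
)
from .fitting import TransmissionFit, global_ptc
from .indices import RootIndices, global_indices

__all__ = [
    "SchemaError",
    "GEOMETRY_COLUMNS",
    "load_cross_section_table",
    "write_cross_section_table",
    "write_connectivity",
    "read_connectivity",
    "write_report",
    "read_report",
]


class SchemaError(ValueError):
    """The file does not conform to the documented column schema."""


GEOMETRY_COLUMNS = (
    "segment_id",
    "order_index",
    "x_mm",
    "y_mm",
    "z_mm",
    "tx",
    "ty",
    "tz",
    "area_mm2",
    "rmin_mm",
    "rmax_mm",
)

_FLOW_RE = re.compile(r"^q_(\d+)$")


def _flow_columns(columns: Iterable[str]) -> list[str]:
    found = [(int(m.group(1)), c) for c in columns if (m := _FLOW_RE.match(c))]
    found.sort()
    if not found:
        raise SchemaError("no flow columns (q_00 ...) found")
    phases = [p for p, _ in found]
    if phases != list(range(len(phases))):
        raise SchemaError(f"flow columns are not contiguous from q_00: {phases}")
    return [c for _, c in found]


def load_cross_section_table(path) -> list[VesselSegment]:
    """Read a cross-section table and group it into ordered vessel segments."""
    df = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    flow_cols = _flow_columns(df.columns)
    flow = df[flow_cols].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(flow))
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"non-finite flow value in record {int(r)} "
            f"(segment {df['segment_id'].iloc[int(r)]!r}, column {flow_cols[int(c)]})"
        )
    segments = []
    for sid, group in df.groupby("segment_id", sort=True):
        group = group.sort_values("order_index")
        cs = []
        for _, row in group.iterrows():
            try:
                cs.append(
                    CrossSection(
                        segment_id=str(sid),
                        order_index=int(row["order_index"]),
                        position=row[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
                        tangent=row[["tx", "ty", "tz"]].to_numpy(dtype=float),
                        area=float(row["area_mm2"]),
                        r_min=float(row["rmin_mm"]),
                        r_max=float(row["rmax_mm"]),
                        trace=FlowTrace(row[flow_cols].to_numpy(dtype=float)),
                    )
                )
            except ValidationError as err:
                raise ValidationError(
                    f"record {int(row.name)} (segment {sid!r}, "
                    f"order_index {int(row['order_index'])}): {err}"
                ) from err
        segments.append(VesselSegment(str(sid), cs))
    return segments


def write_cross_section_table(segments: Sequence[VesselSegment], path) -> None:
    """Write segments to the documented CSV schema (12 significant digits)."""
    if not segments:
        raise ValidationError("no segments to write")
    n_phases = segments[0].n_phases
    flow_cols = [f"q_{i:02d}" for i in range(n_phases)]
    rows = []
    for seg in segments:
        if seg.n_phases != n_phases:
            raise ValidationError("segments have inconsistent phase counts")
        for c in seg.cross_sections:
            rows.append(
                (str(seg.segment_id), c.order_index, *c.position, *c.tangent,
                 c.area, c.r_min, c.r_max, *c.trace.values)
            )
    df = pd.DataFrame(rows, columns=list(GEOMETRY_COLUMNS) + flow_cols)
    df.to_csv(path, index=False, float_format="%.12g")


def write_connectivity(network: VascularNetwork, path) -> None:
    """Emit the connection topology as JSON for manual review."""
    payload = {
        "root_segment_id": network.root_segment_id,
        "edges": [
            {"parent": c.parent_id, "child": c.child_id, "gap_length_mm": c.gap_length}
            for c in network.connections
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_connectivity(segments: Sequence[VesselSegment], path) -> VascularNetwork:
    """Rebuild a network from segments plus a connectivity JSON file."""
    payload = json.loads(Path(path).read_text())
    connections = [
        Connection(e["parent"], e["child"], float(e["gap_length_mm"]))
        for e in payload["edges"]
    ]
    return VascularNetwork(
        segments={s.segment_id: s for s in segments},
        connections=connections,
        root_segment_id=payload["root_segment_id"],
    )


def write_report(
    fits: Sequence[TransmissionFit],
    indices: Sequence[RootIndices] | None,
    path,
) -> dict:
    """Write per-root fits and global (root-averaged) indices as JSON.

    Returns the report dict that was written.  Global p_tc is the arithmetic
    mean of the available root slopes; global p_pi / p_df average the
    supplied root index sets (omitted entirely when none are given).
    """
    if not fits:
        raise ValidationError("report needs at least one fit")
    report: dict = {
        "roots": [
            {
                "segment_id": f.root_segment_id,
                "p_tc_per_m": f.p_tc,
                "beta": f.beta,
                "weighted_r2": f.weighted_r2,
                "n_included": f.n_included,
                "n_excluded": f.n_excluded,
            }
            for f in fits
        ],
        "global": {"p_tc_per_m": global_ptc(fits)},
    }
    if indices:
        g_ppi, g_pdf = global_indices(indices)
        report["global"]["p_pi"] = g_ppi
        report["global"]["p_df"] = g_pdf
    Path(path).write_text(json.dumps(report, indent=2))
    return report


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
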