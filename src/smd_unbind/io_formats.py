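"""Readers and writers for the pipeline's external representations.

Covers the xvg-dialect text files carrying pull force/position traces
(lines starting with ``#`` or ``@`` are metadata, numeric columns follow),
multi-model PDB coordinate files (parsed fixed-column via biotite, Å
converted to nm), and the tab-separated report tables. Every writer's
output is re-readable by its reader with value equality; malformed input is
rejected rather than silently truncated. Numeric formatting always uses
'.' decimals, independent of locale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .geometry import Trajectory
from .simulate import PullTrace

__all__ = [
    "XvgDocument",
    "read_xvg",
    "write_xvg",
    "write_pull_trace",
    "read_pull_trace",
    "read_multimodel_pdb",
    "write_report_tsv",
    "read_report_tsv",
    "write_provenance",
]


# ---------------------------------------------------------------------------
# xvg dialect
# ---------------------------------------------------------------------------

@dataclass
class XvgDocument:
    """Parsed xvg-dialect file: metadata lines plus rectangular numeric columns."""

    columns: np.ndarray                  # (n_rows, n_cols)
    metadata: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] == 0:
            raise ValueError("columns must be a 2-D array with at least one column")


def read_xvg(path) -> XvgDocument:
    """Parse an xvg-dialect file; '#'/'@' lines are metadata, the rest numeric rows."""
    metadata: list[str] = []
    rows: list[list[float]] = []
    arity = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@")):
            metadata.append(line)
            continue
        fields = stripped.split()
        try:
            values = [float(v) for v in fields]
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: non-numeric data row: {line!r}") from err
        if arity is None:
            arity = len(values)
        elif len(values) != arity:
            raise ValueError(f"{path}:{lineno}: ragged row (expected {arity} fields)")
        rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    return XvgDocument(columns=np.array(rows), metadata=metadata)


def write_xvg(document: XvgDocument, path) -> None:
    """Write an xvg-dialect file; inverse of :func:`read_xvg` on the value level."""
    if document.columns.shape[0] == 0:
        raise ValueError("refusing to write xvg document with no data rows")
    lines = list(document.metadata)
    for row in document.columns:
        lines.append("  ".join(format(v, ".10g") for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pull traces as xvg pairs (force vs time, position vs time)
# ---------------------------------------------------------------------------

def write_pull_trace(trace: PullTrace, force_path, position_path) -> None:
    """Write one replicate as two xvg files (time/force and time/position).

    The spring constant, pulling velocity, initial anchor position and
    temperature are stored as '#' metadata so the trace round-trips.
    """
    meta = [
        f"# spring_constant_kJ_mol_nm2 = {trace.spring_constant:.10g}",
        f"# velocity_nm_ns = {trace.velocity:.10g}",
        f"# anchor0_nm = {trace.anchor[0]:.10g}",
        f"# temperature_K = {trace.temperature:.10g}",
    ]
    force_doc = XvgDocument(
        columns=np.column_stack([trace.time, trace.force]),
        metadata=meta + ['@ title "Pull force"', '@ xaxis label "Time (ps)"',
                         '@ yaxis label "Force (kJ/mol/nm)"'],
    )
    pos_doc = XvgDocument(
        columns=np.column_stack([trace.time, trace.position]),
        metadata=meta + ['@ title "Pull position"', '@ xaxis label "Time (ps)"',
                         '@ yaxis label "Position (nm)"'],
    )
    write_xvg(force_doc, force_path)
    write_xvg(pos_doc, position_path)


def _meta_value(metadata: list[str], key: str) -> float:
    for line in metadata:
        if line.startswith(f"# {key}"):
            return float(line.split("=", 1)[1])
    raise ValueError(f"missing metadata key {key!r} in trace file")


def read_pull_trace(force_path, position_path) -> PullTrace:
    """Reconstruct a :class:`PullTrace` from its force/position xvg pair."""
    force_doc = read_xvg(force_path)
    pos_doc = read_xvg(position_path)
    if force_doc.columns.shape[1] != 2 or pos_doc.columns.shape[1] != 2:
        raise ValueError("pull trace xvg files must have exactly two columns")
    time = force_doc.columns[:, 0]
    if not np.array_equal(time, pos_doc.columns[:, 0]):
        raise ValueError("force and position files have mismatched time grids")
    k = _meta_value(force_doc.metadata, "spring_constant_kJ_mol_nm2")
    v = _meta_value(force_doc.metadata, "velocity_nm_ns")
    z0 = _meta_value(force_doc.metadata, "anchor0_nm")
    try:
        temp = _meta_value(force_doc.metadata, "temperature_K")
    except ValueError:
        temp = 298.0
    anchor = z0 + v * 1e-3 * time
    return PullTrace(time=time, anchor=anchor, position=pos_doc.columns[:, 1],
                     force=force_doc.columns[:, 1], spring_constant=k,
                     velocity=v, temperature=temp)


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path) -> Trajectory:
    """Read a (multi-)model PDB file as a Trajectory; Å are converted to nm.

    MODEL/ENDMDL records delimit frames, which must share one atom table;
    missing occupancy/B-factor fields are tolerated by the fixed-column
    parser.
    """
    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure()  # AtomArrayStack, length = model count
    except Exception as err:
        raise ValueError(f"{path}: malformed or inconsistent PDB models: {err}") from err
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    elements = np.array([e.capitalize() if e else "" for e in stack.element])
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float) / 10.0,
        atom_names=np.asarray(stack.atom_name),
        elements=elements,
        resnames=np.asarray(stack.res_name),
        resids=np.asarray(stack.res_id, dtype=int),
        chains=np.asarray(stack.chain_id),
        times=np.arange(stack.stack_depth(), dtype=float),
    )


# ---------------------------------------------------------------------------
# Report tables and provenance
# ---------------------------------------------------------------------------

def write_report_tsv(table, path, decimals: int = 1) -> None:
    """Write a rectangular table as TSV with fixed decimal formatting.

    ``table`` is a DataFrame or a dict of equal-length columns; float
    columns are written with ``decimals`` decimal places (1 by default,
    matching kJ/mol presentation), everything else verbatim.
    """
    if isinstance(table, dict):
        lengths = {len(v) for v in table.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged table: column lengths {sorted(lengths)}")
        table = pd.DataFrame(table)
    if not isinstance(table, pd.DataFrame):
        raise TypeError("table must be a DataFrame or dict of columns")
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{decimals}f")


def read_report_tsv(path) -> pd.DataFrame:
    """Read back a report TSV written by :func:`write_report_tsv`."""
    return pd.read_csv(path, sep="\t")


def write_provenance(path, payload: dict) -> None:
    """JSON provenance sidecar (config hash, seeds, versions) next to outputs."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
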