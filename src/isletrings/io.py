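"""Coordinate-table input and result-record output.

Input is a CSV with columns islet_id, x, y, optional z, cell_type (strings
among beta/alpha/delta, case-insensitive), one row per cell.  Results are
JSON documents with stable key order; every cycle record references cell ids
(0-based row order within the islet), never coordinates, so results are
stable under coordinate reformatting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .datamodel import (
    CELL_TYPES,
    Cell,
    IsletSection,
    ValidationError,
    filter_eligible,  # noqa: F401  (re-exported as part of the I/O surface)
)


class FormatError(ValueError):
    """CSV is missing required columns."""


@dataclass
class AnalysisResult:
    """JSON-serializable per-islet analysis record.

    ``directions`` maps 'ad_around_b' / 'b_around_ad' to dicts holding the
    geometric cycles (ordered vertex-id walks), PH boundaries (edge lists
    with enclosed marker ids), comparison records and NS-component flags.
    """

    islet_id: str
    group: str | None = None
    tau: dict = field(default_factory=dict)
    characteristics: dict = field(default_factory=dict)
    max_persistence: dict = field(default_factory=dict)
    directions: dict = field(default_factory=dict)
    morphometry: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisResult":
        return cls(**d)


def read_cells_csv(path) -> list[IsletSection]:
    """Parse a coordinate table into islet sections.

    Cells are grouped by islet_id (in order of first appearance) and get
    0-based ids in row order within each islet; dim is inferred from the
    presence of a fully populated z column.
    """
    df = pd.read_csv(path, dtype={"islet_id": str})
    required = {"islet_id", "x", "y", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")
    has_z = "z" in df.columns and df["z"].notna().all() and len(df) > 0
    if "z" in df.columns and len(df) and df["z"].notna().any() and not has_z:
        bad = int(df.index[df["z"].isna()][0]) + 2
        raise ValidationError(f"z present for some rows but missing at line {bad}")
    islets: dict[str, list[Cell]] = {}
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        ct = str(row.cell_type).strip().lower()
        if ct not in CELL_TYPES:
            raise ValidationError(
                f"unknown cell_type {row.cell_type!r} at line {row_no}"
            )
        coords = (float(row.x), float(row.y))
        if has_z:
            coords = coords + (float(row.z),)
        cells = islets.setdefault(str(row.islet_id), [])
        cells.append(Cell(id=len(cells), coords=coords, cell_type=ct))
    return [IsletSection(islet_id=k, cells=v) for k, v in islets.items()]


def write_cells_csv(path, islets: list[IsletSection]) -> None:
    rows = []
    for islet in islets:
        for c in islet.cells:
            row = {"islet_id": islet.islet_id, "x": c.coords[0], "y": c.coords[1]}
            if islet.dim == 3:
                row["z"] = c.coords[2]
            row["cell_type"] = c.cell_type
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_json(path, results: list[AnalysisResult]) -> None:
    """Stable-key-order JSON document; round-trips through the reader."""
    doc = {"islets": [r.to_dict() for r in results]}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_results_json(path) -> list[AnalysisResult]:
    doc = json.loads(Path(path).read_text())
    return [AnalysisResult.from_dict(d) for d in doc["islets"]]


def write_summary_csv(path, results: list[AnalysisResult]) -> None:
    """One-row-per-islet summary table."""
    rows = []
    for r in results:
        row = {
            "islet_id": r.islet_id,
            "group": r.group,
            "tau_beta": r.tau.get("beta"),
            "tau_alphadelta": r.tau.get("alphadelta"),
            "beta_fraction": r.characteristics.get("beta_fraction"),
            "log_total": r.characteristics.get("log_total"),
            "max_persistence_beta": r.max_persistence.get("beta"),
            "max_persistence_alphadelta": r.max_persistence.get("alphadelta"),
        }
        for d, rec in r.directions.items():
            row[f"n_geometric_cycles_{d}"] = len(rec.get("geometric_cycles", []))
            row[f"n_ph_cycles_{d}"] = len(rec.get("ph_boundaries", []))
            row[f"ns_in_cycle_{d}"] = rec.get("ns_in_geometric_cycle")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
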