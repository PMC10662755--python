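"""Core data model: typed cells and islet sections.

An islet section is a table of nucleus coordinates (2D slice or 3D volume)
with one of three endocrine cell-type labels per cell: ``beta`` (insulin),
``alpha`` (glucagon) or ``delta`` (somatostatin).  Alpha and delta cells are
pooled into a single "alphadelta" structure class throughout the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

CELL_TYPES = ("beta", "alpha", "delta")

#: the two cell classes the analysis contrasts
CLASSES = ("beta", "alphadelta")


class ValidationError(ValueError):
    """Input table violates the data-model contract."""


class DegenerateInputError(ValueError):
    """Geometrically degenerate input (too few cells, zero extent, ...)."""


def class_of(cell_type: str) -> str:
    """Map a cell type to its analysis class (beta vs pooled alphadelta)."""
    if cell_type == "beta":
        return "beta"
    if cell_type in ("alpha", "delta"):
        return "alphadelta"
    raise ValidationError(f"unknown cell type {cell_type!r}")


@dataclass(frozen=True)
class Cell:
    """One cell: integer id (0-based, row order within its islet), coordinates
    in input units (typically micrometres or pixels) and a type label."""

    id: int
    coords: tuple[float, ...]
    cell_type: str

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValidationError(
                f"cell_type must be one of {CELL_TYPES}, got {self.cell_type!r}"
            )
        if len(self.coords) not in (2, 3):
            raise ValidationError("coords must be 2- or 3-dimensional")

    @property
    def cell_class(self) -> str:
        return class_of(self.cell_type)


@dataclass
class IsletSection:
    """A single islet: its cells plus optional cohort metadata.

    ``group`` carries a cohort label such as a developmental stage
    ("stage0".."stage3") or "control"/"diabetic".
    """

    islet_id: str
    cells: list[Cell]
    group: str | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate cell ids in islet {self.islet_id}")
        dims = {len(c.coords) for c in self.cells}
        if len(dims) > 1:
            raise ValidationError(
                f"mixed 2D/3D coordinates in islet {self.islet_id}"
            )
        seen: dict[tuple, int] = {}
        for c in self.cells:
            if c.coords in seen:
                warnings.warn(
                    f"islet {self.islet_id}: cells {seen[c.coords]} and {c.id} "
                    "share identical coordinates",
                    stacklevel=3,
                )
            else:
                seen[c.coords] = c.id

    @property
    def dim(self) -> int:
        if not self.cells:
            return 2
        return len(self.cells[0].coords)

    def cells_of_class(self, cell_class: str) -> list[Cell]:
        if cell_class not in CLASSES:
            raise ValidationError(f"unknown cell class {cell_class!r}")
        return [c for c in self.cells if c.cell_class == cell_class]

    def coords_of(self, ids: Iterable[int]) -> np.ndarray:
        lookup = {c.id: c.coords for c in self.cells}
        return np.asarray([lookup[i] for i in ids], dtype=float)

    def class_arrays(self, cell_class: str) -> tuple[list[int], np.ndarray]:
        """Ids and an (n, dim) coordinate array for one class."""
        cells = self.cells_of_class(cell_class)
        ids = [c.id for c in cells]
        coords = np.asarray([c.coords for c in cells], dtype=float)
        return ids, coords.reshape(len(ids), self.dim)

    def count(self, cell_type: str) -> int:
        return sum(1 for c in self.cells if c.cell_type == cell_type)

    @property
    def n_beta(self) -> int:
        return self.count("beta")

    @property
    def n_alphadelta(self) -> int:
        return self.count("alpha") + self.count("delta")

    def is_eligible(self, min_beta: int = 5, min_alphadelta: int = 5) -> bool:
        """Whether the islet has enough cells of both classes to analyse
        (at least five beta and five alphadelta cells by default)."""
        return self.n_beta >= min_beta and self.n_alphadelta >= min_alphadelta


def filter_eligible(
    islets: Sequence[IsletSection],
    min_beta: int = 5,
    min_alphadelta: int = 5,
) -> list[IsletSection]:
    """Keep only islets with at least ``min_beta`` beta cells and
    ``min_alphadelta`` pooled alpha+delta cells.  Idempotent."""
    return [i for i in islets if i.is_eligible(min_beta, min_alphadelta)]
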