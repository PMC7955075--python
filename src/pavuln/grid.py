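"""Core spatial containers: grid, raster layers, monthly climate cubes,
protected areas and species records.

Everything downstream works on a single declared planar grid.  Row 0 is the
northernmost row; cell ``(r, c)`` spans the half-open square
``[origin_x + c*cell_size, origin_x + (c+1)*cell_size)`` ×
``[origin_y + (nrows-1-r)*cell_size, origin_y + (nrows-r)*cell_size)``
with ``origin`` the lower-left corner of the grid.  No CRS handling is
attempted: coordinates are in arbitrary planar units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Sequence, Tuple

import numpy as np

Cell = Tuple[int, int]

#: The five taxon groups scored by the species-vulnerability index.
GROUPS = ("birds", "mammals", "amphibians", "reptiles", "plants")

#: The three IUCN threatened categories considered, lowest to highest threat.
CATEGORIES = ("VU", "EN", "CR")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid.

    Parameters
    ----------
    nrows, ncols
        Grid dimensions; must be >= 1.
    cell_size
        Side length of one (square) cell, arbitrary planar units.
    origin
        ``(x, y)`` coordinate of the grid's lower-left corner.
    """

    nrows: int
    ncols: int
    cell_size: float = 1.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(
                f"grid dimensions must be >= 1, got {self.nrows}x{self.ncols}"
            )
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def contains(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.nrows and 0 <= c < self.ncols

    def cell_center(self, cell: Cell) -> Tuple[float, float]:
        """Planar coordinates of a cell's center (row 0 = northernmost)."""
        r, c = cell
        x0, y0 = self.origin
        x = x0 + (c + 0.5) * self.cell_size
        y = y0 + (self.nrows - r - 0.5) * self.cell_size
        return (x, y)

    def cell_bounds(self, cell: Cell) -> Tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of one cell."""
        r, c = cell
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + c * s, y0 + (self.nrows - r - 1) * s,
                x0 + (c + 1) * s, y0 + (self.nrows - r) * s)


@dataclass
class RasterLayer:
    """A gridded real-valued field with NODATA support.

    ``values`` has shape ``grid.shape``; ``nodata_mask`` is ``True`` where a
    cell carries no data.  Masked cells are excluded from all statistics.
    """

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata_mask shape does not match grid")

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.nodata_mask)

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.nodata_mask.copy())


@dataclass
class MonthlyClimateCube:
    """Monthly tmin/tmax/precipitation for a run of years on one grid.

    Arrays have shape ``(n_years, 12, nrows, ncols)``; temperatures in degC,
    precipitation in mm.  ``tmax >= tmin`` and ``prec >= 0`` cell-wise.
    """

    grid: GridSpec
    years: Tuple[int, ...]
    tmin: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        expected = (len(self.years), 12) + self.grid.shape
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expected:
                raise ValueError(f"{name} shape {arr.shape} != {expected}")
            setattr(self, name, arr)
        if np.any(self.tmax < self.tmin):
            raise ValueError("tmax < tmin at some cell")
        if np.any(self.prec < 0):
            raise ValueError("negative precipitation")

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class ProtectedArea:
    """One protected area as a labeled, non-empty set of grid cells."""

    pa_id: str
    cells: FrozenSet[Cell]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", frozenset(tuple(c) for c in self.cells))
        if not self.cells:
            raise ValueError(f"PA {self.pa_id!r} has no cells")

    @property
    def size(self) -> int:
        return len(self.cells)

    def centroid(self, grid: GridSpec) -> Tuple[float, float]:
        """Mean of the member cells' center coordinates."""
        xy = np.array([grid.cell_center(c) for c in sorted(self.cells)])
        return (float(xy[:, 0].mean()), float(xy[:, 1].mean()))


@dataclass(frozen=True)
class SpeciesRecord:
    """A threatened species: taxon group, IUCN category, and range cells."""

    species_id: str
    group: str
    category: str
    range_cells: FrozenSet[Cell]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        object.__setattr__(
            self, "range_cells", frozenset(tuple(c) for c in self.range_cells)
        )
        if not self.range_cells:
            raise ValueError(f"species {self.species_id!r} has an empty range")


def validate_pa_collection(pas: Sequence[ProtectedArea], grid: GridSpec) -> None:
    """Check bounds and pairwise disjointness of a PA collection.

    Raises ``ValueError`` naming the first offending PA (out-of-bounds cell)
    or pair (shared cell).
    """
    seen: dict = {}
    ids = set()
    for pa in pas:
        if pa.pa_id in ids:
            raise ValueError(f"duplicate pa_id {pa.pa_id!r}")
        ids.add(pa.pa_id)
        for cell in pa.cells:
            if not grid.contains(cell):
                raise ValueError(f"PA {pa.pa_id!r} has out-of-bounds cell {cell}")
            if cell in seen:
                raise ValueError(
                    f"PAs {seen[cell]!r} and {pa.pa_id!r} overlap at cell {cell}"
                )
            seen[cell] = pa.pa_id


def pa_centroids(pas: Sequence[ProtectedArea], grid: GridSpec) -> np.ndarray:
    """``(n_pas, 2)`` array of centroid coordinates, in input order."""
    return np.array([pa.centroid(grid) for pa in pas])
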