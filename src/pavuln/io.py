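"""Readers and writers for the pipeline's on-disk formats.

Rasters are exchanged as ESRI ASCII grids; protected-area footprints as
GeoJSON (each PA a polygonal union of its cells); species records and all
tables as UTF-8 comma-separated CSV with a mandatory header row and '.'
decimals; configuration and the run manifest as JSON.  Grid convention in
every writer: row 0 is the northernmost row, cell (r, c) spans the
half-open square starting at ``origin + c * cell_size`` eastward.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape
from shapely.ops import unary_union
from shapely.prepared import prep

from .grid import (
    CATEGORIES,
    GROUPS,
    GridSpec,
    MonthlyClimateCube,
    ProtectedArea,
    RasterLayer,
    SpeciesRecord,
)

NODATA_VALUE = -9999.0

PathLike = Union[str, Path]


# ---------------------------------------------------------------- rasters

def write_ascii_grid(layer: RasterLayer, path: PathLike) -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    g = layer.grid
    vals = np.where(layer.nodata_mask, NODATA_VALUE, layer.values)
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.origin[0]!r}\n"
        f"yllcorner {g.origin[1]!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {NODATA_VALUE}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: PathLike) -> RasterLayer:
    """Read an ESRI ASCII grid into a RasterLayer."""
    header: Dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            key = key.lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {req!r}")
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )
    if vals.shape != grid.shape:
        raise ValueError(f"{path}: data shape {vals.shape} != header {grid.shape}")
    nodata = header.get("nodata_value", NODATA_VALUE)
    mask = vals == nodata
    return RasterLayer(grid, np.where(mask, np.nan, vals), mask)


# ------------------------------------------------------------ PA footprints

def pa_footprint(pa: ProtectedArea, grid: GridSpec):
    """Shapely (multi)polygon union of a PA's cell squares."""
    return unary_union([box(*grid.cell_bounds(c)) for c in sorted(pa.cells)])


def write_pas_geojson(
    pas: Sequence[ProtectedArea], grid: GridSpec, path: PathLike
) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"pa_id": pa.pa_id, "n_cells": pa.size},
            "geometry": mapping(pa_footprint(pa, grid)),
        }
        for pa in pas
    ]
    doc = {
        "type": "FeatureCollection",
        "grid": {
            "nrows": grid.nrows,
            "ncols": grid.ncols,
            "cell_size": grid.cell_size,
            "origin": list(grid.origin),
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_pas_geojson(path: PathLike) -> Tuple[List[ProtectedArea], GridSpec]:
    """Read PA footprints back to cell sets via cell-center containment.

    Overlapping footprints (two PAs claiming one cell) are rejected with
    the offending pair named.
    """
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        g = doc["grid"]
        grid = GridSpec(g["nrows"], g["ncols"], g["cell_size"], tuple(g["origin"]))
    except KeyError as exc:
        raise ValueError(f"{path}: missing grid metadata ({exc})") from exc
    centers = np.array(
        [
            [grid.cell_center((r, c)) for c in range(grid.ncols)]
            for r in range(grid.nrows)
        ]
    )
    pas: List[ProtectedArea] = []
    owner: Dict[Tuple[int, int], str] = {}
    from shapely.geometry import Point

    for feat in doc["features"]:
        pa_id = feat["properties"]["pa_id"]
        geom = prep(shape(feat["geometry"]))
        cells = set()
        minx, miny, maxx, maxy = shape(feat["geometry"]).bounds
        for r in range(grid.nrows):
            for c in range(grid.ncols):
                x, y = centers[r, c]
                if minx <= x <= maxx and miny <= y <= maxy and geom.contains(
                    Point(x, y)
                ):
                    cells.add((r, c))
        for cell in cells:
            if cell in owner:
                raise ValueError(
                    f"{path}: overlapping PA footprints {owner[cell]!r} and "
                    f"{pa_id!r} at cell {cell}"
                )
            owner[cell] = pa_id
        pas.append(ProtectedArea(pa_id=pa_id, cells=frozenset(cells)))
    return pas, grid


# ---------------------------------------------------------------- species CSV

def write_species_csv(species: Sequence[SpeciesRecord], path: PathLike) -> None:
    rows = [
        {
            "species_id": sp.species_id,
            "group": sp.group,
            "category": sp.category,
            "cell_list": ";".join(f"{r}:{c}" for r, c in sorted(sp.range_cells)),
        }
        for sp in species
    ]
    pd.DataFrame(rows, columns=["species_id", "group", "category", "cell_list"]).to_csv(
        path, index=False
    )


def read_species_csv(path: PathLike) -> List[SpeciesRecord]:
    """Read and schema-validate a species CSV.

    Errors name the file, 1-based data row and column of the violation.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["species_id", "group", "category", "cell_list"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: List[SpeciesRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.group not in GROUPS:
            raise ValueError(
                f"{path}: row {i}, column 'group': unknown group {row.group!r}"
            )
        if row.category not in CATEGORIES:
            raise ValueError(
                f"{path}: row {i}, column 'category': unknown category "
                f"{row.category!r} (expected one of {CATEGORIES})"
            )
        try:
            cells = frozenset(
                (int(p.split(":")[0]), int(p.split(":")[1]))
                for p in str(row.cell_list).split(";")
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(
                f"{path}: row {i}, column 'cell_list': unparseable ({exc})"
            ) from exc
        records.append(
            SpeciesRecord(row.species_id, row.group, row.category, cells)
        )
    return records


# ------------------------------------------------------------- climate cube

def write_climate_cube(cube: MonthlyClimateCube, path: PathLike) -> None:
    """Write a monthly climate cube as one plain-text file.

    Format: a JSON header line (grid + years), then one whitespace row of
    ``nrows * ncols`` values per (variable, year, month) record, variables
    ordered tmin, tmax, prec.
    """
    g = cube.grid
    header = json.dumps(
        {
            "nrows": g.nrows,
            "ncols": g.ncols,
            "cell_size": g.cell_size,
            "origin": list(g.origin),
            "years": list(cube.years),
        }
    )
    flat = np.concatenate(
        [arr.reshape(cube.n_years * 12, -1) for arr in (cube.tmin, cube.tmax, cube.prec)]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, flat, fmt="%.8g")


def read_climate_cube(path: PathLike) -> MonthlyClimateCube:
    with open(path, "r", encoding="utf-8") as fh:
        meta = json.loads(fh.readline())
        flat = np.loadtxt(fh, ndmin=2)
    grid = GridSpec(meta["nrows"], meta["ncols"], meta["cell_size"],
                    tuple(meta["origin"]))
    years = tuple(meta["years"])
    per_var = len(years) * 12
    if flat.shape != (3 * per_var, grid.n_cells):
        raise ValueError(f"{path}: unexpected cube shape {flat.shape}")
    shape4 = (len(years), 12, grid.nrows, grid.ncols)
    tmin, tmax, prec = (
        flat[i * per_var:(i + 1) * per_var].reshape(shape4) for i in range(3)
    )
    return MonthlyClimateCube(grid, years, tmin, tmax, prec)


# ---------------------------------------------------------------- manifest

def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: PathLike, config_dict: dict, seeds: Dict[str, int]) -> None:
    """Record everything needed to reproduce a run exactly."""
    from . import __version__

    manifest = {
        "package": "pavuln",
        "version": __version__,
        "config": config_dict,
        "config_hash": config_hash(config_dict),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str),
                          encoding="utf-8")
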