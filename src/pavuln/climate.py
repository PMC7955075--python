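"""Bioclimatic variables, zonal means, climate-space PCA and displacement.

Six bioclimatic summaries are derived from monthly climatologies: mean
annual temperature (MAT), mean temperature of the warmest/coldest quarter
(MTWQ/MTCQ), annual precipitation (MAP), and precipitation of the
driest/wettest quarter (PDQ/PWQ).  A "quarter" is any window of 3
consecutive months, including the wrap-around windows that cross the year
boundary, so there are 12 candidate windows; ties between windows are
broken by the earliest starting month.  Monthly mean temperature is
``(tmin + tmax) / 2`` and MAP is the sum of the 12 monthly precipitation
means — the conventions of the standard bioclim derivation.

Per-protected-area climate change is summarized as the Euclidean distance
between a PA's past and present positions on the first two axes of a PCA
fitted once on the pooled past+present per-PA bioclim table, so both epochs
share one coordinate system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grid import GridSpec, MonthlyClimateCube, ProtectedArea, RasterLayer

BIOCLIM_VARS = ("MAT", "MTWQ", "MTCQ", "MAP", "PDQ", "PWQ")


@dataclass
class Climatology:
    """12-month mean fields of tmin, tmax and prec for one epoch."""

    grid: GridSpec
    tmin: np.ndarray  # (12, nrows, ncols)
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        expected = (12,) + self.grid.shape
        for name in ("tmin", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != expected:
                raise ValueError(f"{name} must have shape {expected}, got {arr.shape}")
            setattr(self, name, arr)


@dataclass
class BioclimSet:
    """The six bioclim variables as rasters on a shared grid.

    Invariants: cell-wise MTCQ <= MAT <= MTWQ and 0 <= PDQ <= PWQ <= MAP.
    """

    MAT: RasterLayer
    MTWQ: RasterLayer
    MTCQ: RasterLayer
    MAP: RasterLayer
    PDQ: RasterLayer
    PWQ: RasterLayer

    def layers(self) -> Dict[str, RasterLayer]:
        return {v: getattr(self, v) for v in BIOCLIM_VARS}


def monthly_climatology(
    cube: MonthlyClimateCube, epoch: Optional[Iterable[int]] = None
) -> Climatology:
    """Cell-wise mean over an epoch's years, per variable and month."""
    if epoch is None:
        idx = np.arange(cube.n_years)
    else:
        epoch = [int(y) for y in epoch]
        if not epoch:
            raise ValueError("epoch contains zero years")
        missing = set(epoch) - set(cube.years)
        if missing:
            raise ValueError(f"epoch years not in cube: {sorted(missing)}")
        lookup = {y: i for i, y in enumerate(cube.years)}
        idx = np.array([lookup[y] for y in epoch])
    return Climatology(
        cube.grid,
        cube.tmin[idx].mean(axis=0),
        cube.tmax[idx].mean(axis=0),
        cube.prec[idx].mean(axis=0),
    )


def compute_bioclim(clim: Climatology) -> BioclimSet:
    """Derive the six bioclim variables from a 12-month climatology."""
    tmean = (clim.tmin + clim.tmax) / 2.0  # (12, r, c)
    prec = clim.prec
    grid = clim.grid

    mat = tmean.mean(axis=0)
    map_ = prec.sum(axis=0)

    # All 12 wrap-around quarters, indexed by starting month.
    starts = np.arange(12)
    win = (starts[:, None] + np.arange(3)[None, :]) % 12  # (12, 3)
    qtemp = tmean[win].mean(axis=1)  # (12, r, c)
    qprec = prec[win].sum(axis=1)

    # argmax/argmin return the first extremum: earliest-start tie-break.
    def _pick(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None], axis=0)[0]

    mtwq = _pick(qtemp, qtemp.argmax(axis=0))
    mtcq = _pick(qtemp, qtemp.argmin(axis=0))
    pwq = _pick(qprec, qprec.argmax(axis=0))
    pdq = _pick(qprec, qprec.argmin(axis=0))

    return BioclimSet(
        MAT=RasterLayer(grid, mat),
        MTWQ=RasterLayer(grid, mtwq),
        MTCQ=RasterLayer(grid, mtcq),
        MAP=RasterLayer(grid, map_),
        PDQ=RasterLayer(grid, pdq),
        PWQ=RasterLayer(grid, pwq),
    )


def zonal_mean(layer: RasterLayer, pa: ProtectedArea) -> float:
    """Arithmetic mean of a raster over a PA's non-NODATA cells.

    Returns ``nan`` (an explicit missing value) when every cell of the PA
    is NODATA.
    """
    rows, cols = zip(*pa.cells)
    rows = np.fromiter(rows, dtype=int)
    cols = np.fromiter(cols, dtype=int)
    if rows.max() >= layer.grid.nrows or cols.max() >= layer.grid.ncols:
        raise ValueError(f"PA {pa.pa_id!r} has cells outside the raster grid")
    valid = ~layer.nodata_mask[rows, cols]
    if not valid.any():
        warnings.warn(f"PA {pa.pa_id!r}: all cells are NODATA", stacklevel=2)
        return float("nan")
    return float(layer.values[rows[valid], cols[valid]].mean())


def zonal_table(
    bioclim: BioclimSet, pas: Sequence[ProtectedArea]
) -> pd.DataFrame:
    """Per-PA zonal means of the six bioclim variables (rows indexed by pa_id)."""
    data = {
        var: [zonal_mean(layer, pa) for pa in pas]
        for var, layer in bioclim.layers().items()
    }
    return pd.DataFrame(data, index=pd.Index([pa.pa_id for pa in pas], name="pa_id"))


@dataclass
class PCAModel:
    """Standardization constants plus the first two principal axes.

    ``loadings`` is the 6x2 matrix of orthonormal axis directions in
    standardized-variable space; ``variance_explained`` holds the fraction
    of total variance carried by each retained axis.
    """

    variables: Tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_vars, 2)
    variance_explained: np.ndarray  # (2,)

    def project(self, X: Union[pd.DataFrame, np.ndarray]) -> np.ndarray:
        """Map rows of a bioclim table to (PC1, PC2) coordinates."""
        if isinstance(X, pd.DataFrame):
            X = X[list(self.variables)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.center) / self.scale
        return Z @ self.loadings


def fit_climate_pca(
    table: pd.DataFrame,
    variables: Sequence[str] = BIOCLIM_VARS,
    scale: bool = True,
) -> PCAModel:
    """Fit a 2-axis PCA on a pooled past+present per-PA bioclim table.

    Variables are centered and (by default) scaled to unit variance before
    decomposition, since the table mixes degC and mm units.  A
    zero-variance column gets scale 1 with a warning rather than failing.
    """
    X = table[list(variables)].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError(f"need >= 3 rows to fit a PCA, got {X.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in the bioclim table")
    center = X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0
        if zero.any():
            bad = [v for v, z in zip(variables, zero) if z]
            warnings.warn(
                f"zero-variance columns {bad}: scale set to 1", stacklevel=2
            )
            sd = np.where(zero, 1.0, sd)
    else:
        sd = np.ones_like(center)
    Z = (X - center) / sd
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(Z)
    return PCAModel(
        variables=tuple(variables),
        center=center,
        scale=sd,
        loadings=pca.components_.T.copy(),
        variance_explained=pca.explained_variance_ratio_.copy(),
    )


@dataclass
class ClimateDisplacement:
    """Per-PA coordinates in PCA climate space for both epochs, plus the
    Euclidean displacement between them (unitless PCA units)."""

    table: pd.DataFrame  # pc1_past, pc2_past, pc1_present, pc2_present, displacement

    @property
    def displacement(self) -> pd.Series:
        return self.table["displacement"]


def _check_aligned(past: pd.DataFrame, present: pd.DataFrame) -> None:
    a, b = set(past.index), set(present.index)
    if a != b:
        only_past = sorted(a - b)
        only_present = sorted(b - a)
        raise ValueError(
            "past/present PA ids do not match; "
            f"only in past: {only_past[:5]}, only in present: {only_present[:5]}"
        )


def climate_displacement(
    model: PCAModel, past_means: pd.DataFrame, present_means: pd.DataFrame
) -> ClimateDisplacement:
    """Euclidean distance between past and present positions in PCA space."""
    _check_aligned(past_means, present_means)
    present_means = present_means.loc[past_means.index]
    pc_past = model.project(past_means)
    pc_present = model.project(present_means)
    disp = np.hypot(
        pc_present[:, 0] - pc_past[:, 0], pc_present[:, 1] - pc_past[:, 1]
    )
    table = pd.DataFrame(
        {
            "pc1_past": pc_past[:, 0],
            "pc2_past": pc_past[:, 1],
            "pc1_present": pc_present[:, 0],
            "pc2_present": pc_present[:, 1],
            "displacement": disp,
        },
        index=past_means.index,
    )
    return ClimateDisplacement(table)


@dataclass
class DeltaMatResult:
    """Per-PA temperature change and the PAs exceeding a warming threshold."""

    delta: pd.Series
    threshold: float
    above_ids: Tuple[str, ...]

    @property
    def n_above(self) -> int:
        return len(self.above_ids)


def delta_mat(
    mat_past: pd.Series,
    mat_present: Union[pd.Series, Sequence[pd.Series]],
    threshold: float = 1.5,
) -> DeltaMatResult:
    """Per-PA change in mean annual temperature, present (or future) minus
    past, and the count of PAs warming beyond ``threshold`` degC.

    ``mat_present`` may be a sequence of layers' per-PA means (e.g. several
    climate-model projections), which are averaged before subtracting.
    """
    if not isinstance(mat_present, pd.Series):
        layers = list(mat_present)
        if not layers:
            raise ValueError("mat_present sequence is empty")
        mat_present = sum(layers[1:], layers[0].copy()) / len(layers)
    if set(mat_past.index) != set(mat_present.index):
        raise ValueError(
            "mismatched PA ids between past and present MAT: "
            f"{sorted(set(mat_past.index) ^ set(mat_present.index))[:5]}"
        )
    delta = (mat_present.loc[mat_past.index] - mat_past).rename("delta_mat")
    above = tuple(delta.index[delta > threshold])
    return DeltaMatResult(delta=delta, threshold=float(threshold), above_ids=above)
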