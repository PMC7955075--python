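"""The three per-PA vulnerability indices: species, anthropogenic, climate.

Species vulnerability weights each threatened species by a geometric
progression over IUCN category — VU: 2, EN: 4, CR: 8 — and sums the weights
of all species whose range intersects the PA, per taxon group and
cumulatively.  Anthropogenic vulnerability is the change in a PA's mean
human footprint between two epochs (later minus earlier, so an increase in
pressure is positive).  Climate vulnerability is the PA's displacement in
PCA climate space.  Each raw signal is min-max normalized to [0, 1] across
PAs before use; a degenerate (constant) raw column normalizes to all zeros,
since it carries no ranking information.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .climate import zonal_mean
from .grid import GROUPS, ProtectedArea, RasterLayer, SpeciesRecord

#: Default IUCN category weights (geometric progression).
DEFAULT_WEIGHTS: Dict[str, int] = {"VU": 2, "EN": 4, "CR": 8}

#: Names of the normalized index columns usable for hotspot testing.
INDEX_COLUMNS: Dict[str, str] = {
    "species": "species_all_norm",
    "climate": "climate_norm",
    "anthropogenic": "anthropogenic_norm",
    **{g: f"species_{g}_norm" for g in GROUPS},
}


def species_raw_score(
    pa: ProtectedArea,
    species: Sequence[SpeciesRecord],
    group: str = "all",
    weights: Mapping[str, int] = DEFAULT_WEIGHTS,
) -> int:
    """Summed category weights of the species intersecting one PA.

    A species counts if and only if its range shares at least one grid cell
    with the PA (a polygon-overlay presence test).  ``group`` restricts the
    sum to one taxon group; ``"all"`` is the cumulative score, identical to
    the sum of the five per-group scores.
    """
    if group != "all" and group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected 'all' or one of {GROUPS}")
    total = 0
    for sp in species:
        if group != "all" and sp.group != group:
            continue
        if not pa.cells.isdisjoint(sp.range_cells):
            total += weights[sp.category]
    return total


def species_score_table(
    pas: Sequence[ProtectedArea],
    species: Sequence[SpeciesRecord],
    weights: Mapping[str, int] = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Raw species scores per PA: one column per group plus ``all``.

    Uses a cell -> PA lookup so each species' range is scanned once,
    regardless of the number of PAs.
    """
    cell_to_pa: Dict[Tuple[int, int], str] = {}
    for pa in pas:
        for cell in pa.cells:
            cell_to_pa[cell] = pa.pa_id
    ids = [pa.pa_id for pa in pas]
    scores = pd.DataFrame(
        0, index=pd.Index(ids, name="pa_id"), columns=list(GROUPS) + ["all"]
    )
    for sp in species:
        hit = {cell_to_pa[c] for c in sp.range_cells if c in cell_to_pa}
        if not hit:
            continue
        w = weights[sp.category]
        rows = list(hit)
        scores.loc[rows, sp.group] += w
        scores.loc[rows, "all"] += w
    return scores


def minmax_normalize(raw: Union[pd.Series, np.ndarray]) -> Union[pd.Series, np.ndarray]:
    """Rescale values to [0, 1] by ``(x - min) / (max - min)``.

    Missing values propagate; an all-missing input is an error.  When the
    finite values are constant (``max == min``) every output is 0 — lowest
    vulnerability — with a warning, since a constant column cannot rank PAs.
    """
    values = np.asarray(raw, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("cannot normalize an all-missing vector")
    lo = values[finite].min()
    hi = values[finite].max()
    if hi == lo:
        warnings.warn(
            "constant raw vector: min-max normalization returns all zeros",
            stacklevel=2,
        )
        out = np.where(finite, 0.0, np.nan)
    else:
        out = (values - lo) / (hi - lo)
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index, name=raw.name)
    return out


def delta_hfp(
    hfp_past: RasterLayer,
    hfp_present: RasterLayer,
    pas: Sequence[ProtectedArea],
) -> pd.Series:
    """Per-PA change in mean human footprint, later epoch minus earlier.

    Positive values mean increasing human pressure.  Both rasters must share
    one grid.
    """
    if hfp_past.grid != hfp_present.grid:
        raise ValueError(
            f"HFP rasters on different grids: {hfp_past.grid} vs {hfp_present.grid}"
        )
    vals = {
        pa.pa_id: zonal_mean(hfp_present, pa) - zonal_mean(hfp_past, pa) for pa in pas
    }
    return pd.Series(vals, name="delta_hfp").rename_axis("pa_id")


def assemble_vulnerability_table(
    species_scores: pd.DataFrame,
    dhfp: pd.Series,
    displacement: pd.Series,
) -> pd.DataFrame:
    """One row per PA with raw and normalized columns for every index.

    Columns: ``species_<group>_raw`` / ``_norm`` for the five groups and
    ``all``; ``delta_hfp_raw`` / ``anthropogenic_norm``;
    ``displacement_raw`` / ``climate_norm``.  All three components must
    cover the same PA ids.
    """
    components = {
        "species_scores": set(species_scores.index),
        "delta_hfp": set(dhfp.index),
        "displacement": set(displacement.index),
    }
    ref = components["species_scores"]
    for name, ids in components.items():
        if ids != ref:
            raise ValueError(
                f"component {name!r} covers different PA ids than species_scores: "
                f"difference {sorted(ids ^ ref)[:5]}"
            )
    idx = species_scores.index
    out = pd.DataFrame(index=idx)
    for g in list(GROUPS) + ["all"]:
        out[f"species_{g}_raw"] = species_scores[g]
        out[f"species_{g}_norm"] = minmax_normalize(species_scores[g])
    out["delta_hfp_raw"] = dhfp.loc[idx]
    out["anthropogenic_norm"] = minmax_normalize(dhfp.loc[idx])
    out["displacement_raw"] = displacement.loc[idx]
    out["climate_norm"] = minmax_normalize(displacement.loc[idx])
    return out
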