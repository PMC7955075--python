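"""Synthetic landscapes with the statistical structure the analysis assumes.

The generators emulate the ingredients of a protected-area vulnerability
assessment: spatially autocorrelated climate and human-footprint fields, a
warming trend between two 10-year epochs, contiguous species ranges with a
VU/EN/CR category mix across five taxon groups, non-overlapping protected
areas, and optional "planted" hotspot signals for recovery experiments.
Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import (
    CATEGORIES,
    GROUPS,
    Cell,
    GridSpec,
    MonthlyClimateCube,
    ProtectedArea,
    RasterLayer,
    SpeciesRecord,
)

#: Human-footprint values live on a bounded 0-50 scale.
HFP_MIN, HFP_MAX = 0.0, 50.0

#: Default species counts per taxon group: the study system's threatened-species
#: pool (103 birds, 86 mammals, 134 amphibians, 50 reptiles, 2983 plants)
#: scaled down ~10x so a full analysis runs in seconds.
DEFAULT_SPECIES_COUNTS: Dict[str, int] = {
    "birds": 10,
    "mammals": 9,
    "amphibians": 13,
    "reptiles": 5,
    "plants": 298,
}

#: Default VU/EN/CR mix: vulnerable species are the most common threatened
#: class and critically endangered the rarest.
DEFAULT_CATEGORY_MIX: Tuple[float, float, float] = (0.5, 0.3, 0.2)


class CapacityError(ValueError):
    """Raised when a packing request cannot fit on the grid."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Full parameterization of one synthetic study landscape.

    The defaults mirror the study conditions at desk scale: a 10-year past
    and present climate epoch separated by a ~1.3 degC warming trend, a
    bounded 0-50 human-footprint surface rising by ~2.5 units on average
    between epochs (so that roughly a quarter of PAs see a change above 4,
    as in heavily developing protected-area systems), 100 disjoint
    protected areas, and a threatened-species pool mixed 50/30/20 across
    VU/EN/CR.

    ``planted_hotspot_ids`` lists PAs whose chosen signals
    (``planted_signals`` subset of {"species", "hfp", "climate"}) are
    inflated by ``hotspot_multiplier`` for recovery experiments.
    """

    seed: int = 0
    nrows: int = 50
    ncols: int = 50
    n_pas: int = 100
    pa_size_range: Tuple[int, int] = (4, 16)
    species_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_COUNTS)
    )
    category_mix: Tuple[float, float, float] = DEFAULT_CATEGORY_MIX
    range_size_range: Tuple[int, int] = (5, 120)
    corr_length: float = 5.0
    warming_trend: float = 1.3
    hfp_mean: float = 12.0
    hfp_sd: float = 6.0
    hfp_increment: float = 2.5
    past_years: Tuple[int, ...] = tuple(range(1961, 1971))
    present_years: Tuple[int, ...] = tuple(range(2010, 2020))
    planted_hotspot_ids: FrozenSet[str] = frozenset()
    planted_signals: FrozenSet[str] = frozenset({"species", "hfp", "climate"})
    hotspot_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise ValueError("category_mix proportions must sum to 1")
        for inc in (self.warming_trend, self.hfp_increment):
            if not math.isfinite(inc):
                raise ValueError("epoch increments must be finite")
        unknown = set(self.planted_signals) - {"species", "hfp", "climate"}
        if unknown:
            raise ValueError(f"unknown planted signals: {sorted(unknown)}")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.nrows, self.ncols)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_autocorrelated_field(
    grid: GridSpec,
    mean: float,
    sd: float,
    corr_length: float,
    seed,
) -> RasterLayer:
    """Gaussian random field with a controllable spatial correlation length.

    White noise is low-pass filtered with a Gaussian kernel of width
    ``corr_length`` (cells, periodic boundary) and then rescaled so the
    realized marginal mean and standard deviation match ``mean`` and ``sd``
    exactly.  ``corr_length = 0`` yields spatially independent noise;
    ``sd = 0`` yields a constant field.
    """
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if corr_length < 0:
        raise ValueError(f"corr_length must be >= 0, got {corr_length}")
    rng = _rng(seed)
    noise = rng.standard_normal(grid.shape)
    if corr_length > 0:
        noise = gaussian_filter(noise, sigma=corr_length, mode="wrap")
    if sd == 0:
        values = np.full(grid.shape, float(mean))
    else:
        s = noise.std()
        if s == 0:  # single-cell grid: no spread to rescale
            values = np.full(grid.shape, float(mean))
        else:
            values = mean + sd * (noise - noise.mean()) / s
    return RasterLayer(grid, values)


def simulate_monthly_climate(
    grid: GridSpec,
    epoch_years: Sequence[int],
    seasonal_amplitude: float = 10.0,
    warming_trend: float = 0.0,
    seed=0,
    *,
    base_seed: Optional[int] = None,
    base_mean_temp: float = 8.0,
    base_sd_temp: float = 4.0,
    base_mean_prec: float = 80.0,
    base_sd_prec: float = 30.0,
    interannual_sd: float = 0.6,
    corr_length: float = 5.0,
    warming_spatial_cv: float = 0.25,
) -> MonthlyClimateCube:
    """Monthly tmin/tmax/prec for one epoch of years.

    The spatial baseline (mean temperature, diurnal range, mean monthly
    precipitation) is seeded by ``base_seed`` (default: ``seed``) so two
    epochs of one scenario share a landscape; year-to-year noise is seeded
    per epoch-year *index* so identical seeds reproduce identical epochs
    regardless of calendar labels.  ``warming_trend`` shifts the epoch's
    temperatures by a spatially autocorrelated field with that mean (and
    relative spread ``warming_spatial_cv``), emulating a past-to-present
    trend that is stronger in some regions than others; the cell-mean
    shift equals ``warming_trend`` exactly, and a zero trend leaves the
    epoch untouched.
    """
    years = tuple(int(y) for y in epoch_years)
    if not years:
        raise ValueError("epoch_years must be non-empty")
    if seasonal_amplitude < 0:
        raise ValueError("seasonal_amplitude must be >= 0")
    if base_seed is None:
        base_seed = seed
    base_rng = np.random.default_rng([int(base_seed), 7])
    t_base = simulate_autocorrelated_field(
        grid, base_mean_temp, base_sd_temp, corr_length, base_rng
    ).values
    dtr = np.clip(
        simulate_autocorrelated_field(grid, 8.0, 1.5, corr_length, base_rng).values,
        0.5,
        None,
    )
    p_base = simulate_autocorrelated_field(
        grid, base_mean_prec, base_sd_prec, corr_length, base_rng
    ).values

    if warming_trend == 0:
        warm_field = np.zeros(grid.shape)
    else:
        warm_field = simulate_autocorrelated_field(
            grid,
            warming_trend,
            warming_spatial_cv * abs(warming_trend),
            corr_length,
            np.random.default_rng([int(seed), 5]),
        ).values

    months = np.arange(12)
    # Warm-season peak in July; precipitation peaks with temperature.
    season_t = -np.cos(2 * np.pi * months / 12.0) * seasonal_amplitude
    season_p = 1.0 + 0.6 * (-np.cos(2 * np.pi * months / 12.0))

    shape = (len(years), 12) + grid.shape
    tmin = np.empty(shape)
    tmax = np.empty(shape)
    prec = np.empty(shape)
    for i in range(len(years)):
        yr_rng = np.random.default_rng([int(seed), 1001 + i])
        for m in range(12):
            eps_t = yr_rng.standard_normal(grid.shape) * interannual_sd
            eps_p = yr_rng.standard_normal(grid.shape) * (0.15 * base_mean_prec)
            tmean = t_base + season_t[m] + warm_field + eps_t
            tmin[i, m] = tmean - dtr / 2.0
            tmax[i, m] = tmean + dtr / 2.0
            prec[i, m] = np.clip(p_base * season_p[m] + eps_p, 0.0, None)
    return MonthlyClimateCube(grid, years, tmin, tmax, prec)


_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _grow_region(
    grid: GridSpec,
    start: Cell,
    target: int,
    rng: np.random.Generator,
    blocked=None,
) -> Optional[FrozenSet[Cell]]:
    """Seeded region accretion from ``start``: add one uniformly chosen
    frontier cell at a time (4-connectivity), guaranteeing contiguity.
    Returns None if growth is blocked before reaching ``target``."""
    cells = {start}
    frontier: List[Cell] = []

    def extend(cell: Cell) -> None:
        r, c = cell
        for dr, dc in _NEIGHBORS:
            nb = (r + dr, c + dc)
            if grid.contains(nb) and nb not in cells:
                if blocked is None or nb not in blocked:
                    frontier.append(nb)

    extend(start)
    while len(cells) < target:
        frontier = [f for f in frontier if f not in cells]
        if not frontier:
            return None
        nb = frontier.pop(rng.integers(len(frontier)))
        cells.add(nb)
        extend(nb)
    return frozenset(cells)


def simulate_protected_areas(
    grid: GridSpec,
    n_pas: int,
    size_range: Tuple[int, int] = (4, 16),
    seed=0,
    max_tries: int = 500,
) -> List[ProtectedArea]:
    """Place ``n_pas`` pairwise-disjoint, connected protected areas.

    Each PA is grown by region accretion from a random unoccupied start cell
    to a size drawn uniformly from ``size_range``; placements overlapping an
    existing PA are rejected and retried (greedy with rejection).
    """
    lo, hi = size_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid size_range {size_range}")
    if n_pas < 1:
        raise ValueError("n_pas must be >= 1")
    if n_pas * hi > grid.n_cells:
        raise CapacityError(
            f"n_pas={n_pas} PAs of up to {hi} cells cannot fit on a "
            f"{grid.nrows}x{grid.ncols} grid ({grid.n_cells} cells); "
            "reduce n_pas or size_range"
        )
    rng = _rng(seed)
    occupied: set = set()
    pas: List[ProtectedArea] = []
    for k in range(n_pas):
        target = int(rng.integers(lo, hi + 1))
        placed = None
        for _ in range(max_tries):
            start = (int(rng.integers(grid.nrows)), int(rng.integers(grid.ncols)))
            if start in occupied:
                continue
            region = _grow_region(grid, start, target, rng, blocked=occupied)
            if region is not None:
                placed = region
                break
        if placed is None:
            raise CapacityError(
                f"could not place PA {k + 1}/{n_pas} of {target} cells after "
                f"{max_tries} tries; grid too crowded (n_pas or size_range too large)"
            )
        occupied |= placed
        pas.append(ProtectedArea(pa_id=f"PA{k:04d}", cells=placed))
    return pas


def simulate_species(
    grid: GridSpec,
    counts_per_group: Mapping[str, int],
    category_mix: Sequence[float] = DEFAULT_CATEGORY_MIX,
    range_size_dist: Tuple[int, int] = (5, 120),
    seed=0,
) -> List[SpeciesRecord]:
    """Generate species with contiguous ranges and a VU/EN/CR category mix.

    Ranges are grown by seeded region accretion from a random start cell
    (mirroring compact real range polygons) and may overlap freely; range
    sizes are uniform over ``range_size_dist``.
    """
    if not counts_per_group:
        raise ValueError("counts_per_group must name at least one group")
    unknown = set(counts_per_group) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups: {sorted(unknown)}")
    mix = np.asarray(category_mix, dtype=float)
    if mix.shape != (3,) or abs(mix.sum() - 1.0) > 1e-9 or np.any(mix < 0):
        raise ValueError("category_mix must be 3 non-negative proportions summing to 1")
    lo, hi = range_size_dist
    if not (1 <= lo <= hi <= grid.n_cells):
        raise ValueError(f"invalid range_size_dist {range_size_dist}")
    rng = _rng(seed)
    records: List[SpeciesRecord] = []
    for group in GROUPS:  # fixed group order keeps output seed-stable
        n = int(counts_per_group.get(group, 0))
        for j in range(n):
            category = CATEGORIES[int(rng.choice(3, p=mix))]
            target = int(rng.integers(lo, hi + 1))
            cells = None
            while cells is None:
                start = (int(rng.integers(grid.nrows)), int(rng.integers(grid.ncols)))
                cells = _grow_region(grid, start, target, rng)
            records.append(
                SpeciesRecord(
                    species_id=f"{group[:2]}{j:04d}",
                    group=group,
                    category=category,
                    range_cells=cells,
                )
            )
    return records


def plant_hotspots(
    scenario: SyntheticScenario,
    pas: Sequence[ProtectedArea],
    species: Sequence[SpeciesRecord],
    hfp_pair: Tuple[RasterLayer, RasterLayer],
    climate_cubes: Tuple[MonthlyClimateCube, MonthlyClimateCube],
):
    """Inject inflated vulnerability signals into the scenario's planted PAs.

    For each PA in ``scenario.planted_hotspot_ids`` the selected signals are
    boosted: *species* adds critically-endangered records confined to the PA
    until its cumulative raw score reaches ``hotspot_multiplier`` times the
    larger of its own baseline and the across-PA median; *hfp* raises the
    later-epoch footprint inside the PA by ``hotspot_multiplier`` times the
    across-PA spread of the footprint change (clamped to the 0-50 scale);
    *climate* warms the later epoch inside the PA by
    ``hotspot_multiplier`` x 0.5 degC.  All other PAs are untouched.

    Returns ``(species, hfp_pair, climate_cubes)`` — new objects; the inputs
    are not mutated.  An empty planted set returns the inputs unchanged.
    """
    planted = set(scenario.planted_hotspot_ids)
    if not planted:
        return list(species), hfp_pair, climate_cubes
    by_id = {pa.pa_id: pa for pa in pas}
    missing = planted - set(by_id)
    if missing:
        raise KeyError(f"unknown planted pa_ids: {sorted(missing)}")

    m = scenario.hotspot_multiplier
    species_out = list(species)
    hfp_past, hfp_present = hfp_pair
    cube_past, cube_present = climate_cubes

    if "species" in scenario.planted_signals:
        from .vulnerability import species_raw_score

        scores = {pa.pa_id: species_raw_score(pa, species, "all") for pa in pas}
        med = float(np.median(list(scores.values())))
        for k, pid in enumerate(sorted(planted)):
            pa = by_id[pid]
            base = max(scores[pid], med, 8.0)
            n_extra = math.ceil((m * base - scores[pid]) / 8.0)
            for j in range(max(n_extra, 0)):
                species_out.append(
                    SpeciesRecord(
                        species_id=f"planted_{pid}_{j:03d}",
                        group=GROUPS[j % len(GROUPS)],
                        category="CR",
                        range_cells=pa.cells,
                    )
                )

    if "hfp" in scenario.planted_signals:
        delta = hfp_present.values - hfp_past.values
        boost = m * max(float(np.std(delta)), 0.5)
        vals = hfp_present.values.copy()
        for pid in planted:
            rr, cc = zip(*by_id[pid].cells)
            vals[list(rr), list(cc)] = np.clip(
                vals[list(rr), list(cc)] + boost, HFP_MIN, HFP_MAX
            )
        hfp_present = RasterLayer(
            hfp_present.grid, vals, hfp_present.nodata_mask.copy()
        )

    if "climate" in scenario.planted_signals:
        warm = m * 0.5
        tmin = cube_present.tmin.copy()
        tmax = cube_present.tmax.copy()
        for pid in planted:
            rr, cc = zip(*by_id[pid].cells)
            tmin[:, :, list(rr), list(cc)] += warm
            tmax[:, :, list(rr), list(cc)] += warm
        cube_present = MonthlyClimateCube(
            cube_present.grid, cube_present.years, tmin, tmax,
            cube_present.prec.copy(),
        )

    return species_out, (hfp_past, hfp_present), (cube_past, cube_present)


def simulate_scenario(scenario: SyntheticScenario):
    """Generate the full landscape for one scenario.

    Returns a dict with keys ``pas``, ``species``, ``hfp`` (past, present
    pair), ``climate`` (past, present cubes).  Planted hotspot signals, if
    any, are already injected.  Deterministic in ``scenario.seed``.
    """
    grid = scenario.grid
    root = np.random.SeedSequence(scenario.seed)
    s_pa, s_sp, s_hfp, s_cpast, s_cpres = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    ]
    pas = simulate_protected_areas(
        grid, scenario.n_pas, scenario.pa_size_range, seed=s_pa
    )
    species = simulate_species(
        grid,
        scenario.species_counts,
        scenario.category_mix,
        scenario.range_size_range,
        seed=s_sp,
    )
    hfp_rng = np.random.default_rng(s_hfp)
    hfp_past = simulate_autocorrelated_field(
        grid, scenario.hfp_mean, scenario.hfp_sd, scenario.corr_length, hfp_rng
    )
    hfp_past.values[:] = np.clip(hfp_past.values, HFP_MIN, HFP_MAX)
    # Later epoch: shared baseline plus a spatially structured increment.
    increment = simulate_autocorrelated_field(
        grid, scenario.hfp_increment, scenario.hfp_increment,
        scenario.corr_length, hfp_rng,
    )
    hfp_present = RasterLayer(
        grid, np.clip(hfp_past.values + increment.values, HFP_MIN, HFP_MAX)
    )
    cube_past = simulate_monthly_climate(
        grid, scenario.past_years, warming_trend=0.0, seed=s_cpast,
        base_seed=s_cpast, corr_length=scenario.corr_length,
    )
    cube_present = simulate_monthly_climate(
        grid, scenario.present_years, warming_trend=scenario.warming_trend,
        seed=s_cpres, base_seed=s_cpast, corr_length=scenario.corr_length,
    )
    species, (hfp_past, hfp_present), (cube_past, cube_present) = plant_hotspots(
        scenario, pas, species, (hfp_past, hfp_present), (cube_past, cube_present)
    )
    return {
        "grid": grid,
        "pas": pas,
        "species": species,
        "hfp": (hfp_past, hfp_present),
        "climate": (cube_past, cube_present),
    }
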