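"""End-to-end driver: simulate -> climate -> indices -> hotspots -> levels
-> comparisons -> correlations, with every artifact written to disk.

All randomness flows from the seeds recorded in the config (one per
stage, spawned deterministically from the master seed), so two runs with
the same config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import climate as cm
from . import hotspots as hs
from . import stats as st
from . import synth
from . import vulnerability as vn
from .grid import pa_centroids
from .io import write_manifest


@dataclass
class PipelineConfig:
    """Every knob of one analysis run, with the study's fixed constants as
    defaults: VU/EN/CR weights 2/4/8, 1000 randomizations at alpha 0.05,
    1000 bootstrap replicates with a 90% CI, 10 distance classes for the
    modified t-test, and warming / footprint-change thresholds of 1.5 degC
    and 4 units."""

    scenario: synth.SyntheticScenario = field(default_factory=synth.SyntheticScenario)
    weights: Dict[str, int] = field(default_factory=lambda: dict(vn.DEFAULT_WEIGHTS))
    n_iter: int = 1000
    alpha: float = 0.05
    n_boot: int = 1000
    ci_level: float = 0.90
    n_classes: int = 10
    warming_threshold: float = 1.5
    hfp_change_threshold: float = 4.0
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("n_iter", "n_boot", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1 and 0 < self.ci_level < 1):
            raise ValueError("alpha and ci_level must be in (0, 1)")

    def stage_seeds(self) -> Dict[str, int]:
        """Deterministic per-stage seeds spawned from the master seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("hot_climate", "hot_anthropogenic", "hot_species",
                 "twotail_species", "boot_climate", "boot_hfp")
        return {
            name: int(s.generate_state(1)[0] % (2**31))
            for name, s in zip(names, root.spawn(len(names)))
        }

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)  # a path, not part of the analysis config
        d["scenario"]["planted_hotspot_ids"] = sorted(
            self.scenario.planted_hotspot_ids
        )
        d["scenario"]["planted_signals"] = sorted(self.scenario.planted_signals)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sc = dict(d.pop("scenario", {}))
        for key in ("planted_hotspot_ids", "planted_signals"):
            if key in sc:
                sc[key] = frozenset(sc[key])
        for key in ("pa_size_range", "category_mix", "range_size_range",
                    "past_years", "present_years"):
            if key in sc:
                sc[key] = tuple(sc[key])
        d["scenario"] = synth.SyntheticScenario(**sc)
        return cls(**d)


@dataclass
class PipelineResult:
    """In-memory bundle of every stage's output plus the summary report."""

    config: PipelineConfig
    vtable: pd.DataFrame
    null_tests: Dict[str, hs.NullTestResult]
    levels: hs.LevelAssignment
    displacement: cm.ClimateDisplacement
    delta_mat: cm.DeltaMatResult
    comparisons: Dict[str, st.BootstrapComparison]
    correlations: st.CorrelationMatrix
    report: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full vulnerability assessment on a synthetic landscape."""
    seeds = config.stage_seeds()
    sc = config.scenario
    land = synth.simulate_scenario(sc)
    grid, pas, species = land["grid"], land["pas"], land["species"]
    hfp_past, hfp_present = land["hfp"]
    cube_past, cube_present = land["climate"]

    # --- climate: climatologies, bioclim, zonal means, PCA, displacement
    bio_past = cm.compute_bioclim(cm.monthly_climatology(cube_past))
    bio_present = cm.compute_bioclim(cm.monthly_climatology(cube_present))
    zpast = cm.zonal_table(bio_past, pas)
    zpresent = cm.zonal_table(bio_present, pas)
    pooled = pd.concat([zpast, zpresent], axis=0)
    pca = cm.fit_climate_pca(pooled)
    disp = cm.climate_displacement(pca, zpast, zpresent)
    dmat = cm.delta_mat(zpast["MAT"], zpresent["MAT"], config.warming_threshold)

    # --- vulnerability indices
    sscores = vn.species_score_table(pas, species, config.weights)
    dhfp = vn.delta_hfp(hfp_past, hfp_present, pas)
    vtable = vn.assemble_vulnerability_table(sscores, dhfp, disp.displacement)

    # --- one-tailed hotspots per index, level classification
    null_tests = {
        name: hs.identify_hot_cold(
            vtable, name, "one_tailed", config.n_iter,
            seed=seeds[f"hot_{name}"], alpha=config.alpha,
        )
        for name in ("climate", "anthropogenic", "species")
    }
    levels = hs.classify_levels(
        null_tests["climate"].flags,
        null_tests["anthropogenic"].flags,
        null_tests["species"].flags,
    )

    # --- two-tailed species hot/cold + bootstrap contrasts
    twotail = hs.identify_hot_cold(
        vtable, "species", "two_tailed", config.n_iter,
        seed=seeds["twotail_species"], alpha=config.alpha,
    )
    hot_ids = sorted(twotail.hotspot_ids())
    cold_ids = sorted(twotail.coldspot_ids())
    comparisons: Dict[str, st.BootstrapComparison] = {}
    if hot_ids and cold_ids:
        comparisons["climate_change"] = st.bootstrap_diff(
            vtable.loc[hot_ids, "displacement_raw"],
            vtable.loc[cold_ids, "displacement_raw"],
            config.n_boot, config.ci_level, seed=seeds["boot_climate"],
        )
        comparisons["hfp_change"] = st.bootstrap_diff(
            vtable.loc[hot_ids, "delta_hfp_raw"],
            vtable.loc[cold_ids, "delta_hfp_raw"],
            config.n_boot, config.ci_level, seed=seeds["boot_hfp"],
        )

    # --- spatially corrected correlations among indices
    coords = pa_centroids(pas, grid)
    correlations = st.index_correlation_matrix(
        vtable, coords, n_classes=config.n_classes
    )

    # --- summary report
    n_pas = len(pas)
    uni = [pa.pa_id for pa in pas]
    hot_sets = {k: v.hotspot_ids() for k, v in null_tests.items()}
    report = {
        "n_pas": n_pas,
        "level_counts": levels.level_counts(),
        "venn": hs.venn_counts(
            hot_sets["climate"], hot_sets["anthropogenic"], hot_sets["species"], uni
        ),
        "hotspot_fractions": {
            k: len(v) / n_pas for k, v in hot_sets.items()
        },
        "n_warming_above_threshold": dmat.n_above,
        "warming_threshold": config.warming_threshold,
        "n_hfp_change_above_threshold": int(
            (vtable["delta_hfp_raw"] > config.hfp_change_threshold).sum()
        ),
        "hfp_change_threshold": config.hfp_change_threshold,
        "pca_variance_explained": [float(v) for v in pca.variance_explained],
        "two_tailed_species": {
            "n_hotspots": len(hot_ids), "n_coldspots": len(cold_ids)
        },
        "bootstrap_comparisons": {
            k: dataclasses.asdict(v) for k, v in comparisons.items()
        },
        "correlation_r": correlations.r.round(6).to_dict(),
        "seeds": seeds,
    }

    result = PipelineResult(
        config=config, vtable=vtable, null_tests=null_tests, levels=levels,
        displacement=disp, delta_mat=dmat, comparisons=comparisons,
        correlations=correlations, report=report,
    )
    if config.out_dir is not None:
        _write_outputs(result, land, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, land: dict, out: Path) -> None:
    from .io import write_ascii_grid, write_pas_geojson, write_species_csv

    out.mkdir(parents=True, exist_ok=True)
    result.vtable.to_csv(out / "vulnerability_table.csv")
    for name, test in result.null_tests.items():
        test.table.to_csv(out / f"flags_{name}.csv")
    result.levels.table.to_csv(out / "levels.csv")
    result.displacement.table.to_csv(out / "climate_displacement.csv")
    rows = [
        {"variable": k, **dataclasses.asdict(v)}
        for k, v in result.comparisons.items()
    ]
    pd.DataFrame(
        rows,
        columns=["variable", "mean_diff", "ci_low", "ci_high", "ci_level",
                 "n_boot", "significant", "p_value"],
    ).to_csv(out / "comparisons.csv", index=False)
    result.correlations.r.to_csv(out / "correlations_r.csv")
    result.correlations.p.to_csv(out / "correlations_p.csv")
    write_pas_geojson(land["pas"], land["grid"], out / "protected_areas.geojson")
    write_species_csv(land["species"], out / "species.csv")
    write_ascii_grid(land["hfp"][0], out / "hfp_past.asc")
    write_ascii_grid(land["hfp"][1], out / "hfp_present.asc")
    (out / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True), encoding="utf-8"
    )
    write_manifest(out / "manifest.json", result.config.to_dict(),
                   result.report["seeds"])
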