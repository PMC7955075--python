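"""Permutation-null hotspot/coldspot detection and 4-level classification.

Significance of a PA's vulnerability score is assessed against a null built
by shuffling the observed score vector across PAs.  Each of ``n_iter``
iterations permutes the full vector (sampling without replacement) and
records, per PA, whether the observed value strictly exceeds the permuted
value assigned to it; ties do not count, so an all-equal score vector
yields no hotspots.  A PA is a hotspot when its exceedance count falls in
the top tail: with the default 1000 iterations and one-tailed alpha = 0.05
that is a count of at least 950; the two-tailed test at the same alpha
flags hotspots at >= 975 and coldspots at <= 25.

PAs are then classified by how many of the three indices (species, climate,
anthropogenic) flag them as hotspots: all three -> Level 1, two -> Level 2,
one -> Level 3, none -> Level 4.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .vulnerability import INDEX_COLUMNS

ONE_TAILED = "one_tailed_high"
TWO_TAILED = "two_tailed"


def hotspot_threshold(n_iter: int, alpha: float, tail: str = ONE_TAILED) -> int:
    """Minimum exceedance count that flags a hotspot."""
    if tail == ONE_TAILED:
        return math.ceil((1.0 - alpha) * n_iter)
    if tail == TWO_TAILED:
        return math.ceil((1.0 - alpha / 2.0) * n_iter)
    raise ValueError(f"unknown tail {tail!r}")


def coldspot_threshold(n_iter: int, alpha: float) -> int:
    """Maximum exceedance count that flags a coldspot (two-tailed only)."""
    return math.floor((alpha / 2.0) * n_iter)


@dataclass
class NullTestResult:
    """Per-PA randomization-test outcome for one vulnerability index.

    ``table`` has columns ``exceed_count``, ``p_value`` and ``flag``
    (one of ``hotspot`` / ``coldspot`` / ``none``), indexed by pa_id.
    ``p_value = 1 - exceed_count / (n_iter + 1)`` — small when the observed
    score sits above nearly all permuted values.
    """

    table: pd.DataFrame
    n_iter: int
    tail: str
    alpha: float

    @property
    def flags(self) -> pd.Series:
        return self.table["flag"]

    def hotspot_ids(self) -> Set[str]:
        return set(self.table.index[self.table["flag"] == "hotspot"])

    def coldspot_ids(self) -> Set[str]:
        return set(self.table.index[self.table["flag"] == "coldspot"])


def randomization_test(
    scores: pd.Series,
    n_iter: int = 1000,
    tail: str = ONE_TAILED,
    alpha: float = 0.05,
    seed=0,
    chunk: int = 250,
) -> NullTestResult:
    """Permutation null test of per-PA scores.

    Each iteration shuffles the score vector across PAs; a PA's exceedance
    count is the number of iterations in which its observed score strictly
    exceeds the permuted value it received.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if tail not in (ONE_TAILED, TWO_TAILED):
        raise ValueError(f"unknown tail {tail!r}")
    obs = scores.to_numpy(dtype=float)
    n = obs.size
    if n < 2:
        raise ValueError("need at least 2 PAs")
    if not np.isfinite(obs).all():
        raise ValueError("scores must be finite")
    if np.all(obs == obs[0]):
        warnings.warn(
            "constant score vector: no PA can be flagged (strict-inequality "
            "tie rule)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exceed = np.zeros(n, dtype=np.int64)
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        perm = rng.permuted(np.broadcast_to(obs, (m, n)), axis=1)
        exceed += (obs[None, :] > perm).sum(axis=0)
        done += m

    p = 1.0 - exceed / (n_iter + 1.0)
    flag = np.full(n, "none", dtype=object)
    hi = hotspot_threshold(n_iter, alpha, tail)
    flag[exceed >= hi] = "hotspot"
    if tail == TWO_TAILED:
        lo = coldspot_threshold(n_iter, alpha)
        flag[exceed <= lo] = "coldspot"
    table = pd.DataFrame(
        {"exceed_count": exceed, "p_value": p, "flag": flag}, index=scores.index
    )
    table.index.name = "pa_id"
    return NullTestResult(table=table, n_iter=n_iter, tail=tail, alpha=alpha)


def identify_hot_cold(
    vtable: pd.DataFrame,
    index: str,
    mode: str = "one_tailed",
    n_iter: int = 1000,
    seed=0,
    alpha: float = 0.05,
) -> NullTestResult:
    """Run the randomization test on one vulnerability index of a table.

    ``index`` is an index name (``species``, ``climate``, ``anthropogenic``
    or a taxon group) or a literal column of ``vtable``.
    """
    column = INDEX_COLUMNS.get(index, index)
    if column not in vtable.columns:
        raise ValueError(
            f"unknown index/column {index!r}; known indices: "
            f"{sorted(INDEX_COLUMNS)} or a vtable column"
        )
    tail = {"one_tailed": ONE_TAILED, "two_tailed": TWO_TAILED}.get(mode, mode)
    return randomization_test(
        vtable[column], n_iter=n_iter, tail=tail, alpha=alpha, seed=seed
    )


@dataclass
class LevelAssignment:
    """Per-PA threat level with the indices that flagged it.

    ``table`` columns: ``level`` (1-4) and ``significant_indices``
    (comma-joined sorted index names, possibly empty).
    """

    table: pd.DataFrame

    def level_counts(self) -> Dict[int, int]:
        counts = self.table["level"].value_counts().to_dict()
        return {lvl: int(counts.get(lvl, 0)) for lvl in (1, 2, 3, 4)}

    def ids_at_level(self, level: int) -> Set[str]:
        return set(self.table.index[self.table["level"] == level])


def classify_levels(
    climate_flags: pd.Series,
    anthro_flags: pd.Series,
    species_flags: pd.Series,
) -> LevelAssignment:
    """Map three per-PA hotspot flag vectors to Levels 1-4.

    Level = 4 minus the number of indices flagging the PA as a hotspot
    (3 hot -> 1, 2 -> 2, 1 -> 3, 0 -> 4); coldspot and none both count as
    not-hot here.
    """
    named = {
        "climate": climate_flags,
        "anthropogenic": anthro_flags,
        "species": species_flags,
    }
    ref = set(climate_flags.index)
    for name, flags in named.items():
        if set(flags.index) != ref:
            raise ValueError(
                f"flag set {name!r} covers different PA ids: "
                f"difference {sorted(set(flags.index) ^ ref)[:5]}"
            )
    idx = climate_flags.index
    hot = pd.DataFrame(
        {name: (flags.loc[idx] == "hotspot") for name, flags in named.items()}
    )
    n_hot = hot.sum(axis=1)
    sig = hot.apply(lambda row: ",".join(sorted(c for c in hot.columns if row[c])), axis=1)
    table = pd.DataFrame({"level": 4 - n_hot, "significant_indices": sig}, index=idx)
    table.index.name = "pa_id"
    return LevelAssignment(table=table)


@dataclass(frozen=True)
class OverlapReport:
    """Set overlap between two hotspot collections within a PA universe."""

    n_a: int
    n_b: int
    n_intersection: int
    pct_of_union: float
    pct_of_a: float
    pct_of_b: float


def hotspot_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapReport:
    """Counts and percentage overlaps of two hotspot sets.

    Percentages are reported against the union, against ``set_a`` and
    against ``set_b``; an empty denominator yields 0 (the intersection is
    then necessarily empty too).  Values are unrounded.
    """
    a, b, uni = set(set_a), set(set_b), set(universe)
    stray = (a | b) - uni
    if stray:
        raise ValueError(f"ids outside the PA universe: {sorted(stray)[:5]}")
    inter = a & b
    union = a | b

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return OverlapReport(
        n_a=len(a),
        n_b=len(b),
        n_intersection=len(inter),
        pct_of_union=pct(len(inter), len(union)),
        pct_of_a=pct(len(inter), len(a)),
        pct_of_b=pct(len(inter), len(b)),
    )


def venn_counts(
    climate_hot: Set[str], anthro_hot: Set[str], species_hot: Set[str], universe
) -> Dict[str, int]:
    """Counts of the 8 regions of the three-set hotspot Venn diagram."""
    uni = set(universe)
    c, a, s = set(climate_hot), set(anthro_hot), set(species_hot)
    return {
        "climate_only": len(c - a - s),
        "anthropogenic_only": len(a - c - s),
        "species_only": len(s - c - a),
        "climate_anthropogenic": len((c & a) - s),
        "climate_species": len((c & s) - a),
        "anthropogenic_species": len((a & s) - c),
        "all_three": len(c & a & s),
        "none": len(uni - c - a - s),
    }
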