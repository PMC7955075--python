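"""Bootstrap group contrasts and spatially corrected Pearson correlations.

Two comparison tools sit here.  ``bootstrap_diff`` contrasts a variable
(e.g. climate displacement or footprint change) between hotspot and
coldspot PAs via a percentile bootstrap of the difference in group means.

``pearson_modified_ttest`` tests a Pearson correlation between two per-PA
variables while accounting for spatial autocorrelation, in the spirit of
the Clifford–Richardson–Hemon / Dutilleul correction: pairwise spatial
covariances are estimated within equal-width distance classes, combined
into an estimate of Var(r), and converted to an effective sample size
m_hat <= n + 1 that replaces n in the t test.  Under spatial independence
m_hat ~ n and the test reduces to the classical one; under strong positive
autocorrelation m_hat < n and the test loses the classical version's
anticonservative bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class BootstrapComparison:
    """Observed difference in group means with a percentile bootstrap CI.

    ``significant`` is True when the CI excludes zero; ``p_value`` is a
    two-sided bootstrap p (twice the smaller tail fraction of replicate
    differences on either side of zero).
    """

    mean_diff: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    significant: bool
    p_value: float


def bootstrap_diff(
    hot_values: Sequence[float],
    cold_values: Sequence[float],
    n_boot: int = 1000,
    ci_level: float = 0.90,
    seed=0,
) -> BootstrapComparison:
    """Percentile bootstrap of mean(hot) - mean(cold).

    Each replicate resamples each group with replacement at its own size;
    the interval is the (alpha/2, 1-alpha/2) percentile range of replicate
    differences (5th-95th at the default 90% level).
    """
    hot = np.asarray(hot_values, dtype=float)
    cold = np.asarray(cold_values, dtype=float)
    if hot.size == 0 or cold.size == 0:
        raise ValueError("both groups must be non-empty")
    if hot.size == 1 or cold.size == 1:
        warnings.warn("group of size 1: bootstrap resampling is degenerate",
                      stacklevel=2)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hot_idx = rng.integers(0, hot.size, size=(n_boot, hot.size))
    cold_idx = rng.integers(0, cold.size, size=(n_boot, cold.size))
    reps = hot[hot_idx].mean(axis=1) - cold[cold_idx].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = 2.0 * min(np.mean(reps <= 0.0), np.mean(reps >= 0.0))
    return BootstrapComparison(
        mean_diff=float(hot.mean() - cold.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=float(ci_level),
        n_boot=int(n_boot),
        significant=not (lo <= 0.0 <= hi),
        p_value=float(min(p, 1.0)),
    )


@dataclass(frozen=True)
class ModifiedCorrelation:
    """Pearson r with autocorrelation-corrected significance.

    ``m_hat`` is the effective sample size; ``df = m_hat - 2``.  When the
    correction leaves fewer than 2 effective degrees of freedom the p-value
    is indeterminate (nan).
    """

    r: float
    m_hat: float
    df: float
    t_stat: float
    p_value: float
    n: int
    n_classes: int


def _class_autocovariances(
    centered: np.ndarray, class_of_pair: np.ndarray, n_classes: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-distance-class mean cross-products of one centered variable,
    scaled by its biased variance; plus ordered-pair counts per class."""
    n = centered.size
    s2 = float(np.mean(centered**2))
    # Condensed (i<j) cross-products, matching pdist pair ordering.
    prod = (centered[:, None] * centered[None, :])[np.triu_indices(n, k=1)]
    rho = np.zeros(n_classes)
    counts = np.zeros(n_classes, dtype=np.int64)
    for k in range(n_classes):
        sel = class_of_pair == k
        m = int(sel.sum())
        counts[k] = 2 * m  # ordered pairs
        if m >= 2:
            rho[k] = float(prod[sel].mean()) / s2
        else:
            counts[k] = 0  # dropped: too few pairs to estimate
    return rho, counts


def pearson_modified_ttest(
    x: Sequence[float],
    y: Sequence[float],
    coords: np.ndarray,
    n_classes: int = 10,
) -> ModifiedCorrelation:
    """Pearson correlation with a spatially corrected t test.

    Pairwise centroid distances are stratified into ``n_classes``
    equal-width classes over (0, max distance]; within each class the mean
    cross-product of centered values estimates the spatial autocovariance
    of each variable.  The variance of r is estimated as
    ``(n + sum_k N_k rho_x(k) rho_y(k)) / n**2`` with ``N_k`` ordered-pair
    counts, the effective sample size as ``m_hat = 1 + 1 / var(r)``
    (clamped so m_hat <= n + 1), and the t statistic evaluated on
    ``m_hat - 2`` (possibly non-integer) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if y.size != n or coords.shape != (n, 2):
        raise ValueError("x, y and coords must cover the same n PAs")
    if n < 10:
        raise ValueError(f"need >= 10 PAs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(coords).all()):
        raise ValueError("non-finite input")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("x and y must be non-constant")

    r = float(np.corrcoef(x, y)[0, 1])

    d = pdist(coords)
    dmax = d.max()
    if dmax == 0:
        raise ValueError("all coordinates coincide")
    # Class k covers distances in (k*w, (k+1)*w]; zero-distance pairs of
    # distinct PAs land in the first class.
    klass = np.clip(np.ceil(d / (dmax / n_classes)).astype(int) - 1, 0, n_classes - 1)

    cx = x - x.mean()
    cy = y - y.mean()
    rho_x, counts = _class_autocovariances(cx, klass, n_classes)
    rho_y, _ = _class_autocovariances(cy, klass, n_classes)

    var_r = (n + float(np.sum(counts * rho_x * rho_y))) / n**2
    # Never claim more information than n iid samples (m_hat <= n + 1).
    var_r = max(var_r, 1.0 / n)
    m_hat = 1.0 + 1.0 / var_r
    df = m_hat - 2.0

    if abs(r) >= 1.0 - 1e-12:
        warnings.warn("|r| = 1: degenerate correlation, p set to 0", stacklevel=2)
        return ModifiedCorrelation(r, m_hat, df, float("inf"), 0.0, n, n_classes)
    if df <= 0:
        warnings.warn(
            "effective sample size m_hat <= 2: p-value indeterminate", stacklevel=2
        )
        return ModifiedCorrelation(r, m_hat, df, float("nan"), float("nan"),
                                   n, n_classes)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return ModifiedCorrelation(r, m_hat, df, float(t), p, n, n_classes)


@dataclass
class CorrelationMatrix:
    """Symmetric matrices of r, p and significance stars over index columns."""

    r: pd.DataFrame
    p: pd.DataFrame
    m_hat: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        def star(p: float) -> str:
            if not np.isfinite(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        return self.p.map(star)


def index_correlation_matrix(
    vtable: pd.DataFrame,
    coords: np.ndarray,
    columns: Optional[Sequence[str]] = None,
    n_classes: int = 10,
) -> CorrelationMatrix:
    """Pairwise modified-test correlations among vulnerability indices.

    Default columns are every normalized index of the vulnerability table
    (five taxon groups, cumulative species, climate, anthropogenic).
    Constant columns are kept in the matrix but marked indeterminate (nan)
    off-diagonal.
    """
    if columns is None:
        columns = [c for c in vtable.columns if c.endswith("_norm")]
    columns = list(columns)
    if len(columns) < 2:
        raise ValueError("need at least 2 index columns")
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    m = pd.DataFrame(np.full((k, k), np.nan), index=columns, columns=columns)
    const = {c for c in columns if vtable[c].nunique() <= 1}
    if const:
        warnings.warn(f"constant columns marked indeterminate: {sorted(const)}",
                      stacklevel=2)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = columns[i], columns[j]
            if a in const or b in const:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = pearson_modified_ttest(
                vtable[a].to_numpy(), vtable[b].to_numpy(), coords, n_classes
            )
            r.loc[a, b] = r.loc[b, a] = res.r
            p.loc[a, b] = p.loc[b, a] = res.p_value
            m.loc[a, b] = m.loc[b, a] = res.m_hat
    return CorrelationMatrix(r=r, p=p, m_hat=m)
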