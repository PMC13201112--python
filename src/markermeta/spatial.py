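"""Spatial autocorrelation on spot lattices: kNN weights, Moran's I,
Lee's L, permutation inference, and covariate residualization.

Spatial weights are k-nearest-neighbor by Euclidean distance (self
excluded, distance ties broken by ascending spot index) and row-
standardized so each spot's k weights sum to 1 (spdep "W" style).

Moran's I (univariate clustering, null expectation -1/(n-1)):

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

with S0 = sum of all weights = n for row-standardized rows.

Lee's L (bivariate spatial association of x and y through their spatial
lags):

    L = n / sum_i (sum_j w_ij)^2
        * sum_i [ (sum_j w_ij z_xj) (sum_j w_ij z_yj) ]
        / ( sqrt(sum z_x^2) * sqrt(sum z_y^2) )

Significance comes from permutation tests with p = (1 + #{T_perm in
tail}) / (1 + n_perm); with 999 permutations the attainable p floor is
0.001.  For bivariate statistics one vector (the second argument) is
permuted while the other is held fixed.  Sequencing-depth artifacts are
handled by OLS-residualizing log UMI counts out of each variable before
recomputing the statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

IMMUNE_FRACTION_COLUMNS = ("cd8_t", "cd4_t", "b_cell", "nk", "macrophage")


@dataclass
class SpatialWeights:
    """Row-standardized kNN weights: neighbors (n, k) and weights (n, k)."""

    n: int
    neighbors: np.ndarray
    weights: np.ndarray

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]

    def lag(self, values: np.ndarray) -> np.ndarray:
        """Spatial lag: per spot, the weighted mean of its neighbors' values."""
        values = np.asarray(values, dtype=float)
        return np.sum(self.weights * values[self.neighbors], axis=1)


@dataclass(frozen=True)
class SpatialTestResult:
    statistic: float
    expectation: float
    p: float
    n_perm: int
    alternative: str


def knn_weights(coords: np.ndarray, k: int = 6, binary: bool = False) -> SpatialWeights:
    """k-nearest-neighbor spatial weights from an n x 2 coordinate array.

    Default k=6 matches the hex-grid neighborhood of Visium arrays.  Ties
    in distance are broken by ascending spot index (deterministic).
    Duplicate coordinates are permitted and logged.  ``binary=True`` keeps
    0/1 weights instead of row-standardizing (each row then sums to k).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k < 1 or k >= n:
        raise ValidationError(f"need 1 <= k < n (k={k}, n={n})")
    if len(np.unique(coords, axis=0)) < n:
        logger.warning("duplicate coordinates present; ties broken by index")
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # stable sort => equal distances keep ascending index order
    neighbors = np.argsort(d2, axis=1, kind="stable")[:, :k]
    weights = np.ones((n, k)) if binary else np.full((n, k), 1.0 / k)
    return SpatialWeights(n=n, neighbors=neighbors, weights=weights)


def _check_vector(values: np.ndarray, w: SpatialWeights, name: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if len(v) != w.n:
        raise ValidationError(f"{name}: length {len(v)} != {w.n} spots")
    if np.ptp(v) == 0:
        raise ValidationError(f"{name}: constant vector has no spatial structure")
    return v


def morans_i(values: np.ndarray, w: SpatialWeights) -> float:
    """Global Moran's I of one spot-level variable."""
    z = _check_vector(values, w, "values")
    z = z - z.mean()
    s0 = float(w.weights.sum())
    num = float(np.sum(z * np.sum(w.weights * z[w.neighbors], axis=1)))
    return (w.n / s0) * num / float(np.sum(z ** 2))


def lees_l(x: np.ndarray, y: np.ndarray, w: SpatialWeights) -> float:
    """Lee's L bivariate spatial association between two spot-level variables."""
    zx = _check_vector(x, w, "x")
    zy = _check_vector(y, w, "y")
    zx = zx - zx.mean()
    zy = zy - zy.mean()
    row_sums = w.weights.sum(axis=1)
    denom_w = float(np.sum(row_sums ** 2))
    lag_x = w.lag(zx)
    lag_y = w.lag(zy)
    num = float(np.sum(lag_x * lag_y))
    scale = float(np.sqrt(np.sum(zx ** 2)) * np.sqrt(np.sum(zy ** 2)))
    return (w.n / denom_w) * num / scale


def permutation_test(stat_fn: Callable[..., float],
                     fixed: np.ndarray | tuple[np.ndarray, np.ndarray],
                     w: SpatialWeights,
                     n_perm: int = 999,
                     alternative: str = "greater",
                     seed: int = 0) -> SpatialTestResult:
    """Permutation test of a spatial statistic.

    ``fixed`` is either one vector (univariate statistic, the vector is
    permuted across spots) or an (x, y) pair (bivariate: y is permuted, x
    held fixed).  p = (1 + #{T_perm >= T_obs}) / (1 + n_perm) for
    ``alternative="greater"``, mirrored for "less", doubled-tail (capped at
    1) for "two-sided".  Reported expectation is the permutation mean.
    Reproducible bit-for-bit for a given (seed, n_perm).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValidationError(f"invalid alternative {alternative!r}")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(fixed, tuple):
        x, y = fixed
        observed = float(stat_fn(x, y, w))
        y = np.asarray(y, dtype=float)
        perm_stats = np.array([
            stat_fn(x, y[rng.permutation(w.n)], w) for _ in range(n_perm)
        ])
    else:
        v = np.asarray(fixed, dtype=float)
        observed = float(stat_fn(v, w))
        perm_stats = np.array([
            stat_fn(v[rng.permutation(w.n)], w) for _ in range(n_perm)
        ])
    ge = int(np.sum(perm_stats >= observed))
    le = int(np.sum(perm_stats <= observed))
    if alternative == "greater":
        p = (1 + ge) / (1 + n_perm)
    elif alternative == "less":
        p = (1 + le) / (1 + n_perm)
    else:
        p = min(1.0, 2.0 * min((1 + ge) / (1 + n_perm), (1 + le) / (1 + n_perm)))
    return SpatialTestResult(statistic=observed,
                             expectation=float(perm_stats.mean()),
                             p=float(p), n_perm=n_perm, alternative=alternative)


def composite_immune_score(fractions: pd.DataFrame) -> np.ndarray:
    """Per-spot sum of CD8+ T, CD4+ T, B, NK, and macrophage fractions."""
    missing = [c for c in IMMUNE_FRACTION_COLUMNS if c not in fractions.columns]
    if missing:
        raise ValidationError(f"composite immune score: missing columns {missing}")
    return fractions[list(IMMUNE_FRACTION_COLUMNS)].sum(axis=1).to_numpy(dtype=float)


def residualize(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """OLS residuals of values on [1, covariate]; mean-zero and orthogonal
    to the covariate."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if v.shape != c.shape:
        raise ValidationError("residualize: length mismatch")
    if np.ptp(c) == 0:
        raise ValidationError("residualize: constant covariate")
    X = np.column_stack([np.ones_like(c), c])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta
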