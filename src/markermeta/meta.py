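"""Standardized-mean-difference meta-analysis.

Per-study effects are Hedges' g (pooled-SD Cohen's d times the small-sample
factor J = 1 - 3/(4m - 1), m = n1 + n0 - 2) with sampling variance
(n1+n0)/(n1*n0) + g^2 / (2(n1+n0)).  Studies are pooled under a
DerSimonian-Laird random-effects model:

    tau^2 = max(0, (Q - df) / C),   C = sum(w) - sum(w^2)/sum(w),  w = 1/v
    I^2   = max(0, (Q - df) / Q) * 100

with random-effects weights 1/(v + tau^2).  The 95% CI on the pooled
estimate uses normal quantiles; the 95% prediction interval uses a
t-quantile with k - 2 degrees of freedom (Higgins convention) and therefore
needs k >= 3.

Small-study/publication bias is assessed by Egger's regression test
(intercept t-test of g/SE on 1/SE, k - 2 df) and the Begg-Mazumdar rank
correlation test (Kendall's tau-b between variance-stabilized deviations
from the fixed-effect mean and the sampling variances, normal approximation
with tie correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .exceptions import ValidationError
from .io import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyEffect:
    """One study's standardized mean difference and its sampling variance."""

    study_id: str
    g: float
    var_g: float
    n1: int
    n0: int

    def __post_init__(self) -> None:
        if self.var_g <= 0:
            raise ValidationError(f"{self.study_id}: var_g must be positive")
        if self.n1 < 2 or self.n0 < 2:
            raise ValidationError(f"{self.study_id}: each group needs n >= 2")

    @property
    def se(self) -> float:
        return math.sqrt(self.var_g)


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects synthesis: estimate, CI, heterogeneity, prediction interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    q: float
    df: int
    tau2: float
    i2: float
    pred_low: float
    pred_high: float
    k: int


@dataclass(frozen=True)
class BiasTestResult:
    method: str  # "egger" | "begg"
    statistic: float
    p: float


def hedges_g(m1: float, s1: float, n1: int, m0: float, s0: float, n0: int,
             study_id: str = "study") -> StudyEffect:
    """Hedges' g between a tumor group (m1, s1, n1) and normal group (m0, s0, n0)."""
    if n1 < 2 or n0 < 2:
        raise ValidationError(f"{study_id}: each group needs n >= 2")
    if s1 <= 0 or s0 <= 0:
        raise ValidationError(f"{study_id}: group SDs must be positive")
    m = n1 + n0 - 2
    sp = math.sqrt(((n1 - 1) * s1 ** 2 + (n0 - 1) * s0 ** 2) / m)
    if sp == 0:
        raise ValidationError(f"{study_id}: pooled SD is zero")
    d = (m1 - m0) / sp
    J = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = J * d
    var_g = (n1 + n0) / (n1 * n0) + g ** 2 / (2.0 * (n1 + n0))
    return StudyEffect(study_id=study_id, g=g, var_g=var_g, n1=n1, n0=n0)


def effect_from_dataset(ds: ExpressionDataset, gene: str) -> StudyEffect:
    """Compute a study's Hedges' g for one gene from its expression matrix."""
    values = ds.gene_values(gene)
    t = values[ds.group_mask("tumor")]
    c = values[ds.group_mask("normal")]
    if len(t) < 2 or len(c) < 2:
        raise ValidationError(f"{ds.dataset_id}: each group needs n >= 2")
    return hedges_g(
        float(t.mean()), float(t.std(ddof=1)), len(t),
        float(c.mean()), float(c.std(ddof=1)), len(c),
        study_id=ds.dataset_id,
    )


def dl_pool(effects: Sequence[StudyEffect]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling of study effects."""
    k = len(effects)
    if k < 2:
        raise ValidationError("random-effects pooling needs k >= 2 studies")
    y = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    w = 1.0 / v
    y_fixed = float(np.sum(w * y) / np.sum(w))
    df = k - 1
    q = float(np.sum(w * (y - y_fixed) ** 2))
    c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c)
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    w_re = 1.0 / (v + tau2)
    estimate = float(np.sum(w_re * y) / np.sum(w_re))
    se = float(1.0 / math.sqrt(np.sum(w_re)))
    z = stats.norm.ppf(0.975)
    ci_low, ci_high = estimate - z * se, estimate + z * se

    if k >= 3:
        t_crit = stats.t.ppf(0.975, k - 2)
        half = t_crit * math.sqrt(tau2 + se ** 2)
        pred_low, pred_high = estimate - half, estimate + half
    else:
        logger.warning("prediction interval needs k >= 3; reporting NaN")
        pred_low = pred_high = float("nan")

    return PooledEffect(
        estimate=estimate, se=se, ci_low=ci_low, ci_high=ci_high,
        q=q, df=df, tau2=tau2, i2=i2,
        pred_low=pred_low, pred_high=pred_high, k=k,
    )


def egger_test(effects: Sequence[StudyEffect]) -> BiasTestResult:
    """Egger's regression asymmetry test.

    Regresses the standardized effect g/SE on precision 1/SE; the intercept's
    two-sided t-test (k - 2 df) is the asymmetry statistic.
    """
    k = len(effects)
    if k < 3:
        raise ValidationError("Egger's test needs k >= 3 studies")
    se = np.array([e.se for e in effects])
    y = np.array([e.g for e in effects]) / se
    X = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, X).fit()
    t_val = float(fit.tvalues[0])
    p = float(2.0 * stats.t.sf(abs(t_val), k - 2))
    return BiasTestResult(method="egger", statistic=t_val, p=p)


def begg_test(effects: Sequence[StudyEffect]) -> BiasTestResult:
    """Begg-Mazumdar rank correlation test for funnel-plot asymmetry.

    Correlates variance-stabilized deviations from the fixed-effect mean,
    t_i = (g_i - g_FE) / sqrt(v_i - 1/sum(1/v_j)), with the sampling
    variances v_i via Kendall's tau-b; two-sided p from the normal
    approximation to Kendall's S with tie correction.
    """
    k = len(effects)
    if k < 3:
        raise ValidationError("Begg's test needs k >= 3 studies")
    y = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    if np.ptp(v) == 0:
        logger.warning("all sampling variances equal; Begg ranks degenerate, p = 1")
        return BiasTestResult(method="begg", statistic=0.0, p=1.0)
    w = 1.0 / v
    y_fixed = np.sum(w * y) / np.sum(w)
    var_dev = v - 1.0 / np.sum(w)
    # guard: the subtraction can hit 0 to rounding for a dominating study
    var_dev = np.maximum(var_dev, np.finfo(float).tiny)
    t_star = (y - y_fixed) / np.sqrt(var_dev)

    s_stat, tau = _kendall_s(t_star, v)
    var_s = _kendall_var_s(t_star, v)
    if var_s <= 0:
        return BiasTestResult(method="begg", statistic=tau, p=1.0)
    z = s_stat / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BiasTestResult(method="begg", statistic=tau, p=min(1.0, p))


def _kendall_s(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's S (concordant minus discordant) and tau-b for paired vectors."""
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, 1)
    s = float(np.sum(dx[iu] * dy[iu]))
    n0 = n * (n - 1) / 2.0
    tx = n0 - np.sum(np.abs(dx[iu]))
    ty = n0 - np.sum(np.abs(dy[iu]))
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    tau = s / denom if denom > 0 else 0.0
    return s, tau


def _kendall_var_s(x: np.ndarray, y: np.ndarray) -> float:
    """Variance of Kendall's S under the null, with tie correction."""
    n = len(x)

    def tie_terms(v: np.ndarray) -> tuple[float, float, float]:
        _, counts = np.unique(v, return_counts=True)
        t1 = float(np.sum(counts * (counts - 1) * (2 * counts + 5)))
        t2 = float(np.sum(counts * (counts - 1) * (counts - 2)))
        t3 = float(np.sum(counts * (counts - 1)))
        return t1, t2, t3

    x1, x2, x3 = tie_terms(x)
    y1, y2, y3 = tie_terms(y)
    base = n * (n - 1) * (2 * n + 5)
    var_s = (base - x1 - y1) / 18.0
    if n > 2:
        var_s += x2 * y2 / (9.0 * n * (n - 1) * (n - 2))
    var_s += x3 * y3 / (2.0 * n * (n - 1))
    return var_s


def forest_table(effects: Sequence[StudyEffect], pooled: PooledEffect) -> "pd.DataFrame":
    """Per-study forest-plot table: g, 95% CI, and random-effects weight %."""
    import pandas as pd

    z = stats.norm.ppf(0.975)
    w_re = np.array([1.0 / (e.var_g + pooled.tau2) for e in effects])
    weights = 100.0 * w_re / w_re.sum()
    return pd.DataFrame({
        "study_id": [e.study_id for e in effects],
        "g": [e.g for e in effects],
        "ci_low": [e.g - z * e.se for e in effects],
        "ci_high": [e.g + z * e.se for e in effects],
        "weight_pct": weights,
    })
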