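"""Median-dichotomized diagnostic synthesis: 2x2 tables, Moses-Littenberg
summary ROC, and pooled accuracy.

Each cohort's continuous biomarker values are dichotomized at the cohort
median (strictly greater than the median counts as test-positive), yielding
one TP/FP/FN/TN table per cohort.  Across cohorts the Moses-Littenberg
model regresses the log diagnostic odds ratio D = logit(sens) -
logit(1-spec) on the threshold proxy S = logit(sens) + logit(1-spec) by
unweighted least squares; the summary curve is recovered through

    logit(TPR) = a/(1-b) + ((1+b)/(1-b)) * logit(FPR)

and its area is obtained by trapezoidal integration on a 10,001-point FPR
grid with the endpoint limits TPR(0)=0, TPR(1)=1 (valid for |b| < 1).

Pooled sensitivity and specificity are univariate DerSimonian-Laird
syntheses of the per-study logits, with variances 1/tp + 1/fn and
1/tn + 1/fp on continuity-corrected cells, back-transformed through the
inverse logit.  A 0.5 continuity correction is added to ALL four cells of
any table containing a zero cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import DegenerateModelError, ValidationError
from .io import ContingencyTable, ExpressionDataset
from .meta import StudyEffect, dl_pool

DEFAULT_GRID_POINTS = 10_001


@dataclass(frozen=True)
class SROCModel:
    """Moses-Littenberg fit: D = a + b*S, with summary-curve AUC."""

    a: float
    b: float
    auc: float
    k: int
    corrected: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PooledAccuracy:
    sens: float
    sens_ci: tuple[float, float]
    spec: float
    spec_ci: tuple[float, float]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray | float):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def dichotomize_at_median(ds: ExpressionDataset, gene: str) -> ContingencyTable:
    """Split a cohort into a 2x2 diagnostic table at the gene's median.

    The threshold is the median over ALL samples (tumor and normal); a
    sample is predicted positive iff its value is strictly greater than the
    threshold, so ties at the median are predicted negative.
    """
    values = ds.gene_values(gene)
    tumor = ds.group_mask("tumor")
    normal = ds.group_mask("normal")
    if not tumor.any() or not normal.any():
        raise ValidationError(f"{ds.dataset_id}: both groups must be non-empty")
    threshold = float(np.median(values))
    positive = values > threshold
    return ContingencyTable(
        study_id=ds.dataset_id,
        tp=int(np.sum(positive & tumor)),
        fp=int(np.sum(positive & normal)),
        fn=int(np.sum(~positive & tumor)),
        tn=int(np.sum(~positive & normal)),
    )


def corrected_cells(ct: ContingencyTable) -> tuple[float, float, float, float]:
    """TP/FP/FN/TN with 0.5 added to all four cells if any cell is zero."""
    cells = (ct.tp, ct.fp, ct.fn, ct.tn)
    if 0 in cells:
        return tuple(c + 0.5 for c in cells)  # type: ignore[return-value]
    return tuple(float(c) for c in cells)  # type: ignore[return-value]


def sens_spec(ct: ContingencyTable, correct: bool = False) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp), optionally
    continuity-corrected (0.5 on all four cells when any cell is zero)."""
    tp, fp, fn, tn = corrected_cells(ct) if correct else map(float, (ct.tp, ct.fp, ct.fn, ct.tn))
    return tp / (tp + fn), tn / (tn + fp)


def moses_littenberg_fit(tables: Sequence[ContingencyTable],
                         weighted: bool = False,
                         n_points: int = DEFAULT_GRID_POINTS) -> SROCModel:
    """Fit the Moses-Littenberg D-on-S regression and integrate the AUC.

    Unweighted least squares is the default (classical variant);
    ``weighted=True`` uses inverse-variance weights 1/(1/tp+1/fp+1/fn+1/tn)
    on corrected cells.  If the studies' S values have zero variance, the
    slope is fixed at 0 and the model flagged degenerate.
    """
    k = len(tables)
    if k < 3:
        raise ValidationError("Moses-Littenberg fit needs k >= 3 studies")
    corrected_any = False
    D, S, W = [], [], []
    for ct in tables:
        cells = corrected_cells(ct)
        corrected_any |= cells != (float(ct.tp), float(ct.fp), float(ct.fn), float(ct.tn))
        tp, fp, fn, tn = cells
        sens = tp / (tp + fn)
        fpr = fp / (fp + tn)
        D.append(_logit(sens) - _logit(fpr))
        S.append(_logit(sens) + _logit(fpr))
        W.append(1.0 / (1.0 / tp + 1.0 / fp + 1.0 / fn + 1.0 / tn))
    D_arr, S_arr = np.array(D), np.array(S)
    w = np.array(W) if weighted else np.ones(k)

    degenerate = False
    if np.ptp(S_arr) == 0:
        b = 0.0
        a = float(np.average(D_arr, weights=w))
        degenerate = True
    else:
        X = np.column_stack([np.ones(k), S_arr])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], D_arr * sw, rcond=None)
        a, b = float(beta[0]), float(beta[1])

    if abs(b) >= 1:
        return SROCModel(a=a, b=b, auc=float("nan"), k=k,
                         corrected=corrected_any, degenerate=True)
    auc = _sroc_auc(a, b, n_points)
    return SROCModel(a=a, b=b, auc=auc, k=k,
                     corrected=corrected_any, degenerate=degenerate)


def _sroc_tpr(a: float, b: float, fpr: np.ndarray) -> np.ndarray:
    logit_fpr = np.log(fpr / (1.0 - fpr))
    return _inv_logit(a / (1.0 - b) + (1.0 + b) / (1.0 - b) * logit_fpr)


def _sroc_auc(a: float, b: float, n_points: int) -> float:
    fpr = np.linspace(0.0, 1.0, n_points)
    tpr = np.empty_like(fpr)
    tpr[0], tpr[-1] = 0.0, 1.0  # limits of the back-transform
    tpr[1:-1] = _sroc_tpr(a, b, fpr[1:-1])
    return float(np.trapezoid(tpr, fpr))


def sroc_curve_points(model: SROCModel, n_points: int = 1_000) -> np.ndarray:
    """Points (fpr, tpr) on the fitted summary curve, on an open grid of (0, 1)."""
    if abs(model.b) >= 1:
        raise DegenerateModelError(
            f"SROC slope |b|={abs(model.b):.3f} >= 1; curve back-transform undefined"
        )
    fpr = np.linspace(0.0, 1.0, n_points + 2)[1:-1]
    return np.column_stack([fpr, _sroc_tpr(model.a, model.b, fpr)])


def pool_logit_accuracy(tables: Sequence[ContingencyTable]) -> PooledAccuracy:
    """DL random-effects pooling of logit sensitivity and logit specificity.

    Variances are 1/tp + 1/fn (sensitivity) and 1/tn + 1/fp (specificity)
    on continuity-corrected cells; point estimate and CI are back-transformed
    through the inverse logit.  A univariate approximation — the joint
    (bivariate) distribution of sensitivity and specificity is not modeled.
    """
    if len(tables) < 2:
        raise ValidationError("pooled accuracy needs k >= 2 studies")
    sens_eff, spec_eff = [], []
    for ct in tables:
        tp, fp, fn, tn = corrected_cells(ct)
        sens_eff.append(StudyEffect(
            study_id=ct.study_id, g=_logit(tp / (tp + fn)),
            var_g=1.0 / tp + 1.0 / fn,
            n1=max(2, ct.n_diseased), n0=max(2, ct.n_healthy)))
        spec_eff.append(StudyEffect(
            study_id=ct.study_id, g=_logit(tn / (tn + fp)),
            var_g=1.0 / tn + 1.0 / fp,
            n1=max(2, ct.n_diseased), n0=max(2, ct.n_healthy)))
    ps = dl_pool(sens_eff)
    pp = dl_pool(spec_eff)
    return PooledAccuracy(
        sens=float(_inv_logit(ps.estimate)),
        sens_ci=(float(_inv_logit(ps.ci_low)), float(_inv_logit(ps.ci_high))),
        spec=float(_inv_logit(pp.estimate)),
        spec_ci=(float(_inv_logit(pp.ci_low)), float(_inv_logit(pp.ci_high))),
    )
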