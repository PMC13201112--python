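"""Expression-derived copy-number scoring for single cells.

The procedure infers a per-cell copy-number burden from log-scale
expression alone, anchored to a presumed-diploid reference population
(B cells in colorectal tumors):

1. **Reference centering** — per gene, subtract the mean over reference
   cells, so the reference profile is ~0 everywhere.
2. **Genomic smoothing** — order genes by (chromosome, start) and replace
   each gene's value by a running mean over its genomic neighbors on the
   same chromosome (window truncated at chromosome ends).  Copy-number
   events move contiguous blocks of genes together; smoothing suppresses
   single-gene transcriptional noise while preserving segment shifts.
3. **Median filtering** — a sliding-window median within each chromosome
   removes residual spikes from the smoothed trace.
4. **Thresholding** — per gene, compute mean mu and SD sigma over the
   reference cells of the *smoothed* trace; a cell's gene value scores
   0 if |v - mu| <= 2 sigma, 1 if within (2 sigma, k_outer sigma]
   (single-copy-level deviation) and 2 beyond k_outer sigma
   (multi-copy-level).  Gains and losses are scored jointly by absolute
   deviation; the signed deviation is available as a side channel.
5. **Malignancy call** — the per-cell total score is the column sum of
   gene scores; cells strictly above the median total are called malignant.

The boundary between score 1 and score 2 has no canonical value; the
default ``k_outer = 4`` (beyond mean +/- 4 SD) is exposed as a parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import GenePosition

logger = logging.getLogger(__name__)

DEFAULT_SMOOTH_WINDOW = 101
DEFAULT_MEDIAN_WIDTH = 5
DEFAULT_K_OUTER = 4.0


@dataclass
class CNVScoreResult:
    """Per-cell per-gene integer CNV scores with totals and malignancy calls.

    ``gene_scores`` is genes x cells with values in {0, 1, 2}; ``total`` is
    the per-cell column sum; ``malignant`` flags cells whose total is
    strictly above the median total.  ``signed`` carries the smoothed
    deviation's sign for scored genes (side channel; 0 where score is 0).
    """

    cells: list[str]
    gene_scores: pd.DataFrame
    total: pd.Series
    malignant: pd.Series
    signed: pd.DataFrame | None = None


def _check_reference(columns, reference_cells: Sequence[str]) -> list[str]:
    ref = list(reference_cells)
    if not ref:
        raise ValidationError("reference cell set is empty")
    missing = sorted(set(ref) - set(columns))
    if missing:
        raise ValidationError(f"reference cells not in matrix: {missing}")
    return ref


def reference_center(expr: pd.DataFrame, reference_cells: Sequence[str]) -> pd.DataFrame:
    """Subtract each gene's mean over the reference cells (log-scale input)."""
    ref = _check_reference(expr.columns, reference_cells)
    return expr.sub(expr[ref].mean(axis=1), axis=0)


def order_genes(expr: pd.DataFrame, positions: Sequence[GenePosition]) -> tuple[pd.DataFrame, list[GenePosition]]:
    """Reindex a genes-x-cells matrix into genomic (chrom, start) order."""
    by_gene = {p.gene: p for p in positions}
    missing = sorted(set(expr.index) - set(by_gene))
    if missing:
        raise ValidationError(f"genes without positions: {missing}")
    ordered = sorted((by_gene[g] for g in expr.index))
    return expr.loc[[p.gene for p in ordered]], ordered


def _running_mean_trunc(block: np.ndarray, window: int) -> np.ndarray:
    """Truncated-window running mean along axis 0 via cumulative sums."""
    n = block.shape[0]
    half = window // 2
    cs = np.vstack([np.zeros((1,) + block.shape[1:]), np.cumsum(block, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def genomic_smooth(centered: pd.DataFrame, positions: Sequence[GenePosition],
                   window: int = DEFAULT_SMOOTH_WINDOW) -> tuple[pd.DataFrame, list[GenePosition]]:
    """Running mean over genomic neighbor genes, per chromosome.

    Genes are sorted by (chromosome, start); each gene's value becomes the
    mean over the ``window`` genes centered on it, truncated at chromosome
    ends.  ``window`` must be odd; window=1 is the identity.  Returns the
    smoothed matrix (in genomic order) and the sorted positions.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"smoothing window must be odd and >= 1, got {window}")
    ordered, pos = order_genes(centered, positions)
    values = ordered.to_numpy(dtype=float)
    out = np.empty_like(values)
    chroms = np.array([p.chrom for p in pos])
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        out[idx] = _running_mean_trunc(values[idx], window)
    return pd.DataFrame(out, index=ordered.index, columns=ordered.columns), pos


def median_filter_trace(values: np.ndarray, width: int = DEFAULT_MEDIAN_WIDTH) -> np.ndarray:
    """Sliding-window median of a per-gene trace, edges truncated.

    At positions closer than width//2 to either end the median is taken
    over the available (shorter) window.  ``width`` must be odd; width=1
    is the identity.
    """
    if width < 1 or width % 2 == 0:
        raise ValidationError(f"median filter width must be odd and >= 1, got {width}")
    v = np.asarray(values, dtype=float)
    n = len(v)
    if width == 1 or n == 0:
        return v.copy()
    half = width // 2
    out = np.empty(n)
    if n >= width:
        windows = np.lib.stride_tricks.sliding_window_view(v, width)
        out[half:n - half] = np.median(windows, axis=1)
        edge = half
    else:
        edge = n  # whole trace shorter than the window
    for i in range(min(edge, n)):
        out[i] = np.median(v[max(0, i - half):i + half + 1])
    for i in range(max(n - edge, 0), n):
        out[i] = np.median(v[max(0, i - half):i + half + 1])
    return out


def median_filter_matrix(smoothed: pd.DataFrame, positions: Sequence[GenePosition],
                         width: int = DEFAULT_MEDIAN_WIDTH) -> pd.DataFrame:
    """Apply :func:`median_filter_trace` per cell within each chromosome."""
    values = smoothed.to_numpy(dtype=float)
    out = np.empty_like(values)
    chroms = np.array([p.chrom for p in positions])
    for chrom in pd.unique(chroms):
        idx = np.where(chroms == chrom)[0]
        block = values[idx]
        out[idx] = np.apply_along_axis(median_filter_trace, 0, block, width)
    return pd.DataFrame(out, index=smoothed.index, columns=smoothed.columns)


def score_cnv(smoothed: pd.DataFrame, reference_cells: Sequence[str],
              k_outer: float = DEFAULT_K_OUTER) -> CNVScoreResult:
    """Threshold smoothed deviations against the reference mean +/- SD bands.

    Per gene, mu and sigma are computed over the reference cells of the
    smoothed matrix (so thresholds match the scored quantity).  Scores:
    0 within 2 sigma, 1 within (2, k_outer] sigma, 2 beyond.  Genes with
    sigma = 0 score 0 everywhere (logged).  Malignant = total strictly
    above the median total.
    """
    ref = _check_reference(smoothed.columns, reference_cells)
    if k_outer <= 2:
        raise ValidationError(f"k_outer must exceed 2, got {k_outer}")
    mu = smoothed[ref].mean(axis=1).to_numpy()
    sigma = smoothed[ref].std(axis=1, ddof=1).to_numpy()
    zero_sd = sigma == 0
    if zero_sd.any():
        logger.warning("%d gene(s) with zero reference SD scored 0", zero_sd.sum())
    dev = smoothed.to_numpy() - mu[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(dev) / sigma[:, None]
    z[zero_sd, :] = 0.0
    scores = np.zeros(smoothed.shape, dtype=int)
    scores[z > 2.0] = 1
    scores[z > k_outer] = 2
    gene_scores = pd.DataFrame(scores, index=smoothed.index, columns=smoothed.columns)
    total = gene_scores.sum(axis=0)
    malignant = total > total.median()
    signed = pd.DataFrame(np.sign(dev) * (scores > 0),
                          index=smoothed.index, columns=smoothed.columns)
    return CNVScoreResult(cells=list(smoothed.columns), gene_scores=gene_scores,
                          total=total, malignant=malignant, signed=signed)


def cnv_pipeline(expr: pd.DataFrame, positions: Sequence[GenePosition],
                 reference_cells: Sequence[str],
                 window: int = DEFAULT_SMOOTH_WINDOW,
                 median_width: int = DEFAULT_MEDIAN_WIDTH,
                 k_outer: float = DEFAULT_K_OUTER) -> CNVScoreResult:
    """Full scoring pipeline: center -> genomic smooth -> median filter -> score."""
    centered = reference_center(expr, reference_cells)
    smoothed, pos = genomic_smooth(centered, positions, window)
    filtered = median_filter_matrix(smoothed, pos, median_width)
    return score_cnv(filtered, reference_cells, k_outer)
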