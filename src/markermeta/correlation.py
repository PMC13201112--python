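"""Per-cohort gene-gene correlation, BH-FDR screening, and E-box scanning.

Pearson correlations between two genes are computed per cohort with a
two-sided p-value from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom; extremely small p-values are evaluated through the log-space
survival function rather than truncated to zero.  Raw p-values across
cohorts are adjusted by the Benjamini-Hochberg step-up procedure with m
equal to the number of tests supplied, and cohorts with FDR strictly below
the chosen alpha are counted as significant.

The promoter scan looks for the canonical E-box hexamer CANNTG (the
binding consensus of MYC-family/MAX basic helix-loop-helix dimers) on both
strands.  The pattern is its own reverse complement, so every plus-strand
hit has a minus-strand counterpart at the same plus-strand coordinate; both
are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

EBOX_LENGTH = 6
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class CohortCorrelation:
    cohort_id: str
    r: float
    n: int | None
    p: float
    fdr: float | None = None


@dataclass(frozen=True)
class MotifHit:
    """An E-box occurrence: 0-based plus-strand offset, strand, matched hexamer."""

    position: int
    strand: str  # "+" or "-"
    matched: str


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value from the t transformation.

    Returns (r, p, n).  Uses the log-space survival function so that p-values
    far below float precision are still positive where representable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson_with_p: vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson_with_p: need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("pearson_with_p: constant input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    log_p = math.log(2.0) + stats.t.logsf(abs(t), n - 2)
    return r, float(np.exp(log_p)), n


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_cohort_table(cors: Sequence[CohortCorrelation]) -> list[CohortCorrelation]:
    """Attach BH-FDR values across a set of cohort correlations (m = len)."""
    fdr = bh_adjust([c.p for c in cors])
    return [replace(c, fdr=float(q)) for c, q in zip(cors, fdr)]


def count_significant(cors: Sequence[CohortCorrelation], alpha: float = 0.05) -> int:
    """Number of cohorts with FDR strictly below alpha."""
    if any(c.fdr is None for c in cors):
        raise ValidationError("count_significant: FDR column not populated")
    return sum(1 for c in cors if c.fdr < alpha)


def read_cohort_correlations(path: str | Path) -> list[CohortCorrelation]:
    """Read a cohort correlation CSV (Cohort,R,p.value[,FDR])."""
    df = pd.read_csv(path)
    required = {"Cohort", "R", "p.value"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: no cohort rows")
    return [
        CohortCorrelation(
            cohort_id=str(row["Cohort"]), r=float(row["R"]),
            n=int(row["n"]) if "n" in df.columns else None,
            p=float(row["p.value"]),
            fdr=float(row["FDR"]) if "FDR" in df.columns else None,
        )
        for _, row in df.iterrows()
    ]


def cohort_correlation(ds, gene_x: str, gene_y: str) -> CohortCorrelation:
    """Per-cohort correlation between two genes of an expression dataset."""
    r, p, n = pearson_with_p(ds.gene_values(gene_x), ds.gene_values(gene_y))
    return CohortCorrelation(cohort_id=ds.dataset_id, r=r, n=n, p=p)


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def ebox_scan(sequence: str) -> list[MotifHit]:
    """All E-box (CANNTG) occurrences on both strands of a DNA sequence.

    Positions are 0-based plus-strand offsets.  Since CANNTG is its own
    reverse-complement pattern, each matching hexamer is reported twice:
    once for the plus strand (matched text as read) and once for the minus
    strand (matched text reverse-complemented).  ``N`` in the sequence only
    matches the pattern's N positions.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"ebox_scan: invalid characters {sorted(bad)}")
    if len(seq) < EBOX_LENGTH:
        raise ValidationError(f"ebox_scan: sequence shorter than {EBOX_LENGTH} bp")
    hits: list[MotifHit] = []
    for i in range(len(seq) - EBOX_LENGTH + 1):
        hexamer = seq[i:i + EBOX_LENGTH]
        if (hexamer[0] == "C" and hexamer[1] == "A"
                and hexamer[4] == "T" and hexamer[5] == "G"
                and "N" not in (hexamer[0], hexamer[1], hexamer[4], hexamer[5])):
            hits.append(MotifHit(position=i, strand="+", matched=hexamer))
            hits.append(MotifHit(position=i, strand="-",
                                 matched=reverse_complement(hexamer)))
    return hits


def write_motif_bed(hits: Sequence[MotifHit], path: str | Path,
                    seq_name: str = "promoter") -> None:
    """Write motif hits as a BED-like TSV (name, start, end, strand, matched)."""
    pd.DataFrame({
        "chrom": [seq_name] * len(hits),
        "start": [h.position for h in hits],
        "end": [h.position + EBOX_LENGTH for h in hits],
        "strand": [h.strand for h in hits],
        "matched": [h.matched for h in hits],
    }).to_csv(path, sep="\t", index=False, header=False)
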