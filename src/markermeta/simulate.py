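"""Seeded generators emulating the statistical structure of each analysis
stage's inputs, with ground truth for recovery tests.

Every generator is a pure function of its parameters and an explicit seed
(no global random state): regeneration from the same arguments is
bit-identical.  Gaussian noise is used throughout because all downstream
statistics operate on log-scale values; count-level models (e.g. negative
binomial) would be absorbed by the log transform anyway.

Scenarios
---------
* :func:`gen_cohorts` — multi-platform tumor/normal cohorts.  One
  designated biomarker gene carries a per-study standardized effect
  delta_i ~ Normal(mu, tau2); all other genes are null, so FDR behavior is
  testable.  Each study receives an additive batch shift on all genes.
* :func:`gen_contingency` — per-study diagnostic 2x2 tables with binomial
  TP/TN draws at common true sensitivity/specificity.
* :func:`gen_single_cell` — a diploid reference population plus a tumor
  clone carrying contiguous copy-number segments (amplitude in units of
  the per-gene noise SD), genes laid out on two synthetic chromosomes.
* :func:`gen_spatial` — a square spot lattice with a moving-average
  smoothed expression field, a log-linear UMI depth gradient, optional
  depth-coupled expression, and five immune fractions drawn from a
  spatially smoothed softmax simplex (summing to <= 1 per spot).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .io import ContingencyTable, ExpressionDataset, GenePosition, SpotTable

BIOMARKER_GENE = "MARKER"


@dataclass
class SimulationTruth:
    """Generative parameters and ground-truth labels for one scenario."""

    scenario: str
    params: dict
    labels: dict = field(default_factory=dict)


def gen_cohorts(k: int = 18,
                n_range: tuple[int, int] = (30, 100),
                mu: float = 1.75,
                tau2: float = 0.63,
                batch_shift_sd: float = 1.0,
                n_genes: int = 20,
                seed: int = 0) -> tuple[list[ExpressionDataset], SimulationTruth]:
    """Simulate k tumor/normal cohorts on distinct platforms.

    Per study i, the biomarker gene's true standardized effect is
    delta_i ~ Normal(mu, tau2): tumor samples draw Normal(delta_i, 1) and
    normal samples Normal(0, 1).  The remaining ``n_genes - 1`` genes are
    null in both groups.  An additive per-study batch shift
    ~ Normal(0, batch_shift_sd) is applied to every gene.  Defaults echo
    the heterogeneity regime of multi-platform colorectal biomarker
    cohorts (k=18, mu=1.75, tau2=0.63).
    """
    if k < 2:
        raise ValidationError("gen_cohorts: need k >= 2 studies")
    if tau2 < 0:
        raise ValidationError("gen_cohorts: tau2 must be >= 0")
    lo, hi = n_range
    if lo < 2 or hi < lo:
        raise ValidationError(f"gen_cohorts: invalid n_range {n_range}")
    rng = np.random.default_rng(seed)
    genes = [BIOMARKER_GENE] + [f"GENE{i:04d}" for i in range(1, n_genes)]
    datasets: list[ExpressionDataset] = []
    deltas, shifts, sizes = [], [], []
    for i in range(k):
        n1 = int(rng.integers(lo, hi + 1))
        n0 = int(rng.integers(lo, hi + 1))
        delta = float(rng.normal(mu, np.sqrt(tau2)))
        shift = float(rng.normal(0.0, batch_shift_sd)) if batch_shift_sd > 0 else 0.0
        values = rng.normal(0.0, 1.0, size=(n_genes, n1 + n0))
        values[0, :n1] += delta
        values += shift
        ds_id = f"SIM{i + 1:02d}"
        datasets.append(ExpressionDataset(
            dataset_id=ds_id,
            genes=list(genes),
            samples=[f"{ds_id}_S{j:03d}" for j in range(n1 + n0)],
            values=values,
            group=np.array(["tumor"] * n1 + ["normal"] * n0, dtype=object),
            batch=np.array([ds_id] * (n1 + n0), dtype=object),
            log_transformed=True,
        ))
        deltas.append(delta)
        shifts.append(shift)
        sizes.append((n1, n0))
    truth = SimulationTruth(
        scenario="cohorts",
        params={"k": k, "mu": mu, "tau2": tau2, "batch_shift_sd": batch_shift_sd,
                "n_genes": n_genes, "seed": seed, "biomarker_gene": BIOMARKER_GENE,
                "deltas": deltas, "batch_shifts": shifts, "sizes": sizes},
    )
    return datasets, truth


def gen_contingency(k: int = 18,
                    sens: float = 0.85,
                    spec: float = 0.86,
                    n_range: tuple[int, int] = (20, 300),
                    seed: int = 0) -> list[ContingencyTable]:
    """Simulate per-study diagnostic tables: TP ~ Bin(n1, sens), TN ~ Bin(n0, spec)."""
    if not (0 < sens < 1 and 0 < spec < 1):
        raise ValidationError("gen_contingency: rates must lie in (0, 1)")
    lo, hi = n_range
    if lo < 1 or hi < lo:
        raise ValidationError(f"gen_contingency: invalid n_range {n_range}")
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(k):
        n1 = int(rng.integers(lo, hi + 1))
        n0 = int(rng.integers(lo, hi + 1))
        tp = int(rng.binomial(n1, sens))
        tn = int(rng.binomial(n0, spec))
        tables.append(ContingencyTable(
            study_id=f"SIM{i + 1:02d}", tp=tp, fp=n0 - tn, fn=n1 - tp, tn=tn))
    return tables


def gen_single_cell(n_ref: int = 250,
                    n_tumor: int = 250,
                    n_genes: int = 200,
                    segments: Sequence[tuple[int, int, float]] = ((40, 50, 3.0),),
                    seed: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[GenePosition], SimulationTruth]:
    """Simulate reference cells and a tumor clone with planted CNV segments.

    ``segments`` are (start_gene, length, amplitude) triples: clone cells'
    log-expression is shifted by ``amplitude`` (in units of the Normal(0,1)
    noise SD) on the segment's genes.  Overlapping segments are rejected.
    Genes are split evenly over two synthetic chromosomes.  Returns the
    genes-x-cells matrix, a cell annotation frame (cell_id, label), the
    gene positions, and the truth (clone membership).
    """
    if n_ref < 1:
        raise ValidationError("gen_single_cell: need at least one reference cell")
    covered: set[int] = set()
    for start, length, _amp in segments:
        span = set(range(start, start + length))
        if start < 0 or start + length > n_genes:
            raise ValidationError(f"segment ({start},{length}) outside gene range")
        if covered & span:
            raise ValidationError("overlapping CNV segments")
        covered |= span
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    half = n_genes // 2
    positions = [
        GenePosition(chrom="chr1" if i < half else "chr2",
                     start=(i if i < half else i - half) * 1000,
                     gene=genes[i])
        for i in range(n_genes)
    ]
    cells = [f"REF{i:04d}" for i in range(n_ref)] + [f"TUM{i:04d}" for i in range(n_tumor)]
    values = rng.normal(0.0, 1.0, size=(n_genes, n_ref + n_tumor))
    for start, length, amp in segments:
        values[start:start + length, n_ref:] += amp
    expr = pd.DataFrame(values, index=genes, columns=cells)
    annotations = pd.DataFrame({
        "cell_id": cells,
        "label": ["reference"] * n_ref + ["tumor"] * n_tumor,
    })
    truth = SimulationTruth(
        scenario="single_cell",
        params={"n_ref": n_ref, "n_tumor": n_tumor, "n_genes": n_genes,
                "segments": [tuple(s) for s in segments], "seed": seed},
        labels={"clone": {c: c.startswith("TUM") for c in cells}},
    )
    return expr, annotations, positions, truth


def _smooth_field(field: np.ndarray, length_scale: int) -> np.ndarray:
    if length_scale <= 0:
        return field
    return ndimage.uniform_filter(field, size=2 * length_scale + 1, mode="reflect")


def gen_spatial(side: int = 20,
                length_scale: int = 3,
                depth_gradient: float = 0.0,
                seed: int = 0,
                depth_coupling: float = 0.0,
                base_umi: float = 5000.0) -> tuple[SpotTable, SimulationTruth]:
    """Simulate a side x side spot lattice.

    The ``marker`` expression field is Gaussian noise smoothed by a moving
    average of half-width ``length_scale`` (0 = white noise), rescaled to
    unit variance, plus ``depth_coupling`` times the centered log-UMI (for
    depth-driven artifacts); ``control`` is independent white noise.  UMI
    depth follows a log-linear gradient along x with slope
    ``depth_gradient`` (per normalized coordinate).  Five immune fractions
    (cd8_t, cd4_t, b_cell, nk, macrophage) come from a 6-component softmax
    of independently smoothed Gaussian fields, so per-spot sums are < 1.
    """
    if side < 4:
        raise ValidationError("gen_spatial: need side >= 4")
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    x = xs.ravel().astype(float)
    y = ys.ravel().astype(float)
    n = side * side

    log_umi = (np.log(base_umi)
               + depth_gradient * (x - x.mean()) / side
               + rng.normal(0.0, 0.1, n))
    umi = np.maximum(1.0, np.round(np.exp(log_umi)))

    field = _smooth_field(rng.normal(0.0, 1.0, (side, side)), length_scale).ravel()
    field = field / field.std()
    marker = field + depth_coupling * (np.log(umi) - np.log(umi).mean())
    control = rng.normal(0.0, 1.0, n)

    comp_fields = [
        _smooth_field(rng.normal(0.0, 1.0, (side, side)), length_scale).ravel()
        for _ in range(6)
    ]
    logits = np.column_stack(comp_fields)
    logits -= logits.max(axis=1, keepdims=True)
    simplex = np.exp(logits)
    simplex /= simplex.sum(axis=1, keepdims=True)
    names = ["cd8_t", "cd4_t", "b_cell", "nk", "macrophage"]
    spot_ids = [f"SPOT{i:04d}" for i in range(n)]
    fractions = pd.DataFrame(simplex[:, :5], columns=names,
                             index=pd.Index(spot_ids, name="spot_id"))

    spots = SpotTable(
        spot_ids=spot_ids, x=x, y=y, umi=umi,
        expr=pd.DataFrame({"marker": marker, "control": control},
                          index=pd.Index(spot_ids, name="spot_id")),
        fractions=fractions,
    )
    truth = SimulationTruth(
        scenario="spatial",
        params={"side": side, "length_scale": length_scale,
                "depth_gradient": depth_gradient,
                "depth_coupling": depth_coupling, "seed": seed},
    )
    return spots, truth
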