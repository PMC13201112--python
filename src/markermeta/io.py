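"""Domain containers, file readers/writers, and shared preprocessing.

The unit of per-cohort analysis is an :class:`ExpressionDataset`: a dense
genes-by-samples matrix with tumor/normal labels and a platform/batch
identifier per sample.  Diagnostic evidence enters as
:class:`ContingencyTable` rows (TP/FP/FN/TN per study), single-cell CNV
scoring needs :class:`GenePosition` records, and spatial analysis consumes a
:class:`SpotTable`.

File conventions
----------------
* Expression matrices: delimited text with genes in rows and a header of
  sample IDs (``.tsv`` tab-separated, ``.csv`` comma-separated), or a
  matrix-market ``.mtx`` triplet file accompanied by ``rows.txt`` (gene
  symbols) and ``cols.txt`` (sample IDs) in the same directory.
* Sample sheets: CSV with columns ``sample_id,group,batch``; the sheet is
  mandatory — groups are never inferred from sample names.
* Contingency tables: CSV with the exact header ``ID,TP,FP,FN,TN``.
* Gene positions: CSV ``gene,chrom,start`` or BED-like 3-column TSV
  ``chrom,start,gene``.  Coordinates are 1-based in files and converted to
  0-based internally.

Missing values in expression matrices are rejected outright; no imputation
is performed anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

VALID_GROUPS = ("tumor", "normal")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Gene-by-sample expression matrix with per-sample annotations.

    Parameters
    ----------
    dataset_id : str
        Cohort/platform identifier.
    genes, samples : list of str
        Row and column labels; sample IDs must be unique.
    values : ndarray of shape (n_genes, n_samples)
        Expression values, raw or log2 scale; must be finite.
    group : ndarray of str
        Per-sample label, each ``"tumor"`` or ``"normal"``.
    batch : ndarray of str
        Per-sample platform/batch identifier.
    log_transformed : bool
        Whether values are already on the log2(x+1) scale.
    """

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    group: np.ndarray
    batch: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        n_g, n_s = len(self.genes), len(self.samples)
        if self.values.shape != (n_g, n_s):
            raise ValidationError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {n_g} genes x {n_s} samples"
            )
        if len(self.group) != n_s or len(self.batch) != n_s:
            raise ValidationError(f"{self.dataset_id}: annotation length mismatch")
        if len(set(self.samples)) != n_s:
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValidationError(f"{self.dataset_id}: duplicate sample IDs {dupes}")
        bad = sorted(set(self.group) - set(VALID_GROUPS))
        if bad:
            raise ValidationError(
                f"{self.dataset_id}: unknown group label(s) {bad}; "
                f"expected one of {VALID_GROUPS}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"{self.dataset_id}: expression matrix contains non-finite values"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector (over samples) for a single gene symbol."""
        try:
            idx = self.genes.index(gene)
        except ValueError:
            raise ValidationError(
                f"{self.dataset_id}: gene {gene!r} not present"
            ) from None
        return self.values[idx]

    def group_mask(self, which: str) -> np.ndarray:
        return self.group == which


@dataclass(frozen=True)
class ContingencyTable:
    """One study's diagnostic 2x2 counts (TP/FP/FN/TN)."""

    study_id: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(
                    f"{self.study_id}: {name.upper()}={v!r} is not an integer"
                )
            if v < 0:
                raise ValidationError(f"{self.study_id}: {name.upper()}={v} is negative")
        if self.tp + self.fn < 1:
            raise ValidationError(f"{self.study_id}: no diseased samples (TP+FN=0)")
        if self.fp + self.tn < 1:
            raise ValidationError(f"{self.study_id}: no non-diseased samples (FP+TN=0)")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True, order=True)
class GenePosition:
    """Genomic anchor for a gene: chromosome and 0-based start coordinate."""

    chrom: str
    start: int  # 0-based internally; files carry 1-based coordinates
    gene: str = field(compare=False)


@dataclass
class SpotTable:
    """Spatial transcriptomics spots: coordinates, UMI depth, expression,
    and cell-type fractions.

    ``expr`` and ``fractions`` are DataFrames indexed by spot ID, with one
    column per gene (log-TPM scale) and per cell type respectively.
    """

    spot_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    umi: np.ndarray
    expr: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.umi = np.asarray(self.umi, dtype=float)
        n = len(self.spot_ids)
        if not (len(self.x) == len(self.y) == len(self.umi) == n):
            raise ValidationError("spot table: column length mismatch")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("spot table: non-finite coordinates")
        if np.any(self.umi <= 0):
            raise ValidationError("spot table: UMI counts must be positive")
        if len(self.expr) != n or len(self.fractions) != n:
            raise ValidationError("spot table: expr/fractions row count mismatch")
        fr = self.fractions.to_numpy(dtype=float)
        if fr.size and (np.any(fr < 0) or np.any(fr > 1)):
            raise ValidationError("spot table: cell fractions must lie in [0, 1]")

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def log_umi(self) -> np.ndarray:
        return np.log(self.umi)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype=str)
    required = {"sample_id", "group", "batch"}
    if not required.issubset(sheet.columns):
        raise ValidationError(
            f"sample sheet {path}: expected columns {sorted(required)}, "
            f"found {list(sheet.columns)}"
        )
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"sample sheet {path}: duplicate sample IDs {dupes}")
    return sheet.set_index("sample_id")


def read_expression_matrix(path: str | Path, sample_sheet: str | Path) -> ExpressionDataset:
    """Read an expression matrix (TSV/CSV or matrix-market) plus sample sheet.

    Every sample present in the matrix must appear in the sheet; unknown
    samples are rejected by name.  The dataset ID is the file stem.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        rows_file = path.parent / "rows.txt"
        cols_file = path.parent / "cols.txt"
        for f in (rows_file, cols_file):
            if not f.exists():
                raise ValidationError(f"matrix-market input {path}: missing {f.name}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = rows_file.read_text().split()
        samples = cols_file.read_text().split()
        values = np.asarray(mat, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"{path}: matrix shape {values.shape} does not match "
                f"{len(genes)} rows / {len(samples)} cols"
            )
        df = pd.DataFrame(values, index=genes, columns=samples)
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)

    sheet = _read_sample_sheet(sample_sheet)
    missing = [s for s in df.columns if s not in sheet.index]
    if missing:
        raise ValidationError(
            f"{path}: sample(s) {missing} absent from sample sheet"
        )
    sheet = sheet.loc[list(df.columns)]
    return ExpressionDataset(
        dataset_id=path.stem,
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group=sheet["group"].to_numpy(),
        batch=sheet["batch"].to_numpy(),
    )


def write_expression_matrix(ds: ExpressionDataset, path: str | Path,
                            sample_sheet: str | Path) -> None:
    """Write a dataset back to TSV/CSV (or .mtx triplet) plus sample sheet."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(ds.values))
        (path.parent / "rows.txt").write_text("\n".join(ds.genes) + "\n")
        (path.parent / "cols.txt").write_text("\n".join(ds.samples) + "\n")
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        pd.DataFrame(ds.values, index=ds.genes, columns=ds.samples).to_csv(path, sep=sep)
    pd.DataFrame(
        {"sample_id": ds.samples, "group": ds.group, "batch": ds.batch}
    ).to_csv(sample_sheet, index=False)


def read_contingency_csv(path: str | Path) -> list[ContingencyTable]:
    """Read per-study diagnostic 2x2 counts from CSV (header ID,TP,FP,FN,TN)."""
    df = pd.read_csv(path)
    expected = ["ID", "TP", "FP", "FN", "TN"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected header {','.join(expected)}, found {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError(f"{path}: no contingency rows")
    tables = []
    for _, row in df.iterrows():
        counts = {}
        for col in ("TP", "FP", "FN", "TN"):
            v = row[col]
            if float(v) != int(v):
                raise ValidationError(f"{path} row {row['ID']}: {col}={v} not an integer")
            counts[col.lower()] = int(v)
        tables.append(ContingencyTable(study_id=str(row["ID"]), **counts))
    return tables


def write_contingency_csv(tables: Sequence[ContingencyTable], path: str | Path) -> None:
    pd.DataFrame(
        [{"ID": t.study_id, "TP": t.tp, "FP": t.fp, "FN": t.fn, "TN": t.tn}
         for t in tables]
    ).to_csv(path, index=False)


def read_gene_positions(path: str | Path) -> list[GenePosition]:
    """Read gene positions from CSV (gene,chrom,start) or BED-like TSV
    (chrom,start,gene).  File coordinates are 1-based; stored 0-based."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        if not {"gene", "chrom", "start"}.issubset(df.columns):
            raise ValidationError(
                f"{path}: expected columns gene,chrom,start; found {list(df.columns)}"
            )
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "gene"])
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValidationError(f"{path}: duplicate gene records {dupes}")
    if (df["start"].astype(int) < 1).any():
        raise ValidationError(f"{path}: start coordinates must be 1-based (>= 1)")
    return [
        GenePosition(chrom=str(r.chrom), start=int(r.start) - 1, gene=str(r.gene))
        for r in df.itertuples()
    ]


def write_gene_positions(positions: Sequence[GenePosition], path: str | Path) -> None:
    pd.DataFrame(
        {"gene": [p.gene for p in positions],
         "chrom": [p.chrom for p in positions],
         "start": [p.start + 1 for p in positions]}
    ).to_csv(path, index=False)


def read_spot_csv(path: str | Path, fractions: str | Path | None = None) -> SpotTable:
    """Read a spot table CSV (spot_id,x,y,umi,<expression columns...>) and an
    optional fractions CSV keyed by spot_id."""
    df = pd.read_csv(path)
    required = ["spot_id", "x", "y", "umi"]
    if not set(required).issubset(df.columns):
        raise ValidationError(f"{path}: expected columns {required}")
    expr_cols = [c for c in df.columns if c not in required]
    fr = pd.DataFrame(index=pd.Index(df["spot_id"], name="spot_id"))
    if fractions is not None:
        fr = pd.read_csv(fractions).set_index("spot_id")
        fr = fr.reindex(df["spot_id"])
        if fr.isna().any().any():
            raise ValidationError(f"{fractions}: missing fractions for some spots")
    return SpotTable(
        spot_ids=[str(s) for s in df["spot_id"]],
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        umi=df["umi"].to_numpy(float),
        expr=df[expr_cols].set_index(pd.Index(df["spot_id"], name="spot_id")),
        fractions=fr,
    )


def write_spot_csv(spots: SpotTable, path: str | Path,
                   fractions: str | Path | None = None) -> None:
    df = pd.DataFrame({"spot_id": spots.spot_ids, "x": spots.x,
                       "y": spots.y, "umi": spots.umi})
    df = pd.concat([df, spots.expr.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)
    if fractions is not None:
        spots.fractions.reset_index().to_csv(fractions, index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def log2p1_transform(ds: ExpressionDataset) -> ExpressionDataset:
    """Return a copy with each value v replaced by log2(v + 1).

    Rejects negative input and double transformation.
    """
    if ds.log_transformed:
        raise ValidationError(f"{ds.dataset_id}: already log2(x+1)-transformed")
    if np.any(ds.values < 0):
        raise ValidationError(
            f"{ds.dataset_id}: negative expression values cannot be log2(x+1)-transformed"
        )
    return replace(ds, values=np.log2(ds.values + 1.0), log_transformed=True)


def batch_adjust(ds: ExpressionDataset) -> ExpressionDataset:
    """Remove additive per-batch location shifts while preserving the
    tumor-vs-normal contrast.

    Per gene, a two-way additive means model (value = grand mean + group
    effect + batch effect) is fitted by least squares over all batches that
    contain both groups, and the mean-centered batch offsets are subtracted.
    Naive per-batch centering is deliberately avoided: it would erase the
    biological group difference whenever group composition differs across
    batches.  Batches containing a single group, and single-batch inputs,
    pass through unchanged with a logged warning.
    """
    batches = pd.unique(ds.batch)
    if len(batches) < 2:
        logger.warning("%s: single batch — batch adjustment is a no-op", ds.dataset_id)
        return replace(ds, values=ds.values.copy())

    usable = [b for b in batches
              if len(set(ds.group[ds.batch == b])) == 2]
    skipped = [b for b in batches if b not in usable]
    if skipped:
        logger.warning(
            "%s: batch(es) %s lack one of the groups; passed through unadjusted",
            ds.dataset_id, skipped,
        )
    if len(usable) < 2:
        logger.warning(
            "%s: fewer than 2 batches with both groups — no adjustment", ds.dataset_id
        )
        return replace(ds, values=ds.values.copy())

    mask = np.isin(ds.batch, usable)
    group_ind = (ds.group[mask] == "tumor").astype(float)
    # full-rank design: intercept, centered group indicator, batch dummies
    # (first usable batch as baseline)
    cols = [np.ones(mask.sum()), group_ind - group_ind.mean()]
    for b in usable[1:]:
        cols.append((ds.batch[mask] == b).astype(float))
    X = np.column_stack(cols)
    Y = ds.values[:, mask]  # genes x usable samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (2 + B-1) x genes

    # per-sample batch offset implied by the fit, centered so the grand mean
    # is untouched
    batch_design = X[:, 2:]
    offsets = batch_design @ beta[2:]          # samples x genes
    offsets = offsets - offsets.mean(axis=0)   # center over adjusted samples
    new_values = ds.values.copy()
    new_values[:, mask] = Y - offsets.T
    return replace(ds, values=new_values)


def merge_datasets(datasets: Sequence[ExpressionDataset],
                   dataset_id: str = "merged") -> ExpressionDataset:
    """Concatenate cohorts sample-wise on their common genes.

    Each input dataset's samples keep their own batch labels, so the merged
    dataset is the natural input to :func:`batch_adjust`.
    """
    if not datasets:
        raise ValidationError("merge_datasets: no datasets given")
    common = [g for g in datasets[0].genes
              if all(g in set(d.genes) for d in datasets[1:])]
    if not common:
        raise ValidationError("merge_datasets: no genes shared by all datasets")
    values = np.hstack([
        d.values[[d.genes.index(g) for g in common], :] for d in datasets
    ])
    samples: list[str] = []
    for d in datasets:
        samples.extend(f"{d.dataset_id}:{s}" for s in d.samples)
    return ExpressionDataset(
        dataset_id=dataset_id,
        genes=list(common),
        samples=samples,
        values=values,
        group=np.concatenate([d.group for d in datasets]),
        batch=np.concatenate([d.batch for d in datasets]),
        log_transformed=all(d.log_transformed for d in datasets),
    )
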