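"""Reading, writing and preprocessing of expression matrices.

Expression data live in delimited text files: a numeric matrix with one
header row and one ID column, plus a two-column labels file mapping
sample IDs to binary class labels (1 = case/cancer, 0 = control/normal).
On disk the common microarray layout is genes-by-samples; in memory the
package always works samples-by-genes.

Preprocessing follows the classic microarray recipe: optional
floor/ceiling clipping with fold-change and absolute-difference
filtering, a base-10 log transform, and per-gene standardization to
zero mean and unit variance across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "read_dataset",
    "write_dataset",
    "preprocess",
    "t_prescreen",
    "t_statistics",
    "write_prescreen_tsv",
]


@dataclass
class ExpressionDataset:
    """An (X, Y) pair of expression values and binary class labels.

    Parameters
    ----------
    X : ndarray, shape (n_samples, n_genes)
        Real-valued expression matrix, one row per sample.
    Y : ndarray of int, shape (n_samples,)
        Binary labels; 1 marks a case (e.g. tumor), 0 a control.
    gene_ids : list of str
        Unique identifiers for the columns of ``X``.
    sample_ids : list of str
        Identifiers for the rows of ``X``.
    """

    X: np.ndarray
    Y: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples-by-genes matrix")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 samples and p >= 1 genes, got {n} x {p}")
        self.Y = np.asarray(self.Y)
        if self.Y.shape != (n,):
            raise ValueError(f"Y has length {self.Y.shape}, expected ({n},)")
        vals = set(np.unique(self.Y).tolist())
        if not vals <= {0, 1}:
            raise ValueError(f"labels must be in {{0, 1}}, found {sorted(vals)}")
        self.Y = self.Y.astype(np.int64)
        if not self.gene_ids:
            self.gene_ids = [f"g{j}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match number of genes")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of samples")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene IDs")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def both_classes_present(self) -> bool:
        return bool((self.Y == 0).any() and (self.Y == 1).any())

    def subset_genes(self, idx) -> "ExpressionDataset":
        """Dataset restricted to the gene columns ``idx`` (in given order)."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            X=self.X[:, idx],
            Y=self.Y.copy(),
            gene_ids=[self.gene_ids[j] for j in idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, idx) -> "ExpressionDataset":
        """Dataset restricted to the sample rows ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionDataset(
            X=self.X[idx],
            Y=self.Y[idx],
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


def _sniff_sep(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_table(path) -> pd.DataFrame:
    # header row + ID column; C engine with round-trip floats so values
    # survive write -> read bit-exactly
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                       float_precision="round_trip")


def read_dataset(expr_path, labels_path, orientation: str = "genes_by_samples") -> ExpressionDataset:
    """Read an expression matrix and matching labels from delimited text.

    Parameters
    ----------
    expr_path : path
        TSV/CSV matrix with a header row and an ID column.
    labels_path : path
        Two-column TSV/CSV mapping sample ID to a label in {0, 1}.
    orientation : {"genes_by_samples", "samples_by_genes"}
        Layout of the matrix on disk. The common microarray layout
        (and the default) stores one row per gene.

    Returns
    -------
    ExpressionDataset
        Always in samples-by-genes orientation; labels are matched to
        samples by ID, never by file position.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(expr_path)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in expression matrix {expr_path}: {exc}") from None
    if orientation == "genes_by_samples":
        df = df.T
    # now rows = samples, columns = genes
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"duplicate gene IDs: {dups}")

    lab = pd.read_csv(labels_path, sep=None, engine="python", header=None, comment="#")
    if lab.shape[1] < 2:
        raise ValueError("labels file must have two columns: sample_id, label")
    # tolerate a header line
    try:
        int(lab.iloc[0, 1])
    except (TypeError, ValueError):
        lab = lab.iloc[1:]
    sample_to_label = {}
    for sid, y in zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]):
        yv = int(y)
        if yv not in (0, 1):
            raise ValueError(f"label {yv} for sample {sid!r} outside {{0, 1}}")
        sample_to_label[sid] = yv
    matrix_ids = [str(s) for s in df.index]
    unknown = sorted(set(sample_to_label) - set(matrix_ids))
    if unknown:
        raise ValueError(f"labels reference sample IDs absent from the matrix: {unknown}")
    missing = [s for s in matrix_ids if s not in sample_to_label]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    Y = np.array([sample_to_label[s] for s in matrix_ids], dtype=np.int64)
    return ExpressionDataset(
        X=df.to_numpy(dtype=float),
        Y=Y,
        gene_ids=[str(g) for g in df.columns],
        sample_ids=matrix_ids,
    )


def write_dataset(ds: ExpressionDataset, expr_path, labels_path,
                  orientation: str = "genes_by_samples") -> None:
    """Write a dataset in the same TSV formats :func:`read_dataset` reads."""
    df = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.gene_ids)
    if orientation == "genes_by_samples":
        out = df.T
        out.index.name = "gene_id"
    elif orientation == "samples_by_genes":
        out = df
        out.index.name = "sample_id"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    out.to_csv(expr_path, sep="\t")  # default float repr round-trips exactly
    pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.Y}).to_csv(
        labels_path, sep="\t", index=False, header=False
    )


def preprocess(ds: ExpressionDataset, do_threshold_filter: bool = False,
               floor: float = 100.0, ceil: float = 16000.0,
               min_fold: float = 5.0, min_diff: float = 500.0) -> ExpressionDataset:
    """Clip/filter (optional), log10-transform and standardize per gene.

    With ``do_threshold_filter`` the raw intensities are clipped to
    ``[floor, ceil]`` and a gene is kept only if ``max/min >= min_fold``
    or ``max - min >= min_diff`` across samples (the classical
    variation filter for oligonucleotide arrays). Surviving values are
    log10-transformed and each gene is standardized to zero mean and
    unit variance (n-1 denominator) across samples. Genes with zero
    variance are dropped with a warning rather than an error.
    """
    X = ds.X.copy()
    gene_ids = list(ds.gene_ids)
    if do_threshold_filter:
        X = np.clip(X, floor, ceil)
        mx = X.max(axis=0)
        mn = X.min(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(mn > 0, mx / mn, np.inf)
        keep = (fold >= min_fold) | ((mx - mn) >= min_diff)
        X = X[:, keep]
        gene_ids = [g for g, k in zip(gene_ids, keep) if k]
        if X.shape[1] == 0:
            raise ValueError("threshold filter removed every gene")
    if np.any(X <= 0):
        bad = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"non-positive expression value at sample {bad[0]}, gene {gene_ids[bad[1]]}: "
            "log10 transform undefined (use do_threshold_filter with a positive floor)"
        )
    X = np.log10(X)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        dropped = [g for g, z in zip(gene_ids, zero_var) if z]
        warnings.warn(f"dropping {len(dropped)} zero-variance gene(s): {dropped[:5]}")
        logger.warning("dropping zero-variance genes: %s", dropped)
        X = X[:, ~zero_var]
        gene_ids = [g for g, z in zip(gene_ids, zero_var) if not z]
        sd = sd[~zero_var]
        if X.shape[1] == 0:
            raise ValueError("all genes have zero variance")
    X = (X - X.mean(axis=0)) / sd
    return ExpressionDataset(X=X, Y=ds.Y.copy(), gene_ids=gene_ids,
                             sample_ids=list(ds.sample_ids))


def t_statistics(ds: ExpressionDataset, equal_var: bool = True) -> np.ndarray:
    """Two-sample t statistic per gene (class 1 minus class 0).

    The pooled-variance (equal-variance) form is the default
    convention; set ``equal_var=False`` for Welch.
    """
    m1 = ds.Y == 1
    m0 = ds.Y == 0
    if m1.sum() < 2 or m0.sum() < 2:
        raise ValueError("each class needs at least 2 samples for a t statistic")
    x1, x0 = ds.X[m1], ds.X[m0]
    n1, n0 = x1.shape[0], x0.shape[0]
    d = x1.mean(axis=0) - x0.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v0 = x0.var(axis=0, ddof=1)
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    else:
        se = np.sqrt(v1 / n1 + v0 / n0)
    t = np.zeros_like(d)
    ok = se > 0
    t[ok] = d[ok] / se[ok]
    degenerate = ~ok & (d != 0)  # zero within-class spread but separated means
    t[degenerate] = np.sign(d[degenerate]) * np.inf
    return t


def t_prescreen(ds: ExpressionDataset, k: int, equal_var: bool = True) -> np.ndarray:
    """Indices of the ``k`` genes with the largest |t|, best first.

    Ties are broken by original gene index ascending, so the screen is
    deterministic and invariant to relabeling the two classes.
    """
    if k > ds.p:
        raise ValueError(f"k={k} exceeds p={ds.p}")
    t = np.abs(t_statistics(ds, equal_var=equal_var))
    # stable sort on -|t| => ties keep ascending original index
    order = np.argsort(-t, kind="stable")
    return order[:k]


def write_prescreen_tsv(ds: ExpressionDataset, order, path,
                        equal_var: bool = True) -> None:
    """Write the prescreen ranking as TSV (rank, gene_id, t_statistic)."""
    t = t_statistics(ds, equal_var=equal_var)
    order = np.asarray(order, dtype=int)
    pd.DataFrame({
        "rank": np.arange(1, order.size + 1),
        "gene_id": [ds.gene_ids[j] for j in order],
        "t_statistic": t[order],
    }).to_csv(path, sep="\t", index=False)
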