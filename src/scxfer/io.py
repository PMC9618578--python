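"""Reading, writing, QC and normalization of expression matrices.

Three on-disk layouts are supported: delimited text (TSV/CSV, samples in
rows by default), MatrixMarket coordinate triplets with sidecar id files,
and AnnData/h5ad containers.  Single-cell QC follows the standard droplet
recipe: drop cells with too few detected genes, drop genes seen in too few
cells, drop high-mitochondrial cells, then CPM-style normalization to a
fixed total, log1p, and per-gene min-max scaling to [0, 1].
"""

from __future__ import annotations

import os
from dataclasses import replace
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .matrix import DrugResponseTable, ExpressionMatrix, ValidationError


class FormatError(ValueError):
    """Unparseable or malformed input file."""


class AlignmentError(ValueError):
    """Gene spaces of two matrices cannot be aligned."""


class EmptyResultError(ValueError):
    """A filtering step removed every cell or every gene."""


# ---------------------------------------------------------------------------
# loading / saving


def _collapse_duplicate_genes(df: pd.DataFrame, how: str = "sum") -> pd.DataFrame:
    if df.columns.duplicated().any():
        if how == "sum":
            df = df.T.groupby(level=0, sort=False).sum().T
        else:  # keep-first
            df = df.loc[:, ~df.columns.duplicated()]
    return df


def load_expression(
    path: str | os.PathLike,
    format: str = "delimited",
    *,
    axis_kind: str = "single_cells",
    samples_in_rows: bool = True,
    sep: Optional[str] = None,
    duplicate_genes: str = "sum",
) -> ExpressionMatrix:
    """Load a raw expression matrix from disk.

    ``format`` is one of ``delimited``, ``mtx_triplet`` (expects sidecar
    ``<stem>.rows.txt``/``<stem>.cols.txt`` id files holding sample and gene
    ids) or ``hdf_container`` (h5ad).  Duplicate gene columns are collapsed
    by summation (``duplicate_genes='sum'``) or first-wins (``'first'``).
    """
    path = os.fspath(path)
    if format == "delimited":
        if sep is None:
            sep = "," if path.endswith(".csv") else "\t"
        try:
            # read header separately: pandas would mangle duplicate gene ids
            with open(path) as fh:
                header = fh.readline().rstrip("\n").split(sep)
            df = pd.read_csv(
                path,
                sep=sep,
                index_col=0,
                header=None,
                skiprows=1,
                float_precision="round_trip",
            )
            df.columns = header[1:]
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if not samples_in_rows:
            df = df.T
        if df.isna().any().any():
            bad = int(df.isna().any(axis=1).to_numpy().argmax()) + 2
            raise FormatError(f"missing value near line {bad} of {path}")
        if df.index.duplicated().any():
            raise ValidationError(f"duplicate sample ids in {path}")
        df = _collapse_duplicate_genes(df, duplicate_genes)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            stage="raw",
            axis_kind=axis_kind,
        )
    if format == "mtx_triplet":
        stem = path[: -len(".mtx")] if path.endswith(".mtx") else path
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
        rows = _read_id_file(stem + ".rows.txt")
        cols = _read_id_file(stem + ".cols.txt")
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if len(set(rows)) != len(rows):
            raise ValidationError(f"duplicate sample ids in {stem}.rows.txt")
        df = pd.DataFrame(dense, index=rows, columns=cols)
        df = _collapse_duplicate_genes(df, duplicate_genes)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            list(df.index),
            list(df.columns),
            stage="raw",
            axis_kind=axis_kind,
        )
    if format == "hdf_container":
        try:
            adata = ad.read_h5ad(path)
        except Exception as exc:
            raise FormatError(f"cannot read h5ad container {path}: {exc}") from exc
        X = adata.X
        if scipy.sparse.issparse(X):
            X = X.toarray()
        df = pd.DataFrame(
            np.asarray(X, dtype=float),
            index=adata.obs_names.astype(str),
            columns=adata.var_names.astype(str),
        )
        if df.index.duplicated().any():
            raise ValidationError(f"duplicate sample ids in {path}")
        df = _collapse_duplicate_genes(df, duplicate_genes)
        stage = str(adata.uns.get("stage", "raw"))
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            list(df.index),
            list(df.columns),
            stage=stage if stage in ("raw", "normalized", "scaled") else "raw",
            axis_kind=axis_kind,
        )
    raise ValueError(f"unknown format {format!r}")


def _read_id_file(path: str) -> list[str]:
    if not os.path.exists(path):
        raise FormatError(f"MTX sidecar id file missing: {path}")
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def save_expression(
    X: ExpressionMatrix, path: str | os.PathLike, format: str = "delimited"
) -> None:
    """Write a matrix in any of the three supported layouts (lossless)."""
    path = os.fspath(path)
    if format == "delimited":
        sep = "," if path.endswith(".csv") else "\t"
        # repr-roundtrip float formatting keeps write->load bit-identical
        X.to_frame().to_csv(path, sep=sep, float_format="%.17g")
    elif format == "mtx_triplet":
        stem = path[: -len(".mtx")] if path.endswith(".mtx") else path
        scipy.io.mmwrite(stem + ".mtx", scipy.sparse.coo_matrix(X.values), precision=17)
        with open(stem + ".rows.txt", "w") as fh:
            fh.write("\n".join(X.sample_ids) + "\n")
        with open(stem + ".cols.txt", "w") as fh:
            fh.write("\n".join(X.gene_ids) + "\n")
    elif format == "hdf_container":
        adata = ad.AnnData(
            X=X.values.copy(),
            obs=pd.DataFrame(index=pd.Index(X.sample_ids, name="sample_id")),
            var=pd.DataFrame(index=pd.Index(X.gene_ids, name="gene_id")),
        )
        adata.uns["stage"] = X.stage
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_response_table(path: str | os.PathLike, sep: str = "\t") -> DrugResponseTable:
    df = pd.read_csv(path, sep=sep)
    return DrugResponseTable(df)


def save_response_table(
    table: DrugResponseTable, path: str | os.PathLike, sep: str = "\t"
) -> None:
    table.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# QC / normalization


def qc_and_normalize_sc(
    X: ExpressionMatrix,
    min_genes: int = 200,
    min_cells: int = 3,
    max_mito_frac: float = 0.10,
    target_sum: float = 10_000.0,
    mito_prefix: str = "MT-",
    scale: bool = True,
) -> ExpressionMatrix:
    """Filter and normalize a raw single-cell count matrix.

    Filters are applied in a fixed order: (1) cells with fewer than
    ``min_genes`` detected genes, (2) genes detected in fewer than
    ``min_cells`` cells, (3) cells whose mitochondrial count fraction
    (genes whose id starts with ``mito_prefix``, case-insensitive) exceeds
    ``max_mito_frac``.  Surviving counts are scaled per cell to
    ``target_sum``, log1p-transformed, then min-max scaled per gene so the
    result lies in [0, 1].  With ``scale=False`` the min-max step is skipped
    and the result is returned at stage ``normalized``.
    """
    if X.stage != "raw":
        raise ValidationError("qc_and_normalize_sc expects a raw matrix")
    if X.values.size and X.values.min() < 0:
        raise ValidationError("negative entries in raw count matrix")
    vals = X.values
    # 1) cell filter
    keep_cells = (vals > 0).sum(axis=1) >= min_genes
    vals = vals[keep_cells]
    sample_ids = [s for s, k in zip(X.sample_ids, keep_cells) if k]
    if vals.shape[0] == 0:
        raise EmptyResultError("no cells survive the min_genes filter")
    # 2) gene filter
    keep_genes = (vals > 0).sum(axis=0) >= min_cells
    vals = vals[:, keep_genes]
    gene_ids = [g for g, k in zip(X.gene_ids, keep_genes) if k]
    if vals.shape[1] == 0:
        raise EmptyResultError("no genes survive the min_cells filter")
    # 3) mito filter
    prefix = mito_prefix.lower()
    mito = np.array([g.lower().startswith(prefix) for g in gene_ids])
    totals = vals.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, vals[:, mito].sum(axis=1) / totals, 0.0)
    keep_cells2 = mito_frac <= max_mito_frac
    vals = vals[keep_cells2]
    sample_ids = [s for s, k in zip(sample_ids, keep_cells2) if k]
    if vals.shape[0] == 0:
        raise EmptyResultError("no cells survive the mitochondrial filter")

    # library-size normalization to target_sum, then log1p
    totals = vals.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    vals = np.log1p(vals / totals * target_sum)
    if scale:
        vals = minmax_per_gene(vals)
    return ExpressionMatrix(
        vals,
        sample_ids,
        gene_ids,
        stage="scaled" if scale else "normalized",
        axis_kind="single_cells",
    )


def minmax_per_gene(values: np.ndarray) -> np.ndarray:
    """Feature-wise min-max scaling to [0, 1]; constant genes map to 0."""
    lo = values.min(axis=0, keepdims=True)
    span = values.max(axis=0, keepdims=True) - lo
    span[span == 0] = 1.0
    return (values - lo) / span


def scale_bulk(X: ExpressionMatrix) -> ExpressionMatrix:
    """Min-max scale an (already normalized, e.g. RMA) bulk matrix per gene."""
    return replace(
        X,
        values=minmax_per_gene(X.values),
        sample_ids=list(X.sample_ids),
        gene_ids=list(X.gene_ids),
        stage="scaled",
    )


def align_gene_spaces(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    mapping: Optional[Sequence[tuple[str, str]]] = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in identical order.

    ``mapping`` optionally translates ``b``'s gene ids into ``a``'s
    namespace (e.g. a user-supplied ortholog table) before intersecting;
    it must be one-to-one.
    """
    b_genes = list(b.gene_ids)
    if mapping is not None:
        fwd = {src: dst for dst, src in mapping}
        if len(fwd) != len(list(mapping)) or len({d for d, _ in mapping}) != len(
            list(mapping)
        ):
            raise AlignmentError("gene mapping must be one-to-one")
        b_genes = [fwd.get(g, g) for g in b_genes]
    a_index = {g: i for i, g in enumerate(a.gene_ids)}
    b_index = {g: i for i, g in enumerate(b_genes)}
    shared = [g for g in a.gene_ids if g in b_index]
    if not shared:
        raise AlignmentError("no shared genes between the two matrices")
    a_idx = np.array([a_index[g] for g in shared])
    b_idx = np.array([b_index[g] for g in shared])
    a2 = a.subset_genes(a_idx)
    b2 = b.subset_genes(b_idx)
    b2.gene_ids = list(shared)
    return a2, b2
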