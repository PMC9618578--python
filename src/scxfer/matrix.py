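"""Core in-memory containers for expression data and drug-response tables.

An :class:`ExpressionMatrix` is a thin, validated wrapper around a dense
``samples x genes`` float array with string identifiers on both axes and a
``stage`` tag recording how far along the preprocessing pipeline the values
are (``raw`` counts/intensities, ``normalized`` log1p-CPM, or ``scaled``
per-gene min-max to [0, 1]).  Bulk cell-line profiles and single-cell
matrices share the container; ``axis_kind`` distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STAGES = ("raw", "normalized", "scaled")
AXIS_KINDS = ("bulk_cell_lines", "single_cells")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """Dense samples x genes expression matrix with identifiers.

    Parameters
    ----------
    values
        2-D float array, one row per sample (cell line or cell).
    sample_ids, gene_ids
        Unique identifiers for rows and columns respectively.
    stage
        One of ``raw`` (non-negative counts/intensities), ``normalized``
        (library-size normalised, log1p) or ``scaled`` (per-gene min-max,
        all values in [0, 1]).
    axis_kind
        ``bulk_cell_lines`` or ``single_cells``.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    stage: str = "raw"
    axis_kind: str = "single_cells"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.gene_ids) != p:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.gene_ids)) != p:
            raise ValidationError("duplicate gene ids")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.axis_kind not in AXIS_KINDS:
            raise ValidationError(f"unknown axis_kind {self.axis_kind!r}")
        if np.isnan(self.values).any():
            raise ValidationError("missing values in expression matrix")
        if self.stage == "raw" and self.values.size and self.values.min() < 0:
            raise ValidationError("raw expression values must be non-negative")
        if self.stage == "scaled" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValidationError("scaled values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
        )

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
        )


@dataclass
class DrugResponseTable:
    """Per cell-line drug response: AUC (lower = more sensitive) and labels.

    ``label`` is 1 for sensitive, 0 for resistant; ``None`` until
    binarization.  (cell_line_id, drug_id) pairs are unique.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("cell_line_id", "drug_id", "auc")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"response table missing column {col!r}")
        if self.table.duplicated(["cell_line_id", "drug_id"]).any():
            raise ValidationError("duplicate (cell_line_id, drug_id) pairs")
        auc = self.table["auc"].to_numpy(dtype=float)
        if not np.all(np.isfinite(auc)) or (auc < 0).any():
            raise ValidationError("auc values must be finite and non-negative")
        if "label" in self.table.columns:
            lab = self.table["label"].dropna()
            if not lab.isin([0, 1]).all():
                raise ValidationError("labels must be 0 (resistant) or 1 (sensitive)")

    def for_drug(self, drug_id: str) -> "DrugResponseTable":
        sub = self.table[self.table["drug_id"] == drug_id].reset_index(drop=True)
        return DrugResponseTable(sub)

    def auc_pairs(self) -> list[tuple[str, float]]:
        return list(
            zip(self.table["cell_line_id"].astype(str), self.table["auc"].astype(float))
        )
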