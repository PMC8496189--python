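"""Core containers shared across the pipeline stages.

Matrices are stored dense (genes x cells) -- plate-based experiments are
small enough that sparsity buys nothing and dense arrays keep the numerics
simple and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SPIKEIN_PREFIX = "ERCC-"

WELL_TYPES = ("single_cell", "bulk_control", "empty_control")


@dataclass
class RawCountMatrix:
    """Integer count matrix, genes as rows and cells as columns.

    Spike-in rows are recognised by the ``ERCC-`` prefix of their gene id.
    Cell ids follow the ``PLATE:WELL`` convention.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if self.counts.size and np.abs(self.counts - rounded).max() > 0:
                raise ValueError("counts must be integral")
            self.counts = rounded.astype(np.int64)
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label}_ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def spikein_mask(self) -> np.ndarray:
        return np.array([g.startswith(SPIKEIN_PREFIX) for g in self.gene_ids])

    def total_counts(self) -> np.ndarray:
        """Per-cell total counts."""
        return self.counts.sum(axis=0)

    def subset_cells(self, mask_or_ids) -> "RawCountMatrix":
        idx = _resolve_index(self.cell_ids, mask_or_ids)
        return RawCountMatrix(self.counts[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, mask_or_ids) -> "RawCountMatrix":
        idx = _resolve_index(self.gene_ids, mask_or_ids)
        return RawCountMatrix(self.counts[idx, :], self.gene_ids[idx], self.cell_ids)

    def copy(self) -> "RawCountMatrix":
        return RawCountMatrix(self.counts.copy(), self.gene_ids.copy(), self.cell_ids.copy())


@dataclass
class ExpressionMatrix:
    """log2(CPM + 1) expression values on the same axes as the source counts."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("expression shape does not match gene/cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_vector(self, gene_id: str) -> np.ndarray:
        idx = np.nonzero(self.gene_ids == gene_id)[0]
        if idx.size == 0:
            raise KeyError(f"gene {gene_id!r} not present")
        return self.values[idx[0]]

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _resolve_index(self.cell_ids, mask_or_ids)
        return ExpressionMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def subset_genes(self, mask_or_ids) -> "ExpressionMatrix":
        idx = _resolve_index(self.gene_ids, mask_or_ids)
        return ExpressionMatrix(self.values[idx, :], self.gene_ids[idx], self.cell_ids)


def _resolve_index(ids: np.ndarray, mask_or_ids) -> np.ndarray:
    arr = np.asarray(mask_or_ids)
    if arr.dtype == bool:
        if arr.shape != ids.shape:
            raise ValueError("boolean mask length mismatch")
        return np.nonzero(arr)[0]
    lookup = {v: i for i, v in enumerate(ids)}
    try:
        return np.array([lookup[v] for v in arr], dtype=int)
    except KeyError as exc:
        raise KeyError(f"id {exc.args[0]!r} not present") from None


def validate_metadata(metadata: pd.DataFrame, cell_ids=None) -> pd.DataFrame:
    """Check the cell-metadata contract and return the frame unchanged.

    Required columns: cell_id, plate_id, well, condition,
    condition_time_order, well_type, sort_gate.
    """
    required = [
        "cell_id",
        "plate_id",
        "well",
        "condition",
        "condition_time_order",
        "well_type",
        "sort_gate",
    ]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if metadata["cell_id"].duplicated().any():
        dup = metadata.loc[metadata["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate cell_id in metadata: {dup!r}")
    bad = set(metadata["well_type"]) - set(WELL_TYPES)
    if bad:
        cell = metadata.loc[metadata["well_type"].isin(bad), "cell_id"].iloc[0]
        raise ValueError(f"unknown well_type {bad.pop()!r} for cell {cell!r}")
    if cell_ids is not None:
        known = set(metadata["cell_id"])
        absent = [c for c in cell_ids if c not in known]
        if absent:
            raise ValueError(f"cells missing from metadata: {absent[:5]}")
    return metadata
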