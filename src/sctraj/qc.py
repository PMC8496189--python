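"""Cell and gene quality control, CPM normalization, per-plate QC accounting.

Filter conventions (all strict inequalities):

* control wells (bulk/empty), ``ERCC-`` spike-in rows and genes detected in
  zero remaining cells are removed first;
* cells must have total raw counts strictly greater than 2^16;
* cells must have housekeeping (Actb) log2-CPM strictly greater than the
  dataset-wide 1st percentile (linear-interpolation percentile).

A cell failing both filters is attributed to the low-read-count column, so
the report's categories are disjoint and rows add up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, RawCountMatrix, validate_metadata

MIN_TOTAL_COUNTS_DEFAULT = 2**16


@dataclass
class QCThresholds:
    actb_gene: str = "Actb"
    actb_percentile: float = 1.0
    min_total_counts: int = MIN_TOTAL_COUNTS_DEFAULT
    actb_scope: str = "dataset"  # or "plate"

    def __post_init__(self) -> None:
        if not 0 < self.actb_percentile < 100:
            raise ValueError("actb_percentile must lie in (0, 100)")
        if self.min_total_counts < 0:
            raise ValueError("min_total_counts must be nonnegative")
        if self.actb_scope not in ("dataset", "plate"):
            raise ValueError("actb_scope must be 'dataset' or 'plate'")


def exclude_controls_and_spikeins(
    matrix: RawCountMatrix, metadata: pd.DataFrame
) -> tuple[RawCountMatrix, dict]:
    """Drop control wells, spike-in rows and undetected genes.

    Returns the reduced matrix and a summary dict with the number removed
    per category. Gene detection is re-evaluated after the control wells
    are gone, so genes seen only in a control well are removed too.
    """
    validate_metadata(metadata, matrix.cell_ids)
    meta = metadata.set_index("cell_id")
    well_type = meta.loc[list(matrix.cell_ids), "well_type"].to_numpy()

    keep_cells = well_type == "single_cell"
    reduced = matrix.subset_cells(keep_cells)

    spike = reduced.spikein_mask
    reduced = reduced.subset_genes(~spike)

    detected = reduced.counts.sum(axis=1) > 0
    summary = {
        "control_wells_removed": int((~keep_cells).sum()),
        "spikein_genes_removed": int(spike.sum()),
        "undetected_genes_removed": int((~detected).sum()),
    }
    return reduced.subset_genes(detected), summary


def compute_log_cpm(matrix: RawCountMatrix) -> ExpressionMatrix:
    """log2(1e6 * x / total + 1) per gene and cell."""
    totals = matrix.total_counts().astype(float)
    zero = totals == 0
    if zero.any():
        bad = list(matrix.cell_ids[zero])
        raise ValueError(f"cells with zero total counts: {bad}")
    values = np.log2(1e6 * matrix.counts / totals[np.newaxis, :] + 1.0)
    return ExpressionMatrix(values, matrix.gene_ids, matrix.cell_ids)


def filter_low_counts(
    matrix: RawCountMatrix, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell ids into (kept, removed) by the strict total-count rule."""
    thresholds = thresholds or QCThresholds()
    totals = matrix.total_counts()
    keep = totals > thresholds.min_total_counts
    return matrix.cell_ids[keep], matrix.cell_ids[~keep]


def filter_low_actb(
    expr: ExpressionMatrix,
    thresholds: QCThresholds | None = None,
    plate_of: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split cell ids into (kept, removed) by the housekeeping percentile rule.

    The threshold is the ``actb_percentile`` percentile (linear interpolation
    between order statistics) of the housekeeping log2-CPM over all candidate
    cells; kept cells are strictly above it. With ``actb_scope='plate'`` the
    percentile is computed within each plate (requires ``plate_of``).
    """
    thresholds = thresholds or QCThresholds()
    actb = expr.gene_vector(thresholds.actb_gene)

    if thresholds.actb_scope == "plate":
        if plate_of is None:
            raise ValueError("plate scope requires a cell_id -> plate mapping")
        plates = np.array([plate_of[c] for c in expr.cell_ids], dtype=object)
        keep = np.zeros(expr.n_cells, dtype=bool)
        for p in np.unique(plates):
            sel = plates == p
            thr = np.percentile(actb[sel], thresholds.actb_percentile)
            keep[sel] = actb[sel] > thr
    else:
        thr = np.percentile(actb, thresholds.actb_percentile)
        keep = actb > thr

    if not keep.any() and expr.n_cells:
        warnings.warn(
            "housekeeping filter removed every cell (degenerate constant expression?)",
            stacklevel=2,
        )
    return expr.cell_ids[keep], expr.cell_ids[~keep]


def _round_half_even(x: float, ndigits: int = 2) -> float:
    # banker's rounding reproduces published accounting tables computed
    # with R's round() (e.g. 80.625 -> 80.62)
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_EVEN))


def build_qc_report(metadata: pd.DataFrame, outcomes: dict[str, str]) -> pd.DataFrame:
    """Per-plate accounting of sequenced / low-read / low-Actb / passed cells.

    ``outcomes`` maps every sequenced cell id to one of ``low_read``,
    ``low_actb`` or ``passed``. The returned frame carries one row per
    (plate, condition) plus a ``TOTAL`` row; per row
    ``passed = sequenced - low_read - low_actb`` and the percentage is
    rounded (half-even) to two decimals.
    """
    validate_metadata(metadata)
    seq = metadata[metadata["well_type"] == "single_cell"]
    missing = [c for c in seq["cell_id"] if c not in outcomes]
    if missing:
        raise ValueError(f"cells without a QC outcome: {missing[:5]}")
    bad = {c: o for c, o in outcomes.items() if o not in ("low_read", "low_actb", "passed")}
    if bad:
        c, o = next(iter(bad.items()))
        raise ValueError(f"invalid outcome {o!r} for cell {c!r}")

    rows = []
    for (plate, condition), grp in seq.groupby(["plate_id", "condition"], sort=True):
        o = [outcomes[c] for c in grp["cell_id"]]
        rows.append(_report_row(plate, condition, len(o), o.count("low_read"), o.count("low_actb")))
    total = _report_row(
        "TOTAL",
        "",
        sum(r["sequenced"] for r in rows),
        sum(r["low_read_count"] for r in rows),
        sum(r["low_actb"] for r in rows),
    )
    return pd.DataFrame(rows + [total])


def build_qc_report_from_counts(rows: list[dict]) -> pd.DataFrame:
    """Build the QC report directly from per-plate count triples.

    Each input row needs ``plate_id``, ``condition``, ``sequenced``,
    ``low_read_count`` and ``low_actb``; ``passed`` and the rounded
    percentage are derived. Used to replay a published accounting table.
    """
    out = [
        _report_row(
            r["plate_id"], r["condition"], int(r["sequenced"]), int(r["low_read_count"]), int(r["low_actb"])
        )
        for r in rows
    ]
    total = _report_row(
        "TOTAL",
        "",
        sum(r["sequenced"] for r in out),
        sum(r["low_read_count"] for r in out),
        sum(r["low_actb"] for r in out),
    )
    return pd.DataFrame(out + [total])


def _report_row(plate, condition, sequenced, low_read, low_actb) -> dict:
    passed = sequenced - low_read - low_actb
    pct = _round_half_even(100.0 * passed / sequenced) if sequenced else 0.0
    return {
        "plate_id": plate,
        "condition": condition,
        "sequenced": sequenced,
        "low_read_count": low_read,
        "low_actb": low_actb,
        "passed": passed,
        "pct_passed": pct,
    }


def run_qc(
    matrix: RawCountMatrix,
    metadata: pd.DataFrame,
    thresholds: QCThresholds | None = None,
):
    """Full QC pass: control/spike-in removal, both cell filters, report.

    Returns ``(filtered_matrix, expression, report, outcomes)`` where
    ``expression`` is the log2-CPM matrix of the passing cells and
    ``outcomes`` maps each candidate cell to its attributed fate.
    """
    thresholds = thresholds or QCThresholds()
    reduced, _summary = exclude_controls_and_spikeins(matrix, metadata)

    _, low_read = filter_low_counts(reduced, thresholds)
    low_read = set(low_read)

    expr_all = compute_log_cpm(
        reduced.subset_cells(reduced.total_counts() > 0)
    )
    plate_of = dict(zip(metadata["cell_id"], metadata["plate_id"]))
    _, low_actb = filter_low_actb(expr_all, thresholds, plate_of=plate_of)
    low_actb = set(low_actb)

    outcomes = {}
    for c in reduced.cell_ids:
        if c in low_read:
            outcomes[c] = "low_read"
        elif c in low_actb:
            outcomes[c] = "low_actb"
        else:
            outcomes[c] = "passed"

    passed_ids = [c for c in reduced.cell_ids if outcomes[c] == "passed"]
    filtered = reduced.subset_cells(passed_ids)
    detected = filtered.counts.sum(axis=1) > 0
    filtered = filtered.subset_genes(detected)
    expr = compute_log_cpm(filtered)
    report = build_qc_report(metadata, outcomes)
    return filtered, expr, report, outcomes
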