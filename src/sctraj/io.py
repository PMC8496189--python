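"""Reading and writing of pipeline artifacts.

Count matrices travel as Matrix Market (.mtx) next to ``genes.tsv`` and
``cells.tsv``; tables are TSV/CSV with a header row. Round trips are
integer-exact for matrices and string-exact for tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scio
from scipy import sparse

from .datatypes import RawCountMatrix, validate_metadata


class ParseError(ValueError):
    pass


def write_count_matrix(matrix: RawCountMatrix, directory: str | Path, prefix: str = "") -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scio.mmwrite(str(d / f"{prefix}matrix.mtx"), sparse.coo_matrix(matrix.counts), field="integer")
    pd.Series(matrix.gene_ids).to_csv(d / f"{prefix}genes.tsv", sep="\t", index=False, header=["gene_id"])
    pd.Series(matrix.cell_ids).to_csv(d / f"{prefix}cells.tsv", sep="\t", index=False, header=["cell_id"])


def read_count_matrix(directory: str | Path, prefix: str = "") -> RawCountMatrix:
    d = Path(directory)
    try:
        m = scio.mmread(str(d / f"{prefix}matrix.mtx"))
    except Exception as exc:  # pragma: no cover - scipy's message is wrapped
        raise ParseError(f"malformed Matrix Market file {d / (prefix + 'matrix.mtx')}: {exc}") from exc
    counts = np.asarray(m.todense() if sparse.issparse(m) else m)
    if not np.issubdtype(counts.dtype, np.integer):
        if np.abs(counts - np.rint(counts)).max() > 0:
            raise ParseError(f"non-integer counts in {prefix}matrix.mtx")
        counts = np.rint(counts).astype(np.int64)
    genes = _read_id_column(d / f"{prefix}genes.tsv", "gene_id")
    cells = _read_id_column(d / f"{prefix}cells.tsv", "cell_id")
    try:
        return RawCountMatrix(counts, genes, cells)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def _read_id_column(path: Path, column: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if column not in df.columns:
        raise ParseError(f"{path}: missing header column {column!r} (line 1)")
    ids = df[column].to_numpy(dtype=object)
    dup = pd.Series(ids).duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: duplicate {column} {ids[dup.idxmax()]!r} (line {line})")
    return ids


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "plate_id": str, "well": str})
    try:
        return validate_metadata(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
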