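"""Plain-text readers and writers for the pipeline's tabular formats.

All matrices are written as dense CSV (or MatrixMarket via scipy); node,
family, expression, and profile tables are TSV with 0-based indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_matrix_mm",
    "read_matrix_mm",
    "write_tsv",
    "read_tsv",
    "write_edge_list",
]


def write_matrix_csv(path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",", fmt="%.10g")


def read_matrix_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",")


def write_matrix_mm(path, matrix: np.ndarray) -> None:
    mmwrite(str(path), np.asarray(matrix, dtype=float))


def read_matrix_mm(path) -> np.ndarray:
    m = mmread(str(path))
    return np.asarray(m.todense()) if hasattr(m, "todense") else np.asarray(m)


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_edge_list(path, edge_i, edge_j, values=None, header=("i", "j", "weight")) -> None:
    cols = {header[0]: edge_i, header[1]: edge_j}
    if values is not None:
        cols[header[2]] = values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
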