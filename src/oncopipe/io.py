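"""Tab-separated and sidecar I/O shared by all pipeline stages.

All writers emit UTF-8, tab-delimited tables with a header row and '.' as the
decimal separator; readers validate required columns and report malformed rows
with their location.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

__all__ = [
    "read_table",
    "write_table",
    "write_counts_mtx",
    "read_counts",
    "read_gmt",
    "write_json",
    "sha256_file",
]


def read_table(path, required_columns=None, numeric_columns=None) -> pd.DataFrame:
    """Read a TSV with schema validation; errors name the offending rows."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if required_columns:
        missing = set(required_columns) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if numeric_columns:
        for col in numeric_columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                rows = (df.index[bad] + 2).tolist()[:5]  # 1-based + header
                raise ValueError(f"{path}: non-numeric values in column {col!r} "
                                 f"at line(s) {rows}")
            df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_counts_mtx(counts: pd.DataFrame, prefix) -> list[Path]:
    """Write a genes x samples count matrix as MatrixMarket + name files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mtx = prefix.with_suffix(".mtx")
    scipy_io.mmwrite(str(mtx), sparse.csr_matrix(counts.to_numpy()))
    rows = prefix.parent / (prefix.name + ".genes.txt")
    cols = prefix.parent / (prefix.name + ".samples.txt")
    rows.write_text("\n".join(map(str, counts.index)) + "\n")
    cols.write_text("\n".join(map(str, counts.columns)) + "\n")
    return [mtx, rows, cols]


def read_counts(path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Read a counts matrix from TSV (genes x samples) or MTX + name files."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy_io.mmread(str(path)).toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        return pd.DataFrame(mat, index=genes, columns=samples)
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {i} has fewer than 3 tab-separated fields")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return super().default(o)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
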