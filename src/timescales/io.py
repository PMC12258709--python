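"""Reading and writing the package's interchange formats.

Matrices of time series travel as delimited text (TSV canonical, CSV
accepted by delimiter sniffing; rows are timepoints, columns are series)
or as dense ``.npy`` arrays.  Fit results and group summaries are TSV
tables with floats serialized at 17 significant digits so a written table
re-reads to the same values bit-for-bit.  Every output table gets a JSON
sidecar recording the full configuration, seed and package version.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

FLOAT_FORMAT = "%.17g"

__all__ = [
    "read_matrix",
    "read_acf_vector",
    "write_table",
    "read_table",
    "write_metadata",
]


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _has_header(first_line: str, delimiter: str) -> bool:
    for token in first_line.strip().split(delimiter):
        try:
            float(token)
        except ValueError:
            return True
    return False


def read_matrix(path: Union[str, Path], transpose: bool = False) -> np.ndarray:
    """Read a timepoints-by-series matrix from TSV/CSV or ``.npy``.

    The delimiter is sniffed (tab vs comma) and a header row is detected by
    attempting to parse the first line as numbers.  ``transpose`` flips a
    series-by-timepoints layout into the canonical orientation.
    """
    path = Path(path)
    if path.suffix == ".npy":
        matrix = np.load(path)
    else:
        with open(path) as handle:
            first_line = handle.readline()
        if not first_line.strip():
            raise ValueError(f"{path}: empty input file")
        delimiter = _sniff_delimiter(first_line)
        header = 0 if _has_header(first_line, delimiter) else None
        frame = pd.read_csv(
            path, sep=delimiter, header=header, float_precision="round_trip"
        )
        try:
            matrix = frame.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric entries in matrix: {exc}") from exc
    matrix = np.atleast_2d(matrix)
    if matrix.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D matrix, got shape {matrix.shape}")
    if transpose:
        matrix = matrix.T
    bad = ~np.isfinite(matrix)
    if bad.any():
        t, v = np.argwhere(bad)[0]
        raise ValueError(f"{path}: non-finite value at row {t}, column {v}")
    return matrix


def read_acf_vector(path: Union[str, Path]) -> np.ndarray:
    """Read a single-column autocorrelation vector ``rho_0..rho_K``."""
    matrix = read_matrix(path)
    if 1 not in matrix.shape:
        raise ValueError(f"{path}: expected a single-column ACF vector")
    return matrix.reshape(-1)


def write_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a result table as TSV with full-precision floats."""
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def write_metadata(
    table_path: Union[str, Path],
    config: dict,
    seed: Optional[int] = None,
) -> Path:
    """Write the JSON sidecar (``<table>.json``) describing a run."""
    from . import __version__

    sidecar = Path(table_path).with_suffix(Path(table_path).suffix + ".json")
    record = {
        "version": __version__,
        "seed": seed,
        "command": " ".join(sys.argv),
        "config": _jsonable(config),
    }
    sidecar.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return sidecar
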