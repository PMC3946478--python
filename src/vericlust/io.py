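"""Reading data matrices and writing index reports.

The data-matrix format is plain delimited text: one row per object, one
column per feature, an optional header row, and optionally a trailing
ground-truth label column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError


def read_data_matrix(
    path: str | Path,
    *,
    label_column: bool = False,
    delimiter: str = ",",
) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a CSV object-by-feature matrix.

    Parameters
    ----------
    path
        Delimited text file; rows are objects, columns are features.
        A header row is detected automatically (first row not fully numeric).
    label_column
        If True the final column holds ground-truth class labels and is
        returned separately (as strings) rather than parsed as a feature.

    Returns
    -------
    (X, labels)
        ``X`` is a float ndarray of shape (n_objects, n_features); ``labels``
        is an object ndarray of length n_objects, or None when
        ``label_column`` is False.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"data file not found: {path}")
    probe = pd.read_csv(path, sep=delimiter, header=None, nrows=1)
    has_header = False
    head_cols = probe.shape[1] - 1 if label_column else probe.shape[1]
    for value in probe.iloc[0, :head_cols]:
        try:
            float(value)
        except (TypeError, ValueError):
            has_header = True
            break
    frame = pd.read_csv(path, sep=delimiter, header=0 if has_header else None)
    if frame.shape[0] == 0:
        raise InputError(f"data file is empty: {path}")
    labels = None
    if label_column:
        if frame.shape[1] < 2:
            raise InputError("label_column requires at least two columns")
        labels = frame.iloc[:, -1].to_numpy()
        frame = frame.iloc[:, :-1]
    try:
        X = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"non-numeric feature value in {path}: {exc}") from exc
    return X, labels


def write_data_matrix(
    path: str | Path,
    X: np.ndarray,
    labels: np.ndarray | None = None,
) -> None:
    """Write a matrix (and optional trailing label column) as headerless CSV."""
    X = np.asarray(X, dtype=float)
    frame = pd.DataFrame(X)
    if labels is not None:
        if len(labels) != X.shape[0]:
            raise InputError("labels length does not match number of rows")
        frame[frame.shape[1]] = np.asarray(labels)
    frame.to_csv(path, header=False, index=False)


def write_index_report(report: dict, path: str | Path) -> None:
    """Serialize an index-name -> value mapping as JSON.

    Non-finite values are encoded as strings ("Infinity", "NaN") so the file
    stays strict JSON.
    """

    def _encode(v):
        if v is None:
            return None
        if isinstance(v, (int, np.integer)):
            return int(v)
        v = float(v)
        if np.isnan(v):
            return "NaN"
        if np.isinf(v):
            return "Infinity" if v > 0 else "-Infinity"
        return v

    payload = {name: _encode(value) for name, value in report.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
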