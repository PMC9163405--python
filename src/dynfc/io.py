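"""Delimited-text formats for time courses, edge stacks, centroids and results.

All intermediates are human-diffable TSV/CSV (UTF-8, '.' decimal) with JSON
sidecars for run metadata.  Readers are strict: ragged rows, non-numeric
cells and header/label mismatches raise with file and row diagnostics
instead of silently coercing or reordering.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TimeCourseMatrix
from .windows import WindowedFCStack, edge_index


def _read_delimited(path: Path, delimiter: str) -> tuple[list[str], np.ndarray]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        rows = list(reader)
    if len(rows) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    width = len(header)
    data = np.empty((len(rows) - 1, width))
    for ri, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ValueError(f"{path}: row {ri} has {len(row)} fields, expected {width}")
        for ci, cell in enumerate(row):
            if cell.strip() == "":
                raise ValueError(f"{path}: missing cell at row {ri}, column {header[ci]!r}")
            try:
                data[ri - 2, ci] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {ri}, column {header[ci]!r}"
                ) from None
    return header, data


def write_timecourses(tc: TimeCourseMatrix, path: str | Path) -> Path:
    """One subject's time courses as TSV: header of network labels, one row per TR."""
    path = Path(path)
    df = pd.DataFrame(tc.data, columns=tc.network_labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_timecourses(path: str | Path, subject_id: str | None = None,
                     tr: float = 2.0,
                     expected_labels: list[str] | None = None) -> TimeCourseMatrix:
    path = Path(path)
    header, data = _read_delimited(path, "\t")
    if expected_labels is not None and header != list(expected_labels):
        raise ValueError(
            f"{path}: network labels {header} do not match expected "
            f"{list(expected_labels)}; no silent reorder is performed")
    sid = subject_id or path.stem
    return TimeCourseMatrix(sid, header, data, tr)


def write_edge_stack(stack: WindowedFCStack, path: str | Path) -> Path:
    """Windowed edge matrix as TSV (header 'i_j' label pairs) + JSON sidecar."""
    path = Path(path)
    labels = stack.network_labels
    cols = [f"{labels[i]}_{labels[j]}" for i, j in edge_index(len(labels))]
    pd.DataFrame(stack.edge_values, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "subject_id": stack.subject_id,
        "network_labels": labels,
        "selected_penalty": stack.selected_penalty,
        "window_centers": stack.window_centers.tolist(),
        "edge_index": edge_index(len(labels)),
    }, indent=1))
    return path


def read_edge_stack(path: str | Path) -> WindowedFCStack:
    path = Path(path)
    header, data = _read_delimited(path, "\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    labels = meta["network_labels"]
    expected = [f"{labels[i]}_{labels[j]}" for i, j in edge_index(len(labels))]
    if header != expected:
        raise ValueError(f"{path}: edge columns do not match the sidecar's labels")
    return WindowedFCStack(meta["subject_id"], data, labels,
                           np.asarray(meta["window_centers"]),
                           meta.get("selected_penalty", 0.0))


def write_covariates(cov: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cov.to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: covariate table needs subject_id and group columns")
    if (df["mean_fd"] < 0).any():
        raise ValueError(f"{path}: negative mean_fd")
    return df


def write_centroids(centroids: np.ndarray, network_labels: list[str],
                    path: str | Path) -> Path:
    path = Path(path)
    cols = [f"{network_labels[i]}_{network_labels[j]}"
            for i, j in edge_index(len(network_labels))]
    df = pd.DataFrame(centroids, columns=cols)
    df.insert(0, "state", np.arange(1, len(centroids) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def write_assignments(assignments: dict[str, np.ndarray], path: str | Path) -> Path:
    path = Path(path)
    rows = [{"subject_id": sid, "window": w, "state": int(s)}
            for sid, lab in assignments.items() for w, s in enumerate(lab)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
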