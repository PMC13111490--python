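"""Reading and writing connectivity matrices, tables and volumes.

Matrices are delimited text (TSV by default, delimiter sniffed on read) with
a mandatory header row of node labels.  Values round-trip bit-exactly at 17
significant digits.  Volumes go through NIfTI via nibabel.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .network import (
    ShapeError,
    ValidationError,
    WeightedNetwork,
)


class FormatError(ValueError):
    """File is not a parsable matrix of the expected layout."""


def write_matrix(network: WeightedNetwork, path) -> None:
    path = Path(path)
    with path.open("w") as f:
        f.write("\t".join(network.node_labels) + "\n")
        for row in network.weights:
            f.write("\t".join(format(v, ".17g") for v in row) + "\n")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,; ").delimiter
    except csv.Error:
        return "\t"


def read_matrix(path) -> WeightedNetwork:
    """Read a square matrix with a node-label header row.

    Enforces the connectivity contract: finite entries in [0, 1], zero
    diagonal (sub-1e-12 diagonal noise is zeroed with a warning).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path} is empty")
    delim = _sniff_delimiter(text.splitlines()[0])
    lines = [ln for ln in text.splitlines() if ln.strip()]
    labels = [c.strip() for c in lines[0].split(delim)]
    try:
        values = np.loadtxt(
            _io.StringIO("\n".join(lines[1:])), delimiter=delim, ndmin=2
        )
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse matrix body: {exc}") from exc
    if values.shape[0] != values.shape[1]:
        raise FormatError(
            f"{path}: matrix is {values.shape[0]}x{values.shape[1]}, not square"
        )
    if len(labels) != values.shape[1]:
        raise FormatError(
            f"{path}: {len(labels)} header labels for {values.shape[1]} columns"
        )
    bad = ~np.isfinite(values) | (values < 0) | (values > 1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: entry at row {i + 1}, column {j + 1} "
            f"({values[i, j]!r}) violates the [0, 1] contract"
        )
    return WeightedNetwork(values, labels)


def write_participants_table(records, paths, out_path) -> None:
    """TSV linking each scan to its matrix file."""
    rows = [
        {
            "participant_id": r.participant_id,
            "group": r.group,
            "scan_index": r.scan_index,
            "path": str(p),
        }
        for r, p in zip(records, paths)
    ]
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)


def read_participants_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"participant_id", "group", "scan_index", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: participants table missing columns {sorted(missing)}"
        )
    return df


def write_volume(values: np.ndarray, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def read_volume(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata())


def write_node_edge_files(network: WeightedNetwork, node_path, edge_path) -> None:
    """Plain-text node/edge export in the convention of common connectome
    viewers: one node per line, and the full weight matrix as the edge file."""
    with Path(node_path).open("w") as f:
        for label in network.node_labels:
            f.write(f"{label}\n")
    np.savetxt(edge_path, network.weights, fmt="%.10g", delimiter="\t")
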