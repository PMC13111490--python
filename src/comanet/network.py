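"""Core network containers.

Connectivity matrices follow the row-to-column convention throughout the
package: entry ``(i, j)`` is the directed edge i -> j.  Weighted matrices hold
streamline connection probabilities ``p_ij`` in ``[0, 1]`` with a structurally
zero diagonal (no self-loops).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: |diagonal| values below this are treated as numeric noise and zeroed.
DIAG_TOL = 1e-12


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class ValidationError(ValueError):
    """Matrix content violates the connectivity-matrix contract."""


class ShapeError(ValueError):
    """Incompatible or non-square array shapes."""


def _default_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"N{i + 1:0{width}d}" for i in range(n)]


def _check_square(a: np.ndarray) -> int:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError(f"expected a square matrix, got shape {a.shape}")
    if a.shape[0] < 2:
        raise ShapeError("a network needs at least 2 nodes")
    return a.shape[0]


def _clean_diagonal(a: np.ndarray) -> None:
    d = np.diagonal(a)
    bad = np.abs(d) > DIAG_TOL
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"diagonal must be zero; entry ({idx},{idx}) = {d[idx]!r}"
        )
    if (d != 0).any():
        warnings.warn("auto-zeroing sub-tolerance diagonal entries", stacklevel=3)
    np.fill_diagonal(a, 0.0)


@dataclass
class WeightedNetwork:
    """Directed weighted network of connection probabilities.

    Parameters
    ----------
    weights
        Square matrix with entries in ``[0, 1]`` and zero diagonal.
    node_labels
        Optional region names, one per node; generated if omitted.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = _check_square(w)
        if not np.isfinite(w).all():
            i, j = np.argwhere(~np.isfinite(w))[0]
            raise ValidationError(f"non-finite entry at ({i},{j})")
        out = (w < 0) | (w > 1)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValidationError(
                f"entry ({i},{j}) = {w[i, j]!r} outside [0, 1]"
            )
        _clean_diagonal(w)
        self.weights = w
        if not self.node_labels:
            self.node_labels = _default_labels(n)
        elif len(self.node_labels) != n:
            raise ShapeError(
                f"{len(self.node_labels)} labels for {n} nodes"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def density(self) -> float:
        n = self.n_nodes
        return float(np.count_nonzero(self.weights)) / (n * (n - 1))

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.weights.copy(), list(self.node_labels))


@dataclass
class BinaryNetwork:
    """Directed binary adjacency matrix (0/1 entries, zero diagonal)."""

    adjacency: np.ndarray
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = _check_square(a)
        if not np.isin(a, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        a = a.astype(np.int8)
        np.fill_diagonal(a, 0)
        self.adjacency = a
        if not self.node_labels:
            self.node_labels = _default_labels(n)
        elif len(self.node_labels) != n:
            raise ShapeError(f"{len(self.node_labels)} labels for {n} nodes")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def density(self) -> float:
        n = self.n_nodes
        return float(self.adjacency.sum()) / (n * (n - 1))

    def copy(self) -> "BinaryNetwork":
        return BinaryNetwork(self.adjacency.copy(), list(self.node_labels))


def matrix_of(network: WeightedNetwork | BinaryNetwork) -> np.ndarray:
    """Underlying float matrix of either network type."""
    if isinstance(network, WeightedNetwork):
        return network.weights
    if isinstance(network, BinaryNetwork):
        return network.adjacency.astype(float)
    raise TypeError(f"not a network: {type(network).__name__}")


def aal116_labels() -> list[str]:
    """The 116 AAL region names (cortical, subcortical, cerebellar)."""
    text = (
        resources.files("comanet.data").joinpath("aal116.tsv").read_text()
    )
    lines = text.strip().splitlines()[1:]
    labels = [line.split("\t")[1] for line in lines]
    assert len(labels) == 116
    return labels
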