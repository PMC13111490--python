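"""Directed graph topology metrics.

Implements the binary-directed and weighted-directed variants used for
structural connectomes: Fagiolo's total directed clustering coefficient,
global efficiency on hop or inverse-weight distances, and directed
degree/strength.  Convention: matrix entry ``(i, j)`` is the edge i -> j,
so out-degree is a row sum and in-degree a column sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .network import BinaryNetwork, ShapeError, WeightedNetwork, matrix_of


@dataclass
class NodalMetrics:
    clustering: np.ndarray | None = None
    k_in: np.ndarray | None = None
    k_out: np.ndarray | None = None
    degree: np.ndarray | None = None
    strength: np.ndarray | None = None


@dataclass
class GlobalMetrics:
    """Cohort-comparable global summaries of one network."""

    clustering: float
    efficiency: float
    degree: float | None = None
    strength: float | None = None


def degree_directed(network: BinaryNetwork) -> NodalMetrics:
    a = network.adjacency.astype(np.int64)
    k_in = a.sum(axis=0)
    k_out = a.sum(axis=1)
    return NodalMetrics(k_in=k_in, k_out=k_out, degree=k_in + k_out)


def strength_directed(network: WeightedNetwork | BinaryNetwork) -> NodalMetrics:
    w = matrix_of(network)
    s = w.sum(axis=0) + w.sum(axis=1)
    return NodalMetrics(strength=s)


def _clustering_directed(w: np.ndarray) -> np.ndarray:
    """Fagiolo total clustering; ``w`` is 0/1 for the binary variant or
    cube-rooted weights for the weighted variant (pattern shared)."""
    a = (w > 0).astype(float)
    sym_w = w + w.T
    t = 0.5 * np.diagonal(sym_w @ sym_w @ sym_w)
    k = a.sum(axis=0) + a.sum(axis=1)
    k_recip = np.diagonal(a @ a)  # reciprocal partners
    denom = k * (k - 1) - 2.0 * k_recip
    c = np.zeros_like(t)
    ok = denom > 0
    c[ok] = t[ok] / denom[ok]
    return c


def clustering_coefficient_bd(network: BinaryNetwork) -> np.ndarray:
    """Per-node binary directed clustering coefficient in [0, 1]."""
    return _clustering_directed(network.adjacency.astype(float))


def clustering_coefficient_wd(network: WeightedNetwork) -> np.ndarray:
    """Weighted directed clustering: triangle intensity uses w**(1/3),
    the denominator comes from the binarized connection pattern."""
    return _clustering_directed(np.cbrt(network.weights))


def shortest_path_lengths(
    network: BinaryNetwork | WeightedNetwork, weighted: bool | None = None
) -> np.ndarray:
    """All-pairs directed distances; hop counts for binary networks,
    inverse-weight lengths (L = 1/w) for weighted ones.  Unreachable
    pairs are +inf; the diagonal is 0."""
    if weighted is None:
        weighted = isinstance(network, WeightedNetwork)
    w = matrix_of(network)
    if weighted:
        lengths = np.zeros_like(w)
        nz = w > 0
        lengths[nz] = 1.0 / w[nz]
        d = _csgraph_shortest_path(lengths, method="D", directed=True)
    else:
        d = _csgraph_shortest_path(
            (w > 0).astype(np.int8), method="D", directed=True, unweighted=True
        )
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(
    network: BinaryNetwork | WeightedNetwork, variant: str = "binary"
) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    if variant not in ("binary", "weighted"):
        raise ValueError(f"unknown efficiency variant {variant!r}")
    n = network.n_nodes
    d = shortest_path_lengths(network, weighted=(variant == "weighted"))
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_metrics(
    network: BinaryNetwork | WeightedNetwork, variant: str = "binary"
) -> GlobalMetrics:
    """The four global measures of one network.

    ``binary`` uses binary-directed clustering/efficiency and degree;
    ``weighted`` uses the weighted-directed variants and strength.
    """
    if variant == "binary":
        if isinstance(network, WeightedNetwork):
            network = BinaryNetwork(
                (network.weights > 0).astype(np.int8), list(network.node_labels)
            )
        c = clustering_coefficient_bd(network)
        k = degree_directed(network).degree
        return GlobalMetrics(
            clustering=float(c.mean()),
            efficiency=global_efficiency(network, "binary"),
            degree=float(k.mean()),
        )
    if variant == "weighted":
        if not isinstance(network, WeightedNetwork):
            raise ShapeError("weighted metrics need a weighted network")
        c = clustering_coefficient_wd(network)
        s = strength_directed(network).strength
        return GlobalMetrics(
            clustering=float(c.mean()),
            efficiency=global_efficiency(network, "weighted"),
            strength=float(s.mean()),
        )
    raise ValueError(f"unknown metric variant {variant!r}")
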