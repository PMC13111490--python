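"""Absolute and proportional thresholding of weighted networks.

Absolute thresholding zeroes entries strictly below a cut-off tau (entries
equal to tau are kept).  Proportional thresholding retains the
``round(p * n * (n - 1))`` largest off-diagonal weights — the denominator
counts every off-diagonal slot, zeros included — with ties at the retention
boundary broken by ascending (row, column) index for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .network import BinaryNetwork, ParameterError, WeightedNetwork


def threshold_absolute(network: WeightedNetwork, tau: float) -> WeightedNetwork:
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"absolute threshold {tau!r} outside [0, 1]")
    w = network.weights.copy()
    w[w < tau] = 0.0
    return WeightedNetwork(w, list(network.node_labels))


def threshold_proportional(network: WeightedNetwork, p: float) -> WeightedNetwork:
    if not 0.0 < p <= 1.0:
        raise ParameterError(f"density target {p!r} outside (0, 1]")
    w = network.weights
    n = w.shape[0]
    m = int(np.rint(p * n * (n - 1)))
    rows, cols = np.where(~np.eye(n, dtype=bool))
    vals = w[rows, cols]
    # primary: weight descending; ties: ascending (row, col)
    order = np.lexsort((cols, rows, -vals))
    keep = order[:m]
    keep = keep[vals[keep] > 0]  # never resurrect zero-weight slots
    out = np.zeros_like(w)
    out[rows[keep], cols[keep]] = vals[keep]
    return WeightedNetwork(out, list(network.node_labels))


def binarize(network: WeightedNetwork | BinaryNetwork) -> BinaryNetwork:
    if isinstance(network, BinaryNetwork):
        return network.copy()
    return BinaryNetwork(
        (network.weights > 0).astype(np.int8), list(network.node_labels)
    )
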