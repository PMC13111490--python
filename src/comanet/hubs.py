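"""Hub disruption index.

The hub index of a participant is the slope of the ordinary-least-squares
regression of per-node differences (participant nodal value minus control
mean) on the control-derived ascending rank of that nodal value.  A negative
slope means the nodes that are strongest in healthy controls lost
disproportionately more connectivity — hub-selective damage.  The nodal
value is degree for binarized (absolute-threshold) analyses and strength
for weighted (proportional-threshold) analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .metrics import degree_directed, strength_directed
from .network import BinaryNetwork, ParameterError, ShapeError, WeightedNetwork
from .threshold import binarize


def _nodal_values(network, basis: str) -> np.ndarray:
    if basis == "degree":
        net = network if isinstance(network, BinaryNetwork) else binarize(network)
        return degree_directed(net).degree.astype(float)
    if basis == "strength":
        return strength_directed(network).strength
    raise ParameterError(f"unknown hub basis {basis!r}")


@dataclass
class HubReference:
    """Control-cohort nodal means and their ascending ranks (1..n)."""

    mean_values: np.ndarray
    ranks: np.ndarray
    basis: str
    node_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return self.mean_values.size


@dataclass
class HubIndexResult:
    slope: float
    intercept: float
    differences: np.ndarray


def build_hub_reference(
    control_networks: list, basis: str = "degree"
) -> HubReference:
    """Average nodal values over every control scan and rank them ascending
    (rank n = strongest node); ties broken by node index."""
    if not control_networks:
        raise ParameterError("need at least one control network")
    n = control_networks[0].n_nodes
    vals = []
    for net in control_networks:
        if net.n_nodes != n:
            raise ShapeError("control networks differ in size")
        vals.append(_nodal_values(net, basis))
    mean_vals = np.mean(vals, axis=0)
    order = np.argsort(mean_vals, kind="stable")  # ties -> lower node index first
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return HubReference(
        mean_values=mean_vals,
        ranks=ranks,
        basis=basis,
        node_labels=list(control_networks[0].node_labels),
    )


def hub_index(participant_network, reference: HubReference) -> HubIndexResult:
    """OLS slope of (participant - control mean) nodal values on the
    control-derived rank."""
    if participant_network.n_nodes != reference.n_nodes:
        raise ShapeError(
            f"participant has {participant_network.n_nodes} nodes, "
            f"reference has {reference.n_nodes}"
        )
    d = _nodal_values(participant_network, reference.basis) - reference.mean_values
    r = reference.ranks.astype(float)
    rc = r - r.mean()
    slope = float(rc @ (d - d.mean()) / (rc @ rc))
    intercept = float(d.mean() - slope * r.mean())
    return HubIndexResult(slope=slope, intercept=intercept, differences=d)


def top_hubs(nodal_values, fraction: float = 0.05) -> list[int]:
    """The ceil(fraction * n) nodes with the largest values (key hubs);
    boundary ties broken by node index.  Returned sorted by node id."""
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction {fraction!r} outside (0, 1]")
    v = np.asarray(nodal_values, dtype=float)
    m = math.ceil(fraction * v.size)
    order = np.lexsort((np.arange(v.size), -v))
    return sorted(int(i) for i in order[:m])
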