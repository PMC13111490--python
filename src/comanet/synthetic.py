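"""Synthetic cohorts of structural connectomes.

Control connectomes are directed Watts–Strogatz-style small-world networks
augmented with a small set of designated high-degree hubs (bilateral
thalamus / putamen / precuneus analogues on the AAL-116 layout).  Patient
connectomes are produced from a per-participant control base network by a
severity-graded, optionally hub-selective edge-attenuation injury model:

    w' = clamp(w * (1 - a_ij) + eps, 0, 1),
    a_ij = s * (1 + gamma * H_ij) / (1 + gamma),

where ``s`` is injury severity, ``gamma`` the hub selectivity, ``H_ij`` is 1
when the edge touches a hub, and ``eps ~ N(0, sigma^2)`` per surviving edge.
With ``gamma > 0`` hub-incident edges lose a disproportionate fraction of
their weight, mimicking preferential damage to high-degree hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .network import ParameterError, WeightedNetwork, aal116_labels

#: 0-based AAL indices of the designated hub analogues:
#: Precuneus_L/R, Putamen_L/R, Thalamus_L/R.
DEFAULT_HUB_NODES = (66, 67, 72, 73, 76, 77)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_participants: int
    n_scans: int
    severity: float


#: Study-like default design: 4 controls with 3 repeat scans each and
#: severity-ordered patient groups (EMCS < AR' < No AR).
DEFAULT_GROUPS = (
    GroupSpec("Control", 4, 3, 0.0),
    GroupSpec("EMCS", 3, 1, 0.15),
    GroupSpec("AR'", 7, 1, 0.35),
    GroupSpec("No AR", 8, 1, 0.55),
)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    The defaults emulate the study design: 116 AAL nodes, a small-world
    base topology (ring of 8 neighbours per side, 10% rewiring), six
    designated hubs receiving extra connections, Beta(2, 2) edge weights,
    and four severity-ordered groups.
    """

    n_nodes: int = 116
    k_ring: int = 8
    beta_rewire: float = 0.1
    hub_nodes: tuple[int, ...] | None = None
    hub_boost: float = 0.6
    weight_law: tuple = ("beta", 2.0, 2.0)
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    hub_selectivity: float = 2.0
    noise_sd: float = 0.02
    scan_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ParameterError("n_nodes must be at least 4")
        if not 1 <= self.k_ring < self.n_nodes / 2:
            raise ParameterError(
                f"k_ring={self.k_ring} out of range [1, n_nodes/2)"
            )
        if not 0 <= self.beta_rewire <= 1:
            raise ParameterError("beta_rewire must lie in [0, 1]")
        if not 0 <= self.hub_boost <= 1:
            raise ParameterError("hub_boost must lie in [0, 1]")
        if self.hub_nodes is None:
            # six designated hubs: the AAL thalamus/putamen/precuneus
            # analogues at full size, evenly spaced nodes otherwise
            if self.n_nodes == 116:
                self.hub_nodes = DEFAULT_HUB_NODES
            else:
                n_hubs = min(6, max(1, self.n_nodes // 4))
                self.hub_nodes = tuple(
                    np.linspace(0, self.n_nodes - 1, n_hubs + 1)[:-1]
                    .round()
                    .astype(int)
                    .tolist()
                )
        bad = [h for h in self.hub_nodes if not 0 <= h < self.n_nodes]
        if bad:
            raise ParameterError(f"hub nodes {bad} outside 0..{self.n_nodes - 1}")
        if self.hub_selectivity < 0 or self.noise_sd < 0 or self.scan_noise_sd < 0:
            raise ParameterError("selectivity and noise SDs must be >= 0")
        groups = tuple(
            g if isinstance(g, GroupSpec) else GroupSpec(*g) for g in self.groups
        )
        if not groups:
            raise ParameterError("at least one group is required")
        for g in groups:
            if g.n_participants < 1 or g.n_scans < 1:
                raise ParameterError(f"group {g.name!r} has empty design")
            if not 0 <= g.severity <= 1:
                raise ParameterError(f"group {g.name!r} severity outside [0, 1]")
        self.groups = groups
        self.hub_nodes = tuple(int(h) for h in self.hub_nodes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [asdict(g) for g in self.groups]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["groups"] = tuple(GroupSpec(**g) for g in d.get("groups", ()))
        d["hub_nodes"] = tuple(d.get("hub_nodes", DEFAULT_HUB_NODES))
        d["weight_law"] = tuple(d.get("weight_law", ("beta", 2.0, 2.0)))
        return cls(**d)


@dataclass
class ParticipantRecord:
    participant_id: str
    group: str
    scan_index: int
    network: WeightedNetwork


def _child_seed(*parts: int) -> int:
    # Documented counter scheme: one master seed, children spawned per
    # (group, participant, scan) through a SeedSequence; kept below 2**31.
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _draw_weights(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    name = law[0]
    if name == "beta":
        w = rng.beta(law[1], law[2], size=size)
    elif name == "uniform":
        lo, hi = law[1], law[2]
        w = rng.uniform(lo, hi, size=size)
    elif name == "constant":
        w = np.full(size, float(law[1]))
    else:
        raise ParameterError(f"unknown weight law {name!r}")
    # keep weights strictly positive so an edge never silently vanishes
    return np.clip(w, np.finfo(float).tiny, 1.0)


def generate_control_network(spec: CohortSpec, seed: int) -> WeightedNetwork:
    """One healthy-control connectome.

    Directed ring lattice (each node sends an edge to its ``k_ring`` nearest
    neighbours on each side), each outgoing edge rewired with probability
    ``beta_rewire`` to a uniformly random non-self, non-duplicate target;
    then, for every ordered pair touching a hub node, a missing edge is added
    with probability ``hub_boost``.  Every retained edge gets an independent
    weight from ``weight_law``.
    """
    rng = np.random.default_rng(seed)
    n, k = spec.n_nodes, spec.k_ring
    adj = np.zeros((n, n), dtype=bool)
    for offset in range(1, k + 1):
        for sign in (1, -1):
            src = np.arange(n)
            adj[src, (src + sign * offset) % n] = True

    # Watts-Strogatz rewiring of out-edges, scanned in deterministic order.
    if spec.beta_rewire > 0:
        for i in range(n):
            for j in np.flatnonzero(adj[i]):
                if rng.random() < spec.beta_rewire:
                    candidates = np.flatnonzero(~adj[i])
                    candidates = candidates[candidates != i]
                    if candidates.size == 0:
                        continue
                    adj[i, j] = False
                    adj[i, rng.choice(candidates)] = True

    if spec.hub_boost > 0 and spec.hub_nodes:
        hub = np.zeros(n, dtype=bool)
        hub[list(spec.hub_nodes)] = True
        touches_hub = hub[:, None] | hub[None, :]
        eligible = touches_hub & ~adj & ~np.eye(n, dtype=bool)
        add = eligible & (rng.random((n, n)) < spec.hub_boost)
        adj |= add

    np.fill_diagonal(adj, False)
    weights = np.zeros((n, n))
    idx = np.flatnonzero(adj)
    weights.flat[idx] = _draw_weights(rng, spec.weight_law, idx.size)
    return WeightedNetwork(weights, aal116_labels() if n == 116 else [])


def apply_injury(
    network: WeightedNetwork,
    s: float,
    gamma: float,
    hub_nodes,
    sigma: float,
    seed: int,
) -> WeightedNetwork:
    """Attenuate edge weights by severity ``s`` with hub selectivity ``gamma``.

    Zero entries stay zero; the diagonal stays zero; results are clamped
    to ``[0, 1]``.
    """
    if s < 0 or sigma < 0:
        raise ParameterError("severity and noise SD must be >= 0")
    if gamma < 0:
        raise ParameterError("hub selectivity must be >= 0")
    w = network.weights.copy()
    n = w.shape[0]
    hub = np.zeros(n, dtype=bool)
    if len(hub_nodes):
        hub[list(hub_nodes)] = True
    h = (hub[:, None] | hub[None, :]).astype(float)
    atten = s * (1.0 + gamma * h) / (1.0 + gamma)
    mask = w > 0
    out = np.zeros_like(w)
    out[mask] = w[mask] * (1.0 - atten[mask])
    if sigma > 0:
        rng = np.random.default_rng(seed)
        out[mask] += rng.normal(0.0, sigma, size=int(mask.sum()))
    np.clip(out, 0.0, 1.0, out=out)
    np.fill_diagonal(out, 0.0)
    return WeightedNetwork(out, list(network.node_labels))


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Deterministic cohort: one base network per participant, injured at the
    group severity once per scan (repeat scans re-draw only the noise term)."""
    records: list[ParticipantRecord] = []
    for g_idx, group in enumerate(spec.groups):
        for p_idx in range(group.n_participants):
            pid = f"{group.name.replace(' ', '')}-{p_idx + 1:02d}"
            base = generate_control_network(
                spec, _child_seed(spec.seed, g_idx, p_idx)
            )
            for scan in range(1, group.n_scans + 1):
                sigma = spec.scan_noise_sd if group.severity == 0 else spec.noise_sd
                net = apply_injury(
                    base,
                    group.severity,
                    spec.hub_selectivity,
                    spec.hub_nodes,
                    sigma,
                    _child_seed(spec.seed, g_idx, p_idx, scan),
                )
                records.append(ParticipantRecord(pid, group.name, scan, net))
    return records


def generate_probability_volumes(
    grid_shape: tuple[int, int, int],
    n_rois: int,
    fill_law: tuple = ("uniform", 0.0, 1.0),
    seed: int = 0,
):
    """Toy streamline-probability volumes plus a block parcellation.

    The grid is partitioned into ``n_rois`` disjoint slabs along the first
    axis (label volume: 0 = background is absent here, labels 1..n_rois).
    Each ROI gets a probability map over the full grid with values drawn
    from ``fill_law``.  Returns ``(label_volume, maps, roi_means)`` where
    ``roi_means[i, j]`` is the mean of map ``i`` over ROI ``j+1`` voxels —
    the oracle for connectivity-matrix construction.
    """
    shape = tuple(int(x) for x in grid_shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ParameterError("grid_shape must be a positive 3-D extent")
    if n_rois < 1:
        raise ParameterError("n_rois must be >= 1")
    if shape[0] < n_rois:
        raise ParameterError(
            f"grid with first extent {shape[0]} cannot host {n_rois} slabs"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    bounds = np.linspace(0, shape[0], n_rois + 1).astype(int)
    for r in range(n_rois):
        labels[bounds[r] : bounds[r + 1]] = r + 1

    nvox = int(np.prod(shape))
    maps = []
    for _ in range(n_rois):
        vals = _draw_weights(rng, fill_law, nvox).reshape(shape)
        maps.append(vals)

    roi_means = np.empty((n_rois, n_rois))
    for j in range(n_rois):
        vox = labels == j + 1
        for i in range(n_rois):
            roi_means[i, j] = maps[i][vox].mean()
    return labels, maps, roi_means
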