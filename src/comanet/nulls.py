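"""Degree-preserving null models and small-world threshold selection.

Random nulls come from pairwise edge swaps ((a->b, c->d) -> (a->d, c->b))
that preserve every node's in- and out-degree exactly.  Lattice nulls use
the same swap mechanics but accept a swap only when it does not increase
the total circular-index distance of the edge set, driving connections
toward the matrix diagonal (a degree-matched regular lattice).  A sweep
over the 0..1 threshold grid compares real networks against both nulls;
a network is small-world where its clustering sits between the random and
lattice references while its efficiency sits between the lattice and
random references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    clustering_coefficient_bd,
    clustering_coefficient_wd,
    global_efficiency,
)
from .network import BinaryNetwork, ParameterError, WeightedNetwork, matrix_of
from .threshold import binarize, threshold_absolute, threshold_proportional

THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)


class NoSmallWorldRegime(RuntimeError):
    """No threshold satisfied the small-world sandwich."""


def _swap_edges(
    matrix: np.ndarray,
    iter_per_edge: int,
    rng: np.random.Generator,
    lattice_cost: np.ndarray | None = None,
) -> np.ndarray:
    """Shared swap engine; ``lattice_cost`` switches on latticization."""
    n = matrix.shape[0]
    rows, cols = np.nonzero(matrix)
    n_edges = rows.size
    if n_edges < 2:
        return matrix.copy()
    out = matrix.copy()
    src = rows.tolist()
    dst = cols.tolist()
    present = set((int(a) * n + int(b)) for a, b in zip(src, dst))
    attempts = int(iter_per_edge) * n_edges
    pick = rng.integers(0, n_edges, size=2 * attempts)
    cost = lattice_cost
    for t in range(attempts):
        e1 = int(pick[2 * t])
        e2 = int(pick[2 * t + 1])
        if e1 == e2:
            continue
        a, b = src[e1], dst[e1]
        c, d = src[e2], dst[e2]
        # distinct endpoints, no self-loops after the swap
        if a == c or b == d or a == d or c == b:
            continue
        if (a * n + d) in present or (c * n + b) in present:
            continue
        if cost is not None and (
            cost[a][d] + cost[c][b] > cost[a][b] + cost[c][d]
        ):
            continue
        present.discard(a * n + b)
        present.discard(c * n + d)
        present.add(a * n + d)
        present.add(c * n + b)
        out[a, d] = out[a, b]
        out[c, b] = out[c, d]
        out[a, b] = 0
        out[c, d] = 0
        dst[e1] = d
        dst[e2] = b
    return out


def _circular_cost(n: int) -> np.ndarray:
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, n - d).astype(float)


def _rebuild(network, matrix):
    if isinstance(network, BinaryNetwork):
        return BinaryNetwork(matrix.astype(np.int8), list(network.node_labels))
    return WeightedNetwork(matrix, list(network.node_labels))


def rewire_degree_preserving(network, iter_per_edge: int = 1000, seed: int = 0):
    """Randomized null with the input's exact in/out-degree sequences.

    Approximately ``iter_per_edge`` swap attempts per edge; weights travel
    with their source edge.  Saturated graphs with no feasible swap are
    returned unchanged.
    """
    if iter_per_edge < 1:
        raise ParameterError("iter_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    return _rebuild(network, _swap_edges(matrix_of(network), iter_per_edge, rng))


def latticize(network, iter_per_edge: int = 1000, seed: int = 0):
    """Degree-matched lattice null: swaps accepted only when the total
    circular-index edge distance does not increase."""
    if iter_per_edge < 1:
        raise ParameterError("iter_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    m = matrix_of(network)
    cost = _circular_cost(m.shape[0]).tolist()
    return _rebuild(network, _swap_edges(m, iter_per_edge, rng, lattice_cost=cost))


def lattice_cost(network) -> float:
    """Total circular-index distance over the edge set."""
    m = matrix_of(network)
    return float((_circular_cost(m.shape[0]) * (m > 0)).sum())


@dataclass
class SweepResult:
    """Per-threshold cohort means/SDs for real networks and both nulls."""

    mode: str
    table: pd.DataFrame
    iter_per_edge: int = 0
    n_null: int = 1
    seed: int = 0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, mode: str = "absolute") -> "SweepResult":
        return cls(mode=mode, table=pd.read_csv(path, sep="\t"))


def _metrics_for(network, mode: str) -> tuple[float, float]:
    if mode == "absolute":
        c = clustering_coefficient_bd(network)
        e = global_efficiency(network, "binary")
    else:
        c = clustering_coefficient_wd(network)
        e = global_efficiency(network, "weighted")
    return float(c.mean()), e


def small_world_sweep(
    cohort: list,
    mode: str = "absolute",
    iter_per_edge: int = 1000,
    n_null: int = 1,
    seed: int = 0,
    thresholds=None,
) -> SweepResult:
    """Sweep the 0..1 threshold grid (0.01 steps) over a cohort of weighted
    networks, computing clustering and efficiency for the thresholded
    networks and their matched random and lattice nulls.

    Absolute mode binarizes and uses binary metrics; proportional mode keeps
    weights and uses the weighted-directed metrics.  When a thresholded
    matrix degenerates to at most one edge, the matrix itself stands in for
    its nulls (degenerate_flag is set for that threshold).
    """
    if not cohort:
        raise ParameterError("cohort must contain at least one network")
    if mode not in ("absolute", "proportional"):
        raise ParameterError(f"unknown threshold mode {mode!r}")
    grid = THRESHOLD_GRID if thresholds is None else np.asarray(thresholds, float)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(grid) * len(cohort) * 2 * max(n_null, 1))
    rows = []
    s_idx = 0
    for tau in grid:
        real_c, real_e, rand_c, rand_e, latt_c, latt_e = [], [], [], [], [], []
        degenerate = False
        for net in cohort:
            if mode == "absolute":
                thr = binarize(threshold_absolute(net, float(tau)))
            else:
                if tau == 0:  # density target 0: empty network, degenerate
                    thr = WeightedNetwork(
                        np.zeros_like(net.weights), list(net.node_labels)
                    )
                else:
                    thr = threshold_proportional(net, float(tau))
            c, e = _metrics_for(thr, mode)
            real_c.append(c)
            real_e.append(e)
            m = matrix_of(thr)
            if np.count_nonzero(m) <= 1:
                # single-element degeneracy: the matrix is its own null
                degenerate = True
                rand_c.append(c), rand_e.append(e)
                latt_c.append(c), latt_e.append(e)
                s_idx += 2 * max(n_null, 1)
                continue
            rc, re_, lc, le = [], [], [], []
            for _ in range(max(n_null, 1)):
                rnd = rewire_degree_preserving(
                    thr, iter_per_edge, int(child_seeds[s_idx] % 2**31)
                )
                s_idx += 1
                lat = latticize(
                    thr, iter_per_edge, int(child_seeds[s_idx] % 2**31)
                )
                s_idx += 1
                cc, ee = _metrics_for(rnd, mode)
                rc.append(cc), re_.append(ee)
                cc, ee = _metrics_for(lat, mode)
                lc.append(cc), le.append(ee)
            rand_c.append(np.mean(rc)), rand_e.append(np.mean(re_))
            latt_c.append(np.mean(lc)), latt_e.append(np.mean(le))
        rows.append(
            {
                "mode": mode,
                "threshold": float(tau),
                "real_clustering_mean": np.mean(real_c),
                "real_clustering_sd": np.std(real_c, ddof=0),
                "real_efficiency_mean": np.mean(real_e),
                "real_efficiency_sd": np.std(real_e, ddof=0),
                "rand_clustering_mean": np.mean(rand_c),
                "rand_efficiency_mean": np.mean(rand_e),
                "latt_clustering_mean": np.mean(latt_c),
                "latt_efficiency_mean": np.mean(latt_e),
                "degenerate": degenerate,
            }
        )
    return SweepResult(
        mode=mode,
        table=pd.DataFrame(rows),
        iter_per_edge=iter_per_edge,
        n_null=n_null,
        seed=seed,
    )


def sandwich_table(sweep: SweepResult) -> pd.DataFrame:
    """Per-threshold evaluation of the small-world sandwich:
    rand_C < real_C < latt_C and latt_E < real_E < rand_E."""
    t = sweep.table
    ok_c = (t["rand_clustering_mean"] < t["real_clustering_mean"]) & (
        t["real_clustering_mean"] < t["latt_clustering_mean"]
    )
    ok_e = (t["latt_efficiency_mean"] < t["real_efficiency_mean"]) & (
        t["real_efficiency_mean"] < t["rand_efficiency_mean"]
    )
    out = t[["threshold"]].copy()
    out["clustering_between"] = ok_c
    out["efficiency_between"] = ok_e
    out["small_world"] = ok_c & ok_e
    return out


def select_threshold(
    sweep: SweepResult, rule: str = "sandwich-smallest", divergence_frac: float = 0.1
) -> tuple[float, pd.DataFrame]:
    """Pick the analysis threshold from a control-cohort sweep.

    ``sandwich-smallest`` (default) returns the smallest grid threshold at
    which mean real clustering lies strictly between the random and lattice
    means and mean real efficiency strictly between the lattice and random
    means.  ``divergence`` returns the smallest threshold at which the
    real-vs-lattice clustering gap exceeds ``divergence_frac`` of the
    lattice value.
    """
    crit = sandwich_table(sweep)
    if rule == "sandwich-smallest":
        hits = crit.loc[crit["small_world"], "threshold"]
        if hits.empty:
            raise NoSmallWorldRegime(
                "no threshold yields the small-world sandwich"
            )
        return float(hits.iloc[0]), crit
    if rule == "divergence":
        t = sweep.table
        latt = t["latt_clustering_mean"]
        gap = (latt - t["real_clustering_mean"]).abs()
        ok = (latt > 0) & (gap > divergence_frac * latt)
        hits = t.loc[ok, "threshold"]
        if hits.empty:
            raise NoSmallWorldRegime("no divergence threshold found")
        return float(hits.iloc[0]), crit
    raise ParameterError(f"unknown selection rule {rule!r}")
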