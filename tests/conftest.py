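"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (triple loops, Floyd–Warshall)
so they share no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from comanet import BinaryNetwork, CohortSpec, WeightedNetwork


@pytest.fixture
def small_spec() -> CohortSpec:
    """Tiny cohort for fast pipeline-level tests."""
    return CohortSpec(
        n_nodes=24,
        k_ring=3,
        groups=(
            ("Control", 4, 3, 0.0),
            ("EMCS", 3, 1, 0.15),
            ("AR'", 3, 1, 0.35),
            ("No AR", 3, 1, 0.55),
        ),
        seed=7,
    )


def clustering_oracle(a: np.ndarray) -> np.ndarray:
    """Directed total clustering by explicit enumeration of ordered triples."""
    a = (np.asarray(a) > 0).astype(int)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                t += (a[i, j] + a[j, i]) * (a[i, h] + a[h, i]) * (a[j, h] + a[h, j])
        t *= 0.5
        k = int(a[i].sum() + a[:, i].sum())
        recip = int((a[i] * a[:, i]).sum())
        denom = k * (k - 1) - 2 * recip
        c[i] = t / denom if denom > 0 else 0.0
    return c


def efficiency_oracle(m: np.ndarray, weighted: bool = False) -> float:
    """Global efficiency via Floyd–Warshall on hop or inverse-weight lengths."""
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and m[i, j] > 0:
                d[i, j] = 1.0 / m[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def all_digraphs(n: int):
    """Every labelled simple digraph on n nodes (off-diagonal bit patterns)."""
    slots = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in itertools.product((0, 1), repeat=len(slots)):
        a = np.zeros((n, n), dtype=int)
        for (i, j), b in zip(slots, bits):
            a[i, j] = b
        yield a


def random_weighted(n: int, density: float, rng: np.random.Generator) -> WeightedNetwork:
    w = rng.random((n, n))
    w[rng.random((n, n)) > density] = 0.0
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w)


def random_binary(n: int, density: float, rng: np.random.Generator) -> BinaryNetwork:
    a = (rng.random((n, n)) < density).astype(int)
    np.fill_diagonal(a, 0)
    return BinaryNetwork(a)
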