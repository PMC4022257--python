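"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from seapattern.mi_network import AssociationNetwork


def two_cliques_network(clique_size: int = 4) -> AssociationNetwork:
    """Two disconnected equal cliques with unit weights."""
    n = 2 * clique_size
    A = np.zeros((n, n))
    for block in (range(clique_size), range(clique_size, n)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    return AssociationNetwork(
        nodes=[f"n{i}" for i in range(n)], types=["OTU"] * n, A=A
    )


def random_unit_network(n: int, p: float, rng: np.random.Generator) -> AssociationNetwork:
    """Erdős–Rényi-style unit-weight network with at least one edge."""
    A = np.triu((rng.random((n, n)) < p).astype(float), k=1)
    A = A + A.T
    if A.sum() == 0:
        A[0, 1] = A[1, 0] = 1.0
    return AssociationNetwork(
        nodes=[f"n{i}" for i in range(n)], types=["OTU"] * n, A=A
    )


def set_partitions(items: list):
    """Yield every partition of ``items`` into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def newman_modularity_oracle(A: np.ndarray, community_of: dict) -> float:
    """Brute-force Newman modularity: explicit double sum over node pairs."""
    two_i = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if community_of[i] == community_of[j]:
                q += A[i, j] - k[i] * k[j] / two_i
    return q / two_i


def binned_mi_oracle(x: np.ndarray, y: np.ndarray, M: int) -> tuple[float, float, float]:
    """Brute-force plug-in entropies/MI from an explicit contingency table.

    Builds the M x M table by interval-membership tests, sums the
    entropies term by term, and returns (H(X), H(Y), I(X, Y)).  Entirely
    independent of the bincount/searchsorted implementation it checks.
    """
    S = len(x)

    def edges(v):
        lo, hi = min(v), max(v)
        e = [lo + (hi - lo) * t / M for t in range(M + 1)]
        e[0], e[-1] = lo, hi  # endpoints exact despite rounding
        return e

    def which_bin(value, e):
        for b in range(M):
            left, right = e[b], e[b + 1]
            if (value >= left and value < right) or (b == M - 1 and value <= right):
                return b
        raise AssertionError("value outside partition")

    ex, ey = edges(x), edges(y)
    joint = [[0] * M for _ in range(M)]
    for s in range(S):
        joint[which_bin(x[s], ex)][which_bin(y[s], ey)] += 1

    def H(counts):
        total = 0.0
        for c in counts:
            if c > 0:
                p = c / S
                total -= p * np.log(p)
        return total

    hx = H([sum(joint[b]) for b in range(M)])
    hy = H([sum(joint[b][g] for b in range(M)) for g in range(M)])
    hxy = H([joint[b][g] for b in range(M) for g in range(M)])
    return hx, hy, hx + hy - hxy


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
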