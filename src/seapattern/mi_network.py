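"""Binned mutual information, permutation significance, and network assembly.

Association strength between two variables (OTU or environmental factor)
is measured by plug-in mutual information over equal-width bins:

    I(X, Y) = H(X) + H(Y) - H(X, Y)

with entropies computed from empirical bin frequencies.  MI captures
nonlinear dependence, is symmetric, and is invariant to monotone affine
rescaling of either variable under equal-width binning (the bins move with
the data), so the upstream normalization choice cannot change it.

Edge significance comes from a permutation test: the second variable's
samples are shuffled, MI is recomputed, and the p-value is the add-one
rank of the observed MI among the permuted values.  The network keeps an
edge when its p-value clears a type-dependent threshold (stricter for
pairs involving an OTU than for environment-environment pairs).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .abundance import VAR_ENV, AbundanceMatrix

__all__ = [
    "BinPartition",
    "MIResult",
    "AssociationNetwork",
    "make_bins",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "permutation_pvalue",
    "build_network",
]


@dataclass(frozen=True)
class BinPartition:
    """Equal-width partition of a variable's observed range into M bins.

    ``edges`` are the M+1 ascending bin boundaries; every bin is
    half-open on the right except the last, which is closed, so the bins
    are disjoint and their union is exactly the observed range.
    """

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-D array of >= 2 values")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly ascending")
        object.__setattr__(self, "edges", edges)

    @property
    def M(self) -> int:
        return self.edges.size - 1

    def assign(self, x: np.ndarray) -> np.ndarray:
        """Bin index for every value of ``x`` (values clipped to the range)."""
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.edges, x, side="right") - 1
        return np.clip(idx, 0, self.M - 1)


@dataclass(frozen=True)
class MIResult:
    """Observed MI and its permutation p-value."""

    I: float
    p_value: float
    n_permutations: int


def make_bins(x: np.ndarray, M: int) -> BinPartition:
    """M equal-width bins spanning ``[min(x), max(x)]``."""
    x = np.asarray(x, dtype=float)
    if M < 1:
        raise ValueError("M must be >= 1")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("cannot bin a constant vector")
    return BinPartition(edges=np.linspace(lo, hi, M + 1))


def _entropy_from_counts(counts: np.ndarray, S: int) -> float:
    p = counts[counts > 0] / S
    return float(-(p * np.log(p)).sum())


def entropy(x: np.ndarray, bins: BinPartition) -> float:
    """Plug-in entropy of ``x`` under ``bins``, in nats (0·log 0 := 0)."""
    x = np.asarray(x, dtype=float)
    counts = np.bincount(bins.assign(x), minlength=bins.M)
    return _entropy_from_counts(counts, x.size)


def joint_entropy(
    x: np.ndarray, y: np.ndarray, bins_x: BinPartition, bins_y: BinPartition
) -> float:
    """Plug-in joint entropy of ``(x, y)`` under the product partition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    xi, yi = bins_x.assign(x), bins_y.assign(y)
    counts = np.bincount(xi * bins_y.M + yi, minlength=bins_x.M * bins_y.M)
    return _entropy_from_counts(counts, x.size)


def mutual_information(x: np.ndarray, y: np.ndarray, M: int) -> float:
    """Plug-in mutual information with M equal-width bins per variable.

    Always nonnegative (clamped at 0 against rounding) and symmetric.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    bx, by = make_bins(x, M), make_bins(y, M)
    i = entropy(x, bx) + entropy(y, by) - joint_entropy(x, y, bx, by)
    return max(i, 0.0)


def _mi_from_indices(
    xi: np.ndarray, yi: np.ndarray, M: int, S: int, hx: float, hy: float
) -> float:
    joint = np.bincount(xi * M + yi, minlength=M * M)
    return hx + hy - _entropy_from_counts(joint, S)


# Permuted MI values within this of the observed value count as ties (>=);
# distinct contingency tables frequently share an MI value exactly, and
# floating-point noise must not break those ties.
_TIE_TOL = 1e-12


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    M: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MIResult:
    """Permutation test of independence based on binned MI.

    ``y`` is shuffled ``n_perm`` times; the p-value is
    ``(1 + #{I_perm >= I_obs}) / (1 + n_perm)`` (add-one rank, so p is
    never 0 and never below ``1/(n_perm+1)``).  Only the joint entropy
    changes under permutation, so the marginal entropies are computed once.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    S = x.size
    bx, by = make_bins(x, M), make_bins(y, M)
    xi, yi = bx.assign(x), by.assign(y)
    hx = _entropy_from_counts(np.bincount(xi, minlength=M), S)
    hy = _entropy_from_counts(np.bincount(yi, minlength=M), S)
    i_obs = _mi_from_indices(xi, yi, M, S, hx, hy)
    ge = 0
    for _ in range(n_perm):
        yp = rng.permutation(yi)
        if _mi_from_indices(xi, yp, M, S, hx, hy) >= i_obs - _TIE_TOL:
            ge += 1
    return MIResult(
        I=max(i_obs, 0.0),
        p_value=(1 + ge) / (1 + n_perm),
        n_permutations=n_perm,
    )


@dataclass
class AssociationNetwork:
    """Weighted undirected association network over typed nodes.

    ``A`` is the symmetric nonnegative adjacency matrix; a strictly
    positive entry means the edge was retained and its weight is the
    observed MI.  ``pvalues`` mirrors ``A`` with the test p-values
    (NaN where no edge).
    """

    nodes: list[str]
    types: list[str]
    A: np.ndarray
    pvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.nodes)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape mismatch with node list")
        if len(self.types) != n:
            raise ValueError("types length mismatch with node list")
        if not np.allclose(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if (self.A < 0).any():
            raise ValueError("adjacency must be nonnegative")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if self.pvalues is None:
            self.pvalues = np.where(self.A > 0, np.nan, np.nan)
        else:
            self.pvalues = np.asarray(self.pvalues, dtype=float)
            if self.pvalues.shape != (n, n):
                raise ValueError("pvalues shape mismatch")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def l(self) -> int:  # noqa: E743 - the conventional symbol for edge count
        return int(np.count_nonzero(np.triu(self.A, k=1) > 0))

    def isolated_nodes(self) -> list[str]:
        deg = (self.A > 0).sum(axis=1)
        return [self.nodes[i] for i in np.flatnonzero(deg == 0)]

    def edges(self) -> list[tuple[str, str, float, float]]:
        """Retained edges as (node_a, node_b, weight, p_value), a < b."""
        out = []
        iu, ju = np.nonzero(np.triu(self.A, k=1) > 0)
        for i, j in zip(iu, ju):
            a, b = self.nodes[i], self.nodes[j]
            if b < a:
                a, b = b, a
            out.append((a, b, float(self.A[i, j]), float(self.pvalues[i, j])))
        out.sort(key=lambda e: (e[0], e[1]))
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for name, t in zip(self.nodes, self.types):
            g.add_node(name, type=t)
        for a, b, w, p in self.edges():
            g.add_edge(a, b, weight=w, p_value=p)
        return g


def _pair_rng(seed: int, label_a: str, label_b: str) -> np.random.Generator:
    """Deterministic per-pair RNG, invariant to variable ordering."""
    a, b = sorted((label_a, label_b))
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(a.encode()), zlib.crc32(b.encode())]
    )


def default_bin_count(n_samples: int) -> int:
    """Default bin count: ceil(sqrt(S)), a standard plug-in rule."""
    return max(1, math.ceil(math.sqrt(n_samples)))


def build_network(
    matrix: AbundanceMatrix,
    M: int | None = None,
    alpha_otu: float = 0.01,
    alpha_env: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    bh_correct: bool = False,
) -> AssociationNetwork:
    """Test all variable pairs and keep the significant MI edges.

    An edge is retained when its permutation p-value is at or below
    ``alpha_otu`` (default 0.01) if at least one endpoint is an OTU, or
    ``alpha_env`` (default 0.05) if both endpoints are environmental
    factors.  Retained edge weight is the observed MI.  Isolated nodes stay
    in the node set (see :meth:`AssociationNetwork.isolated_nodes`).

    ``bh_correct=True`` applies a Benjamini–Hochberg adjustment across all
    tested pairs before thresholding; off by default, matching the raw
    per-edge thresholds of the protocol this implements.

    Deterministic for a fixed ``seed`` and invariant to row order (each
    pair derives its own RNG from the pair's labels).
    """
    if matrix.n_variables < 2:
        raise ValueError("need at least 2 variables")
    if M is None:
        M = default_bin_count(matrix.n_samples)
    values = matrix.values
    for i in range(matrix.n_variables):
        if np.unique(values[i]).size < 2:
            raise ValueError(
                f"constant variable {matrix.labels[i]!r}: filter before "
                "building the network"
            )
    nv = matrix.n_variables
    A = np.zeros((nv, nv))
    P = np.full((nv, nv), np.nan)
    results = []
    for i in range(nv):
        for j in range(i + 1, nv):
            rng = _pair_rng(seed, matrix.labels[i], matrix.labels[j])
            # order the pair by label so the permuted variable (the second)
            # does not depend on row order
            if matrix.labels[j] < matrix.labels[i]:
                x, y = values[j], values[i]
            else:
                x, y = values[i], values[j]
            res = permutation_pvalue(x, y, M, n_perm, rng)
            both_env = (
                matrix.var_types[i] == VAR_ENV and matrix.var_types[j] == VAR_ENV
            )
            alpha = alpha_env if both_env else alpha_otu
            results.append((i, j, res, alpha))
    if bh_correct:
        m = len(results)
        order = sorted(range(m), key=lambda k: results[k][2].p_value)
        adj = [0.0] * m
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            k = order[rank_pos]
            q = results[k][2].p_value * m / (rank_pos + 1)
            prev = min(prev, q)
            adj[k] = prev
        pvals = adj
    else:
        pvals = [res.p_value for _, _, res, _ in results]
    for (i, j, res, alpha), p in zip(results, pvals):
        P[i, j] = P[j, i] = p
        if p <= alpha:
            A[i, j] = A[j, i] = res.I
    return AssociationNetwork(
        nodes=list(matrix.labels),
        types=list(matrix.var_types),
        A=A,
        pvalues=P,
    )
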