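"""Symmetric NMF community detection with fuzzy-modularity model selection.

A weighted undirected network with adjacency ``A`` is summarized by a
feature matrix ``O`` (by default ``A`` itself, which already encodes
node–node similarity).  Community structure is sought as a symmetric
nonnegative factorization

    min_{W >= 0}  F_G(O, W) = 1/2 || O - W^T W ||_F^2

where ``W`` is an r × n clique–node similarity matrix: ``W[k, i]`` is the
closeness of node ``i`` to clique ``k``.  Column-normalizing ``W`` yields a
fuzzy membership matrix ``U`` whose columns sum to one; the hard label of a
node is its strongest clique.  The number of communities ``r`` is chosen by
scanning a range and keeping the factorization whose memberships maximize
the fuzzy modularity

    Q_f = 1/(2I) * sum_ij [A_ij - k_i k_j / (2I)] * s_ij,
    s_ij = sum_k U[k, i] U[k, j]

with weighted degrees ``k_i`` and total edge weight ``I``.  For a one-hot
``U`` (every node fully in one community) ``s_ij`` is the community
indicator and ``Q_f`` reduces to Newman modularity.

The factorization is solved by the damped multiplicative update

    W <- W ∘ ( 1/2 + 1/2 * (W O) / (W W^T W) )

whose fixed points are exactly those of the undamped rule
``W <- W ∘ (W O)/(W W^T W)`` (both are stationary iff ``W O = W W^T W`` on
the support of W); the 1/2 damping is what makes the objective provably
non-increasing at every step for symmetric factorizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .mi_network import AssociationNetwork

__all__ = [
    "SNMFResult",
    "CommunityModel",
    "feature_matrix",
    "snmf_factorize",
    "membership",
    "hard_assign",
    "fuzzy_modularity",
    "detect_communities",
]

_EPS = 2.0**-52


@dataclass
class SNMFResult:
    """Outcome of a single symmetric-NMF run."""

    W: np.ndarray
    F_G: float
    n_iter: int
    F_history: list[float] = field(default_factory=list)


@dataclass
class CommunityModel:
    """Selected community structure of a network.

    ``labels`` are 0-based hard assignments (argmax of each U column,
    ties to the smallest clique index).  ``q_by_r`` records the fuzzy
    modularity reached at every candidate r, for inspection.
    """

    r: int
    W: np.ndarray
    U: np.ndarray
    labels: np.ndarray
    Q_f: float
    F_G: float
    n_iter: int
    q_by_r: dict[int, float] = field(default_factory=dict)


def feature_matrix(
    net: AssociationNetwork, mode: str = "adjacency"
) -> np.ndarray:
    """Feature matrix O of the network.

    ``adjacency`` (default) uses A itself — the MI weights already measure
    node–node similarity.  ``row-normalized`` uses the symmetrically
    normalized adjacency ``D^{-1/2} A D^{-1/2}``, which equalizes the
    influence of high-degree hubs; it requires every node to have positive
    weighted degree.
    """
    if net.n == 0:
        raise ValueError("empty network")
    A = net.A
    if mode == "adjacency":
        return A.copy()
    if mode == "row-normalized":
        deg = A.sum(axis=1)
        if (deg == 0).any():
            iso = [net.nodes[i] for i in np.flatnonzero(deg == 0)]
            raise ValueError(
                f"isolated node(s) {iso} have zero degree; use "
                "mode='adjacency' or remove them first"
            )
        d = 1.0 / np.sqrt(deg)
        O = A * d[:, None] * d[None, :]
        return (O + O.T) / 2.0
    raise ValueError(f"unknown mode {mode!r}")


def snmf_factorize(
    O: np.ndarray,
    r: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
) -> SNMFResult:
    """Factorize a symmetric nonnegative matrix as O ≈ WᵀW, W >= 0.

    W is initialized elementwise uniform on (0, 1] scaled by
    ``sqrt(mean(O)/r)`` so that WᵀW starts on O's scale, then refined by
    the damped multiplicative update until the relative decrease of
    ``F_G = 1/2 ||O - WᵀW||²_F`` falls below ``tol`` or ``max_iter`` is
    reached.  The update preserves nonnegativity and never increases F_G.
    """
    O = np.asarray(O, dtype=float)
    if O.ndim != 2 or O.shape[0] != O.shape[1]:
        raise ValueError("O must be square")
    n = O.shape[0]
    if not (1 <= r <= n):
        raise ValueError(f"r must be in [1, {n}]")
    if not np.allclose(O, O.T):
        raise ValueError("O must be symmetric")
    if (O < 0).any():
        raise ValueError("O must be nonnegative")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scale = np.sqrt(max(O.mean(), _EPS) / r)
    W = (1.0 - rng.random((r, n))) * scale  # uniform on (0, 1], scaled

    def objective(w: np.ndarray) -> float:
        d = O - w.T @ w
        return 0.5 * float((d * d).sum())

    F = objective(W)
    history = [F]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        WO = W @ O
        WWtW = W @ W.T @ W
        W = W * (0.5 + 0.5 * WO / (WWtW + _EPS))
        F_new = objective(W)
        history.append(F_new)
        if F > 0 and (F - F_new) / F < tol:
            F = F_new
            break
        F = F_new
    return SNMFResult(W=W, F_G=F, n_iter=n_iter, F_history=history)


def membership(W: np.ndarray) -> np.ndarray:
    """Column-normalize W into the fuzzy membership matrix U.

    Every column of U sums to 1.  An all-zero column (a node no clique
    claims) is mapped to the uniform membership 1/r with a warning.
    """
    W = np.asarray(W, dtype=float)
    if (W < 0).any():
        raise ValueError("W must be nonnegative")
    sums = W.sum(axis=0)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} node(s) have all-zero membership; "
            "assigned uniform 1/r",
            stacklevel=2,
        )
    U = np.where(zero[None, :], 1.0 / W.shape[0], W / np.where(zero, 1.0, sums))
    return U


def hard_assign(U: np.ndarray) -> np.ndarray:
    """Hard labels: argmax over cliques per column, ties to the lowest index."""
    U = np.asarray(U, dtype=float)
    return U.argmax(axis=0)


def fuzzy_modularity(
    net: AssociationNetwork, U: np.ndarray, weighted: bool = True
) -> float:
    """Fuzzy modularity Q_f of memberships U on the network.

    Uses weighted degrees and total edge weight by default; with
    ``weighted=False`` the adjacency is binarized first so that degrees and
    edge totals are plain counts.  For a one-hot U this is exactly Newman
    modularity of the hard partition.
    """
    U = np.asarray(U, dtype=float)
    A = net.A if weighted else (net.A > 0).astype(float)
    if U.shape[1] != net.n:
        raise ValueError("U columns must match the node count")
    two_i = A.sum()
    if two_i == 0:
        raise ValueError("network has no edges")
    k = A.sum(axis=1)
    S = U.T @ U  # s_ij = sum_k U_ki U_kj
    q = (A * S).sum() - (k @ S @ k) / two_i
    return float(q / two_i)


def detect_communities(
    net: AssociationNetwork,
    r_min: int = 2,
    r_max: int | None = None,
    restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    mode: str = "adjacency",
) -> CommunityModel:
    """Scan community counts and keep the model with the highest Q_f.

    For each r in ``[r_min, r_max]`` the factorization is run ``restarts``
    times from different seeded initializations; the restart with the
    lowest F_G is kept and its fuzzy modularity computed.  The model with
    the highest Q_f wins (ties go to the smaller r).  Fully deterministic
    for a fixed ``seed``.
    """
    if net.n == 0:
        raise ValueError("empty network")
    if r_max is None:
        r_max = min(net.n, 20)
    if r_min > r_max:
        raise ValueError("r_min must be <= r_max")
    if not (1 <= r_min and r_max <= net.n):
        raise ValueError(f"r range must lie within [1, {net.n}]")
    O = feature_matrix(net, mode=mode)
    best: CommunityModel | None = None
    q_by_r: dict[int, float] = {}
    for r in range(r_min, r_max + 1):
        best_run: SNMFResult | None = None
        for restart in range(restarts):
            rng = np.random.default_rng(
                [seed & 0x7FFFFFFF, r, restart]
            )
            run = snmf_factorize(O, r, max_iter=max_iter, tol=tol, seed=rng)
            if best_run is None or run.F_G < best_run.F_G:
                best_run = run
        assert best_run is not None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            U = membership(best_run.W)
        q = fuzzy_modularity(net, U)
        q_by_r[r] = q
        if best is None or q > best.Q_f:
            best = CommunityModel(
                r=r,
                W=best_run.W,
                U=U,
                labels=hard_assign(U),
                Q_f=q,
                F_G=best_run.F_G,
                n_iter=best_run.n_iter,
            )
    assert best is not None
    best.q_by_r = q_by_r
    return best
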