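"""Greedy OTU clustering with homopolymer-aware neighbor seeds (NbHClust).

Pyrosequencing platforms mis-call the length of homopolymer runs far more
often than they substitute bases, which inflates the number of operational
taxonomic units (OTUs) produced by conventional greedy clustering: a read
whose only defect is a run-length slip can fall below the identity threshold
against its true seed and found a spurious cluster.  NbHClust counters this
by comparing each incoming read not only against a cluster's seed but
against the seed's *neighbor seeds* — every variant of the seed obtained by
stretching or shrinking a single homopolymer run — and by dissolving
undersized clusters into their nearest large cluster afterwards.

The module exposes the clustering primitives individually
(:func:`dereplicate`, :func:`identity`, :func:`neighbor_seeds`) and the full
algorithm (:func:`cluster`).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from Bio import Align

__all__ = [
    "SequenceRead",
    "OTUClustering",
    "dereplicate",
    "identity",
    "neighbor_seeds",
    "homopolymer_runs",
    "cluster",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRead:
    """A single amplicon read.

    Parameters
    ----------
    id : str
        Unique read identifier.
    bases : str
        Uppercase DNA sequence over the alphabet ``{A, C, G, T, N}``.
    sample_id : str
        Identifier of the sample the read came from (empty if unassigned).
    copies : int
        Dereplication multiplicity; ``>= 1``.
    """

    id: str
    bases: str
    sample_id: str = ""
    copies: int = 1

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.bases) - _VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)!r}; "
                "expected A/C/G/T/N (uppercase)"
            )
        if self.copies < 1:
            raise ValueError(f"read {self.id!r}: copies must be >= 1")


@dataclass
class OTUClustering:
    """Seed-labelled partition of a read set into OTUs.

    ``clusters`` is a list of ``(seed_read_id, member_read_ids)`` pairs in
    founding order; every input read id appears in exactly one member list.
    """

    clusters: list[tuple[str, list[str]]]
    threshold: float
    min_cluster_size: int = 1

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> dict[str, int]:
        """Map every read id to its 0-based cluster index."""
        out: dict[str, int] = {}
        for k, (_, members) in enumerate(self.clusters):
            for rid in members:
                out[rid] = k
        return out

    def sizes(self) -> list[int]:
        return [len(members) for _, members in self.clusters]


# ---------------------------------------------------------------------------
# dereplication


def dereplicate(reads: list[SequenceRead]) -> list[SequenceRead]:
    """Collapse identical base strings, summing multiplicities.

    The representative of each distinct sequence is the member with the
    lexicographically smallest id.  Output is sorted by copies descending,
    ties broken by representative id ascending, so the result is independent
    of input order.
    """
    groups: dict[str, list[SequenceRead]] = {}
    for r in reads:
        groups.setdefault(r.bases, []).append(r)
    out = []
    for bases, members in groups.items():
        rep = min(members, key=lambda r: r.id)
        out.append(
            SequenceRead(
                id=rep.id,
                bases=bases,
                sample_id=rep.sample_id,
                copies=sum(m.copies for m in members),
            )
        )
    out.sort(key=lambda r: (-r.copies, r.id))
    return out


def _dereplicate_with_members(
    reads: list[SequenceRead],
) -> list[tuple[SequenceRead, list[str]]]:
    """Like :func:`dereplicate` but keeps the original member read ids."""
    groups: dict[str, list[SequenceRead]] = {}
    for r in reads:
        groups.setdefault(r.bases, []).append(r)
    derep = []
    for bases, members in groups.items():
        rep = min(members, key=lambda r: r.id)
        merged = SequenceRead(
            id=rep.id,
            bases=bases,
            sample_id=rep.sample_id,
            copies=sum(m.copies for m in members),
        )
        derep.append((merged, sorted(m.id for m in members)))
    derep.sort(key=lambda t: (-t[0].copies, t[0].id))
    return derep


# ---------------------------------------------------------------------------
# pairwise identity

# Global alignment with free end gaps: the standard choice for amplicon
# reads that may be truncated at either end.  Identity is matches divided by
# alignment columns (end-gap columns included).
_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2
_aligner.end_gap_score = 0


def identity(a: str, b: str) -> float:
    """Pairwise identity of two DNA strings in ``[0, 1]``.

    Computed from the optimal global alignment with free end gaps
    (match +1, mismatch −1, gap −2) as matches / alignment columns.
    Arguments are ordered canonically before aligning: co-optimal
    alignments can differ in their match/column counts, so picking the
    aligner's first optimum for (a, b) and (b, a) independently would
    break symmetry.
    """
    if not a or not b:
        raise ValueError("identity() requires nonempty sequences")
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    aln = _aligner.align(a, b)[0]
    return aln.counts().identities / aln.length


def _identity_upper_bound(a: str, b: str, k: int = 8) -> float:
    """A provable upper bound on :func:`identity`, cheap to compute.

    Combines two facts about any global alignment of ``a`` and ``b``:
    matches <= min(|a|,|b|) and columns >= max(|a|,|b|); and the q-gram
    lemma — an edit script with ``e`` operations destroys at most ``e * k``
    of the shorter string's k-mer occurrences in the longer, so a low
    shared-k-mer count forces errors in every alignment.
    """
    la, lb = len(a), len(b)
    bound = min(la, lb) / max(la, lb)
    short, long_ = (a, b) if la <= lb else (b, a)
    ls = len(short)
    if ls >= k:
        long_kmers = {long_[i : i + k] for i in range(len(long_) - k + 1)}
        shared = sum(
            1 for i in range(ls - k + 1) if short[i : i + k] in long_kmers
        )
        e_min = max(0, -(-((ls - k + 1) - shared) // k))  # ceil division
        if e_min > 0:
            # columns <= |a| + |b|, so identity <= 1 - e_min / (la + lb)
            bound = min(bound, 1.0 - e_min / (la + lb))
    return bound


# ---------------------------------------------------------------------------
# neighbor seeds

_RUN_RE = re.compile(r"(.)\1*")


def homopolymer_runs(seq: str) -> list[tuple[str, int]]:
    """Decompose ``seq`` into maximal (base, run_length) homopolymer runs."""
    return [(m.group(1), len(m.group(0))) for m in _RUN_RE.finditer(seq)]


def neighbor_seeds(seed: str, max_run_delta: int = 1) -> set[str]:
    """All sequences reachable from ``seed`` by resizing one homopolymer run.

    Returns the set containing ``seed`` itself plus every sequence obtained
    by changing the length of exactly one run by up to ``±max_run_delta``
    (run lengths never drop below 1).  Because adjacent runs use different
    bases, shrinking a run can never merge two runs, so each edit stays a
    single-run edit.
    """
    if not seed:
        raise ValueError("neighbor_seeds() requires a nonempty seed")
    if max_run_delta < 1:
        raise ValueError("max_run_delta must be >= 1")
    runs = homopolymer_runs(seed)
    out = {seed}
    for i, (base, length) in enumerate(runs):
        for d in itertools.chain(
            range(-min(max_run_delta, length - 1), 0),
            range(1, max_run_delta + 1),
        ):
            new = runs.copy()
            new[i] = (base, length + d)
            out.add("".join(b * n for b, n in new))
    return out


# ---------------------------------------------------------------------------
# the clustering algorithm


@dataclass
class _Cluster:
    seed: SequenceRead
    neighbors: list[str]  # sorted neighbor-seed sequences, seed included
    members: list[int] = field(default_factory=list)  # indices into derep


def _best_neighbor_identity(
    query: str, cl: _Cluster, threshold: float, prefilter: bool
) -> bool:
    """True if the query reaches ``threshold`` against any neighbor seed."""
    # The seed itself is in the neighbor list; try it first since it is the
    # most likely match.
    if identity(query, cl.seed.bases) >= threshold:
        return True
    for nb in cl.neighbors:
        if nb == cl.seed.bases:
            continue
        if prefilter and _identity_upper_bound(query, nb) < threshold:
            continue
        if identity(query, nb) >= threshold:
            return True
    return False


def cluster(
    reads: list[SequenceRead],
    threshold: float = 0.97,
    max_run_delta: int = 1,
    min_cluster_size: int = 2,
    prefilter: bool = True,
) -> OTUClustering:
    """Cluster reads into OTUs with the neighbor-seed greedy heuristic.

    The reads are dereplicated and visited in abundance order (copies
    descending, id ascending).  Each read joins the first existing cluster
    whose neighbor-seed set contains a sequence at identity ``>= threshold``
    to the read; otherwise it founds a new cluster and its neighbor-seed set
    is generated.  Afterwards every cluster smaller than
    ``min_cluster_size`` (counting original, pre-dereplication reads) is
    dissolved and its members are reassigned to the surviving cluster whose
    seed is most similar (ties: larger cluster, then lower cluster index).

    Parameters
    ----------
    reads : list of SequenceRead
        Input reads; must be nonempty.
    threshold : float
        Identity threshold in ``(0, 1]``; 0.97 is the conventional
        species-level cutoff.
    max_run_delta : int
        Maximum homopolymer run-length change covered by neighbor seeds.
    min_cluster_size : int
        Clusters below this size are dissolved during refinement.
    prefilter : bool
        Skip alignments whose identity provably cannot reach the threshold
        (never changes the result; see :func:`_identity_upper_bound`).

    Returns
    -------
    OTUClustering
        A partition of the input read ids, deterministic for fixed input.
    """
    if not reads:
        raise ValueError("cluster() requires at least one read")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if min_cluster_size < 1:
        raise ValueError("min_cluster_size must be >= 1")

    derep = _dereplicate_with_members(reads)
    clusters: list[_Cluster] = []
    for idx, (read, _members) in enumerate(derep):
        placed = False
        for cl in clusters:
            if prefilter and _identity_upper_bound(
                read.bases, cl.seed.bases
            ) < threshold - 2.0 * max_run_delta / len(read.bases):
                # Even a neighbor seed (at most max_run_delta bases away
                # from the seed) cannot bridge this gap.
                continue
            if _best_neighbor_identity(read.bases, cl, threshold, prefilter):
                cl.members.append(idx)
                placed = True
                break
        if not placed:
            clusters.append(
                _Cluster(
                    seed=read,
                    neighbors=sorted(neighbor_seeds(read.bases, max_run_delta)),
                    members=[idx],
                )
            )

    # refinement: dissolve undersized clusters into the nearest survivor
    def cluster_size(cl: _Cluster) -> int:
        return sum(len(derep[i][1]) for i in cl.members)

    sizes = [cluster_size(cl) for cl in clusters]
    survivors = [
        i for i, s in enumerate(sizes) if s >= min_cluster_size
    ]
    if survivors and len(survivors) < len(clusters):
        for i, cl in enumerate(clusters):
            if i in survivors:
                continue
            for idx in cl.members:
                query = derep[idx][0].bases
                best = max(
                    survivors,
                    key=lambda j: (
                        identity(query, clusters[j].seed.bases),
                        sizes[j],
                        -j,
                    ),
                )
                clusters[best].members.append(idx)
        clusters = [clusters[i] for i in survivors]

    out = []
    for cl in clusters:
        member_ids = sorted(
            itertools.chain.from_iterable(derep[i][1] for i in cl.members)
        )
        out.append((cl.seed.id, member_ids))
    return OTUClustering(
        clusters=out, threshold=threshold, min_cluster_size=min_cluster_size
    )
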