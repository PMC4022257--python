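"""Synthetic fixtures emulating the statistical structure of amplicon studies.

Three generators cover the three pipeline stages:

* :func:`simulate_reads` — amplicon reads derived from template sequences
  with the homopolymer run-length slips characteristic of pyrosequencing
  (and optional base substitutions).  Read ids encode the true template,
  so clustering accuracy can be scored exactly.
* :func:`simulate_abundance` — a variables × samples matrix of independent
  noise rows plus planted linearly linked pairs, for calibrating the MI
  permutation test and network assembly.
* :func:`planted_graph` — a stochastic block model with known community
  labels, for benchmarking community detection.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .abundance import VAR_ENV, VAR_OTU, AbundanceMatrix
from .mi_network import AssociationNetwork
from .nbhclust import SequenceRead, homopolymer_runs, identity

__all__ = [
    "ReadSimSpec",
    "PlantedGraphSpec",
    "random_templates",
    "simulate_reads",
    "simulate_abundance",
    "planted_graph",
]

_BASES = "ACGT"


def random_templates(
    n: int,
    n_runs: int = 16,
    max_run: int = 8,
    seed: int = 0,
    max_pairwise_identity: float = 0.90,
) -> list[str]:
    """Random homopolymer-structured template sequences.

    Each template is a concatenation of ``n_runs`` homopolymer runs with
    lengths uniform on ``[1, max_run]`` and adjacent runs on different
    bases (~72 nt at the defaults — the length of a short hypervariable
    region, with the long homopolymer runs that make pyrosequencing
    error-prone).  The run count controls the per-read error burden of
    :func:`simulate_reads`: at the default per-run slip rate of 0.1 a read
    carries 1.6 slips on average, so the error-free sequence of each
    template stays the most abundant dereplicated read — the regime deep
    amplicon sequencing operates in.  Rejection-samples until all pairwise
    identities are below ``max_pairwise_identity``.
    """
    rng = np.random.default_rng(seed)
    templates: list[str] = []
    attempts = 0
    while len(templates) < n:
        attempts += 1
        if attempts > 100 * n:
            raise RuntimeError("could not generate sufficiently distinct templates")
        runs = []
        prev = None
        for _ in range(n_runs):
            base = _BASES[rng.integers(4)]
            while base == prev:
                base = _BASES[rng.integers(4)]
            runs.append(base * int(rng.integers(1, max_run + 1)))
            prev = base
        cand = "".join(runs)
        if all(identity(cand, t) < max_pairwise_identity for t in templates):
            templates.append(cand)
    return templates


@dataclass
class ReadSimSpec:
    """Specification of a homopolymer-error read simulation.

    ``homopolymer_error_rate`` is the per-run probability that a run's
    length slips by one base (direction uniform; a length-1 run can only
    grow).  ``substitution_rate`` is the per-base probability of a random
    substitution, applied after the run slips.  Defaults model a
    moderately noisy pyrosequencing run over 50 reads per template.
    """

    templates: list[str]
    reads_per_template: int = 50
    homopolymer_error_rate: float = 0.1
    substitution_rate: float = 0.0
    seed: int = 0
    n_samples: int = 1
    check_identity_below: float | None = 0.97

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("need at least one template")
        if not (0 <= self.homopolymer_error_rate <= 1):
            raise ValueError("homopolymer_error_rate must be in [0, 1]")
        if not (0 <= self.substitution_rate <= 1):
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.reads_per_template < 1:
            raise ValueError("reads_per_template must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.check_identity_below is not None:
            for a, b in itertools.combinations(self.templates, 2):
                ident = identity(a, b)
                if ident >= self.check_identity_below:
                    raise ValueError(
                        f"template pair at identity {ident:.3f} >= "
                        f"{self.check_identity_below}; templates must be "
                        "distinguishable at the clustering threshold"
                    )


def simulate_reads(spec: ReadSimSpec) -> list[SequenceRead]:
    """Simulate error-bearing reads from templates; ids encode ground truth.

    Read ``t{k}_r{j}`` derives from ``spec.templates[k]``.  Each read is
    assigned uniformly at random to one of ``spec.n_samples`` synthetic
    samples, so per-sample OTU counts carry realistic multinomial
    variation.
    """
    rng = np.random.default_rng(spec.seed)
    reads = []
    width = len(str(spec.reads_per_template - 1))
    for k, template in enumerate(spec.templates):
        runs = homopolymer_runs(template)
        for j in range(spec.reads_per_template):
            new_runs = []
            for base, length in runs:
                if rng.random() < spec.homopolymer_error_rate:
                    if length == 1:
                        length = 2
                    else:
                        length += 1 if rng.random() < 0.5 else -1
                new_runs.append((base, length))
            seq = list("".join(b * n for b, n in new_runs))
            if spec.substitution_rate > 0:
                for pos in range(len(seq)):
                    if rng.random() < spec.substitution_rate:
                        seq[pos] = _BASES[
                            (_BASES.index(seq[pos]) + int(rng.integers(1, 4))) % 4
                        ]
            reads.append(
                SequenceRead(
                    id=f"t{k}_r{j:0{width}d}",
                    bases="".join(seq),
                    sample_id=f"S{int(rng.integers(spec.n_samples)) + 1}",
                )
            )
    return reads


def true_template_labels(reads: list[SequenceRead]) -> dict[str, int]:
    """Ground-truth template index for reads produced by simulate_reads."""
    return {r.id: int(r.id.split("_")[0][1:]) for r in reads}


def simulate_abundance(
    n_otu: int,
    n_env: int,
    S: int,
    n_linked_pairs: int = 0,
    link_strength: float = 0.8,
    seed: int = 0,
) -> tuple[AbundanceMatrix, list[tuple[str, str]]]:
    """Independent-noise abundance matrix with planted linked pairs.

    All rows are standard Gaussian noise over ``S`` samples; for each of
    ``n_linked_pairs`` disjoint row pairs (a, b), row b is replaced by
    ``link_strength * a + sqrt(1 - link_strength^2) * noise`` so that the
    pair correlates at ``link_strength`` while staying standardized
    (``link_strength=1`` duplicates the row exactly).  Returns the matrix
    and the planted pair list (the ground truth for edge-detection
    benchmarks).  Rows emulate the post-normalization matrix: OTU rows
    first (``OTU_1`` ...), then environmental rows (``E1`` ...).
    """
    if not (0 < link_strength <= 1) and n_linked_pairs > 0:
        raise ValueError("link_strength must be in (0, 1]")
    n_rows = n_otu + n_env
    if 2 * n_linked_pairs > n_rows:
        raise ValueError("too many linked pairs for the row count")
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_rows, S))
    labels = [f"OTU_{i + 1}" for i in range(n_otu)] + [
        f"E{j + 1}" for j in range(n_env)
    ]
    var_types = [VAR_OTU] * n_otu + [VAR_ENV] * n_env
    order = rng.permutation(n_rows)
    linked = []
    for p in range(n_linked_pairs):
        a, b = order[2 * p], order[2 * p + 1]
        values[b] = link_strength * values[a] + np.sqrt(
            1 - link_strength**2
        ) * rng.normal(size=S)
        linked.append(tuple(sorted((labels[a], labels[b]))))
    matrix = AbundanceMatrix(
        values=values, labels=labels, var_types=var_types, samples=[
            f"S{s + 1}" for s in range(S)
        ]
    )
    return matrix, sorted(linked)


@dataclass
class PlantedGraphSpec:
    """Stochastic-block-model graph with known communities.

    Within-block edges appear with probability ``p_in``, between-block
    with ``p_out`` (must be smaller).  ``weight_law`` is ``"unit"`` or
    ``"uniform"`` (weights uniform on [0.5, 1.5]).
    """

    block_sizes: list[int] = field(default_factory=lambda: [20, 20, 20])
    p_in: float = 0.3
    p_out: float = 0.02
    weight_law: str = "unit"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.weight_law not in ("unit", "uniform"):
            raise ValueError("weight_law must be 'unit' or 'uniform'")


def planted_graph(
    spec: PlantedGraphSpec,
) -> tuple[AssociationNetwork, np.ndarray]:
    """Sample a planted-partition network; returns (network, true labels)."""
    rng = np.random.default_rng(spec.seed)
    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    n = labels.size
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = spec.p_in if labels[i] == labels[j] else spec.p_out
            if rng.random() < p:
                w = 1.0 if spec.weight_law == "unit" else rng.uniform(0.5, 1.5)
                A[i, j] = A[j, i] = w
    net = AssociationNetwork(
        nodes=[f"n{i}" for i in range(n)],
        types=["OTU"] * n,
        A=A,
    )
    return net, labels
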