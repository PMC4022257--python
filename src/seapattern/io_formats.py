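"""Readers and writers for every on-disk representation the pipeline touches.

Formats
-------
* FASTA for reads (``;size=N`` header annotations are honored as
  dereplication multiplicities).
* TSV for the sample map (read_id, sample_id), abundance/count tables,
  OTU cluster membership, and community assignments.
* Weighted edge-list TSV or GraphML for association networks.  The edge
  list is written once per undirected edge with ``node_a < node_b``
  lexicographically (canonical, diff-friendly); isolated nodes are kept in
  ``#node`` comment lines so round-trips are lossless.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix, CountTable
from .mi_network import AssociationNetwork
from .nbhclust import OTUClustering, SequenceRead
from .snmf import CommunityModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_sample_map",
    "write_sample_map",
    "read_table",
    "write_table",
    "read_counts",
    "write_counts",
    "write_network",
    "read_network",
    "write_clustering",
    "read_clustering",
    "write_communities",
    "read_communities",
]

_SIZE_RE = re.compile(r";size=(\d+)")
_VALID_SEQ_RE = re.compile(r"^[ACGTN]+$")


class FastaParseError(ValueError):
    """FASTA syntax violation, carrying the offending line number."""

    def __init__(self, path: str | Path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.line = line


def read_fasta(path: str | Path) -> list[SequenceRead]:
    """Read amplicon reads from a FASTA file.

    Sequences are uppercased; characters outside ``{A, C, G, T, N}`` are
    rejected.  A ``;size=N`` annotation in the header sets the read's
    multiplicity.  Parse errors name the offending line.  (A bespoke
    scanner rather than a generic parser so that diagnostics carry exact
    line numbers.)
    """
    reads: list[SequenceRead] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(at_line: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(path, header_line, f"record {header!r} has an empty sequence")
        if not _VALID_SEQ_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FastaParseError(
                path, header_line, f"record {header!r} contains invalid characters {bad}"
            )
        m = _SIZE_RE.search(header)
        copies = int(m.group(1)) if m else 1
        rid = _SIZE_RE.sub("", header).split()[0]
        reads.append(SequenceRead(id=rid, bases=seq, copies=copies))
        header = None
        chunks.clear()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(path, lineno, "empty FASTA header")
                header_line = lineno
            else:
                if header is None:
                    raise FastaParseError(
                        path, lineno, "sequence data before any '>' header"
                    )
                chunks.append(line.strip())
        flush(header_line + 1)
    return reads


def write_fasta(reads: list[SequenceRead], path: str | Path) -> None:
    """Write reads as FASTA; multiplicities > 1 become ``;size=N``."""
    with open(path, "w") as fh:
        for r in reads:
            size = f";size={r.copies}" if r.copies > 1 else ""
            fh.write(f">{r.id}{size}\n{r.bases}\n")


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a read_id → sample_id TSV (header optional, two columns)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rid, sid = parts
            if lineno == 1 and rid in ("read_id", "id"):
                continue
            if rid in out:
                raise ValueError(f"{path}:{lineno}: duplicate read id {rid!r}")
            out[rid] = sid
    if not out:
        raise ValueError(f"{path}: empty sample map")
    return out


def write_sample_map(sample_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\n")
        for rid in sorted(sample_map):
            fh.write(f"{rid}\t{sample_map[rid]}\n")


def read_table(
    path: str | Path,
    orientation: str = "variables-by-samples",
    var_type: str = "OTU",
) -> AbundanceMatrix:
    """Read a labelled numeric TSV as an :class:`AbundanceMatrix`.

    ``orientation`` is ``variables-by-samples`` (rows are variables) or
    ``samples-by-variables`` (the transpose); output is always normalized
    to variables-by-samples.  Non-numeric cells and duplicate labels raise
    with the offending label.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row labels {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column labels {dups}")
    values = np.empty(df.shape)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = df.index[bad.values.argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        values[:, j] = converted.values
    if orientation == "samples-by-variables":
        values = values.T
        labels, samples = list(df.columns), list(df.index)
    elif orientation == "variables-by-samples":
        labels, samples = list(df.index), list(df.columns)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return AbundanceMatrix(
        values=values,
        labels=[str(x) for x in labels],
        var_types=[var_type] * len(labels),
        samples=[str(x) for x in samples],
    )


def write_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write an abundance matrix as variables-by-samples TSV."""
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def read_counts(path: str | Path, totals: dict[str, int] | None = None) -> CountTable:
    """Read an OTU × sample integer count TSV.

    ``totals`` defaults to the column sums (i.e. every sequenced read is
    accounted for by some OTU).
    """
    m = read_table(path)
    counts = pd.DataFrame(
        m.values.astype(np.int64), index=m.labels, columns=m.samples
    )
    if not np.array_equal(counts.values, m.values):
        raise ValueError(f"{path}: count table must contain integers")
    tot = counts.sum(axis=0) if totals is None else pd.Series(totals)
    return CountTable(counts=counts, totals=tot)


def write_counts(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


_NET_HEADER = "node_a\tnode_b\tweight\tp_value\ttype_a\ttype_b"


def write_network(
    net: AssociationNetwork, path: str | Path, format: str = "edge-list"
) -> None:
    """Serialize a network as canonical edge-list TSV or GraphML.

    The edge list carries one line per undirected edge (``node_a <
    node_b``), weights at 12 significant digits, and ``#node`` comment
    lines for the full typed node set so reading it back restores the
    network exactly.
    """
    if format == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), str(path))
        return
    if format != "edge-list":
        raise ValueError(f"unknown format {format!r}")
    typ = dict(zip(net.nodes, net.types))
    with open(path, "w") as fh:
        for name in net.nodes:
            fh.write(f"#node\t{name}\t{typ[name]}\n")
        fh.write(_NET_HEADER + "\n")
        for a, b, w, p in net.edges():
            p_str = "NA" if np.isnan(p) else f"{p:.12g}"
            fh.write(f"{a}\t{b}\t{w:.12g}\t{p_str}\t{typ[a]}\t{typ[b]}\n")


def read_network(path: str | Path, format: str = "edge-list") -> AssociationNetwork:
    """Read a network written by :func:`write_network`."""
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(str(path))
        nodes = list(g.nodes())
        types = [g.nodes[v].get("type", "OTU") for v in nodes]
        pos = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        P = np.full((len(nodes), len(nodes)), np.nan)
        for a, b, data in g.edges(data=True):
            i, j = pos[a], pos[b]
            A[i, j] = A[j, i] = float(data.get("weight", 1.0))
            P[i, j] = P[j, i] = float(data.get("p_value", np.nan))
        return AssociationNetwork(nodes=nodes, types=types, A=A, pvalues=P)
    if format != "edge-list":
        raise ValueError(f"unknown format {format!r}")
    nodes: list[str] = []
    types: list[str] = []
    edges: list[tuple[str, str, float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#node\t"):
                _, name, t = line.split("\t")
                nodes.append(name)
                types.append(t)
                continue
            if line.startswith("node_a\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            a, b, w, p, _ta, _tb = parts
            edges.append(
                (a, b, float(w), np.nan if p == "NA" else float(p))
            )
    pos = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    P = np.full((len(nodes), len(nodes)), np.nan)
    for a, b, w, p in edges:
        if a not in pos or b not in pos:
            raise ValueError(f"{path}: edge references unknown node {a!r}/{b!r}")
        i, j = pos[a], pos[b]
        A[i, j] = A[j, i] = w
        P[i, j] = P[j, i] = p
    return AssociationNetwork(nodes=nodes, types=types, A=A, pvalues=P)


def write_clustering(clustering: OTUClustering, path: str | Path) -> None:
    """Write cluster membership TSV: otu_id, seed_id, read_id."""
    with open(path, "w") as fh:
        fh.write(f"#threshold\t{clustering.threshold:.12g}\n")
        fh.write(f"#min_cluster_size\t{clustering.min_cluster_size}\n")
        fh.write("otu_id\tseed_id\tread_id\n")
        for k, (seed, members) in enumerate(clustering.clusters):
            for rid in members:
                fh.write(f"OTU_{k + 1}\t{seed}\t{rid}\n")


def read_clustering(path: str | Path) -> OTUClustering:
    """Read a clustering written by :func:`write_clustering`."""
    threshold = 0.97
    min_size = 1
    order: list[str] = []
    seeds: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("otu_id\t"):
                continue
            if line.startswith("#threshold\t"):
                threshold = float(line.split("\t")[1])
                continue
            if line.startswith("#min_cluster_size\t"):
                min_size = int(line.split("\t")[1])
                continue
            otu, seed, rid = line.split("\t")
            if otu not in members:
                order.append(otu)
                seeds[otu] = seed
                members[otu] = []
            members[otu].append(rid)
    return OTUClustering(
        clusters=[(seeds[o], members[o]) for o in order],
        threshold=threshold,
        min_cluster_size=min_size,
    )


def write_communities(
    model: CommunityModel, nodes: list[str], path: str | Path
) -> None:
    """Write community assignments: node_id, hard_label, U memberships.

    Hard labels are 0-based clique indices; the remaining ``r`` columns
    expose the full fuzzy membership of each node.
    """
    r = model.r
    with open(path, "w") as fh:
        fh.write(f"#r\t{r}\n")
        fh.write(f"#Q_f\t{model.Q_f:.12g}\n")
        header = "\t".join(["node_id", "hard_label"] + [f"u{k}" for k in range(r)])
        fh.write(header + "\n")
        for i, name in enumerate(nodes):
            u_cols = "\t".join(f"{model.U[k, i]:.12g}" for k in range(r))
            fh.write(f"{name}\t{model.labels[i]}\t{u_cols}\n")


def read_communities(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read community assignments; returns (nodes, hard_labels, U)."""
    nodes: list[str] = []
    labels: list[int] = []
    u_rows: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "node_id\t")):
                continue
            parts = line.split("\t")
            nodes.append(parts[0])
            labels.append(int(parts[1]))
            u_rows.append([float(x) for x in parts[2:]])
    return nodes, np.asarray(labels), np.asarray(u_rows).T
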