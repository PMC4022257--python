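"""OTU count tables and relative-abundance matrices.

The association analysis works on a variables × samples matrix holding one
row per OTU and one row per environmental factor.  OTU rows start as raw
per-sample read counts, are converted to relative abundances, have
low-count cells zeroed (to damp sequencing-effort bias), are dropped when
too sparse (to avoid spuriously high associations driven by a couple of
shared zeros), and are finally z-scored together with the environmental
rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nbhclust import OTUClustering

__all__ = [
    "CountTable",
    "AbundanceMatrix",
    "build_count_table",
    "relative_abundance",
    "filter_sparse",
    "zero_mean_normalize",
]

VAR_OTU = "OTU"
VAR_ENV = "env"


@dataclass
class CountTable:
    """OTU × sample read counts plus per-sample sequencing totals.

    ``counts`` is a nonnegative integer DataFrame (rows: OTUs, columns:
    samples); ``totals`` holds the total sequence number per sample, which
    may exceed the column sums when reads were discarded upstream.
    """

    counts: pd.DataFrame
    totals: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.totals = self.totals.astype(np.int64).reindex(self.counts.columns)
        if self.totals.isna().any():
            missing = self.totals.index[self.totals.isna()].tolist()
            raise ValueError(f"totals missing for samples {missing}")
        if (self.totals <= 0).any():
            bad = self.totals.index[self.totals <= 0].tolist()
            raise ValueError(f"nonpositive totals for samples {bad}")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) > self.totals).any():
            raise ValueError("column sums exceed per-sample totals")


@dataclass
class AbundanceMatrix:
    """Variables × samples real matrix with typed rows.

    Rows are OTUs or environmental factors (``var_types`` entries are
    :data:`VAR_OTU` or :data:`VAR_ENV`); columns are samples.  Row order is
    stable through every transformation.
    """

    values: np.ndarray
    labels: list[str]
    var_types: list[str]
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (variables x samples)")
        nv, ns = self.values.shape
        if len(self.labels) != nv or len(self.var_types) != nv:
            raise ValueError("labels/var_types length mismatch with values")
        if len(self.samples) != ns:
            raise ValueError("samples length mismatch with values")
        if len(set(self.labels)) != nv:
            raise ValueError("duplicate variable labels")
        bad = set(self.var_types) - {VAR_OTU, VAR_ENV}
        if bad:
            raise ValueError(f"unknown var_types {sorted(bad)}")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.samples)

    def row(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]

    @staticmethod
    def vstack(*parts: "AbundanceMatrix") -> "AbundanceMatrix":
        """Stack matrices sharing the same sample axis (order included)."""
        first = parts[0]
        for p in parts[1:]:
            if p.samples != first.samples:
                raise ValueError("sample labels/order differ between parts")
        return AbundanceMatrix(
            values=np.vstack([p.values for p in parts]),
            labels=[lab for p in parts for lab in p.labels],
            var_types=[t for p in parts for t in p.var_types],
            samples=list(first.samples),
        )


def build_count_table(
    clustering: OTUClustering,
    sample_map: dict[str, str],
    copies: dict[str, int] | None = None,
    totals: dict[str, int] | None = None,
    otu_prefix: str = "OTU",
) -> CountTable:
    """Tabulate an :class:`OTUClustering` into per-sample OTU counts.

    Parameters
    ----------
    clustering : OTUClustering
        Clusters over read ids.
    sample_map : dict
        read_id -> sample_id for every clustered read.
    copies : dict, optional
        Per-read multiplicities (defaults to 1 each).
    totals : dict, optional
        Per-sample total sequence numbers; defaults to the column sums.
    otu_prefix : str
        OTUs are named ``{prefix}_{k+1}`` in cluster order.
    """
    samples = sorted(set(sample_map.values()))
    sample_pos = {s: j for j, s in enumerate(samples)}
    n = np.zeros((clustering.n_clusters, len(samples)), dtype=np.int64)
    for k, (_seed, members) in enumerate(clustering.clusters):
        for rid in members:
            if rid not in sample_map:
                raise KeyError(f"read {rid!r} missing from sample map")
            mult = 1 if copies is None else copies.get(rid, 1)
            n[k, sample_pos[sample_map[rid]]] += mult
    otu_ids = [f"{otu_prefix}_{k + 1}" for k in range(clustering.n_clusters)]
    counts = pd.DataFrame(n, index=otu_ids, columns=samples)
    if totals is None:
        tot = counts.sum(axis=0)
    else:
        tot = pd.Series(totals).reindex(samples)
    return CountTable(counts=counts, totals=tot)


def relative_abundance(table: CountTable, min_count: int = 5) -> AbundanceMatrix:
    """Per-sample relative abundances with a low-count floor.

    Each cell becomes ``N_us / N_s`` (OTU reads over the sample's total),
    then cells whose raw count is below ``min_count`` are set to zero so
    that barely-detected OTUs do not contribute noise correlations.  The
    default floor of 5 reads reflects typical pyrosequencing error rates.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    x = table.counts.values / table.totals.values[np.newaxis, :]
    x[table.counts.values < min_count] = 0.0
    return AbundanceMatrix(
        values=x,
        labels=list(table.counts.index),
        var_types=[VAR_OTU] * table.counts.shape[0],
        samples=list(table.counts.columns),
    )


def filter_sparse(matrix: AbundanceMatrix, min_nonzero: int = 3) -> AbundanceMatrix:
    """Drop OTU rows observed in fewer than ``min_nonzero`` samples.

    A pair of vectors that are both zero almost everywhere can show a
    deceptively strong association; requiring at least 3 nonzero entries
    (the default) guards against that.  Environmental-factor rows are never
    removed.  Idempotent; row order preserved.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    keep = [
        i
        for i in range(matrix.n_variables)
        if matrix.var_types[i] == VAR_ENV
        or int(np.count_nonzero(matrix.values[i])) >= min_nonzero
    ]
    return AbundanceMatrix(
        values=matrix.values[keep],
        labels=[matrix.labels[i] for i in keep],
        var_types=[matrix.var_types[i] for i in keep],
        samples=list(matrix.samples),
    )


def zero_mean_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Z-score every row: mean 0, population standard deviation 1.

    Raises on constant rows (they carry no association signal and should
    have been filtered); names the offending row in the error.
    """
    values = matrix.values.copy()
    sd = values.std(axis=1)  # population SD (ddof=0)
    const = np.flatnonzero(sd == 0.0)
    if const.size:
        raise ValueError(
            f"constant row(s) cannot be normalized: "
            f"{[matrix.labels[i] for i in const]}"
        )
    values = (values - values.mean(axis=1, keepdims=True)) / sd[:, np.newaxis]
    return AbundanceMatrix(
        values=values,
        labels=list(matrix.labels),
        var_types=list(matrix.var_types),
        samples=list(matrix.samples),
    )
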