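"""End-to-end orchestration: reads → OTUs → abundances → network → communities.

:func:`run_pipeline` wires the five stages together, writes every
intermediate artifact to the output directory (each one a valid input to
the corresponding standalone subcommand), and records a manifest with the
full configuration so that a rerun reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__, abundance, io_formats, mi_network, snmf, topology
from .snmf import CommunityModel
from .topology import TopologyReport

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage parameter of the pipeline, with the standard defaults.

    Clustering: ``threshold`` (greedy identity cutoff), ``max_run_delta``
    (neighbor-seed homopolymer radius), ``min_cluster_size`` (refinement).
    Abundance: ``min_count`` (low-count floor), ``min_nonzero`` (sparsity
    filter).  Network: ``bins`` (None → ceil(sqrt(S))), the two
    significance levels, and the permutation count.  Communities: the r
    scan range (``r_max`` None → min(n, 20)) and restart count.
    """

    threshold: float = 0.97
    max_run_delta: int = 1
    min_cluster_size: int = 2
    min_count: int = 5
    min_nonzero: int = 3
    bins: int | None = None
    alpha_otu: float = 0.01
    alpha_env: float = 0.05
    n_perm: int = 1000
    r_min: int = 2
    r_max: int | None = None
    restarts: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    reads: str | Path,
    samples: str | Path,
    env: str | Path | None,
    outdir: str | Path,
) -> tuple[TopologyReport, CommunityModel]:
    """Run the full pipeline from files to a topology report.

    Parameters
    ----------
    config : PipelineConfig
        Stage parameters.
    reads : path
        FASTA file of amplicon reads.
    samples : path
        TSV sample map (read_id, sample_id).
    env : path or None
        TSV of environmental factors (variables × samples); None for an
        OTU-only network.
    outdir : path
        Directory for artifacts: ``otus.tsv``, ``counts.tsv``,
        ``matrix.tsv``, ``network.tsv``, ``communities.tsv``,
        ``report.tsv``, ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    read_list = stage("read_fasta", io_formats.read_fasta, reads)
    sample_map = stage("read_sample_map", io_formats.read_sample_map, samples)

    from . import nbhclust

    clustering = stage(
        "cluster",
        nbhclust.cluster,
        read_list,
        threshold=config.threshold,
        max_run_delta=config.max_run_delta,
        min_cluster_size=config.min_cluster_size,
    )
    io_formats.write_clustering(clustering, outdir / "otus.tsv")

    copies = {r.id: r.copies for r in read_list}
    table = stage(
        "count_table",
        abundance.build_count_table,
        clustering,
        sample_map,
        copies=copies,
    )
    io_formats.write_counts(table, outdir / "counts.tsv")

    matrix = stage(
        "relative_abundance",
        abundance.relative_abundance,
        table,
        min_count=config.min_count,
    )
    matrix = stage(
        "filter_sparse", abundance.filter_sparse, matrix, config.min_nonzero
    )
    if env is not None:
        env_matrix = stage(
            "read_env", io_formats.read_table, env, var_type=abundance.VAR_ENV
        )
        matrix = stage(
            "combine", abundance.AbundanceMatrix.vstack, matrix, env_matrix
        )
    matrix = stage("normalize", abundance.zero_mean_normalize, matrix)
    io_formats.write_table(matrix, outdir / "matrix.tsv")

    net = stage(
        "build_network",
        mi_network.build_network,
        matrix,
        M=config.bins,
        alpha_otu=config.alpha_otu,
        alpha_env=config.alpha_env,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    io_formats.write_network(net, outdir / "network.tsv")

    r_max = config.r_max
    if r_max is not None:
        r_max = min(r_max, net.n)
    model = stage(
        "detect_communities",
        snmf.detect_communities,
        net,
        r_min=min(config.r_min, net.n),
        r_max=r_max,
        restarts=config.restarts,
        seed=config.seed,
    )
    io_formats.write_communities(model, net.nodes, outdir / "communities.tsv")

    rep = stage("report", topology.report, net, model)
    with open(outdir / "report.tsv", "w") as fh:
        for key, value in rep.to_dict().items():
            fh.write(f"{key}\t{value:.12g}\n")

    manifest = {
        "seapattern_version": __version__,
        "config": config.to_dict(),
        "inputs": {
            "reads": str(reads),
            "samples": str(samples),
            "env": None if env is None else str(env),
        },
        "artifacts": [
            "otus.tsv",
            "counts.tsv",
            "matrix.tsv",
            "network.tsv",
            "communities.tsv",
            "report.tsv",
        ],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return rep, model
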