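"""OTU clustering under homopolymer errors.

Simulates reads from three template sequences with pyrosequencing-style
homopolymer run-length slips, clusters them at the 97% species-level
threshold with neighbor seeds, and scores the result against the known
template of every read.  A naive method would inflate the OTU count;
neighbor seeds plus small-cluster dissolution recover exactly one OTU
per template.
"""

import collections

from seapattern import cluster, synthetic

templates = synthetic.random_templates(3, seed=8)
spec = synthetic.ReadSimSpec(
    templates=templates,
    reads_per_template=50,
    homopolymer_error_rate=0.1,
    seed=8,
)
reads = synthetic.simulate_reads(spec)
print(f"{len(reads)} reads from {len(templates)} templates "
      f"({sum(r.bases != templates[int(r.id[1])] for r in reads)} carry errors)")

clustering = cluster(reads, threshold=0.97, min_cluster_size=5)
truth = synthetic.true_template_labels(reads)
purity = sum(
    collections.Counter(truth[m] for m in members).most_common(1)[0][1]
    for _, members in clustering.clusters
) / len(reads)

print(f"OTUs found: {clustering.n_clusters} (sizes {clustering.sizes()})")
print(f"purity vs ground truth: {purity:.3f}")
# 3 OTUs at purity 1.000 means every error-bearing read was pulled back
# to its template's cluster: no inflation, no misassignment.
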