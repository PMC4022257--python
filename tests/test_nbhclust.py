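"""Unit and property tests for the neighbor-seed OTU clustering."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seapattern import synthetic
from seapattern.nbhclust import (
    OTUClustering,
    SequenceRead,
    _identity_upper_bound,
    cluster,
    dereplicate,
    homopolymer_runs,
    identity,
    neighbor_seeds,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def _reads(seqs, prefix="r"):
    return [SequenceRead(id=f"{prefix}{i}", bases=s) for i, s in enumerate(seqs)]


class TestSequenceRead:
    def test_rejects_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            SequenceRead(id="a", bases="")
        with pytest.raises(ValueError, match="invalid characters"):
            SequenceRead(id="a", bases="ACGX")
        with pytest.raises(ValueError):
            SequenceRead(id="a", bases="ACGT", copies=0)


class TestDereplicate:
    def test_merges_identical_sequences(self):
        out = dereplicate(_reads(["AAA", "AAA", "AAT"]))
        assert [(r.bases, r.copies) for r in out] == [("AAA", 2), ("AAT", 1)]

    def test_distinct_input_unchanged(self):
        out = dereplicate(_reads(["AAA", "CCC", "GGG"]))
        assert len(out) == 3
        assert all(r.copies == 1 for r in out)

    def test_order_independence(self, rng):
        reads = _reads(["ACGT", "ACGT", "AATT", "CCGG", "AATT", "AATT"])
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        assert dereplicate(reads) == dereplicate(shuffled)


class TestIdentity:
    def test_self_identity_is_one(self):
        assert identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_disjoint_is_zero(self):
        # free end gaps: the optimal alignment staggers the sequences
        assert identity("AAAA", "TTTT") == 0.0

    def test_single_mismatch(self):
        # 7 matches over 8 columns in the optimal global alignment
        assert identity("ACGTACGT", "ACGTACGA") == pytest.approx(0.875)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            identity("", "ACGT")

    @settings(max_examples=50, derandomize=True)
    @given(a=dna, b=dna)
    def test_symmetric_and_bounded(self, a, b):
        ab = identity(a, b)
        assert ab == identity(b, a)
        assert 0.0 <= ab <= 1.0

    @settings(max_examples=50, derandomize=True)
    @given(a=dna, b=dna)
    def test_upper_bound_is_valid(self, a, b):
        assert _identity_upper_bound(a, b) >= identity(a, b) - 1e-12


class TestNeighborSeeds:
    def test_enumerates_single_run_edits(self):
        assert neighbor_seeds("AAT", 1) == {"AAT", "AT", "AAAT", "AATT"}

    def test_single_base_cannot_shrink(self):
        assert neighbor_seeds("A", 1) == {"A", "AA"}

    def test_delta_two_reaches_further(self):
        out = neighbor_seeds("AAA", 2)
        assert out == {"A", "AA", "AAA", "AAAA", "AAAAA"}

    @settings(max_examples=50, derandomize=True)
    @given(seed=dna, delta=st.integers(min_value=1, max_value=2))
    def test_seed_in_result_and_edits_are_single_run(self, seed, delta):
        out = neighbor_seeds(seed, delta)
        assert seed in out
        base_pattern = [b for b, _ in homopolymer_runs(seed)]
        for nb in out:
            runs = homopolymer_runs(nb)
            assert [b for b, _ in runs] == base_pattern
            diffs = [
                abs(n1 - n2)
                for (_, n1), (_, n2) in zip(runs, homopolymer_runs(seed))
                if n1 != n2
            ]
            assert len(diffs) <= 1
            assert all(d <= delta for d in diffs)


class TestCluster:
    def test_identical_copies_form_one_cluster(self):
        reads = _reads(["ACGTACGTAA"] * 100)
        out = cluster(reads, threshold=0.97, min_cluster_size=1)
        assert out.n_clusters == 1
        assert out.sizes() == [100]

    def test_distant_templates_stay_separate(self):
        t1, t2 = synthetic.random_templates(2, seed=11, max_pairwise_identity=0.5)
        reads = _reads([t1] * 50 + [t2] * 50)
        out = cluster(reads, threshold=0.97, min_cluster_size=1)
        assert out.n_clusters == 2
        assert sorted(out.sizes()) == [50, 50]

    def test_homopolymer_variants_merge_into_template(self):
        template = "AACCCGGGTTACGGA"
        variants = sorted(neighbor_seeds(template, 1) - {template})
        reads = _reads([template] * 5 + variants)
        out = cluster(reads, threshold=0.97, min_cluster_size=1)
        # direct identity to the template is < 0.97 for every variant,
        # so only the neighbor-seed match can merge them
        assert all(identity(v, template) < 0.97 for v in variants)
        assert out.n_clusters == 1

    def test_partition_property(self):
        tpl = synthetic.random_templates(3, seed=2)
        reads = synthetic.simulate_reads(
            synthetic.ReadSimSpec(templates=tpl, reads_per_template=20, seed=2)
        )
        out = cluster(reads, threshold=0.97)
        all_ids = sorted(r.id for r in reads)
        clustered = sorted(
            itertools.chain.from_iterable(m for _, m in out.clusters)
        )
        assert clustered == all_ids

    def test_read_order_invariance(self, rng):
        tpl = synthetic.random_templates(2, seed=3)
        reads = synthetic.simulate_reads(
            synthetic.ReadSimSpec(templates=tpl, reads_per_template=15, seed=3)
        )
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        a = cluster(reads, threshold=0.97)
        b = cluster(shuffled, threshold=0.97)
        assert a.clusters == b.clusters

    def test_threshold_monotonicity(self):
        tpl = synthetic.random_templates(3, seed=4)
        reads = synthetic.simulate_reads(
            synthetic.ReadSimSpec(templates=tpl, reads_per_template=20, seed=4)
        )
        counts = [
            cluster(reads, threshold=t, min_cluster_size=1).n_clusters
            for t in (0.90, 0.95, 0.99)
        ]
        assert counts == sorted(counts)

    def test_prefilter_never_changes_result(self):
        tpl = synthetic.random_templates(3, seed=5)
        reads = synthetic.simulate_reads(
            synthetic.ReadSimSpec(templates=tpl, reads_per_template=25, seed=5)
        )
        with_pf = cluster(reads, threshold=0.97, prefilter=True)
        without_pf = cluster(reads, threshold=0.97, prefilter=False)
        assert with_pf.clusters == without_pf.clusters

    def test_small_clusters_dissolved_into_nearest(self):
        t1, t2 = synthetic.random_templates(2, seed=6, max_pairwise_identity=0.5)
        # one junk read too distant to join either template directly
        junk = t1[: len(t1) // 2] + t2[len(t2) // 2 :]
        reads = _reads([t1] * 10 + [t2] * 10) + [SequenceRead(id="junk", bases=junk)]
        out = cluster(reads, threshold=0.97, min_cluster_size=2)
        assert out.n_clusters == 2
        home = out.labels()["junk"]
        seed_bases = {0: t1, 1: t2}
        other = 1 - home
        assert identity(junk, seed_bases[home]) >= identity(junk, seed_bases[other])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster([])

    def test_invariants_of_result_object(self):
        with pytest.raises(ValueError):
            cluster(_reads(["ACGT"]), threshold=1.5)
        out = cluster(_reads(["ACGT", "ACGT"]), min_cluster_size=1)
        assert isinstance(out, OTUClustering)
        assert out.threshold == 0.97
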