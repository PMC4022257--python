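"""Tests for binned MI, the permutation test, and network assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import binned_mi_oracle
from seapattern.abundance import VAR_ENV, VAR_OTU, AbundanceMatrix
from seapattern.mi_network import (
    build_network,
    default_bin_count,
    entropy,
    joint_entropy,
    make_bins,
    mutual_information,
    permutation_pvalue,
)


def _matrix(values, var_types=None):
    values = np.asarray(values, dtype=float)
    return AbundanceMatrix(
        values=values,
        labels=[f"v{i}" for i in range(values.shape[0])],
        var_types=var_types or [VAR_OTU] * values.shape[0],
        samples=[f"S{j}" for j in range(values.shape[1])],
    )


class TestMakeBins:
    def test_equal_width_edges(self):
        bins = make_bins(np.array([0.0, 0.3, 1.0]), 2)
        assert bins.edges == pytest.approx([0.0, 0.5, 1.0])
        assert bins.M == 2

    def test_single_bin(self):
        bins = make_bins(np.array([1.0, 4.0]), 1)
        assert (bins.assign(np.array([1.0, 2.5, 4.0])) == 0).all()

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            make_bins(np.ones(5), 3)

    @settings(max_examples=50, derandomize=True)
    @given(
        xs=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30
        ).filter(lambda v: len(set(v)) > 1),
        m=st.integers(min_value=1, max_value=6),
    )
    def test_every_sample_in_exactly_one_bin(self, xs, m):
        x = np.array(xs)
        bins = make_bins(x, m)
        idx = bins.assign(x)
        assert ((idx >= 0) & (idx < m)).all()
        # bin membership: value lies within its bin's edges
        assert (x >= bins.edges[idx] - 1e-9).all()
        assert (x <= bins.edges[idx + 1] + 1e-9).all()


class TestEntropy:
    def test_single_bin_zero(self):
        x = np.array([1.0, 1.1, 1.2, 5.0])
        assert entropy(x, make_bins(x, 1)) == 0.0

    def test_uniform_two_bins(self):
        x = np.array([0.0, 0.1, 0.9, 1.0])
        assert entropy(x, make_bins(x, 2)) == pytest.approx(np.log(2))

    def test_three_one_split(self):
        # counts (3, 1) over two bins: -(3/4 log 3/4 + 1/4 log 1/4)
        x = np.array([0.0, 0.1, 0.2, 1.0])
        assert entropy(x, make_bins(x, 2)) == pytest.approx(
            0.5623351446188083, abs=1e-12
        )


class TestMutualInformation:
    def test_self_mi_equals_entropy(self, rng):
        x = rng.normal(size=25)
        for m in (2, 3, 5):
            assert mutual_information(x, x, m) == pytest.approx(
                entropy(x, make_bins(x, m))
            )

    def test_perfect_dependence(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        y = np.array([5.0, 5.0, 9.0, 9.0])
        assert mutual_information(x, y, 2) == pytest.approx(np.log(2))

    def test_affine_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        base = mutual_information(x, y, 4)
        assert mutual_information(3.7 * x + 11.0, y, 4) == pytest.approx(base)
        assert mutual_information(x, 0.2 * y - 5.0, 4) == pytest.approx(base)

    def test_symmetric_and_nonnegative(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=15), rng.normal(size=15)
            i_xy = mutual_information(x, y, 3)
            assert i_xy == pytest.approx(mutual_information(y, x, 3), abs=1e-12)
            assert i_xy >= 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(np.ones(3), np.ones(4), 2)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            S = int(rng.integers(4, 21))
            M = int(rng.integers(1, 5))
            x, y = rng.normal(size=S), rng.normal(size=S)
            hx, hy, i_oracle = binned_mi_oracle(list(x), list(y), M)
            assert entropy(x, make_bins(x, M)) == pytest.approx(hx, abs=1e-12)
            assert entropy(y, make_bins(y, M)) == pytest.approx(hy, abs=1e-12)
            assert mutual_information(x, y, M) == pytest.approx(
                max(i_oracle, 0.0), abs=1e-12
            )

    def test_joint_entropy_subadditive(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        bx, by = make_bins(x, 4), make_bins(y, 4)
        hxy = joint_entropy(x, y, bx, by)
        assert hxy <= entropy(x, bx) + entropy(y, by) + 1e-12


class TestPermutationPvalue:
    def test_strong_dependence_gives_minimum_p(self):
        x = np.arange(20.0)
        res = permutation_pvalue(x, x, M=4, n_perm=99, seed=1)
        assert res.p_value == pytest.approx(0.01)
        assert res.n_permutations == 99

    def test_addone_floor(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        res = permutation_pvalue(x, y, M=3, n_perm=49, seed=2)
        assert 1 / 50 <= res.p_value <= 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        x, y = rng.normal(size=18), rng.normal(size=18)
        a = permutation_pvalue(x, y, M=4, n_perm=200, seed=7)
        b = permutation_pvalue(x, y, M=4, n_perm=200, seed=7)
        assert a == b

    def test_rejects_bad_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.arange(5.0), np.arange(5.0), 2, n_perm=0)

    def test_superuniform_under_null(self, rng):
        # P(p <= alpha) <= alpha for independent data (quick check at 0.05)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.normal(size=20), rng.normal(size=20)
            if permutation_pvalue(x, y, M=4, n_perm=39, seed=rng).p_value <= 0.05:
                hits += 1
        # binomial(200, 0.05) 3-sigma upper bound
        assert hits <= 10 + 3 * np.sqrt(200 * 0.05 * 0.95)


class TestBuildNetwork:
    def test_duplicated_rows_always_linked(self, rng):
        x = rng.normal(size=20)
        m = _matrix([x, x.copy(), rng.normal(size=20)])
        net = build_network(m, M=4, n_perm=99, seed=0)
        i, j = net.nodes.index("v0"), net.nodes.index("v1")
        assert net.A[i, j] > 0
        assert net.A[i, j] == net.A.max()

    def test_alpha_one_gives_complete_graph(self, rng):
        m = _matrix(rng.normal(size=(4, 12)))
        net = build_network(m, M=3, alpha_otu=1.0, alpha_env=1.0, n_perm=19, seed=0)
        assert net.l == 6

    def test_env_pairs_use_looser_alpha(self, rng):
        # alpha_env=1 retains every env-env pair even when alpha_otu
        # rejects everything
        vals = rng.normal(size=(4, 15))
        m = _matrix(vals, var_types=[VAR_OTU, VAR_OTU, VAR_ENV, VAR_ENV])
        net = build_network(
            m, M=3, alpha_otu=1e-9, alpha_env=1.0, n_perm=19, seed=0
        )
        i, j = net.nodes.index("v2"), net.nodes.index("v3")
        assert net.A[i, j] > 0
        assert net.l == 1

    def test_row_order_invariance(self, rng):
        vals = rng.normal(size=(5, 16))
        m = _matrix(vals)
        perm = [3, 0, 4, 1, 2]
        m_perm = AbundanceMatrix(
            values=vals[perm],
            labels=[m.labels[i] for i in perm],
            var_types=[VAR_OTU] * 5,
            samples=list(m.samples),
        )
        net_a = build_network(m, M=4, alpha_otu=0.3, n_perm=99, seed=5)
        net_b = build_network(m_perm, M=4, alpha_otu=0.3, n_perm=99, seed=5)
        assert net_a.edges() == net_b.edges()

    def test_constant_variable_rejected(self, rng):
        m = _matrix([np.ones(10), rng.normal(size=10)])
        with pytest.raises(ValueError, match="constant"):
            build_network(m, M=2, n_perm=9)

    def test_isolated_nodes_kept_and_flagged(self, rng):
        x = rng.normal(size=20)
        m = _matrix([x, x.copy(), rng.normal(size=20)])
        net = build_network(m, M=4, alpha_otu=0.01, n_perm=199, seed=3)
        assert set(net.nodes) == {"v0", "v1", "v2"}
        assert "v2" in net.isolated_nodes()

    def test_default_bin_count_rule(self):
        assert default_bin_count(16) == 4
        assert default_bin_count(20) == 5
        assert default_bin_count(24) == 5
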