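"""Covariation metrics: contingency tables, MI, chi-square, phi, clustering."""

import math
import random

import numpy as np
import pytest

from conftest import clade_size
from udgx.coevolution import (
    ContingencyTable,
    chi_square_stat,
    cluster_tree,
    coevolution_matrix,
    consensus_phi,
    mutual_information,
    pair_contingency,
)
from udgx.conservation import column_profile, joint_entropy
from udgx.exceptions import InsufficientDataError
from udgx.msa import Msa
from udgx.simulate import MsaTruth, generate_msa


def msa_from_columns(*cols: str) -> Msa:
    n = len(cols[0])
    seqs = ["".join(c[i] for c in cols) for i in range(n)]
    return Msa(tuple(f"s{i}" for i in range(n)), tuple(seqs))


def random_pair_msa(rng: random.Random, n: int = 40) -> Msa:
    c1 = "".join(rng.choice("QARNH") for _ in range(n))
    c2 = "".join(rng.choice("KPWDE") for _ in range(n))
    return msa_from_columns(c1, c2)


class TestPairContingency:
    def test_toy_counts(self):
        msa = msa_from_columns("QQAA", "RRKK")
        t = pair_contingency(msa, 1, 2)
        assert t.residues_i == ("A", "Q") and t.residues_j == ("K", "R")
        assert t.counts.tolist() == [[2, 0], [0, 2]]
        assert t.n == 4

    def test_identical_columns_give_diagonal_table(self):
        msa = msa_from_columns("QQAR", "QQAR")
        t = pair_contingency(msa, 1, 2)
        assert np.count_nonzero(t.counts - np.diag(np.diag(t.counts))) == 0

    def test_disjoint_gap_patterns_raise(self):
        msa = msa_from_columns("Q-A-", "-R-K")
        with pytest.raises(InsufficientDataError):
            pair_contingency(msa, 1, 2)


class TestMutualInformation:
    def test_exact_product_table_is_zero(self):
        # counts = outer([2,4],[3,5]) -> exact independence
        t = ContingencyTable(("A", "Q"), ("K", "R"), np.array([[6, 10], [12, 20]]))
        assert mutual_information(t) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_coupled_two_state_table(self):
        t = ContingencyTable(("A", "Q"), ("K", "R"), np.array([[2, 0], [0, 2]]))
        assert mutual_information(t) == pytest.approx(1.0)

    def test_entropy_identity_oracle(self):
        # MI = H(i) + H(j) - H(i,j), the two sides computed independently
        rng = random.Random(7)
        for _ in range(100):
            msa = random_pair_msa(rng)
            mi = mutual_information(pair_contingency(msa, 1, 2))
            hi = column_profile(msa, 1).entropy_bits
            hj = column_profile(msa, 2).entropy_bits
            hij = joint_entropy(msa, 1, 2)
            assert mi == pytest.approx(hi + hj - hij, abs=1e-10)

    def test_symmetry_and_min_entropy_bound(self):
        rng = random.Random(8)
        for _ in range(50):
            msa = random_pair_msa(rng)
            mi_ij = mutual_information(pair_contingency(msa, 1, 2))
            mi_ji = mutual_information(pair_contingency(msa, 2, 1))
            assert mi_ij == pytest.approx(mi_ji, abs=1e-12)
            hi = column_profile(msa, 1).entropy_bits
            hj = column_profile(msa, 2).entropy_bits
            assert mi_ij <= min(hi, hj) + 1e-10

    def test_null_bias_shrinks_with_sample_size(self):
        # independent columns: finite-sample MI bias decreases as n grows
        means = []
        for n in (100, 1000):
            truth = MsaTruth(
                n_sequences=n, length=42, subfamily_fraction=1.0,
                signature_a={1: "Q"}, signature_b={1: "Q"}, seed=5,
            )
            msa, _ = generate_msa(truth)
            mis = [
                mutual_information(pair_contingency(msa, i, j))
                for i in range(2, 42) for j in range(i + 1, 42)
            ]
            means.append(sum(mis) / len(mis))
        assert means[1] < means[0]


class TestChiSquare:
    def test_product_table_is_zero(self):
        t = ContingencyTable(("A", "Q"), ("K", "R"), np.array([[6, 10], [12, 20]]))
        stat, dof = chi_square_stat(t)
        assert stat == pytest.approx(0.0, abs=1e-12) and dof == 1

    def test_diagonal_table_hand_computed(self):
        t = ContingencyTable(("A", "Q"), ("K", "R"), np.array([[10, 0], [0, 10]]))
        assert chi_square_stat(t) == (pytest.approx(20.0), 1)

    def test_label_permutation_invariance(self):
        c = np.array([[5, 1, 2], [0, 7, 3]])
        t1 = ContingencyTable(("A", "Q"), ("K", "R", "W"), c)
        t2 = ContingencyTable(("Q", "A"), ("W", "K", "R"), c[::-1, [2, 0, 1]])
        assert chi_square_stat(t1)[0] == pytest.approx(chi_square_stat(t2)[0])

    def test_degenerate_single_row(self):
        t = ContingencyTable(("Q",), ("K", "R"), np.array([[3, 4]]))
        assert chi_square_stat(t) == (0.0, 0)


class TestConsensusPhi:
    def test_self_correlation_is_one(self):
        msa = msa_from_columns("QQQAA", "QQQAA")
        assert consensus_phi(msa, 1, 2) == pytest.approx(1.0)

    def test_anti_coupled_pair(self):
        # consensus at col 1 (Q) exactly when col 2 misses its consensus (K)
        msa = msa_from_columns("QQQAA", "RRSKK")
        assert consensus_phi(msa, 1, 2) == pytest.approx(-1.0)

    def test_zero_variance_indicator_is_nan(self):
        msa = msa_from_columns("QQQQ", "QARN")
        assert math.isnan(consensus_phi(msa, 1, 2))

    def test_independent_planted_columns_near_zero(self):
        truth = MsaTruth(
            n_sequences=2000, length=20, subfamily_fraction=1.0,
            signature_a={1: "Q"}, signature_b={1: "Q"}, seed=7,
        )
        msa, _ = generate_msa(truth)
        phis = [abs(consensus_phi(msa, i, j)) for i in range(2, 20) for j in range(i + 1, 20)]
        assert max(phis) < 0.1


class TestCoevolutionMatrix:
    def test_two_positions_symmetric(self, planted):
        msa, _, rm = planted
        m = coevolution_matrix(msa, rm, [53, 107], metric="mi")
        assert m.scores.shape == (2, 2)
        assert np.allclose(m.values, m.values.T)

    def test_diagonal_is_column_entropy_for_mi(self, planted):
        msa, _, rm = planted
        m = coevolution_matrix(msa, rm, [53, 107], metric="mi")
        h53 = column_profile(msa, rm.col_for(53)).entropy_bits
        assert m.scores.loc[53, 53] == pytest.approx(h53, abs=1e-10)

    def test_reordering_positions_permutes_matrix(self, planted):
        msa, _, rm = planted
        a = coevolution_matrix(msa, rm, [53, 107, 109], metric="mi")
        b = coevolution_matrix(msa, rm, [109, 53, 107], metric="mi")
        assert np.allclose(
            a.scores.loc[[53, 107, 109], [53, 107, 109]],
            b.scores.loc[[53, 107, 109], [53, 107, 109]],
        )

    def test_planted_coupling_beats_background(self, planted):
        msa, _, rm = planted
        positions = [53, 107, 109, 25, 140, 170]  # last three are background
        m = coevolution_matrix(msa, rm, positions, metric="mi")
        coupled = min(
            m.scores.loc[53, 107], m.scores.loc[53, 109], m.scores.loc[107, 109]
        )
        background = max(
            m.scores.loc[p, q]
            for p in (53, 107, 109) for q in (25, 140, 170)
        )
        assert coupled > background


class TestClusterTree:
    def test_coupled_trio_forms_clade(self, planted):
        msa, _, rm = planted
        m = coevolution_matrix(msa, rm, [53, 107, 109, 140], metric="mi")
        newick = cluster_tree(m)
        assert clade_size(newick, {"53", "107", "109"}) == 3

    def test_two_positions_single_cherry(self, planted):
        msa, _, rm = planted
        m = coevolution_matrix(msa, rm, [53, 107], metric="mi")
        newick = cluster_tree(m)
        assert newick.count("(") == 1 and "53" in newick and "107" in newick

    def test_identical_rows_join_at_zero_height(self):
        import pandas as pd

        from udgx.coevolution import CoevolutionMatrix

        s = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]],
            index=[1, 2, 3], columns=[1, 2, 3],
        )
        m = CoevolutionMatrix(metric="mi", positions=(1, 2, 3), scores=s)
        newick = cluster_tree(m)
        assert "(1:0,2:0)" in newick.replace(" ", "")

    def test_missing_entries_refuse_clustering(self):
        import pandas as pd

        from udgx.coevolution import CoevolutionMatrix

        s = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=[1, 2], columns=[1, 2]
        )
        m = CoevolutionMatrix(metric="mi", positions=(1, 2), scores=s)
        with pytest.raises(ValueError, match="missing"):
            cluster_tree(m)
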