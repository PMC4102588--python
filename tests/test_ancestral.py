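import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from norascan.ancestral import (
    ANCESTOR_ID,
    StarTree,
    estimate_branch_lengths,
    k2p_distance,
    k2p_transition_matrix,
    reconstruct_ancestor,
    three_point_branch_lengths,
)
from norascan.align import CodonAlignment

BASES = "ACGT"


def k2p_rate_matrix(kappa):
    """Independent oracle: explicit K2P generator, scaled to one expected
    substitution per unit time."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    ts = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    Q = np.zeros((4, 4))
    for i, x in enumerate(BASES):
        for j, y in enumerate(BASES):
            if i != j:
                Q[i, j] = alpha if (x, y) in ts else beta
        Q[i, i] = -Q[i].sum()
    return Q


class TestK2PMatrix:
    @pytest.mark.parametrize("t", [0.0, 0.05, 0.2, 1.0])
    @pytest.mark.parametrize("kappa", [0.5, 2.0, 10.0])
    def test_matches_matrix_exponential(self, t, kappa):
        M = k2p_transition_matrix(t, kappa)
        np.testing.assert_allclose(M, expm(k2p_rate_matrix(kappa) * t),
                                   atol=1e-12)

    def test_zero_length_is_identity(self):
        np.testing.assert_allclose(k2p_transition_matrix(0.0, 2.0), np.eye(4))

    def test_rows_sum_to_one(self):
        M = k2p_transition_matrix(0.37, 3.1)
        np.testing.assert_allclose(M.sum(axis=1), 1.0)


class TestK2PDistance:
    def test_zero_for_identical(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form(self):
        # 1 transition + 1 transversion in 10 sites: P=0.1, Q=0.1
        a = "AAAAAAAAAA"
        b = "GAAAAAAAAC"
        d = k2p_distance(a, b)
        P, Q = 0.1, 0.1
        expected = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
        assert d == pytest.approx(expected)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance("AAAA", "GGGG")


class TestThreePoint:
    @pytest.mark.parametrize(
        "d,expected",
        [
            ((0.2, 0.2, 0.2), (0.1, 0.1, 0.1)),
            ((0.3, 0.3, 0.4), (0.1, 0.2, 0.2)),
            ((0.0, 0.0, 0.0), (0.0, 0.0, 0.0)),
        ],
    )
    def test_formula(self, d, expected):
        assert three_point_branch_lengths(*d) == pytest.approx(expected)

    def test_clamped_at_zero(self):
        b = three_point_branch_lengths(0.1, 0.1, 0.5)
        assert b[0] == 0.0 and all(x >= 0 for x in b)

    def test_identical_rows_give_zero_lengths(self):
        codons = ["ATG", "GCT", "GGT", "AAA"]
        aln = CodonAlignment("g", {"a": codons, "b": codons, "c": codons})
        tree = estimate_branch_lengths(aln)
        assert tree.branch_lengths == (0.0, 0.0, 0.0)

    def test_no_gap_free_columns_is_error(self):
        aln = CodonAlignment("g", {"a": ["---"], "b": ["ATG"], "c": ["ATG"]})
        with pytest.raises(ValueError, match="gap-free"):
            estimate_branch_lengths(aln)

    def test_saturated_pair_named(self):
        aln = CodonAlignment(
            "g",
            {"a": ["AAA", "AAA"], "b": ["AAA", "AAA"], "c": ["GGG", "GGG"]},
        )
        with pytest.raises(ValueError, match="c"):
            estimate_branch_lengths(aln)


def column_alignment(col_a, col_b, col_c):
    """One codon column per tip, built from three codons."""
    return CodonAlignment("g", {"a": [col_a], "b": [col_b], "c": [col_c]})


def brute_force_column(tips, branch_lengths, kappa):
    """Likelihood of each root state for one nt column, by direct product."""
    mats = [k2p_transition_matrix(b, kappa) for b in branch_lengths]
    like = []
    for x in range(4):
        p = 1.0
        for M, tip in zip(mats, tips):
            if tip is not None:
                p *= M[x, BASES.index(tip)]
        like.append(p)
    return np.array(like)


class TestReconstruction:
    def test_unanimous_column(self):
        tree = StarTree(("a", "b", "c"), (0.1, 0.1, 0.1), 2.0)
        anc = reconstruct_ancestor(column_alignment("AAA", "AAA", "AAA"), tree)
        assert anc.states == "AAA"
        assert np.all(anc.support > 0.9)

    def test_two_to_one_column_against_brute_force(self):
        tree = StarTree(("a", "b", "c"), (0.1, 0.1, 0.1), 2.0)
        anc = reconstruct_ancestor(column_alignment("AAA", "AAA", "GAA"), tree)
        like = brute_force_column(("A", "A", "G"), tree.branch_lengths, 2.0)
        assert anc.states[0] == BASES[int(np.argmax(like))] == "A"
        assert anc.support[0] == pytest.approx(like.max() / like.sum(), abs=1e-12)

    def test_support_matches_brute_force_everywhere(self, rng):
        tree = StarTree(("a", "b", "c"), (0.3, 0.05, 0.17), 1.7)
        codons = [
            "".join(rng.choice(list(BASES), size=3)) for _ in range(4)
        ]
        aln = CodonAlignment(
            "g",
            {
                "a": codons,
                "b": ["".join(rng.choice(list(BASES), size=3)) for _ in range(4)],
                "c": codons[::-1],
            },
        )
        anc = reconstruct_ancestor(aln, tree)
        for i in range(12):
            tips = [aln.row_nt(t)[i] for t in ("a", "b", "c")]
            like = brute_force_column(tips, tree.branch_lengths, 1.7)
            assert anc.states[i] == BASES[int(np.argmax(like))]
            assert anc.support[i] == pytest.approx(
                like.max() / like.sum(), abs=1e-12
            )

    def test_majority_gap_column_is_gap(self):
        tree = StarTree(("a", "b", "c"), (0.1, 0.1, 0.1), 2.0)
        anc = reconstruct_ancestor(column_alignment("---", "---", "AAA"), tree)
        assert anc.states == "---"
        assert anc.codons == ["---"]

    def test_single_gap_reconstructed_from_present_tips(self):
        tree = StarTree(("a", "b", "c"), (0.1, 0.1, 0.1), 2.0)
        anc = reconstruct_ancestor(column_alignment("---", "GGG", "GGG"), tree)
        assert anc.states == "GGG"

    def test_zero_branch_lengths_give_strict_consensus(self):
        tree = StarTree(("a", "b", "c"), (0.0, 0.0, 0.0), 2.0)
        anc = reconstruct_ancestor(column_alignment("ACA", "ACA", "ACA"), tree)
        assert anc.states == "ACA"
        assert np.all(anc.support == 1.0)

    def test_tie_breaks_in_base_order(self):
        # equidistant tips make A and G exactly tied; A < G wins
        tree = StarTree(("a", "b", "c"), (0.1, 0.1, 0.1), 2.0)
        anc = reconstruct_ancestor(column_alignment("AAA", "GGG", "CCC"), tree)
        assert anc.states[0] == "A"

    def test_invariant_under_tip_permutation(self, rng):
        codons = {
            t: ["".join(rng.choice(list(BASES), size=3)) for _ in range(5)]
            for t in "abc"
        }
        bl = (0.2, 0.1, 0.3)
        tree = StarTree(("a", "b", "c"), bl, 2.0)
        anc1 = reconstruct_ancestor(CodonAlignment("g", dict(codons)), tree)
        order = ["c", "a", "b"]
        tree2 = StarTree(tuple(order), (bl[2], bl[0], bl[1]), 2.0)
        anc2 = reconstruct_ancestor(
            CodonAlignment("g", {t: codons[t] for t in order}), tree2
        )
        assert anc1.states == anc2.states
        np.testing.assert_allclose(anc1.support, anc2.support)

    def test_stop_codon_mask(self):
        tree = StarTree(("a", "b", "c"), (0.0, 0.0, 0.0), 2.0)
        anc = reconstruct_ancestor(column_alignment("TAA", "TAA", "TAA"), tree)
        assert list(anc.stop_codon_mask) == [True]
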