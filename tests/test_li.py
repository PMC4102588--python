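import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from norascan import li
from norascan.codons import SENSE_CODONS

from conftest import ancestor_from_codons, make_alignment


# --- independent oracle ----------------------------------------------------
# A from-scratch implementation of the counting rules, deliberately written
# against Biopython's translation rather than the package's code tables.

STOPS = {"TAA", "TAG", "TGA"}
TS_PAIRS = {frozenset("AG"), frozenset("CT")}


def aa(codon):
    return str(Seq(codon).translate())


def oracle_degeneracy(codon):
    classes = []
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOPS and aa(mut) == aa(codon):
                syn += 1
        classes.append({0: 0, 1: 2, 2: 2, 3: 4}[syn])
    return tuple(classes)


def oracle_pair(a, b):
    """Pathway-averaged per-class increments, enumerated over orderings."""
    idx = {0: 0, 2: 1, 4: 2}
    sites = np.zeros(3)
    for pos in range(3):
        sites[idx[oracle_degeneracy(a)[pos]]] += 0.5
        sites[idx[oracle_degeneracy(b)[pos]]] += 0.5
    diffs = [p for p in range(3) if a[p] != b[p]]
    per_order = []
    for order in itertools.permutations(diffs):
        current = a
        ts = np.zeros(3)
        tv = np.zeros(3)
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            kind = ts if frozenset((current[pos], b[pos])) in TS_PAIRS else tv
            kind[idx[oracle_degeneracy(a)[pos]]] += 0.5
            kind[idx[oracle_degeneracy(b)[pos]]] += 0.5
            current = nxt
        if not blocked:
            per_order.append((ts, tv))
    if diffs and not per_order:
        return None  # pair skipped: all orderings pass through a stop
    if not diffs:
        per_order = [(np.zeros(3), np.zeros(3))]
    ts = np.mean([o[0] for o in per_order], axis=0)
    tv = np.mean([o[1] for o in per_order], axis=0)
    return sites, ts, tv


class TestSiteClasses:
    @pytest.mark.parametrize(
        "codon,expected",
        [("GGG", (0, 0, 4)), ("TTT", (0, 0, 2)), ("ATT", (0, 0, 2))],
    )
    def test_known_profiles_match_enumeration(self, codon, expected):
        assert oracle_degeneracy(codon) == expected  # oracle sanity
        assert li.classify_sites(codon) == expected

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            li.classify_sites("TAA")

    def test_all_sense_codons_match_oracle(self):
        for codon in SENSE_CODONS:
            assert li.classify_sites(codon) == oracle_degeneracy(codon)

    def test_profiles_sum_to_three_sites(self):
        for codon in SENSE_CODONS:
            sites = li.count_codon_pair(codon, codon).sites
            assert sites.sum() == pytest.approx(3.0)


class TestPairCounting:
    def test_single_transition_at_fourfold_site(self):
        pc = li.count_codon_pair("GGA", "GGG")
        np.testing.assert_allclose(pc.transitions, [0, 0, 1])
        np.testing.assert_allclose(pc.transversions, [0, 0, 0])

    def test_single_transversion_at_twofold_site(self):
        pc = li.count_codon_pair("TTT", "TTA")
        np.testing.assert_allclose(pc.transversions, [0, 1, 0])
        np.testing.assert_allclose(pc.transitions, [0, 0, 0])

    def test_identical_codons_contribute_sites_only(self):
        pc = li.count_codon_pair("TTT", "TTT")
        assert pc.transitions.sum() == 0 and pc.transversions.sum() == 0
        assert pc.sites.sum() == pytest.approx(3.0)

    def test_split_weight_when_classes_differ(self):
        # AAA pos3 is twofold, ACA pos3 is fourfold; the changed position
        # is pos2 (0-fold in both), so L splits only at pos3
        pc = li.count_codon_pair("AAA", "ACA")
        np.testing.assert_allclose(pc.sites, [2.0, 0.5, 0.5])
        np.testing.assert_allclose(pc.transversions, [1.0, 0, 0])


class TestK2PCorrection:
    def test_zero_divergence(self):
        assert li.k2p_correct(0.0, 0.0) == (0.0, 0.0)

    def test_closed_form_evaluation(self):
        A, B = li.k2p_correct(0.2, 0.1)
        # independent direct evaluation
        expected_A = 0.5 * math.log(1 / (1 - 0.4 - 0.1)) - 0.25 * math.log(1 / 0.8)
        expected_B = 0.5 * math.log(1 / 0.8)
        assert A == pytest.approx(expected_A, abs=1e-12)
        assert B == pytest.approx(expected_B, abs=1e-12)

    def test_saturation(self):
        with pytest.raises(li.SaturationError):
            li.k2p_correct(0.5, 0.1)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            li.k2p_correct(0.7, 0.5)


class TestKaKs:
    def test_identical_sequences(self):
        est = li.estimate_pair(["ATG", "GCT"] * 10, ["ATG", "GCT"] * 10)
        assert est.valid
        assert est.ka == 0.0 and est.ks == 0.0

    def test_single_nonsynonymous_transversion_straight_line(self):
        """100-codon pair, one A->C transversion at a nondegenerate site;
        expected Ka written out from the formulas by hand."""
        a = ["AAA"] * 100
        b = ["ACA"] + ["AAA"] * 99
        est = li.estimate_pair(a, b)
        # straight-line arithmetic: AAA profile (0,0,2), ACA profile (0,0,4)
        L0 = 2 * 100  # pos1+pos2 nondegenerate in every pair
        L2 = 99 + 0.5
        L4 = 0.5
        Q0 = 1.0 / L0
        B0 = 0.5 * math.log(1 / (1 - 2 * Q0))
        A0 = 0.5 * math.log(1 / (1 - Q0)) - 0.25 * math.log(1 / (1 - 2 * Q0))
        expected_ka = A0 + (L0 * B0 + L2 * 0.0) / (L0 + L2)
        np.testing.assert_allclose(est.counts.sites, [L0, L2, L4])
        assert est.ka == pytest.approx(expected_ka, abs=1e-12)
        assert est.ks == 0.0
        assert est.valid

    def test_all_gap_overlap_invalid(self, as_ancestor):
        aln = make_alignment({"a": ["---", "---"], "b": ["ATG", "GCT"],
                              "c": ["ATG", "GCT"]})
        est = li.branch_ka(aln, ancestor_from_codons(["ATG", "GCT"]), "a")
        assert not est.valid
        assert "no comparable codons" in est.invalid_reason

    def test_symmetric_in_the_two_sequences(self, rng):
        for _ in range(25):
            n = 40
            a = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            b = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            ab = li.estimate_pair(a, b)
            ba = li.estimate_pair(b, a)
            if ab.valid:
                assert ab.ka == pytest.approx(ba.ka, abs=1e-12)
                assert ab.ks == pytest.approx(ba.ks, abs=1e-12)

    def test_saturated_estimate_flagged_not_clipped(self):
        # every codon pair differs by a transversion at its nondegenerate
        # positions: P/Q blow past the K2P ceiling
        a = ["AAA"] * 30
        b = ["CCC"] * 30
        est = li.estimate_pair(a, b)
        assert not est.valid
        assert math.isnan(est.ka) or math.isnan(est.ks)


class TestOracleEquivalence:
    def test_all_pairs_match_brute_force(self):
        """Pathway-averaged counts equal independent enumeration for all
        61 x 61 sense-codon pairs, including which pairs are skipped."""
        stats, ok = li.pair_tables()
        for i, a in enumerate(SENSE_CODONS):
            for j, b in enumerate(SENSE_CODONS):
                expected = oracle_pair(a, b)
                if expected is None:
                    assert not ok[i, j]
                    continue
                assert ok[i, j]
                sites, ts, tv = expected
                np.testing.assert_allclose(stats[i, j, 0:3], sites, atol=1e-12)
                np.testing.assert_allclose(stats[i, j, 3:6], ts, atol=1e-12)
                np.testing.assert_allclose(stats[i, j, 6:9], tv, atol=1e-12)

    def test_site_count_conservation_random_alignments(self, rng):
        """L0+L2+L4 == 3 x codons on random gap-free codon alignments."""
        for _ in range(200):
            n = int(rng.integers(5, 40))
            a = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            b = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
            est = li.estimate_pair(a, b)
            total = est.counts.sites.sum() + 3 * est.counts.n_skipped
            assert total == pytest.approx(3 * n)


class TestBranchKa:
    def test_tip_identical_to_ancestor(self, as_ancestor):
        codons = ["ATG", "GCT", "GGT", "AAA"]
        aln = make_alignment({"a": codons, "b": codons, "c": codons})
        est = li.branch_ka(aln, as_ancestor(codons), "a")
        assert est.ka == 0.0

    def test_window_equals_excised_subalignment(self, rng, as_ancestor):
        n = 60
        anc = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
        tip = list(anc)
        for i in rng.integers(0, n, 12):
            tip[i] = SENSE_CODONS[rng.integers(0, 61)]
        aln = make_alignment({"a": tip, "b": anc, "c": anc})
        full = li.branch_ka(aln, as_ancestor(anc), "a", codon_range=(11, 40))
        sub = li.branch_ka(
            aln.subset((11, 40)), as_ancestor(anc[10:40]), "a"
        )
        assert full.ka == pytest.approx(sub.ka, abs=1e-15, nan_ok=True)
        np.testing.assert_allclose(full.counts.sites, sub.counts.sites)

    def test_gap_only_range_invalid(self, as_ancestor):
        aln = make_alignment(
            {"a": ["---", "ATG"], "b": ["GCT", "ATG"], "c": ["GCT", "ATG"]}
        )
        est = li.branch_ka(aln, as_ancestor(["GCT", "ATG"]), "a",
                           codon_range=(1, 1))
        assert not est.valid

    def test_vectorised_path_matches_scalar(self, rng, as_ancestor):
        """ka_from_sums over summed column stats reproduces compute_ka_ks."""
        n = 80
        anc = [SENSE_CODONS[i] for i in rng.integers(0, 61, n)]
        tip = [
            SENSE_CODONS[rng.integers(0, 61)] if rng.random() < 0.3 else c
            for c in anc
        ]
        stats, usable = li.column_stats(
            li.encode_codons(tip), li.encode_codons(anc)
        )
        ka_vec, ks_vec = li.ka_ks_from_sums(stats.sum(axis=0))
        aln = make_alignment({"a": tip, "b": anc, "c": anc})
        est = li.branch_ka(aln, as_ancestor(anc), "a")
        assert float(ka_vec) == pytest.approx(est.ka, abs=1e-12, nan_ok=True)
        assert float(ks_vec) == pytest.approx(est.ks, abs=1e-12, nan_ok=True)


class TestSelectionResponse:
    def test_mean_ka_monotone_in_omega(self):
        """On simulated branches, mean Ka increases with the acceptance
        ratio omega at fixed branch length."""
        from norascan.simulate import SimConfig, simulate

        means = []
        for omega in (0.0, 0.1, 0.5, 1.0):
            kas = []
            for seed in range(5):
                s = simulate(
                    SimConfig(n_codons=300, branch_lengths=(0.3, 0.3, 0.3),
                              omega_background=omega, seed=500 + seed)
                )
                for tip in s.config.tip_ids:
                    est = li.estimate_pair(s.tips[tip], s.root)
                    if est.valid:
                        kas.append(est.ka)
            means.append(np.mean(kas))
        assert all(x <= y for x, y in zip(means, means[1:]))
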