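"""K2P distances, rank stratification, nucleotide diversity and Ka/Ks."""

import math
from itertools import product

import numpy as np
import pytest

from conftest import random_block
from mitocomp import divergence as dv
from mitocomp.genetic_code import get_code
from mitocomp.genome_io import AlignmentBlock, Taxonomy
from mitocomp.synthetic_data import (GenePlan, SimulationConfig,
                                     simulate_set)

CODE5 = get_code(5)


class TestK2P:
    def test_identical(self):
        r = dv.k2p("ACGT", "ACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_transition_worked_value(self):
        r = dv.k2p("AAAA", "AGAA")
        assert r.P == 0.25 and r.Q == 0.0
        assert r.d == pytest.approx(-0.5 * math.log(0.5), rel=1e-12)

    def test_transversion_worked_value(self):
        r = dv.k2p("AAAA", "ACAA")
        assert r.P == 0.0 and r.Q == 0.25
        assert r.d == pytest.approx(
            -0.5 * math.log(0.75) - 0.25 * math.log(0.5), rel=1e-12)

    def test_pairwise_deletion(self):
        r = dv.k2p("A-GTN", "AAGTC")
        assert r.sites_compared == 3
        assert r.d == 0.0

    def test_saturation_sentinel(self):
        r = dv.k2p("AAAA", "GGGG")
        assert r.saturated and math.isnan(r.d)

    def test_no_comparable_sites(self):
        r = dv.k2p("NN", "AC")
        assert r.sites_compared == 0 and math.isnan(r.d)

    @pytest.mark.parametrize("seed", range(5))
    def test_k2p_at_least_p_distance(self, seed):
        rng = np.random.default_rng(seed)
        blk = random_block(rng, n_samples=2, n_sites=300)
        a, b = blk.matrix
        d = dv.k2p(a, b).d
        if not math.isnan(d):
            assert d >= dv.p_distance(a, b) - 1e-12

    def test_matches_jc_under_equal_rates(self):
        # kappa = 1 with uniform frequencies is the JC process; K2P's two
        # parameters then add nothing and the two corrections agree in
        # expectation
        tax = {"A": Taxonomy("s", "t", "g", "sp", "A"),
               "B": Taxonomy("s", "t", "g", "sp", "B")}
        diffs = []
        for rep in range(8):
            cfg = SimulationConfig(
                tree="(A:0.08,B:0.08);", seed=300 + rep,
                gene_plan=[GenePlan("rrnS", "rRNA", 8000, 1.0)],
                taxonomy=tax, base_freqs=(0.25,) * 4, kappa=1.0)
            blk = simulate_set(cfg).blocks["rrnS"]
            a, b = blk.matrix
            k2p_d = dv.k2p(a, b).d
            p = dv.p_distance(a, b)
            jc_d = -0.75 * math.log(1 - 4 * p / 3)
            diffs.append(k2p_d - jc_d)
        assert abs(np.mean(diffs)) < 3 * np.std(diffs, ddof=1)


class TestPairwiseMatrix:
    def test_identical_rows_zero(self):
        blk = AlignmentBlock("g", ["a", "b"],
                             np.array([list("ACGT"), list("ACGT")]))
        m = dv.pairwise_matrix(blk)
        assert np.all(m.values == 0)

    def test_matches_per_pair_oracle(self):
        rng = np.random.default_rng(9)
        blk = random_block(rng, n_samples=5, n_sites=200)
        m = dv.pairwise_matrix(blk)
        for i, j in product(range(5), range(5)):
            if i == j:
                continue
            expected = dv.k2p(blk.matrix[i], blk.matrix[j]).d
            assert m.values[i, j] == pytest.approx(expected, nan_ok=True)

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        blk = random_block(rng, n_samples=6, n_sites=150, gap_frac=0.05)
        m = dv.pairwise_matrix(blk)
        assert np.allclose(m.values, m.values.T, equal_nan=True)


class TestRankStratification:
    def _tax(self, sf, tr, g, sp, ind):
        return Taxonomy(sf, tr, g, sp, ind)

    def test_conspecific_pair(self):
        tax = {"a": self._tax("S", "T", "G", "sp1", "a"),
               "b": self._tax("S", "T", "G", "sp1", "b")}
        m = dv.DistanceMatrix("g", ["a", "b"],
                              np.array([[0, 0.001], [0.001, 0]]))
        out = dv.rank_mean_distances(m, tax)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["rank_category"] == "within_species"
        assert row["mean_distance"] == pytest.approx(0.001)
        assert row["n_pairs"] == 1

    def test_congeneric_mean(self):
        tax = {c: self._tax("S", "T", "G", f"sp_{c}", c) for c in "abc"}
        vals = np.array([[0, 0.06, 0.08], [0.06, 0, 0.10],
                         [0.08, 0.10, 0]])
        out = dv.rank_mean_distances(
            dv.DistanceMatrix("g", ["a", "b", "c"], vals), tax)
        row = out.iloc[0]
        assert row["rank_category"] == "among_species_within_genus"
        assert row["mean_distance"] == pytest.approx(0.08)
        assert row["n_pairs"] == 3

    def test_categories_partition_pairs(self, study_sim):
        tax = study_sim.config.taxonomy
        blk = study_sim.blocks["cox1"]
        m = dv.pairwise_matrix(blk)
        out = dv.rank_mean_distances(m, tax)
        n = len(blk.samples)
        assert out["n_pairs"].sum() + out["n_saturated"].sum() == \
            n * (n - 1) // 2

    def test_saturated_pairs_excluded_not_propagated(self):
        tax = {c: self._tax("S", "T", "G", f"sp_{c}", c) for c in "abc"}
        vals = np.array([[0, 0.06, np.nan], [0.06, 0, 0.10],
                         [np.nan, 0.10, 0]])
        out = dv.rank_mean_distances(
            dv.DistanceMatrix("g", ["a", "b", "c"], vals), tax)
        row = out.iloc[0]
        assert row["mean_distance"] == pytest.approx(0.08)
        assert row["n_saturated"] == 1


class TestNucleotideDiversity:
    def test_two_rows(self):
        m = np.array([list("A" * 100), list("A" * 95 + "C" * 5)])
        blk = AlignmentBlock("g", ["a", "b"], m)
        assert dv.nucleotide_diversity(blk) == pytest.approx(0.05)

    def test_three_rows_mean_over_pairs(self):
        # pairwise p-distances 0.1, 0.2, 0.3 -> pi = 0.2
        L = 100
        a = "A" * L
        b = "C" * 10 + "A" * 90              # d(a,b)=0.1
        c = "G" * 20 + "A" * 70 + "C" * 10   # d(a,c)=0.3, d(b,c)=0.2? no:
        # b vs c: 10 C/G + 10 A/G + 10 A/C -> 30 diffs; adjust c
        c = "C" * 10 + "G" * 20 + "A" * 70   # d(a,c)=0.3, d(b,c)=0.2
        blk = AlignmentBlock("g", ["a", "b", "c"],
                             np.array([list(a), list(b), list(c)]))
        assert dv.nucleotide_diversity(blk) == pytest.approx(0.2)

    def test_complete_deletion(self):
        m = np.array([list("AC-T"), list("ACNT"), list("GCAT")])
        blk = AlignmentBlock("g", ["a", "b", "c"], m)
        # columns 3 and 4 dropped (gap, N); diffs only in column 1
        assert dv.nucleotide_diversity(blk) == pytest.approx((2 / 3) / 3)

    def test_window_count(self):
        rng = np.random.default_rng(2)
        blk = random_block(rng, n_samples=3, n_sites=350)
        prof = dv.sliding_pi(blk)
        assert prof.pi_values.size == (350 - 300) // 25 + 1 == 3

    def test_short_gene_genewide_only(self):
        rng = np.random.default_rng(2)
        blk = random_block(rng, n_samples=3, n_sites=100)
        prof = dv.sliding_pi(blk)
        assert prof.pi_values.size == 0
        assert not math.isnan(prof.mean_pi)

    def test_windows_average_to_genewide(self):
        rng = np.random.default_rng(4)
        blk = random_block(rng, n_samples=4, n_sites=2400)
        prof = dv.sliding_pi(blk, window=300, step=25)
        assert np.mean(prof.pi_values) == pytest.approx(prof.mean_pi,
                                                        rel=0.02)


class TestNeiGojobori:
    def test_identical(self):
        r = dv.nei_gojobori("TTTAAA", "TTTAAA", CODE5)
        assert r.Ka == 0 and r.Ks == 0

    def test_ttt_synonymous_sites_against_enumeration(self):
        # exhaustive single-mutation enumeration: of the 9 mutants of TTT
        # only TTC is synonymous (Phe), none are stops
        syn = viable = 0
        for pos in range(3):
            for b in "ACGT":
                if b == "TTT"[pos]:
                    continue
                mut = "TTT"[:pos] + b + "TTT"[pos + 1:]
                if mut in CODE5.stop_codons:
                    continue
                viable += 1
                syn += CODE5.forward[mut] == "F"
        assert syn == 1 and viable == 9
        assert dv.syn_site_fraction("TTT", CODE5) == pytest.approx(1 / 3)

    def test_fourfold_enumeration(self):
        # GGA (Gly): all three third-position mutations synonymous
        assert dv.syn_site_fraction("GGA", CODE5) == pytest.approx(1.0)

    def test_synonymous_only_pair(self):
        # CTT/GGA vs CTT/GGG: one third-position synonymous change,
        # S = 2 (both codons four-fold at position 3), so ps = 0.5
        r = dv.nei_gojobori("CTTGGA", "CTTGGG", CODE5)
        assert r.Ka == 0.0
        assert r.Ks == pytest.approx(-0.75 * math.log(1 - 4 * 0.5 / 3))
        assert math.isnan(r.ratio) is False

    def test_nonsynonymous_only_pair(self):
        r = dv.nei_gojobori("TTTAAA", "TTTGAA", CODE5)  # Lys -> Glu
        assert r.Ks == 0.0 and r.Ka > 0

    def test_site_counts_sum(self):
        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        a = "".join(bases[rng.integers(0, 4, 90)])
        b = "".join(bases[rng.integers(0, 4, 90)])
        r = dv.nei_gojobori(a, b, CODE5)
        assert r.S + r.N == pytest.approx(3 * r.codons_compared)

    def test_pathway_averaging_two_differences(self):
        # TTA (Leu) vs CTG (Leu): both paths pass through Leu codons, so
        # both steps are synonymous on every path
        sd, nd = dv._pathway_counts("TTA", "CTG", CODE5)
        assert sd == pytest.approx(2.0)
        assert nd == pytest.approx(0.0)

    def test_gapped_codons_skipped(self):
        r = dv.nei_gojobori("TTT-AA", "TTTGAA", CODE5)
        assert r.codons_compared == 1
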