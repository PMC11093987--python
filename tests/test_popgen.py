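"""Diversity statistics: pi, theta_W, Tajima's D, NG86 piN/piS, domains, windows, tails."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from nlrkit.io import Alignment, HaplotypeMatrix, SequenceRecord
from nlrkit.popgen import (
    _codon_pair_differences,
    _codon_site_fractions,
    balancing_selection_flags,
    diversity_stats,
    domain_columns,
    domain_stats,
    empirical_tail_flags,
    expected_window_count,
    nucleotide_diversity,
    pin_pis,
    sliding_window_stats,
    stats_from_vcf_gene,
    tajima_constants,
    tajimas_d,
)


def _aln(*seqs):
    return Alignment(
        [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)],
        alphabet="nucleotide",
    )


class TestBasicDiversity:
    def test_one_difference_in_100_sites(self):
        st = nucleotide_diversity(_aln("A" * 100, "A" * 99 + "T"))
        assert st.pi_per_site == pytest.approx(0.01)

    def test_identical_sequences(self):
        st = diversity_stats(_aln("ACGT", "ACGT"))
        assert st.pi_total == 0 and st.S == 0 and math.isnan(st.tajimas_d)

    def test_three_sequence_hand_enumeration(self, three_seq_alignment):
        # pairs: (a,b)=1, (a,c)=2, (b,c)=1 -> pi_total = 4/3; S=2, a1=1.5
        st = diversity_stats(three_seq_alignment)
        assert st.pi_total == pytest.approx(4 / 3)
        assert st.S == 2
        assert st.theta_w_total == pytest.approx(4 / 3)
        assert st.tajimas_d == 0.0  # numerator vanishes exactly

    def test_n2_closed_form(self):
        st = diversity_stats(_aln("AAAA", "ATAT"))
        assert st.constants.a1 == 1.0
        assert st.theta_w_total == st.S == 2
        assert st.pi_total == st.S  # n=2 gap-free identity

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            diversity_stats(Alignment([SequenceRecord("a", "ACGT")], alphabet="nucleotide"))

    def test_gap_columns_do_not_segregate(self):
        st = diversity_stats(_aln("A-GT", "AAGT", "ANGT"))
        assert st.S == 0  # one real allele + gap/N is not segregating
        assert st.pi_total == 0.0

    def test_order_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(6)]
        a = diversity_stats(_aln(*seqs))
        order = rng.permutation(6)
        b = diversity_stats(_aln(*[seqs[i] for i in order]))
        assert a.pi_total == pytest.approx(b.pi_total)
        assert a.S == b.S


class TestTajimasD:
    def test_hand_evaluated_constants_n4(self):
        c = tajima_constants(4)
        assert c.a1 == pytest.approx(11 / 6, abs=1e-12)
        assert c.a2 == pytest.approx(49 / 36, abs=1e-12)
        assert c.e1 * 2 + c.e2 * 2 * 1 == pytest.approx(0.016400, abs=5e-5)

    def test_two_singletons_worked_example(self):
        h = HaplotypeMatrix(
            matrix=np.array([[1, 0], [0, 1], [0, 0], [0, 0]]),
            positions=[3, 7],
            sample_ids=list("abcd"),
        )
        st = tajimas_d(h, L=10)
        assert st.pi_total == pytest.approx(1.0)
        assert st.tajimas_d == pytest.approx(-0.710, abs=1e-3)

    def test_monomorphic_undefined_not_zero(self):
        st = diversity_stats(_aln("ACGT", "ACGT", "ACGT", "ACGT"))
        assert math.isnan(st.tajimas_d) and not st.d_defined

    def test_n2_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            tajimas_d(_aln("AAAA", "ATAT"))


class TestNeiGojobori:
    def test_site_fractions_match_brute_enumeration(self):
        # independent recount straight from the standard table via Bio.Seq
        for codon in ("TTT", "ATG", "CGA", "GGG", "TGG", "ATT"):
            aa = str(Seq(codon).translate())
            syn = 0.0
            for pos in range(3):
                changes = []
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    alt_aa = str(Seq(codon[:pos] + b + codon[pos + 1:]).translate())
                    if alt_aa != "*":
                        changes.append(alt_aa == aa)
                if changes:
                    syn += sum(changes) / len(changes)
            got_syn, got_nonsyn = _codon_site_fractions(codon)
            assert got_syn == pytest.approx(syn, abs=1e-12)
            assert got_syn + got_nonsyn == pytest.approx(3.0)

    def test_single_synonymous_difference_pair(self):
        cd = pin_pis(Alignment([SequenceRecord("a", "TTT"), SequenceRecord("b", "TTC")],
                               alphabet="codon"))
        assert cd.pi_n == 0.0
        assert cd.syn_sites == pytest.approx(1 / 3)
        assert cd.pi_s == pytest.approx(3.0)

    def test_identical_sequences_undefined_ratio(self):
        cd = pin_pis(Alignment([SequenceRecord("a", "ATGAAA"), SequenceRecord("b", "ATGAAA")],
                               alphabet="codon"))
        assert cd.pi_n == cd.pi_s == 0.0 and math.isnan(cd.ratio)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            pin_pis(Alignment([SequenceRecord("a", "TAAAAA"), SequenceRecord("b", "TATAAA")],
                              alphabet="codon"))

    def test_gap_codon_pairs_skipped_and_counted(self):
        cd = pin_pis(Alignment(
            [SequenceRecord("a", "TTT---AAA"), SequenceRecord("b", "TTCCCGAAA")],
            alphabet="codon"))
        assert cd.n_skipped_codon_pairs == 1

    def test_pathway_averaging_two_step_pair(self):
        # TTT (Phe) vs GTA (Val): pathways TTT->GTT(Val)->GTA(Val) has
        # nonsyn+syn; TTT->TTA(Leu)->GTA(Val) has nonsyn+nonsyn; average
        # Sd=0.5, Nd=1.5
        sd, nd = _codon_pair_differences("TTT", "GTA")
        assert sd == pytest.approx(0.5) and nd == pytest.approx(1.5)

    def test_omega_zero_clades_have_zero_pin(self, rng):
        from nlrkit.simulate import simulate_codon_clade

        for _ in range(20):
            caln, _ = simulate_codon_clade(8, 5.0, 0.0, 60, seed=rng)
            assert pin_pis(caln).pi_n == 0.0


class TestDomains:
    def _aln3(self):
        return _aln("AAATTTGGG", "AAATTTGGG", "AAATTTGGC")

    def test_unanimous_vote(self):
        aln = self._aln3()
        iv = {f"s{i}": [(1, 9, "NBARC")] for i in range(3)}
        dmap = domain_columns(aln, iv)
        assert dmap.column_labels == ["NBARC"] * 9

    def test_plurality_beats_none(self):
        aln = self._aln3()
        iv = {"s0": [(1, 9, "LRR")], "s1": [(1, 9, "LRR")]}  # s2 votes none
        dmap = domain_columns(aln, iv)
        assert dmap.column_labels == ["LRR"] * 9

    def test_tie_gives_none(self):
        aln = _aln("AAAA", "AAAA")
        iv = {"s0": [(1, 4, "CC")], "s1": [(1, 4, "LRR")]}
        assert domain_columns(aln, iv).column_labels == ["none"] * 4

    def test_staggered_fixture_hand_vote(self):
        aln = _aln("AAATTT", "AAATTT", "AAATTT", "AAATTT", "AAATTT")
        iv = {
            "s0": [(1, 3, "CC"), (4, 6, "NBARC")],
            "s1": [(1, 3, "CC"), (4, 6, "NBARC")],
            "s2": [(1, 4, "CC"), (5, 6, "NBARC")],
            "s3": [(1, 2, "CC"), (3, 6, "NBARC")],
            "s4": [(1, 3, "CC")],
        }
        # col 3: CC x4, NBARC x1 -> CC; col 4: NBARC x3, CC x1, none x1 -> NBARC
        labels = domain_columns(aln, iv).column_labels
        assert labels == ["CC", "CC", "CC", "NBARC", "NBARC", "NBARC"]

    def test_interval_beyond_length_rejected(self):
        aln = _aln("AAA", "AAA")
        with pytest.raises(ValueError, match="beyond"):
            domain_columns(aln, {"s0": [(1, 5, "CC")]})

    def test_domain_partition_reproduces_genewide_S(self, rng):
        from nlrkit.simulate import simulate_codon_clade

        caln, _ = simulate_codon_clade(8, 30.0, 0.7, 50, seed=rng, infinite_sites=False)
        iv = [(1, 60, "CC"), (61, 100, "NBARC"), (101, 150, "LRR")]
        dmap = domain_columns(caln, {r.id: iv for r in caln.records})
        ds = domain_stats(caln, dmap)
        assert ds["S"].sum() == diversity_stats(caln).S
        assert ds["L"].sum() == caln.length


class TestWindows:
    def _gene(self, L, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(4)]
        return _aln(*seqs)

    def test_exact_fit_single_window(self, rng):
        tr = sliding_window_stats(self._gene(300, rng), "s0", "pi")
        assert len(tr) == 1
        assert tr.table.loc[0, "midpoint"] == 150

    def test_two_windows_at_length_375(self, rng):
        tr = sliding_window_stats(self._gene(375, rng), "s0", "pi")
        assert tr.table["start"].tolist() == [1, 76]

    @pytest.mark.parametrize("L", [299, 300, 374, 375, 1000, 2000])
    def test_window_count_formula(self, L, rng):
        tr = sliding_window_stats(self._gene(max(L, 10), rng), "s0", "pi")
        assert len(tr) == expected_window_count(L if L >= 300 else L)

    def test_window_values_match_slice_recompute(self, rng):
        aln = self._gene(600, rng)
        tr = sliding_window_stats(aln, "s0", "pi")
        for _, row in tr.table.iterrows():
            s, e = int(row["start"]), int(row["end"])
            sub = _aln(*[r.seq[s - 1 : e] for r in aln.records])
            assert row["value"] == pytest.approx(
                diversity_stats(sub).pi_per_site, abs=1e-12
            )

    def test_short_cds_gives_empty_track(self, rng):
        tr = sliding_window_stats(self._gene(100, rng), "s0", "pi")
        assert len(tr) == 0


class TestVcfGeneStats:
    def test_zero_snps(self):
        h = HaplotypeMatrix(np.zeros((4, 0), dtype=np.int8), np.array([]), list("abcd"))
        st = stats_from_vcf_gene(h, cds_length=900)
        assert st.pi_per_site == 0.0 and not st.d_defined

    def test_single_snp_hand_pi(self):
        h = HaplotypeMatrix(np.array([[1], [1], [0], [0]]), [42], list("abcd"))
        st = stats_from_vcf_gene(h, cds_length=100)
        # 2*2 discordant pairs of 6 -> pi_total = 4/6
        assert st.pi_total == pytest.approx(4 / 6)
        assert st.pi_per_site == pytest.approx(4 / 600)

    def test_dual_path_equality_with_alignment(self, rng):
        from nlrkit.simulate import simulate_genealogy_haplotypes

        L = 500
        h, _ = simulate_genealogy_haplotypes(8, 4.0, L, seed=rng)
        # rebuild the same haplotypes as explicit sequences
        base = np.full((8, L), "A", dtype="U1")
        for j, pos in enumerate(h.positions):
            base[h.matrix[:, j] == 1, pos - 1] = "T"
        aln = _aln(*["".join(row) for row in base])
        a = stats_from_vcf_gene(h, cds_length=L)
        b = diversity_stats(aln)
        assert a.pi_total == pytest.approx(b.pi_total)
        assert a.S == b.S
        assert a.tajimas_d == pytest.approx(b.tajimas_d, nan_ok=True)


class TestEmpiricalTails:
    def test_background_1_to_100(self):
        bg = np.arange(1, 101, dtype=float)
        flags = empirical_tail_flags(pd.Series({"g": 99.0}), bg, "top5")
        assert bool(flags.flags["g"])

    def test_value_at_threshold_is_excluded(self):
        bg = np.arange(1, 101, dtype=float)
        thr = np.quantile(bg, 0.95)
        flags = empirical_tail_flags(pd.Series({"g": thr}), bg, "top5")
        assert not bool(flags.flags["g"])

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            empirical_tail_flags(pd.Series({"g": 1.0}), [], "top5")

    def test_joint_balancing_criterion_brute_force(self, rng):
        pi_bg = rng.normal(size=500)
        d_bg = rng.normal(size=500)
        genes = [f"g{i}" for i in range(10)]
        pi = pd.Series(rng.normal(size=10), index=genes)
        d = pd.Series(rng.normal(size=10), index=genes)
        # place exactly one gene in both tails
        pi["g3"] = pi_bg.max() + 1
        d["g3"] = d_bg.max() + 1
        pi["g5"] = pi_bg.max() + 1  # top pi only
        joint = balancing_selection_flags(pi, d, pi_bg, d_bg)
        expected = {
            g
            for g in genes
            if pi[g] > np.quantile(pi_bg, 0.95) and d[g] > np.quantile(d_bg, 0.95)
        }
        assert set(joint.index[joint]) == expected == {"g3"}
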