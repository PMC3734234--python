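import math
import warnings

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bacevol import evorate
from bacevol.genetics import CODONS, STOP_CODONS
from bacevol.io_core import GeneRecord
from oracles import global_alignment_oracle, ng86_oracle

SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


class TestAlignment:
    def test_identical_sequences_gapless(self):
        aln = evorate.align_proteins_global("MKVLW", "MKVLW")
        assert aln.a == aln.b == "MKVLW"
        assert aln.identity == 1.0 and aln.coverage == 1.0

    def test_single_residue_gap(self):
        aln = evorate.align_proteins_global("MKV", "MV")
        assert aln.a == "MKV"
        assert aln.b == "M-V"
        assert aln.identity == 1.0  # both aligned columns match
        assert aln.coverage == 1.0  # 2 aligned columns / len("MV")

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_enumeration_oracle(self, seed):
        blosum = substitution_matrices.load("BLOSUM62")
        rng = np.random.default_rng(seed)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(3):
            a = "".join(rng.choice(aas, int(rng.integers(2, 6))))
            b = "".join(rng.choice(aas, int(rng.integers(2, 6))))
            want = global_alignment_oracle(
                a, b, lambda x, y: blosum[x, y], 11.0, 1.0)
            assert evorate.alignment_score(a, b) == pytest.approx(want)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            evorate.align_proteins_global("", "MKV")


class TestReciprocalBestHits:
    def test_mutual_best_pair_retained(self):
        ab = {("a1", "b1"): 10.0, ("a1", "b2"): 5.0}
        ba = {("b1", "a1"): 10.0, ("b2", "a1"): 5.0}
        assert evorate.reciprocal_best_hits(ab, ba) == [("a1", "b1")]

    def test_non_mutual_pair_dropped(self):
        ab = {("a1", "b1"): 10.0}
        ba = {("b1", "a2"): 12.0, ("b1", "a1"): 10.0}
        assert evorate.reciprocal_best_hits(ab, ba) == []

    def test_tied_best_dropped(self):
        ab = {("a1", "b1"): 10.0, ("a1", "b2"): 10.0}
        ba = {("b1", "a1"): 10.0, ("b2", "a1"): 10.0}
        assert evorate.reciprocal_best_hits(ab, ba) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_argmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = 6, 7
        scores = rng.integers(0, 40, (n_a, n_b)).astype(float)
        ab = {(f"a{i}", f"b{j}"): scores[i, j]
              for i in range(n_a) for j in range(n_b)}
        ba = {(f"b{j}", f"a{i}"): scores[i, j]
              for i in range(n_a) for j in range(n_b)}
        got = evorate.reciprocal_best_hits(ab, ba)
        want = []
        for i in range(n_a):
            row = scores[i]
            col_best = np.flatnonzero(row == row.max())
            if len(col_best) != 1:
                continue
            j = col_best[0]
            row_best = np.flatnonzero(scores[:, j] == scores[:, j].max())
            if len(row_best) == 1 and row_best[0] == i:
                want.append((f"a{i}", f"b{j}"))
        assert got == sorted(want)


class TestFilterPair:
    def test_identity_threshold(self):
        keep, reasons = evorate.filter_pair(0.25, 0.9, 100, 100)
        assert not keep and reasons == ("identity",)

    def test_coverage_threshold(self):
        keep, reasons = evorate.filter_pair(0.5, 0.7, 100, 100)
        assert not keep and reasons == ("coverage",)

    def test_exactly_30_aa_dropped(self):
        keep, reasons = evorate.filter_pair(0.9, 0.9, 30, 100)
        assert not keep and "length" in reasons
        keep, _ = evorate.filter_pair(0.9, 0.9, 31, 31)
        assert keep

    def test_hgt_exclusion(self):
        keep, reasons = evorate.filter_pair(
            0.9, 0.9, 100, 100, "gX", "gY", hgt_exclusion={"gX"})
        assert not keep and reasons == ("hgt",)

    def test_evalue_only_when_supplied(self):
        keep, _ = evorate.filter_pair(0.9, 0.9, 100, 100)
        assert keep
        keep, reasons = evorate.filter_pair(0.9, 0.9, 100, 100, evalue=1e-3)
        assert not keep and reasons == ("evalue",)


class TestBacktranslate:
    def test_gapless_case_concatenates_codons(self):
        aln = evorate.align_proteins_global("MK", "MK")
        ca, cb = evorate.backtranslate(aln, "ATGAAA", "ATGAAG")
        assert ca == "ATGAAA" and cb == "ATGAAG"

    def test_gap_becomes_gap_codon(self):
        aln = evorate.align_proteins_global("MKV", "MV")
        ca, cb = evorate.backtranslate(aln, "ATGAAAGTG", "ATGGTG")
        assert ca == "ATGAAAGTG"
        assert cb == "ATG---GTG"

    def test_trailing_stop_codon_tolerated(self):
        aln = evorate.align_proteins_global("MK", "MK")
        ca, _ = evorate.backtranslate(aln, "ATGAAATAA", "ATGAAA")
        assert ca == "ATGAAA"

    def test_mismatch_raises_with_position(self):
        aln = evorate.align_proteins_global("MK", "MK")
        with pytest.raises(ValueError, match="residue 1"):
            evorate.backtranslate(aln, "ATGGTG", "ATGAAA")  # MV, not MK

    def test_round_trip_random_fixture(self):
        from bacevol.genetics import translate_cds
        rng = np.random.default_rng(1)
        codons_a = ["ATG"] + list(rng.choice(SENSE_CODONS, 20))
        codons_b = ["ATG"] + list(rng.choice(SENSE_CODONS, 18))
        cds_a, cds_b = "".join(codons_a), "".join(codons_b)
        aln = evorate.align_proteins_global(translate_cds(cds_a),
                                            translate_cds(cds_b))
        ca, cb = evorate.backtranslate(aln, cds_a, cds_b)
        # translating the back-translation reproduces the alignment rows
        def tr(codstr):
            return "".join("-" if codstr[i:i+3] == "---"
                           else translate_cds(codstr[i:i+3])
                           for i in range(0, len(codstr), 3))
        assert tr(ca) == aln.a
        assert tr(cb) == aln.b


class TestNG86:
    def test_identical_sequences_zero_rates(self):
        r = evorate.ka_ng86("ATGAAACGT", "ATGAAACGT")
        assert r.ka == 0.0 and r.ks == 0.0

    def test_synonymous_only_difference(self):
        r = evorate.ka_ng86("TTT", "TTC")
        assert r.pn == 0.0 and r.ka == 0.0
        assert r.ps > 0  # the single difference is synonymous
        assert "saturated_ks" in r.flags  # one codon: ps = 3 saturates JC

    def test_nonsynonymous_only_difference(self):
        # AAA (Lys) vs AGA (Arg): one nonsynonymous difference
        r = evorate.ka_ng86("AAA", "AGA")
        pn, ps, N, S = ng86_oracle(["AAA"], ["AGA"])
        assert r.pn == pytest.approx(pn)
        assert r.ps == pytest.approx(ps) == 0.0
        assert r.ks == 0.0
        assert r.ka == pytest.approx(-0.75 * math.log(1 - 4 * pn / 3))

    def test_site_fractions_sum_to_three_without_stop_adjacency(self):
        # codons whose single-nucleotide neighbours include no stop codon
        for codon in ("TTT", "GGG", "CCC", "CTG"):
            s, n = evorate._codon_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_stop_adjacent_codon_total_reduced(self):
        # TGG (Trp): TGA and TAG one change away -> excluded, total < 3
        s, n = evorate._codon_sites("TGG")
        assert s + n < 3.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        ca = list(rng.choice(SENSE_CODONS, n))
        cb = [c if rng.random() < 0.6 else str(rng.choice(SENSE_CODONS))
              for c in ca]
        r = evorate.ka_ng86("".join(ca), "".join(cb))
        pn, ps, N, S = ng86_oracle(ca, cb)
        assert r.pn == pytest.approx(pn)
        assert r.ps == pytest.approx(ps)
        assert r.n_sites == pytest.approx(N)
        assert r.s_sites == pytest.approx(S)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(SENSE_CODONS, 25))
        b = "".join(rng.choice(SENSE_CODONS, 25))
        r1, r2 = evorate.ka_ng86(a, b), evorate.ka_ng86(b, a)
        assert r1.pn == r2.pn and r1.ps == r2.ps

    def test_gap_and_stop_columns_excluded(self):
        r = evorate.ka_ng86("ATG---TAAAAA", "ATGCCCTAAAAA")
        assert r.n_codons == 2  # ATG and AAA columns only

    def test_agrees_with_biopython_ng86(self):
        # independent implementation cross-check; the two differ only in
        # stop-codon conventions (site exclusion and blocked-path handling),
        # which perturbs rates by a few percent on random sequences
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        rng = np.random.default_rng(4)
        for _ in range(5):
            ca = list(rng.choice(SENSE_CODONS, 40))
            cb = [c if rng.random() < 0.75 else str(rng.choice(SENSE_CODONS))
                  for c in ca]
            a, b = "".join(ca), "".join(cb)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            r = evorate.ka_ng86(a, b)
            if r.ks is not None and ds > 0:
                assert r.ks == pytest.approx(ds, rel=0.10)
            if r.ka is not None and dn > 0:
                assert r.ka == pytest.approx(dn, rel=0.10)

    def test_saturation_flagged(self):
        # maximally different codon columns push p past 3/4
        r = evorate.ka_ng86("AAAAAAAAA", "GGCGGCGGC")
        assert r.ka is None and "saturated_ka" in r.flags


class TestERTransform:
    def test_closed_forms(self):
        assert evorate.er_transform(0.0) == pytest.approx(math.log(0.001))
        assert evorate.er_transform(0.999) == pytest.approx(0.0)

    def test_monotone(self):
        grid = np.linspace(0, 2, 50)
        vals = [evorate.er_transform(k) for k in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            evorate.er_transform(-0.1)


def test_ortholog_ka_end_to_end():
    a = GeneRecord("gA", "ATG" + "AAA" * 40, "M" + "K" * 40)
    b = GeneRecord("gB", "ATG" + "AAA" * 39 + "AGA", "M" + "K" * 39 + "R")
    result = evorate.ortholog_ka(a, b)
    assert result.keep
    assert result.ng is not None and result.ng.ka > 0
    assert result.er == pytest.approx(math.log(result.ng.ka + 0.001))
    # short proteins are rejected
    short_a = GeneRecord("sA", "ATG" + "AAA" * 10, "M" + "K" * 10)
    short_b = GeneRecord("sB", "ATG" + "AAA" * 10, "M" + "K" * 10)
    assert not evorate.ortholog_ka(short_a, short_b).keep
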