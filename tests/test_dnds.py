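"""Codon alignment construction and the NG86 dN/dS estimator.

The per-codon oracle is a brute-force enumeration written here, independent
of the package's pathway-averaging code; Biopython's NG86 implementation is
a second, external cross-check.
"""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexvarscan.config import SimulationConfig
from sexvarscan.dnds import (
    CODON_TO_AA,
    AlignmentError,
    CodonAlignment,
    classify_selection,
    codon_align,
    ds_filter,
    ng86_dnds,
    translate,
)
from sexvarscan.simulate import _SENSE_CODONS, generate_ortholog_pairs


def pairs_from(seed, n=20, gene_length=300, planted=None):
    cfg = SimulationConfig(seed=seed, gene_length_bp=gene_length)
    return generate_ortholog_pairs(cfg, n_pairs=n, planted=planted).pairs


class TestCodonAlign:
    def test_no_gap_concatenates_source_codons(self):
        aln = codon_align("MA", "MA", "ATGGCT", "ATGGCC")
        assert (aln.seq_a, aln.seq_b) == ("ATGGCT", "ATGGCC")

    def test_gap_column_dropped_entirely(self):
        aln = codon_align("M-A", "MKA", "ATGGCT", "ATGAAAGCC")
        assert (aln.seq_a, aln.seq_b) == ("ATGGCT", "ATGGCC")
        assert len(aln.seq_a) == 6

    def test_translation_mismatch_names_residue(self):
        with pytest.raises(AlignmentError, match="residue 2"):
            codon_align("MA", "MA", "ATGCGT", "ATGGCC")  # CGT is R, not A

    def test_terminal_stop_stripped(self):
        aln = codon_align("MA", "MA", "ATGGCTTAA", "ATGGCC")
        assert aln.seq_a == "ATGGCT"

    def test_internal_stop_is_hard_error(self):
        with pytest.raises(AlignmentError, match="stop"):
            CodonAlignment("x", "ATGTAAGCT", "ATGAAAGCT")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(AlignmentError):
            codon_align("MX", "MX", "ATGNNN", "ATGNNN")
        with pytest.raises(AlignmentError, match="unsupported codon"):
            translate("ATGNNN")

    def test_retranslation_matches_common_columns(self):
        # proteins with staggered gaps; output must re-translate to the
        # gap-free shared columns
        prot_a, prot_b = "M-AK", "MKA-"
        cds_a, cds_b = "ATGGCTAAA", "ATGAAAGCT"
        aln = codon_align(prot_a, prot_b, cds_a, cds_b)
        common = "".join(
            a for a, b in zip(prot_a, prot_b) if a != "-" and b != "-"
        )
        assert translate(aln.seq_a) == common
        assert translate(aln.seq_b) == common


def brute_force_ng86(seq_a, seq_b):
    """Independent per-codon enumeration: site fractions from the genetic
    code table; differences from explicit pathway enumeration."""
    S = Sd = Nd = 0.0
    n_codons = len(seq_a) // 3
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        for codon in (ca, cb):
            syn = sum(
                1
                for j in range(3)
                for b in "ACGT"
                if b != codon[j]
                and CODON_TO_AA[codon[:j] + b + codon[j + 1 :]] == CODON_TO_AA[codon]
            )
            S += syn / 6.0  # averaged over both sequences
        diffs = [j for j in range(3) if ca[j] != cb[j]]
        if diffs:
            paths = list(itertools.permutations(diffs))
            tot_s = tot_n = 0
            for order in paths:
                cur = ca
                for j in order:
                    nxt = cur[:j] + cb[j] + cur[j + 1 :]
                    if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                        tot_s += 1
                    else:
                        tot_n += 1
                    cur = nxt
            Sd += tot_s / len(paths)
            Nd += tot_n / len(paths)
    return S, 3 * n_codons - S, Sd, Nd


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_dnds(CodonAlignment("x", "ATGGCTAAA", "ATGGCTAAA"))
        assert (r.counts.Sd, r.counts.Nd) == (0.0, 0.0)
        assert r.dN == 0.0 and r.dS == 0.0 and r.omega is None

    def test_worked_three_codon_pair(self):
        """TTT GCT AAA vs TTC GCT AAA: per-codon synonymous sites 1/3 + 1 +
        1/3 give S = 5/3; the single difference is synonymous, so pS = 0.6
        and dS = -(3/4) ln(0.2)."""
        r = ng86_dnds(CodonAlignment("x", "TTTGCTAAA", "TTCGCTAAA"))
        assert r.counts.S == pytest.approx(5 / 3, abs=1e-12)
        assert r.counts.Sd == 1.0 and r.counts.Nd == 0.0
        assert r.pS == pytest.approx(0.6, abs=1e-12)
        assert r.dS == pytest.approx(-(3 / 4) * math.log(0.2), abs=1e-9)
        assert r.dN == 0.0 and r.omega == 0.0

    def test_symmetry_on_random_pairs(self):
        for p in pairs_from(seed=5, n=100, gene_length=60):
            fwd = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            rev = ng86_dnds(CodonAlignment(p.pair_id, p.cds_b, p.cds_a))
            assert (fwd.counts.S, fwd.counts.Sd, fwd.counts.Nd) == (
                rev.counts.S, rev.counts.Sd, rev.counts.Nd,
            )
            assert fwd.dN == rev.dN and fwd.dS == rev.dS

    def test_site_conservation(self):
        for p in pairs_from(seed=6, n=20):
            r = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            assert r.counts.S + r.counts.N == pytest.approx(len(p.cds_a), abs=1e-9)

    def test_planted_syn_only_gives_zero_nd(self):
        for p in pairs_from(seed=7, n=10, planted=[(4, 0)] * 10):
            r = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            assert r.counts.Nd == 0.0
            assert r.counts.Sd == 4.0

    def test_planted_nonsyn_only_gives_zero_sd_and_undefined_omega(self):
        for p in pairs_from(seed=8, n=10, planted=[(0, 3)] * 10):
            r = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            assert r.counts.Sd == 0.0 and r.counts.Nd == 3.0
            assert r.dS == 0.0 and r.omega is None
            assert r.selection_class == "undefined"

    def test_matches_bruteforce_enumeration(self):
        for p in pairs_from(seed=9, n=30, gene_length=90):
            r = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            S, N, Sd, Nd = brute_force_ng86(p.cds_a, p.cds_b)
            assert r.counts.S == pytest.approx(S, abs=1e-9)
            assert r.counts.N == pytest.approx(N, abs=1e-9)
            assert r.counts.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.counts.Nd == pytest.approx(Nd, abs=1e-9)

    def test_matches_biopython_reference(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        for p in pairs_from(seed=10, n=25, gene_length=150):
            r = ng86_dnds(CodonAlignment(p.pair_id, p.cds_a, p.cds_b))
            dn, ds = cal_dn_ds(CodonSeq(p.cds_a), CodonSeq(p.cds_b), method="NG86")
            if r.dN is not None:
                assert r.dN == pytest.approx(dn, abs=1e-9)
            if r.dS is not None:
                assert r.dS == pytest.approx(ds, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=40, deadline=None)
    def test_low_divergence_first_order_agreement(self, seed):
        """A single synonymous one-step difference: dN stays 0 and the JC
        correction inflates the raw proportion only mildly at low
        divergence (d >= p, d -> p as p -> 0)."""
        pairs = pairs_from(seed=seed % 2**31, n=1, gene_length=300, planted=[(1, 0)])
        p = pairs[0]
        r = ng86_dnds(CodonAlignment("x", p.cds_a, p.cds_b))
        assert r.counts.Nd == 0 and r.dN == 0.0
        assert r.dS is not None and r.dS >= r.pS > 0
        assert r.dS == pytest.approx(r.pS, rel=0.05)  # p ~ 1/S is small here


class TestDsFilterAndClassification:
    def result(self, ds):
        r = ng86_dnds(CodonAlignment("x", "TTTGCTAAA", "TTTGCTAAA"))
        r.dS = ds
        return r

    @pytest.mark.parametrize(
        "ds,kept",
        [(0.005, False), (0.01, True), (0.5, True), (2.0, True), (2.5, False), (None, False)],
    )
    def test_boundaries_inclusive(self, ds, kept):
        kept_list, dropped = ds_filter([self.result(ds)])
        assert (len(kept_list) == 1) is kept
        assert (kept_list or dropped)[0].kept_by_ds_filter is kept

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            ds_filter([], lo=2.0, hi=0.01)

    @pytest.mark.parametrize(
        "omega,expected",
        [(4.6, "adaptive"), (0.5, "purifying"), (1.0, "neutral"), (None, "undefined")],
    )
    def test_selection_classes(self, omega, expected):
        assert classify_selection(omega) == expected
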