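"""NG86 site/difference counting, JC correction and batch behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arkmito.selection import (
    CodonAlignment,
    SaturationError,
    align_cds_pair,
    batch_kaks,
    codon_align,
    jukes_cantor,
    ng86,
    pathway_differences,
    syn_site_fraction,
)
from arkmito.synthetic_data import SENSE_CODONS, diverge_cds, random_cds

from .oracles import ng86_enumerate


class TestSiteCounting:
    def test_fourfold_degenerate_third_position(self):
        # CTN all encode Leu in table 5 -> third position fully synonymous
        assert syn_site_fraction("CTA") >= 1.0

    def test_s_plus_n_is_three_per_codon(self):
        for codon in SENSE_CODONS[:30]:
            s = syn_site_fraction(codon)
            assert 0.0 <= s <= 3.0

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            syn_site_fraction("TAA")


class TestPathways:
    def test_identical_codons_no_differences(self):
        assert pathway_differences("AAA", "AAA") == (0.0, 0.0)

    def test_single_synonymous_change(self):
        # TTT -> TTC, both Phe
        sd, nd = pathway_differences("TTT", "TTC")
        assert (sd, nd) == (1.0, 0.0)

    def test_double_change_averages_pathways(self):
        sd, nd = pathway_differences("TTT", "GTA")
        assert sd + nd == pytest.approx(2.0)


class TestNg86:
    def test_identical_pair_undefined_ratio(self):
        pairs = [("AAA", "AAA")] * 10
        res = ng86(CodonAlignment("x", pairs))
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert math.isnan(res.ratio)

    def test_synonymous_only_example(self):
        pairs = [("AAA", "AAA")] * 9 + [("TTT", "TTC")]
        res = ng86(CodonAlignment("x", pairs))
        assert res.Nd == 0.0 and res.Sd == 1.0
        assert res.Ka == 0.0 and res.Ks > 0.0
        S, N, Sd, Nd = ng86_enumerate(pairs)
        assert res.S == pytest.approx(S)
        assert res.Ks == pytest.approx(-0.75 * math.log1p(-4 * (Sd / S) / 3))

    def test_site_sum_is_three_l(self):
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(40):
            c1 = SENSE_CODONS[rng.integers(60)]
            c2 = list(c1)
            if rng.random() < 0.3:
                c2[rng.integers(3)] = "ACGT"[rng.integers(4)]
            c2 = "".join(c2)
            pairs.append((c1, c1 if c2 in ("TAA", "TAG") else c2))
        res = ng86(CodonAlignment("x", pairs))
        assert res.S + res.N == pytest.approx(3 * len(pairs))

    def test_symmetry_under_sequence_swap(self):
        rng = np.random.default_rng(1)
        pairs = []
        for _ in range(30):
            c1 = SENSE_CODONS[rng.integers(60)]
            c2 = list(c1)
            for pos in range(3):
                if rng.random() < 0.15:
                    c2[pos] = "ACGT"[rng.integers(4)]
            c2 = "".join(c2)
            pairs.append((c1, c1 if c2 in ("TAA", "TAG") else c2))
        a = ng86(CodonAlignment("x", pairs))
        b = ng86(CodonAlignment("x", [(q, p) for p, q in pairs]))
        for attr in ("S", "N", "Sd", "Nd", "Ka", "Ks"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 50))
        pairs = []
        for _ in range(L):
            c1 = SENSE_CODONS[rng.integers(60)]
            # mostly-similar partner to keep divergence below saturation
            c2 = list(c1)
            for pos in range(3):
                if rng.random() < 0.15:
                    c2[pos] = "ACGT"[rng.integers(4)]
            c2 = "".join(c2)
            if c2 in ("TAA", "TAG"):
                c2 = c1
            pairs.append((c1, c2))
        res = ng86(CodonAlignment("x", pairs))
        S, N, Sd, Nd = ng86_enumerate(pairs)
        assert res.S == pytest.approx(S)
        assert res.N == pytest.approx(N)
        assert res.Sd == pytest.approx(Sd)
        assert res.Nd == pytest.approx(Nd)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jukes_cantor(0.8)

    def test_planted_divergence_recovered(self):
        """ps*S is close to the planted synonymous substitution count."""
        rng = np.random.default_rng(5)
        cds = random_cds(rng, 903, "ATG", "TAA")  # 300 codons
        mutated, applied = diverge_cds(cds, 20, 4, seed=6)
        res = ng86(align_cds_pair(cds, mutated, "g"))
        assert res.ratio < 1.0
        assert res.Sd == pytest.approx(20, abs=3)
        assert res.Nd == pytest.approx(4, abs=2)


class TestCodonAlign:
    def test_identical_cds_all_paired(self):
        cds = random_cds(np.random.default_rng(2), 90, "ATG", "TAA")
        prot = "M" + "".join([])  # alignment rows from translation
        from arkmito.selection import _translate_nostop
        from arkmito.orf_scan import INVERTEBRATE_MITO

        p = _translate_nostop(cds[:-3], INVERTEBRATE_MITO)
        aln = codon_align((p, p), cds, cds)
        assert len(aln.pairs) == 29
        assert all(a == b for a, b in aln.pairs)

    def test_gap_column_dropped(self):
        from arkmito.selection import _translate_nostop
        from arkmito.orf_scan import INVERTEBRATE_MITO

        cdsA = "ATGAAATTTTAA"  # MKF
        cdsB = "ATGTTTTAA"  # MF
        pa = _translate_nostop(cdsA[:-3], INVERTEBRATE_MITO)
        pb = _translate_nostop(cdsB[:-3], INVERTEBRATE_MITO)
        aln = codon_align((pa, pb[0] + "-" + pb[1]), cdsA, cdsB)
        assert aln.pairs == [("ATG", "ATG"), ("TTT", "TTT")]

    def test_translation_mismatch_errors(self):
        with pytest.raises(ValueError):
            codon_align(("MK", "MK"), "ATGAAATAA", "ATGCCCTAA")


class TestBatch:
    def test_identical_genomes_all_zero(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(3):
            cds = random_cds(rng, 300, "ATG", "TAA")
            pairs.append((f"g{i}", "PCG", cds, cds))
        rows, _ = batch_kaks(pairs)
        assert all(r.Ka == 0.0 and r.Ks == 0.0 for _, _, r in rows)

    def test_group_means_ordered_by_planted_omega(self):
        rng = np.random.default_rng(4)
        pairs = []
        for i in range(5):
            cds = random_cds(rng, 600, "ATG", "TAA")
            mut, _ = diverge_cds(cds, 10, 1, seed=100 + i)
            pairs.append((f"pcg{i}", "PCG", cds, mut))
        for i in range(5):
            cds = random_cds(rng, 600, "ATG", "TAA")
            mut, _ = diverge_cds(cds, 10, 10, seed=200 + i)
            pairs.append((f"orf{i}", "ORF", cds, mut))
        rows, summary = batch_kaks(pairs)
        assert summary["mean_ratio_PCG"] < summary["mean_ratio_ORF"] < 1.0
        assert "mannwhitney_p" in summary
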