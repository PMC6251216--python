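"""Splice-aware consequence prediction: retention, translation, truncation."""

import pytest

from bsamap.consequence import (
    AlternativeSpliceSite,
    GeneModel,
    SpliceVariantEvent,
    alternative_splice_isoforms,
    apply_gene_variant,
    characterize,
    diff_proteins,
    domain_overlap,
    retained_introns,
    translate_orf,
)

# hand-buildable toy: 3 exons, introns GT..AG, CDS from the first exon base
#   exon1          intron1      exon2        intron2      exon3
E1 = "ATGGCTACT"          # M A T
I1 = "GTAAGCCTAG"         # 10 nt
E2 = "GGTTGGCAT"          # continues the frame
I2 = "GTTTTTCCAG"
E3 = "CATTAAGGG"          # ...stop TAA in frame


def toy_gene():
    seq = E1 + I1 + E2 + I2 + E3
    exons = [
        (1, len(E1)),
        (len(E1) + len(I1) + 1, len(E1) + len(I1) + len(E2)),
        (len(E1) + len(I1) + len(E2) + len(I2) + 1, len(seq)),
    ]
    return GeneModel("toy", seq, exons, cds_start_gene=1)


class TestGeneModel:
    def test_transcript_is_exon_concatenation(self):
        g = toy_gene()
        assert g.transcript() == E1 + E2 + E3
        assert len(g.introns()) == 2

    def test_noncanonical_introns_rejected_unless_flagged(self):
        seq = "ATGAAA" + "CTAAAAAAAG" + "TAA"
        with pytest.raises(ValueError, match="GT..AG"):
            GeneModel("bad", seq, [(1, 6), (17, 19)], cds_start_gene=1)
        g = GeneModel("ok", seq, [(1, 6), (17, 19)], cds_start_gene=1, noncanonical=True)
        assert g.transcript() == "ATGAAATAA"

    def test_cds_start_must_be_exonic_atg(self):
        with pytest.raises(ValueError, match="ATG"):
            GeneModel("x", "CCCGCTTAA", [(1, 9)], cds_start_gene=1)


class TestTranslate:
    def test_minimal_orf(self):
        res = translate_orf("ATGAAATAA", 1)
        assert res.protein == "MK"
        assert res.stop_codon == "TAA" and res.stop_residue == 3
        assert res.orf_length_nt == 9 and not res.non_stop

    def test_matches_brute_force_codon_table(self):
        """Random ORFs agree with an independently coded codon loop."""
        import numpy as np

        table = {}
        bases = "TCAG"
        aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
        i = 0
        for b1 in bases:
            for b2 in bases:
                for b3 in bases:
                    table[b1 + b2 + b3] = aas[i]
                    i += 1
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_codons = int(rng.integers(2, 60))
            seq = "ATG" + "".join(
                "ACGT"[rng.integers(0, 4)] for _ in range(3 * n_codons)
            )
            expected = []
            stopped = False
            for j in range(0, len(seq) - 2, 3):
                aa = table[seq[j : j + 3]]
                if aa == "*":
                    stopped = True
                    break
                expected.append(aa)
            res = translate_orf(seq, 1)
            assert res.protein == "".join(expected)
            assert res.non_stop == (not stopped)
            if stopped:
                assert res.orf_length_nt == 3 * (len(expected) + 1)

    def test_requires_atg_at_cds_start(self):
        with pytest.raises(ValueError, match="ATG"):
            translate_orf("CCCAAATAA", 1)

    def test_nonstop_transcript_flagged(self):
        res = translate_orf("ATGAAAGGG", 1)
        assert res.non_stop and res.stop_codon is None


class TestApplyVariant:
    def test_donor_loss_retains_intron_one(self):
        """Deleting intron 1's donor yields exon1'+intron1'+exon2+exon3."""
        g = toy_gene()
        # remove the last exon1 base and the GT donor (span 9-11)
        event = SpliceVariantEvent(len(E1), len(E1) + 2, "")
        mut = apply_gene_variant(g, event)
        expected = (E1[:-1] + I1[2:]) + E2 + E3  # intron 1 retained, intron 2 spliced
        assert mut.transcript() == expected
        assert retained_introns(g, event) == [1]
        assert len(mut.exons) == 2

    def test_identity_replacement_changes_nothing(self):
        g = toy_gene()
        event = SpliceVariantEvent(3, 7, g.sequence[2:7])
        mut = apply_gene_variant(g, event)
        assert mut.sequence == g.sequence
        assert mut.exons == g.exons
        assert mut.transcript() == g.transcript()

    def test_exonic_deletion_keeps_all_introns_spliced(self):
        g = toy_gene()
        event = SpliceVariantEvent(4, 6, "")  # in-frame 3-nt loss inside exon 1
        mut = apply_gene_variant(g, event)
        assert len(mut.exons) == 3
        assert mut.transcript() == E1[:3] + E1[6:] + E2 + E3
        wild_p = translate_orf(g.transcript(), 1).protein
        mut_p = translate_orf(mut.transcript(), 1).protein
        assert len(mut_p) == len(wild_p) - 1

    def test_whole_intron_deletion_unsupported(self):
        g = toy_gene()
        s, e = g.introns()[0]
        with pytest.raises(ValueError, match="unsupported"):
            apply_gene_variant(g, SpliceVariantEvent(s - 1, e + 1, ""))

    def test_start_codon_loss_rejected(self):
        g = toy_gene()
        with pytest.raises(ValueError, match="start codon"):
            apply_gene_variant(g, SpliceVariantEvent(1, 4, ""))

    def test_round_trip_restores_wild_type(self, kan1_gene, kan1_event):
        """Applying an event and then its inverse restores the transcript
        and protein exactly."""
        mut = apply_gene_variant(kan1_gene, kan1_event)
        original = kan1_gene.sequence[kan1_event.start - 1 : kan1_event.end]
        inverse = SpliceVariantEvent(
            kan1_event.start,
            kan1_event.start + len(kan1_event.replacement) - 1,
            original,
        )
        back = apply_gene_variant(mut, inverse)
        assert back.sequence == kan1_gene.sequence
        assert back.transcript() == kan1_gene.transcript()

    def test_retained_intron_lengthens_transcript(self, kan1_gene, kan1_event):
        mut = apply_gene_variant(kan1_gene, kan1_event)
        wild_len = len(kan1_gene.transcript())
        assert len(mut.transcript()) > wild_len + kan1_event.net_change


class TestDiffAndDomains:
    def test_identical_proteins(self):
        d = diff_proteins("MKL", "MKL")
        assert d.first_diff is None and d.classification == "synonymous-length"

    def test_elongating(self):
        d = diff_proteins("MK", "MKLLL")
        assert d.classification == "elongating" and d.truncation == -3

    def test_domain_statuses(self):
        lost, disrupted, intact = (
            domain_overlap([("d", 350, 400)], 299, 295, 300)[0],
            domain_overlap([("d", 271, 323)], 299, 295, 300)[0],
            domain_overlap([("d", 1, 50)], 299, 295, 300)[0],
        )
        assert (lost.status, disrupted.status, intact.status) == (
            "lost", "disrupted", "intact",
        )


class TestEngineeredGene:
    def test_full_report_reproduces_truncation_anatomy(
        self, kan1_gene, kan1_event, kan1_domains
    ):
        """The donor-destroying 20->6 nt replacement truncates the 440-aa
        product to 299 aa with the frameshift at ORF position 883 and the
        new TAA terminator at residue 300, inside the MYB domain."""
        rep = characterize(kan1_gene, kan1_event, kan1_domains)
        assert rep.wild_protein_length_aa == 440
        assert rep.mutant_protein_length_aa == 299
        assert rep.mutant_orf_length_nt == 900
        assert rep.mutant_orf_length_nt == 3 * (rep.mutant_protein_length_aa + 1)
        assert rep.first_altered_residue == 295
        assert rep.frameshift_cdna_pos == 883
        assert len(rep.wild_run) == len(rep.mutant_run) == 5
        assert rep.premature_stop_codon == "TAA"
        assert rep.premature_stop_residue == 300
        assert rep.classification == "truncating"
        assert rep.retained_introns == [2]
        (myb,) = rep.domain_overlaps
        assert myb.status == "disrupted"

    def test_orf_arithmetic_invariant(self, kan1_gene):
        tr = translate_orf(kan1_gene.transcript(), kan1_gene.cds_start)
        assert tr.orf_length_nt == 3 * (len(tr.protein) + 1)


class TestAlternativeIsoforms:
    def _gene_with_nagnag(self):
        # exon2 starts with a 3-nt codon-aligned stretch that an acceptor
        # shift can remove: AG|GCT GGT ... vs AG....GCT| GGT
        e1 = "ATGGCTACT"
        i1 = "GTAAGCCTAGGCTAG"  # ends ...CTAG: AG at 14-15 and a second AG at 11-12... use shift 3
        e2 = "GGTTGGCATCATTAAGGG"
        seq = e1 + i1 + e2
        exons = [(1, 9), (25, len(seq))]
        return GeneModel("nag", seq, exons, cds_start_gene=1)

    def test_zero_shift_yields_single_isoform(self):
        g = toy_gene()
        out = alternative_splice_isoforms(g, AlternativeSpliceSite(1, 0))
        assert len(out) == 1

    def test_three_nt_shift_drops_exactly_one_residue(self):
        g = self._gene_with_nagnag()
        out = alternative_splice_isoforms(g, AlternativeSpliceSite(1, 3, end="acceptor"))
        p1 = out[0].translation.protein
        p2 = out[1].translation.protein
        assert len(p1) - len(p2) == 1
        assert not out[1].frameshifted
        d = diff_proteins(p1, p2)
        assert d.classification == "truncating" and d.truncation == 1

    def test_one_nt_shift_is_flagged_frameshift(self):
        g = self._gene_with_nagnag()
        out = alternative_splice_isoforms(g, AlternativeSpliceSite(1, 1, end="acceptor"))
        assert out[1].frameshifted

    def test_invalid_intron_index_rejected(self):
        with pytest.raises(ValueError, match="introns"):
            alternative_splice_isoforms(toy_gene(), AlternativeSpliceSite(9, 3))
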