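import pytest

from bescan.disruption import (
    predict_consequence,
    simulate_intron_retention,
    splice_candidates,
    start_candidates,
    stop_candidates,
)
from bescan.edit_chemistry import ABE, CBE, EDITORS, BaseEdit, apply_edit
from bescan.genome_io import GeneModel, GenomeSequences, revcomp, spliced_cds, translate
from bescan.summary_report import collect_candidates

PAD = "ACGTACGTACGTACGTACGTACGTACGTAC"  # neutral 30-nt flank


def make_gene(cds, introns_at=None, strand="+", chrom="c1"):
    """Toy single-gene genome; ``introns_at`` maps CDS offset -> intron seq."""
    introns_at = dict(sorted((introns_at or {}).items()))
    parts, exons = [], []
    prev = pos = 0
    for d, iseq in introns_at.items():
        parts.append(cds[prev:d])
        exons.append((pos, pos + d - prev))
        pos += d - prev + len(iseq)
        parts.append(iseq)
        prev = d
    parts.append(cds[prev:])
    exons.append((pos, pos + len(cds) - prev))
    local = "".join(parts)
    if strand == "-":
        L = len(local)
        local = revcomp(local)
        exons = sorted((L - e, L - s) for s, e in exons)
    gs = len(PAD)
    seqs = GenomeSequences()
    seqs[chrom] = PAD + local + PAD
    exons = [(gs + s, gs + e) for s, e in exons]
    gene = GeneModel("toy", chrom, strand, exons, list(exons))
    return seqs, gene


def edit_at(pos, ref, alt, editor="CBE", chrom="c1"):
    return BaseEdit("manual", chrom, "+", 6, ref, alt, pos, ref, alt, editor)


class TestStopCandidates:
    def test_cag_to_tag_in_first_quarter(self):
        cds = "ATG" + "CAG" + "GCT" * 38 + "TAA"  # 41 codons
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0] + 3, "C", "T")
        (cand,) = stop_candidates(gene, [e], seqs)
        assert (cand.codon_index, cand.ref_codon, cand.alt_codon) == (2, "CAG", "TAG")
        assert cand.within_5prime_quarter  # ceil(0.25*41) = 11

    def test_quarter_rule_boundary(self):
        cds = "ATG" + "GCT" * 38 + "CAG" + "TAA"  # CAG at codon 40 of 41
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0] + 3 * 39, "C", "T")
        (cand,) = stop_candidates(gene, [e], seqs)
        assert cand.codon_index == 40 and not cand.within_5prime_quarter

    def test_final_codon_excluded(self):
        cds = "ATG" + "GCT" * 10 + "CGA"  # CGA is the terminal codon... not a stop
        # make a gene whose *last sense* codon is CGA and ends with TAA
        cds = "ATG" + "GCT" * 9 + "CGA" + "TAA"
        seqs, gene = make_gene(cds)
        # edit on the genuine stop codon's C? none: target CGA at codon 11 of 12
        e = edit_at(gene.span[0] + 3 * 10, "C", "T")
        cands = stop_candidates(gene, [e], seqs)
        assert [c.codon_index for c in cands] == [11]
        # an edit creating a stop in the final codon would be dropped: codon 12
        # is already a stop, so no candidate can exist there at all
        assert all(c.codon_index < 12 for c in cands)

    def test_fixture_w55_and_r292(self, alba):
        """Opposite-strand G>A edits hit codon 55 (TGG) and a direct C>T hits
        codon 292 (CGA), reproducing the two nonsense conversions."""
        seqs, genes = alba
        cands = collect_candidates(seqs, genes, CBE, pam="NGG",
                                   strategies=("stop",))
        changes = {(c.codon_index, c.ref_codon, c.alt_codon) for c in cands}
        assert (55, "TGG", "TAG") in changes
        assert (55, "TGG", "TGA") in changes
        assert (292, "CGA", "TGA") in changes

    def test_abe_never_yields_stop_candidates(self, alba, sim_small):
        for seqs, genes in (alba, sim_small[:2]):
            cands = collect_candidates(seqs, genes, ABE, pam="NG",
                                       strategies=("stop",))
            assert cands == []


class TestStartCandidates:
    def test_abe_position1_gives_gtg(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0], "A", "G", editor="ABE")
        (cand,) = start_candidates(gene, [e], seqs)
        assert (cand.codon_index, cand.alt_codon) == (1, "GTG")

    def test_cbe_position3_gives_ata(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0] + 2, "G", "A", editor="CBE")
        (cand,) = start_candidates(gene, [e], seqs)
        assert cand.alt_codon == "ATA"

    def test_abe_position2_gives_acg(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0] + 1, "T", "C", editor="ABE")
        (cand,) = start_candidates(gene, [e], seqs)
        assert cand.alt_codon == "ACG"

    def test_edit_elsewhere_gives_nothing(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0] + 9, "G", "A")
        assert start_candidates(gene, [e], seqs) == []


class TestSpliceCandidates:
    INTRON = "GT" + "C" * 20 + "A" + "C" * 20 + "CAG"  # 46 nt, branch A inside

    def _gene(self, strand="+"):
        cds = "ATG" + "GCT" * 20 + "TAA"
        return make_gene(cds, introns_at={6: self.INTRON}, strand=strand)

    def _intron_coord(self, gene, pos):
        """Genomic coordinate of 1-based intron position (transcription sense)."""
        s, e = gene.introns_tx_order[0]
        return s + pos - 1 if gene.strand == "+" else e - pos

    def test_donor_hit(self):
        seqs, gene = self._gene()
        coord = self._intron_coord(gene, 2)  # the T of GT
        e = edit_at(coord, "T", "C", editor="ABE")
        (cand,) = splice_candidates(gene, [e], seqs)
        assert (cand.splice_subsite, cand.tier, cand.intron_index) == ("donor", 1, 1)

    def test_acceptor_hit(self):
        seqs, gene = self._gene()
        coord = self._intron_coord(gene, len(self.INTRON) - 1)  # A of terminal AG
        e = edit_at(coord, "A", "G", editor="ABE")
        (cand,) = splice_candidates(gene, [e], seqs)
        assert (cand.splice_subsite, cand.tier) == ("acceptor", 1)

    def test_branch_region_adenine(self):
        seqs, gene = self._gene()
        coord = self._intron_coord(gene, 23)  # lone A, 24 nt from the 3' end
        e = edit_at(coord, "A", "G", editor="ABE")
        (cand,) = splice_candidates(gene, [e], seqs)
        assert (cand.splice_subsite, cand.tier) == ("branch_region", 2)

    def test_non_adenine_interior_is_other_intronic(self):
        seqs, gene = self._gene()
        coord = self._intron_coord(gene, 10)
        e = edit_at(coord, "C", "T", editor="CBE")
        (cand,) = splice_candidates(gene, [e], seqs)
        assert (cand.splice_subsite, cand.tier) == ("other_intronic", 2)

    def test_exonic_edit_never_emitted(self):
        seqs, gene = self._gene()
        e = edit_at(gene.span[0] + 3, "G", "A")
        assert splice_candidates(gene, [e], seqs) == []

    def test_minus_strand_subsites_match_plus(self):
        for pos, subsite in ((2, "donor"), (len(self.INTRON) - 1, "acceptor")):
            seqs, gene = self._gene(strand="-")
            coord = self._intron_coord(gene, pos)
            plus_ref = revcomp(self.INTRON[pos - 1])
            alt = {"T": "C", "A": "G"}[self.INTRON[pos - 1]]
            e = edit_at(coord, plus_ref, revcomp(alt), editor="ABE")
            (cand,) = splice_candidates(gene, [e], seqs)
            assert cand.splice_subsite == subsite


class TestIntronRetention:
    def test_frameshift_iff_length_not_multiple_of_three(self):
        cds = "ATG" + "GCT" * 20 + "TAA"
        for iseq, fs in (("GT" + "C" * 6 + "AG", True),  # 10 nt
                         ("GT" + "C" * 5 + "AG", False)):  # 9 nt
            seqs, gene = make_gene(cds, introns_at={6: iseq})
            cons = simulate_intron_retention(gene, 1, seqs)
            assert cons.frameshift is fs

    def test_in_frame_intron_with_internal_stop(self):
        # retained 9-nt intron GTATAACAG puts TAA in frame at codon 4:
        # ATG GCA | GTA TAA ... -> 3 aa then PTC (hand translation)
        cds = "ATGGCATGGGCTGCTTAA"
        seqs, gene = make_gene(cds, introns_at={6: "GTATAACAG"})
        cons = simulate_intron_retention(gene, 1, seqs)
        assert not cons.frameshift
        assert cons.ptc_codon_index == 4
        assert cons.truncated_length_aa == 3

    def test_strand_symmetric(self):
        cds = "ATG" + "GCAGCTTGGATT" * 6 + "TAA"
        intron = "GT" + "ACGTACG" + "AG"
        a = make_gene(cds, introns_at={9: intron}, strand="+")
        b = make_gene(cds, introns_at={9: intron}, strand="-")
        ca = simulate_intron_retention(a[1], 1, a[0])
        cb = simulate_intron_retention(b[1], 1, b[0])
        assert ca == cb

    def test_index_out_of_range(self):
        cds = "ATG" + "GCT" * 10 + "TAA"
        seqs, gene = make_gene(cds, introns_at={6: "GTACGTACAG"})
        with pytest.raises(IndexError):
            simulate_intron_retention(gene, 2, seqs)


class TestPredictConsequence:
    def test_nonsense_truncation_length(self, alba):
        seqs, genes = alba
        cands = collect_candidates(seqs, genes, CBE, pam="NGG",
                                   strategies=("stop",))
        c55 = next(c for c in cands if c.codon_index == 55)
        cons = predict_consequence(genes[0], c55, seqs)
        assert cons.kind == "nonsense"
        assert cons.truncated_length_aa == 54

    def test_start_loss_reports_next_inframe_atg(self):
        cds = "ATG" + "GCT" * 10 + "ATG" + "GCT" * 10 + "TAA"  # ATG at codon 12
        seqs, gene = make_gene(cds)
        e = edit_at(gene.span[0], "A", "G", editor="ABE")
        (cand,) = start_candidates(gene, [e], seqs)
        cons = predict_consequence(gene, cand, seqs)
        assert cons.kind == "start_loss" and cons.next_inframe_atg == 12

    def test_splice_delegates_to_retention(self, alba):
        seqs, genes = alba
        cands = collect_candidates(seqs, genes, ABE, pam="NGG",
                                   strategies=("splice",))
        donor2 = next(c for c in cands
                      if c.intron_index == 2 and c.splice_subsite == "donor")
        cons = predict_consequence(genes[0], donor2, seqs)
        assert cons.kind == "intron_retention"
        assert cons.retained_intron == 2
        assert cons.frameshift  # intron 2 is 61 nt

    def test_retained_intron1_of_fixture_is_in_frame(self, alba):
        seqs, genes = alba
        cons = simulate_intron_retention(genes[0], 1, seqs)
        assert not cons.frameshift  # intron 1 is 60 nt


class TestEditRetranslateConsistency:
    def test_first_stop_lands_exactly_at_reported_codon(self, alba):
        """Applying each premature-stop edit and retranslating the re-extracted
        CDS must place the first stop at the candidate's codon index."""
        seqs, genes = alba
        gene = genes[0]
        cands = collect_candidates(seqs, genes, CBE, pam="NG", strategies=("stop",))
        assert cands
        for c in cands:
            mutated = apply_edit(seqs, c.edit)
            aa = translate(spliced_cds(gene, mutated))
            assert aa.index("*") + 1 == c.codon_index
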