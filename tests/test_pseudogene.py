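import numpy as np
import pytest

from lgtscreen.pseudogene import (
    AmpliconPrediction,
    annotate_locus,
    infer_intron_structure,
    insilico_pcr,
)
from lgtscreen.seqio import revcomp
from lgtscreen.synthetic_data import AA20, reverse_translate, STOP_CODONS


@pytest.fixture()
def protein(rng):
    return "".join(rng.choice(list(AA20), size=200))


@pytest.fixture()
def cds(protein, rng):
    return reverse_translate(protein, rng, 0.35)


class TestAnnotateLocus:
    def test_exact_reverse_translation_is_intact(self, protein, cds):
        rep = annotate_locus(cds, protein)
        assert rep.n_frameshifts == 0
        assert rep.n_internal_stops == 0
        assert rep.truncation_fraction == pytest.approx(1.0, abs=0.01)
        assert rep.identity_aa == pytest.approx(1.0)
        assert rep.intact

    def test_no_false_frameshifts_after_substitutions(self, rng):
        # divergence without indels must never produce frameshift calls
        for _ in range(10):
            p = "".join(rng.choice(list(AA20), size=150))
            nt = list(reverse_translate(p, rng, 0.3))
            for i in range(len(nt)):
                if rng.random() < 0.12:
                    nt[i] = "ACGT".replace(nt[i], "")[int(rng.integers(3))]
            rep = annotate_locus("".join(nt), p)
            assert rep.n_frameshifts == 0

    def test_single_deletion_counts_one_frameshift(self, protein, cds):
        mutated = cds[:300] + cds[301:]  # 1-nt deletion mid-sequence
        rep = annotate_locus(mutated, protein)
        assert rep.n_frameshifts == 1
        assert rep.n_internal_stops == 0

    def test_internal_stops_counted(self, protein, cds):
        codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        for pos in (40, 90, 140):
            codons[pos] = "TAA"
        rep = annotate_locus("".join(codons), protein)
        assert rep.n_internal_stops == 3
        assert rep.n_frameshifts == 0

    def test_truncation_fraction(self, protein, cds):
        rep = annotate_locus(cds[: 100 * 3], protein)
        assert rep.truncation_fraction == pytest.approx(0.5, abs=0.02)
        assert not rep.intact

    def test_short_homolog_rejected(self, cds):
        with pytest.raises(ValueError):
            annotate_locus(cds, "MKVLW")

    def test_no_homology_returns_none(self, rng):
        random_nt = "".join(rng.choice(list("ACGT"), size=400))
        random_prot = "".join(rng.choice(list(AA20), size=100))
        assert annotate_locus(random_nt, random_prot) is None


class TestGeneratorRecovery:
    """Closing the loop: annotation recovers the generator's implant truth."""

    def test_implant_parameters_recovered(self, dataset):
        from lgtscreen.seqio import extract_region

        proteins = {p.id: p.sequence
                    for p in dataset.donors.donorA + dataset.donors.donorB}
        for ev in dataset.truth_events:
            locus = extract_region(dataset.assembly, ev.locus)
            rep = annotate_locus(locus, proteins[ev.homolog_id])
            assert rep.n_frameshifts == ev.n_frameshifts, ev.event_id
            assert rep.n_internal_stops == ev.n_internal_stops, ev.event_id
            assert rep.truncation_fraction == pytest.approx(
                ev.truncation_fraction, abs=0.02), ev.event_id


class TestIntronInference:
    def _gene_with_intron(self, rng, donor="GT", acceptor="AG", body_alphabet="ACGT"):
        protein = "".join(rng.choice(list(AA20), size=150))
        cds = reverse_translate(protein, rng, 0.35)
        intron = donor + "".join(rng.choice(list(body_alphabet), size=200)) + acceptor
        split = 225  # codon boundary
        return protein, cds[:split] + intron + cds[split:], split, len(intron)

    def test_two_exon_gene_recovered_at_boundaries(self, rng):
        protein, gene, split, ilen = self._gene_with_intron(rng)
        exons, nc = infer_intron_structure(gene, protein)
        assert len(exons) == 2
        assert nc == 0
        assert exons[0].end == split
        assert exons[1].start == split + ilen + 1

    def test_intronless_gene_is_single_exon(self, rng):
        protein = "".join(rng.choice(list(AA20), size=120))
        cds = reverse_translate(protein, rng, 0.35)
        exons, nc = infer_intron_structure(cds, protein)
        assert len(exons) == 1 and nc == 0

    def test_mutated_donor_site_flagged_noncanonical(self):
        # hand-built gene with NO GT dinucleotide anywhere: the intron can
        # only be explained by the flagged non-canonical move
        protein = "E" * 75 + "D" * 75
        exon1 = "GAA" * 75   # E codons; GAAGAA.. contains no GT
        exon2 = "GAC" * 75   # D codons; no GT
        intron = "GA" + "ACT" * 40 + "CAG"[1:]  # starts GA, ends AG, G-free body
        gene = exon1 + intron + exon2
        assert "GT" not in gene
        exons, nc = infer_intron_structure(gene, protein)
        assert len(exons) == 2
        assert nc == 1

    def test_generator_intron_structure_recovered(self, dataset):
        from lgtscreen.seqio import extract_region

        proteins = {p.id: p.sequence
                    for p in dataset.donors.donorA + dataset.donors.donorB}
        for ev in dataset.truth_events:
            if ev.cls != "functional_LGT" or len(ev.exons) < 2:
                continue
            locus = extract_region(dataset.assembly, ev.locus)
            exons, nc = infer_intron_structure(locus, proteins[ev.homolog_id])
            assert len(exons) == len(ev.exons), ev.event_id


class TestInsilicoPcr:
    FWD = "AATTGTTGGATTGAGATCAGCA"
    REV = "ACAAAGACTGTTCTCATATTGTTCG"

    def _template(self, gap_len):
        between = "G" * gap_len
        return "T" * 30 + self.FWD + between + revcomp(self.REV) + "C" * 30

    def test_product_length_by_construction(self):
        tpl = self._template(40)
        products = insilico_pcr(tpl, self.FWD, self.REV)
        assert len(products) == 1
        assert products[0].product_length == len(self.FWD) + 40 + len(self.REV)

    def test_absent_primers_give_nothing(self):
        assert insilico_pcr("ACGT" * 100, self.FWD, self.REV) == []

    def test_revcomp_template_with_swapped_primers_invariant(self):
        tpl = self._template(33)
        fwd_products = insilico_pcr(tpl, self.FWD, self.REV)
        swapped = insilico_pcr(revcomp(tpl), self.REV, self.FWD)
        assert fwd_products[0].product_length == swapped[0].product_length

    def test_smallest_product_reported_first(self):
        tpl = self._template(40) + self._template(10)
        products = insilico_pcr(tpl, self.FWD, self.REV)
        assert products[0].product_length == len(self.FWD) + 10 + len(self.REV)

    def test_primer_length_bounds(self):
        with pytest.raises(ValueError):
            insilico_pcr("ACGT" * 50, "ACGT", self.REV)

    def test_mismatch_tolerance(self):
        tpl = self._template(40)
        fwd_mut = "G" + self.FWD[1:]
        assert insilico_pcr(tpl, fwd_mut, self.REV, mismatch_max=0) == []
        prods = insilico_pcr(tpl, fwd_mut, self.REV, mismatch_max=1)
        assert prods and prods[0].product_length == len(self.FWD) + 40 + len(self.REV)
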