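import numpy as np
import pytest

from lgtscreen import lgt_filter as lf
from lgtscreen.homology import AlignmentHit, e_value
from lgtscreen.seqio import Assembly, GenomicInterval, Scaffold


def _hit(bits=80.0, q=(1, 100), s=(1, 100), subject="b1", db="bacterial",
         e=None, ident=90.0):
    return AlignmentHit(
        query_id="q", subject_id=subject, subject_db=db,
        percent_identity=ident, aln_len=q[1] - q[0] + 1,
        q_start=q[0], q_end=q[1], s_start=s[0], s_end=s[1],
        raw_score=bits, bit_score=bits,
        e_value=e if e is not None else e_value(bits, 100, 10000))


def _cand():
    return lf.CandidateRecord("q", GenomicInterval("s", 1, 300), "assembly_ppp",
                              peptide="M" * 100)


class TestBacterialScreen:
    def test_just_below_threshold_fails(self):
        c = _cand()
        assert not lf.bacterial_screen(c, [_hit(bits=39.9)])
        assert c.verdicts["bacterial_screen"].startswith("fail")

    def test_at_threshold_passes(self):
        assert lf.bacterial_screen(_cand(), [_hit(bits=40.0)])

    def test_no_hits(self):
        c = _cand()
        assert not lf.bacterial_screen(c, [])
        assert c.verdicts["bacterial_screen"] == "fail:no_bacterial_hit"

    def test_vacuous_threshold(self):
        assert lf.bacterial_screen(_cand(), [_hit(bits=1.0)], bits_min=0.0)


class TestInvertebrateComparison:
    def _screened(self, bact_bits, bq=(1, 100)):
        c = _cand()
        lf.bacterial_screen(c, [_hit(bits=bact_bits, q=bq)])
        return c

    def test_clear_margin_passes(self):
        c = self._screened(100)
        assert lf.invertebrate_comparison(c, [_hit(bits=60, db="invertebrate", q=(150, 250))])

    def test_stronger_invertebrate_on_common_region_is_conserved_gene(self):
        c = self._screened(60, bq=(1, 100))
        assert not lf.invertebrate_comparison(
            c, [_hit(bits=100, db="invertebrate", q=(5, 95))])
        assert c.verdicts["invertebrate_comparison"] == "fail:conserved_gene"

    def test_tie_fails_strict_inequality(self):
        c = self._screened(60, bq=(1, 100))
        assert not lf.invertebrate_comparison(
            c, [_hit(bits=60, db="invertebrate", q=(150, 250))])

    def test_absent_invertebrate_hit_passes(self):
        assert lf.invertebrate_comparison(self._screened(50), [])


class TestFullProteinRecheck:
    def test_small_delta_fails(self):
        c = _cand()
        assert not lf.full_protein_recheck(c, [_hit(bits=80)], [_hit(bits=75)])
        assert c.verdicts["full_protein_recheck"] == "fail:animal_origin"

    def test_large_delta_passes(self):
        assert lf.full_protein_recheck(_cand(), [_hit(bits=95)], [_hit(bits=70)])

    def test_no_animal_hit_passes(self):
        assert lf.full_protein_recheck(_cand(), [_hit(bits=50)], [])


class TestWeakAndRepeat:
    def _with_hit(self, bits, e, peptide="MKVLWEAHRNDTQYFGSI" * 6, q=None):
        c = lf.CandidateRecord("q", None, "assembly_ppp", peptide=peptide)
        q = q or (1, min(100, len(peptide)))
        lf.bacterial_screen(c, [_hit(bits=bits, e=e, q=q)], bits_min=0.0)
        return c

    def test_weak_conjunction_fails(self):
        c = self._with_hit(44.0, 0.01)
        assert not lf.weak_and_repeat_filter(c, c.peptide)
        assert c.verdicts["weak_and_repeat"] == "fail:weak"

    def test_low_e_rescues_low_bits(self):
        c = self._with_hit(44.0, 1e-6)
        assert lf.weak_and_repeat_filter(c, c.peptide)

    def test_tandem_repeat_region_fails(self):
        pep = "QA" * 50
        c = self._with_hit(80.0, 1e-10, peptide=pep, q=(1, 100))
        assert not lf.weak_and_repeat_filter(c, pep)
        assert c.verdicts["weak_and_repeat"] == "fail:repeat"

    def test_autocorrelation_detects_period(self):
        assert lf.tandem_repeat_fraction("QAQAQAQAQAQAQAQA") == 1.0
        random_pep = "MKVLWEAHRNDTQYFGSICP" * 3
        assert lf.tandem_repeat_fraction(random_pep) < 0.8


class TestScaffoldTriage:
    def test_classification_against_truth(self, dataset):
        bact_nt = list(dataset.donors.donorA_genome) + list(dataset.donors.donorB_genome)
        verdicts = lf.classify_scaffolds(
            dataset.assembly, bact_nt, dataset.related_genome,
            reads=[r.read for r in dataset.reads])
        for sid, truth_cls in dataset.scaffold_truth.items():
            assert verdicts[sid].cls == truth_cls, sid

    def test_short_scaffold_without_evidence_is_contaminant(self, dataset):
        junk = [s for s in dataset.assembly if s.id.startswith("JUNK")]
        assert junk
        bact_nt = list(dataset.donors.donorA_genome)
        verdicts = lf.classify_scaffolds(
            Assembly(junk), bact_nt, dataset.related_genome)
        for s in junk:
            v = verdicts[s.id]
            assert v.cls == "contaminant" and v.short_flag and not v.host_hit


class TestChimericReads:
    def test_junction_support_rule(self, dataset):
        bact_nt = list(dataset.donors.donorA_genome) + list(dataset.donors.donorB_genome)
        calls = lf.detect_chimeric_reads(
            [r.read for r in dataset.reads], bact_nt, list(dataset.assembly),
            vector_db=[dataset.vector])
        by_id = {c.read_id: c for c in calls}
        truth = {r.read.id: r.category for r in dataset.reads}
        # multi-read supported junctions are LGT evidence
        support_ids = [rid for rid, cat in truth.items() if cat == "junction_support"]
        assert support_ids
        assert all(by_id[r].verdict == "chimera_lgt_evidence" for r in support_ids)
        # singleton artifacts never become evidence
        artifact_ids = [rid for rid, cat in truth.items() if cat == "artifact_chimera"]
        assert all(by_id[r].verdict != "chimera_lgt_evidence" for r in artifact_ids)
        # vector reads are excluded up front
        vec_ids = [rid for rid, cat in truth.items() if cat == "vector"]
        assert all(by_id[r].verdict == "vector" for r in vec_ids)

    def test_single_region_both_dbs_is_conserved(self, dataset):
        # contaminant-derived reads hit the bacterial db AND the assembly
        # (which contains the contaminant scaffolds) over one region
        bact_nt = list(dataset.donors.donorA_genome) + list(dataset.donors.donorB_genome)
        calls = lf.detect_chimeric_reads(
            [r.read for r in dataset.reads], bact_nt, list(dataset.assembly))
        truth = {r.read.id: r.category for r in dataset.reads}
        contam = [c for c in calls if truth[c.read_id] == "contaminant"]
        assert contam
        frac_conserved = np.mean([c.verdict == "conserved" for c in contam])
        assert frac_conserved > 0.9


class TestSymbiontScreen:
    def test_high_identity_fragment_recovered_and_contaminants_excluded(self, rng):
        host = Scaffold(id="H1", sequence="".join(
            rng.choice(list("ACGT"), size=20000, p=[0.35, 0.15, 0.15, 0.35])))
        symbiont = Scaffold(id="symb", sequence="".join(
            rng.choice(list("ACGT"), size=8000, p=[0.37, 0.13, 0.13, 0.37])))
        # implant a 500-nt symbiont fragment at 95% identity
        frag = list(symbiont.sequence[1000:1500])
        for i in range(len(frag)):
            if rng.random() < 0.05:
                frag[i] = "ACGT".replace(frag[i], "")[int(rng.integers(3))]
        host.sequence = host.sequence[:5000] + "".join(frag) + host.sequence[5500:]
        asm = Assembly([host])
        cands = [c for c in lf.symbiont_nt_screen([symbiont], asm, None) if c.alive]
        assert any(abs(c.locus.start - 5001) < 50 and abs(c.locus.end - 5500) < 50
                   for c in cands)
        # the same fragment on a contaminant-classified scaffold is excluded
        verdicts = {"H1": lf.ScaffoldVerdict("H1", "contaminant", 1.0, False, False)}
        assert lf.symbiont_nt_screen([symbiont], asm, verdicts) == []


class TestExpandParalogs:
    def test_tandem_copies_found_from_one_seed(self, rng):
        from lgtscreen.synthetic_data import reverse_translate, AA20

        protein = "".join(rng.choice(list(AA20), size=150))
        copies = [reverse_translate(protein, rng, 0.3) for _ in range(1)]
        gene = copies[0]
        spacer = lambda: "".join(rng.choice(list("ACGT"), size=3000,
                                            p=[0.35, 0.15, 0.15, 0.35]))
        seq = spacer()
        starts = []
        for _ in range(5):
            starts.append(len(seq) + 1)
            seq += gene + spacer()
        asm = Assembly([Scaffold(id="S", sequence=seq)])
        seed = lf.CandidateRecord(
            "seed", GenomicInterval("S", starts[0], starts[0] + len(gene) - 1),
            "final", peptide=protein)
        extra = lf.expand_paralogs([seed], asm, bits_min=40.0)
        # 4 additional non-overlapping loci, none overlapping the seed
        assert len(extra) == 4
        for e in extra:
            assert e.locus.overlap(seed.locus) == 0

    def test_no_paralogs_no_extras(self, rng):
        from lgtscreen.synthetic_data import reverse_translate, AA20

        protein = "".join(rng.choice(list(AA20), size=150))
        gene = reverse_translate(protein, rng, 0.3)
        seq = "".join(rng.choice(list("ACGT"), size=2000)) + gene + \
              "".join(rng.choice(list("ACGT"), size=2000))
        asm = Assembly([Scaffold(id="S", sequence=seq)])
        seed = lf.CandidateRecord(
            "seed", GenomicInterval("S", 2001, 2000 + len(gene)), "final",
            peptide=protein)
        assert lf.expand_paralogs([seed], asm, bits_min=40.0) == []


def test_funnel_monotone(pipeline_run):
    counts = [row["count"] for row in pipeline_run.funnel]
    screen_part = counts[:5]  # enumeration through scaffold triage
    assert all(a >= b for a, b in zip(screen_part, screen_part[1:]))
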