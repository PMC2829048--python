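import numpy as np
import pytest

from lgtscreen import synthetic_data as sd
from lgtscreen.seqio import extract_region, translate


class TestHostAssembly:
    def test_determinism_byte_identical(self, tmp_path):
        d1 = sd.generate(sd.GeneratorConfig(seed=7))
        d2 = sd.generate(sd.GeneratorConfig(seed=7))
        d1.write(tmp_path / "a")
        d2.write(tmp_path / "b")
        for name in ("assembly.fasta", "reads.fasta", "qpcr.csv", "truth_events.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_gc_concentration(self):
        cfg = sd.GeneratorConfig(seed=3, host_gc=0.30)
        asm, _ = sd.generate_host_assembly(cfg)
        seq = "".join(s.sequence for s in asm).replace("N", "")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.29 <= gc <= 0.31

    def test_gap_track_count(self):
        cfg = sd.GeneratorConfig(seed=3, n_gap_runs=5)
        _, gaps = sd.generate_host_assembly(cfg)
        assert len(gaps) == 5

    def test_degenerate_config_rejected(self):
        with pytest.raises(sd.GeneratorConfigError):
            sd.GeneratorConfig(seed=1, n_scaffolds=0).validate()
        with pytest.raises(sd.GeneratorConfigError):
            sd.GeneratorConfig(seed=1, coverage=0).validate()


class TestDonorEvolution:
    def test_zero_divergence_identity(self, rng):
        p = "MKVLW" * 20
        assert sd.diverge_protein(p, 0.0, rng) == p

    def test_divergence_expectation(self, rng):
        p = "".join(rng.choice(list(sd.AA20), size=300))
        idents = []
        for _ in range(20):
            q = sd.diverge_protein(p, 0.35, rng)
            idents.append(sum(a == b for a, b in zip(p, q)) / len(p))
        assert abs(np.mean(idents) - 0.65) < 0.05

    def test_conserved_decoy_count_and_reservation(self, dataset):
        cfg = dataset.cfg
        n_conserved = int(round(cfg.conserved_fraction * cfg.n_decoy_proteins))
        assert len(dataset.donors.conserved_pairs) == n_conserved
        # reserved families never serve as transfer sources
        used = {e.homolog_id for e in dataset.truth_events}
        assert not (used & dataset.donors.reserved_donor_ids)

    def test_core_families_are_orthologous(self, dataset):
        group = next(iter(dataset.donors.ortholog_groups.values()))
        by_id = {p.id: p.sequence for p in
                 dataset.donors.donorA + dataset.donors.donorB + dataset.donors.outgroup}
        a, b = by_id[group["donorA"]], by_id[group["donorB"]]
        assert len(a) == len(b)
        ident = sum(x == y for x, y in zip(a, b)) / len(a)
        assert 0.4 < ident < 0.75  # two lineage divergences from the ancestor


class TestImplants:
    def test_functional_implants_have_intact_spliced_cds(self, dataset):
        for ev in dataset.truth_events:
            if ev.cls in ("functional_LGT", "paralog_cluster", "chimeric_fusion"):
                seq = dataset.assembly[ev.locus.scaffold_id].sequence
                cds = "".join(seq[a - 1:b] for a, b in ev.exons)
                assert "*" not in translate(cds), ev.event_id

    def test_stop_riddled_fragment_structure(self, dataset):
        ev = next(e for e in dataset.truth_events if e.event_id == "atph01_psi")
        pep = translate(extract_region(dataset.assembly, ev.locus))
        assert len(pep) == 100
        assert pep.count("*") == 3

    def test_frameshift_count_recorded(self, dataset):
        ev = next(e for e in dataset.truth_events if e.event_id == "ldca03_psi")
        assert ev.n_frameshifts == 11
        assert len(ev.indels) == 11
        assert all(abs(size) in (1, 2) for _, size in ev.indels)

    def test_truth_loci_avoid_gaps_and_overlap_rules(self, dataset):
        for ev in dataset.truth_events:
            region = extract_region(dataset.assembly, ev.locus)
            assert "N" not in region, ev.event_id
        # non-overlap except within a declared cluster scaffold
        by_scaffold = {}
        for ev in dataset.truth_events:
            by_scaffold.setdefault(ev.locus.scaffold_id, []).append(ev)
        for sid, evs in by_scaffold.items():
            evs.sort(key=lambda e: e.locus.start)
            for a, b in zip(evs, evs[1:]):
                assert a.locus.overlap(b.locus) == 0

    def test_paralog_cluster_tandem_and_identity(self, dataset):
        rlpa = [e for e in dataset.truth_events if e.cluster_id == "rlpa"]
        assert len(rlpa) == 5
        assert len({e.locus.scaffold_id for e in rlpa}) == 1
        seqs = [extract_region(dataset.assembly, e.locus) for e in rlpa]
        ident = np.mean([a == b for a, b in zip(seqs[0], seqs[1])])
        assert 0.94 <= ident <= 0.995

    def test_truth_validation_invariants(self, dataset):
        for ev in dataset.truth_events:
            ev.validate()


class TestContaminantsAndReads:
    def test_contaminant_identity_limit(self, rng):
        cfg = sd.GeneratorConfig(seed=2, contaminant_identity=1.0)
        donors = sd.evolve_donor_proteomes(cfg, np.random.default_rng(2))
        contam, _, _ = sd.make_contaminants(donors, cfg, np.random.default_rng(3))
        genomes = {"donorA": donors.donorA_genome[0].sequence,
                   "donorB": donors.donorB_genome[0].sequence}
        for s in contam:
            if s.id.startswith("CONTAM"):
                assert any(s.sequence in g for g in genomes.values())

    def test_read_count_coverage_arithmetic(self, dataset):
        cfg = dataset.cfg
        total = dataset.assembly.total_length()
        normal = [r for r in dataset.reads if r.category in ("host", "contaminant")]
        expected = cfg.coverage * total / cfg.read_len_mean
        assert abs(len(normal) - expected) / expected < 0.10

    def test_zero_chimeric_rate(self):
        cfg = sd.GeneratorConfig(seed=4, chimeric_read_rate=0.0)
        ds = sd.generate(cfg)
        assert not any(r.category == "artifact_chimera" for r in ds.reads)

    def test_junction_support_reads_emitted(self, dataset):
        support = [r for r in dataset.reads if r.category == "junction_support"]
        assert len(support) == dataset.cfg.junction_support

    def test_reads_have_no_assembly_gap_ns(self, dataset):
        n_frac = [r.read.sequence.count("N") / len(r.read.sequence)
                  for r in dataset.reads]
        assert max(n_frac) == 0.0


class TestQpcrSimulation:
    def test_noiseless_limit(self):
        cfg = sd.GeneratorConfig(seed=5, qpcr_sigma_genomic=0.0, qpcr_tech_sigma=0.0)
        t = sd.simulate_qpcr(["g"], [], cfg, np.random.default_rng(5))
        assert np.allclose(t["ratio"], 1.0)

    def test_genomic_sample_mean_concentration(self):
        hit = 0
        for seed in range(40):
            cfg = sd.GeneratorConfig(seed=seed, qpcr_sigma_genomic=0.1,
                                     qpcr_tech_sigma=0.0, qpcr_tech_reps=1)
            t = sd.simulate_qpcr(["g"], [], cfg, np.random.default_rng(seed))
            if abs(t["ratio"].mean() - 1.0) <= 0.12:
                hit += 1
        assert hit >= 38  # >= 95% of seeds

    def test_contaminant_cv_exceeds_genomic(self):
        wins = 0
        for seed in range(20):
            cfg = sd.GeneratorConfig(seed=seed)
            t = sd.simulate_qpcr(["g"], ["c"], cfg, np.random.default_rng(seed))
            cv = t.groupby("locus")["ratio"].apply(lambda r: r.std() / r.mean())
            wins += cv["c"] > cv["g"]
        assert wins >= 18
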