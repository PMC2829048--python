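"""End-to-end orchestration: generate/load -> screen -> annotate -> attribute -> verify.

The run follows the published screening order:

1. enumerate PPPs (>=60 aa stop-to-stop peptides) and 1 kb/200 nt windows;
2. protein and six-frame searches against the bacterial proteomes
   (bit >= 40), then the invertebrate comparison and weak/repeat filters;
3. scaffold triage (contaminants, chimeric scaffolds) removes candidates
   wholesale;
4. read-pool chimera analysis and the symbiont nucleotide screen (E<1e-5)
   contribute additional evidence/candidates;
5. surviving hits are merged into gene-level loci, paralogs are expanded by
   translated search of candidate peptides against the assembly;
6. final candidates are annotated against their best donor homolog
   (frameshifts/stops/truncation/introns), placed on NJ trees with
   bootstrap support, and checked against replicate qPCR copy numbers.

Against a synthetic dataset the report additionally scores recovery versus
the implanted truth.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import lgt_filter as lf
from .copy_number import copy_number_call
from .homology import AlignmentHit, best_hit, search
from .orf_screen import extract_ppps, make_windows
from .phylo_stats import PlacementCall, placement_report
from .pseudogene import PseudogeneReport, annotate_locus
from .seqio import Assembly, GenomicInterval, Scaffold, extract_region
from .synthetic_data import GeneratorConfig, SyntheticDataset, TruthEvent, generate


@dataclass
class RunConfig:
    """Thresholds and stage switches; defaults follow the published screen."""

    min_ppp_len: int = 60
    window_len: int = 1000
    window_overlap: int = 200
    protein_bits_min: float = 40.0
    nt_bits_min: float = 55.0
    margin_bits: float = 0.0
    weak_bits_max: float = 45.0
    weak_e_min: float = 0.001
    symbiont_e_max: float = 1e-5
    merge_gap: int = 2500
    protein_seed_len: int | None = 4  # k-mer prefilter for protein searches
    run_read_screen: bool = True
    run_symbiont_screen: bool = True
    run_placement: bool = True
    run_qpcr: bool = True
    bootstrap_replicates: int = 200
    placement_support_min: float = 70.0
    seed: int = 0


@dataclass
class CandidateLocus:
    locus: GenomicInterval
    subject_id: str
    bit_score: float
    sources: list[str]
    peptide: str = ""
    pseudogene: PseudogeneReport | None = None
    placement: PlacementCall | None = None
    paralog_of: str | None = None

    @property
    def locus_id(self) -> str:
        return f"{self.locus.scaffold_id}:{self.locus.start}-{self.locus.end}"


@dataclass
class RunReport:
    funnel: list[dict]
    candidates: list[CandidateLocus]
    scaffold_verdicts: dict
    chimera_calls: list
    copy_number: list
    recovery: dict | None = None
    timings: dict = field(default_factory=dict)

    def inventory_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append({
                "locus": c.locus_id,
                "scaffold": c.locus.scaffold_id,
                "start": c.locus.start, "end": c.locus.end,
                "top_hit": c.subject_id, "bit_score": round(c.bit_score, 1),
                "sources": "+".join(sorted(set(c.sources))),
                "n_frameshifts": c.pseudogene.n_frameshifts if c.pseudogene else None,
                "n_internal_stops": c.pseudogene.n_internal_stops if c.pseudogene else None,
                "truncation": round(c.pseudogene.truncation_fraction, 3) if c.pseudogene else None,
                "intact": c.pseudogene.intact if c.pseudogene else None,
                "lineage": c.placement.lineage if c.placement else None,
                "placement_support": c.placement.support if c.placement else None,
                "paralog_of": c.paralog_of,
            })
        return pd.DataFrame(rows)


def run_pipeline(dataset: SyntheticDataset, cfg: RunConfig | None = None) -> RunReport:
    """Run the full screen against a (synthetic or loaded) dataset."""
    if cfg is None:
        cfg = RunConfig()
    t0 = time.time()
    assembly = dataset.assembly
    bacterial_prot = list(dataset.donors.donorA) + list(dataset.donors.donorB)
    invertebrate_prot = list(dataset.donors.decoy)
    bacterial_nt = list(dataset.donors.donorA_genome) + list(dataset.donors.donorB_genome)
    funnel: list[tuple[str, int]] = []
    timings: dict[str, float] = {}

    # --- stage 1: enumeration -------------------------------------------------
    ppps = extract_ppps(assembly, min_len=cfg.min_ppp_len)
    windows = make_windows(assembly, cfg.window_len, cfg.window_overlap)
    funnel.append(("ppps_enumerated", len(ppps)))
    timings["enumeration"] = time.time() - t0

    # --- stage 2: bacterial screen -------------------------------------------
    t = time.time()
    ppp_seqs = [p.to_scaffold() for p in ppps]
    ppp_hits = search(
        ppp_seqs, bacterial_prot, mode="prot-prot",
        bits_min=cfg.protein_bits_min, db_tag="bacterial",
        seed_len=cfg.protein_seed_len, min_seeds=1,
    )
    # report window hits down to half the threshold: an alignment split by
    # a window boundary is re-joined on the genome and re-scored before the
    # threshold applies (the windowing is a processing device, not a unit
    # of significance)
    win_hits_raw = search(
        [w.to_scaffold() for w in windows], bacterial_prot, mode="translated-query",
        bits_min=cfg.protein_bits_min / 2, db_tag="bacterial",
        seed_len=5, min_seeds=1, best_per_pair=False,
    )
    window_hsps = _merge_window_hits(
        win_hits_raw, windows, assembly, bacterial_prot, cfg.protein_bits_min)

    hits_by_query: dict[str, list[AlignmentHit]] = {}
    for h in ppp_hits:
        hits_by_query.setdefault(h.query_id, []).append(h)

    ppp_by_id = {p.id: p for p in ppps}
    win_by_id = {w.id: w for w in windows}
    candidates: list[lf.CandidateRecord] = []
    window_region: dict[str, str] = {}
    for qid in sorted(hits_by_query):
        p = ppp_by_id[qid]
        cand = lf.CandidateRecord(qid, p.interval, "assembly_ppp", peptide=p.peptide)
        lf.bacterial_screen(cand, hits_by_query[qid], mode="protein",
                            bits_min=cfg.protein_bits_min)
        if cand.alive:
            candidates.append(cand)
    for qid, iv, region, hit in window_hsps:
        cand = lf.CandidateRecord(qid, iv, "window")
        lf.bacterial_screen(cand, [hit], mode="protein",
                            bits_min=cfg.protein_bits_min)
        if cand.alive:
            candidates.append(cand)
            window_region[qid] = region
    funnel.append(("bacterial_screen", len(candidates)))
    timings["bacterial_screen"] = time.time() - t

    # --- stage 3: invertebrate comparison ------------------------------------
    t = time.time()
    surv_seqs = []
    for cand in candidates:
        if cand.source == "assembly_ppp":
            surv_seqs.append(Scaffold(id=cand.query_id, sequence=cand.peptide))
        else:
            surv_seqs.append(Scaffold(id=cand.query_id,
                                      sequence=window_region[cand.query_id]))
    ppp_queries = [s for s, c in zip(surv_seqs, candidates) if c.source == "assembly_ppp"]
    win_queries = [s for s, c in zip(surv_seqs, candidates) if c.source == "window"]
    inv_hits: dict[str, list[AlignmentHit]] = {}
    for h in search(ppp_queries, invertebrate_prot, mode="prot-prot", bits_min=10.0,
                    db_tag="invertebrate", seed_len=cfg.protein_seed_len, min_seeds=1):
        inv_hits.setdefault(h.query_id, []).append(h)
    for h in search(win_queries, invertebrate_prot, mode="translated-query",
                    bits_min=10.0, db_tag="invertebrate", seed_len=5, min_seeds=1):
        inv_hits.setdefault(h.query_id, []).append(h)
    for cand in candidates:
        lf.invertebrate_comparison(cand, inv_hits.get(cand.query_id, []),
                                   margin_bits=cfg.margin_bits)
    candidates = [c for c in candidates if c.alive]
    funnel.append(("invertebrate_comparison", len(candidates)))
    timings["invertebrate_comparison"] = time.time() - t

    # --- stage 4: weak / repeat ----------------------------------------------
    for cand in candidates:
        if cand.source == "assembly_ppp":
            qseq = cand.peptide
        else:
            qseq = window_region[cand.query_id]
        lf.weak_and_repeat_filter(cand, qseq, weak_bits_max=cfg.weak_bits_max,
                                  weak_e_min=cfg.weak_e_min)
    candidates = [c for c in candidates if c.alive]
    funnel.append(("weak_and_repeat", len(candidates)))

    # --- stage 5: scaffold triage --------------------------------------------
    t = time.time()
    reads = [r.read for r in dataset.reads]
    verdicts = lf.classify_scaffolds(
        assembly, bacterial_nt, dataset.related_genome,
        reads=reads if cfg.run_read_screen else None,
    )
    for cand in candidates:
        v = verdicts.get(cand.locus.scaffold_id) if cand.locus else None
        ok = v is None or v.cls == "host"
        cand.record("scaffold_triage", ok, v.cls if v else "unknown_scaffold")
    candidates = [c for c in candidates if c.alive]
    funnel.append(("scaffold_triage", len(candidates)))
    timings["scaffold_triage"] = time.time() - t

    # --- stage 6: read chimera analysis --------------------------------------
    t = time.time()
    chimera_calls = []
    if cfg.run_read_screen:
        chimera_calls = lf.detect_chimeric_reads(
            reads, bacterial_nt, list(assembly), vector_db=[dataset.vector])
    timings["read_screen"] = time.time() - t

    # --- stage 7: symbiont nucleotide screen ---------------------------------
    t = time.time()
    symbiont_cands: list[lf.CandidateRecord] = []
    if cfg.run_symbiont_screen:
        symbiont_cands = [
            c for c in lf.symbiont_nt_screen(
                dataset.donors.donorB_genome, assembly, verdicts,
                related_genome=dataset.related_genome, e_max=cfg.symbiont_e_max)
            if c.alive
        ]
    timings["symbiont_screen"] = time.time() - t

    # --- stage 8: merge into loci, expand paralogs ----------------------------
    t = time.time()
    loci_in = []
    for cand in candidates:
        h = cand.best_bacterial
        loci_in.append((cand.locus, h.subject_id, h.bit_score))
    for cand in symbiont_cands:
        loci_in.append((cand.locus, cand.best_bacterial.query_id, cand.best_bacterial.bit_score))
    merged = lf.merge_candidate_loci(loci_in, cfg.merge_gap)
    # collapse loci of different subjects overlapping the same span; a
    # protein-database subject wins over a genome-window subject so the
    # downstream annotation has a homolog to align against
    prot_by_id = {p.id: p for p in bacterial_prot}
    merged_final: list[tuple[GenomicInterval, str, float]] = []
    for iv, subject, bits in sorted(merged, key=lambda x: (x[0].scaffold_id, x[0].start, -x[2])):
        absorbed = False
        for k, (miv, msub, mbits) in enumerate(merged_final):
            if miv.overlap(iv) > 0.5 * min(len(miv), len(iv)):
                lo = min(miv.start, iv.start)
                hi = max(miv.end, iv.end)
                prefer_new = (subject in prot_by_id, bits) > (msub in prot_by_id, mbits)
                if prefer_new:
                    msub, mbits = subject, bits
                merged_final[k] = (GenomicInterval(miv.scaffold_id, lo, hi), msub, mbits)
                absorbed = True
                break
        if not absorbed:
            merged_final.append((iv, subject, bits))

    final: list[CandidateLocus] = []
    for iv, subject, bits in merged_final:
        final.append(CandidateLocus(iv, subject, bits, sources=["screen"],
                                    peptide=""))
    funnel.append(("merged_loci", len(final)))

    # paralog expansion uses the best available peptide per locus: the
    # conceptual translation of the aligned donor frame via annotation below
    timings["merge"] = time.time() - t

    # --- stage 9: pseudogene annotation --------------------------------------
    # the screen's hit intervals seed each locus; the frameshift-aware
    # annotation (run with flanks, both orientations) defines the gene span
    t = time.time()
    flank = 1200
    for c in final:
        homolog = prot_by_id.get(c.subject_id)
        if homolog is None:
            continue
        scaffold_len = len(assembly[c.locus.scaffold_id].sequence)
        lo = max(1, c.locus.start - flank)
        hi = min(scaffold_len, c.locus.end + flank)
        best = None
        best_strand = "+"
        for strand in "+-":
            ext = GenomicInterval(c.locus.scaffold_id, lo, hi, strand)
            locus_nt = extract_region(assembly, ext)
            try:
                rep_s = annotate_locus(
                    locus_nt, homolog.sequence, locus_id=c.locus_id,
                    homolog_id=homolog.id)
            except ValueError:
                rep_s = None
            if rep_s is not None and (best is None or rep_s.score > best.score):
                best = rep_s
                best_strand = strand
        c.pseudogene = best
        if best is not None:
            a, b = best.aligned_locus_span
            if best_strand == "+":
                new_lo, new_hi = lo + a - 1, lo + b - 1
            else:
                ext_len = hi - lo + 1
                new_lo, new_hi = lo + (ext_len - b), lo + (ext_len - a)
            c.locus = GenomicInterval(c.locus.scaffold_id, new_lo, new_hi, best_strand)
        if c.pseudogene is not None:
            # candidate peptide for paralog expansion and placement: the
            # conceptual translation of the locus' aligned exon codons
            from .seqio import translate

            ext = GenomicInterval(c.locus.scaffold_id, lo, hi, best_strand)
            locus_nt = extract_region(assembly, ext)
            pep = ""
            for ex in c.pseudogene.exons:
                seg = locus_nt[ex.start - 1: ex.end]
                pep += translate(seg[: len(seg) - len(seg) % 3]).replace("*", "X")
            c.peptide = pep
    timings["pseudogene"] = time.time() - t

    # --- stage 10: paralog expansion ------------------------------------------
    t = time.time()
    seed_records = [
        lf.CandidateRecord(c.locus_id, c.locus, "final", peptide=c.peptide)
        for c in final
    ]
    extra = lf.expand_paralogs(seed_records, assembly, bits_min=cfg.protein_bits_min,
                               scaffold_verdicts=verdicts, merge_gap=cfg.merge_gap)
    for e in extra:
        final.append(CandidateLocus(e.locus, e.query_id, 0.0,
                                    sources=["paralog_expansion"],
                                    paralog_of=e.query_id.split(":", 1)[1]))
    funnel.append(("with_paralogs", len(final)))
    timings["paralog_expansion"] = time.time() - t

    # --- stage 11: placement ---------------------------------------------------
    t = time.time()
    if cfg.run_placement:
        lineages = {p.id: "donorA" for p in dataset.donors.donorA}
        lineages.update({p.id: "donorB" for p in dataset.donors.donorB})
        lineages.update({p.id: "outgroup" for p in dataset.donors.outgroup})
        for c in final:
            if not c.peptide or len(c.peptide) < 30:
                continue
            refs = _pick_references(c, dataset)
            if len(refs) < 3:
                continue
            c.placement = placement_report(
                Scaffold(id="candidate", sequence=c.peptide), refs, lineages,
                support_min=cfg.placement_support_min,
                B=cfg.bootstrap_replicates, seed=cfg.seed + 17)
    timings["placement"] = time.time() - t

    # --- stage 12: copy number -------------------------------------------------
    t = time.time()
    cn_verdicts = []
    if cfg.run_qpcr and dataset.qpcr is not None and len(dataset.qpcr):
        cn_verdicts = copy_number_call(dataset.qpcr)
    timings["copy_number"] = time.time() - t

    final.sort(key=lambda c: (c.locus.scaffold_id, c.locus.start))
    report = RunReport(
        funnel=lf.funnel_summary(funnel),
        candidates=final,
        scaffold_verdicts=verdicts,
        chimera_calls=chimera_calls,
        copy_number=cn_verdicts,
        timings=timings,
    )
    report.recovery = compare_to_truth(report, dataset.truth_events, dataset)
    return report


def _merge_window_hits(
    win_hits, windows, assembly: Assembly, bacterial_prot, bits_min: float,
    join_gap: int = 300,
) -> list[tuple[str, GenomicInterval, str, AlignmentHit]]:
    """Join window-level translated hits into genome-level HSPs.

    Hits to the same subject whose genomic intervals fall within
    ``join_gap`` are merged; joined or sub-threshold groups are re-aligned
    over the merged genomic region against their subject, and the bit
    threshold is applied to the genome-level alignment.  Returns
    (id, genomic interval, region sequence, hit with region-relative query
    coordinates) for every HSP at or above the threshold.
    """
    win_by_id = {w.id: w for w in windows}
    entries: dict[tuple[str, str], list[tuple[int, int, AlignmentHit]]] = {}
    for h in win_hits:
        w = win_by_id[h.query_id]
        g_lo = w.start + min(h.q_start, h.q_end) - 1
        g_hi = w.start + max(h.q_start, h.q_end) - 1
        entries.setdefault((w.scaffold_id, h.subject_id), []).append((g_lo, g_hi, h))
    prot_by_id = {p.id: p for p in bacterial_prot}
    out = []
    for (sid, subject), items in sorted(entries.items()):
        items.sort(key=lambda x: (x[0], x[1]))
        groups: list[list[tuple[int, int, AlignmentHit]]] = [[items[0]]]
        for it in items[1:]:
            if it[0] <= groups[-1][-1][1] + join_gap:
                groups[-1].append(it)
            else:
                groups.append([it])
        for grp in groups:
            lo = min(g[0] for g in grp)
            hi = max(g[1] for g in grp)
            best = max(grp, key=lambda g: g[2].bit_score)[2]
            if len(grp) == 1 and best.bit_score >= bits_min:
                iv = GenomicInterval(sid, lo, hi)
                region = extract_region(assembly, iv)
                hit = best
            else:
                # re-align the joined genomic region against the subject
                pad_lo = max(1, lo - 30)
                pad_hi = min(len(assembly[sid].sequence), hi + 30)
                iv0 = GenomicInterval(sid, pad_lo, pad_hi)
                region = extract_region(assembly, iv0)
                rehits = search(
                    [Scaffold(id="region", sequence=region)],
                    [prot_by_id[subject]], mode="translated-query",
                    bits_min=bits_min, db_tag="bacterial")
                if not rehits:
                    continue
                hit = rehits[0]
                iv = GenomicInterval(sid, pad_lo + min(hit.q_start, hit.q_end) - 1,
                                     pad_lo + max(hit.q_start, hit.q_end) - 1)
                region = extract_region(assembly, iv)
            qid = f"{sid}:hsp{iv.start}:{subject}"
            out.append((qid, iv, region, hit))
    return out


def _pick_references(c: CandidateLocus, dataset: SyntheticDataset) -> list[Scaffold]:
    """Reference proteins for placement: the candidate's ortholog family.

    The family tree of the best-hit protein — its orthologs in both donor
    lineages plus the distant outgroup lineage — is the informative
    comparison set; a lineage-specific gene without a family yields no
    references and the candidate stays unplaced.
    """
    group = dataset.donors.family_of(c.subject_id)
    if group is None:
        return []
    by_id = {p.id: p for p in (dataset.donors.donorA + dataset.donors.donorB
                               + dataset.donors.outgroup)}
    return [by_id[pid] for pid in group.values() if pid in by_id]


def compare_to_truth(
    report: RunReport, truth: list[TruthEvent], dataset: SyntheticDataset,
) -> dict:
    """Locus-level recovery: >=50% reciprocal-overlap matching to truth events."""
    matched_truth: set[str] = set()
    tp = 0
    fp_contaminant = 0
    fp_other = 0
    assignments: dict[str, str] = {}
    for c in report.candidates:
        hit = None
        for ev in truth:
            ov = c.locus.overlap(ev.locus)
            if ov >= 0.5 * len(ev.locus) and ov >= 0.5 * len(c.locus):
                hit = ev
                break
        if hit is not None:
            tp += 1
            matched_truth.add(hit.event_id)
            assignments[c.locus_id] = hit.event_id
        else:
            cls = dataset.scaffold_truth.get(c.locus.scaffold_id, "host")
            if cls != "host":
                fp_contaminant += 1
            else:
                fp_other += 1
    n_truth = len(truth)
    per_class: dict[str, dict] = {}
    for ev in truth:
        d = per_class.setdefault(ev.cls, {"total": 0, "recovered": 0})
        d["total"] += 1
        d["recovered"] += ev.event_id in matched_truth
    sensitivity = len(matched_truth) / n_truth if n_truth else float("nan")
    n_cand = len(report.candidates)
    return {
        "sensitivity": sensitivity,
        "n_truth": n_truth,
        "n_candidates": n_cand,
        "n_matched_candidates": tp,
        "contaminant_false_candidates": fp_contaminant,
        "other_false_candidates": fp_other,
        "precision_vs_contaminants": 1.0 - (fp_contaminant / n_cand) if n_cand else float("nan"),
        "per_class": per_class,
        "missed": sorted(ev.event_id for ev in truth if ev.event_id not in matched_truth),
        "assignments": assignments,
    }


def run_synthetic(seed: int = 1, gen_cfg: GeneratorConfig | None = None,
                  run_cfg: RunConfig | None = None) -> tuple[SyntheticDataset, RunReport]:
    """Generate the default synthetic scenario and screen it."""
    if gen_cfg is None:
        gen_cfg = GeneratorConfig(seed=seed)
    dataset = generate(gen_cfg)
    if run_cfg is None:
        run_cfg = RunConfig(seed=seed)
    return dataset, run_pipeline(dataset, run_cfg)


def write_report(report: RunReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.funnel).to_csv(out / "funnel.tsv", sep="\t", index=False)
    report.inventory_frame().to_csv(out / "candidates.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"scaffold_id": v.scaffold_id, "class": v.cls,
         "bacterial_coverage": v.bacterial_coverage, "host_hit": v.host_hit,
         "short": v.short_flag}
        for v in report.scaffold_verdicts.values()
    ]).to_csv(out / "scaffold_verdicts.tsv", sep="\t", index=False)
    if report.chimera_calls:
        pd.DataFrame([
            {"read_id": c.read_id, "verdict": c.verdict, "support": c.support}
            for c in report.chimera_calls
        ]).to_csv(out / "read_chimeras.tsv", sep="\t", index=False)
    if report.copy_number:
        pd.DataFrame([
            {"locus": v.locus, "mean_ratio": round(v.mean_ratio, 3),
             "se": round(v.se_ratio, 3), "anova_p": v.anova_p,
             "strain_t_p": v.strain_t_p, "call": v.call}
            for v in report.copy_number
        ]).to_csv(out / "copy_number.tsv", sep="\t", index=False)
    with open(out / "candidates.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for c in report.candidates:
            fh.write("\t".join([
                c.locus.scaffold_id, "lgtscreen", "LGT_candidate",
                str(c.locus.start), str(c.locus.end), f"{c.bit_score:.1f}",
                c.locus.strand, ".",
                f"ID={c.locus_id};top_hit={c.subject_id}",
            ]) + "\n")
    if report.recovery:
        rec = {k: v for k, v in report.recovery.items() if k not in ("assignments",)}
        pd.Series(rec, dtype=object).to_json(out / "recovery.json", indent=2)
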