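# lgtscreen

A tested pipeline for detecting **bacteria-to-insect lateral gene transfer
(LGT)** in a draft genome assembly, exercised end-to-end on truth-tagged
synthetic data.

Obligate insect symbioses raise the question of whether host genomes have
absorbed genes from their bacterial partners (as organelle-bearing
lineages did) or from other infecting bacteria. Answering it from a draft
assembly is mostly a *filtering* problem: bacterial-looking sequence in an
insect assembly is usually a contaminant scaffold, a cloning chimera, a
broadly conserved gene, or a spurious weak hit — and only rarely a
transferred locus, which may be a functional intron-bearing gene, a
tandem-duplicated family, a host–donor fusion, or a decaying pseudogene
riddled with frameshifts and premature stops.

`lgtscreen` implements that screen as a library:

* **Enumeration** — stop-to-stop potential polypeptides (PPPs, ≥ 60 aa,
  all six frames) and overlapping 1,000/200-nt windows for translated
  searches.
* **Search** — affine Smith–Waterman with Karlin–Altschul bit/E
  statistics (S′ = (λS − ln K)/ln 2, E = mn·2^(−S′)), k-mer-seeded at
  genome scale, plus an adapter for external 12-column tabular reports.
* **Filter cascade** — bacterial similarity (≥ 40 bits protein / ≥ 55 nt),
  invertebrate comparison with conserved-gene exclusion, the Δ ≥ 13-bit
  full-protein recheck, weak-hit (≤ 45 bits AND E ≥ 0.001) and
  repeat/low-complexity exclusion, contaminant- and chimeric-scaffold
  triage, read-pool chimera analysis with multi-read junction support,
  a symbiont-genome nucleotide screen (E < 1e−5), and paralog expansion.
* **Annotation** — a spliced, frameshift-aware protein-vs-DNA dynamic
  program that counts frameshift junctions and internal stops, measures
  truncation, and recovers GT..AG exon chains.
* **Attribution** — neighbor joining with bootstrap support over each
  candidate's ortholog family, and Tajima's relative-rate test
  (χ² = (m1−m2)²/(m1+m2)) for pseudogene acceleration.
* **Verification** — replicate qPCR copy-number ratios: one-way ANOVA +
  Tukey–Kramer across samples, a strain t-test, and a calibrated
  single-copy-genomic vs variable-titer verdict.
* **Synthetic truth** — a generator that implants all of the above event
  types into an AT-rich gapped assembly, with contaminants, chimeric
  reads, vector reads and qPCR tables, every feature truth-tagged.

## Worked example

```python
from lgtscreen.pipeline import RunConfig, run_pipeline
from lgtscreen.synthetic_data import GeneratorConfig, generate

dataset = generate(GeneratorConfig(seed=1))     # 12 implanted transfers
report = run_pipeline(dataset, RunConfig(seed=1))

for row in report.funnel:
    print(f"{row['stage']:<24s}{row['count']:>6d}")
rec = report.recovery
print(f"sensitivity={rec['sensitivity']:.2f}  "
      f"contaminant_false_candidates={rec['contaminant_false_candidates']}")
```

prints (seed 1):

```
ppps_enumerated            375
bacterial_screen           152
invertebrate_comparison    142
weak_and_repeat            142
scaffold_triage             58
merged_loci                 12
with_paralogs               12
sensitivity=1.00  contaminant_false_candidates=0
```

The funnel narrows exactly as the screen intends: 375 stop-to-stop
peptides enumerated, 152 PPP/window items with credible bacterial
similarity (≥ 40 bits), 142 more similar to bacterial than to
invertebrate proteins, 58 surviving contaminant-scaffold triage, and a
final merge to exactly the 12 implanted loci — with zero
contaminant-scaffold loci in the final inventory. Each candidate row carries its frameshift /
internal-stop / truncation annotation (e.g. the decayed LdcA-family copy
reports its 11 implanted frameshifts; the AtpH-like fragment its 3 stops
at 100 of 177 codons) and its bootstrap-supported donor-lineage call.

The same run is scripted as a narrative under `analysis/`
(`01_simulate.py` … `05_copy_number.py`, writing tables under
`results/`), and a `lgtscreen` CLI (`generate`, `screen`) wraps the same
two calls.

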