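# Methods

`lgtscreen` reimplements, as a tested pipeline, a genome-wide screen for
bacteria-to-insect lateral gene transfer (LGT): six-frame enumeration of
candidate peptides, translated homology search under bit-score/E-value
statistics, a cascade of exclusion filters (conserved genes, weak hits,
repeats, bacterial contaminants, chimeric artifacts), pseudogene
annotation, neighbor-joining donor attribution, and qPCR copy-number
verification. Because the original inputs (a specific draft assembly,
discarded-read pool, and period database snapshots) are not reproducible
at desk scale, the pipeline is exercised end-to-end on a truth-tagged
synthetic genome whose statistical structure mirrors the real screen's
assumptions. This note records the models, the defaults, and the design
choices that were genuinely open.

## Screening model

**Screening unit.** A *potential polypeptide* (PPP) is the conceptual
translation of a stop-to-stop DNA stretch, with no requirement for an
initiation codon; stretches shorter than 60 aa are discarded, overlaps
between frames are permitted, and stretches abutting a scaffold end
without a closing stop are kept but flagged `terminal` (a `require_stop`
switch restores the strict reading). Stretches crossing assembly gaps
carry `X` residues and are split only at stop codons: splitting at gaps
would silently delete gap-spanning candidates.

**Window strategy.** Scaffolds are also sliced into 1,000-nt windows
overlapping by 200 nt and searched in all six frames; this catches loci
whose reading frame is interrupted (internal stops, frameshifts) and which
therefore never yield a long PPP. A 300-nt locus can straddle a window
boundary (stride 800 > 1,000 − 300), so window-level hits to the same
subject within 300 nt on the genome are re-joined and re-aligned before
the bit threshold is applied: the windowing is a processing device, and
significance belongs to the genome-level alignment.

**Search engine and statistics.** Local alignment is affine-gap
Smith–Waterman (BLOSUM62, gap open 11 / extend 1 for proteins). Raw scores
convert to bits via S′ = (λS − ln K)/ln 2 with the standard gapped
BLOSUM62 parameters λ = 0.267, K = 0.041, and E = m·n·2^(−S′). All
cascade thresholds are in bits: ≥ 40 for protein-scored searches, ≥ 55 for
nucleotide searches, E < 1e−5 for the symbiont-genome screen. For
nucleotide scoring we use +5/−6 with gap open 12 / extend 4 (λ = 0.21,
K = 0.18) rather than the textbook +5/−4: on an AT-rich genome the
compositional match fraction of unrelated sequences (~50%) exceeds
+5/−4's 44% break-even, which manufactures arbitrarily long spurious
gapped alignments, while −6 moves the break-even to 54.5% and leaves
genuinely homologous (≥ 65% identity) alignments strongly positive. An
exact k-mer seed prefilter (aa 4–5-mers, nt 13-mers; clusters on a
diagonal band, split at large positional gaps) restricts which pairs are
aligned at genome scale; the exhaustive mode remains the reference
behaviour and is what the oracle-equivalence tests check. For
near-identical screening (read pools, vector matching, contaminant
coverage) densely seeded clusters are reported directly from their seed
extent, with identity estimated as (seed-start density)^(1/k) — exact in
expectation under i.i.d. substitution — instead of being re-aligned.
Both query strands are searched in nucleotide mode. A 12-column tabular
adapter lets an external search tool feed the same cascade.

## Filter cascade

1. **Bacterial screen** — best bacterial bit score ≥ 40 (protein) / ≥ 55 (nt).
2. **Invertebrate comparison** — the candidate must be strictly more
   similar to bacterial than to invertebrate proteins (margin 0 bits).
   When both hits cover one common query region and the invertebrate hit
   is at least as strong, the locus is a broadly conserved gene, not LGT.
3. **Full-protein recheck** — when a candidate lies inside a predicted
   host protein, the full protein is re-queried; a bacterial advantage
   below 13 bits at whole-protein scale indicates animal origin. The
   synthetic pipeline has no gene predictor, so this stage runs only when
   gene models are supplied (skipped-with-log otherwise).
4. **Weak and repeat exclusion** — hits with bit score ≤ 45 AND E ≥ 0.001
   are unreliable; aligned query regions that are short-period tandem
   repeats (self-match fraction ≥ 0.8 at lag ≤ 12) or low-complexity
   (minimum sliding-window entropy below 1.5 bits/symbol for peptides,
   1.0 for nucleotides — an AT-rich genome's compositional entropy is only
   ~1.9 bits, so the peptide threshold cannot be reused) are dropped.
5. **Scaffold triage** — a scaffold is a *contaminant* when near-identical
   bacterial sequence (identity ≥ 0.90) covers ≥ 50% of it and nothing on
   it matches a related insect genome, or when it is < 2 kb with no such
   evidence at all; it is *chimeric* when a sub-kilobase near-identical
   bacterial segment sits inside an otherwise host-supported scaffold
   with at most single-read support. Candidates on non-host scaffolds are
   discarded wholesale.
6. **Read-pool chimera analysis** — vector-matching and low-complexity
   reads are excluded first; a read with a bacterial-only and a host-only
   region (each ≥ 100 nt, mutual overlap ≤ 30 nt) is chimeric; chimeric
   reads are genuine LGT evidence only when ≥ 2 reads share the junction
   (same host and donor source within 1 kb), otherwise they are
   cloning/sequencing artifacts. This formalizes what was originally a
   visual one-by-one inspection; the numbers (100/30 nt) are our own.
7. **Symbiont nucleotide screen** — symbiont genomes (1-kb slices) vs the
   assembly at E < 1e−5, contaminant/chimeric scaffolds excluded, and
   segments whose back-search against the related insect genome is at
   least as strong discarded as insect-derived.
8. **Paralog expansion** — translated search of each confirmed candidate
   peptide against the assembly; non-overlapping loci ≥ 40 bits on host
   scaffolds are added as paralogs of their seed.

Surviving hits are merged into gene-level loci (same scaffold and subject,
gap ≤ 2.5 kb — wider than the largest intron, narrower than tandem-copy
spacing), and the frameshift-aware annotation below refines each locus to
the aligned gene span.

## Pseudogene annotation

A locus is aligned to its donor homolog with a single dynamic program over
(nucleotides consumed, residues consumed): codon moves (3 nt → 1 aa,
BLOSUM62 on the conceptual translation), frameshift moves (1/2/4/5 nt →
1 aa at −16 each; each move is one indel junction), residue/codon gap
moves (−12), and intron moves that skip a ≥ 50-nt stretch without
consuming residues (GT..AG bounded at −15; any-dinucleotide at −40,
flagged non-canonical). We chose this direct DP over stitching three
per-frame local alignments because it counts junctions exactly and
handles splicing in the same pass. Aligning a stop codon to a residue
costs −10: dearer than any ordinary mismatch, but a pair of stops (−20)
stays cheaper than a pair of frameshifts (−32), so genuine stop runs are
not re-explained as indels. Three repairs make the counts robust at
realistic divergence: (i) terminal inter-intron segments scoring below
the chance level (45 raw) are trimmed, since an intron move can attach a
chance downstream match to the genuine block; (ii) short (≤ 60 nt)
locus tails the local alignment trimmed are force-aligned with a free
homolog end, recovering diverged-but-real terminal codons, stops and
frameshifts; (iii) a zero-net frameshift pair enclosing in-frame stop
codons in a homologous context (mean non-stop codon score ≥ 0.5) is the
DP stepping around stops and is reported as the stops; conversely,
frameshift moves within 25 nt are one biological junction. Truncation is
the aligned homolog span over the homolog length; a report is `intact`
with no frameshifts, no stops, and truncation ≥ 0.9.

In-silico PCR finds exact (or ≤ `mismatch_max`) primer sites on both
template orientations and reports the smallest product, measured 5′ end
to 5′ end inclusive; equal-length alternatives are returned flagged
ambiguous.

## Phylogenetics and rate test

Distances are p-distances or Poisson-corrected (−ln(1−p)) on gap-free
columns (complete deletion). Neighbor joining is the canonical Q-criterion
agglomeration with deterministic label-order tie-breaks and negative
branch lengths clamped to zero; scikit-bio's implementation serves as an
independent cross-check in the tests, never as the engine. Bootstrap
support resamples columns with replacement (default B = 1,000; the
pipeline's placement stage uses B = 200, which bounds the support
standard error at ~3.5 points and is ample for a 70% support floor).
Multiple alignment for placement is anchor projection: every sequence is
pairwise-aligned (end-gap-free, so fragments are not smeared across
full-length orthologs) to the longest sequence and projected onto its
columns. This is crude next to a progressive aligner but
column-consistent and adequate at the divergences involved; a
user-supplied alignment is accepted wherever an alignment is consumed.
Bayesian and maximum-likelihood inference are out of scope; alignments
can be exported for external tools.

A candidate is attributed to the donor lineage of its smallest
bootstrap-supported (≥ 70%) enclosing clade on the NJ tree of its
ortholog family (both donor lineages plus a distant outgroup lineage);
clades containing only the outgroup attribute to no donor, and mixed or
unsupported configurations are unresolved.

The relative-rate test is Tajima's 1D test: m1 counts sites where ingroup
1 alone differs from the outgroup, m2 the converse, and
(m1−m2)²/(m1+m2) is referred to χ²(1). The published supplement does not
name its variant; Tajima's test is the standard choice and is recorded
here as an assumption. Pseudogenes, free of purifying selection, are
expected to reject toward the decayed copy. The power simulations use
branch lengths at the divergence scale of the decayed fragments
themselves — 0.15 substitutions/site on the intact ingroup, 0.30 on the
accelerated copy (a fragment ~66% identical to the donor lineage's
copy), outgroup 0.45 in total — at 300 sites; power there is ~90%.

## Copy-number verification

The published criterion — ratios "nearly constant across samples and
centered around 1" — is formalized as a conjunction: among-sample one-way
ANOVA not significant, between-strain t-test (on per-sample means) not
significant, pooled mean inside [0.5, 2.0], and a confidence interval
(over sample means) containing 1. The stated `alpha` (default 0.05) is
the family-wise level of the whole call: the three stochastic components
run at the Šidák-corrected level 1 − (1−α)^(1/3), so a genuinely genomic
locus is mis-called at a rate near α overall — this is what makes the
verdict calibrated rather than a stack of uncorrected tests.
Tukey–Kramer pairwise comparisons (unequal-n studentized range)
accompany the ANOVA. Tissue fold changes are ratio-of-means against a
whole-body reference with Tukey-adjusted flags.

## The synthetic data generator

The generator's defaults define the study conditions; they are fixed, not
tuning knobs.

* **Host assembly**: 10 scaffolds (one 45-kb scaffold to host the tandem
  cluster, the rest 6–14 kb), i.i.d. nucleotides at GC = 0.30, with 10
  N-runs of 50–300 nt. Total ≈ 140 kb — a deliberate miniature: large
  enough that every filter has genuine negatives to reject, small enough
  that the whole screen runs in tens of seconds.
* **Donor lineages**: 26 core gene families are generated as ancestor
  proteins and diverged independently into donorA (rickettsia-like,
  GC 0.42), donorB (obligate-symbiont-like, GC 0.26) and a distant
  outgroup lineage (0.45 substitutions/site; used only for
  phylogenetics), at 0.25 substitutions/site per donor lineage, plus
  lineage-specific proteins to 40 (A) and 30 (B). Donor genomes
  concatenate back-translated CDSs with random intergenic spacers. The
  invertebrate decoy proteome shares 20% of its proteins with reserved
  core families (diverged 0.40) — the broadly conserved genes that the
  cascade's box-3 comparison must recognize; three of these are also
  implanted as native host genes.
* **Implants** (12 events, mirroring a realistic inventory): a host–donor
  fusion gene whose truth locus is the bacterial domain; a five-copy
  tandem cluster (copies at 97% nt identity, 3.2–5-kb spacers); a
  three-copy family whose third copy carries 11 frameshifts and 30%
  truncation; an intron-bearing functional singleton; and two
  symbiont-derived fragments — one truncated to 10% of a 1,100-aa
  protein, one truncated to 100/177 codons with three internal stops.
  Divergence tiers are 0.30–0.35 amino-acid substitutions. Transfers are
  back-translated with host-composition codon usage (so implants are not
  trivially detectable by composition), functional events receive GT..AG
  introns of 60–2,000 nt (exons ≥ 210 nt), and events are placed ≥ 4 kb
  apart, away from assembly gaps. Implanted frameshifts are 1–2-nt
  indels spaced ≥ 55 nt, confined to the 3′ 70% of the retained
  sequence, and kept clear of the ends; implanted stops are ≥ 8 codons
  from the ends and each other. These spacings make each implanted event
  *individually resolvable*: two canceling indels a few codons apart are
  mathematically indistinguishable from substitutions in any alignment,
  so a truth set that demands exact recovery must not implant them.
* **Contamination and reads**: six contaminant scaffolds (2–8-kb donor
  genome fragments at 97% identity), one short junk scaffold, and one
  host scaffold with a 400-nt near-identical bacterial insert supported
  by exactly one read. Reads are Sanger-style (800 ± 100 nt) at 6.2×
  coverage with random orientation, never containing assembly-gap Ns;
  the pool includes one genuine unassembled host/donor junction covered
  by three reads, singleton artifact chimeras at rate 0.004, five vector
  reads and three low-complexity reads. Junction and artifact donor
  segments are drawn from donor-genome regions that did **not** leak into
  the assembly, otherwise they would legitimately look assembly-derived.
* **qPCR**: each strain (3 and 4 biological samples) is measured in
  technical triplicate. A genomic locus' per-sample ratio is
  Normal(1, 0.01) — target and standard are quantified in the same DNA
  batch, so batch effects essentially cancel in the ratio — with 10%
  multiplicative technical noise; a contaminant locus' per-sample titer
  is log-normal with σ = 1.0. The among-sample-variance signature, not
  the mean alone, is what separates the classes.

What the generator does **not** emulate: sequencing error and quality
values, realistic codon-level selection (dN/dS), gene-family birth/death,
transposable elements, GC heterogeneity along scaffolds, and real
database taxonomy. Passing tests therefore demonstrate that the decision
logic is correct and calibrated under the screen's own assumptions — not
that the thresholds would achieve the same sensitivity/precision on a
real draft genome against period databases.

## Problem sizes and determinism

Default end-to-end runs use the ~140-kb scenario (≈ 360 PPPs, ≈ 190
windows, ≈ 1,250 reads) and complete in well under a minute each; the
acceptance checks run the screen across seeds 1–20 and the statistical
calibrations at 150–2,000 simulations. All randomness flows from a single
integer seed; identical configuration and seed give byte-identical
outputs, including the bootstrap.

## Known limitations

* The internal search engine is exhaustive-at-desk-scale with seed
  acceleration; it makes no claim of BLAST performance parity,
  composition-based statistics, or HSP chaining beyond the
  window-joining described above.
* The frameshift DP reports *resolvable* events; indel pairs that cancel
  within a few codons are inherently ambiguous and will be read as
  substitutions by any method.
* Anchor-projection alignment degrades for deep divergences (> ~0.5
  substitutions/site) and discards insertions relative to the anchor;
  supply a proper multiple alignment in such cases.
* The symbiont nucleotide screen needs ≥ 2 exact 11-mers on a diagonal;
  fragments much more diverged than ~70% nt identity are found by the
  protein route instead (as in the original screen, where the
  nucleotide arm contributed no additional candidates).
* Printed genome-scale counts from the original study (PPP census,
  funnel sizes, contaminant-scaffold count) depend on its assembly and
  database snapshots and are reproduced in *shape* (a monotone,
  stage-labelled funnel), not in absolute numbers.
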