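"""Truth-tagged synthetic inputs for the lateral-gene-transfer screen.

The generator emulates the data situation of a draft insect genome screened
for bacteria-derived loci:

* an AT-rich host assembly with N-gap runs and accession-like scaffold ids;
* two donor bacterial lineages — ``donorA`` (rickettsia-like, the source of
  the functional transfers) and ``donorB`` (an obligate-symbiont lineage,
  the source of highly truncated pseudogene fragments) — as proteome and
  genome FASTA sets, plus an invertebrate decoy proteome sharing a
  configurable fraction of conserved proteins with the donors;
* implanted transfer events mirroring the composition of a real candidate
  inventory: a chimeric host-donor fusion gene, a five-copy tandem paralog
  cluster, a three-copy paralog family with one frameshifted pseudogene,
  a functional singleton with an intron, and two heavily truncated
  symbiont-derived pseudogene fragments;
* contaminant scaffolds (near-identical donor genomic fragments with no
  host context), one short no-evidence scaffold, and one chimeric scaffold
  carrying a small single-read bacterial insert;
* Sanger-style reads at ~6x coverage, including multi-read-supported
  genuine host/donor junction reads, singleton artifact chimeras, vector
  reads and low-complexity reads;
* replicate qPCR copy-number ratios: tight around 1 for genomic loci,
  log-normally fluctuating for contaminant loci.

Every implanted feature is recorded in a :class:`TruthEvent` table so that
each downstream stage can be scored against ground truth.  The same
configuration and seed always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .seqio import Assembly, GenomicInterval, Scaffold, revcomp, translate, write_fasta

AA20 = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TAG", "TGA")

# standard genetic code, codon -> aa, built once
_CODON_TABLE: dict[str, str] = {}
for _c1 in "TCAG":
    for _c2 in "TCAG":
        for _c3 in "TCAG":
            _codon = _c1 + _c2 + _c3
            _CODON_TABLE[_codon] = translate(_codon) or "*"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa != "*":
        _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()


class GeneratorConfigError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class EventSpec:
    """Roster entry describing one implant to make."""

    event_id: str
    cls: str  # functional_LGT | pseudogene_LGT | paralog_cluster | chimeric_fusion | buchnera_fragment
    donor_lineage: str  # donorA | donorB
    divergence_tier: float = 0.3
    n_frameshifts: int = 0
    n_internal_stops: int = 0
    truncation_fraction: float = 1.0
    n_introns: int = 0
    cluster_id: str | None = None  # shared by tandem/family copies
    copy_of: str | None = None  # nt-level duplicate of an earlier event
    same_source_as: str | None = None  # independently diverged copy of an earlier event's source
    paralog_nt_identity: float = 0.97
    protein_len: int | None = None  # draw from config range when None
    fusion_host_domain_len: int = 150  # aa, chimeric_fusion only


@dataclass
class TruthEvent:
    """Ground truth for one implanted locus (coordinates of the coding span)."""

    event_id: str
    cls: str
    donor_lineage: str
    locus: GenomicInterval
    divergence_tier: float
    n_frameshifts: int
    n_internal_stops: int
    truncation_fraction: float
    homolog_id: str
    cluster_id: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)  # genomic, low<=high
    indels: list[tuple[int, int]] = field(default_factory=list)  # (cds nt pos, +ins/-del size)

    def validate(self) -> None:
        if self.cls in ("functional_LGT", "chimeric_fusion") or (
            self.cls == "paralog_cluster"
        ):
            assert self.n_frameshifts == 0 and self.n_internal_stops == 0
        if self.cls == "pseudogene_LGT":
            assert (
                self.n_frameshifts + self.n_internal_stops >= 1
                or self.truncation_fraction < 1.0
            )


def default_roster() -> list[EventSpec]:
    """Twelve implants mirroring a realistic candidate inventory.

    One host-donor fusion gene, a five-copy tandem cluster, a three-copy
    family whose third copy is a frameshift-riddled pseudogene, one intron
    bearing functional singleton, and two truncated symbiont-derived
    fragments (one of them stop-riddled).
    """
    roster: list[EventSpec] = [
        EventSpec("fusion01", "chimeric_fusion", "donorA", divergence_tier=0.35,
                  n_introns=1, protein_len=200),
    ]
    for i in range(1, 6):
        roster.append(EventSpec(
            f"rlpa{i:02d}", "paralog_cluster", "donorA", divergence_tier=0.30,
            n_introns=1, cluster_id="rlpa", protein_len=230,
            copy_of=None if i == 1 else "rlpa01",
        ))
    roster += [
        EventSpec("ldca01", "paralog_cluster", "donorA", divergence_tier=0.30,
                  n_introns=1, cluster_id="ldca", protein_len=420),
        EventSpec("ldca02", "paralog_cluster", "donorA", divergence_tier=0.30,
                  n_introns=1, cluster_id="ldca", copy_of="ldca01", protein_len=420),
        EventSpec("ldca03_psi", "pseudogene_LGT", "donorA", divergence_tier=0.30,
                  n_frameshifts=11, truncation_fraction=0.7, cluster_id="ldca",
                  same_source_as="ldca01", protein_len=420),
        EventSpec("amid01", "functional_LGT", "donorA", divergence_tier=0.30,
                  n_introns=1, protein_len=280),
        EventSpec("dnae01_psi", "buchnera_fragment", "donorB", divergence_tier=0.34,
                  truncation_fraction=0.10, protein_len=1100),
        EventSpec("atph01_psi", "buchnera_fragment", "donorB", divergence_tier=0.34,
                  truncation_fraction=100 / 177, n_internal_stops=3, protein_len=177),
    ]
    return roster


@dataclass
class GeneratorConfig:
    """All knobs of the generator; the defaults define the study conditions."""

    seed: int = 1
    # host assembly
    host_gc: float = 0.30
    n_scaffolds: int = 10
    scaffold_len_min: int = 6000
    scaffold_len_max: int = 14000
    cluster_scaffold_len: int = 45000
    n_gap_runs: int = 10
    gap_len_min: int = 50
    gap_len_max: int = 300
    # donors and decoy
    n_donorA_proteins: int = 40
    n_donorB_proteins: int = 30
    n_decoy_proteins: int = 40
    protein_len_min: int = 120
    protein_len_max: int = 450
    donorA_gc: float = 0.42
    donorB_gc: float = 0.26
    # shared core gene families: each exists in both donor lineages and in
    # a distant outgroup lineage, diverged per-lineage from a common ancestor
    n_core_families: int = 26
    lineage_divergence: float = 0.25  # each lineage from the family ancestor
    outgroup_divergence: float = 0.45
    conserved_fraction: float = 0.2
    conserved_divergence: float = 0.40
    n_conserved_host_genes: int = 3
    # implants
    roster: list[EventSpec] = field(default_factory=default_roster)
    intron_len_min: int = 60
    intron_len_max: int = 2000
    min_exon_len: int = 210
    cluster_spacer_min: int = 3200
    cluster_spacer_max: int = 5000
    event_margin: int = 4000
    # contamination
    n_contaminant_scaffolds: int = 6
    contaminant_identity: float = 0.97
    contaminant_len_min: int = 2000
    contaminant_len_max: int = 8000
    n_short_junk_scaffolds: int = 1
    include_chimeric_scaffold: bool = True
    chimeric_insert_len: int = 400
    # related-insect evidence genome
    related_identity: float = 0.90
    related_coverage: float = 0.5
    # reads
    coverage: float = 6.2
    read_len_mean: int = 800
    read_len_sd: int = 100
    chimeric_read_rate: float = 0.004
    n_unassembled_junctions: int = 1
    junction_support: int = 3
    n_vector_reads: int = 5
    n_lowcomplexity_reads: int = 3
    # qPCR: per-sample (biological batch) effects plus technical replicates
    qpcr_sigma_genomic: float = 0.01  # among-sample sd: target/standard ratios cancel batch effects
    qpcr_tech_sigma: float = 0.10  # within-sample technical sd
    qpcr_tech_reps: int = 3
    qpcr_contaminant_log_sd: float = 1.0  # among-sample titer (log scale)
    qpcr_strains: dict = field(default_factory=lambda: {"LSR1": 3, "ISO": 4})

    def validate(self) -> None:
        if self.n_scaffolds < 1:
            raise GeneratorConfigError("need at least one scaffold")
        if not (0.0 <= self.host_gc <= 1.0):
            raise GeneratorConfigError("host_gc must be in [0,1]")
        for p in (self.conserved_fraction, self.contaminant_identity,
                  self.related_identity, self.chimeric_read_rate):
            if not (0.0 <= p <= 1.0):
                raise GeneratorConfigError("probabilities must be in [0,1]")
        if self.coverage <= 0:
            raise GeneratorConfigError("coverage must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["roster"] = [dataclasses.asdict(e) for e in self.roster]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["roster"] = [EventSpec(**e) for e in d.get("roster", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# elementary sequence randomisation

def _rand_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _rand_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def diverge_protein(seq: str, tier: float, rng: np.random.Generator) -> str:
    """Substitute each residue independently with probability ``tier``."""
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < tier:
            choices = AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _codon_weights(gc: float) -> dict[str, np.ndarray]:
    """Codon usage implied by host base composition (AT-rich bias)."""
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    weights = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
        weights[aa] = w / w.sum()
    return weights


def reverse_translate(protein: str, rng: np.random.Generator, gc: float) -> str:
    """Back-translate with codon usage matching the host base composition."""
    weights = _codon_weights(gc)
    parts = []
    for aa in protein:
        codons = _CODONS_BY_AA[aa]
        parts.append(codons[rng.choice(len(codons), p=weights[aa])])
    return "".join(parts)


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if out[i] != "N" and rng.random() < rate:
            choices = "ACGT".replace(out[i], "")
            out[i] = choices[rng.integers(3)]
    return "".join(out)


def _mutate_exons_no_stop(
    exons: list[str], rate: float, rng: np.random.Generator
) -> list[str]:
    """Substitute exon bases at ``rate`` without creating in-frame stop codons.

    The spliced CDS frame is tracked across exons so a substitution is
    rejected (position left unchanged) whenever it would turn the codon it
    sits in into a stop.
    """
    cds = "".join(exons)
    out = list(cds)
    for i in range(len(out)):
        if rng.random() >= rate:
            continue
        choices = "ACGT".replace(out[i], "")
        base = choices[rng.integers(3)]
        c0 = (i // 3) * 3
        codon = out[c0:c0 + 3]
        codon[i - c0] = base
        if len(codon) == 3 and "".join(codon) in STOP_CODONS:
            continue
        out[i] = base
    mutated = "".join(out)
    result, pos = [], 0
    for ex in exons:
        result.append(mutated[pos:pos + len(ex)])
        pos += len(ex)
    return result


# ---------------------------------------------------------------------------
# host assembly

def generate_host_assembly(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[Assembly, list[GenomicInterval]]:
    """i.i.d. host scaffolds at ``host_gc`` with N-gap runs; deterministic under seed."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    scaffolds = []
    for i in range(cfg.n_scaffolds):
        if i == 0 and cfg.cluster_scaffold_len:
            L = cfg.cluster_scaffold_len
        else:
            L = int(rng.integers(cfg.scaffold_len_min, cfg.scaffold_len_max + 1))
        scaffolds.append(Scaffold(id=f"HOST{i + 1:03d}", sequence=_rand_dna(rng, L, cfg.host_gc)))
    gaps: list[GenomicInterval] = []
    for _ in range(cfg.n_gap_runs):
        si = int(rng.integers(len(scaffolds)))
        s = scaffolds[si]
        run = int(rng.integers(cfg.gap_len_min, cfg.gap_len_max + 1))
        if len(s.sequence) < run + 200:
            continue
        pos = int(rng.integers(100, len(s.sequence) - run - 100))
        s.sequence = s.sequence[:pos] + "N" * run + s.sequence[pos + run:]
        gaps.append(GenomicInterval(s.id, pos + 1, pos + run))
    gaps.sort(key=lambda g: (g.scaffold_id, g.start))
    return Assembly(scaffolds), gaps


# ---------------------------------------------------------------------------
# donors and decoy

@dataclass
class DonorSet:
    donorA: list[Scaffold]
    donorB: list[Scaffold]
    outgroup: list[Scaffold]  # distant bacterial lineage, phylogeny only
    decoy: list[Scaffold]
    donorA_genome: list[Scaffold]
    donorB_genome: list[Scaffold]
    conserved_pairs: list[tuple[str, str]]  # (decoy_id, donor_id)
    reserved_donor_ids: set[str]
    ortholog_groups: dict[str, dict[str, str]] = field(default_factory=dict)
    # family id -> {lineage: protein id}; also indexable by any member id

    def genome_of(self, lineage: str) -> list[Scaffold]:
        return self.donorA_genome if lineage == "donorA" else self.donorB_genome

    def proteome_of(self, lineage: str) -> list[Scaffold]:
        return self.donorA if lineage == "donorA" else self.donorB

    def family_of(self, protein_id: str) -> dict[str, str] | None:
        """The ortholog group containing a protein id, if it is a core gene."""
        for group in self.ortholog_groups.values():
            if protein_id in group.values():
                return group
        return None


def _build_donor_genome(
    proteome: Sequence[Scaffold], rng: np.random.Generator, gc: float, tag: str
) -> list[Scaffold]:
    """A single-replicon donor genome: CDSs with stops, random intergenic spacers."""
    parts = []
    for prot in proteome:
        parts.append(_rand_dna(rng, int(rng.integers(100, 400)), gc))
        parts.append(reverse_translate(prot.sequence, rng, gc))
        parts.append(STOP_CODONS[rng.integers(3)])
    parts.append(_rand_dna(rng, 200, gc))
    return [Scaffold(id=f"{tag}_genome", sequence="".join(parts))]


def evolve_donor_proteomes(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> DonorSet:
    """Donor proteomes, donor genomes, an outgroup lineage, and a decoy proteome.

    Core gene families are generated as ancestor proteins and then diverged
    independently into each lineage (donorA, donorB, and a distant outgroup
    used only for phylogenetics), so orthologs exist across lineages the
    way real bacterial core genes do.  Each lineage also carries
    lineage-specific proteins.  A ``conserved_fraction`` of decoy proteins
    are diverged twins of core ancestors (broadly conserved genes shared by
    bacteria and animals); those families are reserved and never used as
    transfer sources.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    # honour explicit protein lengths requested by roster entries so every
    # source protein has the intended size; the sources are core families
    wanted = [e.protein_len for e in cfg.roster
              if e.copy_of is None and e.protein_len]
    ancestors: list[Scaffold] = []
    for i in range(cfg.n_core_families):
        if i < len(wanted):
            L = wanted[i]
        else:
            L = int(rng.integers(cfg.protein_len_min, cfg.protein_len_max + 1))
        ancestors.append(Scaffold(id=f"fam{i + 1:03d}", sequence=_rand_protein(rng, L)))

    ortholog_groups: dict[str, dict[str, str]] = {}
    donorA: list[Scaffold] = []
    donorB: list[Scaffold] = []
    outgroup: list[Scaffold] = []
    for i, anc in enumerate(ancestors):
        ga = Scaffold(id=f"donorA_p{i + 1:03d}",
                      sequence=diverge_protein(anc.sequence, cfg.lineage_divergence, rng))
        gb = Scaffold(id=f"donorB_p{i + 1:03d}",
                      sequence=diverge_protein(anc.sequence, cfg.lineage_divergence, rng))
        go = Scaffold(id=f"outgrp_p{i + 1:03d}",
                      sequence=diverge_protein(anc.sequence, cfg.outgroup_divergence, rng))
        donorA.append(ga)
        donorB.append(gb)
        outgroup.append(go)
        ortholog_groups[anc.id] = {"donorA": ga.id, "donorB": gb.id, "outgroup": go.id}
    # lineage-specific proteins fill the proteomes to their configured sizes
    for i in range(cfg.n_core_families, cfg.n_donorA_proteins):
        L = int(rng.integers(cfg.protein_len_min, cfg.protein_len_max + 1))
        donorA.append(Scaffold(id=f"donorA_p{i + 1:03d}", sequence=_rand_protein(rng, L)))
    for i in range(cfg.n_core_families, cfg.n_donorB_proteins):
        L = int(rng.integers(cfg.protein_len_min, cfg.protein_len_max + 1))
        donorB.append(Scaffold(id=f"donorB_p{i + 1:03d}", sequence=_rand_protein(rng, L)))

    n_conserved = int(round(cfg.conserved_fraction * cfg.n_decoy_proteins))
    # reserve core families (not requested by the roster) for conserved twins
    reserved_fams = ancestors[len(wanted):len(wanted) + n_conserved]
    reserved_ids: set[str] = set()
    for fam in reserved_fams:
        group = ortholog_groups[fam.id]
        reserved_ids.update(group.values())
    conserved_pairs = []
    decoy = []
    for i in range(cfg.n_decoy_proteins):
        if i < len(reserved_fams):
            fam = reserved_fams[i]
            seq = diverge_protein(fam.sequence, cfg.conserved_divergence, rng)
            decoy.append(Scaffold(id=f"decoy_p{i + 1:03d}", sequence=seq))
            conserved_pairs.append((decoy[-1].id, ortholog_groups[fam.id]["donorA"]))
        else:
            L = int(rng.integers(cfg.protein_len_min, cfg.protein_len_max + 1))
            decoy.append(Scaffold(id=f"decoy_p{i + 1:03d}", sequence=_rand_protein(rng, L)))

    genomeA = _build_donor_genome(donorA, rng, cfg.donorA_gc, "donorA")
    genomeB = _build_donor_genome(donorB, rng, cfg.donorB_gc, "donorB")
    return DonorSet(
        donorA=donorA, donorB=donorB, outgroup=outgroup, decoy=decoy,
        donorA_genome=genomeA, donorB_genome=genomeB,
        conserved_pairs=conserved_pairs,
        reserved_donor_ids=reserved_ids,
        ortholog_groups=ortholog_groups,
    )


# ---------------------------------------------------------------------------
# gene construction

def _insert_introns(
    cds: str, n_introns: int, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int]]]:
    """Insert GT..AG introns at codon boundaries, keeping every exon >= min_exon_len.

    Returns the gene sequence and 0-based intron (start, end) positions on it.
    """
    n_codons = len(cds) // 3
    min_ex = cfg.min_exon_len
    if n_introns == 0 or n_codons * 3 < (n_introns + 1) * min_ex + 6:
        return cds, []
    # choose codon-boundary insertion points leaving min_ex nt per exon
    points: list[int] = []
    tries = 0
    while len(points) < n_introns and tries < 200:
        tries += 1
        cand = 3 * int(rng.integers(min_ex // 3, n_codons - min_ex // 3))
        if all(abs(cand - p) >= min_ex for p in points):
            points.append(cand)
    points.sort()
    gene = cds
    introns: list[tuple[int, int]] = []
    offset = 0
    for p in points:
        ilen = int(rng.integers(cfg.intron_len_min, cfg.intron_len_max + 1))
        intron = "GT" + _rand_dna(rng, ilen - 4, cfg.host_gc) + "AG"
        pos = p + offset
        gene = gene[:pos] + intron + gene[pos:]
        introns.append((pos, pos + len(intron)))
        offset += len(intron)
    return gene, introns


def pseudogenize(
    cds: str,
    n_frameshifts: int,
    n_internal_stops: int,
    truncation_fraction: float,
    rng: np.random.Generator,
    intact_head_fraction: float = 0.30,
    min_indel_spacing: int = 55,
) -> str:
    """Truncate, substitute internal stops, and apply frameshifting indels.

    Frameshifts (1–2 nt insertions/deletions) are confined to the 3' part
    of the retained sequence so that the 5' stretch keeps a
    screen-detectable reading frame, as real decaying transfers do.  Indels
    are spaced at least ``min_indel_spacing`` nt apart and kept away from
    the sequence ends: two canceling indels a few codons apart are
    indistinguishable from substitutions in any alignment, so each
    implanted event is made individually resolvable.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    keep = max(10, int(round(truncation_fraction * len(codons))))
    codons = codons[:keep]
    # internal stop substitutions, kept clear of the ends and of each other
    # so every implanted stop sits inside an alignable context
    stop_positions: list[int] = []
    tries = 0
    while len(stop_positions) < n_internal_stops and tries < 2000:
        tries += 1
        p = int(rng.integers(8, keep - 8))
        if codons[p] not in STOP_CODONS and all(abs(p - q) >= 8 for q in stop_positions):
            codons[p] = STOP_CODONS[rng.integers(3)]
            stop_positions.append(p)
    seq = "".join(codons)
    protected = {3 * p + k for p in stop_positions for k in range(3)}
    # frameshift indels in the 3' zone
    zone_lo = max(15, int(intact_head_fraction * len(seq)))
    zone_hi = len(seq) - 30
    positions: list[int] = []
    if n_frameshifts:
        span = zone_hi - zone_lo - (n_frameshifts - 1) * min_indel_spacing
        if span <= n_frameshifts:
            raise PlacementError("could not place the requested frameshifts")
        for _ in range(200):
            # order-statistics construction: guaranteed minimum spacing
            u = np.sort(rng.uniform(0, span, size=n_frameshifts))
            cand = [int(zone_lo + u[k] + k * min_indel_spacing)
                    for k in range(n_frameshifts)]
            if not any((p + d) in protected for p in cand for d in range(-2, 3)):
                positions = cand
                break
        if len(positions) < n_frameshifts:
            raise PlacementError("could not place the requested frameshifts")
    out = seq
    indels = []
    for p in sorted(positions, reverse=True):
        size = int(rng.integers(1, 3))  # 1 or 2 nt
        if rng.random() < 0.5:
            out = out[:p] + out[p + size:]  # deletion
            indels.append((p, -size))
        else:
            ins = _rand_dna(rng, size, 0.3)
            out = out[:p] + ins + out[p:]  # insertion
            indels.append((p, size))
    pseudogenize.last_indels = sorted(indels)  # introspection for truth tables
    return out


# ---------------------------------------------------------------------------
# implanting

@dataclass
class _Placement:
    occupied: dict[str, list[tuple[int, int]]]
    gaps: dict[str, list[tuple[int, int]]]

    def fits(self, sid: str, lo: int, hi: int, margin: int) -> bool:
        for a, b in self.occupied.get(sid, []):
            if lo - margin <= b and a <= hi + margin:
                return False
        for a, b in self.gaps.get(sid, []):
            if lo <= b and a <= hi:
                return False
        return True

    def claim(self, sid: str, lo: int, hi: int) -> None:
        self.occupied.setdefault(sid, []).append((lo, hi))


def _place(
    assembly: Assembly, placement: _Placement, sid: str, gene: str,
    rng: np.random.Generator, margin: int, at: int | None = None,
) -> int:
    """Overwrite host sequence with ``gene`` at a clash-free position; return 1-based start."""
    scaffold = assembly[sid]
    L = len(scaffold.sequence)
    glen = len(gene)
    if glen + 1000 > L:
        raise PlacementError(f"gene of {glen} nt does not fit scaffold {sid}")
    if L - glen - 1000 <= 0:
        raise PlacementError(f"gene of {glen} nt does not fit scaffold {sid}")
    for _ in range(300):
        pos = at if at is not None else int(rng.integers(500, L - glen - 500))
        if placement.fits(sid, pos, pos + glen - 1, margin):
            scaffold.sequence = (
                scaffold.sequence[:pos] + gene + scaffold.sequence[pos + glen:]
            )
            placement.claim(sid, pos, pos + glen - 1)
            return pos + 1
        if at is not None:
            raise PlacementError(f"fixed position {at} clashes on {sid}")
    raise PlacementError(f"no clash-free position on {sid} for {glen} nt")


def _place_round_robin(
    assembly: Assembly, placement: _Placement, sids: Sequence[str], rr: int,
    gene: str, rng: np.random.Generator, margin: int,
) -> tuple[str, int]:
    """Place on the rr-th scaffold, falling back to the others in order."""
    last_err: PlacementError | None = None
    for k in range(len(sids)):
        sid = sids[(rr + k) % len(sids)]
        try:
            return sid, _place(assembly, placement, sid, gene, rng, margin)
        except PlacementError as err:
            last_err = err
    raise PlacementError(f"roster does not fit the assembly: {last_err}")


def implant_events(
    assembly: Assembly,
    donors: DonorSet,
    roster: Sequence[EventSpec],
    cfg: GeneratorConfig,
    gaps: list[GenomicInterval],
    rng: np.random.Generator | None = None,
) -> list[TruthEvent]:
    """Implant the roster into the assembly in place; return the truth table."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    placement = _Placement(occupied={}, gaps={})
    for g in gaps:
        placement.gaps.setdefault(g.scaffold_id, []).append((g.start - 1, g.end - 1))

    scaffold_ids = [s.id for s in assembly]
    cluster_sid = scaffold_ids[0]
    other_sids = scaffold_ids[1:] or scaffold_ids

    # assign source proteins per lineage, skipping conserved-reserved ones
    available = {
        "donorA": [s for s in donors.donorA if s.id not in donors.reserved_donor_ids],
        "donorB": [s for s in donors.donorB if s.id not in donors.reserved_donor_ids],
    }
    next_idx = {"donorA": 0, "donorB": 0}

    def _take_source(spec: EventSpec) -> Scaffold:
        pool = available[spec.donor_lineage]
        want = spec.protein_len
        if want is not None:
            for i in range(next_idx[spec.donor_lineage], len(pool)):
                if len(pool[i].sequence) == want:
                    pool[i], pool[next_idx[spec.donor_lineage]] = (
                        pool[next_idx[spec.donor_lineage]], pool[i])
                    break
        src = pool[next_idx[spec.donor_lineage]]
        next_idx[spec.donor_lineage] += 1
        return src

    truth: list[TruthEvent] = []
    built_genes: dict[str, dict] = {}  # event_id -> {gene, introns, homolog, spec}
    cluster_cursor = 1500
    rr = 0  # round-robin over non-cluster scaffolds

    for spec in roster:
        event_indels: list[tuple[int, int]] = []
        if spec.copy_of is not None:
            base = built_genes[spec.copy_of]
            # nt-level duplicate: exon substitutions avoid stops, introns free
            gene0, introns0 = base["gene"], base["introns"]
            segs, exseqs, prev = [], [], 0
            for (a, b) in introns0:
                exseqs.append(gene0[prev:a])
                prev = b
            exseqs.append(gene0[prev:])
            rate = 1.0 - spec.paralog_nt_identity
            exseqs = _mutate_exons_no_stop(exseqs, rate, rng)
            introns = []
            parts = []
            pos = 0
            for k, (a, b) in enumerate(introns0):
                parts.append(exseqs[k])
                pos += len(exseqs[k])
                iseq = mutate_dna(gene0[a:b], rate, rng)
                iseq = "GT" + iseq[2:-2] + "AG"
                introns.append((pos, pos + len(iseq)))
                parts.append(iseq)
                pos += len(iseq)
            parts.append(exseqs[-1])
            gene = "".join(parts)
            homolog = base["homolog"]
            tier = base["spec"].divergence_tier
        else:
            if spec.same_source_as is not None:
                base_homolog = built_genes[spec.same_source_as]["homolog"]
                pool = donors.proteome_of(spec.donor_lineage)
                src = next(s for s in pool if s.id == base_homolog)
            else:
                src = _take_source(spec)
            homolog = src.id
            tier = spec.divergence_tier
            transferred = diverge_protein(src.sequence, tier, rng)
            cds = reverse_translate(transferred, rng, cfg.host_gc)
            if spec.cls == "chimeric_fusion":
                # eukaryotic N-terminal domain fused to the bacterial domain;
                # only the bacterial part is transferred material (the truth locus)
                host_dom = reverse_translate(
                    _rand_protein(rng, spec.fusion_host_domain_len), rng, cfg.host_gc)
                gene_bact, introns = _insert_introns(cds, spec.n_introns, cfg, rng)
                gene = host_dom + gene_bact
                introns = [(a + len(host_dom), b + len(host_dom)) for a, b in introns]
                built_genes[spec.event_id] = {
                    "gene": gene, "introns": introns, "homolog": homolog, "spec": spec}
                sid, start = _place_round_robin(
                    assembly, placement, other_sids, rr, gene, rng, cfg.event_margin)
                rr += 1
                b_lo = start + len(host_dom)
                b_hi = start + len(gene) - 1
                exons = _exon_intervals(start, gene, introns)
                truth.append(TruthEvent(
                    spec.event_id, spec.cls, spec.donor_lineage,
                    GenomicInterval(sid, b_lo, b_hi, "+"),
                    tier, 0, 0, 1.0, homolog, spec.cluster_id, exons))
                continue
            if spec.cls in ("pseudogene_LGT", "buchnera_fragment") and (
                spec.n_frameshifts or spec.n_internal_stops or spec.truncation_fraction < 1.0
            ):
                gene = pseudogenize(
                    cds, spec.n_frameshifts, spec.n_internal_stops,
                    spec.truncation_fraction, rng)
                event_indels = list(pseudogenize.last_indels)
                introns = []
            else:
                gene, introns = _insert_introns(cds, spec.n_introns, cfg, rng)
        built_genes.setdefault(spec.event_id, {
            "gene": gene, "introns": introns, "homolog": homolog, "spec": spec})

        if spec.cluster_id == "rlpa":
            # tandem copies on the cluster scaffold, separated by long spacers;
            # the cursor walks forward over gap runs until the copy fits
            at = cluster_cursor
            while not placement.fits(cluster_sid, at, at + len(gene) - 1, 0):
                at += 211
                if at + len(gene) + 500 > len(assembly[cluster_sid].sequence):
                    raise PlacementError("tandem cluster does not fit its scaffold")
            start = _place(assembly, placement, cluster_sid, gene, rng, 0, at=at)
            cluster_cursor = at + len(gene) + int(
                rng.integers(cfg.cluster_spacer_min, cfg.cluster_spacer_max + 1))
            sid = cluster_sid
        else:
            sid, start = _place_round_robin(
                assembly, placement, other_sids, rr, gene, rng, cfg.event_margin)
            rr += 1
        exons = _exon_intervals(start, gene, introns)
        truth.append(TruthEvent(
            spec.event_id, spec.cls, spec.donor_lineage,
            GenomicInterval(sid, start, start + len(gene) - 1, "+"),
            tier, spec.n_frameshifts, spec.n_internal_stops,
            spec.truncation_fraction, homolog, spec.cluster_id, exons,
            indels=event_indels))

    # conserved host genes: near-identical to decoy proteins that have donor twins
    for i, (decoy_id, _donor_id) in enumerate(
        donors.conserved_pairs[: cfg.n_conserved_host_genes]
    ):
        decoy_seq = next(s.sequence for s in donors.decoy if s.id == decoy_id)
        prot = diverge_protein(decoy_seq, 0.05, rng)
        cds = reverse_translate(prot, rng, cfg.host_gc)
        gene, _ = _insert_introns(cds, 1, cfg, rng)
        _place_round_robin(assembly, placement, other_sids, rr, gene, rng,
                           cfg.event_margin)
        rr += 1

    for ev in truth:
        ev.validate()
    return truth


def _exon_intervals(start: int, gene: str, introns: list[tuple[int, int]]) -> list[tuple[int, int]]:
    exons = []
    prev = 0
    for a, b in introns:
        exons.append((start + prev, start + a - 1))
        prev = b
    exons.append((start + prev, start + len(gene) - 1))
    return exons


# ---------------------------------------------------------------------------
# contaminants, related genome, reads

@dataclass
class ReadRecord:
    read: Scaffold
    category: str  # host | contaminant | junction_support | artifact_chimera | vector | lowcomplexity
    source: str = ""


def _sample_fragment(
    seq: str, length: int, rng: np.random.Generator, avoid_n: bool = False,
) -> tuple[str, int]:
    if len(seq) <= length:
        return seq, 0
    pos = int(rng.integers(0, len(seq) - length))
    if avoid_n:
        for _ in range(60):
            if "N" not in seq[pos:pos + length]:
                break
            pos = int(rng.integers(0, len(seq) - length))
    return seq[pos:pos + length], pos


def make_contaminants(
    donors: DonorSet, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[Scaffold], dict[str, str], list[tuple[str, int, int]]]:
    """Contaminant scaffolds (near-identical donor fragments) and short junk scaffolds.

    Also returns the donor-genome source intervals of the contaminants so
    that read simulation can sample junction/artifact donor segments from
    regions that did NOT leak into the assembly.
    """
    scaffolds: list[Scaffold] = []
    truth: dict[str, str] = {}
    sources: list[tuple[str, int, int]] = []
    for i in range(cfg.n_contaminant_scaffolds):
        lineage = "donorA" if i % 2 == 0 else "donorB"
        genome = donors.genome_of(lineage)[0].sequence
        L = int(rng.integers(cfg.contaminant_len_min, cfg.contaminant_len_max + 1))
        frag, pos = _sample_fragment(genome, L, rng)
        frag = mutate_dna(frag, 1.0 - cfg.contaminant_identity, rng)
        sid = f"CONTAM{i + 1:03d}"
        scaffolds.append(Scaffold(id=sid, sequence=frag))
        truth[sid] = "contaminant"
        sources.append((lineage, pos, pos + L))
    for i in range(cfg.n_short_junk_scaffolds):
        sid = f"JUNK{i + 1:03d}"
        scaffolds.append(Scaffold(id=sid, sequence=_rand_dna(rng, int(rng.integers(1200, 1900)), 0.5)))
        truth[sid] = "contaminant"  # short, no evidence of host origin
    return scaffolds, truth, sources


def make_related_genome(
    host_pristine: dict[str, str], cfg: GeneratorConfig, rng: np.random.Generator
) -> list[Scaffold]:
    """A related insect genome: diverged copies of host scaffold segments.

    Built from the pre-implant host sequence only, so it provides
    host-origin evidence for true host scaffolds and none for contaminants
    or transferred material.
    """
    out = []
    for i, (sid, seq) in enumerate(sorted(host_pristine.items())):
        L = len(seq)
        seg_len = int(cfg.related_coverage * L)
        n_seg = max(1, seg_len // 5000)
        per = seg_len // n_seg
        for j in range(n_seg):
            frag, _ = _sample_fragment(seq, per, rng)
            frag = mutate_dna(frag, 1.0 - cfg.related_identity, rng)
            out.append(Scaffold(id=f"REL{i + 1:03d}_{j + 1}", sequence=frag))
    return out


def _sample_donor_segment(
    donors: DonorSet, lineage: str, length: int,
    excluded: Sequence[tuple[str, int, int]], rng: np.random.Generator,
) -> tuple[str, int]:
    """A donor genomic segment avoiding intervals that leaked into the assembly."""
    genome = donors.genome_of(lineage)[0].sequence
    for _ in range(200):
        seg, pos = _sample_fragment(genome, length, rng)
        if not any(lin == lineage and pos < hi and pos + length > lo
                   for lin, lo, hi in excluded):
            return seg, pos
    return seg, pos  # fall back rather than fail; rare


def make_reads(
    assembly: Assembly,
    donors: DonorSet,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    chimeric_insert: tuple[str, int, int] | None = None,
    donor_excluded: Sequence[tuple[str, int, int]] = (),
) -> tuple[list[ReadRecord], Scaffold, list[dict]]:
    """Sanger-style read pool over assembly + contaminants, with special reads.

    Returns (reads, vector sequence, junction truth records).  When
    ``chimeric_insert`` = (scaffold_id, start, end) is given, ordinary reads
    avoid that segment and exactly one read spans it (the single-read
    artifact support situation).
    """
    sources = list(assembly)
    lengths = np.array([len(s.sequence) for s in sources], dtype=float)
    total = lengths.sum()
    n_reads = int(round(cfg.coverage * total / cfg.read_len_mean))
    probs = lengths / total
    reads: list[ReadRecord] = []
    counter = 0

    def _new_id() -> str:
        nonlocal counter
        counter += 1
        return f"READ{counter:05d}"

    def _emit(seq: str, category: str, source: str) -> None:
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(ReadRecord(Scaffold(id=_new_id(), sequence=seq), category, source))

    for _ in range(n_reads):
        si = int(rng.choice(len(sources), p=probs))
        s = sources[si]
        rl = int(np.clip(rng.normal(cfg.read_len_mean, cfg.read_len_sd), 300, 1200))
        rl = min(rl, len(s.sequence))
        pos = None
        for _try in range(60):
            cand = int(rng.integers(0, max(1, len(s.sequence) - rl + 1)))
            if chimeric_insert and s.id == chimeric_insert[0]:
                lo, hi = chimeric_insert[1] - 50, chimeric_insert[2] + 50
                if cand <= hi and cand + rl - 1 >= lo:
                    continue
            # reads come from sequencing, not from the assembly: they never
            # contain assembly-gap Ns
            if "N" in s.sequence[cand:cand + rl]:
                continue
            pos = cand
            break
        if pos is None:
            continue  # scaffold region saturated with gaps/exclusions
        category = "contaminant" if s.id.startswith(("CONTAM", "JUNK")) else "host"
        _emit(s.sequence[pos:pos + rl], category, f"{s.id}:{pos + 1}")

    if chimeric_insert is not None:
        sid, lo, hi = chimeric_insert
        s = assembly[sid]
        center = (lo + hi) // 2
        start = max(0, center - cfg.read_len_mean // 2)
        _emit(s.sequence[start:start + cfg.read_len_mean], "chimeric_scaffold_read", f"{sid}:{start + 1}")

    # genuine (but unassembled) host/donor junctions, multi-read supported
    junctions = []
    host_ids = [s.id for s in assembly if s.id.startswith("HOST")]
    for j in range(cfg.n_unassembled_junctions):
        hs = assembly[host_ids[int(rng.integers(len(host_ids)))]]
        hseg, hpos = _sample_fragment(hs.sequence, 700, rng, avoid_n=True)
        dseg, dpos = _sample_donor_segment(donors, "donorA", 700, donor_excluded, rng)
        template = hseg + dseg
        junctions.append({
            "junction_id": f"JUNCTION{j + 1}", "host_source": f"{hs.id}:{hpos + 1}",
            "donor_source": f"donorA_genome:{dpos + 1}", "support": cfg.junction_support,
        })
        for _k in range(cfg.junction_support):
            # each supporting read spans the junction with >=300 nt on each side
            start = len(hseg) - int(rng.integers(300, 501))
            seg = template[start:start + cfg.read_len_mean]
            _emit(seg, "junction_support", f"JUNCTION{j + 1}")

    # singleton artifact chimeras: unique host/donor junctions
    n_chim = int(round(cfg.chimeric_read_rate * n_reads))
    for _ in range(n_chim):
        hs = assembly[host_ids[int(rng.integers(len(host_ids)))]]
        hseg, _ = _sample_fragment(hs.sequence, 400, rng, avoid_n=True)
        lineage = "donorA" if rng.random() < 0.5 else "donorB"
        dseg, _ = _sample_donor_segment(donors, lineage, 400, donor_excluded, rng)
        _emit(hseg + dseg, "artifact_chimera", "artifact")

    vector = Scaffold(id="VECTOR_pUC_like", sequence=_rand_dna(rng, 2700, 0.5))
    for _ in range(cfg.n_vector_reads):
        seg, _ = _sample_fragment(vector.sequence, 700, rng)
        _emit(seg, "vector", "vector")

    for _ in range(cfg.n_lowcomplexity_reads):
        unit = _rand_dna(rng, int(rng.integers(2, 7)), 0.3)
        seq = (unit * (600 // len(unit) + 1))[:600]
        _emit(mutate_dna(seq, 0.02, rng), "lowcomplexity", "lowcomplexity")

    return reads, vector, junctions


def simulate_qpcr(
    genomic_loci: Sequence[str],
    contaminant_loci: Sequence[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate copy-number ratios (target per single-copy standard).

    Each strain contributes several biological samples (DNA batches), each
    measured with ``qpcr_tech_reps`` technical replicates.  Genomic loci
    have small among-sample effects around a mean of 1; contaminant loci
    have log-normal per-sample titers whose among-sample scatter dwarfs the
    technical noise, mimicking infection-level variation among individuals.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    rows = []

    def _emit(locus: str, truth: str) -> None:
        for strain, n_samples in cfg.qpcr_strains.items():
            for sample in range(1, n_samples + 1):
                if truth == "genomic":
                    base = rng.normal(1.0, cfg.qpcr_sigma_genomic)
                    while base <= 0.05:
                        base = rng.normal(1.0, cfg.qpcr_sigma_genomic)
                else:
                    base = float(np.exp(rng.normal(0.0, cfg.qpcr_contaminant_log_sd)))
                for rep in range(1, cfg.qpcr_tech_reps + 1):
                    r = base * max(rng.normal(1.0, cfg.qpcr_tech_sigma), 0.05)
                    rows.append((locus, strain, sample, rep, max(r, 1e-6), truth))

    for locus in genomic_loci:
        _emit(locus, "genomic")
    for locus in contaminant_loci:
        _emit(locus, "contaminant")
    return pd.DataFrame(
        rows, columns=["locus", "strain", "sample", "replicate", "ratio", "truth_class"])


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticDataset:
    cfg: GeneratorConfig
    assembly: Assembly  # host + contaminant scaffolds (the thing screened)
    gaps: list[GenomicInterval]
    donors: DonorSet
    related_genome: list[Scaffold]
    truth_events: list[TruthEvent]
    scaffold_truth: dict[str, str]  # scaffold id -> host|contaminant|chimeric_scaffold
    chimeric_insert: tuple[str, int, int] | None
    reads: list[ReadRecord]
    vector: Scaffold
    junctions: list[dict]
    qpcr: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for ev in self.truth_events:
            rows.append({
                "event_id": ev.event_id, "class": ev.cls,
                "donor_lineage": ev.donor_lineage,
                "scaffold_id": ev.locus.scaffold_id, "start": ev.locus.start,
                "end": ev.locus.end, "strand": ev.locus.strand,
                "divergence_tier": ev.divergence_tier,
                "n_frameshifts": ev.n_frameshifts,
                "n_internal_stops": ev.n_internal_stops,
                "truncation_fraction": round(ev.truncation_fraction, 4),
                "homolog_id": ev.homolog_id, "cluster_id": ev.cluster_id or "",
            })
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(list(self.assembly), out / "assembly.fasta")
        write_fasta([r.read for r in self.reads], out / "reads.fasta")
        write_fasta(self.donors.donorA, out / "donorA_proteome.fasta")
        write_fasta(self.donors.donorB, out / "donorB_proteome.fasta")
        write_fasta(self.donors.decoy, out / "decoy_proteome.fasta")
        write_fasta(self.donors.donorA_genome, out / "donorA_genome.fasta")
        write_fasta(self.donors.donorB_genome, out / "donorB_genome.fasta")
        write_fasta(self.related_genome, out / "related_genome.fasta")
        write_fasta([self.vector], out / "vector.fasta")
        self.truth_frame().to_csv(out / "truth_events.tsv", sep="\t", index=False)
        with open(out / "truth_events.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for ev in self.truth_events:
                fh.write("\t".join([
                    ev.locus.scaffold_id, "lgtscreen_synth", "LGT_event",
                    str(ev.locus.start), str(ev.locus.end), ".", ev.locus.strand, ".",
                    f"ID={ev.event_id};class={ev.cls};donor={ev.donor_lineage}",
                ]) + "\n")
            for g in self.gaps:
                fh.write("\t".join([
                    g.scaffold_id, "lgtscreen_synth", "gap",
                    str(g.start), str(g.end), ".", "+", ".", "ID=gap",
                ]) + "\n")
        pd.DataFrame(
            [{"scaffold_id": k, "class": v} for k, v in sorted(self.scaffold_truth.items())]
        ).to_csv(out / "scaffold_truth.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"read_id": r.read.id, "category": r.category, "source": r.source}
             for r in self.reads]
        ).to_csv(out / "read_truth.tsv", sep="\t", index=False)
        self.qpcr.to_csv(out / "qpcr.csv", index=False)
        self.cfg.to_yaml(out / "config.yaml")


def generate(cfg: GeneratorConfig) -> SyntheticDataset:
    """Run the whole generator pipeline deterministically from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    assembly, gaps = generate_host_assembly(cfg, rng)
    host_pristine = {s.id: s.sequence for s in assembly}
    donors = evolve_donor_proteomes(cfg, rng)
    truth_events = implant_events(assembly, donors, cfg.roster, cfg, gaps, rng)
    related = make_related_genome(host_pristine, cfg, rng)

    contam, scaffold_truth, contam_sources = make_contaminants(donors, cfg, rng)
    for s in list(assembly):
        scaffold_truth.setdefault(s.id, "host")

    chimeric_insert = None
    if cfg.include_chimeric_scaffold:
        # bacterial micro-insert into a host scaffold without implanted events
        used = {ev.locus.scaffold_id for ev in truth_events}
        candidates = [s for s in assembly if s.id not in used and s.id.startswith("HOST")]
        target = candidates[-1] if candidates else list(assembly)[-1]
        genome = donors.donorA_genome[0].sequence
        frag, fpos = _sample_fragment(genome, cfg.chimeric_insert_len, rng)
        frag = mutate_dna(frag, 0.01, rng)
        contam_sources.append(("donorA", fpos, fpos + len(frag)))
        L = len(target.sequence)
        pos = int(rng.integers(L // 3, 2 * L // 3))
        target.sequence = (
            target.sequence[:pos] + frag + target.sequence[pos + len(frag):]
        )
        chimeric_insert = (target.id, pos + 1, pos + len(frag))
        scaffold_truth[target.id] = "chimeric_scaffold"

    all_scaffolds = list(assembly) + contam
    full_assembly = Assembly(all_scaffolds)

    reads, vector, junctions = make_reads(
        full_assembly, donors, cfg, rng, chimeric_insert, donor_excluded=contam_sources)

    qpcr = simulate_qpcr(
        [ev.event_id for ev in truth_events],
        sorted(sid for sid, c in scaffold_truth.items() if sid.startswith("CONTAM")),
        cfg, rng,
    )
    return SyntheticDataset(
        cfg=cfg, assembly=full_assembly, gaps=gaps, donors=donors,
        related_genome=related, truth_events=truth_events,
        scaffold_truth=scaffold_truth, chimeric_insert=chimeric_insert,
        reads=reads, vector=vector, junctions=junctions, qpcr=qpcr,
    )
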