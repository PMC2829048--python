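"""Donor-lineage attribution: distances, neighbor joining, bootstrap,
and a relative-rate test for pseudogene acceleration.

Neighbor joining is implemented here in full (Q-criterion agglomeration,
deterministic label-order tie-breaks, negative branch lengths clamped to
zero) because placement calls depend on its exact behaviour; scikit-bio's
implementation serves as an independent cross-check in the test suite, not
as the engine.  Bootstrap support resamples alignment columns with
replacement and scores each split of the point-estimate tree by the
fraction of replicate trees containing it.

The relative-rate test is Tajima's 1D test: with an outgroup O and two
ingroups A and B, m1 counts sites where A differs while B agrees with O,
m2 the converse; under rate equality (m1-m2)^2/(m1+m2) is asymptotically
chi-square with 1 df.  Pseudogenes, free of purifying selection, are
expected to reject toward the faster ingroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .homology import PROTEIN_SCHEME, ScoringScheme, _aligner
from .seqio import Scaffold


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    """Minimal unrooted-tree node; children with branch lengths."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name] if self.name else []
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, include_support: bool = True) -> str:
        return self._newick(include_support) + ";"

    def _newick(self, sup: bool) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(
            f"{child._newick(sup)}:{bl:.6f}" for child, bl in self.children
        )
        label = ""
        if sup and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}"


@dataclass
class TreeResult:
    tree: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self) -> str:
        return self.tree.newick()


@dataclass
class RateTestResult:
    ingroup1: str
    ingroup2: str
    outgroup: str
    m1: int
    m2: int
    chi2: float
    p: float
    n_sites: int


# ---------------------------------------------------------------------------
# alignment utilities

def drop_gap_columns(seqs: Sequence[str]) -> list[str]:
    """Remove every column holding a gap in any row (complete-deletion)."""
    if not seqs:
        return []
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned rows must have equal length")
    keep = [k for k in range(L) if all(s[k] not in "-." for s in seqs)]
    return ["".join(s[k] for k in keep) for s in seqs]


_GLOBAL_ALIGNERS: dict = {}


def pairwise_align(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> tuple[str, str]:
    """End-gap-free global pairwise alignment (for distance computation).

    Free end gaps keep fragments (e.g. a truncated pseudogene against a
    full-length ortholog) aligned compactly instead of smeared across the
    longer sequence.
    """
    key = (scheme.matrix, scheme.match, scheme.mismatch,
           scheme.gap_open, scheme.gap_extend)
    aligner = _GLOBAL_ALIGNERS.get(key)
    if aligner is None:
        import copy

        aligner = copy.deepcopy(_aligner(scheme))
        aligner.mode = "global"
        aligner.end_gap_score = 0.0
        _GLOBAL_ALIGNERS[key] = aligner
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def anchor_msa(seqs: Sequence[Scaffold], anchor_index: int | None = None) -> list[Scaffold]:
    """Quick multiple alignment by projection onto an anchor sequence.

    Every sequence is pairwise-aligned to the longest sequence (the anchor)
    and its residues are projected onto anchor columns; insertions relative
    to the anchor are discarded.  Crude next to a true progressive aligner,
    but column-consistent, fast, and adequate for the moderately diverged
    protein sets the placement step sees.  A user-supplied alignment can be
    passed straight to the downstream operations instead.
    """
    if anchor_index is None:
        anchor_index = max(range(len(seqs)), key=lambda i: len(seqs[i].sequence))
    anchor = seqs[anchor_index].sequence
    rows = []
    for s in seqs:
        if s.sequence == anchor:
            rows.append(Scaffold(id=s.id, sequence=anchor))
            continue
        sa, sb = pairwise_align(anchor, s.sequence)
        proj = []
        for ca, cb in zip(sa, sb):
            if ca == "-":
                continue  # insertion relative to anchor: dropped
            proj.append(cb)
        rows.append(Scaffold(id=s.id, sequence="".join(proj)))
    return rows


def pairwise_distances(
    seqs: Sequence[Scaffold], model: str = "poisson"
) -> DistanceMatrix:
    """p-distances or Poisson-corrected distances on aligned rows.

    Columns containing a gap in any row are omitted first.  Pairs with
    p >= 1 (impossible under the correction) are flagged saturated and
    assigned a large finite distance.
    """
    taxa = [s.id for s in seqs]
    rows = drop_gap_columns([s.sequence for s in seqs])
    L = len(rows[0]) if rows else 0
    if L == 0:
        raise ValueError("no comparable gap-free sites")
    n = len(taxa)
    D = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sum(1 for a, b in zip(rows[i], rows[j]) if a != b)
            p = diffs / L
            if model == "p-distance":
                d = p
            elif model == "poisson":
                if p >= 1.0:
                    d = 10.0
                    saturated.add((taxa[i], taxa[j]))
                else:
                    d = -math.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            D[i, j] = D[j, i] = d
    return DistanceMatrix(taxa, D, saturated)


# ---------------------------------------------------------------------------
# neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical NJ agglomeration with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step (ties broken
    by label order); negative branch lengths are clamped to zero.  Returns
    an unrooted tree (trifurcating root node).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    labels = list(dm.taxa)
    D = dm.matrix.astype(float).copy()

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * D[i, j] - r[i] - r[j]
                key = (q, min(labels[i], labels[j]), max(labels[i], labels[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (k - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (D[i, :] + D[j, :] - d_ij)
        keep = [x for x in range(k) if x not in (i, j)]
        D_new = np.zeros((k - 1, k - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = D_new[:-1, -1] = new_d[keep]
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(l for l in (labels[i], labels[j]))]
        D = D_new

    # terminal trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max(0.0, 0.5 * (d01 + d02 - d12))
    l1 = max(0.0, 0.5 * (d01 + d12 - d02))
    l2 = max(0.0, 0.5 * (d02 + d12 - d01))
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def tree_splits(tree: TreeNode, all_taxa: frozenset | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, as min-side leaf sets."""
    if all_taxa is None:
        all_taxa = frozenset(tree.leaves())
    splits: set[frozenset] = set()

    def _walk(node: TreeNode) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            sub = _walk(child)
            if 1 < len(sub) < len(all_taxa) - 1:
                other = all_taxa - sub
                splits.add(sub if sorted(sub) <= sorted(other) else other)
            below = below | sub
        return below

    _walk(tree)
    return splits


def _annotate_supports(tree: TreeNode, supports: dict[frozenset, float],
                       all_taxa: frozenset) -> None:
    def _walk(node: TreeNode) -> frozenset:
        if not node.children:
            return frozenset([node.name])
        below = frozenset()
        for child, _ in node.children:
            below = below | _walk(child)
        if 1 < len(below) < len(all_taxa) - 1:
            other = all_taxa - below
            key = below if sorted(below) <= sorted(other) else other
            if key in supports:
                node.support = supports[key]
        return below

    _walk(tree)


def bootstrap_support(
    seqs: Sequence[Scaffold],
    B: int = 1000,
    seed: int = 0,
    model: str = "poisson",
) -> TreeResult:
    """NJ tree with column-resampled bootstrap support (percent).

    Columns of the (gap-free) alignment are resampled with replacement B
    times; each split of the point-estimate tree is scored by the fraction
    of replicate trees containing it.
    """
    rows = drop_gap_columns([s.sequence for s in seqs])
    taxa = [s.id for s in seqs]
    L = len(rows[0])
    if L < 2:
        raise ValueError("alignment must have at least 2 comparable columns")
    point = neighbor_joining(pairwise_distances(
        [Scaffold(id=t, sequence=r) for t, r in zip(taxa, rows)], model))
    all_taxa = frozenset(taxa)
    target_splits = tree_splits(point, all_taxa)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in rows])
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        try:
            rep_tree = neighbor_joining(pairwise_distances(
                [Scaffold(id=t, sequence=r) for t, r in zip(taxa, rep_rows)], model))
        except ValueError:
            continue
        rep_splits = tree_splits(rep_tree, all_taxa)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / B for s, c in counts.items()}
    _annotate_supports(point, supports, all_taxa)
    return TreeResult(tree=point, supports=supports)


# ---------------------------------------------------------------------------
# relative-rate test

def relative_rate_test(
    in1: str, in2: str, outgroup: str,
    labels: tuple[str, str, str] = ("ingroup1", "ingroup2", "outgroup"),
) -> RateTestResult:
    """Tajima's 1D relative-rate test on three aligned sequences.

    Gap columns are removed; m1 counts sites where ingroup 1 alone differs
    (ingroup 2 matches the outgroup), m2 the mirror image; the statistic
    (m1-m2)^2/(m1+m2) is referred to chi-square with 1 df.
    """
    a, b, o = drop_gap_columns([in1, in2, outgroup])
    if not a:
        raise ValueError("no comparable sites")
    m1 = sum(1 for x, y, z in zip(a, b, o) if x != z and y == z)
    m2 = sum(1 for x, y, z in zip(a, b, o) if y != z and x == z)
    if m1 + m2 == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (m1 - m2) ** 2 / (m1 + m2)
        p = float(stats.chi2.sf(chi2, df=1))
    return RateTestResult(labels[0], labels[1], labels[2], m1, m2, chi2, p, len(a))


# ---------------------------------------------------------------------------
# placement

def write_alignment(seqs: Sequence[Scaffold], path, fmt: str = "fasta") -> None:
    """Export an alignment (FASTA or relaxed PHYLIP) for external tree tools."""
    with open(path, "w") as fh:
        if fmt == "fasta":
            for s in seqs:
                fh.write(f">{s.id}\n{s.sequence}\n")
        elif fmt == "phylip":
            fh.write(f" {len(seqs)} {len(seqs[0].sequence)}\n")
            for s in seqs:
                fh.write(f"{s.id}  {s.sequence}\n")
        else:
            raise ValueError(f"unknown alignment format {fmt!r}")


@dataclass
class PlacementCall:
    candidate_id: str
    lineage: str  # donor lineage tag, or "unresolved"
    support: float
    low_information: bool = False
    tree: TreeResult | None = None


def placement_report(
    candidate: Scaffold,
    references: Sequence[Scaffold],
    lineages: dict[str, str],
    support_min: float = 70.0,
    B: int = 1000,
    seed: int = 0,
) -> PlacementCall:
    """Attribute a candidate peptide to the donor lineage of its smallest
    supported enclosing clade in a bootstrapped NJ tree.

    ``lineages`` maps reference ids to lineage tags.  With references from
    a single lineage the call is that lineage, flagged low-information.
    When no enclosing clade reaches ``support_min`` (or the best-supported
    clade mixes lineages), the call is unresolved.
    """
    tags = {lineages[r.id] for r in references}
    if len(tags) == 1:
        return PlacementCall(candidate.id, tags.pop(), 100.0, low_information=True)
    msa = anchor_msa([candidate] + list(references))
    try:
        result = bootstrap_support(msa, B=B, seed=seed)
    except ValueError:
        # projection left too few comparable columns: no alignable signal
        return PlacementCall(candidate.id, "unresolved", 0.0)
    # clades containing the candidate, smallest first
    cand_clades: list[tuple[int, frozenset, float]] = []
    all_taxa = frozenset(s.id for s in msa)
    for split, sup in result.supports.items():
        side = split if candidate.id in split else all_taxa - split
        members = side - {candidate.id}
        if members:
            cand_clades.append((len(members), side, sup))
    cand_clades.sort(key=lambda x: (x[0], sorted(x[1])))
    for _size, side, sup in cand_clades:
        if sup < support_min:
            continue
        member_tags = {lineages[m] for m in side if m != candidate.id}
        if member_tags == {"outgroup"}:
            continue  # grouping with the outgroup attributes to no donor
        if len(member_tags) == 1:
            return PlacementCall(candidate.id, member_tags.pop(), sup, tree=result)
    return PlacementCall(candidate.id, "unresolved", 0.0, tree=result)
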