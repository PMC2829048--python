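"""Pseudogene annotation against donor homologs, and in-silico PCR.

The central operation aligns a genomic locus (nucleotides) to a homologous
protein with a dynamic program whose moves mirror the biology of decaying
transferred genes:

* a codon move consumes 3 nt and 1 residue, scored by the substitution
  matrix on the codon's conceptual translation (internal stop codons align
  as ``*`` at a penalty, so stop-riddled loci stay alignable);
* frameshift moves consume 1, 2, 4 or 5 nt per residue at a fixed penalty —
  each such move is one frameshifting indel event;
* gap moves handle residue deletions and extra codons;
* intron moves skip an arbitrary nt stretch bounded by GT..AG (canonical,
  mild penalty) or by any dinucleotides (non-canonical, steep penalty,
  flagged) without consuming homolog residues.

The traceback therefore yields, in one pass, the frameshift count, the
internal-stop count, the aligned homolog span (truncation), the amino-acid
identity, and the exon chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import GenomicInterval, revcomp, translate

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = _BLOSUM.alphabet
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHA)}
_BLOSUM_ARR = np.array(_BLOSUM)

# codon -> row index into the BLOSUM array of its conceptual translation
_CODON_ROW: dict[str, int] = {}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            _cdn = _a + _b + _c
            _CODON_ROW[_cdn] = _AA_INDEX[translate(_cdn) or "*"]

DEFAULT_FRAMESHIFT_PENALTY = -16.0
# Aligning a stop codon to a homolog residue costs -11: dearer than any
# ordinary mismatch (so stops are never preferred to substitutions) but a
# pair of stops (-20) stays cheaper than a pair of frameshifts (-32), so
# genuine stop runs are not re-explained as indels.
DEFAULT_STOP_PENALTY = -10.0
DEFAULT_GAP_AA = -12.0  # residue missing from the locus
DEFAULT_GAP_CODON = -12.0  # extra codon in the locus
DEFAULT_INTRON_PENALTY = -15.0
DEFAULT_NONCANONICAL_PENALTY = -40.0
MIN_INTRON = 50


@dataclass
class Exon:
    start: int  # 1-based on the locus
    end: int


@dataclass
class PseudogeneReport:
    locus_id: str
    homolog_id: str
    n_frameshifts: int
    n_internal_stops: int
    truncation_fraction: float
    identity_aa: float
    score: float
    exons: list[Exon] = field(default_factory=list)
    noncanonical_introns: int = 0
    aligned_homolog_span: tuple[int, int] = (0, 0)
    aligned_locus_span: tuple[int, int] = (0, 0)

    @property
    def intact(self) -> bool:
        return (
            self.n_frameshifts == 0
            and self.n_internal_stops == 0
            and self.truncation_fraction >= 0.9
        )


# move codes for the traceback
_STOP_MOVE, _CODON, _FS1, _FS2, _FS4, _FS5, _GAPC, _GAPA, _INTRON, _NCINTRON = range(10)
_FS_MOVES = {_FS1: 1, _FS2: 2, _FS4: 4, _FS5: 5}


def align_protein_to_locus(
    locus_nt: str,
    homolog: str,
    frameshift_penalty: float = DEFAULT_FRAMESHIFT_PENALTY,
    stop_penalty: float = DEFAULT_STOP_PENALTY,
    gap_aa: float = DEFAULT_GAP_AA,
    gap_codon: float = DEFAULT_GAP_CODON,
    spliced: bool = True,
    intron_penalty: float = DEFAULT_INTRON_PENALTY,
    noncanonical_penalty: float = DEFAULT_NONCANONICAL_PENALTY,
    min_intron: int = MIN_INTRON,
):
    """Local spliced frameshift-aware alignment; returns (score, path, spans).

    The path is a list of (move, i, j) with i nt and j residues consumed
    *after* the move, in alignment order.
    """
    n = len(locus_nt)
    m = len(homolog)
    if n < 3 or m < 1:
        raise ValueError("locus or homolog too short to align")
    hom_idx = np.array([_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in homolog])
    # per-position codon substitution vectors (rows i>=3 refer to nt[i-3:i])
    codon_rows = np.full(n + 1, -1, dtype=np.int64)
    for i in range(3, n + 1):
        codon_rows[i] = _CODON_ROW.get(locus_nt[i - 3:i], _AA_INDEX["X"])

    S = np.full((n + 1, m + 1), 0.0)
    NEG = -1e9
    # running best donor rows for intron moves, per homolog position
    don_best = np.full(m + 1, NEG)
    don_row = np.full(m + 1, -1, dtype=np.int64)
    nc_best = np.full(m + 1, NEG)
    nc_row = np.full(m + 1, -1, dtype=np.int64)
    gt_rows = []  # (row, values) awaiting min_intron delay
    any_rows = []

    for i in range(1, n + 1):
        cand = np.zeros(m + 1)
        if i >= 3:
            if codon_rows[i] == _AA_INDEX["*"]:
                sub = np.full(m, stop_penalty)
            else:
                sub = _BLOSUM_ARR[codon_rows[i], hom_idx]  # vs each homolog residue
            cand[1:] = np.maximum(cand[1:], S[i - 3, :-1] + sub)
            cand = np.maximum(cand, S[i - 3, :] + gap_codon)
        for mv, k in _FS_MOVES.items():
            if i >= k:
                cand[1:] = np.maximum(cand[1:], S[i - k, :-1] + frameshift_penalty)
        if spliced:
            # fold donor rows that are now far enough back
            while gt_rows and gt_rows[0][0] <= i - min_intron:
                r, vals = gt_rows.pop(0)
                upd = vals > don_best
                don_best[upd] = vals[upd]
                don_row[upd] = r
            while any_rows and any_rows[0][0] <= i - min_intron:
                r, vals = any_rows.pop(0)
                upd = vals > nc_best
                nc_best[upd] = vals[upd]
                nc_row[upd] = r
            if i >= 2 and locus_nt[i - 2:i] == "AG":
                cand = np.maximum(cand, don_best + intron_penalty)
            cand = np.maximum(cand, nc_best + noncanonical_penalty)
        # residue gaps within the row (linear): running max trick
        j_idx = np.arange(m + 1)
        shifted = cand - j_idx * gap_aa
        run = np.maximum.accumulate(shifted)
        cand = np.maximum(cand, run + j_idx * gap_aa)
        cand = np.maximum(cand, 0.0)
        S[i] = cand
        if spliced:
            if i + 2 <= n and locus_nt[i:i + 2] == "GT":
                gt_rows.append((i, S[i].copy()))
            any_rows.append((i, S[i].copy()))

    # locate optimum and trace back by re-deriving the move at each cell
    flat = int(np.argmax(S))
    bi, bj = divmod(flat, m + 1)
    best_score = S[bi, bj]
    path: list[tuple[int, int, int]] = []
    i, j = bi, bj
    eps = 1e-6

    def _donor_lookup(i: int, j: int, canonical: bool) -> int | None:
        """Best donor row r for an intron ending at i (recomputed exactly)."""
        pen = intron_penalty if canonical else noncanonical_penalty
        best_r, best_v = None, NEG
        for r in range(1, i - min_intron + 1):
            if canonical and locus_nt[r:r + 2] != "GT":
                continue
            v = S[r, j] + pen
            if v > best_v + eps:
                best_v, best_r = v, r
        if best_r is not None and abs(best_v - S[i, j]) < eps:
            return best_r
        return None

    while i > 0 and j >= 0 and S[i, j] > eps:
        v = S[i, j]
        moved = False
        if i >= 3 and j >= 1:
            if codon_rows[i] == _AA_INDEX["*"]:
                sub = stop_penalty
            else:
                sub = _BLOSUM_ARR[codon_rows[i], hom_idx[j - 1]]
            if abs(S[i - 3, j - 1] + sub - v) < eps:
                mv = _STOP_MOVE if codon_rows[i] == _AA_INDEX["*"] else _CODON
                path.append((mv, i, j))
                i, j = i - 3, j - 1
                moved = True
        if not moved:
            for mvk, k in _FS_MOVES.items():
                if i >= k and j >= 1 and abs(S[i - k, j - 1] + frameshift_penalty - v) < eps:
                    path.append((mvk, i, j))
                    i, j = i - k, j - 1
                    moved = True
                    break
        if not moved and i >= 3 and abs(S[i - 3, j] + gap_codon - v) < eps:
            path.append((_GAPC, i, j))
            i = i - 3
            moved = True
        if not moved and j >= 1 and abs(S[i, j - 1] + gap_aa - v) < eps:
            path.append((_GAPA, i, j))
            j = j - 1
            moved = True
        if not moved and spliced and i >= 2 and locus_nt[i - 2:i] == "AG":
            r = _donor_lookup(i, j, canonical=True)
            if r is not None:
                path.append((_INTRON, i, j))
                i = r
                moved = True
        if not moved and spliced:
            r = _donor_lookup(i, j, canonical=False)
            if r is not None:
                path.append((_NCINTRON, i, j))
                i = r
                moved = True
        if not moved:
            break  # hit the local-alignment floor
    path.reverse()
    return best_score, path, (i, j), (bi, bj)


def _forced_extension(
    locus_seg: str,
    hom_seg: str,
    stop_penalty: float,
    frameshift_penalty: float = DEFAULT_FRAMESHIFT_PENALTY,
    gap_aa: float = DEFAULT_GAP_AA,
    gap_codon: float = DEFAULT_GAP_CODON,
    reverse: bool = False,
    accept_tol: float = 40.0,
    max_locus_tail: int = 60,
) -> tuple[int, int, int, int] | None:
    """Extend an alignment end through a short remaining locus segment.

    A local alignment trims diverged terminal codons, but the reading frame
    of a genuine fragment runs to the fragment boundary.  This DP forcibly
    consumes the whole remaining locus segment (codon, frameshift, stop and
    gap moves allowed) with a free homolog end, and the extension is
    accepted when it costs at most ``accept_tol``.  Segments longer than
    ``max_locus_tail`` nt are left to the local alignment (they are usually
    flanking DNA, not trimmed homology).  Returns (nt_consumed,
    aa_consumed, n_frameshifts, n_stops) or None.
    """
    n = len(locus_seg)
    if n == 0 or n > max_locus_tail:
        return None
    m = min(len(hom_seg), n + 20)
    if reverse:
        locus_seg = locus_seg[::-1]
        hom_seg = hom_seg[::-1]

    def codon_at(i: int) -> str:
        c = locus_seg[i - 3:i]
        return c[::-1] if reverse else c

    NEG = -1e9
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    moves: dict[tuple[int, int], tuple[int, int, str]] = {}
    for i in range(n + 1):
        for j in range(m + 1):
            v = D[i][j]
            if v <= NEG / 2:
                continue
            if i + 3 <= n and j + 1 <= m:
                c = codon_at(i + 3)
                row = _CODON_ROW.get(c, _AA_INDEX["X"])
                if row == _AA_INDEX["*"]:
                    s, kind = stop_penalty, "stop"
                else:
                    aa = hom_seg[j] if not reverse else hom_seg[j]
                    s = _BLOSUM_ARR[row, _AA_INDEX.get(aa, _AA_INDEX["X"])]
                    kind = "codon"
                if v + s > D[i + 3][j + 1]:
                    D[i + 3][j + 1] = v + s
                    moves[(i + 3, j + 1)] = (i, j, kind)
            for k in (1, 2, 4, 5):
                if i + k <= n and j + 1 <= m and v + frameshift_penalty > D[i + k][j + 1]:
                    D[i + k][j + 1] = v + frameshift_penalty
                    moves[(i + k, j + 1)] = (i, j, "fs")
            if i + 3 <= n and v + gap_codon > D[i + 3][j]:
                D[i + 3][j] = v + gap_codon
                moves[(i + 3, j)] = (i, j, "gapc")
            if j + 1 <= m and v + gap_aa > D[i][j + 1]:
                D[i][j + 1] = v + gap_aa
                moves[(i, j + 1)] = (i, j, "gapa")
    best_j, best_v = None, NEG
    for j in range(m + 1):
        if D[n][j] > best_v:
            best_v, best_j = D[n][j], j
    if best_j is None or best_v < -accept_tol:
        return None
    # trim trailing pure-gap moves on the homolog side (they add no span)
    i, j = n, best_j
    n_fs = n_stop = 0
    while (i, j) in moves:
        pi, pj, kind = moves[(i, j)]
        if kind == "fs":
            n_fs += 1
        elif kind == "stop":
            n_stop += 1
        i, j = pi, pj
    return n, best_j, n_fs, n_stop


def _trim_weak_terminal_segments(
    path, locus_nt, homolog, span0, span1,
    fs_pen, stop_pen, gap_aa, gap_codon,
    min_terminal_score: float = 45.0,
):
    """Drop leading/trailing inter-intron segments below the chance level.

    Returns the trimmed path and updated (i0, j0), (i1, j1) spans.
    """
    def move_score(mv, i, j):
        if mv == _CODON:
            return float(_BLOSUM_ARR[_CODON_ROW.get(locus_nt[i - 3:i], _AA_INDEX["X"]),
                                     _AA_INDEX.get(homolog[j - 1], _AA_INDEX["X"])])
        if mv == _STOP_MOVE:
            return stop_pen
        if mv in _FS_MOVES:
            return fs_pen
        if mv == _GAPC:
            return gap_codon
        if mv == _GAPA:
            return gap_aa
        return 0.0  # intron moves separate segments

    segments: list[list] = [[]]
    for entry in path:
        if entry[0] in (_INTRON, _NCINTRON):
            segments.append([entry])  # intron leads its following segment
        else:
            segments[-1].append(entry)

    def seg_score(seg):
        return sum(move_score(*e) for e in seg if e[0] not in (_INTRON, _NCINTRON))

    while len(segments) > 1 and seg_score(segments[0]) < min_terminal_score:
        segments.pop(0)
        # the popped segment's trailing intron belongs to the next one
    while len(segments) > 1 and seg_score(segments[-1]) < min_terminal_score:
        segments.pop()
    # drop a leading intron move left at the front
    if segments and segments[0] and segments[0][0][0] in (_INTRON, _NCINTRON):
        segments[0] = segments[0][1:]
    new_path = [e for seg in segments for e in seg]
    if not new_path:
        return [], span0, span1
    first = new_path[0]
    last = new_path[-1]
    mv, i, j = first
    width = 3 if mv in (_CODON, _STOP_MOVE, _GAPC) else _FS_MOVES.get(mv, 0)
    j_used = 0 if mv in (_GAPC,) else 1
    i0 = i - width
    j0 = j - j_used
    i1, j1 = last[1], last[2]
    return new_path, (i0, j0), (i1, j1)


def annotate_locus(
    locus_nt: str,
    homolog_protein: str,
    locus_id: str = "locus",
    homolog_id: str = "homolog",
    bits_min_score: float = 40.0,
    spliced: bool = True,
    **dp_kwargs,
) -> PseudogeneReport | None:
    """Annotate frameshifts, internal stops, truncation and exon chain.

    Returns ``None`` when no alignment of at least ``bits_min_score`` raw
    score exists (no credible homology).
    """
    if len(homolog_protein) < 30:
        raise ValueError("homolog shorter than 30 aa")
    score, path, (i0, j0), (i1, j1) = align_protein_to_locus(
        locus_nt, homolog_protein, spliced=spliced, **dp_kwargs)
    if score < bits_min_score or not path:
        return None
    stop_pen = dp_kwargs.get("stop_penalty", DEFAULT_STOP_PENALTY)
    fs_pen = dp_kwargs.get("frameshift_penalty", DEFAULT_FRAMESHIFT_PENALTY)
    # terminal exons must carry independent signal: an intron move can
    # attach a chance downstream match to the genuine block, so terminal
    # inter-intron segments scoring below the chance level are trimmed
    path, (i0, j0), (i1, j1) = _trim_weak_terminal_segments(
        path, locus_nt, homolog_protein, (i0, j0), (i1, j1),
        fs_pen, stop_pen,
        dp_kwargs.get("gap_aa", DEFAULT_GAP_AA),
        dp_kwargs.get("gap_codon", DEFAULT_GAP_CODON),
    )
    if not path:
        return None
    # end repair: a local alignment trims diverged-but-real terminal
    # stretches; force-align the short remaining locus segments
    ext_fs = ext_stop = 0
    tail = _forced_extension(
        locus_nt[i1:], homolog_protein[j1:], stop_pen, fs_pen)
    if tail is not None:
        nt_used, aa_used, t_fs, t_stop = tail
        i1 += nt_used
        j1 += aa_used
        ext_fs += t_fs
        ext_stop += t_stop
    head = _forced_extension(
        locus_nt[:i0], homolog_protein[:j0], stop_pen, fs_pen, reverse=True)
    if head is not None:
        nt_used, aa_used, h_fs, h_stop = head
        i0 -= nt_used
        j0 -= aa_used
        ext_fs += h_fs
        ext_stop += h_stop
    # (start, end, width) of each frameshift move, in locus order
    fs_moves = sorted(
        (i - _FS_MOVES[mv], i, _FS_MOVES[mv])
        for mv, i, _ in path if mv in _FS_MOVES
    )
    # A frameshift pair with zero net frame offset whose bracket, re-read in
    # the flanking reading frame, contains stop codons is the DP's way of
    # stepping around those stops; report it as the stops instead.
    reinterpreted_stops = 0
    keep: list[tuple[int, int, int]] = []
    k = 0
    while k < len(fs_moves):
        if k + 1 < len(fs_moves):
            s1, e1, w1 = fs_moves[k]
            s2, e2, w2 = fs_moves[k + 1]
            # stop-stepping leaves the reading frame unchanged: the pair's
            # net frame offset must be exactly zero, and the re-read
            # bracket must look homologous (canceling indels enclose
            # shifted garbage, which scores negatively)
            if s2 - e1 <= 40 and (w1 - 3) + (w2 - 3) == 0:
                j_first = next(j for mv, i, j in path
                               if mv in _FS_MOVES and i == e1)
                stops_in_frame = 0
                nonstop_scores = []
                jj = j_first
                for p in range(s1, e2 - 2, 3):
                    row = _CODON_ROW.get(locus_nt[p:p + 3], _AA_INDEX["X"])
                    if row == _AA_INDEX["*"]:
                        stops_in_frame += 1
                    elif jj - 1 < len(homolog_protein):
                        nonstop_scores.append(float(_BLOSUM_ARR[
                            row, _AA_INDEX.get(homolog_protein[jj - 1], _AA_INDEX["X"])]))
                    jj += 1
                homologous = (not nonstop_scores
                              or sum(nonstop_scores) / len(nonstop_scores) >= 0.5)
                if stops_in_frame and homologous:
                    reinterpreted_stops += stops_in_frame
                    k += 2
                    continue
        keep.append(fs_moves[k])
        k += 1
    # one biological indel may still be decomposed into adjacent DP moves;
    # frameshift moves within 25 nt count as one junction
    n_fs = ext_fs
    prev_end = None
    for s, e, _w in keep:
        if prev_end is None or s - prev_end >= 25:
            n_fs += 1
        prev_end = e
    # stops are counted over every codon the path consumes in frame,
    # including codons skipped by gap moves (the conceptual reading frame
    # still contains them)
    n_stop = ext_stop + reinterpreted_stops
    for mv, i, j in path:
        if mv == _STOP_MOVE:
            n_stop += 1
        elif mv == _GAPC and _CODON_ROW.get(locus_nt[i - 3:i]) == _AA_INDEX["*"]:
            n_stop += 1
    nc = sum(1 for mv, _, _ in path if mv == _NCINTRON)
    matches = 0
    codon_cols = 0
    for mv, i, j in path:
        if mv in (_CODON, _STOP_MOVE):
            codon_cols += 1
            if translate(locus_nt[i - 3:i]) == homolog_protein[j - 1]:
                matches += 1
    identity = matches / codon_cols if codon_cols else 0.0
    truncation = (j1 - j0) / len(homolog_protein)
    # exon chain: contiguous nt-consuming stretches between intron moves
    exons: list[Exon] = []
    cur_start = i0 + 1
    prev_i = i0
    for mv, i, j in path:
        if mv in (_INTRON, _NCINTRON):
            donor_row = prev_i  # nt consumed before the intron
            if donor_row >= cur_start:
                exons.append(Exon(cur_start, donor_row))
            cur_start = i + 1
        prev_i = i
    if max(prev_i, i1) >= cur_start:
        exons.append(Exon(cur_start, max(prev_i, i1)))
    return PseudogeneReport(
        locus_id=locus_id, homolog_id=homolog_id,
        n_frameshifts=n_fs, n_internal_stops=n_stop,
        truncation_fraction=truncation, identity_aa=identity, score=score,
        exons=exons, noncanonical_introns=nc,
        aligned_homolog_span=(j0 + 1, j1), aligned_locus_span=(i0 + 1, i1),
    )


def infer_intron_structure(
    locus_nt: str,
    evidence: str,
    evidence_type: str = "protein",
    **kwargs,
) -> tuple[list[Exon], int]:
    """Exon chain from spliced alignment against a homolog or transcript.

    Transcript evidence is used through its frame-0 conceptual translation.
    Returns (exons, number of non-canonical introns); a locus with no
    recoverable splice structure comes back as a single exon.
    """
    protein = evidence if evidence_type == "protein" else translate(evidence).rstrip("*")
    report = annotate_locus(locus_nt, protein, spliced=True, **kwargs)
    if report is None or not report.exons:
        return [Exon(1, len(locus_nt))], 0
    return report.exons, report.noncanonical_introns


# ---------------------------------------------------------------------------
# in-silico PCR

@dataclass
class AmpliconPrediction:
    primer_fwd: str
    primer_rev: str
    template_id: str
    start: int  # 1-based 5' position of the forward primer on the template
    end: int  # 1-based 5' position of the reverse primer (template top strand)
    product_length: int
    ambiguous: bool = False


def _find_sites(template: str, primer: str, mismatch_max: int) -> list[int]:
    """0-based start positions where primer matches with <= mismatch_max mismatches."""
    sites = []
    pl = len(primer)
    if mismatch_max == 0:
        pos = template.find(primer)
        while pos != -1:
            sites.append(pos)
            pos = template.find(primer, pos + 1)
        return sites
    for pos in range(len(template) - pl + 1):
        mm = sum(1 for a, b in zip(template[pos:pos + pl], primer) if a != b)
        if mm <= mismatch_max:
            sites.append(pos)
    return sites


def insilico_pcr(
    template: str,
    primer_fwd: str,
    primer_rev: str,
    mismatch_max: int = 0,
    template_id: str = "template",
) -> list[AmpliconPrediction]:
    """Predict PCR products: forward primer plus downstream reverse-complemented
    reverse primer; both template orientations are scanned.

    Product length runs from the forward primer's 5' base to the reverse
    primer's 5' base inclusive.  The smallest product is reported first;
    equal-length alternatives are all returned, flagged ambiguous.
    """
    for p in (primer_fwd, primer_rev):
        if not (15 <= len(p) <= 35):
            raise ValueError("primers must be 15-35 nt")
    products: list[AmpliconPrediction] = []
    for tpl, flip in ((template, False), (revcomp(template), True)):
        fwd_sites = _find_sites(tpl, primer_fwd, mismatch_max)
        rev_sites = _find_sites(tpl, revcomp(primer_rev), mismatch_max)
        for f in fwd_sites:
            for r in rev_sites:
                rev_5p = r + len(primer_rev) - 1  # 5' base of the reverse primer
                if rev_5p <= f + len(primer_fwd) - 1:
                    continue
                length = rev_5p - f + 1
                if flip:
                    start = len(template) - f
                    end = len(template) - rev_5p
                else:
                    start = f + 1
                    end = rev_5p + 1
                products.append(AmpliconPrediction(
                    primer_fwd, primer_rev, template_id, start, end, length))
    products.sort(key=lambda p: (p.product_length, p.start))
    if not products:
        return []
    shortest = products[0].product_length
    out = [p for p in products if p.product_length == shortest]
    if len(out) > 1:
        for p in out:
            p.ambiguous = True
    return out


def extract_locus_for_annotation(assembly, interval: GenomicInterval, flank: int = 0) -> str:
    """Locus sequence in reading orientation, optionally with flanks."""
    from .seqio import extract_region

    lo = max(1, interval.start - flank)
    hi = min(len(assembly[interval.scaffold_id].sequence), interval.end + flank)
    iv = GenomicInterval(interval.scaffold_id, lo, hi, interval.strand)
    return extract_region(assembly, iv)
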