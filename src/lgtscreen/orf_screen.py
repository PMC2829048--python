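"""Candidate enumeration for the two screening strategies.

A *potential polypeptide* (PPP) is the conceptual translation of a
stop-to-stop DNA stretch, irrespective of initiation codons: the stretch
begins on the first codon after the previous stop and ends at the next stop
(or at the scaffold edge, in which case it is flagged ``terminal``).  All
six reading frames are scanned and overlapping frames are permitted.  The
default minimum length is 60 aa.

The window strategy slices every scaffold into fixed-length nucleotide
windows (default 1,000 nt, overlapping by 200 nt) for translated searches;
it catches loci whose reading frame is interrupted by stops or frameshifts
and which therefore never yield a long PPP.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import Assembly, GenomicInterval, Scaffold, revcomp, translate


@dataclass
class PPP:
    """A stop-to-stop conceptual peptide with its genomic provenance."""

    id: str
    peptide: str
    interval: GenomicInterval
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse
    terminal: bool = False  # ends at a scaffold edge without a stop codon

    def __len__(self) -> int:
        return len(self.peptide)

    def to_scaffold(self) -> Scaffold:
        desc = (
            f"frame={self.frame:+d} {self.interval.start}-{self.interval.end}"
            f" strand={self.interval.strand} terminal={int(self.terminal)}"
        )
        return Scaffold(id=self.id, sequence=self.peptide, description=desc)


def _frame_segments(peptide: str) -> list[tuple[int, int, bool]]:
    """Split a frame translation at '*': (aa_start, aa_end, has_closing_stop)."""
    segments = []
    start = 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            if i > start:
                segments.append((start, i, True))
            start = i + 1
    if start < len(peptide):
        segments.append((start, len(peptide), False))
    return segments


def extract_ppps(
    assembly: Assembly,
    min_len: int = 60,
    require_stop: bool = False,
) -> list[PPP]:
    """Enumerate PPPs of at least ``min_len`` aa in all six frames.

    With ``require_stop`` (the strict stop-to-stop reading), stretches that
    run into a scaffold edge without a closing stop codon are dropped;
    by default they are kept and flagged ``terminal``.  Stretches crossing
    assembly gaps carry ``X`` residues and are split only at stop codons.
    """
    ppps: list[PPP] = []
    for scaffold in assembly:
        L = len(scaffold.sequence)
        for strand in "+-":
            seq = scaffold.sequence if strand == "+" else revcomp(scaffold.sequence)
            for off in range(3):
                peptide = translate(seq, off)
                if not peptide:
                    continue
                frame = (off + 1) if strand == "+" else -(off + 1)
                for aa_lo, aa_hi, closed in _frame_segments(peptide):
                    if aa_hi - aa_lo < min_len:
                        continue
                    if require_stop and not closed:
                        continue
                    # coordinates on the translated strand, then mapped back
                    lo = off + aa_lo * 3 + 1
                    hi = off + aa_hi * 3
                    if strand == "+":
                        iv = GenomicInterval(scaffold.id, lo, hi, "+")
                    else:
                        iv = GenomicInterval(scaffold.id, L - hi + 1, L - lo + 1, "-")
                    ppps.append(PPP(
                        id=f"{scaffold.id}:{frame:+d}:{iv.start}",
                        peptide=peptide[aa_lo:aa_hi],
                        interval=iv,
                        frame=frame,
                        terminal=not closed,
                    ))
    ppps.sort(key=lambda p: (p.interval.scaffold_id, p.frame, p.interval.start))
    return ppps


@dataclass
class Window:
    """A fixed-stride nucleotide slice of a scaffold (1-based start)."""

    scaffold_id: str
    start: int
    sequence: str

    @property
    def id(self) -> str:
        return f"{self.scaffold_id}:w{self.start}"

    def to_scaffold(self) -> Scaffold:
        return Scaffold(id=self.id, sequence=self.sequence,
                        description=f"window start={self.start}")


def make_windows(
    assembly: Assembly, window_len: int = 1000, overlap: int = 200
) -> list[Window]:
    """Slice scaffolds into overlapping windows (default 1,000 nt / 200 nt overlap).

    Window starts are 1, 1+stride, 1+2*stride, ... with stride =
    window_len - overlap; the final window may be short.  Every base is
    covered at least once.
    """
    if window_len <= overlap or overlap < 0:
        raise ValueError("window_len must exceed overlap and overlap must be >= 0")
    stride = window_len - overlap
    windows: list[Window] = []
    for scaffold in assembly:
        L = len(scaffold.sequence)
        start = 1
        while True:
            end = min(start + window_len - 1, L)
            windows.append(Window(scaffold.id, start, scaffold.sequence[start - 1 : end]))
            if end >= L:
                break
            start += stride
    return windows
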