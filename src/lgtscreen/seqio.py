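"""Sequence I/O and coordinate arithmetic.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive, the way assembly tables
  list them; a feature on the minus strand is written with start > end and
  normalised internally to (low, high, strand='-');
* nucleotide sequences are upper-case over {A, C, G, T, N} (``U`` is mapped
  to ``T`` on input);
* conceptual translation uses the standard genetic code, keeps internal
  stops as ``*`` and renders any codon containing ``N`` as ``X`` — assembly
  gaps inside a locus must not abort translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import Seq

_VALID_NT = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (e.g. sequence before header)."""


@dataclass
class Scaffold:
    """A named assembly sequence (scaffold, read, or database entry)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; minus strand encoded as start > end on input."""

    scaffold_id: str
    start: int
    end: int
    strand: str = field(default="+")

    @classmethod
    def from_table(cls, scaffold_id: str, start: int, end: int) -> "GenomicInterval":
        """Build from table-style coordinates where start > end means minus strand."""
        if start > end:
            return cls(scaffold_id, end, start, "-")
        return cls(scaffold_id, start, end, "+")

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.scaffold_id}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "GenomicInterval") -> int:
        if self.scaffold_id != other.scaffold_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def read_fasta(path: str | Path) -> list[Scaffold]:
    """Read a FASTA file into :class:`Scaffold` records.

    The id is the first whitespace-delimited token of the header; the
    remainder is kept as ``description``.  Sequences are upper-cased and
    ``U`` is mapped to ``T``.  An empty file yields an empty list; sequence
    data before the first header raises :class:`FastaFormatError` naming
    the offending line.
    """
    records: list[Scaffold] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(_make_record(header, chunks))
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                chunks.append(line)
    if header is not None:
        records.append(_make_record(header, chunks))
    return records


def _make_record(header: str, chunks: list[str]) -> Scaffold:
    parts = header.split(None, 1)
    rec_id = parts[0] if parts else ""
    desc = parts[1] if len(parts) > 1 else ""
    return Scaffold(id=rec_id, sequence="".join(chunks), description=desc)


def write_fasta(records: Iterable[Scaffold], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fasta(path: str | Path) -> Iterator[Scaffold]:
    yield from read_fasta(path)


class Assembly:
    """Scaffold collection with id lookup."""

    def __init__(self, scaffolds: Iterable[Scaffold]):
        self.scaffolds: dict[str, Scaffold] = {}
        for s in scaffolds:
            if s.id in self.scaffolds:
                raise ValueError(f"duplicate scaffold id {s.id!r}")
            self.scaffolds[s.id] = s

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Assembly":
        return cls(read_fasta(path))

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self) -> Iterator[Scaffold]:
        return iter(self.scaffolds.values())

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.scaffolds

    def __getitem__(self, scaffold_id: str) -> Scaffold:
        try:
            return self.scaffolds[scaffold_id]
        except KeyError:
            raise KeyError(f"unknown scaffold id {scaffold_id!r}") from None

    def total_length(self) -> int:
        return sum(len(s) for s in self)


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(assembly: Assembly, interval: GenomicInterval) -> str:
    """Extract a 1-based inclusive region; reverse-complemented on the minus strand."""
    scaffold = assembly[interval.scaffold_id]
    if interval.end > len(scaffold):
        raise IndexError(
            f"interval {interval.start}-{interval.end} exceeds scaffold "
            f"{interval.scaffold_id} length {len(scaffold)}"
        )
    sub = scaffold.sequence[interval.start - 1 : interval.end]
    return revcomp(sub) if interval.strand == "-" else sub


def translate(nt: str, frame: int = 0) -> str:
    """Conceptual translation: internal stops as ``*``, N-containing codons as ``X``.

    ``frame`` is 0, 1 or 2; the trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate(table=1))
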