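"""Genome records, FASTA I/O and assembly-level descriptive statistics.

A :class:`GenomeRecord` is an ordered set of named scaffolds. The statistics
computed here are the conventional assembly-report quantities (total length,
N50/L50, GC%), plus two descriptors relevant to near-complete fungal
assemblies: telomere-repeat presence at scaffold ends (TTAGGG / CCCTAA
arrays) and a size-based organelle (mitochondrial) scaffold heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "AssemblyStats",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "assembly_stats",
    "detect_organelle",
    "telomere_scan",
]


class FastaFormatError(ValueError):
    """Raised on malformed FASTA input (empty file, duplicate headers)."""


@dataclass
class GenomeRecord:
    """A named set of scaffold sequences with free-form metadata.

    Scaffold names must be unique and sequences non-empty; order is
    significant and preserved through I/O round-trips.
    """

    id: str
    scaffolds: list[tuple[str, str]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate scaffold names in record {self.id!r}")
        for name, seq in self.scaffolds:
            if not seq:
                raise ValueError(f"empty sequence for scaffold {name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)

    def scaffold(self, name: str) -> str:
        for n, s in self.scaffolds:
            if n == name:
                return s
        raise KeyError(name)


@dataclass
class AssemblyStats:
    """Assembly-level descriptive statistics.

    ``telomere_status`` maps scaffold name to a ``(five_prime, three_prime)``
    pair of booleans. ``total_length_nuclear`` excludes the detected organelle
    scaffold (equal to ``total_length`` when none is detected), since
    published genome-size figures do not always state whether the
    mitochondrial scaffold is included.
    """

    total_length: int
    n_scaffolds: int
    n50: int
    l50: int
    gc_percent: float
    organelle_scaffold: Optional[str] = None
    organelle_length: Optional[int] = None
    telomere_status: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    @property
    def total_length_nuclear(self) -> int:
        return self.total_length - (self.organelle_length or 0)

    def to_tsv(self) -> str:
        rows = [
            ("Genome size", f"{self.total_length:,} bp"),
            ("Genome size (nuclear only)", f"{self.total_length_nuclear:,} bp"),
            ("Number of scaffolds", str(self.n_scaffolds)),
            ("Contig N50", f"{self.n50:,} bp"),
            ("Contig L50", str(self.l50)),
            ("GC percent", f"{self.gc_percent:.2f}"),
        ]
        if self.organelle_scaffold is not None:
            rows.append(
                ("Non-nuclear (Mitochondrion MT) size", f"{self.organelle_length:,} bp")
            )
        if self.telomere_status:
            both = sum(1 for a, b in self.telomere_status.values() if a and b)
            rows.append(("Telomere-to-telomere scaffolds", str(both)))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def read_fasta(path: str | Path, record_id: Optional[str] = None) -> GenomeRecord:
    """Read a (multi-)FASTA file into a :class:`GenomeRecord`.

    One scaffold per entry, order preserved, surrounding whitespace stripped,
    case preserved. Empty files and duplicate headers raise
    :class:`FastaFormatError`.
    """
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise FastaFormatError(f"no FASTA records in {path}")
    names = [e.id for e in entries]
    if len(set(names)) != len(names):
        raise FastaFormatError(f"duplicate FASTA headers in {path}")
    scaffolds = [(e.id, str(e.seq).strip()) for e in entries]
    return GenomeRecord(id=record_id or path.stem, scaffolds=scaffolds)


def write_fasta(g: GenomeRecord, path: str | Path, width: int = 70) -> None:
    """Write a record as wrapped multi-FASTA."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in g.scaffolds
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _n50_l50(lengths: list[int]) -> tuple[int, int]:
    # N50 = length at which the descending cumulative sum first reaches
    # >= total/2; L50 = its 1-based rank.
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    acc = 0
    for rank, length in enumerate(desc, start=1):
        acc += length
        if acc * 2 >= total:
            return length, rank
    raise AssertionError("unreachable")


def assembly_stats(g: GenomeRecord) -> AssemblyStats:
    """Compute total length, N50/L50 and GC% for a genome record.

    GC is computed over unambiguous bases only: N and IUPAC ambiguity codes
    are excluded from both numerator and denominator. A record with no
    unambiguous base has undefined GC and raises ``ValueError``.
    """
    if not g.scaffolds:
        raise ValueError("record has no scaffolds")
    lengths = [len(s) for _, s in g.scaffolds]
    n50, l50 = _n50_l50(lengths)
    gc = at = 0
    for _, seq in g.scaffolds:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    if gc + at == 0:
        raise ValueError("GC undefined: no unambiguous (ACGT) bases in record")
    return AssemblyStats(
        total_length=sum(lengths),
        n_scaffolds=len(lengths),
        n50=n50,
        l50=l50,
        gc_percent=100.0 * gc / (gc + at),
        telomere_status=telomere_scan(g),
    )


def detect_organelle(
    g: GenomeRecord, max_len: int = 100_000
) -> Optional[tuple[str, int]]:
    """Return ``(name, length)`` of the putative organelle scaffold.

    Size heuristic: the shortest scaffold, if its length is <= ``max_len``
    (fungal mitogenomes are typically well under 100 kb while nuclear
    chromosomes are Mb-scale). Returns ``None`` when nothing qualifies.
    """
    if not g.scaffolds:
        raise ValueError("record has no scaffolds")
    name, seq = min(g.scaffolds, key=lambda ns: len(ns[1]))
    if len(seq) <= max_len:
        return name, len(seq)
    return None


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _count_occurrences(haystack: str, needle: str) -> int:
    # overlapping occurrences
    count = start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def telomere_scan(
    g: GenomeRecord,
    motif: str = "TTAGGG",
    window: int = 500,
    min_copies: int = 3,
) -> dict[str, tuple[bool, bool]]:
    """Flag telomere-repeat arrays at scaffold ends.

    An end is flagged when the motif or its reverse complement occurs at
    least ``min_copies`` times (case-insensitive, overlapping counts) within
    the terminal ``window`` bp.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if window < len(motif):
        raise ValueError("window must be at least the motif length")
    fwd = motif.upper()
    rev = _revcomp(fwd)
    status: dict[str, tuple[bool, bool]] = {}
    for name, seq in g.scaffolds:
        up = seq.upper()
        head, tail = up[:window], up[-window:]
        five = (
            _count_occurrences(head, fwd) + _count_occurrences(head, rev)
        ) >= min_copies
        three = (
            _count_occurrences(tail, fwd) + _count_occurrences(tail, rev)
        ) >= min_copies
        status[name] = (five, three)
    return status
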