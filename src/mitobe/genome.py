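"""Circular genome container, coordinate conventions and FASTA I/O.

The human mitochondrial genome is a circular duplex; every position has a
well-defined neighbour on both sides, so all indexing here is modular.
Internally coordinates are 0-based half-open on the strand written in the
FASTA (the "top" strand); user-facing output is 1-based inclusive to match
mtDNA mutation nomenclature (m.11778G>A).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a circular genome.

    ``end`` may exceed the genome length to denote an interval that wraps
    past the origin; ``strand`` is "top" (as written in the FASTA) or
    "bottom" (its reverse complement).
    """

    start: int
    end: int
    strand: str = "top"

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    def __len__(self) -> int:
        return self.end - self.start

    def to_bed_lines(self, genome_length: int, name: str = ".", score: int = 0) -> list[str]:
        """BED6 lines; a wraparound interval is split into two lines."""
        strand_sym = "+" if self.strand == "top" else "-"
        start = self.start % genome_length
        end = start + len(self)
        if end <= genome_length:
            return [f"\t{start}\t{end}\t{name}\t{score}\t{strand_sym}"]
        return [
            f"\t{start}\t{genome_length}\t{name}\t{score}\t{strand_sym}",
            f"\t0\t{end - genome_length}\t{name}\t{score}\t{strand_sym}",
        ]


@dataclass(frozen=True)
class CircularGenome:
    """A named circular nucleotide sequence with modular indexing."""

    name: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains non-IUPAC characters: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, i: int) -> str:
        """Base at (possibly negative or over-length) position i, modularly."""
        return self.sequence[i % self.length]

    def fetch(self, interval: GenomicInterval) -> str:
        """Subsequence for an interval, with wraparound; bottom-strand
        intervals return the reverse complement of the top-strand slice."""
        if len(interval) > self.length and self.topology == "circular":
            raise ValueError("interval longer than genome")
        if self.topology == "linear" and interval.end > self.length:
            raise ValueError("interval exceeds linear sequence")
        start = interval.start % self.length
        doubled = self.sequence + self.sequence
        sub = doubled[start : start + len(interval)]
        if interval.strand == "bottom":
            sub = reverse_complement(sub)
        return sub

    def rotate(self, offset: int) -> "CircularGenome":
        """Rewrite the sequence to start at ``offset mod length``; the
        biological content is unchanged."""
        k = offset % self.length
        return replace(self, sequence=self.sequence[k:] + self.sequence[:k])

    def reverse_complement(self) -> "CircularGenome":
        return replace(self, sequence=reverse_complement(self.sequence))


def load_genome(path: str | Path, record_name: str | None = None,
                topology: str = "circular") -> CircularGenome:
    """Load a single-record FASTA as a CircularGenome.

    Multi-record files are rejected unless ``record_name`` selects one.
    Lowercase input is accepted and uppercased; U is folded to T.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_name is not None:
        matches = [r for r in records if r.id == record_name]
        if not matches:
            raise ValueError(f"record {record_name!r} not found in {path}")
        record = matches[0]
    elif len(records) > 1:
        raise ValueError(
            f"{path} holds {len(records)} records; pass record_name to pick one"
        )
    else:
        record = records[0]
    seq = str(record.seq).upper().replace("U", "T")
    if not seq:
        raise ValueError(f"record {record.id!r} has an empty sequence")
    return CircularGenome(name=record.id, sequence=seq, topology=topology)


def write_genome(genome: CircularGenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([record], str(path), "fasta")


def iter_circular_windows(genome: CircularGenome, width: int) -> Iterator[tuple[int, str]]:
    """Yield (start, top-strand window) for every start position, wrapping
    past the origin. Width must not exceed the genome length."""
    if width > genome.length:
        raise ValueError("window wider than genome")
    doubled = genome.sequence + genome.sequence
    for i in range(genome.length):
        yield i, doubled[i : i + width]
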