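"""Small shared sequence helpers: complements, random DNA, FASTA/FASTQ I/O.

All coordinates in this package are 0-based, half-open; strands are '+'/'-'.
Reverse-complementing is done explicitly at I/O boundaries, never implicitly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of a sequence; ambiguous bases count as non-GC."""
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n``."""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def check_dna(seq: str, name: str = "sequence", allow_n: bool = True) -> str:
    """Validate an uppercase DNA string, returning it unchanged."""
    alphabet = set("ACGTN" if allow_n else "ACGT")
    if not seq or not set(seq) <= alphabet:
        raise ValueError(f"{name} must be non-empty uppercase DNA "
                         f"({'ACGTN' if allow_n else 'ACGT'}), got {seq[:40]!r}")
    return seq


@dataclass
class FastqRead:
    """A single long read: id, sequence and a uniform quality string."""

    id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            # qualities are not used downstream; fixed Q12
            self.quality = chr(12 + 33) * len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> list[FastqRead]:
    with _open_text(path) as fh:
        return [
            FastqRead(rec.id, str(rec.seq).upper(),
                      "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


@dataclass
class Interval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def write_bed(path: str | Path, rows: Iterable[tuple]) -> None:
    """Write (chrom, start, end, name, ...) rows as BED."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
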