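"""Dual-index demultiplexing of pooled long reads.

Assignment follows the exact-match rule used for capture-enriched nanopore
libraries: a read belongs to a sample iff both of that sample's indexes occur
exactly once in the read (each searched as given and reverse-complemented,
with the occurrence required to sit within ``search_window`` nt of a read
end), and no other sample's index pair also matches. No mismatches are
tolerated and no trimming is performed. Reads with more than one occurrence
of an index anywhere in the read are excluded as ``multi_match`` (an index
embedded mid-read indicates a chimera or concatenated adapters); reads
lacking an index are excluded as ``missing_index``; reads matching several
samples are excluded as ``ambiguous_sample``.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seq import FastqRead, check_dna, revcomp

DEFAULT_SEARCH_WINDOW = 250


class DemuxError(ValueError):
    pass


@dataclass(frozen=True)
class SampleSheet:
    """Rows of (sample id, index1, index2); pairs unique, uniform lengths."""

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise DemuxError("sample sheet is empty")
        pairs = [(i1, i2) for _, i1, i2 in self.rows]
        if len(set(pairs)) != len(pairs):
            raise DemuxError("index pairs must be unique across samples")
        if len({s for s, _, _ in self.rows}) != len(self.rows):
            raise DemuxError("sample ids must be unique")
        for _, i1, i2 in self.rows:
            check_dna(i1, "index1", allow_n=False)
            check_dna(i2, "index2", allow_n=False)
        for col in (1, 2):
            if len({len(r[col]) for r in self.rows}) != 1:
                raise DemuxError(f"index{col} sequences must have uniform length")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        """Read a TSV with header columns sample, index1, index2."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample", "index1", "index2"}
        if not required <= set(df.columns):
            raise DemuxError(f"sample sheet must have columns {sorted(required)}")
        return cls(tuple((r.sample, r.index1.upper(), r.index2.upper())
                         for r in df.itertuples()))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(list(self.rows), columns=["sample", "index1", "index2"]) \
            .to_csv(path, sep="\t", index=False)


def _occurrences(read: str, index: str) -> list[int]:
    """Start positions of exact occurrences of ``index`` in either orientation."""
    hits = [m.start() for m in re.finditer(re.escape(index), read)]
    rc = revcomp(index)
    if rc != index:
        hits += [m.start() for m in re.finditer(re.escape(rc), read)]
    return sorted(hits)


def _window_hit(hits: list[int], read_len: int, idx_len: int, window: int) -> bool:
    return any(p < window or p + idx_len > read_len - window for p in hits)


@dataclass
class DemuxResult:
    assigned: dict[str, list[FastqRead]]
    excluded: list[tuple[FastqRead, str]]
    summary: pd.DataFrame = field(repr=False, default=None)


def demultiplex(reads: list[FastqRead], sheet: SampleSheet,
                search_window: int = DEFAULT_SEARCH_WINDOW) -> DemuxResult:
    """Partition ``reads`` into per-sample bins plus an excluded bin.

    Exclusion reason codes: ``multi_match`` (>1 occurrence of some matching
    sample's index), ``missing_index`` (no sample has both indexes present),
    ``ambiguous_sample`` (more than one sample's pair matches). The output is
    a partition: every read lands in exactly one bin, untrimmed.
    """
    assigned: dict[str, list[FastqRead]] = {s: [] for s, _, _ in sheet.rows}
    excluded: list[tuple[FastqRead, str]] = []
    reasons: Counter = Counter()
    for read in reads:
        seq = read.sequence
        matches: list[str] = []
        multi = False
        partial = False
        for sample, i1, i2 in sheet.rows:
            h1 = _occurrences(seq, i1)
            h2 = _occurrences(seq, i2)
            if not h1 and not h2:
                continue
            if len(h1) > 1 or len(h2) > 1:
                multi = True
                continue
            if not h1 or not h2:
                partial = True
                continue
            if _window_hit(h1, len(seq), len(i1), search_window) and \
                    _window_hit(h2, len(seq), len(i2), search_window):
                matches.append(sample)
            else:
                partial = True
        if len(matches) == 1:
            assigned[matches[0]].append(read)
        else:
            if len(matches) > 1:
                reason = "ambiguous_sample"
            elif multi:
                reason = "multi_match"
            else:
                reason = "missing_index"
            excluded.append((read, reason))
            reasons[reason] += 1
    counts = [{"bin": s, "count": len(rs)} for s, rs in assigned.items()]
    counts += [{"bin": f"excluded:{r}", "count": n} for r, n in sorted(reasons.items())]
    counts.append({"bin": "total", "count": len(reads)})
    return DemuxResult(assigned, excluded, pd.DataFrame(counts))


def write_demux_output(result: DemuxResult, outdir: str | Path) -> None:
    """Per-sample FASTQ files, an excluded FASTQ and a summary TSV."""
    from .seq import write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample, rs in result.assigned.items():
        write_fastq(outdir / f"{sample}.fastq", rs)
    write_fastq(outdir / "excluded.fastq",
                [FastqRead(f"{r.id} reason={reason}", r.sequence, r.quality)
                 for r, reason in result.excluded])
    result.summary.to_csv(outdir / "demux_summary.tsv", sep="\t", index=False)
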