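"""Minimizer seed-chain-extend long-read alignment and two-pass mapping.

The built-in aligner follows the standard long-read recipe: canonical k-mer
minimizers are indexed over each reference (window minimum of an invertible
64-bit mixing hash); read minimizers are matched to the index, anchors are
chained per (reference, strand) with a gap-penalized dynamic program, and
each selected chain is polished by a banded edit-distance alignment of the
corresponding read segment against a padded reference window (edlib), from
which per-operation runs, identity and an affine-gap score are derived.
Non-overlapping secondary chains above a score floor are emitted as
supplementary records, so chimeric/split reads yield one record per part.

``two_pass_map`` orchestrates the transgene-first mapping scheme used for
capture-enriched knock-in libraries: reads are first aligned to the transgene
reference, the mapped subset is extracted, and those same full reads are then
realigned to the genome to locate them at the target site or at sites of
random integration. ``capture_efficiency`` is the fraction of input reads
mapping to the transgene.

An external aligner can stand behind the same record model: records can be
imported from PAF and exported as PAF or SAM (with supplementary flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .seq import FastqRead, revcomp


class AlignError(ValueError):
    pass


@dataclass
class AlignParams:
    k: int = 15
    w: int = 10
    max_gap: int = 5000          # chaining gap limit, nt
    diag_band: int = 500         # anchors within this diagonal band co-chain
    band_extra: int = 200        # reference window padding around a chain
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2
    score_floor: int = 100
    max_chains: int = 6
    min_anchors: int = 3
    max_occ: int = 32            # skip minimizers more repetitive than this
    max_extension: int = 150     # max unseeded query extension past a chain end
    max_query_overlap: float = 0.5  # between primary and supplementary chains


@dataclass
class AlignmentRecord:
    """One (possibly supplementary) alignment of a read segment.

    ``q_start``/``q_end`` are on the read as stored; ``ops`` is a run-length
    list over {'=', 'X', 'I', 'D'} ('I' consumes query, 'D' target).
    """

    read_id: str
    q_start: int
    q_end: int
    target: str
    t_start: int
    t_end: int
    strand: str
    ops: list[tuple[str, int]]
    identity: float
    score: float
    is_supplementary: bool = False

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start

    def aligned_target_runs(self) -> Iterable[tuple[int, int]]:
        """Target intervals covered by match/mismatch columns (D excluded)."""
        t = self.t_start
        for op, n in self.ops:
            if op in "=XM":
                yield t, t + n
                t += n
            elif op == "D":
                t += n


# ---------------------------------------------------------------------------
# Minimizer index
# ---------------------------------------------------------------------------

_ENC = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i


def _mix(h: np.ndarray) -> np.ndarray:
    """Invertible 64-bit mixing (splitmix64 finalizer) to de-bias k-mer ranks."""
    h = h.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        h ^= h >> np.uint64(30)
        h *= np.uint64(0xBF58476D1CE4E5B9)
        h ^= h >> np.uint64(27)
        h *= np.uint64(0x94D049BB133111EB)
        h ^= h >> np.uint64(31)
    return h


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for all k-mers; N-containing k-mers are invalid."""
    b = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    four = np.uint64(4)
    for j in range(k):
        col = b[j:j + n]
        codes = codes * four + np.maximum(col, 0).astype(np.uint64)
        valid &= col >= 0
    return codes, valid


def _canonical(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical minimizer-ready hashes: (hash, fwd_is_canonical, valid)."""
    codes, valid = _kmer_codes(seq, k)
    rc_codes, rc_valid = _kmer_codes(revcomp(seq), k)
    rc_codes = rc_codes[::-1] if rc_codes.size else rc_codes
    rc_valid = rc_valid[::-1] if rc_valid.size else rc_valid
    fwd = codes <= rc_codes
    canon = np.where(fwd, codes, rc_codes)
    return _mix(canon), fwd, valid & rc_valid


def _minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, bool]]:
    """(position, hash, fwd_canonical) of window minima, deduplicated."""
    hashes, fwd, valid = _canonical(seq, k)
    n = hashes.size
    if n == 0:
        return []
    h = hashes.copy()
    h[~valid] = np.iinfo(np.uint64).max
    if n <= w:
        idx = np.array([int(np.argmin(h))])
    else:
        windows = np.lib.stride_tricks.sliding_window_view(h, w)
        idx = np.unique(windows.argmin(axis=1) + np.arange(n - w + 1))
    out = []
    for i in idx:
        if valid[i]:
            out.append((int(i), int(h[i]), bool(fwd[i])))
    return out


class MinimizerIndex:
    """Minimizer index over a set of named reference sequences."""

    def __init__(self, references: dict[str, str], k: int = 15, w: int = 10):
        if not references:
            raise AlignError("cannot index an empty reference set")
        if not 1 <= k <= 28:
            raise AlignError("k must be in [1, 28]")
        if w < 1:
            raise AlignError("w must be >= 1")
        self.k, self.w = k, w
        self.references = {name: seq.upper() for name, seq in references.items()}
        self.names = list(self.references)
        self._table: dict[int, list[tuple[int, int, bool]]] = {}
        for sid, (name, seq) in enumerate(self.references.items()):
            for pos, h, fwd in _minimizers(seq, k, w):
                self._table.setdefault(h, []).append((sid, pos, fwd))

    def occurrences(self, h: int) -> list[tuple[int, int, bool]]:
        return self._table.get(h, [])

    def minimizer_positions(self, name: str) -> list[int]:
        sid = self.names.index(name)
        return sorted(pos for hits in self._table.values()
                      for s, pos, _ in hits if s == sid)


def index_reference(references: dict[str, str], k: int = 15, w: int = 10
                    ) -> MinimizerIndex:
    return MinimizerIndex(references, k, w)


# ---------------------------------------------------------------------------
# Chaining and extension
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    sid: int
    strand: str
    q_start: int  # on the read as stored
    q_end: int
    t_start: int
    t_end: int
    n_anchors: int
    score: float


@dataclass
class _Cluster:
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_anchors: int
    score: float


def _cluster_anchors(anchors: np.ndarray, k: int, p: "AlignParams") -> list[_Cluster]:
    """Chain anchors by diagonal banding, then merge colinear clusters.

    ``anchors`` rows are (q, t) in a shared orientation frame. Anchors whose
    diagonals (t - q) fall within ``diag_band`` of each other form one
    cluster (small indels keep the diagonal); clusters that are ordered
    consistently in both query and target with gaps below ``max_gap`` are
    merged, so a single large insertion or deletion still yields one chain.
    Tandem repeats (target restarting behind itself) never merge, which is
    what exposes concatemer junctions as split alignments.
    """
    diag = anchors[:, 1] - anchors[:, 0]
    order = np.argsort(diag, kind="stable")
    diag_sorted = diag[order]
    breaks = np.flatnonzero(np.diff(diag_sorted) > p.diag_band) + 1
    clusters: list[_Cluster] = []
    for rows in np.split(order, breaks):
        q = np.sort(anchors[rows, 0])
        t = anchors[rows, 1]
        coverage = float(np.minimum(np.diff(q), k).sum() + k) if len(q) > 1 else float(k)
        clusters.append(_Cluster(int(q[0]), int(q[-1]) + k,
                                 int(t.min()), int(t.max()) + k,
                                 len(rows), coverage))
    clusters.sort(key=lambda c: c.q_start)
    merged: list[_Cluster] = []
    overlap_tol = 2 * k
    for c in clusters:
        if merged:
            m = merged[-1]
            q_gap = c.q_start - m.q_end
            t_gap = c.t_start - m.t_end
            if (-overlap_tol <= q_gap <= p.max_gap
                    and -overlap_tol <= t_gap <= p.max_gap):
                merged[-1] = _Cluster(m.q_start, max(m.q_end, c.q_end),
                                      min(m.t_start, c.t_start),
                                      max(m.t_end, c.t_end),
                                      m.n_anchors + c.n_anchors,
                                      m.score + c.score)
                continue
        merged.append(c)
    return merged


_OP_MAP = {"=": "=", "X": "X", "I": "I", "D": "D", "M": "="}


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((_OP_MAP[ch], int(num)))
            num = ""
    return ops


def _run_score(op: str, n: int, p: AlignParams) -> float:
    if op == "=":
        return p.match * n
    if op == "X":
        return p.mismatch * n
    return p.gap_open + p.gap_extend * n


def _trim_ops(ops: list[tuple[str, int]], p: AlignParams, window_cols: int = 400
              ) -> tuple[list[tuple[str, int]], tuple[int, int], tuple[int, int]]:
    """Trim low-scoring terminal runs (local-alignment-style end behaviour).

    Edit-distance extension aligns the whole query segment, so unmatchable
    read termini (barcode remnants, terminal error clusters) show up as
    negative-score runs at the alignment ends. Within the first/last
    ``window_cols`` columns, the cut minimizing the cumulative prefix
    (suffix) score is removed; interior structural gaps are never touched.
    Returns (ops, (q_trim_front, t_trim_front), (q_trim_back, t_trim_back)).
    """

    def front_cut(runs: list[tuple[str, int]]) -> tuple[int, int, int]:
        cum, best, best_cut = 0.0, 0.0, 0
        q = t = bq = bt = 0
        cols = 0
        for idx, (op, n) in enumerate(runs):
            if cols >= window_cols:
                break
            cum += _run_score(op, n, p)
            if op in "=X":
                q += n
                t += n
            elif op == "I":
                q += n
            else:
                t += n
            cols += n
            if cum < best:
                best, best_cut, bq, bt = cum, idx + 1, q, t
        return best_cut, bq, bt

    f_cut, fq, ft = front_cut(ops)
    trimmed = ops[f_cut:]
    b_cut, bq, bt = front_cut(trimmed[::-1])
    if b_cut:
        trimmed = trimmed[:len(trimmed) - b_cut]
    return trimmed, (fq, ft), (bq, bt)


def _score_ops(ops: list[tuple[str, int]], p: AlignParams) -> tuple[float, float]:
    """(affine score, identity) from run-length operations."""
    score, matches, cols = 0.0, 0, 0
    for op, n in ops:
        if op == "=":
            score += p.match * n
            matches += n
            cols += n
        elif op == "X":
            score += p.mismatch * n
            cols += n
        else:
            score += p.gap_open + p.gap_extend * n
            cols += n
    return score, (matches / cols if cols else 0.0)


def map_read(read: FastqRead | tuple[str, str], index: MinimizerIndex,
             params: Optional[AlignParams] = None) -> list[AlignmentRecord]:
    """Map one read; unmappable reads return an empty list.

    The best chain yields the primary record; additional chains whose read
    intervals do not substantially overlap already-accepted ones are emitted
    as supplementary records (split-read support). Ties between equal-score
    chains resolve to the leftmost target coordinate, then the '+' strand.
    """
    p = params or AlignParams()
    if isinstance(read, tuple):
        read = FastqRead(read[0], read[1])
    seq = read.sequence.upper()
    L = len(seq)
    if L < p.k:
        return []
    mins = _minimizers(seq, p.k, p.w)
    buckets: dict[tuple[int, str], list[tuple[int, int]]] = {}
    for qpos, h, qfwd in mins:
        occ = index.occurrences(h)
        if len(occ) > p.max_occ:
            continue
        for sid, tpos, tfwd in occ:
            strand = "+" if qfwd == tfwd else "-"
            # shared orientation frame: q' increases along the target
            q = qpos if strand == "+" else L - p.k - qpos
            buckets.setdefault((sid, strand), []).append((q, tpos))
    chains: list[_Chain] = []
    for (sid, strand), pairs in buckets.items():
        arr = np.array(pairs, dtype=np.int64)
        for cl in _cluster_anchors(arr, p.k, p):
            if cl.n_anchors < p.min_anchors:
                continue
            qs, qe = cl.q_start, cl.q_end
            if strand == "-":
                qs, qe = L - qe, L - qs
            chains.append(_Chain(sid, strand, int(qs), int(qe),
                                 cl.t_start, cl.t_end, cl.n_anchors, cl.score))
    if not chains:
        return []
    chains.sort(key=lambda c: (-c.score, c.t_start, c.strand))
    accepted: list[_Chain] = []
    for c in chains:
        if len(accepted) >= p.max_chains:
            break
        span = c.q_end - c.q_start
        if any(min(c.q_end, o.q_end) - max(c.q_start, o.q_start)
               > p.max_query_overlap * span for o in accepted):
            continue
        accepted.append(c)
    # extend each chain's query interval outward by a bounded margin (to pick
    # up unseeded sequence near the chain ends), stopping halfway into the
    # gap before a neighbouring accepted chain
    bounds = {}
    ordered = sorted(accepted, key=lambda c: c.q_start)
    for i, c in enumerate(ordered):
        lo = 0 if i == 0 else (ordered[i - 1].q_end + c.q_start) // 2
        hi = L if i == len(ordered) - 1 else (c.q_end + ordered[i + 1].q_start) // 2
        lo = max(lo, c.q_start - p.max_extension)
        hi = min(hi, c.q_end + p.max_extension)
        bounds[id(c)] = (lo, hi)
    records: list[AlignmentRecord] = []
    for c in accepted:
        lo, hi = bounds[id(c)]
        ext_left, ext_right = c.q_start - lo, hi - c.q_end
        if c.strand == "-":
            ext_left, ext_right = ext_right, ext_left
        ref = index.references[index.names[c.sid]]
        tw_s = max(0, c.t_start - ext_left - p.band_extra)
        tw_e = min(len(ref), c.t_end + ext_right + p.band_extra)
        qseg = seq[lo:hi]
        if c.strand == "-":
            qseg = revcomp(qseg)
        res = edlib.align(qseg, ref[tw_s:tw_e], mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("locations"):
            continue
        loc = res["locations"][0]
        ops = _parse_cigar(res["cigar"])
        ops, (fq, ft), (bq, bt) = _trim_ops(ops, p)
        if not ops:
            continue
        score, identity = _score_ops(ops, p)
        if score < p.score_floor:
            continue
        t_start = tw_s + loc[0] + ft
        t_end = tw_s + loc[1] + 1 - bt
        if c.strand == "+":
            q_start, q_end = lo + fq, hi - bq
        else:
            q_start, q_end = lo + bq, hi - fq
        records.append(AlignmentRecord(
            read_id=read.id, q_start=q_start, q_end=q_end,
            target=index.names[c.sid],
            t_start=t_start, t_end=t_end,
            strand=c.strand, ops=ops, identity=identity, score=score))
    if not records:
        return []
    records.sort(key=lambda r: (-r.score, r.t_start, 0 if r.strand == "+" else 1))
    for r in records[1:]:
        r.is_supplementary = True
    return records


def map_reads(reads: Sequence[FastqRead], index: MinimizerIndex,
              params: Optional[AlignParams] = None) -> dict[str, list[AlignmentRecord]]:
    """Map many reads; returns {read_id: records} for mapped reads only."""
    out = {}
    for read in reads:
        recs = map_read(read, index, params)
        if recs:
            out[read.id] = recs
    return out


# ---------------------------------------------------------------------------
# Two-pass (transgene first, genome second) mapping
# ---------------------------------------------------------------------------

@dataclass
class TwoPassResult:
    total_reads: int
    transgene_mapped: list[str]
    pass1: dict[str, list[AlignmentRecord]]
    pass2: dict[str, list[AlignmentRecord]]

    def check_invariants(self) -> None:
        assert set(self.pass2) <= set(self.transgene_mapped)
        assert len(self.transgene_mapped) <= self.total_reads


def two_pass_map(reads: Sequence[FastqRead],
                 transgene_ref: dict[str, str] | MinimizerIndex,
                 genome_ref: dict[str, str] | MinimizerIndex,
                 params: Optional[AlignParams] = None) -> TwoPassResult:
    """Align to the transgene, extract mapped reads, realign those to the genome."""
    p = params or AlignParams()
    tg_index = transgene_ref if isinstance(transgene_ref, MinimizerIndex) \
        else MinimizerIndex(transgene_ref, p.k, p.w)
    g_index = genome_ref if isinstance(genome_ref, MinimizerIndex) \
        else MinimizerIndex(genome_ref, p.k, p.w)
    pass1 = map_reads(reads, tg_index, p)
    mapped_ids = list(pass1)
    mapped_reads = [r for r in reads if r.id in pass1]
    pass2 = map_reads(mapped_reads, g_index, p)
    result = TwoPassResult(len(reads), mapped_ids, pass1, pass2)
    result.check_invariants()
    return result


def capture_efficiency(result: TwoPassResult) -> float:
    """Fraction of total input reads mapping to the transgene."""
    if result.total_reads == 0:
        raise AlignError("capture efficiency undefined for zero input reads")
    return len(result.transgene_mapped) / result.total_reads


# ---------------------------------------------------------------------------
# Interchange formats
# ---------------------------------------------------------------------------

def to_paf(records: Iterable[AlignmentRecord], read_lengths: dict[str, int]) -> str:
    """Render records as PAF lines (query/target coordinates, cg tag)."""
    lines = []
    for r in records:
        matches = sum(n for op, n in r.ops if op == "=")
        block = sum(n for _, n in r.ops)
        cg = "".join(f"{n}{op}" for op, n in r.ops)
        lines.append("\t".join(map(str, [
            r.read_id, read_lengths[r.read_id], r.q_start, r.q_end, r.strand,
            r.target, "*", r.t_start, r.t_end, matches, block, 60,
            f"tp:A:{'S' if r.is_supplementary else 'P'}", f"cg:Z:{cg}"])))
    return "\n".join(lines) + ("\n" if lines else "")


def from_paf(text: str) -> list[AlignmentRecord]:
    """Parse (built-in or external-aligner) PAF into alignment records."""
    records = []
    for line in text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        tags = {t.split(":", 1)[0]: t.split(":", 2)[2] for t in f[12:] if ":" in t}
        ops = _parse_cigar(tags["cg"]) if "cg" in tags else [("=", int(f[9]))]
        matches, block = int(f[9]), int(f[10])
        records.append(AlignmentRecord(
            read_id=f[0], q_start=int(f[2]), q_end=int(f[3]), strand=f[4],
            target=f[5], t_start=int(f[7]), t_end=int(f[8]), ops=ops,
            identity=matches / block if block else 0.0, score=float(matches),
            is_supplementary=tags.get("tp") == "S"))
    return records


def write_sam(path: str | Path, records: Sequence[AlignmentRecord],
              references: dict[str, str], reads: dict[str, str]) -> None:
    """Write records as SAM with supplementary flags and soft clips."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in records:
            seq = reads[r.read_id]
            flag = 0
            if r.strand == "-":
                flag |= 16
                seq = revcomp(seq)
                left, right = len(seq) - r.q_end, r.q_start
            else:
                left, right = r.q_start, len(seq) - r.q_end
            if r.is_supplementary:
                flag |= 2048
            cigar = (f"{left}S" if left else "") + \
                "".join(f"{n}{op}" for op, n in r.ops) + \
                (f"{right}S" if right else "")
            fh.write("\t".join(map(str, [
                r.read_id, flag, r.target, r.t_start + 1, 60, cigar,
                "*", 0, 0, seq, "*"])) + "\n")
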