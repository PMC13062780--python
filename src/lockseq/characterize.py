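"""Outcome calling from two-pass alignments of capture-enriched long reads.

Given per-read alignments against the transgene, the genome and the two
allele models (expected knock-in and wild type), this module derives:

* normalized per-base depth tracks (raw depth / total mapped reads);
* ranked ~20 kb candidate windows of genome-wide transgene-read depth;
* clustered insert<->genome junction breakpoints from split reads;
* per-read allele classification and a zygosity/mosaicism genotype with
  Wilson confidence intervals on allele fractions;
* donor-concatemer events (read-level donor-donor junctions with topology,
  plus copy-number gain from depth);
* random-integration events away from the target locus, each requiring
  multiple independent reads sharing a tight junction (unique-junction
  library chimeras fall below the support threshold and are reported as
  putative artifacts), annotated with vector-ITR presence;
* the cross-library fusion-read rate; and
* anchored majority-vote consensus sequences for candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from statsmodels.stats.proportion import proportion_confint

from .align import AlignmentRecord
from .constructs import AlleleMap
from .seq import Interval, revcomp


class CharacterizeError(ValueError):
    pass


@dataclass
class CallParams:
    """Thresholds of the caller; all reported events reference these."""

    tolerance: int = 50          # junction clustering tolerance, nt
    min_support: int = 3         # independent reads per RI event
    max_spread: int = 100        # max junction positional spread, nt
    locus_pad: int = 5000        # distance from target locus to call RI, nt
    min_sv: int = 30             # min structural deviation size, nt
    junction_slop: int = 20      # tolerated deviation at KI junctions, nt
    cnv_gain: float = 1.5        # depth-gain factor for copy-number calls
    min_allele_frac: float = 0.1
    min_consensus_reads: int = 5
    min_seg: int = 200           # min split-segment length, nt
    min_indel: int = 4           # min contiguous cut-site indel run, nt
    sv_margin: int = 150         # SV search margin around the insert, nt
    itr_min_len: int = 60
    itr_min_identity: float = 0.9


# ---------------------------------------------------------------------------
# Depth
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    reference: str
    raw: np.ndarray
    total_mapped_reads: int

    @property
    def normalized(self) -> np.ndarray:
        if self.total_mapped_reads == 0:
            return np.zeros_like(self.raw, dtype=float)
        return self.raw / self.total_mapped_reads

    def to_bedgraph(self, path, normalized: bool = True) -> None:
        values = self.normalized if normalized else self.raw.astype(float)
        with open(path, "w") as fh:
            prev_val, start = None, 0
            for i, v in enumerate(values):
                if prev_val is None:
                    prev_val, start = v, i
                elif v != prev_val:
                    if prev_val != 0:
                        fh.write(f"{self.reference}\t{start}\t{i}\t{prev_val:.6g}\n")
                    prev_val, start = v, i
            if prev_val is not None and prev_val != 0:
                fh.write(f"{self.reference}\t{start}\t{len(values)}\t{prev_val:.6g}\n")


def depth_profile(alignments: Iterable[AlignmentRecord], reference: str,
                  reference_length: int, total_mapped_reads: int) -> DepthTrack:
    """Per-base raw depth over one reference; deletions in the read do not cover.

    The normalized track divides by the sample's total mapped read count, so
    the summed normalized depth equals (aligned bases) / (mapped reads) exactly.
    """
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    for rec in alignments:
        if rec.target != reference:
            continue
        for s, e in rec.aligned_target_runs():
            diff[s] += 1
            diff[min(e, reference_length)] -= 1
    raw = np.cumsum(diff[:-1])
    return DepthTrack(reference, raw, total_mapped_reads)


def top_depth_windows(depth_tracks: dict[str, DepthTrack], window: int = 20000,
                      k: int = 10, exclude: Optional[Interval] = None
                      ) -> list[tuple[str, int, int, float]]:
    """Top-k non-overlapping genome windows by summed depth, target excluded."""
    if window <= 0 or k < 1:
        raise CharacterizeError("window must be > 0 and k >= 1")
    candidates = []
    for chrom, track in depth_tracks.items():
        n = len(track.raw)
        for start in range(0, n, window):
            end = min(start + window, n)
            if exclude is not None and exclude.chrom == chrom \
                    and exclude.overlap(start, end) > 0:
                continue
            total = float(track.raw[start:end].sum())
            if total > 0:
                candidates.append((chrom, start, end, total))
    candidates.sort(key=lambda c: (-c[3], c[0], c[1]))
    return candidates[:k]


# ---------------------------------------------------------------------------
# Junction clustering
# ---------------------------------------------------------------------------

@dataclass
class JunctionObservation:
    read_id: str
    genome_chrom: str
    genome_pos: int
    genome_orient: str
    transgene_pos: int
    transgene_orient: str
    dedup_key: tuple


@dataclass
class BreakpointCluster:
    genome_chrom: str
    genome_pos: int
    genome_orient: str
    transgene_pos: int
    transgene_orient: str
    read_ids: list[str]
    spread: int

    @property
    def support(self) -> int:
        return len(self.read_ids)


def _junction_side(rec: AlignmentRecord, read_right: bool) -> tuple[int, str]:
    """Target coordinate and continuation orientation at one read-side end."""
    if (rec.strand == "+") == read_right:
        return rec.t_end, "+"
    return rec.t_start, "-"


def junction_observations(pass1: dict[str, list[AlignmentRecord]],
                          pass2: dict[str, list[AlignmentRecord]],
                          tolerance: int = 50,
                          min_seg: int = 200) -> list[JunctionObservation]:
    """Transgene<->genome junctions read off split reads.

    A junction is observed where a transgene segment and a genome segment of
    the same read are adjacent on the read (gap/overlap <= ``tolerance``).
    """
    obs: list[JunctionObservation] = []
    for read_id in pass1:
        tg = [r for r in pass1.get(read_id, []) if r.query_span >= min_seg]
        gn = [r for r in pass2.get(read_id, []) if r.query_span >= min_seg]
        for t in tg:
            for g in gn:
                # adjacency on the read, either order; overlapping segments
                # (e.g. a homology arm mapping to both references) are not
                # junctions
                if abs(g.q_end - t.q_start) <= tolerance:
                    first, second = g, t
                elif abs(t.q_end - g.q_start) <= tolerance:
                    first, second = t, g
                else:
                    continue
                g_pos, g_orient = _junction_side(g, read_right=(g is first))
                t_pos, t_orient = _junction_side(t, read_right=(t is first))
                obs.append(JunctionObservation(
                    read_id, g.target, g_pos, g_orient, t_pos, t_orient,
                    dedup_key=(g.target, g.t_start, g.t_end, t.t_start, t.t_end)))
    return obs


def call_junctions(pass1: dict[str, list[AlignmentRecord]],
                   pass2: dict[str, list[AlignmentRecord]],
                   tolerance: int = 50,
                   min_seg: int = 200) -> list[BreakpointCluster]:
    """Cluster junction observations within ``tolerance`` on both sides.

    Support counts independent reads only: exact-duplicate fragments (same
    aligned source intervals on both sides) are collapsed first.
    """
    obs = junction_observations(pass1, pass2, tolerance, min_seg)
    # PCR-duplicate guard: one observation per identical fragment signature
    seen: dict[tuple, JunctionObservation] = {}
    for o in obs:
        key = (o.dedup_key, o.read_id)
        seen.setdefault(key, o)
    unique = {}
    for (frag_key, read_id), o in seen.items():
        unique.setdefault(frag_key, o)
    deduped = list(unique.values())
    clusters: list[BreakpointCluster] = []
    by_group: dict[tuple, list[JunctionObservation]] = {}
    for o in deduped:
        by_group.setdefault((o.genome_chrom, o.genome_orient, o.transgene_orient),
                            []).append(o)
    for group in by_group.values():
        group.sort(key=lambda o: (o.genome_pos, o.transgene_pos))
        current: list[JunctionObservation] = []
        for o in group:
            if current and (o.genome_pos - current[-1].genome_pos > tolerance
                            or abs(o.transgene_pos - current[0].transgene_pos)
                            > tolerance):
                clusters.append(_finish_cluster(current))
                current = []
            current.append(o)
        if current:
            clusters.append(_finish_cluster(current))
    clusters.sort(key=lambda c: -c.support)
    return clusters


def _finish_cluster(members: list[JunctionObservation]) -> BreakpointCluster:
    g_positions = [o.genome_pos for o in members]
    t_positions = [o.transgene_pos for o in members]
    spread = max(max(g_positions) - min(g_positions),
                 max(t_positions) - min(t_positions))
    o = members[0]
    return BreakpointCluster(o.genome_chrom, int(np.median(g_positions)),
                             o.genome_orient, int(np.median(t_positions)),
                             o.transgene_orient,
                             sorted({m.read_id for m in members}), spread)


# ---------------------------------------------------------------------------
# Allele classification and genotype
# ---------------------------------------------------------------------------

@dataclass
class AlleleModels:
    """The two locus references a read is scored against."""

    ki: AlleleMap
    wt: AlleleMap
    insert: tuple[int, int]   # novel (payload) interval on the KI allele
    cut: int                  # cut site on the wild-type allele
    donor_span: Optional[tuple[int, int]] = None  # arms+payload on the KI allele


@dataclass
class ReadClass:
    read_id: str
    model: str        # 'ki' | 'wt'
    label: str        # wild_type / precise_ki / cut_site_indel / partial_ki / imprecise_ki
    size: int = 0     # indel / missing / extra span, nt
    interval: Optional[tuple[int, int]] = None  # on the model reference


@dataclass
class Genotype:
    n_spanning: int
    fractions: dict[str, float]
    intervals: dict[str, tuple[float, float]]  # Wilson 95% CI per class
    call: str
    mosaic: bool
    no_call: bool = False


def _indel_runs(rec: AlignmentRecord) -> list[tuple[str, int, int, int]]:
    """(op, target_pos, query_consumed_before, run_length) for I/D runs."""
    runs, t = [], rec.t_start
    for op, n in rec.ops:
        if op in "=X":
            t += n
        elif op == "D":
            runs.append(("D", t, 0, n))
            t += n
        elif op == "I":
            runs.append(("I", t, 0, n))
    return runs


def _gap_clusters(rec: AlignmentRecord, merge_gap: int = 50
                  ) -> list[tuple[int, int, int]]:
    """Merged indel clusters as (target_start, target_end, net_inserted_nt).

    Edit-distance alignments fragment large insertions/deletions through
    coincidental short matches, so single runs understate structural gaps.
    Indel runs separated by at most ``merge_gap`` match/mismatch columns are
    pooled; the cluster's net size is insertions minus deletions (negative =
    net deletion in the read relative to the reference).
    """
    clusters: list[tuple[int, int, int]] = []
    t = rec.t_start
    cur_start, cur_end, cur_net, sep = None, 0, 0, 0
    for op, n in rec.ops:
        if op in "=X":
            sep += n
            t += n
            if cur_start is not None and sep > merge_gap:
                clusters.append((cur_start, cur_end, cur_net))
                cur_start, cur_net = None, 0
            continue
        if cur_start is None:
            cur_start, cur_net = t, 0
        cur_net += n if op == "I" else -n
        sep = 0
        if op == "D":
            t += n
        cur_end = t
    if cur_start is not None:
        clusters.append((cur_start, cur_end, cur_net))
    return clusters


def _aligned_query_range(rec: AlignmentRecord, t_lo: int, t_hi: int
                         ) -> Optional[tuple[int, int]]:
    """Query span (in aligned orientation, relative to q_start) covering
    target interval [t_lo, t_hi)."""
    t, q = rec.t_start, 0
    aq_lo = aq_hi = None
    for op, n in rec.ops:
        dt = n if op in "=XD" else 0
        dq = n if op in "=XI" else 0
        if aq_lo is None and t + dt > t_lo:
            aq_lo = q + (max(0, t_lo - t) if op in "=X" else 0)
        if aq_hi is None and t + dt >= t_hi:
            aq_hi = q + (max(0, t_hi - t) if op in "=X" else dq)
            break
        t += dt
        q += dq
    if aq_lo is None:
        return None
    if aq_hi is None:
        aq_hi = q
    return aq_lo, aq_hi


_AFFINE = Align.PairwiseAligner(mode="global", match_score=2,
                                mismatch_score=-4, open_gap_score=-9,
                                extend_gap_score=-1)
# free terminal gaps on the reference side (semi-global in the read segment)
for _attr in ("open_left_insertion_score", "extend_left_insertion_score",
              "open_right_insertion_score", "extend_right_insertion_score"):
    setattr(_AFFINE, _attr, 0)


def _cut_site_indel_net(wt: AlignmentRecord, read_seq: Optional[str],
                        wt_ref: str, cut: int, params: CallParams,
                        window: int = 150, pad: int = 60) -> int:
    """Net indel size at the cut after affine-gap local realignment.

    Unit-cost alignments smear small indels across co-optimal paths, so the
    read segment covering the cut window is realigned with affine gap costs,
    which consolidates a genuine cut-site indel into one gap while scattered
    sequencing-error indels stay short. Returns the summed net size of gaps
    >= ``min_indel`` nt near the cut (0 if none, or without the read sequence
    falls back to merged edit-path clusters).
    """
    if read_seq is None:
        nets = [net for gs, ge, net in _gap_clusters(wt)
                if min(ge, cut + window) - max(gs, cut - window) >= 0
                and abs(net) >= params.min_indel]
        return sum(nets) if nets else 0
    t_lo, t_hi = cut - window - pad, cut + window + pad
    span = _aligned_query_range(wt, t_lo, t_hi)
    if span is None:
        return 0
    oriented = read_seq[wt.q_start:wt.q_end]
    if wt.strand == "-":
        oriented = revcomp(oriented)
    segment = oriented[span[0]:span[1]]
    ref = wt_ref[max(0, t_lo):t_hi]
    if not segment or not ref:
        return 0
    aln = max(_AFFINE.align(ref, segment), key=lambda a: a.score)
    blocks_t, blocks_q = aln.aligned
    net_total = 0
    for (t1, t2), (q1, q2) in zip(zip(blocks_t, blocks_t[1:]),
                                  zip(blocks_q, blocks_q[1:])):
        gap_t = int(t2[0] - t1[1])
        gap_q = int(q2[0] - q1[1])
        net = gap_q - gap_t
        pos = max(0, t_lo) + int(t1[1])
        if abs(net) >= params.min_indel and abs(pos - cut) <= window + pad:
            net_total += net
    return net_total


def _classify_read(read_id: str, ki: Optional[AlignmentRecord],
                   wt: Optional[AlignmentRecord], models: AlleleModels,
                   params: CallParams,
                   read_seq: Optional[str] = None) -> Optional[ReadClass]:
    ins_s, ins_e = models.insert
    slop = params.junction_slop
    # symmetric spanning rule: a wild-type read must cover a window at the
    # cut as wide as the insert junction-to-junction window, otherwise short
    # fragments (which can span the cut but never the insert) bias the
    # allele-fraction estimate toward wild type
    half = (ins_e - ins_s) / 2 + slop
    ki_spans = ki is not None and ki.t_start <= ins_s - slop \
        and ki.t_end >= ins_e + slop
    wt_spans = wt is not None and wt.t_start <= models.cut - half \
        and wt.t_end >= models.cut + half
    ki_score = ki.score if ki_spans else float("-inf")
    wt_score = wt.score if wt_spans else float("-inf")
    if ki_score == wt_score == float("-inf"):
        return None
    if ki_spans and wt_spans:
        # a mostly-deleted insert can score closer to wild type than to the
        # KI model; when the KI view shows a large in-insert deletion AND the
        # wild-type view shows the residual donor sequence as a large cut-site
        # insertion, the two views agree the read carries a partial insert
        ki_dels = [(gs, -net) for gs, ge, net in _gap_clusters(ki)
                   if net <= -params.min_sv
                   and min(ge, ins_e + params.sv_margin)
                   - max(gs, ins_s - params.sv_margin) >= 0]
        wt_ins = [net for gs, ge, net in _gap_clusters(wt)
                  if net >= params.min_sv
                  and min(ge, models.cut + params.sv_margin)
                  - max(gs, models.cut - params.sv_margin) >= 0]
        if ki_dels and wt_ins:
            pos = min(p for p, _ in ki_dels)
            total = sum(n for _, n in ki_dels)
            return ReadClass(read_id, "ki", "partial_ki", size=total,
                             interval=(pos, pos + total))
    if wt_score >= ki_score:
        net = _cut_site_indel_net(wt, read_seq, models.wt.sequence,
                                  models.cut, params)
        if net != 0:
            return ReadClass(read_id, "wt", "cut_site_indel", size=net)
        return ReadClass(read_id, "wt", "wild_type")
    w_lo, w_hi = ins_s - params.sv_margin, ins_e + params.sv_margin
    gaps = [(gs, net) for gs, ge, net in _gap_clusters(ki)
            if min(ge, w_hi) - max(gs, w_lo) >= 0 and abs(net) >= params.min_sv]
    dels = [(pos, -net) for pos, net in gaps if net < 0]
    inss = [(pos, net) for pos, net in gaps if net > 0]
    if dels and (not inss or max(n for _, n in dels) >= max(n for _, n in inss)):
        pos = min(p for p, _ in dels)
        total = sum(n for _, n in dels)
        return ReadClass(read_id, "ki", "partial_ki", size=total,
                         interval=(pos, pos + total))
    if inss:
        pos = min(p for p, _ in inss)
        total = sum(n for _, n in inss)
        return ReadClass(read_id, "ki", "imprecise_ki", size=total,
                         interval=(pos, pos + total))
    return ReadClass(read_id, "ki", "precise_ki")


def classify_alleles(ki_alignments: dict[str, list[AlignmentRecord]],
                     wt_alignments: dict[str, list[AlignmentRecord]],
                     models: AlleleModels,
                     params: Optional[CallParams] = None,
                     read_sequences: Optional[dict[str, str]] = None
                     ) -> tuple[list[ReadClass], Genotype]:
    """Label each locus-spanning read by its best-scoring allele model.

    Only reads spanning both junction regions (KI model) or the cut region
    (wild-type model) vote on the genotype; non-spanning reads contribute to
    depth only. The genotype is the allele-fraction vector over called
    classes with Wilson 95% intervals; more than two classes above
    ``min_allele_frac`` flags mosaicism; no spanning reads yields a no-call.
    """
    params = params or CallParams()
    classes: list[ReadClass] = []
    for read_id in set(ki_alignments) | set(wt_alignments):
        ki = next((r for r in ki_alignments.get(read_id, [])
                   if not r.is_supplementary), None)
        wt = next((r for r in wt_alignments.get(read_id, [])
                   if not r.is_supplementary), None)
        seq = read_sequences.get(read_id) if read_sequences else None
        rc = _classify_read(read_id, ki, wt, models, params, seq)
        if rc is not None:
            classes.append(rc)
    n = len(classes)
    if n == 0:
        return classes, Genotype(0, {}, {}, "no-call", False, no_call=True)
    counts: dict[str, int] = {}
    for rc in classes:
        counts[rc.label] = counts.get(rc.label, 0) + 1
    fractions = {lbl: c / n for lbl, c in counts.items()}
    intervals = {lbl: tuple(proportion_confint(c, n, alpha=0.05, method="wilson"))
                 for lbl, c in counts.items()}
    called = sorted((lbl for lbl, f in fractions.items()
                     if f >= params.min_allele_frac),
                    key=lambda l: -fractions[l])
    mosaic = len(called) > 2
    if not called:
        call = "no-call"
    elif mosaic:
        call = "mosaic(" + "/".join(called) + ")"
    elif len(called) == 1:
        call = f"{called[0]}/{called[0]}"
    else:
        call = "/".join(called)
    return classes, Genotype(n, fractions, intervals, call, mosaic)


# ---------------------------------------------------------------------------
# Concatemers
# ---------------------------------------------------------------------------

@dataclass
class ConcatemerEvent:
    topology: Optional[str]
    copies: int
    support_reads: list[str]
    evidence: str                 # 'junction' | 'depth' | 'junction+depth'
    gain_interval: Optional[tuple[int, int]] = None


def detect_concatemer(ki_alignments: dict[str, list[AlignmentRecord]],
                      insert_track: DepthTrack,
                      models: AlleleModels,
                      params: Optional[CallParams] = None) -> list[ConcatemerEvent]:
    """Donor-concatenation events at the target site.

    Read evidence: single reads carrying >=2 query-disjoint segments matching
    overlapping parts of the insert, with the junction topology derived from
    segment orientations. Depth evidence: contiguous insert sub-intervals
    with normalized depth >= ``cnv_gain`` x the insert median, and a gain of
    the whole insert against the flank median; copy estimates are rounded
    depth ratios.
    """
    params = params or CallParams()
    ins_s, ins_e = models.insert
    mid = (ins_s + ins_e) / 2
    topo_votes: dict[str, list[str]] = {}
    read_copies: dict[str, int] = {}
    for read_id, recs in ki_alignments.items():
        insert_recs = [r for r in recs
                       if min(r.t_end, ins_e) - max(r.t_start, ins_s) >= params.min_sv]
        if len(insert_recs) < 2:
            continue
        insert_recs.sort(key=lambda r: r.q_start)
        found = False
        for a, b in zip(insert_recs, insert_recs[1:]):
            if b.q_start - a.q_end < -params.tolerance:
                continue
            overlap = min(a.t_end, b.t_end) - max(a.t_start, b.t_start)
            if overlap < params.min_sv:
                continue
            if a.strand == b.strand:
                topo = "head_to_tail"
            else:
                c1, _ = _junction_side(a, read_right=True)
                c2, _ = _junction_side(b, read_right=False)
                topo = "tail_to_tail" if (c1 + c2) / 2 > mid else "head_to_head"
            topo_votes.setdefault(topo, []).append(read_id)
            found = True
        if found:
            read_copies[read_id] = len(insert_recs)
    events: list[ConcatemerEvent] = []
    norm = insert_track.normalized
    insert_depth = norm[ins_s:ins_e]
    insert_median = float(np.median(insert_depth)) if insert_depth.size else 0.0
    # baseline from genomic sequence immediately outside the donor span: the
    # homology arms are themselves multiplied in a concatemer, and coverage
    # tapers toward the reference edges, so neither can serve as baseline
    fw = 1000
    d_s, d_e = models.donor_span or models.insert
    flank = np.concatenate([norm[max(0, d_s - fw):d_s], norm[d_e:d_e + fw]])
    flank_median = float(np.median(flank)) if flank.size else 0.0
    depth_copies = 0
    gain_interval = None
    if insert_median > 0:
        # a gained sub-interval must stand out against both the insert and
        # the flank baseline, otherwise partially covered inserts (e.g. a
        # random-integration allele adding partial cassette coverage) would
        # masquerade as copy gains
        floor = params.cnv_gain * max(insert_median, flank_median)
        runs = [(s, e) for s, e in _bool_runs(insert_depth >= floor)
                if e - s >= params.min_sv]
        if runs:
            s, e = max(runs, key=lambda r: r[1] - r[0])
            gain_interval = (ins_s + s, ins_s + e)
            baseline = max(insert_median, flank_median)
            depth_copies = int(round(float(np.median(insert_depth[s:e])) / baseline))
    whole_gain = flank_median > 0 and insert_median >= params.cnv_gain * flank_median
    if whole_gain:
        depth_copies = max(depth_copies, int(round(insert_median / flank_median)))
        if gain_interval is None:
            gain_interval = (ins_s, ins_e)
    if topo_votes:
        topo = max(topo_votes, key=lambda t: len(topo_votes[t]))
        support = sorted(set(topo_votes[topo]))
        copies_read = int(np.median([read_copies.get(r, 2) for r in support]))
        copies = depth_copies if whole_gain else max(copies_read, depth_copies, 2)
        evidence = "junction+depth" if depth_copies >= 2 else "junction"
        events.append(ConcatemerEvent(topo, copies, support, evidence, gain_interval))
    elif depth_copies >= 2:
        events.append(ConcatemerEvent(None, depth_copies, [], "depth", gain_interval))
    return events


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


# ---------------------------------------------------------------------------
# ITR detection
# ---------------------------------------------------------------------------

@dataclass
class ItrMatch:
    seq_id: str
    start: int
    end: int
    variant: str
    strand: str
    identity: float


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local", match_score=2,
                                    mismatch_score=-3, open_gap_score=-5,
                                    extend_gap_score=-2)
    return aligner


def detect_itr(sequences: dict[str, str], itr_refs: dict[str, str],
               min_len: int = 60, min_identity: float = 0.9) -> list[ItrMatch]:
    """Local-alignment scan for vector ITR segments in reads or assemblies.

    Reports matches of at least ``min_len`` aligned nt at ``min_identity``,
    on either strand, labelled with the matching ITR variant.
    """
    if not itr_refs:
        raise CharacterizeError("itr_refs must be non-empty")
    aligner = _local_aligner()
    matches: list[ItrMatch] = []
    for seq_id, seq in sequences.items():
        if not seq:
            continue
        for variant, itr in itr_refs.items():
            for strand, query in (("+", itr), ("-", revcomp(itr))):
                try:
                    aln = max(aligner.align(seq, query), key=lambda a: a.score)
                except (ValueError, OverflowError):
                    continue
                t_span = aln.aligned[0]
                if not len(t_span):
                    continue
                start, end = int(t_span[0][0]), int(t_span[-1][1])
                counts = aln.counts()
                cols = counts.identities + counts.mismatches + counts.gaps
                identity = counts.identities / cols if cols else 0.0
                if end - start >= min_len and identity >= min_identity:
                    matches.append(ItrMatch(seq_id, start, end, variant,
                                            strand, identity))
    return matches


# ---------------------------------------------------------------------------
# Random integration
# ---------------------------------------------------------------------------

@dataclass
class RandomIntegrationEvent:
    chrom: str
    position: int
    support: int
    spread: int
    itr_detected: bool
    in_top_window: bool
    read_ids: list[str]


def detect_random_integration(clusters: Sequence[BreakpointCluster],
                              candidate_windows: Sequence[tuple[str, int, int, float]],
                              target_locus: Interval,
                              read_sequences: dict[str, str],
                              itr_refs: dict[str, str],
                              params: Optional[CallParams] = None
                              ) -> tuple[list[RandomIntegrationEvent],
                                         list[BreakpointCluster]]:
    """Call RI events from junction clusters; under-supported ones are artifacts.

    An event requires a genome-side position outside the target locus +/-
    ``locus_pad``, support from >= ``min_support`` independent reads, and a
    positional spread <= ``max_spread``. Each event is annotated with whether
    vector ITR sequence is present on its junction reads and whether it falls
    inside a top-depth candidate window.
    """
    params = params or CallParams()
    events: list[RandomIntegrationEvent] = []
    artifacts: list[BreakpointCluster] = []
    for cluster in clusters:
        near_target = (cluster.genome_chrom == target_locus.chrom
                       and target_locus.start - params.locus_pad
                       <= cluster.genome_pos
                       <= target_locus.end + params.locus_pad)
        if near_target:
            continue
        if cluster.support < params.min_support or cluster.spread > params.max_spread:
            artifacts.append(cluster)
            continue
        seqs = {rid: read_sequences[rid] for rid in cluster.read_ids
                if rid in read_sequences}
        itr_hits = detect_itr(seqs, itr_refs, params.itr_min_len,
                              params.itr_min_identity)
        with_itr = len({m.seq_id for m in itr_hits})
        itr_flag = with_itr >= max(1, round(len(seqs) / 2))
        in_window = any(c == cluster.genome_chrom and s <= cluster.genome_pos < e
                        for c, s, e, _ in candidate_windows)
        events.append(RandomIntegrationEvent(
            cluster.genome_chrom, cluster.genome_pos, cluster.support,
            cluster.spread, itr_flag, in_window, cluster.read_ids))
    return events, artifacts


# ---------------------------------------------------------------------------
# Fusion-read (cross-library chimera) rate
# ---------------------------------------------------------------------------

def estimate_fusion_rate(alignments: dict[str, list[AlignmentRecord]],
                         insert_refs: tuple[str, str],
                         min_seg: int = 200) -> tuple[float, list[str]]:
    """Fraction of insert-mapping reads aligning to both of two distinct inserts."""
    ref_a, ref_b = insert_refs
    if ref_a == ref_b:
        raise CharacterizeError("fusion-rate estimation needs two distinct inserts")
    either, both = 0, []
    for read_id, recs in alignments.items():
        hits = {r.target for r in recs
                if r.target in (ref_a, ref_b) and r.query_span >= min_seg}
        if hits:
            either += 1
            if len(hits) == 2:
                both.append(read_id)
    if either == 0:
        return 0.0, []
    return len(both) / either, sorted(both)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_region(read_sequences: dict[str, str],
                     alignments: Iterable[AlignmentRecord],
                     region: tuple[int, int],
                     reference: str,
                     min_reads: int = 5) -> Optional[str]:
    """Anchored majority-vote consensus over a reference region.

    Reads are anchored by their alignments; each reference column in
    ``region`` collects base/gap votes from aligned reads (read insertions
    are not represented). Ties break toward the reference base; columns whose
    majority is a gap are dropped. Returns None (no-call) when fewer than
    ``min_reads`` reads overlap the region.
    """
    start, end = region
    votes: dict[int, dict[str, int]] = {i: {} for i in range(start, end)}
    covering: set[str] = set()
    for rec in alignments:
        if rec.t_end <= start or rec.t_start >= end:
            continue
        seq = read_sequences.get(rec.read_id)
        if seq is None:
            continue
        covering.add(rec.read_id)
        sseq = seq[rec.q_start:rec.q_end]
        if rec.strand == "-":
            sseq = revcomp(sseq)
        t, q = rec.t_start, 0
        for op, n in rec.ops:
            if op in "=X":
                for j in range(n):
                    if start <= t + j < end:
                        base = sseq[q + j]
                        votes[t + j][base] = votes[t + j].get(base, 0) + 1
                t += n
                q += n
            elif op == "D":
                for j in range(n):
                    if start <= t + j < end:
                        votes[t + j]["-"] = votes[t + j].get("-", 0) + 1
                t += n
            elif op == "I":
                q += n
    if len(covering) < min_reads:
        return None
    out = []
    for i in range(start, end):
        col = votes[i]
        ref_base = reference[i]
        if not col:
            out.append(ref_base)
            continue
        best = max(col.values())
        winners = {b for b, c in col.items() if c == best}
        base = ref_base if ref_base in winners else sorted(winners)[0]
        if base != "-":
            out.append(base)
    return "".join(out)


def extract_region_reads(alignments: dict[str, list[AlignmentRecord]],
                         reads: dict[str, str],
                         region: Interval) -> list[str]:
    """Ids of reads with an alignment overlapping a candidate region.

    Used to export per-window FASTQ subsets (e.g. the top-depth candidate
    windows) for external assembly or manual review.
    """
    ids = set()
    for read_id, recs in alignments.items():
        for r in recs:
            if r.target == region.chrom and \
                    min(r.t_end, region.end) - max(r.t_start, region.start) > 0:
                ids.add(read_id)
                break
    return sorted(i for i in ids if i in reads)


# ---------------------------------------------------------------------------
# Sample-level call set
# ---------------------------------------------------------------------------

@dataclass
class SampleCallSet:
    """Everything the caller concluded about one sample."""

    sample: str
    total_reads: int
    transgene_mapped: int
    total_mapped: int
    capture_efficiency_total: float       # transgene-mapped / total reads
    capture_efficiency_mapped: float      # transgene-mapped / total mapped
    read_length_quartiles: tuple[float, float, float]
    genotype: Genotype
    read_classes: list[ReadClass] = field(default_factory=list)
    concatemer_events: list[ConcatemerEvent] = field(default_factory=list)
    ri_events: list[RandomIntegrationEvent] = field(default_factory=list)
    artifacts: list[BreakpointCluster] = field(default_factory=list)
    fusion_rate: Optional[float] = None
    candidate_windows: list[tuple[str, int, int, float]] = field(default_factory=list)
    partial_deletion_estimate: Optional[int] = None
    imprecise_extra_estimate: Optional[int] = None
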