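"""Truth-annotated simulation of edited genomes and capture-enriched long reads.

The simulator emulates the experimental workflow this package analyses:
a small genome carrying a mixture of editing outcomes at a target locus
(precise knock-in, cut-site indels, partial or imprecise knock-ins, donor
concatemers, random integrations with or without retained vector ITRs) is
fragmented (Tn5 tagmentation ~1 kb or mechanical shearing ~8 kb, log-normal
lengths), filtered through a hybridization-capture model (fragments
overlapping a probe interval by >= ``min_overlap`` nt are kept with
probability ``p_on``, everything else with ``p_bg``), dual-index barcoded,
optionally chimerized by blunt-joining two independent fragments, and
error-mutated with independent per-base substitutions/insertions/deletions.

Every emitted read carries a truth row (allele of origin, source interval,
strand, chimera and on-target flags), which is what makes parameter-recovery
testing of the downstream caller possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constructs import AlleleMap, ITR_CANONICAL
from .seq import FastqRead, Interval, random_dna, revcomp

OUTCOME_KINDS = ("wild_type", "precise_ki", "cut_site_indel", "partial_ki",
                 "imprecise_ki", "concatemer", "random_integration")
CONCATEMER_TOPOLOGIES = ("head_to_tail", "head_to_head", "tail_to_tail")

#: Probe panels cover the insert, homology arms and this much genomic flank.
DEFAULT_PROBE_FLANK = 2000

TRUTH_COLUMNS = ["read_id", "sample", "allele", "chrom", "start", "end",
                 "strand", "barcode_status", "chimera", "on_target",
                 "chimera_partner"]


class SimulationError(ValueError):
    pass


@dataclass
class EditOutcomeSpec:
    """One allele class present in a (possibly mosaic) sample."""

    kind: str
    allele_fraction: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in OUTCOME_KINDS:
            raise SimulationError(f"unknown outcome kind {self.kind!r}")
        if not 0 <= self.allele_fraction <= 1:
            raise SimulationError("allele_fraction must be in [0, 1]")
        if self.kind == "concatemer":
            if self.params.get("copies", 2) < 2:
                raise SimulationError("concatemer copy count must be >= 2")
            topo = self.params.get("topology", "head_to_tail")
            if topo not in CONCATEMER_TOPOLOGIES:
                raise SimulationError(f"unknown concatemer topology {topo!r}")


@dataclass
class Haplotype:
    """One full-genome allele with its sampling fraction and truth tracks."""

    name: str
    kind: str
    seqs: dict[str, str]
    fraction: float
    capture_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


@dataclass
class CaptureModel:
    p_on: float = 0.9
    p_bg: float = 0.001
    min_overlap: int = 50

    def __post_init__(self) -> None:
        for p in (self.p_on, self.p_bg):
            if not 0 <= p <= 1:
                raise SimulationError("capture probabilities must be in [0, 1]")


@dataclass
class SimConfig:
    """Knobs of one simulated library; identical seed+config => identical output."""

    seed: int = 0
    n_reads: int = 1000
    sample: str = "sample"
    fragmentation: str = "shear"  # 'shear' | 'tagmentation'
    frag_mean: Optional[float] = None
    frag_sd: Optional[float] = None
    capture: CaptureModel = field(default_factory=CaptureModel)
    error_sub: float = 0.02
    error_ins: float = 0.02
    error_del: float = 0.02
    index1: str = "ACGTACGTAC"
    index2: str = "TGCATGCATG"
    chimera_rate: float = 0.0
    min_fragment: int = 100

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise SimulationError("n_reads must be >= 0")
        for p in (self.error_sub, self.error_ins, self.error_del, self.chimera_rate):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must be in [0, 1]")
        if self.fragmentation not in ("shear", "tagmentation"):
            raise SimulationError(f"unknown fragmentation {self.fragmentation!r}")
        if self.frag_mean is None:
            self.frag_mean = 1000.0 if self.fragmentation == "tagmentation" else 8000.0
        if self.frag_sd is None:
            self.frag_sd = 400.0 if self.fragmentation == "tagmentation" else 3000.0


# ---------------------------------------------------------------------------
# Edited-genome construction
# ---------------------------------------------------------------------------

def _insert_interval(expected: AlleleMap, locus_name: str) -> tuple[int, int]:
    """Donor-derived span of the expected allele (everything not locus-sourced)."""
    donor_spans = [(a.start, a.end) for a in expected.annotations if a.source != locus_name]
    if not donor_spans:
        raise SimulationError("expected allele carries no donor-derived annotation")
    return min(s for s, _ in donor_spans), max(e for _, e in donor_spans)


def build_edited_genome(base_genome: dict[str, str],
                        target_locus: Interval,
                        expected_allele: AlleleMap,
                        outcomes: Sequence[EditOutcomeSpec],
                        locus_name: Optional[str] = None,
                        probe_flank: int = DEFAULT_PROBE_FLANK,
                        rng: Optional[np.random.Generator] = None) -> list[Haplotype]:
    """Materialize one full-genome haplotype per outcome spec.

    ``expected_allele.sequence`` replaces ``target_locus`` on the precise-KI
    haplotype; other outcome kinds are derived from it (or from wild type) as
    documented on :class:`EditOutcomeSpec`. Each haplotype carries probe
    (capture) intervals covering the edited locus plus ``probe_flank`` nt of
    genomic flank, and BED-ready truth tracks in its own coordinates.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    total = sum(o.allele_fraction for o in outcomes)
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"allele fractions must sum to 1, got {total}")
    chrom = target_locus.chrom
    if chrom not in base_genome:
        raise SimulationError(f"target chromosome {chrom!r} absent from genome")
    locus_name = locus_name or expected_allele.name
    base_seq = base_genome[chrom]
    ins_s, ins_e = _insert_interval(expected_allele, locus_name)
    precise = (base_seq[:target_locus.start] + expected_allele.sequence
               + base_seq[target_locus.end:])
    # insert coordinates on the precise haplotype
    g_ins_s, g_ins_e = target_locus.start + ins_s, target_locus.start + ins_e

    haplotypes: list[Haplotype] = []
    for i, out in enumerate(outcomes):
        name = f"{out.kind}_{i}"
        seqs = dict(base_genome)
        truth: dict = {"kind": out.kind}
        if out.kind == "wild_type":
            truth["locus"] = (chrom, target_locus.start, target_locus.end)
        elif out.kind == "precise_ki":
            seqs[chrom] = precise
            truth["insert"] = (chrom, g_ins_s, g_ins_e)
            truth["junctions"] = [(chrom, g_ins_s), (chrom, g_ins_e)]
        elif out.kind == "cut_site_indel":
            size = int(out.params["size"])
            cut = int(out.params["cut"])
            if size < 0:
                seqs[chrom] = base_seq[:cut] + base_seq[cut - size:]
            else:
                filler = out.params.get("sequence") or random_dna(rng, size)
                seqs[chrom] = base_seq[:cut] + filler + base_seq[cut:]
            truth["indel"] = (chrom, cut, size)
        elif out.kind == "partial_ki":
            m_s, m_e = out.params["missing"]
            if not (ins_s <= m_s < m_e <= ins_e):
                raise SimulationError("partial_ki missing interval must lie in the insert")
            gs, ge = target_locus.start + m_s, target_locus.start + m_e
            seqs[chrom] = precise[:gs] + precise[ge:]
            truth["insert"] = (chrom, g_ins_s, g_ins_e - (m_e - m_s))
            truth["missing"] = (m_s, m_e)
        elif out.kind == "imprecise_ki":
            pos = target_locus.start + int(out.params["position"])
            extra = out.params.get("extra") or random_dna(rng, int(out.params["extra_len"]))
            seqs[chrom] = precise[:pos] + extra + precise[pos:]
            truth["insert"] = (chrom, g_ins_s, g_ins_e + len(extra))
            truth["extra"] = (int(out.params["position"]), len(extra))
        elif out.kind == "concatemer":
            copies = int(out.params.get("copies", 2))
            topo = out.params.get("topology", "head_to_tail")
            c_s, c_e = out.params.get("cassette", (ins_s, ins_e))
            cassette = expected_allele.sequence[c_s:c_e]
            # orientation pattern: head_to_tail = all forward;
            # tail_to_tail = +,-,+,...; head_to_head = -,+,-,...
            units = []
            for c in range(copies):
                if topo == "head_to_tail":
                    fwd = True
                elif topo == "tail_to_tail":
                    fwd = c % 2 == 0
                else:  # head_to_head
                    fwd = c % 2 == 1
                units.append(cassette if fwd else revcomp(cassette))
            gs, ge = target_locus.start + c_s, target_locus.start + c_e
            seqs[chrom] = precise[:gs] + "".join(units) + precise[ge:]
            truth["insert"] = (chrom, g_ins_s, g_ins_e + (copies - 1) * len(cassette))
            truth["concatemer"] = {"copies": copies, "topology": topo,
                                   "cassette": (c_s, c_e)}
        elif out.kind == "random_integration":
            ri_chrom = out.params["chrom"]
            ri_pos = int(out.params["position"])
            if ri_chrom not in seqs or not 0 <= ri_pos <= len(seqs[ri_chrom]):
                raise SimulationError(
                    f"random integration position {ri_chrom}:{ri_pos} outside genome")
            if ri_chrom == chrom and ri_pos < target_locus.end:
                raise SimulationError(
                    "random integration on the target chromosome must lie 3' of "
                    "the target locus to keep truth coordinates unambiguous")
            itr = bool(out.params.get("itr_retained", False))
            cassette = out.params.get("cassette") or expected_allele.sequence[ins_s:ins_e]
            if itr:
                cassette = ITR_CANONICAL + cassette + ITR_CANONICAL
            if out.params.get("base_kind") == "precise_ki":
                seqs[chrom] = precise
                truth["insert"] = (chrom, g_ins_s, g_ins_e)
            host = seqs[ri_chrom]
            seqs[ri_chrom] = host[:ri_pos] + cassette + host[ri_pos:]
            truth["ri"] = {"chrom": ri_chrom, "position": ri_pos,
                           "itr_retained": itr, "length": len(cassette)}
        hap = Haplotype(name=name, kind=out.kind, seqs=seqs,
                        fraction=out.allele_fraction, truth=truth)
        # capture panel: edited locus +/- flank (in this haplotype's own
        # coordinates), plus any random-integration site +/- flank
        if out.kind == "random_integration":
            shift = (len(expected_allele) - len(target_locus)) \
                if out.params.get("base_kind") == "precise_ki" else 0
        else:
            shift = len(seqs[chrom]) - len(base_seq)
        locus_span = (max(0, target_locus.start - probe_flank),
                      min(len(seqs[chrom]), target_locus.end + shift + probe_flank))
        hap.capture_intervals = {chrom: [locus_span]}
        if "ri" in truth:
            ri = truth["ri"]
            span = (max(0, ri["position"] - probe_flank),
                    min(len(seqs[ri["chrom"]]),
                        ri["position"] + ri["length"] + probe_flank))
            hap.capture_intervals.setdefault(ri["chrom"], []).append(span)
        haplotypes.append(hap)
    return haplotypes


def truth_bed_rows(haplotypes: Sequence[Haplotype]) -> list[tuple]:
    """Flatten haplotype truth tracks into BED-style rows."""
    rows: list[tuple] = []
    for hap in haplotypes:
        t = hap.truth
        if "insert" in t:
            c, s, e = t["insert"]
            rows.append((c, s, e, f"{hap.name}:insert"))
        for c, p in t.get("junctions", []):
            rows.append((c, p, p + 1, f"{hap.name}:junction"))
        if "ri" in t:
            ri = t["ri"]
            rows.append((ri["chrom"], ri["position"], ri["position"] + ri["length"],
                         f"{hap.name}:random_integration:itr={ri['itr_retained']}"))
    return rows


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class _Fragment:
    allele: str
    chrom: str
    start: int
    end: int
    sequence: str
    on_target: bool


def _draw_fragment(rng: np.random.Generator, haps: Sequence[Haplotype],
                   config: SimConfig, mu: float, sigma: float) -> _Fragment:
    fractions = np.array([h.fraction for h in haps])
    hap = haps[rng.choice(len(haps), p=fractions / fractions.sum())]
    chroms = list(hap.seqs)
    lengths = np.array([len(hap.seqs[c]) for c in chroms], dtype=float)
    chrom = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
    seq = hap.seqs[chrom]
    flen = max(config.min_fragment, int(rng.lognormal(mu, sigma)))
    flen = min(flen, len(seq))
    start = int(rng.integers(0, len(seq) - flen + 1))
    end = start + flen
    cap = config.capture
    overlap = max((min(end, e) - max(start, s)
                   for s, e in hap.capture_intervals.get(chrom, [])), default=0)
    return _Fragment(hap.name, chrom, start, end, seq[start:end],
                     overlap >= cap.min_overlap)


def _accept(rng: np.random.Generator, frag_on_target: bool, cap: CaptureModel) -> bool:
    p = cap.p_on if frag_on_target else cap.p_bg
    return bool(rng.random() < p)


def _mutate(rng: np.random.Generator, seq: str, config: SimConfig) -> str:
    """Independent per-base substitution/insertion/deletion errors."""
    if config.error_sub == config.error_ins == config.error_del == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    keep = rng.random(n) >= config.error_del
    sub = (rng.random(n) < config.error_sub) & keep
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    # substitute with a uniformly chosen different base
    arr = arr.copy()
    if sub.any():
        shifts = rng.integers(1, 4, size=int(sub.sum()))
        idx = np.searchsorted(bases, arr[sub])
        arr[sub] = bases[(idx + shifts) % 4]
    ins = rng.random(n) < config.error_ins
    out = bytearray()
    ins_bases = bases[rng.integers(0, 4, size=int(ins.sum()))]
    j = 0
    for i in range(n):
        if keep[i]:
            out.append(arr[i])
        if ins[i]:
            out.append(ins_bases[j])
            j += 1
    return bytes(out).decode()


def simulate_reads(haplotypes: Sequence[Haplotype], config: SimConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> tuple[list[FastqRead], pd.DataFrame]:
    """Emit exactly ``config.n_reads`` barcoded, capture-filtered reads.

    With all error rates and ``chimera_rate`` zero, every read is an exact
    substring (or reverse complement) of ``index1 + fragment + revcomp(index2)``
    built from its source allele. Returns the reads and one truth row each.
    """
    if config.n_reads > 0 and not haplotypes:
        raise SimulationError("cannot simulate reads from an empty allele set")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu, sigma = _lognormal_params(config.frag_mean, config.frag_sd)
    reads: list[FastqRead] = []
    rows: list[dict] = []
    for i in range(config.n_reads):
        is_chimera = bool(rng.random() < config.chimera_rate)
        while True:
            frag = _draw_fragment(rng, haplotypes, config, mu, sigma)
            partner = _draw_fragment(rng, haplotypes, config, mu, sigma) \
                if is_chimera else None
            on = frag.on_target or (partner is not None and partner.on_target)
            if _accept(rng, on, config.capture):
                break
        insert = frag.sequence + (partner.sequence if partner else "")
        raw = config.index1 + insert + revcomp(config.index2)
        strand = "+"
        if rng.random() < 0.5:
            raw, strand = revcomp(raw), "-"
        mutated = _mutate(rng, raw, config)
        rid = f"{config.sample}_{i:06d}"
        reads.append(FastqRead(rid, mutated))
        rows.append({
            "read_id": rid, "sample": config.sample, "allele": frag.allele,
            "chrom": frag.chrom, "start": frag.start, "end": frag.end,
            "strand": strand, "barcode_status": "dual",
            "chimera": is_chimera, "on_target": on,
            "chimera_partner": (f"{partner.allele}:{partner.chrom}:"
                                f"{partner.start}-{partner.end}" if partner else ""),
        })
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return reads, truth


def plan_mixed_run(samples: Sequence[tuple[Sequence[Haplotype], SimConfig]],
                   chimera_rate: float = 0.0,
                   seed: int = 0) -> tuple[list[FastqRead], pd.DataFrame]:
    """Pool >=2 barcoded libraries and form cross-sample chimeras after pooling.

    Each library is simulated chimera-free; after pooling, each read is, with
    probability ``chimera_rate``, blunt-joined to a fragment re-drawn from a
    *different* sample, giving every artifact a unique junction position.
    The pooled stream is shuffled deterministically.
    """
    if len(samples) < 2:
        raise SimulationError("a mixed run needs at least two samples")
    pairs = [(cfg.index1, cfg.index2) for _, cfg in samples]
    if len(set(pairs)) != len(pairs):
        raise SimulationError("duplicate barcode pairs across samples")
    rng = np.random.default_rng(seed)
    all_reads: list[FastqRead] = []
    all_rows: list[pd.DataFrame] = []
    per_sample = []
    for haps, cfg in samples:
        cfg = replace(cfg, chimera_rate=0.0)
        reads, truth = simulate_reads(haps, cfg, rng=np.random.default_rng(cfg.seed))
        per_sample.append((haps, cfg))
        all_reads.extend(reads)
        all_rows.append(truth)
    truth = pd.concat(all_rows, ignore_index=True)
    mus = [_lognormal_params(cfg.frag_mean, cfg.frag_sd) for _, cfg in per_sample]
    sample_names = [cfg.sample for _, cfg in per_sample]
    for i in range(len(all_reads)):
        if rng.random() >= chimera_rate:
            continue
        own = sample_names.index(truth.at[i, "sample"])
        others = [j for j in range(len(per_sample)) if j != own]
        j = others[int(rng.integers(0, len(others)))]
        haps, cfg = per_sample[j]
        mu, sigma = mus[j]
        while True:
            frag = _draw_fragment(rng, haps, cfg, mu, sigma)
            if _accept(rng, frag.on_target, cfg.capture):
                break
        extra = _mutate(rng, frag.sequence, cfg)
        r = all_reads[i]
        all_reads[i] = FastqRead(r.id, r.sequence + extra)
        truth.at[i, "chimera"] = True
        truth.at[i, "chimera_partner"] = (f"{frag.allele}:{frag.chrom}:"
                                          f"{frag.start}-{frag.end}@{cfg.sample}")
    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[k] for k in order]
    truth = truth.iloc[order].reset_index(drop=True)
    return all_reads, truth
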