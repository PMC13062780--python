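"""End-to-end per-sample characterization.

Glue between the stage modules: builds the reference set for a knock-in
project (transgene per donor, expected-KI and wild-type locus models),
runs two-pass mapping, and derives a :class:`~lockseq.characterize.SampleCallSet`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import (AlignParams, AlignmentRecord, MinimizerIndex,
                    capture_efficiency, map_reads, two_pass_map)
from .characterize import (AlleleModels, CallParams, DepthTrack, SampleCallSet,
                           call_junctions, classify_alleles, depth_profile,
                           detect_concatemer, detect_random_integration,
                           top_depth_windows)
from .constructs import (AlleleMap, DonorSpec, GuideTarget, ITR_ALTERNATIVE,
                         ITR_CANONICAL, find_guide_sites)
from .seq import FastqRead, Interval
from .simulate import _insert_interval

DEFAULT_ITR_REFS = {"canonical": ITR_CANONICAL, "alternative": ITR_ALTERNATIVE}


def novel_interval(ki_seq: str, wt_seq: str) -> tuple[int, int]:
    """Span of the knock-in model sequence absent from the wild type.

    Computed as the region between the longest common prefix and suffix of
    the two locus models: the homology arms and flanks cancel, leaving the
    novel insert. This is the interval zygosity-informative reads must span.
    """
    if ki_seq == wt_seq:
        raise ValueError("KI and wild-type locus models are identical")
    limit = min(len(ki_seq), len(wt_seq))
    p = 0
    while p < limit and ki_seq[p] == wt_seq[p]:
        p += 1
    s = 0
    while s < limit - p and ki_seq[-1 - s] == wt_seq[-1 - s]:
        s += 1
    return p, len(ki_seq) - s


@dataclass
class ProjectReferences:
    """Reference sequences a knock-in project is analysed against."""

    genome: dict[str, str]
    transgene: dict[str, str]        # one sequence per donor: ITR+arm+payload+arm+ITR
    models: AlleleModels
    target_locus: Interval
    itr_refs: dict[str, str]


def build_project_references(genome: dict[str, str],
                             target_locus: Interval,
                             expected_allele: AlleleMap,
                             donors: Sequence[DonorSpec],
                             first_guide: GuideTarget,
                             locus_name: Optional[str] = None,
                             flank: int = 2000,
                             itr_refs: Optional[dict[str, str]] = None
                             ) -> ProjectReferences:
    """Assemble transgene and allele-model references for one project.

    The transgene reference is each donor's full vector genome (insert,
    homology arms and ITRs as one sequence), matching the capture panel
    design. The KI and wild-type locus models carry ``flank`` nt of genomic
    sequence on each side so junction-spanning reads anchor in unique
    genomic context.
    """
    chrom_seq = genome[target_locus.chrom]
    lo = max(0, target_locus.start - flank)
    hi = min(len(chrom_seq), target_locus.end + flank)
    left_flank = chrom_seq[lo:target_locus.start]
    right_flank = chrom_seq[target_locus.end:hi]
    ki_seq = left_flank + expected_allele.sequence + right_flank
    wt_seq = chrom_seq[lo:hi]
    wt_allele = AlleleMap("wt_locus", wt_seq)
    sites = find_guide_sites(first_guide, wt_seq)
    if len(sites) != 1:
        raise ValueError(f"guide {first_guide.name!r} must have exactly one "
                         f"site in the wild-type locus model, found {len(sites)}")
    d_s, d_e = _insert_interval(expected_allele,
                                locus_name or expected_allele.name)
    models = AlleleModels(
        ki=AlleleMap("ki_locus", ki_seq),
        wt=wt_allele,
        insert=novel_interval(ki_seq, wt_seq),
        cut=sites[0].cut,
        donor_span=(len(left_flank) + d_s, len(left_flank) + d_e))
    transgene = {d.name: d.full_sequence for d in donors}
    return ProjectReferences(genome, transgene, models, target_locus,
                             itr_refs or dict(DEFAULT_ITR_REFS))


def characterize_sample(sample: str,
                        reads: Sequence[FastqRead],
                        refs: ProjectReferences,
                        align_params: Optional[AlignParams] = None,
                        call_params: Optional[CallParams] = None) -> SampleCallSet:
    """Run the full caller on one demultiplexed sample."""
    ap = align_params or AlignParams()
    cp = call_params or CallParams()
    genome_index = MinimizerIndex(refs.genome, ap.k, ap.w)
    tg_index = MinimizerIndex(refs.transgene, ap.k, ap.w)
    two_pass = two_pass_map(reads, tg_index, genome_index, ap)
    eff_total = capture_efficiency(two_pass) if two_pass.total_reads else 0.0

    # total mapped reads: transgene-mapped plus genome-only background
    unmapped_pass1 = [r for r in reads if r.id not in two_pass.pass1]
    genome_only = map_reads(unmapped_pass1, genome_index, ap)
    total_mapped = len(two_pass.pass1) + len(genome_only)
    eff_mapped = len(two_pass.transgene_mapped) / total_mapped if total_mapped else 0.0

    mapped_lengths = [len(r) for r in reads if r.id in two_pass.pass1]
    quartiles = tuple(np.percentile(mapped_lengths, [25, 50, 75])) \
        if mapped_lengths else (0.0, 0.0, 0.0)

    # allele-model mapping for classification and insert depth; all reads
    # participate so the genomic flank keeps its full coverage baseline
    ki_index = MinimizerIndex({"ki": refs.models.ki.sequence}, ap.k, ap.w)
    wt_index = MinimizerIndex({"wt": refs.models.wt.sequence}, ap.k, ap.w)
    ki_aln = map_reads(reads, ki_index, ap)
    wt_aln = map_reads(reads, wt_index, ap)
    read_seqs_all = {r.id: r.sequence for r in reads}
    classes, genotype = classify_alleles(ki_aln, wt_aln, refs.models, cp,
                                         read_sequences=read_seqs_all)

    ki_records = [rec for recs in ki_aln.values() for rec in recs]
    insert_track = depth_profile(ki_records, "ki", len(refs.models.ki),
                                 total_mapped or 1)
    concat = detect_concatemer(ki_aln, insert_track, refs.models, cp)

    # genome-wide depth of transgene-mapped reads -> candidate windows
    pass2_records = [rec for recs in two_pass.pass2.values() for rec in recs]
    genome_tracks = {
        chrom: depth_profile(pass2_records, chrom, len(seq), total_mapped or 1)
        for chrom, seq in refs.genome.items()}
    windows = top_depth_windows(genome_tracks, exclude=refs.target_locus)

    clusters = call_junctions(two_pass.pass1, two_pass.pass2,
                              cp.tolerance, cp.min_seg)
    read_seqs = {r.id: r.sequence for r in reads}
    ri_events, artifacts = detect_random_integration(
        clusters, windows, refs.target_locus, read_seqs, refs.itr_refs, cp)

    deletion_sizes = [c.size for c in classes if c.label == "partial_ki"]
    extra_sizes = [c.size for c in classes if c.label == "imprecise_ki"]
    return SampleCallSet(
        sample=sample,
        total_reads=len(reads),
        transgene_mapped=len(two_pass.transgene_mapped),
        total_mapped=total_mapped,
        capture_efficiency_total=eff_total,
        capture_efficiency_mapped=eff_mapped,
        read_length_quartiles=tuple(float(q) for q in quartiles),
        genotype=genotype,
        read_classes=classes,
        concatemer_events=concat,
        ri_events=ri_events,
        artifacts=artifacts,
        candidate_windows=windows,
        partial_deletion_estimate=int(np.median(deletion_sizes))
        if deletion_sizes else None,
        imprecise_extra_estimate=int(np.median(extra_sizes))
        if extra_sizes else None,
    )
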