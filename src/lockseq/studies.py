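"""Seeded simulation studies validating the whole toolkit end to end.

Each study builds a small knock-in project on a synthetic mini-genome,
simulates a capture-enriched library under stated conditions, runs the full
pipeline, and compares its calls against the simulation truth. The studies
are the package's own validation surface: the test suite asserts on their
outputs, and the acceptance script reports them.

Problem sizes (mini-genome of 100 kb over two chromosomes, hundreds of reads
per sample) are chosen so every study is a desk-scale experiment while still
exercising every caller code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .align import AlignParams, MinimizerIndex, map_read, map_reads
from .characterize import CallParams, estimate_fusion_rate
from .constructs import (AlleleMap, DonorSpec, GuideTarget, HomologyArm,
                         ITR_CANONICAL, find_guide_sites,
                         reconstruct_sequential_ki, validate_donor)
from .demux import SampleSheet, demultiplex
from .pipeline import (ProjectReferences, build_project_references,
                       characterize_sample)
from .seq import FastqRead, Interval, random_dna, revcomp
from .simulate import (CaptureModel, EditOutcomeSpec, Haplotype, SimConfig,
                       build_edited_genome, plan_mixed_run, simulate_reads)


# ---------------------------------------------------------------------------
# Demo knock-in project on a synthetic mini-genome
# ---------------------------------------------------------------------------

@dataclass
class DemoProject:
    genome: dict[str, str]
    cut: int
    guide: GuideTarget
    donor: DonorSpec
    target_locus: Interval
    locus_map: AlleleMap
    expected: AlleleMap
    refs: ProjectReferences
    payload_span: tuple[int, int]   # payload interval in expected-allele coords


def demo_project(seed: int,
                 chrom_sizes: Optional[dict[str, int]] = None,
                 cut: int = 30000,
                 arm_len: int = 600,
                 payload_len: int = 1500,
                 locus_half: int = 1500,
                 flank: int = 2000) -> DemoProject:
    """A single-donor knock-in project with a unique guide site.

    The mini-genome is random DNA with an SpCas9 site implanted at ``cut`` on
    chr1; the donor carries genomic homology arms around the cut and a random
    payload, flanked by canonical ITRs.
    """
    chrom_sizes = chrom_sizes or {"chr1": 60000, "chr2": 40000}
    rng = np.random.default_rng(seed)
    for _ in range(20):
        genome = {c: random_dna(rng, n) for c, n in chrom_sizes.items()}
        proto = random_dna(rng, 20)
        chr1 = genome["chr1"]
        site_start = cut - 17
        genome["chr1"] = chr1[:site_start] + proto + "AGG" + chr1[site_start + 23:]
        guide = GuideTarget("g1", proto)
        payload = random_dna(rng, payload_len)
        hits = sum(len(find_guide_sites(guide, s)) for s in genome.values())
        if hits == 1 and not find_guide_sites(guide, payload):
            break
    else:
        raise RuntimeError("could not place a unique guide site")
    left = HomologyArm("left", genome["chr1"][cut - arm_len:cut])
    right = HomologyArm("right", genome["chr1"][cut:cut + arm_len])
    donor = DonorSpec("donor1", ITR_CANONICAL, ITR_CANONICAL, left, right,
                      (("payload", payload),))
    assert validate_donor(donor, guide).ok
    target_locus = Interval("chr1", cut - locus_half, cut + locus_half)
    locus_map = AlleleMap("locus",
                          genome["chr1"][target_locus.start:target_locus.end])
    expected = reconstruct_sequential_ki(locus_map, [guide], [donor])
    refs = build_project_references(genome, target_locus, expected, [donor],
                                    guide, locus_name="locus", flank=flank)
    return DemoProject(genome, cut, guide, donor, target_locus, locus_map,
                       expected, refs,
                       payload_span=(locus_half, locus_half + payload_len))


def _barcodes(rng: np.random.Generator, n: int, length: int = 12
              ) -> list[tuple[str, str]]:
    pairs = set()
    while len(pairs) < n:
        pairs.add((random_dna(rng, length), random_dna(rng, length)))
    return sorted(pairs)


def simulate_sample(project: DemoProject, outcomes: Sequence[EditOutcomeSpec],
                    seed: int, n_reads: int = 600, sample: str = "sample",
                    **config_kwargs) -> tuple[list[FastqRead], "object",
                                              list[Haplotype]]:
    """Build haplotypes for the outcome mix and simulate one library."""
    haps = build_edited_genome(project.genome, project.target_locus,
                               project.expected, outcomes,
                               locus_name="locus",
                               rng=np.random.default_rng(seed))
    cfg = SimConfig(seed=seed, n_reads=n_reads, sample=sample,
                    fragmentation="shear", frag_mean=3000, frag_sd=1200,
                    **config_kwargs)
    reads, truth = simulate_reads(haps, cfg)
    return reads, truth, haps


# ---------------------------------------------------------------------------
# Genotype / zygosity recovery across all outcome kinds
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    name: str
    outcomes: list[EditOutcomeSpec]
    expected_classes: Optional[set[str]] = None
    expect_mosaic: bool = False
    expect_concatemer: Optional[str] = None   # topology
    expect_ri: Optional[tuple[str, int]] = None


def recovery_scenarios(project: DemoProject) -> list[Scenario]:
    ps, pe = project.payload_span
    cut = project.cut
    return [
        Scenario("wild_type",
                 [EditOutcomeSpec("wild_type", 1.0)],
                 {"wild_type"}),
        Scenario("hom_ki",
                 [EditOutcomeSpec("precise_ki", 1.0)],
                 {"precise_ki"}),
        Scenario("het_ki",
                 [EditOutcomeSpec("precise_ki", 0.5),
                  EditOutcomeSpec("wild_type", 0.5)],
                 {"precise_ki", "wild_type"}),
        Scenario("ki_over_indel",
                 [EditOutcomeSpec("precise_ki", 0.5),
                  EditOutcomeSpec("cut_site_indel", 0.5,
                                  {"size": -8, "cut": cut})],
                 {"precise_ki", "cut_site_indel"}),
        Scenario("het_partial_432",
                 [EditOutcomeSpec("partial_ki", 0.5,
                                  {"missing": (ps + 200, ps + 632)}),
                  EditOutcomeSpec("wild_type", 0.5)],
                 {"partial_ki", "wild_type"}),
        Scenario("het_imprecise",
                 [EditOutcomeSpec("imprecise_ki", 0.5,
                                  {"position": ps, "extra_len": 150}),
                  EditOutcomeSpec("wild_type", 0.5)],
                 {"imprecise_ki", "wild_type"}),
        Scenario("mosaic_founder",
                 [EditOutcomeSpec("precise_ki", 0.4),
                  EditOutcomeSpec("wild_type", 0.35),
                  EditOutcomeSpec("cut_site_indel", 0.25,
                                  {"size": 12, "cut": cut})],
                 {"precise_ki", "wild_type", "cut_site_indel"},
                 expect_mosaic=True),
        Scenario("concatemer_ht",
                 [EditOutcomeSpec("concatemer", 1.0,
                                  {"copies": 2, "topology": "head_to_tail"})],
                 expect_concatemer="head_to_tail"),
        Scenario("ri_with_itr",
                 [EditOutcomeSpec("precise_ki", 0.4),
                  EditOutcomeSpec("wild_type", 0.3),
                  EditOutcomeSpec("random_integration", 0.3,
                                  {"chrom": "chr2", "position": 20000,
                                   "itr_retained": True})],
                 expect_ri=("chr2", 20000)),
        Scenario("het_partial_54",
                 [EditOutcomeSpec("partial_ki", 0.5,
                                  {"missing": (ps + 300, ps + 354)}),
                  EditOutcomeSpec("wild_type", 0.5)],
                 {"partial_ki", "wild_type"}),
    ]


def _called_classes(callset, min_frac: float) -> set[str]:
    return {lbl for lbl, f in callset.genotype.fractions.items() if f >= min_frac}


def scenario_recovered(scenario: Scenario, callset) -> bool:
    cp = CallParams()
    if scenario.expect_concatemer is not None:
        return any(e.topology == scenario.expect_concatemer
                   for e in callset.concatemer_events)
    if scenario.expect_ri is not None:
        chrom, pos = scenario.expect_ri
        return any(e.chrom == chrom and abs(e.position - pos) <= 100
                   for e in callset.ri_events)
    ok = _called_classes(callset, cp.min_allele_frac) == scenario.expected_classes
    if scenario.expect_mosaic:
        ok = ok and callset.genotype.mosaic
    return ok


def run_genotype_recovery(seed: int, n_samples: int = 40,
                          n_reads: int = 800) -> dict:
    """Recover the genotype class of ``n_samples`` simulated samples.

    Samples cycle through scenarios covering every outcome kind; returns the
    recovery fraction, the heterozygous precise-KI allele-fraction estimates,
    and per-sample records.
    """
    project = demo_project(seed)
    scenarios = recovery_scenarios(project)
    results = []
    het_fractions = []
    for i in range(n_samples):
        scenario = scenarios[i % len(scenarios)]
        reads, truth, _ = simulate_sample(project, scenario.outcomes,
                                          seed=seed * 1000 + i + 1,
                                          n_reads=n_reads,
                                          sample=f"s{i:02d}")
        callset = characterize_sample(f"s{i:02d}", reads, project.refs)
        recovered = scenario_recovered(scenario, callset)
        results.append({"sample": f"s{i:02d}", "scenario": scenario.name,
                        "recovered": recovered,
                        "call": callset.genotype.call,
                        "on_target": callset.transgene_mapped})
        if scenario.name == "het_ki":
            het_fractions.append(
                callset.genotype.fractions.get("precise_ki", 0.0))
    recovery = sum(r["recovered"] for r in results) / len(results)
    return {"n_samples": n_samples,
            "recovery_fraction": recovery,
            "het_ki_fractions": het_fractions,
            "min_on_target": min(r["on_target"] for r in results),
            "per_sample": results}


# ---------------------------------------------------------------------------
# Structural integrity: internal deletions and concatemers
# ---------------------------------------------------------------------------

def run_deletion_recovery(seed: int, spans: Sequence[int] = (54, 432, 1000),
                          n_reads: int = 600) -> dict:
    """Recover internal-deletion sizes from heterozygous partial-KI samples."""
    project = demo_project(seed)
    ps, _ = project.payload_span
    estimates = {}
    for j, span in enumerate(spans):
        outcomes = [EditOutcomeSpec("partial_ki", 0.5,
                                    {"missing": (ps + 100, ps + 100 + span)}),
                    EditOutcomeSpec("wild_type", 0.5)]
        reads, _, _ = simulate_sample(project, outcomes,
                                      seed=seed * 500 + j + 1,
                                      n_reads=n_reads, sample=f"del{span}")
        callset = characterize_sample(f"del{span}", reads, project.refs)
        estimates[span] = callset.partial_deletion_estimate
    return {"true_spans": list(spans), "estimates": estimates}


def run_concatemer_study(seed: int, n_reads: int = 600) -> dict:
    """Head-to-tail 2-copy junction evidence and 3-copy depth evidence."""
    project = demo_project(seed)
    out: dict = {}
    reads, _, _ = simulate_sample(
        project, [EditOutcomeSpec("concatemer", 1.0,
                                  {"copies": 2, "topology": "head_to_tail"})],
        seed=seed * 700 + 1, n_reads=n_reads, sample="concat2")
    cs2 = characterize_sample("concat2", reads, project.refs)
    out["two_copy_events"] = [(e.topology, e.copies, e.evidence)
                              for e in cs2.concatemer_events]
    # short-read library: depth evidence dominates
    haps = build_edited_genome(project.genome, project.target_locus,
                               project.expected,
                               [EditOutcomeSpec("concatemer", 1.0,
                                                {"copies": 3,
                                                 "topology": "head_to_tail"})],
                               locus_name="locus",
                               rng=np.random.default_rng(seed))
    cfg = SimConfig(seed=seed * 700 + 2, n_reads=n_reads, sample="concat3",
                    fragmentation="tagmentation")
    reads3, _ = simulate_reads(haps, cfg)
    cs3 = characterize_sample("concat3", reads3, project.refs)
    out["three_copy_events"] = [(e.topology, e.copies, e.evidence)
                                for e in cs3.concatemer_events]
    # control: a precise het sample must stay concatemer-free
    reads0, _, _ = simulate_sample(
        project, [EditOutcomeSpec("precise_ki", 0.5),
                  EditOutcomeSpec("wild_type", 0.5)],
        seed=seed * 700 + 3, n_reads=n_reads, sample="control")
    cs0 = characterize_sample("control", reads0, project.refs)
    out["control_events"] = [(e.topology, e.copies) for e in cs0.concatemer_events]
    return out


# ---------------------------------------------------------------------------
# Random integration and fusion artifacts
# ---------------------------------------------------------------------------

def run_ri_study(seed: int, n_reads: int = 800, itr_retained: bool = True,
                 chimera_rate: float = 0.02) -> dict:
    """Localize a known random integration amid unique-junction chimeras."""
    project = demo_project(seed)
    ri_pos = 20000
    outcomes = [EditOutcomeSpec("precise_ki", 0.4),
                EditOutcomeSpec("wild_type", 0.3),
                EditOutcomeSpec("random_integration", 0.3,
                                {"chrom": "chr2", "position": ri_pos,
                                 "itr_retained": itr_retained})]
    reads, truth, _ = simulate_sample(project, outcomes,
                                      seed=seed * 900 + 1, n_reads=n_reads,
                                      sample="ri", chimera_rate=chimera_rate)
    callset = characterize_sample("ri", reads, project.refs)
    true_events = [e for e in callset.ri_events
                   if e.chrom == "chr2" and abs(e.position - ri_pos) <= 200]
    false_events = [e for e in callset.ri_events if e not in true_events]
    loc_error = min((abs(e.position - ri_pos) for e in true_events),
                    default=None)
    n_chimeras = int(truth["chimera"].sum())
    return {"ri_truth": ("chr2", ri_pos),
            "detected": bool(true_events),
            "localization_error": loc_error,
            "itr_flag": true_events[0].itr_detected if true_events else None,
            "false_ri_calls": len(false_events),
            "putative_artifacts": len(callset.artifacts),
            "n_chimeras_injected": n_chimeras,
            "in_top_window": true_events[0].in_top_window if true_events else None}


def _fusion_project_haplotypes(project: DemoProject
                               ) -> tuple[list[Haplotype], tuple[int, int]]:
    """Homozygous precise-KI haplotypes with capture restricted to the payload."""
    haps = build_edited_genome(project.genome, project.target_locus,
                               project.expected,
                               [EditOutcomeSpec("precise_ki", 1.0)],
                               locus_name="locus")
    ps, pe = project.payload_span
    g_ps = project.target_locus.start + ps
    g_pe = project.target_locus.start + pe
    for hap in haps:
        hap.capture_intervals = {"chr1": [(g_ps, g_pe)]}
    return haps, (g_ps, g_pe)


def run_fusion_study(seed: int, n_reads: int = 2500,
                     chimera_rate: float = 0.02) -> dict:
    """Cross-library fusion-read rate on a two-project mixed flow cell.

    Both libraries are insert-captured (probes on the payload only, high
    minimum overlap), so essentially every read carries insert sequence and
    the fusion estimator's denominator matches the pool.
    """
    proj_a = demo_project(seed)
    proj_b = demo_project(seed + 101)
    haps_a, _ = _fusion_project_haplotypes(proj_a)
    haps_b, _ = _fusion_project_haplotypes(proj_b)
    rng = np.random.default_rng(seed)
    (i1a, i2a), (i1b, i2b) = _barcodes(rng, 2)
    capture = CaptureModel(p_on=0.9, p_bg=0.0, min_overlap=400)
    cfg_a = SimConfig(seed=seed * 11 + 1, n_reads=n_reads // 2, sample="libA",
                      fragmentation="shear", frag_mean=3000, frag_sd=1200,
                      capture=capture, index1=i1a, index2=i2a)
    cfg_b = replace(cfg_a, seed=seed * 11 + 2, sample="libB",
                    index1=i1b, index2=i2b)
    reads, truth = plan_mixed_run([(haps_a, cfg_a), (haps_b, cfg_b)],
                                  chimera_rate=chimera_rate, seed=seed * 11 + 3)
    payload_a = proj_a.donor.payload_sequence
    payload_b = proj_b.donor.payload_sequence
    index = MinimizerIndex({"insertA": payload_a, "insertB": payload_b})
    aln = map_reads(reads, index)
    rate, fused = estimate_fusion_rate(aln, ("insertA", "insertB"))
    truth_rate = float(truth["chimera"].mean())
    return {"configured_rate": chimera_rate, "estimate": rate,
            "truth_rate": truth_rate, "n_reads": len(reads),
            "n_either": sum(1 for v in aln.values() if v),
            "fused_reads": len(fused)}


# ---------------------------------------------------------------------------
# Demultiplexing exactness
# ---------------------------------------------------------------------------

def run_demux_study(seed: int, n_samples: int = 4, n_reads: int = 4000) -> dict:
    """Error-free pooled demultiplexing against simulation truth."""
    project = demo_project(seed)
    rng = np.random.default_rng(seed + 7)
    pairs = _barcodes(rng, n_samples)
    samples = []
    for i, (i1, i2) in enumerate(pairs):
        haps = build_edited_genome(project.genome, project.target_locus,
                                   project.expected,
                                   [EditOutcomeSpec("precise_ki", 0.5),
                                    EditOutcomeSpec("wild_type", 0.5)],
                                   locus_name="locus")
        cfg = SimConfig(seed=seed * 31 + i, n_reads=n_reads // n_samples,
                        sample=f"pool{i}", fragmentation="shear",
                        frag_mean=3000, frag_sd=1200,
                        error_sub=0.0, error_ins=0.0, error_del=0.0,
                        index1=i1, index2=i2)
        samples.append((haps, cfg))
    reads, truth = plan_mixed_run(samples, chimera_rate=0.0, seed=seed * 31 + 99)
    sheet = SampleSheet(tuple((f"pool{i}", i1, i2)
                              for i, (i1, i2) in enumerate(pairs)))
    result = demultiplex(reads, sheet)
    truth_by_id = dict(zip(truth["read_id"], truth["sample"]))
    cross = sum(1 for sample, rs in result.assigned.items()
                for r in rs if truth_by_id[r.id] != sample)
    n_assigned = sum(len(rs) for rs in result.assigned.values())
    return {"n_reads": len(reads), "n_assigned": n_assigned,
            "n_excluded": len(result.excluded),
            "cross_assignments": cross,
            "partition_ok": n_assigned + len(result.excluded) == len(reads)}


# ---------------------------------------------------------------------------
# Aligner oracle equivalence
# ---------------------------------------------------------------------------

def smith_waterman_interval(read: str, target: str, params: AlignParams
                            ) -> tuple[int, int]:
    """Full quadratic local-alignment oracle (target interval of the optimum).

    Both read orientations are scored; the better one's target interval is
    returned (coordinates are on the forward target either way).
    """
    aligner = Align.PairwiseAligner(mode="local",
                                    match_score=params.match,
                                    mismatch_score=params.mismatch,
                                    open_gap_score=params.gap_open + params.gap_extend,
                                    extend_gap_score=params.gap_extend)
    best = None
    for query in (read, revcomp(read)):
        aln = max(aligner.align(target, query), key=lambda a: a.score)
        if best is None or aln.score > best.score:
            best = aln
    spans = best.aligned[0]
    return int(spans[0][0]), int(spans[-1][1])


def run_aligner_oracle_study(seed: int, n_reads: int = 60,
                             target_len: int = 10000) -> dict:
    """Endpoint agreement of the built-in aligner with a Smith-Waterman oracle.

    Reads of 300-800 nt at ~3% error are drawn from a random 10 kb target;
    both strands. Reports the per-end deviation of the reported target
    interval from the oracle's.
    """
    rng = np.random.default_rng(seed)
    target = random_dna(rng, target_len)
    params = AlignParams()
    index = MinimizerIndex({"t": target}, params.k, params.w)
    cfg = SimConfig(error_sub=0.01, error_ins=0.01, error_del=0.01)
    from .simulate import _mutate
    deviations = []
    unmapped = 0
    for i in range(n_reads):
        length = int(rng.integers(300, 801))
        start = int(rng.integers(0, target_len - length + 1))
        frag = target[start:start + length]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        read_seq = _mutate(rng, frag, cfg)
        recs = map_read(FastqRead(f"r{i}", read_seq), index, params)
        if not recs:
            unmapped += 1
            continue
        rec = recs[0]
        o_start, o_end = smith_waterman_interval(read_seq, target, params)
        deviations.append(max(abs(rec.t_start - o_start),
                              abs(rec.t_end - o_end)))
    return {"n_reads": n_reads, "n_mapped": n_reads - unmapped,
            "max_endpoint_deviation": max(deviations) if deviations else None,
            "mean_endpoint_deviation": float(np.mean(deviations))
            if deviations else None}


# ---------------------------------------------------------------------------
# Capture-efficiency estimation
# ---------------------------------------------------------------------------

def run_capture_study(seed: int, n_reads: int = 3000,
                      on_target_share: float = 0.15) -> dict:
    """Capture-efficiency estimate on a pool with a configured on-target share.

    On-target reads (insert-captured precise-KI library) and pure background
    reads are mixed binomially at ``on_target_share``; the two-pass capture
    efficiency should recover the realized share.
    """
    project = demo_project(seed)
    haps_on, _ = _fusion_project_haplotypes(project)
    # background drawn from the non-target chromosome so it carries no
    # transgene homology (arms would otherwise count as capture signal)
    haps_bg = [Haplotype("background", "wild_type",
                         {"chr2": project.genome["chr2"]}, 1.0)]
    rng = np.random.default_rng(seed * 13 + 5)
    n_on = int(rng.binomial(n_reads, on_target_share))
    capture_on = CaptureModel(p_on=1.0, p_bg=0.0, min_overlap=400)
    capture_bg = CaptureModel(p_on=1.0, p_bg=1.0, min_overlap=50)
    cfg_on = SimConfig(seed=seed * 13 + 6, n_reads=n_on, sample="on",
                       fragmentation="shear", frag_mean=3000, frag_sd=1200,
                       capture=capture_on)
    cfg_bg = SimConfig(seed=seed * 13 + 7, n_reads=n_reads - n_on, sample="bg",
                       fragmentation="shear", frag_mean=3000, frag_sd=1200,
                       capture=capture_bg)
    reads_on, _ = simulate_reads(haps_on, cfg_on)
    reads_bg, _ = simulate_reads(haps_bg, cfg_bg)
    reads = reads_on + reads_bg
    from .align import capture_efficiency, two_pass_map
    result = two_pass_map(reads, project.refs.transgene, project.genome)
    return {"configured_share": on_target_share,
            "realized_share": n_on / n_reads,
            "estimate": capture_efficiency(result),
            "n_reads": n_reads}
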