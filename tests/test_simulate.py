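"""Edited-genome construction and capture-enriched read simulation."""

import numpy as np
import pytest

from lockseq.constructs import ITR_CANONICAL
from lockseq.seq import revcomp
from lockseq.simulate import (CaptureModel, EditOutcomeSpec, SimConfig,
                              SimulationError, build_edited_genome,
                              plan_mixed_run, simulate_reads)
from lockseq.studies import demo_project, simulate_sample


@pytest.fixture(scope="module")
def proj():
    return demo_project(23)


def build(proj, outcomes, seed=0):
    return build_edited_genome(proj.genome, proj.target_locus, proj.expected,
                               outcomes, locus_name="locus",
                               rng=np.random.default_rng(seed))


class TestBuildEditedGenome:
    def test_precise_plus_wt_gives_two_alleles_with_expected_sequence(self, proj):
        haps = build(proj, [EditOutcomeSpec("precise_ki", 0.5),
                            EditOutcomeSpec("wild_type", 0.5)])
        assert len(haps) == 2
        ki = haps[0].seqs["chr1"]
        s = proj.target_locus.start
        assert ki[s:s + len(proj.expected)] == proj.expected.sequence
        assert haps[1].seqs["chr1"] == proj.genome["chr1"]

    def test_partial_ki_allele_is_shorter_by_exactly_432(self, proj):
        ps = proj.payload_span[0]
        haps = build(proj, [EditOutcomeSpec("partial_ki", 1.0,
                                            {"missing": (ps, ps + 432)})])
        precise_len = len(proj.genome["chr1"]) - len(proj.target_locus) \
            + len(proj.expected)
        assert len(haps[0].seqs["chr1"]) == precise_len - 432

    def test_random_integration_with_itr_flanks_cassette(self, proj):
        haps = build(proj, [EditOutcomeSpec(
            "random_integration", 1.0,
            {"chrom": "chr2", "position": 15000, "itr_retained": True})])
        chr2 = haps[0].seqs["chr2"]
        assert chr2[15000:15000 + len(ITR_CANONICAL)] == ITR_CANONICAL
        insert_len = haps[0].truth["ri"]["length"]
        assert chr2[15000 + insert_len - len(ITR_CANONICAL):15000 + insert_len] \
            == ITR_CANONICAL

    def test_concatemer_topologies_orient_copies(self, proj):
        for topo, check in [
            ("head_to_tail", lambda c, seg: seg == c + c),
            ("tail_to_tail", lambda c, seg: seg == c + revcomp(c)),
            ("head_to_head", lambda c, seg: seg == revcomp(c) + c),
        ]:
            haps = build(proj, [EditOutcomeSpec("concatemer", 1.0,
                                                {"copies": 2, "topology": topo})])
            hap = haps[0]
            c_s, c_e = hap.truth["concatemer"]["cassette"]
            cassette = proj.expected.sequence[c_s:c_e]
            gs = proj.target_locus.start + c_s
            seg = hap.seqs["chr1"][gs:gs + 2 * len(cassette)]
            assert check(cassette, seg), topo

    def test_fraction_sum_and_copy_count_validation(self, proj):
        with pytest.raises(SimulationError, match="sum to 1"):
            build(proj, [EditOutcomeSpec("wild_type", 0.6)])
        with pytest.raises(SimulationError, match="copy count"):
            EditOutcomeSpec("concatemer", 1.0, {"copies": 1})

    def test_ri_position_outside_genome_rejected(self, proj):
        with pytest.raises(SimulationError, match="outside genome"):
            build(proj, [EditOutcomeSpec("random_integration", 1.0,
                                         {"chrom": "chr2", "position": 10**7})])


class TestSimulateReads:
    def test_read_and_truth_count_conservation(self, proj):
        haps = build(proj, [EditOutcomeSpec("wild_type", 1.0)])
        cfg = SimConfig(seed=7, n_reads=200)
        reads, truth = simulate_reads(haps, cfg)
        assert len(reads) == 200 and len(truth) == 200
        assert truth["read_id"].is_unique

    def test_error_free_reads_are_exact_substrings(self, proj):
        haps = build(proj, [EditOutcomeSpec("precise_ki", 1.0)])
        cfg = SimConfig(seed=3, n_reads=60, error_sub=0, error_ins=0,
                        error_del=0)
        reads, truth = simulate_reads(haps, cfg)
        by_name = {h.name: h for h in haps}
        for read, row in zip(reads, truth.itertuples()):
            seq = read.sequence
            if row.strand == "-":
                seq = revcomp(seq)
            frag = seq[len(cfg.index1):-len(cfg.index2)]
            # independent containment oracle: plain substring search
            assert frag in by_name[row.allele].seqs[row.chrom]

    def test_pure_capture_filter_keeps_only_probe_overlaps(self, proj):
        haps = build(proj, [EditOutcomeSpec("precise_ki", 1.0)])
        cfg = SimConfig(seed=5, n_reads=80,
                        capture=CaptureModel(p_on=1.0, p_bg=0.0, min_overlap=50))
        reads, truth = simulate_reads(haps, cfg)
        assert truth["on_target"].all()
        intervals = haps[0].capture_intervals
        for row in truth.itertuples():
            overlap = max((min(row.end, e) - max(row.start, s)
                           for s, e in intervals.get(row.chrom, [])), default=0)
            assert overlap >= 50

    def test_same_seed_gives_byte_identical_output(self, proj):
        haps = build(proj, [EditOutcomeSpec("wild_type", 1.0)])
        cfg = SimConfig(seed=11, n_reads=50, chimera_rate=0.05)
        r1, t1 = simulate_reads(haps, cfg)
        r2, t2 = simulate_reads(haps, cfg)
        assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]
        assert t1.equals(t2)

    def test_chimera_count_is_binomial(self, proj):
        haps = build(proj, [EditOutcomeSpec("wild_type", 1.0)])
        n, rate, seeds = 1000, 0.02, 10
        counts = []
        for s in range(seeds):
            cfg = SimConfig(seed=100 + s, n_reads=n, chimera_rate=rate)
            _, truth = simulate_reads(haps, cfg)
            counts.append(int(truth["chimera"].sum()))
        expected = n * rate
        sd = np.sqrt(n * rate * (1 - rate) / seeds)
        assert abs(np.mean(counts) - expected) <= 3 * sd

    def test_fragment_length_mean_within_5_percent(self, proj):
        haps = build(proj, [EditOutcomeSpec("wild_type", 1.0)])
        cfg = SimConfig(seed=9, n_reads=5000, frag_mean=1500, frag_sd=500,
                        capture=CaptureModel(p_on=1.0, p_bg=1.0))
        _, truth = simulate_reads(haps, cfg)
        mean = (truth["end"] - truth["start"]).mean()
        assert abs(mean - 1500) / 1500 < 0.05

    def test_empty_allele_set_rejected(self):
        with pytest.raises(SimulationError):
            simulate_reads([], SimConfig(n_reads=10))


class TestMixedRun:
    def _samples(self, proj, chimera=0.0):
        haps = build(proj, [EditOutcomeSpec("precise_ki", 1.0)])
        cfg_a = SimConfig(seed=1, n_reads=150, sample="a",
                          index1="ACGTACGTACGT", index2="TGCATGCATGCA")
        cfg_b = SimConfig(seed=2, n_reads=150, sample="b",
                          index1="GGTTAACCGGTT", index2="AACCGGTTAACC")
        return [(haps, cfg_a), (haps, cfg_b)]

    def test_single_sample_rejected(self, proj):
        with pytest.raises(SimulationError):
            plan_mixed_run(self._samples(proj)[:1])

    def test_duplicate_barcodes_rejected(self, proj):
        samples = self._samples(proj)
        dup = [(samples[0][0], samples[0][1]), (samples[0][0], samples[0][1])]
        with pytest.raises(SimulationError, match="duplicate barcode"):
            plan_mixed_run(dup)

    def test_no_chimeras_means_no_cross_sample_reads(self, proj):
        reads, truth = plan_mixed_run(self._samples(proj), chimera_rate=0.0,
                                      seed=5)
        assert not truth["chimera"].any()
        assert (truth["chimera_partner"] == "").all()

    def test_cross_sample_chimera_rate_is_binomial(self, proj):
        reads, truth = plan_mixed_run(self._samples(proj), chimera_rate=0.05,
                                      seed=6)
        n = len(truth)
        k = int(truth["chimera"].sum())
        sd = np.sqrt(n * 0.05 * 0.95)
        assert abs(k - n * 0.05) <= 3 * sd
        partners = truth.loc[truth["chimera"], "chimera_partner"]
        own = truth.loc[truth["chimera"], "sample"]
        assert all(p.split("@")[-1] != s for p, s in zip(partners, own))
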