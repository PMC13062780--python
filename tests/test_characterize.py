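"""Depth analytics, junction clustering, ITR scan, fusion rate, consensus."""

import numpy as np
import pytest

from lockseq.align import AlignmentRecord, MinimizerIndex, map_reads
from lockseq.characterize import (CallParams, CharacterizeError,
                                  classify_alleles, call_junctions,
                                  consensus_region, depth_profile, detect_itr,
                                  estimate_fusion_rate, top_depth_windows)
from lockseq.constructs import ITR_CANONICAL
from lockseq.seq import FastqRead, Interval, random_dna, revcomp
from lockseq.simulate import SimConfig, _mutate


def rec(read_id, t_start, t_end, target="ref", q_start=0, strand="+",
        suppl=False, ops=None):
    length = t_end - t_start
    return AlignmentRecord(read_id=read_id, q_start=q_start,
                           q_end=q_start + length, target=target,
                           t_start=t_start, t_end=t_end, strand=strand,
                           ops=ops or [("=", length)], identity=1.0,
                           score=2.0 * length, is_supplementary=suppl)


class TestDepth:
    def test_single_read_covers_its_interval_only(self):
        track = depth_profile([rec("r1", 10, 20)], "ref", 40, 5)
        assert list(np.nonzero(track.raw)[0]) == list(range(10, 20))
        assert track.normalized[15] == pytest.approx(1 / 5)

    def test_no_alignments_gives_all_zero_track(self):
        track = depth_profile([], "ref", 30, 3)
        assert not track.raw.any()

    def test_deletions_in_the_read_do_not_cover(self):
        ops = [("=", 5), ("D", 3), ("=", 5)]
        track = depth_profile([rec("r", 0, 13, ops=ops)], "ref", 20, 1)
        assert list(track.raw[:13]) == [1] * 5 + [0] * 3 + [1] * 5

    def test_normalization_identity_is_exact(self):
        records = [rec("a", 0, 11), rec("b", 4, 19),
                   rec("c", 2, 12, ops=[("=", 4), ("D", 2), ("=", 4)])]
        total_mapped = 3
        track = depth_profile(records, "ref", 30, total_mapped)
        aligned_bases = sum(e - s for r in records
                            for s, e in r.aligned_target_runs())
        assert track.normalized.sum() * total_mapped == pytest.approx(aligned_bases)
        assert track.normalized.sum() == pytest.approx(aligned_bases / total_mapped)


class TestTopWindows:
    def test_concentrated_depth_ranks_its_window_first(self):
        tracks = {"chr": depth_profile([rec("r", 45000, 46000, target="chr")], "chr", 100000, 1)}
        windows = top_depth_windows(tracks, window=20000, k=10)
        assert windows[0][:3] == ("chr", 40000, 60000)

    def test_excluded_target_window_disappears(self):
        tracks = {"chr": depth_profile([rec("r", 45000, 46000, target="chr")], "chr", 100000, 1)}
        windows = top_depth_windows(tracks, window=20000, k=10,
                                    exclude=Interval("chr", 44000, 47000))
        assert windows == []


class TestJunctions:
    def _split_read(self, rid, g_pos, t_pos, frag_shift=0):
        """A read: genome segment then transgene segment, blunt junction."""
        g = rec(rid, g_pos - 400 - frag_shift, g_pos, target="chr",
                q_start=0)
        t = rec(rid, t_pos, t_pos + 400 + frag_shift, target="tg",
                q_start=400 + frag_shift)
        return {rid: [t]}, {rid: [g]}

    def test_identical_junction_from_five_reads_clusters_with_support_5(self):
        pass1, pass2 = {}, {}
        for i in range(5):
            p1, p2 = self._split_read(f"r{i}", 5000, 100, frag_shift=10 * i)
            pass1.update(p1)
            pass2.update(p2)
        clusters = call_junctions(pass1, pass2, tolerance=50, min_seg=200)
        assert len(clusters) == 1
        assert clusters[0].support == 5
        assert clusters[0].spread == 0
        assert clusters[0].genome_pos == 5000

    def test_scattered_junctions_do_not_cluster(self):
        pass1, pass2 = {}, {}
        for i in range(5):
            p1, p2 = self._split_read(f"r{i}", 5000 + 1000 * i, 100 + 1000 * i)
            pass1.update(p1)
            pass2.update(p2)
        clusters = call_junctions(pass1, pass2, tolerance=50, min_seg=200)
        assert len(clusters) == 5
        assert all(c.support == 1 for c in clusters)

    def test_exact_duplicate_fragments_counted_once(self):
        pass1, pass2 = {}, {}
        for i in range(4):  # same fragment boundaries both sides: PCR dups
            p1, p2 = self._split_read(f"dup{i}", 5000, 100, frag_shift=0)
            pass1.update(p1)
            pass2.update(p2)
        clusters = call_junctions(pass1, pass2, tolerance=50, min_seg=200)
        assert clusters[0].support == 1


class TestItr:
    def test_full_canonical_itr_detected_with_high_identity(self, rng):
        read = random_dna(rng, 300) + ITR_CANONICAL + random_dna(rng, 300)
        matches = detect_itr({"r": read}, {"canonical": ITR_CANONICAL})
        assert matches and matches[0].identity >= 0.99
        assert matches[0].variant == "canonical"
        assert abs(matches[0].start - 300) <= 2

    def test_itr_free_read_yields_no_match(self, rng):
        matches = detect_itr({"r": random_dna(rng, 600)},
                             {"canonical": ITR_CANONICAL})
        assert matches == []

    def test_errored_itr_detected_at_90_percent_identity(self, rng):
        cfg = SimConfig(error_sub=0.01, error_ins=0.01, error_del=0.01)
        read = random_dna(rng, 200) + _mutate(rng, ITR_CANONICAL, cfg) \
            + random_dna(rng, 200)
        matches = detect_itr({"r": read}, {"canonical": ITR_CANONICAL},
                             min_identity=0.9)
        assert matches

    def test_empty_itr_refs_rejected(self, rng):
        with pytest.raises(CharacterizeError):
            detect_itr({"r": "ACGT"}, {})


class TestFusionRate:
    def test_one_in_ten_dual_insert_reads_gives_10_percent(self):
        aln = {f"r{i}": [rec(f"r{i}", 0, 400, target="insertA")]
               for i in range(9)}
        aln["r9"] = [rec("r9", 0, 400, target="insertA"),
                     rec("r9", 0, 400, target="insertB", q_start=400,
                         suppl=True)]
        rate, fused = estimate_fusion_rate(aln, ("insertA", "insertB"))
        assert rate == pytest.approx(0.10)
        assert fused == ["r9"]

    def test_identical_insert_references_rejected(self):
        with pytest.raises(CharacterizeError):
            estimate_fusion_rate({}, ("insertA", "insertA"))

    def test_no_dual_mapping_reads_gives_zero(self):
        aln = {"r0": [rec("r0", 0, 400, target="insertA")]}
        assert estimate_fusion_rate(aln, ("insertA", "insertB"))[0] == 0.0


class TestConsensus:
    def test_identical_error_free_reads_reproduce_the_source(self, rng):
        source = random_dna(rng, 800)
        index = MinimizerIndex({"ref": source})
        reads = [FastqRead(f"r{i}", source[50:750]) for i in range(10)]
        aln = map_reads(reads, index)
        records = [r for recs in aln.values() for r in recs]
        seqs = {r.id: r.sequence for r in reads}
        cons = consensus_region(seqs, records, (100, 700), source, min_reads=5)
        assert cons == source[100:700]

    def test_too_few_reads_is_a_no_call(self, rng):
        source = random_dna(rng, 800)
        index = MinimizerIndex({"ref": source})
        reads = [FastqRead(f"r{i}", source[50:750]) for i in range(3)]
        aln = map_reads(reads, index)
        records = [r for recs in aln.values() for r in recs]
        seqs = {r.id: r.sequence for r in reads}
        assert consensus_region(seqs, records, (100, 700), source,
                                min_reads=5) is None

    def test_errored_reads_yield_accurate_consensus(self, rng):
        source = random_dna(rng, 2000)
        index = MinimizerIndex({"ref": source})
        cfg = SimConfig(error_sub=0.01, error_ins=0.01, error_del=0.01)
        reads = [FastqRead(f"r{i}", _mutate(rng, source, cfg))
                 for i in range(20)]
        aln = map_reads(reads, index)
        records = [r for recs in aln.values() for r in recs]
        seqs = {r.id: r.sequence for r in reads}
        cons = consensus_region(seqs, records, (100, 1900), source, min_reads=5)
        truth = source[100:1900]
        matches = sum(a == b for a, b in zip(cons, truth))
        assert matches / len(truth) >= 0.995


def test_region_read_extraction_selects_overlapping_reads_only():
    from lockseq.characterize import extract_region_reads

    aln = {"in": [rec("in", 45000, 46000, target="chr")],
           "out": [rec("out", 80000, 81000, target="chr")],
           "other": [rec("other", 45000, 46000, target="chrX")]}
    reads = {"in": "A" * 10, "out": "A" * 10, "other": "A" * 10}
    ids = extract_region_reads(aln, reads, Interval("chr", 40000, 60000))
    assert ids == ["in"]


def test_no_spanning_reads_is_a_genotype_no_call():
    from lockseq.characterize import AlleleModels
    from lockseq.constructs import AlleleMap

    models = AlleleModels(ki=AlleleMap("ki", "ACGT" * 300),
                          wt=AlleleMap("wt", "ACGT" * 200),
                          insert=(400, 800), cut=400)
    classes, genotype = classify_alleles({}, {}, models)
    assert genotype.no_call and genotype.call == "no-call"
    assert classes == []
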