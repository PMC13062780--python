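"""Capture probe panel layout, GC flagging and throughput arithmetic."""

import numpy as np
import pytest

from lockseq.probes import (FORWARD_TAIL, REVERSE_TAIL, ProbeDesignError,
                            SpacingAdvisory, design_asymmetric_pcr_probes,
                            design_tiling_panel, flag_gc_rich, throughput_plan)
from lockseq.seq import random_dna, revcomp


def layout_oracle(target_len, probe_len, spacing):
    """Independent arithmetic layout: regular starts, back-shifted tail."""
    period = probe_len + spacing
    starts = []
    s = 0
    while s + probe_len <= target_len:
        starts.append(s)
        s += period
    if starts and starts[-1] + probe_len < target_len:
        starts[-1] = target_len - probe_len
    return starts


class TestTilingPanel:
    def test_1450_target_layout_matches_arithmetic_oracle(self, rng):
        target = random_dna(rng, 1450)
        panel = design_tiling_panel(target, probe_len=125, spacing=20)
        starts = [p.start for p in panel.probes]
        assert starts == layout_oracle(1450, 125, 20)
        assert len(panel) == 10
        assert starts[:3] == [0, 145, 290]
        assert panel.probes[-1].end == 1450  # back-shifted, uniform length
        assert all(p.end - p.start == 125 for p in panel.probes)

    def test_zero_spacing_probes_abut_exactly(self, rng):
        target = random_dna(rng, 1000)
        panel = design_tiling_panel(target, probe_len=100, spacing=0)
        for a, b in zip(panel.probes, panel.probes[1:-1]):
            assert b.start == a.end

    def test_alternating_strand_probes_are_reverse_complemented(self, rng):
        target = random_dna(rng, 600)
        panel = design_tiling_panel(target, probe_len=100, spacing=20,
                                    strand="alternating")
        strands = [p.strand for p in panel.probes]
        assert strands == ["+", "-"] * (len(strands) // 2) + \
            (["+"] if len(strands) % 2 else [])
        for p in panel.probes:
            sub = target[p.start:p.end]
            assert p.sequence == (sub if p.strand == "+" else revcomp(sub))

    def test_probe_sequence_fidelity_property(self, rng):
        target = random_dna(rng, 2000)
        panel = design_tiling_panel(target, probe_len=125, spacing=20,
                                    strand="double")
        for p in panel.probes:
            sub = target[p.start:p.end]
            assert p.sequence == (sub if p.strand == "+" else revcomp(sub))

    def test_panel_coverage_gap_never_exceeds_spacing(self, rng):
        for tlen, plen, sp in [(1450, 125, 20), (900, 125, 0), (3000, 120, 30)]:
            target = random_dna(rng, tlen)
            panel = design_tiling_panel(target, probe_len=plen, spacing=sp)
            assert panel.max_gap_to_probe(tlen) <= sp

    def test_short_target_yields_single_full_probe(self, rng):
        target = random_dna(rng, 80)
        panel = design_tiling_panel(target, probe_len=125, spacing=20)
        assert len(panel) == 1 and panel.probes[0].sequence == target
        with pytest.raises(ProbeDesignError):
            design_tiling_panel(target, probe_len=125, short_target="error")

    def test_wide_spacing_emits_capture_loss_advisory(self, rng):
        target = random_dna(rng, 3000)
        with pytest.warns(SpacingAdvisory):
            design_tiling_panel(target, probe_len=125, spacing=500)

    def test_gc_rich_probes_get_internal_biotin_recommendation(self, rng):
        target = random_dna(rng, 300) + "GC" * 40 + random_dna(rng, 300)
        panel = design_tiling_panel(target, probe_len=125, spacing=20)
        over_gc = [p for p in panel.probes
                   if any(p.start < fe and p.end > fs
                          for fs, fe in panel.flagged_gc_intervals)]
        assert over_gc
        assert all(p.biotin_mode == "internal_enriched" for p in over_gc)


def at_context(rng, n):
    """A/T-only context so flagged-interval trimming is unambiguous."""
    return "".join("AT"[i] for i in rng.integers(0, 2, size=n))


class TestGcFlagging:
    def test_60_nt_gc_run_in_at_context_flagged_exactly(self, rng):
        seq = at_context(rng, 200) + "G" * 30 + "C" * 30 + at_context(rng, 200)
        flagged = flag_gc_rich(seq, gc_threshold=0.70, window=50)
        assert flagged == [(200, 260)]

    def test_uniform_50_percent_gc_never_flagged(self):
        assert flag_gc_rich("GA" * 300, gc_threshold=0.70, window=50) == []

    def test_49_nt_run_fails_the_length_rule(self, rng):
        seq = at_context(rng, 200) + "G" * 49 + at_context(rng, 200)
        assert flag_gc_rich(seq, gc_threshold=0.70, window=50) == []

    def test_n_bases_count_as_non_gc(self):
        assert flag_gc_rich("N" * 200, gc_threshold=0.70, window=50) == []


class TestAsymmetricPcr:
    def test_1300_target_fits_four_140_to_270_amplicons(self, rng):
        target = random_dna(rng, 1300)
        amps = design_asymmetric_pcr_probes(target, amplicon_spacing=300,
                                            min_len=140, max_len=270)
        assert len(amps) == 4
        assert [a.start for a in amps] == [0, 300, 600, 900]
        assert all(140 <= a.end - a.start <= 270 for a in amps)

    def test_spacing_larger_than_target_rejected(self, rng):
        with pytest.raises(ProbeDesignError):
            design_asymmetric_pcr_probes(random_dna(rng, 200),
                                         amplicon_spacing=300)

    def test_forward_primer_carries_the_universal_tail_5prime(self, rng):
        target = random_dna(rng, 1300)
        for a in design_asymmetric_pcr_probes(target):
            assert a.forward_primer.startswith(FORWARD_TAIL)
            assert a.reverse_primer.startswith(REVERSE_TAIL)
            assert a.forward_primer[len(FORWARD_TAIL):] == \
                target[a.start:a.start + 20]
            assert a.probe_sequence == FORWARD_TAIL + target[a.start:a.end] \
                + revcomp(REVERSE_TAIL)


class TestThroughput:
    @pytest.mark.parametrize("reads,eff,samples,expected", [
        (1_000_000, 0.10, 100, 1000.0),
        (30_000_000, 0.10, 100, 30000.0),
        (500, 1.0, 1, 500.0),
    ])
    def test_reads_per_sample_arithmetic(self, reads, eff, samples, expected):
        assert throughput_plan(reads, eff, samples) == expected

    def test_nonpositive_inputs_rejected(self):
        for args in [(0, 0.1, 10), (100, 0, 10), (100, 0.1, 0)]:
            with pytest.raises(ProbeDesignError):
                throughput_plan(*args)
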