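"""Donor/guide modelling and in-silico sequential HDR reconstruction."""

import re

import numpy as np
import pytest

from lockseq.constructs import (AlleleMap, Annotation, ConstructError,
                                DonorSpec, GuideTarget, HomologyArm,
                                ITR_CANONICAL, ReconstructionError,
                                find_guide_sites, load_construct_config,
                                reconstruct_sequential_ki, validate_donor)
from lockseq.seq import random_dna, revcomp


def make_guide(proto="ACGTACGTTGCACCGGTTAA", name="g", cut_offset=3):
    return GuideTarget(name, proto, "NGG", cut_offset)


def regex_site_oracle(proto, seq):
    """Independent brute-force scan for proto+NGG on both strands."""
    hits = []
    for m in re.finditer(f"(?={re.escape(proto)}[ACGT]GG)", seq):
        hits.append((m.start(), "+"))
    rc = revcomp(seq)
    for m in re.finditer(f"(?={re.escape(proto)}[ACGT]GG)", rc):
        hits.append((len(seq) - m.start() - len(proto), "-"))
    return sorted(hits)


class TestGuideSites:
    def test_constructed_forward_hit_and_cut_coordinate(self, rng):
        proto = random_dna(rng, 20)
        x = random_dna(rng, 57)
        seq = x + proto + "AGG" + random_dna(rng, 40)
        sites = find_guide_sites(make_guide(proto), seq)
        assert [(s.position, s.strand) for s in sites] == [(len(x), "+")]
        assert sites[0].cut == len(x) + 17

    def test_absent_protospacer_yields_no_sites(self, rng):
        proto = random_dna(rng, 20)
        seq = random_dna(rng, 300)
        assert regex_site_oracle(proto, seq) == []
        assert find_guide_sites(make_guide(proto), seq) == []

    def test_reverse_strand_hit_matches_regex_oracle(self, rng):
        proto = random_dna(rng, 20)
        seq = random_dna(rng, 30) + revcomp(proto + "TGG") + random_dna(rng, 30)
        sites = find_guide_sites(make_guide(proto), seq)
        oracle = regex_site_oracle(proto, seq)
        assert [(s.position, s.strand) for s in sites] == oracle
        assert sites[0].strand == "-"
        # cut 3 nt 5' of the PAM on the protospacer strand
        assert sites[0].cut == sites[0].position + 3

    @pytest.mark.parametrize("n_decoys", [1, 3])
    def test_both_strand_scan_agrees_with_oracle(self, rng, n_decoys):
        proto = random_dna(rng, 20)
        seq = random_dna(rng, 80)
        for _ in range(n_decoys):
            ins = proto + "AGG" if rng.random() < 0.5 else revcomp(proto + "CGG")
            seq = seq + ins + random_dna(rng, 40)
        got = sorted((s.position, s.strand)
                     for s in find_guide_sites(make_guide(proto), seq))
        assert got == regex_site_oracle(proto, seq)

    def test_n_in_subject_never_matches(self):
        proto = "A" * 20
        assert find_guide_sites(make_guide(proto), "A" * 20 + "NGG") == []

    def test_malformed_guide_rejected(self):
        with pytest.raises(ConstructError):
            GuideTarget("bad", "ACGT", "NGG")
        with pytest.raises(ConstructError):
            GuideTarget("bad", "A" * 20, "NGA")


def make_donor(rng, arm_len=800, payload_len=2000, guide=None):
    left = HomologyArm("left", random_dna(rng, arm_len))
    right = HomologyArm("right", random_dna(rng, arm_len))
    payload = random_dna(rng, payload_len)
    return DonorSpec("d", ITR_CANONICAL, ITR_CANONICAL, left, right,
                     (("payload", payload),), embedded_guide=guide)


class TestValidateDonor:
    def test_guide_site_in_payload_is_a_violation(self, rng):
        guide = make_guide(random_dna(rng, 20))
        left = HomologyArm("left", random_dna(rng, 800))
        right = HomologyArm("right", random_dna(rng, 800))
        payload = random_dna(rng, 500) + guide.protospacer + "TGG" + random_dna(rng, 500)
        donor = DonorSpec("d", ITR_CANONICAL, ITR_CANONICAL, left, right,
                          (("payload", payload),))
        report = validate_donor(donor, guide)
        assert "guide_site_in_donor" in {c for c, _ in report.violations}

    def test_payload_size_boundary_is_exact_at_4700(self, rng):
        guide = make_guide(random_dna(rng, 20))
        itr_total = 2 * len(ITR_CANONICAL)
        for payload_len, oversize in [(4700 - 1600 - itr_total, False),
                                      (4701 - 1600 - itr_total, True)]:
            donor = make_donor(rng, arm_len=800, payload_len=payload_len)
            assert len(donor) == (4701 if oversize else 4700)
            report = validate_donor(donor, guide)
            assert ("payload_oversize" in {c for c, _ in report.violations}) == oversize

    def test_clean_donor_passes_with_no_findings(self, rng):
        guide = make_guide(random_dna(rng, 20))
        donor = make_donor(rng, arm_len=800, payload_len=2000)
        report = validate_donor(donor, guide)
        assert report.ok and not report.warnings

    def test_arm_length_warning_outside_recommended_range(self, rng):
        guide = make_guide(random_dna(rng, 20))
        donor = make_donor(rng, arm_len=300, payload_len=500)
        report = validate_donor(donor, guide)
        assert report.ok
        assert "arm_length_warning" in {c for c, _ in report.warnings}


def string_surgery_oracle(locus_seq, left, payload, right):
    """Independent reconstruction: replace [arm..arm] span via str.find."""
    ls = locus_seq.find(left)
    rs = locus_seq.find(right)
    return locus_seq[:ls] + left + payload + right + locus_seq[rs + len(right):]


class TestReconstruction:
    def _toy(self, rng, locus_len=200, arm=30, payload_len=50):
        guide = make_guide(random_dna(rng, 20))
        locus_seq = (random_dna(rng, locus_len // 2 - 20)
                     + guide.protospacer + "AGG"
                     + random_dna(rng, locus_len // 2 - 3))
        cut = find_guide_sites(guide, locus_seq)[0].cut
        left = HomologyArm("left", locus_seq[cut - arm:cut])
        right = HomologyArm("right", locus_seq[cut:cut + arm])
        payload = random_dna(rng, payload_len)
        donor = DonorSpec("d1", ITR_CANONICAL, ITR_CANONICAL, left, right,
                          (("payload", payload),))
        locus = AlleleMap("locus", locus_seq)
        return guide, donor, locus, payload

    def test_single_donor_matches_string_surgery_oracle(self, rng):
        guide, donor, locus, payload = self._toy(rng)
        allele = reconstruct_sequential_ki(locus, [guide], [donor])
        assert len(allele) == 250
        assert allele.sequence == string_surgery_oracle(
            locus.sequence, donor.left_arm.sequence, payload,
            donor.right_arm.sequence)
        assert [a.label for a in allele.annotations] == \
            ["locus", "left_arm", "payload", "right_arm", "locus"]

    def test_guide_site_destroyed_in_product(self, rng):
        guide, donor, locus, _ = self._toy(rng)
        allele = reconstruct_sequential_ki(locus, [guide], [donor])
        assert find_guide_sites(guide, allele.sequence) == []

    def test_two_donor_sequential_insertion(self, rng):
        guide1, donor1, locus, payload1 = self._toy(rng, locus_len=400, arm=40,
                                                    payload_len=80)
        # donor1 embeds guide2's site at the 3' end of its payload
        guide2 = make_guide(random_dna(rng, 20), name="g2")
        payload1b = payload1 + guide2.protospacer + "AGG"
        donor1 = DonorSpec("d1", ITR_CANONICAL, ITR_CANONICAL,
                           donor1.left_arm, donor1.right_arm,
                           (("payload", payload1b),), embedded_guide=guide2)
        mid = reconstruct_sequential_ki(locus, [guide1], [donor1])
        cut2 = find_guide_sites(guide2, mid.sequence)[0].cut
        left2 = HomologyArm("left", mid.sequence[cut2 - 40:cut2])
        right2 = HomologyArm("right", mid.sequence[cut2:cut2 + 40])
        payload2 = random_dna(rng, 60)
        donor2 = DonorSpec("d2", ITR_CANONICAL, ITR_CANONICAL, left2, right2,
                           (("payload", payload2),))
        final = reconstruct_sequential_ki(locus, [guide1, guide2],
                                          [donor1, donor2])
        oracle_mid = string_surgery_oracle(locus.sequence,
                                           donor1.left_arm.sequence, payload1b,
                                           donor1.right_arm.sequence)
        oracle = string_surgery_oracle(oracle_mid, left2.sequence, payload2,
                                       right2.sequence)
        assert final.sequence == oracle
        assert find_guide_sites(guide2, final.sequence) == []
        assert payload2 in final.sequence

    def test_mismatched_arms_raise_reconstruction_error(self, rng):
        guide, donor, locus, _ = self._toy(rng)
        bad = DonorSpec("d", ITR_CANONICAL, ITR_CANONICAL,
                        HomologyArm("left", random_dna(rng, 30)),
                        donor.right_arm, donor.payload)
        with pytest.raises(ReconstructionError, match="left arm"):
            reconstruct_sequential_ki(locus, [guide], [bad])

    def test_annotations_must_tile_without_gaps(self):
        with pytest.raises(ConstructError):
            AlleleMap("a", "ACGTACGT",
                      [Annotation("x", "x", 0, 3), Annotation("y", "y", 4, 8)])


def test_construct_config_round_trip(tmp_path, rng):
    guide = make_guide(random_dna(rng, 20))
    cfg = tmp_path / "construct.yaml"
    cfg.write_text(f"""
locus:
  name: locus
  sequence: {random_dna(rng, 120)}
guides:
  - name: {guide.name}
    protospacer: {guide.protospacer}
donors:
  - name: d1
    itr5: canonical
    itr3: alternative
    left_arm: {random_dna(rng, 50)}
    right_arm: {random_dna(rng, 50)}
    payload:
      - label: cds
        sequence: {random_dna(rng, 80)}
""")
    loaded = load_construct_config(cfg)
    assert loaded["locus"].name == "locus"
    assert loaded["guides"][0].protospacer == guide.protospacer
    assert loaded["donors"][0].itr5 == ITR_CANONICAL
    assert len(loaded["donors"][0].payload_sequence) == 80


def test_unknown_config_keys_rejected(tmp_path):
    cfg = tmp_path / "c.yaml"
    cfg.write_text("locus: {name: l, sequence: ACGT}\nbogus: 1\n")
    with pytest.raises(ConstructError, match="bogus"):
        load_construct_config(cfg)
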