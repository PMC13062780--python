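"""Models of rAAV donors, guide targets and knock-in alleles.

A knock-in project is described by a genomic locus, one or more SpCas9 guides
and one or more ITR-flanked rAAV donors. Donors carry a payload between two
homology arms; in a sequential multi-donor design, each donor embeds the guide
target site that licenses the *next* insertion, so consecutive HDR events
reconstitute a composite insert larger than one vector's ~4.7 kb capacity.

This module validates donor designs (payload size, homology-arm length range,
absence of the cutting guide's own site from the donor) and reconstructs the
expected composite allele by applying each HDR event in order as exact string
surgery on the intermediate allele. ITRs are never incorporated into the HDR
product: a precise knock-in carries no vector ITR, and ITR retention is
modelled only as an aberrant (random-integration) outcome elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .seq import check_dna, read_fasta, revcomp, write_bed

# Canonical AAV2 inverted terminal repeat and the alternative variant used on
# the opposite end of some vectors (uppercase, 5'->3').
ITR_CANONICAL = (
    "CCTGCAGGCAGCTGCGCGCTCGCTCGCTCACTGAGGCCGCCCGGGCAAAGCCCGGGCGTCGGGCGACCTTTG"
    "GTCGCCCGGCCTCAGTGAGCGAGCGAGCGCGCAGAGAGGGAGTGGCCAACTCCATCACTAGGGGTTCCT"
)
ITR_ALTERNATIVE = (
    "AGGAACCCCTAGTGATGGAGTTGGCCACTCCCTCTCTGCGCGCTCGCTCGCTCACTGAGGCCGGGCGACCAA"
    "AGGTCGCCCGACGCCCGGGCGGCCTCAGTGAGCGAGCGAGCGCGCAGCTGCCTGCAGG"
)
# Primer annealing to the ITR hairpin, used to flag vector-genome retention.
ITR_HAIRPIN_PRIMER = "TGGCCAACTCCATCACTAGG"

#: rAAV packaging capacity in nt, ITRs included.
MAX_DONOR_LENGTH = 4700

#: Recommended homology-arm length range in nt (outside -> warning, not error).
ARM_LENGTH_RANGE = (400, 1200)


class ConstructError(ValueError):
    """Raised for malformed or inconsistent construct descriptions."""


class ReconstructionError(ConstructError):
    """Raised when a sequential-HDR reconstruction cannot be applied."""


@dataclass(frozen=True)
class GuideTarget:
    """An SpCas9 guide: 20 nt protospacer followed by an NGG PAM.

    ``cut_offset`` is the distance (nt) of the blunt cut 5' of the PAM-proximal
    end of the protospacer; the SpCas9 default is 3.
    """

    name: str
    protospacer: str
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        check_dna(self.protospacer, "protospacer", allow_n=False)
        if len(self.protospacer) != 20:
            raise ConstructError(f"protospacer of {self.name!r} must be 20 nt, "
                                 f"got {len(self.protospacer)}")
        if not re.fullmatch("[ACGTN]GG", self.pam):
            raise ConstructError(f"PAM of {self.name!r} must match NGG, got {self.pam!r}")
        if not 0 <= self.cut_offset <= len(self.protospacer):
            raise ConstructError(f"cut_offset of {self.name!r} out of range")


@dataclass(frozen=True)
class GuideSite:
    """One occurrence of a guide target site on a sequence.

    ``position`` is the forward-strand start of the protospacer match;
    ``cut`` is the blunt-cut coordinate on the forward strand.
    """

    position: int
    strand: str
    cut: int


@dataclass(frozen=True)
class HomologyArm:
    side: str  # 'left' | 'right'
    sequence: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ConstructError(f"arm side must be left/right, got {self.side!r}")
        check_dna(self.sequence, f"{self.side} arm", allow_n=False)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length_warning(self) -> bool:
        lo, hi = ARM_LENGTH_RANGE
        return not lo <= len(self) <= hi


@dataclass(frozen=True)
class DonorSpec:
    """An ITR-flanked rAAV donor: left arm, ordered payload segments, right arm.

    ``embedded_guide`` is the guide site the payload creates for the *next*
    donor in a sequential design (None for the last/only donor).
    """

    name: str
    itr5: str
    itr3: str
    left_arm: HomologyArm
    right_arm: HomologyArm
    payload: tuple[tuple[str, str], ...]
    embedded_guide: Optional[GuideTarget] = None

    def __post_init__(self) -> None:
        check_dna(self.itr5, "itr5", allow_n=False)
        check_dna(self.itr3, "itr3", allow_n=False)
        for label, seg in self.payload:
            check_dna(seg, f"payload segment {label!r}", allow_n=False)
        if self.left_arm.side != "left" or self.right_arm.side != "right":
            raise ConstructError(f"donor {self.name!r}: arm sides are swapped")

    @property
    def payload_sequence(self) -> str:
        return "".join(seg for _, seg in self.payload)

    @property
    def insert_sequence(self) -> str:
        """Arm-to-arm HDR product contributed by this donor (no ITRs)."""
        return self.left_arm.sequence + self.payload_sequence + self.right_arm.sequence

    @property
    def full_sequence(self) -> str:
        """The packaged vector genome, ITRs included."""
        return self.itr5 + self.insert_sequence + self.itr3

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass
class Annotation:
    label: str
    source: str
    start: int
    end: int


@dataclass
class AlleleMap:
    """A named allele sequence with provenance annotations tiling it exactly."""

    name: str
    sequence: str
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        check_dna(self.sequence, f"allele {self.name!r}")
        if not self.annotations:
            self.annotations = [Annotation(self.name, self.name, 0, len(self.sequence))]
        self.validate()

    def validate(self) -> None:
        pos = 0
        for ann in self.annotations:
            if ann.start != pos or ann.end < ann.start:
                raise ConstructError(
                    f"annotations of {self.name!r} must tile without gaps/overlap; "
                    f"{ann.label!r} starts at {ann.start}, expected {pos}")
            pos = ann.end
        if pos != len(self.sequence):
            raise ConstructError(f"annotations of {self.name!r} end at {pos}, "
                                 f"sequence length is {len(self.sequence)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def find(self, label: str) -> Annotation:
        for ann in self.annotations:
            if ann.label == label:
                return ann
        raise KeyError(label)

    def to_bed(self, path: str | Path) -> None:
        write_bed(path, ((self.name, a.start, a.end, f"{a.source}:{a.label}")
                         for a in self.annotations))


def _pam_matches(pam_pattern: str, observed: str) -> bool:
    return all(p == "N" or p == o for p, o in zip(pam_pattern, observed))


def find_guide_sites(guide: GuideTarget, sequence: str) -> list[GuideSite]:
    """All protospacer+PAM occurrences on both strands of ``sequence``.

    Returns forward-strand protospacer start positions with the blunt-cut
    coordinate (``cut_offset`` nt 5' of the PAM on the protospacer strand),
    in 0-based forward-strand coordinates. N in the subject never matches.
    """
    check_dna(sequence, "sequence")
    proto, pam, off = guide.protospacer, guide.pam, guide.cut_offset
    plen, pamlen = len(proto), len(pam)
    sites: list[GuideSite] = []
    # forward strand: proto followed by PAM
    start = 0
    while (pos := sequence.find(proto, start)) != -1:
        observed = sequence[pos + plen: pos + plen + pamlen]
        if len(observed) == pamlen and "N" not in observed and _pam_matches(pam, observed):
            sites.append(GuideSite(pos, "+", pos + plen - off))
        start = pos + 1
    # reverse strand: revcomp(PAM)+revcomp(proto) on the forward strand
    rc_proto = revcomp(proto)
    start = 0
    while (pos := sequence.find(rc_proto, start)) != -1:
        observed = sequence[pos - pamlen: pos]
        if len(observed) == pamlen and "N" not in observed and \
                _pam_matches(pam, revcomp(observed)):
            sites.append(GuideSite(pos, "-", pos + off))
        start = pos + 1
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


@dataclass
class ValidationReport:
    """Findings from donor validation; an empty report is a pass."""

    violations: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def codes(self) -> set[str]:
        return {code for code, _ in self.violations} | {code for code, _ in self.warnings}


def validate_donor(donor: DonorSpec, cutting_guide: GuideTarget) -> ValidationReport:
    """Check a donor against the design rules.

    Violations: ``guide_site_in_donor`` (the donor's own cutting guide can
    cleave the packaged vector genome on either strand) and
    ``payload_oversize`` (total vector length above 4.7 kb packaging limit).
    Arm lengths outside the recommended 400-1200 nt range raise the
    ``arm_length_warning`` warning only.
    """
    report = ValidationReport()
    if find_guide_sites(cutting_guide, donor.full_sequence):
        report.violations.append((
            "guide_site_in_donor",
            f"cutting guide {cutting_guide.name!r} has a target site inside donor "
            f"{donor.name!r}; the donor would be cleaved"))
    if len(donor) > MAX_DONOR_LENGTH:
        report.violations.append((
            "payload_oversize",
            f"donor {donor.name!r} is {len(donor)} nt, above the "
            f"{MAX_DONOR_LENGTH} nt rAAV packaging capacity"))
    for arm in (donor.left_arm, donor.right_arm):
        if arm.length_warning:
            report.warnings.append((
                "arm_length_warning",
                f"{arm.side} arm of {donor.name!r} is {len(arm)} nt, outside the "
                f"recommended {ARM_LENGTH_RANGE[0]}-{ARM_LENGTH_RANGE[1]} nt range"))
    return report


def _find_unique(haystack: str, needle: str, what: str) -> int:
    first = haystack.find(needle)
    if first == -1:
        raise ReconstructionError(f"{what} not found in intermediate allele")
    if haystack.find(needle, first + 1) != -1:
        raise ReconstructionError(f"{what} is ambiguous (multiple matches)")
    return first


def _clip_annotations(annotations: list[Annotation], start: int, end: int,
                      shift: int) -> tuple[list[Annotation], list[Annotation]]:
    """Split annotations around the replaced interval [start, end)."""
    left, right = [], []
    for ann in annotations:
        if ann.start < start:
            left.append(Annotation(ann.label, ann.source, ann.start, min(ann.end, start)))
        if ann.end > end:
            right.append(Annotation(ann.label, ann.source,
                                    max(ann.start, end) + shift, ann.end + shift))
    return left, right


def reconstruct_sequential_ki(locus: AlleleMap,
                              guides: list[GuideTarget],
                              donors: list[DonorSpec]) -> AlleleMap:
    """Expected composite allele after 1-3 sequential HDR events.

    Donor ``i`` is applied at guide ``i``'s (unique) cut site on the current
    intermediate allele: the region between the exact matches of its homology
    arms is replaced by ``left_arm + payload + right_arm`` (ITRs excluded).
    The left arm must end at or 5' of the cut and the right arm begin at or
    3' of it. After each step the applied guide's site must be destroyed and,
    if the donor embeds the next guide's site, that site must now exist.
    """
    if len(guides) != len(donors):
        raise ReconstructionError("guides and donors must pair up one-to-one")
    allele = AlleleMap(locus.name, locus.sequence,
                       [Annotation(a.label, a.source, a.start, a.end)
                        for a in locus.annotations])
    for guide, donor in zip(guides, donors):
        sites = find_guide_sites(guide, allele.sequence)
        if not sites:
            raise ReconstructionError(
                f"guide {guide.name!r} has no site in intermediate allele")
        if len(sites) > 1:
            raise ReconstructionError(
                f"guide {guide.name!r} site is ambiguous ({len(sites)} occurrences)")
        cut = sites[0].cut
        left, right = donor.left_arm.sequence, donor.right_arm.sequence
        l_start = _find_unique(allele.sequence, left, f"left arm of donor {donor.name!r}")
        r_start = _find_unique(allele.sequence, right, f"right arm of donor {donor.name!r}")
        l_end, r_end = l_start + len(left), r_start + len(right)
        if l_end > cut:
            raise ReconstructionError(
                f"left arm of donor {donor.name!r} ends at {l_end}, 3' of the cut at {cut}")
        if r_start < cut:
            raise ReconstructionError(
                f"right arm of donor {donor.name!r} begins at {r_start}, 5' of the cut at {cut}")
        replacement = donor.insert_sequence
        shift = len(replacement) - (r_end - l_start)
        before, after = _clip_annotations(allele.annotations, l_start, r_end, shift)
        new_ann = before
        pos = l_start
        segments = ([("left_arm", left)] + [(lbl, s) for lbl, s in donor.payload]
                    + [("right_arm", right)])
        for label, segseq in segments:
            new_ann.append(Annotation(label, donor.name, pos, pos + len(segseq)))
            pos += len(segseq)
        new_ann.extend(after)
        new_seq = allele.sequence[:l_start] + replacement + allele.sequence[r_end:]
        allele = AlleleMap(allele.name, new_seq, new_ann)
        if find_guide_sites(guide, allele.sequence):
            raise ReconstructionError(
                f"guide {guide.name!r} site survives HDR of donor {donor.name!r}; "
                "check arm placement")
        if donor.embedded_guide is not None and \
                not find_guide_sites(donor.embedded_guide, allele.sequence):
            raise ReconstructionError(
                f"donor {donor.name!r} should create a site for "
                f"{donor.embedded_guide.name!r} but none is present")
    return allele


# ---------------------------------------------------------------------------
# Construct description files
# ---------------------------------------------------------------------------

_ITR_ALIASES = {"canonical": ITR_CANONICAL, "alternative": ITR_ALTERNATIVE}


def _resolve_itr(value: str) -> str:
    return _ITR_ALIASES.get(value, value.upper())


def load_construct_config(path: str | Path) -> dict:
    """Load a YAML construct description.

    Schema (all sequences uppercase DNA; FASTA paths are relative to the
    config file)::

        locus:  {name, fasta | sequence}
        guides: [{name, protospacer, pam?, cut_offset?}]
        donors: [{name, itr5, itr3, left_arm, payload: [{label, sequence}],
                  right_arm, embedded_guide?}]

    ``itr5``/``itr3`` accept the aliases ``canonical``/``alternative``.
    Returns {'locus': AlleleMap, 'guides': [GuideTarget], 'donors': [DonorSpec]}.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    unknown = set(cfg) - {"locus", "guides", "donors"}
    if unknown:
        raise ConstructError(f"unknown construct config keys: {sorted(unknown)}")
    loc = cfg["locus"]
    seq = loc.get("sequence")
    if seq is None:
        fasta = read_fasta(path.parent / loc["fasta"])
        seq = next(iter(fasta.values()))
    locus = AlleleMap(loc["name"], seq.upper())
    guides = [GuideTarget(g["name"], g["protospacer"].upper(),
                          g.get("pam", "NGG").upper(), g.get("cut_offset", 3))
              for g in cfg.get("guides", [])]
    by_name = {g.name: g for g in guides}
    donors = []
    for d in cfg.get("donors", []):
        donors.append(DonorSpec(
            name=d["name"],
            itr5=_resolve_itr(d["itr5"]),
            itr3=_resolve_itr(d["itr3"]),
            left_arm=HomologyArm("left", d["left_arm"].upper()),
            right_arm=HomologyArm("right", d["right_arm"].upper()),
            payload=tuple((p["label"], p["sequence"].upper()) for p in d["payload"]),
            embedded_guide=by_name[d["embedded_guide"]] if d.get("embedded_guide") else None,
        ))
    return {"locus": locus, "guides": guides, "donors": donors}
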