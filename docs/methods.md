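# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the order a sample flows through them, followed by what the
synthetic-data generator does and does not emulate.

## Construct model and in-silico sequential HDR

A guide is a 20 nt protospacer followed by an NGG PAM; the blunt cut sits
`cut_offset` nt 5' of the PAM on the protospacer strand (default 3, the
SpCas9 position; configurable because other nucleases differ). Site search
is exact string matching on both strands; N in the subject never matches.

A donor is `ITR5 + left arm + payload + right arm + ITR3`. Validation
enforces two hard rules — the packaged vector may not exceed 4 700 nt and
the donor's own cutting guide must have no site anywhere in the vector on
either strand (a cuttable donor is destroyed before it can template repair)
— and one advisory: arms outside 400–1200 nt get a warning, not an error,
because that range is a design recommendation, not a physical constraint.

Sequential reconstruction applies each (guide, donor) pair in order to the
intermediate allele: the guide's site must be unique; the arms must match
the intermediate exactly (mismatched-arm designs are rejected rather than
fuzzily aligned — reconstruction must be unambiguous); the left arm must
end at or 5' of the cut and the right arm begin at or 3' of it; the region
between the arm matches is replaced by `left arm + payload + right arm`.
ITRs are never incorporated: a precise HDR product carries no vector ITR,
which is exactly why ITR presence at a junction is treated downstream as a
random-integration signature. After each step the applied guide's site must
be gone and the donor-embedded next-guide site (if any) must exist;
violations raise errors instead of producing an allele. Annotations carry
per-segment provenance (donor name + segment label) and always tile the
sequence exactly; they export as BED.

## Read simulation

Each outcome allele is a full haplotype genome. Fragment lengths are
log-normal: tagmentation-style libraries default to mean 1 kb (sd 0.4 kb),
mechanical-shear libraries to mean 8 kb (sd 3 kb). The capture model keeps a
fragment overlapping a probe interval by ≥ `min_overlap` (50 nt) with
probability `p_on` (0.9) and anything else with `p_bg` (0.001); rejected
draws are redrawn, so exactly `n_reads` reads are emitted. Probe intervals
default to the edited locus ± 2 kb (insert, arms and genomic flanks — the
same footprint a real panel tiles) plus any random-integration site ± 2 kb.

Reads are `index1 + fragment + revcomp(index2)`, strand-flipped with
probability 0.5, then error-mutated with independent per-base substitution/
insertion/deletion rates of 2 %/2 %/2 % (≈ 94 % identity, nanopore-like;
all configurable). Errors hit the indexes too — that is what makes exact-
match demultiplexing lossy in practice, as it is on real data. Chimeras are
blunt joins of two independently drawn fragments, so every chimera junction
is unique; in pooled runs (`plan_mixed_run`) the chimera partner is drawn
from a different sample, making the configured rate the cross-library
fusion rate. Mosaicism is per-read multinomial sampling over allele
fractions. Qualities are a constant Q12 because nothing downstream uses
them. Identical seed + config gives byte-identical output.

Coordinate bookkeeping restriction: a simulated random integration on the
target chromosome must lie 3' of the target locus so truth and probe
intervals lift unambiguously; integrations on other chromosomes are
unrestricted.

## Demultiplexing

A read is assigned to a sample iff each of that sample's two indexes occurs
exactly once in the read — searched as given and reverse-complemented,
with the occurrence required within 250 nt of a read end — and no other
sample's pair also matches. Occurrence counting scans the whole read: an
index embedded mid-read marks a chimera or adapter concatemer, and such
reads are excluded as `multi_match`. Reads lacking an index are
`missing_index`; reads matching several samples are `ambiguous_sample`.
There is no mismatch rescue and no trimming; assigned + excluded always
equals input. The 250 nt window is a declared default (the assignment rule
itself does not fix a search region); barcodes should avoid
self-reverse-complementary or pair-complementary sequences, which collapse
the two orientations of the occurrence count.

## Alignment

The built-in aligner follows the standard minimizer seed–chain–extend
recipe. Canonical k-mers (k = 15, the min of a k-mer and its reverse
complement) are ranked by an invertible 64-bit mixing hash and the minimum
per w = 10 window is indexed. Read minimizers are matched against the index
(minimizers occurring > 32 times are skipped); anchors are grouped per
(reference, strand) in a shared orientation frame and chained by diagonal
banding: anchors within 500 nt of diagonal form a cluster, and clusters
that are consistently ordered in query and target with gaps ≤ 5 kb merge —
so one large insertion or deletion still yields a single chain, while a
tandem repeat (target restarting behind itself) or a chimera never merges
and surfaces as split (supplementary) records.

Each chain is extended by edlib (banded edit distance, semi-global in the
query) over the chain's query interval widened by at most 150 nt and a
padded target window. Because edit-distance alignment has no gap-open
penalty, two corrections follow: terminal runs are trimmed at the cut that
minimizes the cumulative prefix/suffix score within the outer 400 columns
(local-alignment end behaviour; interior structural gaps are untouched),
and the trimmed operations are re-scored with affine gaps (match +2,
mismatch −4, open −4, extend −2; records below score 100 are dropped). On
300–800 nt reads at 3 % error against a 10 kb target the reported endpoints
agree with a full quadratic Smith–Waterman oracle within ±4 nt.

Two-pass mapping mirrors the capture assay's logic: all reads are aligned
to the transgene reference (each donor's full vector: insert, arms and
ITRs — matching the probe design footprint), the mapped subset is realigned
to the genome, and capture efficiency is the transgene-mapped fraction.
Both denominators (total reads; total mapped reads) are reported, because
the field uses both. Records import/export as PAF and SAM, so an external
aligner can stand behind the same record model.

## Calling

**Depth.** Raw depth counts aligned (match/mismatch) bases only — a
deletion in the read does not cover. Normalized depth divides by the
sample's total mapped reads, giving the exact identity
`sum(normalized) = aligned bases / mapped reads`. Candidate windows tile
the genome in non-overlapping 20 kb bins ranked by summed pass-2 depth of
transgene-mapped reads, excluding the target locus; the top 10 are kept.

**Junctions.** For every read, each (transgene segment, genome segment)
pair that is adjacent on the read (gap/overlap ≤ 50 nt; segments ≥ 200 nt)
yields a junction observation with positions and orientations on both
sides. Overlapping segments are not junctions — a homology arm maps to both
references and would otherwise fabricate them. Observations deduplicate by
exact fragment signature (same aligned intervals both sides ⇒ PCR
duplicate) and single-linkage cluster within 50 nt on both sides.

**Classification.** Only locus-spanning reads vote on the genotype. A read
spans under the KI model if its alignment covers the novel insert interval
(computed as the region between the longest common prefix and suffix of
the KI and wild-type locus models) ± 20 nt; under the wild-type model it
must cover a window at the cut *as wide as the insert window* — a
deliberately symmetric rule, because short fragments can span a 40 nt cut
window but never a 1.5 kb insert, and the naive rule biases allele
fractions toward wild type. The winning model is the higher affine score.

Structural deviations are read off merged indel clusters: indel runs
separated by ≤ 50 match/mismatch columns pool into one cluster with net
size I − D. This matters because unit-cost edit paths fragment a 432 nt
deletion into many sub-runs through coincidental 1–2 nt matches; the
cluster net is stable. In-insert clusters with |net| ≥ 30 nt (`min_sv`)
within ±150 nt of the insert (`sv_margin`, covering co-optimal placement
jitter at the junctions) classify the read as `partial_ki` (net deletion)
or `imprecise_ki` (net insertion). A read whose KI view shows a large
in-insert deletion *and* whose wild-type view shows a matching large
cut-site insertion is `partial_ki` regardless of which model scores higher
— a mostly-deleted insert legitimately scores closer to wild type. Small
cut-site indels are called from an affine-gap local realignment
(match +2 / mismatch −4 / open −9 / extend −1) of the read segment around
the cut (±210 nt), which consolidates a genuine indel into one gap while
scattered error indels stay short; gaps ≥ 4 nt (`min_indel`) count. Error
indels are overwhelmingly 1–2 nt at the default error rates, so 4 nt
separates signal from drift; real 1–3 nt indels are below the resolution
of this error model and are a documented limitation.

Genotype: fractions over classes with Wilson 95 % intervals
(statsmodels); classes ≥ 10 % (`min_allele_frac`) are called; one class ⇒
homozygous, two ⇒ heterozygous, more ⇒ mosaic; no spanning reads ⇒
no-call.

**Concatemers.** Read evidence: ≥ 2 query-disjoint segments of one read
matching overlapping parts of the insert, topology from orientations (same
strand ⇒ head-to-tail; opposite strands near the cassette 3' end ⇒
tail-to-tail, near the 5' end ⇒ head-to-head). Depth evidence: the insert's
normalized depth against the genomic flank immediately outside the donor
span — the arms themselves are multiplied in a concatemer and reference
edges taper, so neither can serve as baseline — flags whole-insert gains
(≥ 1.5×, `cnv_gain`), and gained sub-intervals must exceed 1.5× both the
insert and flank medians (otherwise a random-integration allele adding
partial cassette coverage false-positives). Copies: rounded depth ratio
when the whole insert is gained, else the median split-segment count.

**Random integration.** A junction cluster becomes an RI event iff its
genome side lies outside the target locus ± 5 kb, support ≥ 3 independent
reads, and spread ≤ 100 nt. Clusters failing support or spread are reported
as putative artifacts — this is the operational form of the observation
that real fusions have one tight junction supported by multiple reads while
library chimeras each have a unique junction. Events are annotated with
vector-ITR presence (local-alignment scan of supporting reads against both
ITR variants, ≥ 60 nt at ≥ 90 % identity, flag set when at least half the
junction reads carry a hit) and with membership in a top-depth window.

**Fusion rate.** Over reads mapping to either of two distinct insert
references (segments ≥ 200 nt), the fraction mapping to both.

**Consensus.** Reads anchored by their alignments vote per reference
column (base or gap; read insertions are not represented — a known
limitation of pileup consensus); ties break toward the reference base;
majority-gap columns are dropped; fewer than 5 overlapping reads is a
no-call. At 20× and 3 % error the consensus is ≥ 99.5 % identical to truth.

## Probe design

Tiling: probes start at multiples of `probe_len + spacing` (defaults 125
and 20 — the configuration with the best measured capture in this assay
class; single-strand top tiling outperforms alternating and double-strand
layouts). The final probe is back-shifted to end exactly at the target end,
keeping probe length uniform; if back-shifting would leave its predecessor
more than `2 × spacing` away, an extra overlapping probe is appended
instead, so the maximum distance from any target base to the nearest probe
base never exceeds the spacing. Spacing ≥ 500 nt triggers an advisory
(capture drops more than two-fold out there).

GC flagging: a stretch is flagged when a run of 50 nt sub-windows all
exceed 70 % GC; the reported interval is the union of those windows trimmed
to its outermost G/C base and must be strictly longer than 50 nt (so a
49 nt run never flags and a 60 nt pure-GC island flags as exactly 60 nt).
Probes overlapping a flagged interval are recommended for internal biotin
enrichment. N counts as non-GC.

Asymmetric-PCR amplicons are placed every ~300 nt (start-to-start), each as
long as the 140–270 nt bounds allow; forward/reverse primers carry the
universal tails at their 5' ends and the expected probe is the full tailed
product. Throughput planning is the plain arithmetic
`total_reads × capture_efficiency / n_samples`.

## Prioritization and reporting

Rank 1: precise-KI-positive, ITR-negative, RI-free. Rank 2: precise-KI
with any ITR/RI finding. Rank 3: only partial/imprecise product. Rank 4:
negative. Ties break by precise-KI fraction. Reports are JSON (sorted keys,
schema-versioned), events TSV and bedGraph depth, byte-stable for fixed
inputs. Exit codes: 0 success, 2 validation failure, 3 no-call.

## What the simulator does and does not emulate

It emulates fragment-length dispersion, probe-footprint capture with
background leakage, dual-index orientation, nanopore-scale indel-heavy
error, library chimeras, mosaicism, and every outcome class the caller
targets — enough that parameter-recovery tests are meaningful end to end.
It does not emulate signal-level artifacts (homopolymer-length errors,
systematic strand bias), PCR duplication beyond exact-fragment duplicates,
hybridization kinetics (GC-dependent capture dropout), basecaller quality
strings, or real genomic repeat structure (the mini-genome is uniform
random DNA, so mapping ambiguity is rarer than on a real genome). Passing
the studies therefore demonstrates the *algorithms* recover truth under a
faithful statistical model of the assay, not that real-genome repeat
content is handled at the same accuracy.

## Study problem sizes

Validation studies run on a 100 kb two-chromosome mini-genome (60 + 40 kb)
with a 1.5 kb payload and 600 nt arms: 40 samples × 800 reads for genotype
recovery (≥ 300 on-target reads each), 600–800 reads for the structural and
RI studies, 2 500 pooled reads for the fusion study, 4 000 for
demultiplexing, 60 reads for the aligner oracle. These sizes keep every
study a desk-scale experiment while exercising each caller code path; all
randomness derives from a single seed.

## Known limitations

* Indels < 4 nt at the cut are indistinguishable from sequencing error
  under the default error model.
* A partial KI deleting essentially the whole insert converges to the
  wild-type-plus-junction allele and cannot be separated from large NHEJ
  insertions without donor-sequence matching of the inserted segment.
* Depth-based copy estimates assume capture uniformity; tagmentation-style
  short-fragment libraries bias the insert/flank ratio upward by roughly
  one copy at high copy number.
* Junction orientation inference assumes blunt joins; microhomology at
  junctions shifts positions within the clustering tolerance.
* No off-target cleavage prediction: recurrence of an RI locus across
  samples is the only off-target signal surfaced.
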