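# lockseq

Characterization of multi-kilobase CRISPR/Cas9 knock-ins from
capture-enriched nanopore sequencing, plus the simulation, probe-design and
construct-validation tooling around it.

## The problem

Large knock-ins (KIs) made with rAAV donors and Cas9 RNPs — including
sequential designs where two or three donors insert one after another, each
donor creating the guide site that licenses the next — are hard to genotype.
Junction PCRs miss partial inserts, donor concatemers and random vector
integrations, and cannot resolve zygosity in mosaic founders. Hybridization
capture of barcoded long-read libraries solves this: probes tiled over the
insert, homology arms and genomic flanks enrich the edited locus (and any
randomly integrated donor copy, wherever it landed), and long reads spanning
the whole insert read the allele structure directly.

This package implements the analysis side of that assay as a tested toolkit:

* **constructs** — model guides (20 nt protospacer + NGG PAM, blunt cut 3 nt
  5' of the PAM), ITR-flanked rAAV donors (≤ 4.7 kb packaged, 400–1200 bp
  arms, no self-cutting guide site) and reconstruct the expected composite
  allele of 1–3 sequential HDR events in silico.
* **simulate** — truth-annotated synthetic genomes carrying any mixture of
  outcome alleles (precise KI, cut-site indels, partial/imprecise KI,
  head-to-tail/head-to-head/tail-to-tail concatemers, random integrations
  with or without retained ITRs) and capture-enriched, dual-indexed,
  error-bearing long reads.
* **demux** — the exact dual-index rule: both indexes must occur exactly
  once (either orientation, near a read end); reads with extra or missing
  index occurrences are excluded with reason codes; no trimming.
* **align** — a built-in minimizer seed–chain–extend long-read aligner with
  split-read (supplementary) output, orchestrated as a two-pass scheme:
  reads are mapped to the transgene first, the mapped subset is re-mapped to
  the genome to locate the target site and any random-integration loci.
  PAF/SAM interchange for external aligners.
* **characterize** — normalized depth tracks, top-depth candidate windows,
  clustered insert↔genome junction breakpoints, per-read allele
  classification with a zygosity/mosaicism genotype (Wilson intervals),
  concatemer and random-integration calls with ITR flags, fusion-read
  artifact rate, and anchored majority-vote consensus.
* **probes** — tiling capture panels (default 125 nt probes, 20 nt spacing,
  top strand), GC-rich flagging (>70 % GC over >50 nt → internal biotin
  enrichment), asymmetric-PCR probe amplicon layout with universal tails,
  and flow-cell throughput planning.
* **cli / report** — a `lockseq` command-line tool, founder/clone
  prioritization (precise-KI⁺, ITR⁻, RI-free first), and byte-stable
  JSON/TSV/bedGraph reports.

## The statistics at the core

A sample's genotype is the allele-fraction vector over read classes. Each
read spanning the locus is scored against the expected-KI model and the
wild-type model; structural deviations are read off merged indel clusters of
the alignment (with an affine-gap realignment at the cut site for small
indels). For class *c* with *k* of *n* spanning reads, the fraction *k/n*
carries a Wilson 95 % interval; more than two classes above 10 % flags
mosaicism. A random integration is called where ≥ 3 independent reads share
a transgene↔genome junction within 50 nt on both sides (spread ≤ 100 nt)
away from the target locus — library chimeras lack a consistent junction
and fall below this support, so they are reported as putative artifacts
instead. Capture efficiency is the fraction of reads mapping to the
transgene (reported against both total and mapped-read denominators).

## Worked example

```bash
lockseq run --seed 2 --n-reads 200 --out demo/
```

simulates a heterozygous precise-KI sample (1.5 kb payload, 600 bp arms) on
a 100 kb two-chromosome mini-genome, demultiplexes, maps and calls it:

```json
{
  "sample": "demo",
  "reads": 200,
  "assigned": 59,
  "capture_efficiency": 0.4237,
  "genotype": "precise_ki/wild_type",
  "ki_fraction": 0.75,
  "rank": 1
}
```

200 reads were simulated at ~6 % sequencing error; 59 survive exact
dual-index demultiplexing (exact matching is deliberately strict — a single
error in an index excludes the read). Of those, 42 % map to the transgene
reference (capture efficiency), and the spanning reads support both the
knock-in and the wild-type allele models, so the call is heterozygous
(`ki_fraction` is 0.75 here — with only a handful of spanning reads after
demultiplexing the fraction is noisy; its Wilson interval in the JSON
report spans 0.5, and the 40-sample study below shows the estimator
concentrates in [0.45, 0.56] at ≥ 300 on-target reads). The sample earns
prioritization rank 1: precise KI, no ITR signal, no random integration.
`demo/` holds the FASTQ, truth table, JSON report and event TSV.

Library-level use mirrors the CLI:

```python
from lockseq import studies
project = studies.demo_project(seed=2)           # construct + references
res = studies.run_ri_study(seed=2)               # RI localization study
print(res["localization_error"], res["itr_flag"])  # 0 True
```

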