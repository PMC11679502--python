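# knockaid

Knockout gRNA design for Target-AID cytosine base editing.

Target-AID (SpCas9 fused to activation-induced cytidine deaminase) converts
C to T inside a narrow window 17–19 nt from the NGG PAM, without double-strand
breaks — which makes it attractive for knocking out several genes at once.
`knockaid` automates the guide design for that strategy: given a UCSC-style
refFlat annotation and a genome FASTA, it enumerates and filters guide RNAs
that knock out protein-coding genes by either of two routes:

* **Premature termination codons (PTC).** A single C→T edit converts
  CAA→TAA, CAG→TAG or CGA→TGA on the sense strand, or (editing the
  antisense strand, a sense G→A) TGG→TAG / TGG→TGA, truncating the protein
  and — in multi-exon genes — triggering nonsense-mediated decay (NMD).
* **Splice-site disruption.** Editing the consensus G of an intronic GT
  donor or AG acceptor (as a C on the antisense strand) forces skipping of
  the targeted exon; when the exon length is not a multiple of 3 the
  skipped transcript is frameshifted.

Candidates are filtered to experiment-ready guides: spacers containing the
pol III terminator TTTT are excluded; single-exon PTCs must lie in the
first 50 % of the CDS; multi-exon PTCs in the last exon are excluded and
survivors carry four NMD-susceptibility flags (PTC ≥ 150 nt from the start
codon, > 50 nt upstream of the last exon junction, containing exon ≤ 400 nt,
not in the last exon) whose conjunction is the `Recommended` column; splice
guides must target internal, frame-shifting exons (2 … n−2). For
multi-isoform genes only guides surviving in **every** isoform are
reported. Each output row carries the 23-nt sequence (spacer + PAM) and a
CRISPRdirect link for off-target review.

Intended users: genome engineers designing single- or large-scale (CRISPR
screening) knockouts in mouse, human, or any species with exon-annotated
genomes.

## Worked example

No downloads needed — the package ships a toy-genome generator
(`knockaid.toy_fixtures`) whose ground truth comes from an independent
brute-force oracle:

```sh
python examples/01_design_for_one_gene.py
```

prints, for a single-exon gene `Alpha` carrying a CAA codon with a PAM in
editing range, and a 4-exon gene `Bravo` with splice targets on exon 2:

```
== Alpha ==
-- premature termination codon gRNAs --
CTCAATCTCATTACCATCCTTGG  target Q9  https://crispr.dbcls.jp/?userseq=CTCAATCTCATTACCATCCTTGG&pam=NGG&db=toy

== Bravo ==
-- premature termination codon gRNAs --
CTCAAATCCCTCCTTACCCTCGG  target Q12 Recommended=False  https://crispr.dbcls.jp/?userseq=...
-- exon-skipping (splice-site) gRNAs --
AAGCTAAGGGTAAAAATAGATGG  exon 2  https://crispr.dbcls.jp/?userseq=...
```

`target Q9` means the guide's edit converts glutamine 9 into a stop codon;
`Recommended=False` flags a PTC too close to the start codon to reliably
trigger NMD (here glutamine 12, i.e. 33 nt into the CDS); `exon 2` marks a
guide that destroys a splice consensus so exon 2 (100 nt, frame-shifting)
is skipped. The same rows are written as CSV, one file per query.

The command-line interface wraps the same library:

```sh
knockaid preprocess --refflat refFlat.txt --fasta genome.fa --cache-dir caches --assembly-tag mm39
knockaid name Trp53 --cache-dir caches
knockaid batch genes.csv --cache-dir caches       # headerless CSV or .xlsx
knockaid summary --cache-dir caches               # annotation-wide targetability
knockaid make-fixtures --out fixtures --seed 1    # toy FASTA + refFlat
```

The other `examples/` scripts show batch mode, the annotation-wide
targetability summary (per-gene guide counts, histograms capped at 10
guides / 20 exons), and the pipeline-vs-oracle cross-check.

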