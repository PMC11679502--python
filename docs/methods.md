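# Methods

## Coordinate model

refFlat input is treated as 0-based half-open throughout (UCSC convention),
and all derived coordinates keep that convention. Every transcript is
normalized into a `TranscriptModel`: the pre-mRNA is the genomic span
txStart–txEnd read in the transcription direction (reverse-complemented for
minus-strand genes), with exon and CDS intervals re-expressed relative to
the transcript start. For a minus-strand gene each genomic interval
[s, e) maps to [L−e, L−s) with L = txEnd − txStart and the exon order is
reversed, so all downstream searches are strand-free. Guides are searched
over the pre-mRNA only: protospacer and PAM are read from the contiguous
genomic sequence (a window may run across an exon junction into an intron),
but never beyond the transcript bounds.

Annotation filtering keeps protein-coding transcripts on primary
assemblies: NR_ accessions are dropped, as are chromosomes whose name
contains `_alt`, `_random`, `_fix` or `_Un` or begins with `chrUn` (UCSC
unplaced scaffolds carry the `chrUn_` prefix rather than an internal `_Un`
component, so both spellings are denied). Duplicate rows sharing a
(gene symbol, NM accession) pair keep the first occurrence, with file order
as the tie-break. Transcripts whose spliced CDS length is not a positive
multiple of 3 are treated as annotation errors and dropped with a warning.
Caches are plain pickles of the model mapping and the filtered record
table; the cache format is an implementation detail, not a contract.

## Editing window and candidate geometry

The editor converts C to T at protospacer positions 2–4 counted from the
PAM-distal end, i.e. 17–19 nt from the NGG PAM. For an edited base at
pre-mRNA position q this means the PAM starts at q+17, q+18 or q+19
(sense-strand case, requiring GG at the PAM's last two positions), or —
for edits carried on the antisense strand — the PAM reads CCN on the sense
strand at p…p+2 with the edited sense-strand G at p+19, p+20 or p+21; the
reported protospacer and PAM are then reverse complements of the sense
slices. Both geometries are exercised against the same worked example and
against exhaustive enumeration (below).

PTC candidates come from an in-frame scan of the spliced CDS: CAA, CAG and
CGA are targeted through the sense-strand C at codon position 1 (yielding
TAA, TAG, TGA respectively); TGG is targeted through antisense editing of
the G at codon position 2 (→TAG) or 3 (→TGA). Only single-base conversions
are modeled; a TGG→TAA double edit is out of scope. The annotated stop
codon itself is never a target, and codons whose three bases span an exon
junction are skipped — their window geometry is ambiguous between pre-mRNA
and mRNA frames. Candidates identical in (protospacer, PAM, codon,
resulting stop, CDS position) are collapsed; distinct PAM placements for
the same codon are distinct candidates. N bases never satisfy a PAM or
consensus requirement.

Splice candidates require the canonical GT–AG consensus: the donor target
is the G at intron position +1 (immediately 3′ of an exon), the acceptor
target the G of the AG immediately 5′ of an exon, each edited as a C on
the antisense strand. Destroying the donor of exon i or the acceptor of
exon j removes that exon from the mature transcript, so the candidate's
target exon is the exon whose boundary carries the edited site.

## Filtering rules and boundary conventions

All positional comparisons use the first base of the newly created stop
codon, in CDS coordinates (start codon = 0) or spliced-mRNA coordinates as
noted. Boundaries are inclusive on the failing side:

* poly-T: a TTTT anywhere in the 20-nt spacer (the transcribed guide;
  the PAM is not part of the guide) excludes the candidate — TTTT
  terminates pol III transcription.
* single-exon genes (no NMD possible): keep stop position < 0.5 × CDS
  length, strict; exactly 50 % fails.
* multi-exon genes: stops whose first base falls in the last exon are
  excluded (no NMD). Survivors carry four flags, reported rather than
  filtered on: position ≥ 150 nt from the start codon; distance from the
  last exon–exon junction (in spliced-mRNA coordinates) > 50 nt; length of
  the containing exon ≤ 400 nt; not in the last exon (always true for
  survivors). `Recommended` is their conjunction.
* splice guides: the target exon must be internal (indices 2 … n−2 — the
  first exon is excluded because losing its donor causes intron retention
  rather than cassette-exon skipping, and skipping either of the two
  terminal exons does not trigger NMD) and its mRNA length must not be a
  multiple of 3, so the skip is frame-shifting.

The thresholds live in one `RuleThresholds` record shared — as values,
never as code — with the test oracle, so boundary conventions cannot
silently diverge between implementation and check.

## Reporting

A RefSeq accession resolves to one transcript; a gene symbol to all
retained isoforms. Multi-isoform results are intersected on the 23-nt
sequence+PAM, so every reported guide knocks out every isoform;
`Recommended` is True only if True in each isoform carrying flags.
Amino-acid labels (e.g. `Q9`) are shown only for single-transcript queries
because codon numbering differs between isoforms; splice-row exon numbers
are shown only when all isoforms agree. PTC rows are ordered by stop
position and splice rows by edited-base position. CSV output uses one
header row with columns kind, sequence_with_pam, crisprdirect_url,
target_amino_acid, target_exon, recommended, isoforms_covered
(semicolon-joined). CRISPRdirect links are deterministic URLs embedding
the sequence, the NGG PAM specification and an assembly tag; no live
queries are made. Batch lists are headerless CSV or Excel (first sheet,
first column, blanks skipped); unknown names are reported and skipped.
The targetability summary counts a gene as targetable when its merged
(all-isoform) output retains at least one guide, and histograms are capped
at 10 guides per gene and 20 exons.

## Synthetic fixtures and the brute-force oracle

The toy generator emulates the geometric features the designer keys on —
in-frame targetable codons with a PAM at window distance, GT…AG introns
with antisense-PAM placements against either consensus G, poly-T decoys,
codons without a PAM — inside genes with a clean ORF (ATG … stop, CDS a
multiple of 3, 6-nt 5′ UTR, 3–5 nt 3′ UTR). Default geometry: 1–6 exons of
60–242 nt, introns of 30–120 nt, whole fixtures under 5 kb; filler
sequence is low-G (coding filler drawn from G-free, stop-free,
non-targetable codons chosen so no pair forms TTTT) to limit accidental
PAMs. Accidental candidates that arise anyway are legitimate: ground truth
is always derived by the oracle, never by the pipeline, so fixtures need
not be sterile. Minus-strand genes are produced by reverse-complementing
the built pre-mRNA into the chromosome and mirroring the annotation.

The oracle shares no code with the pipeline. It enumerates every 23-mer on
both strands of each transcribed region, checks the PAM and the 17–19 nt
window positionally, and classifies each eligible edit by simulation:
mutate the base, re-splice, re-read the affected codon (for PTCs) or the
consensus dinucleotide (for splice sites). It then applies every filter
literally. It refuses inputs above 50 kb; it is O(L·W) by construction and
meant only for fixtures.

What passing these checks shows — and does not. Exact pipeline/oracle
agreement over hundreds of randomized fixtures, edit-simulation soundness,
the rule suite, and strand symmetry establish that the implementation
computes the stated rules correctly. The fixtures are geometric, not
biological: they say nothing about editing efficiency, off-target risk,
real splice-site strength, NMD penetrance, or annotation quality in real
refFlat files. Numbers from full mouse/human annotations additionally
depend on the exact refFlat snapshot used.

## Problem sizes and determinism

The acceptance script uses 200 two-gene randomized fixtures for the oracle
comparison, 60 for edit-soundness and rule checks, and 40 for strand
symmetry — sizes at which the exhaustive oracle remains fast while
exercising all exon-count regimes the generator produces. Per-fixture
seeds derive arithmetically from the single `--seed` argument, and the
generator is fully deterministic given a seed, so every reported number is
reproducible bit-for-bit.

## Known limitations

Only the NGG PAM is supported (no NG-PAM editor variants); no off-target
scoring or on-target efficiency prediction (links to CRISPRdirect stand in
for off-target review); guides are not sought outside transcript bounds,
and windows straddling txStart/txEnd are not considered; codons split
across exon junctions are never targeted; simultaneous multi-C edits are
not modeled; GTF/GFF input is not read.
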