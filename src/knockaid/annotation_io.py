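"""Read and filter refFlat + FASTA inputs and build strand-normalized transcript models.

refFlat is the 11-column UCSC gene-annotation table (gene symbol, transcript
accession, chromosome, strand, transcript/CDS bounds, exon count, exon
start/end lists).  All genomic and transcript-relative coordinates are
0-based half-open throughout the package.

A :class:`TranscriptModel` holds the pre-mRNA (txStart..txEnd read in the
transcription direction, i.e. reverse-complemented for minus-strand genes)
together with exon and CDS intervals expressed relative to the transcript
start, so every downstream search runs in a single, strand-free coordinate
system.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: chromosome-name components marking alternative/unplaced assemblies
ALT_ASSEMBLY_MARKERS = ("_alt", "_random", "_fix", "_Un")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class RefFlatParseError(ValueError):
    """A malformed refFlat line (wrong field count, bad coordinate, mismatched exon lists)."""


@dataclass(frozen=True)
class RefFlatRecord:
    """One refFlat annotation row."""

    gene_symbol: str
    refseq_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_count: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(
                f"{self.refseq_id}: require txStart <= cdsStart <= cdsEnd <= txEnd"
            )
        if not (len(self.exon_starts) == len(self.exon_ends) == self.exon_count):
            raise ValueError(f"{self.refseq_id}: exon list lengths != exonCount")
        prev_end = self.tx_start - 1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.refseq_id}: exon [{s},{e}) outside tx bounds")
            if s <= prev_end:
                raise ValueError(f"{self.refseq_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def exons(self) -> list[tuple[int, int]]:
        return list(zip(self.exon_starts, self.exon_ends))


#: chromosome name -> uppercase nucleotide string
GenomeSequence = Mapping[str, str]


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-normalized pre-mRNA with transcript-relative exon/CDS intervals.

    ``premrna_seq`` runs 5'->3' in the transcription direction; ``rel_exons``
    are sorted in that direction.  For minus-strand genes each genomic
    interval [s, e) maps to [L - e, L - s) with L = txEnd - txStart and the
    exon order is reversed.
    """

    refseq_id: str
    gene_symbol: str
    premrna_seq: str
    rel_exons: tuple[tuple[int, int], ...]
    rel_cds_start: int
    rel_cds_end: int
    source_strand: str
    chrom: str = ""
    tx_start: int = 0
    tx_end: int = 0

    @property
    def n_exons(self) -> int:
        return len(self.rel_exons)

    @property
    def mrna_len(self) -> int:
        return sum(e - s for s, e in self.rel_exons)

    def spliced_mrna(self) -> str:
        """Concatenation of the exon sequences, 5'->3'."""
        return "".join(self.premrna_seq[s:e] for s, e in self.rel_exons)

    def exon_mrna_offsets(self) -> list[int]:
        """Spliced-mRNA coordinate at which each exon starts."""
        offs, acc = [], 0
        for s, e in self.rel_exons:
            offs.append(acc)
            acc += e - s
        return offs

    def premrna_to_mrna(self, pos: int) -> int | None:
        """Map a pre-mRNA position to its spliced-mRNA coordinate (None if intronic)."""
        acc = 0
        for s, e in self.rel_exons:
            if s <= pos < e:
                return acc + (pos - s)
            acc += e - s
        return None

    def mrna_to_premrna(self, pos: int) -> int:
        acc = 0
        for s, e in self.rel_exons:
            if pos < acc + (e - s):
                return s + (pos - acc)
            acc += e - s
        raise IndexError(f"mRNA position {pos} beyond spliced length {acc}")

    def cds_mrna_bounds(self) -> tuple[int, int]:
        """CDS start/end in spliced-mRNA coordinates."""
        start = self.premrna_to_mrna(self.rel_cds_start)
        # rel_cds_end is half-open; map the last CDS base then add 1
        end = self.premrna_to_mrna(self.rel_cds_end - 1)
        if start is None or end is None:
            raise ValueError(f"{self.refseq_id}: CDS bounds fall in an intron")
        return start, end + 1

    def cds_seq(self) -> str:
        s, e = self.cds_mrna_bounds()
        return self.spliced_mrna()[s:e]

    def rel_to_genomic(self, pos: int) -> int:
        if self.source_strand == "+":
            return self.tx_start + pos
        return self.tx_end - 1 - pos

    def genomic_to_rel(self, gpos: int) -> int:
        if self.source_strand == "+":
            return gpos - self.tx_start
        return self.tx_end - 1 - gpos


def read_refflat(path: str | Path) -> list[RefFlatRecord]:
    """Parse a refFlat file into records, raising :class:`RefFlatParseError` with the line number."""
    records: list[RefFlatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 11:
                raise RefFlatParseError(
                    f"{path}:{lineno}: expected 11 tab-separated fields, got {len(fields)}"
                )
            try:
                starts = tuple(int(x) for x in fields[9].rstrip(",").split(","))
                ends = tuple(int(x) for x in fields[10].rstrip(",").split(","))
                rec = RefFlatRecord(
                    gene_symbol=fields[0],
                    refseq_id=fields[1],
                    chrom=fields[2],
                    strand=fields[3],
                    tx_start=int(fields[4]),
                    tx_end=int(fields[5]),
                    cds_start=int(fields[6]),
                    cds_end=int(fields[7]),
                    exon_count=int(fields[8]),
                    exon_starts=starts,
                    exon_ends=ends,
                )
            except ValueError as exc:
                raise RefFlatParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def filter_transcripts(records: Iterable[RefFlatRecord]) -> list[RefFlatRecord]:
    """Keep protein-coding transcripts on primary assemblies, one row per (gene, NM accession).

    Drops NR_ accessions, chromosomes carrying an alternative-assembly name
    component, and duplicate (gene symbol, NM accession) rows (first
    occurrence wins).  Idempotent and order-preserving.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[RefFlatRecord] = []
    for rec in records:
        if rec.refseq_id.startswith("NR"):
            continue
        if any(m in rec.chrom for m in ALT_ASSEMBLY_MARKERS) or rec.chrom.startswith("chrUn"):
            continue
        key = (rec.gene_symbol, rec.refseq_id)
        if key in seen:
            continue
        seen.add(key)
        kept.append(rec)
    return kept


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record, possibly lower-case) FASTA into an uppercase dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome_fasta(genome: GenomeSequence, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def build_transcript_model(record: RefFlatRecord, genome: GenomeSequence) -> TranscriptModel:
    """Extract the pre-mRNA in transcription direction and convert annotation to relative coordinates."""
    if record.chrom not in genome:
        raise KeyError(f"chromosome {record.chrom!r} not present in genome")
    chrom_seq = genome[record.chrom]
    if record.tx_end > len(chrom_seq):
        raise IndexError(
            f"{record.refseq_id}: txEnd {record.tx_end} beyond chromosome "
            f"{record.chrom} length {len(chrom_seq)}"
        )
    region = chrom_seq[record.tx_start : record.tx_end]
    L = record.tx_end - record.tx_start
    if record.strand == "+":
        premrna = region
        rel = lambda s, e: (s - record.tx_start, e - record.tx_start)  # noqa: E731
        rel_exons = tuple(rel(s, e) for s, e in record.exons)
        cds_lo, cds_hi = rel(record.cds_start, record.cds_end)
    else:
        premrna = reverse_complement(region)
        rel = lambda s, e: (record.tx_end - e, record.tx_end - s)  # noqa: E731
        rel_exons = tuple(rel(s, e) for s, e in reversed(record.exons))
        cds_lo, cds_hi = rel(record.cds_start, record.cds_end)
    assert len(premrna) == L
    return TranscriptModel(
        refseq_id=record.refseq_id,
        gene_symbol=record.gene_symbol,
        premrna_seq=premrna,
        rel_exons=rel_exons,
        rel_cds_start=cds_lo,
        rel_cds_end=cds_hi,
        source_strand=record.strand,
        chrom=record.chrom,
        tx_start=record.tx_start,
        tx_end=record.tx_end,
    )


@dataclass
class Caches:
    """Preprocessed annotation: transcript models keyed by accession, plus the filtered table."""

    models: dict[str, TranscriptModel] = field(default_factory=dict)
    records: list[RefFlatRecord] = field(default_factory=list)
    assembly_tag: str = "custom"

    def isoforms_of(self, gene_symbol: str) -> list[TranscriptModel]:
        return [
            self.models[r.refseq_id]
            for r in self.records
            if r.gene_symbol == gene_symbol and r.refseq_id in self.models
        ]


MODELS_CACHE = "refseq_to_transcript_models.pkl"
RECORDS_CACHE = "unique_coding_refflat.pkl"


def build_caches(
    refflat_path: str | Path,
    fasta_path: str | Path,
    cache_dir: str | Path,
    assembly_tag: str = "custom",
) -> Caches:
    """Preprocess annotation + genome into serialized caches for fast repeated queries.

    Records whose CDS length is not a positive multiple of 3 (suspected
    annotation errors) are dropped with a warning.
    """
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    records = filter_transcripts(read_refflat(refflat_path))
    genome = read_genome_fasta(fasta_path)
    models: dict[str, TranscriptModel] = {}
    kept_records: list[RefFlatRecord] = []
    for rec in records:
        model = build_transcript_model(rec, genome)
        s, e = model.cds_mrna_bounds()
        cds_len = e - s
        if cds_len <= 0 or cds_len % 3 != 0:
            log.warning(
                "dropping %s (%s): CDS length %d is not a positive multiple of 3",
                rec.refseq_id, rec.gene_symbol, cds_len,
            )
            continue
        models[rec.refseq_id] = model
        kept_records.append(rec)
    caches = Caches(models=models, records=kept_records, assembly_tag=assembly_tag)
    with open(cache_dir / MODELS_CACHE, "wb") as fh:
        pickle.dump(models, fh)
    with open(cache_dir / RECORDS_CACHE, "wb") as fh:
        pickle.dump({"records": kept_records, "assembly_tag": assembly_tag}, fh)
    return caches


def load_caches(cache_dir: str | Path) -> Caches:
    cache_dir = Path(cache_dir)
    with open(cache_dir / MODELS_CACHE, "rb") as fh:
        models = pickle.load(fh)
    with open(cache_dir / RECORDS_CACHE, "rb") as fh:
        meta = pickle.load(fh)
    return Caches(models=models, records=meta["records"], assembly_tag=meta["assembly_tag"])


def translate_cds(cds: str) -> str:
    """Translate a CDS, stopping at (and including) the first stop as '*'."""
    return str(Seq(cds).translate())
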