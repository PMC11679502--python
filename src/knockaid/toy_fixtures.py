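"""Synthetic toy genomes with known gRNA placements, for download-free testing.

Each :class:`ToyGeneSpec` describes a small gene (exon/intron lengths,
strand) plus a list of planted features: targetable codons with a PAM at
editing-window distance, splice-consensus targets with an antisense PAM,
and decoys (poly-T spacer, codon without a PAM).  The generator builds the
pre-mRNA in transcription direction — open reading frame from ATG to stop,
canonical GT..AG introns, low-G filler to limit accidental PAMs — then
projects it onto a genomic chromosome, writing standard refFlat + FASTA.

Ground truth is always derived by the brute-force oracle
(:mod:`knockaid.oracle`), never by the pipeline under test.  Accidental
candidates arising from filler are legitimate and appear in both.

Fixtures are geometric, not biological: no codon-usage or splice-strength
realism is attempted.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .annotation_io import reverse_complement
from .candidate_search import PtcCandidate, SpliceCandidate
from .oracle import GroundTruth, PtcKey, SpliceKey, brute_force_oracle

FEATURE_KINDS = (
    "CAA_with_PAM",
    "CAG_with_PAM",
    "CGA_with_PAM",
    "TGG_with_antisense_PAM",
    "donor_G_with_antisense_PAM",
    "acceptor_G_with_antisense_PAM",
    "polyT_decoy",
    "no_PAM_decoy",
)

# filler codons: no stop, no targetable codon, no G, and no pair forms TTTT
_SAFE_CODONS = ("ACT", "TCT", "CTT", "ACA", "CAT", "TAC", "TCA", "CCT", "ATC")
_FILLER_BASES = "ACTACTTCA"  # low-G non-coding filler alphabet


class FixtureConstructionError(ValueError):
    """A planted feature does not fit its exon or collides with another plant."""


@dataclass(frozen=True)
class ToyGeneSpec:
    gene_symbol: str
    refseq_id: str
    strand: str = "+"
    exon_lengths: tuple[int, ...] = (120,)
    intron_lengths: tuple[int, ...] = ()
    #: (kind, 1-based exon index, offset within the exon)
    features: tuple[tuple[str, int, int], ...] = ()
    utr5: int = 6

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise FixtureConstructionError("need exactly n_exons - 1 introns")
        for kind, ei, off in self.features:
            if kind not in FEATURE_KINDS:
                raise FixtureConstructionError(f"unknown feature kind {kind!r}")
            if not (1 <= ei <= len(self.exon_lengths)):
                raise FixtureConstructionError(f"feature exon {ei} out of range")
            if not (0 <= off < self.exon_lengths[ei - 1]):
                raise FixtureConstructionError(f"feature offset {off} outside exon {ei}")


@dataclass
class ToyGenome:
    genome: dict[str, str]
    refflat_rows: list[tuple]
    truth: GroundTruth

    def refflat_text(self) -> str:
        lines = []
        for row in self.refflat_rows:
            lines.append("\t".join(str(x) for x in row))
        return "\n".join(lines) + "\n"


class _GeneBuilder:
    """Assembles one gene's pre-mRNA and tracks claimed (planted) intervals."""

    def __init__(self, spec: ToyGeneSpec, rng: random.Random):
        self.spec = spec
        self.rng = rng
        self.exons: list[tuple[int, int]] = []
        pos = 0
        for i, ex_len in enumerate(spec.exon_lengths):
            self.exons.append((pos, pos + ex_len))
            pos += ex_len
            if i < len(spec.intron_lengths):
                pos += spec.intron_lengths[i]
        self.L = pos
        self.mrna_len = sum(spec.exon_lengths)
        # CDS: skip utr5, end on a codon boundary leaving a >=3 nt 3' UTR
        cds_len = self.mrna_len - spec.utr5 - 3
        cds_len -= cds_len % 3
        if cds_len < 9:
            raise FixtureConstructionError("gene too short for an ORF")
        self.cds_lo = spec.utr5
        self.cds_hi = spec.utr5 + cds_len
        self.seq = self._initial_premrna()
        self.claimed: set[int] = set()
        # protect ORF anchors and splice consensus dinucleotides
        for k in range(3):
            self.claimed.add(self._pre_pos(self.cds_lo + k))
            self.claimed.add(self._pre_pos(self.cds_hi - 3 + k))
        for i, (s, e) in enumerate(self.exons):
            if i < len(self.exons) - 1:
                self.claimed.update((e, e + 1))
            if i > 0:
                self.claimed.update((s - 2, s - 1))

    def _initial_premrna(self) -> list[str]:
        rng = self.rng
        mrna = [rng.choice(_FILLER_BASES) for _ in range(self.cds_lo)]
        mrna += list("ATG")
        for _ in range(self.cds_lo + 3, self.cds_hi - 3, 3):
            mrna += list(rng.choice(_SAFE_CODONS))
        mrna += list("TAA")
        mrna += [rng.choice(_FILLER_BASES) for _ in range(self.mrna_len - self.cds_hi)]
        assert len(mrna) == self.mrna_len
        seq = ["N"] * self.L
        acc = 0
        for s, e in self.exons:
            seq[s:e] = mrna[acc : acc + (e - s)]
            acc += e - s
        # introns: canonical GT ... AG around low-G filler
        for i in range(len(self.exons) - 1):
            s = self.exons[i][1]
            e = self.exons[i + 1][0]
            intron = ["G", "T"] + [rng.choice(_FILLER_BASES) for _ in range(e - s - 4)] + ["A", "G"]
            seq[s:e] = intron
        return seq

    # --- coordinate helpers -------------------------------------------------
    def _pre_pos(self, mrna_pos: int) -> int:
        acc = 0
        for s, e in self.exons:
            if mrna_pos < acc + (e - s):
                return s + (mrna_pos - acc)
            acc += e - s
        raise IndexError(mrna_pos)

    def _mrna_pos(self, pre_pos: int) -> int | None:
        acc = 0
        for s, e in self.exons:
            if s <= pre_pos < e:
                return acc + (pre_pos - s)
            acc += e - s
        return None

    def _write(self, pos: int, bases: str) -> None:
        span = range(pos, pos + len(bases))
        if span[0] < 0 or span[-1] >= self.L:
            raise FixtureConstructionError("planted feature extends past transcript bounds")
        if any(p in self.claimed for p in span):
            raise FixtureConstructionError(f"planted features overlap at {pos}")
        for p, b in zip(span, bases):
            self.seq[p] = b
            self.claimed.add(p)

    def _codon_start_near(self, exon_index: int, offset: int) -> int:
        """Pre-mRNA position of an in-frame, exon-contiguous codon near (exon, offset)."""
        ex_s, ex_e = self.exons[exon_index - 1]
        m = self._mrna_pos(ex_s + offset)
        assert m is not None
        ci = (m - self.cds_lo) // 3
        ci = max(1, min(ci, (self.cds_hi - self.cds_lo) // 3 - 2))  # skip ATG and stop
        for shift in range(0, 2 * len(self.spec.exon_lengths) * 50):
            for cand in (ci + shift, ci - shift):
                m0 = self.cds_lo + 3 * cand
                if not (self.cds_lo + 3 <= m0 <= self.cds_hi - 6):
                    continue
                ps = [self._pre_pos(m0 + k) for k in range(3)]
                if ps[1] == ps[0] + 1 and ps[2] == ps[0] + 2 and not (
                    ex_s > ps[0] or ps[2] >= ex_e
                ):
                    return ps[0]
        raise FixtureConstructionError(
            f"no in-frame contiguous codon available in exon {exon_index}"
        )

    # --- feature planting ---------------------------------------------------
    def plant(self, kind: str, exon_index: int, offset: int) -> None:
        rng = self.rng
        if kind in ("CAA_with_PAM", "CAG_with_PAM", "CGA_with_PAM"):
            q = self._codon_start_near(exon_index, offset)
            self._write(q, kind[:3])
            d = rng.choice((17, 18, 19))
            self._write(q + d + 1, "GG")  # PAM = NGG; N stays as-is
        elif kind == "TGG_with_antisense_PAM":
            q = self._codon_start_near(exon_index, offset)
            self._write(q, "TGG")
            g = q + rng.choice((1, 2))
            d = rng.choice((17, 18, 19))
            self._write(g - d - 2, "CC")
        elif kind == "donor_G_with_antisense_PAM":
            if exon_index >= len(self.exons):
                raise FixtureConstructionError("last exon has no donor")
            g = self.exons[exon_index - 1][1]  # the G of GT
            d = rng.choice((17, 18, 19))
            self._write(g - d - 2, "CC")
        elif kind == "acceptor_G_with_antisense_PAM":
            if exon_index <= 1:
                raise FixtureConstructionError("first exon has no acceptor")
            g = self.exons[exon_index - 1][0] - 1  # the G of AG
            d = rng.choice((17, 18, 19))
            self._write(g - d - 2, "CC")
        elif kind == "polyT_decoy":
            q = self._codon_start_near(exon_index, offset)
            self._write(q, "CAA")
            d = rng.choice((17, 18, 19))
            self._write(q + d + 1, "GG")
            self._write(q + 4, "TTTT")  # inside the spacer, downstream of the codon
        elif kind == "no_PAM_decoy":
            q = self._codon_start_near(exon_index, offset)
            self._write(q, "CAA")
        else:  # pragma: no cover
            raise FixtureConstructionError(kind)

    def build(self) -> tuple[str, list[tuple[int, int]], int, int]:
        for kind, ei, off in self.spec.features:
            self.plant(kind, ei, off)
        return "".join(self.seq), self.exons, self.cds_lo, self.cds_hi


def make_toy_genome(
    specs: list[ToyGeneSpec],
    seed: int = 0,
    out_dir: str | Path | None = None,
    chrom: str = "chrT",
    spacer: int = 40,
) -> ToyGenome:
    """Build a deterministic toy chromosome + refFlat from gene specs.

    Genes are laid head-to-tail with ``spacer`` nt of filler between; a
    minus-strand spec's pre-mRNA is reverse-complemented into the genome.
    Ground truth comes from the brute-force oracle.  If ``out_dir`` is
    given, ``toy.fa`` and ``toy.refflat`` are written there.
    """
    rng = random.Random(seed)
    chrom_parts: list[str] = []
    rows: list[tuple] = []
    offset = 0
    for spec in specs:
        gap = "".join(rng.choice(_FILLER_BASES) for _ in range(spacer))
        chrom_parts.append(gap)
        offset += spacer
        premrna, rel_exons, cds_lo, cds_hi = _GeneBuilder(spec, rng).build()
        L = len(premrna)
        if spec.strand == "+":
            gseq = premrna
            g_exons = [(offset + s, offset + e) for s, e in rel_exons]
            g_cds = (offset + cds_premrna(rel_exons, cds_lo), offset + cds_premrna(rel_exons, cds_hi - 1) + 1)
        else:
            gseq = reverse_complement(premrna)
            g_exons = sorted((offset + L - e, offset + L - s) for s, e in rel_exons)
            lo = cds_premrna(rel_exons, cds_lo)
            hi = cds_premrna(rel_exons, cds_hi - 1) + 1
            g_cds = (offset + L - hi, offset + L - lo)
        rows.append(
            (
                spec.gene_symbol,
                spec.refseq_id,
                chrom,
                spec.strand,
                offset,
                offset + L,
                g_cds[0],
                g_cds[1],
                len(g_exons),
                ",".join(str(s) for s, _ in g_exons) + ",",
                ",".join(str(e) for _, e in g_exons) + ",",
            )
        )
        chrom_parts.append(gseq)
        offset += L
    chrom_parts.append("".join(rng.choice(_FILLER_BASES) for _ in range(spacer)))
    genome = {chrom: "".join(chrom_parts)}
    truth = brute_force_oracle(genome, rows)
    toy = ToyGenome(genome=genome, refflat_rows=rows, truth=truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .annotation_io import write_genome_fasta

        write_genome_fasta(genome, out_dir / "toy.fa")
        (out_dir / "toy.refflat").write_text(toy.refflat_text())
    return toy


def cds_premrna(rel_exons: list[tuple[int, int]], mrna_pos: int) -> int:
    """Map a spliced-mRNA position to its pre-mRNA coordinate."""
    acc = 0
    for s, e in rel_exons:
        if mrna_pos < acc + (e - s):
            return s + (mrna_pos - acc)
        acc += e - s
    raise IndexError(mrna_pos)


def random_gene_spec(rng: random.Random, gene_symbol: str, refseq_id: str) -> ToyGeneSpec:
    """Draw a randomized small gene spec with 0-4 planted features."""
    n_exons = rng.randint(1, 6)
    exon_lengths = tuple(rng.randrange(60, 241, 3) + rng.choice((0, 1, 2)) for _ in range(n_exons))
    intron_lengths = tuple(rng.randint(30, 120) for _ in range(n_exons - 1))
    kinds = list(FEATURE_KINDS)
    features = []
    for _ in range(rng.randint(0, 4)):
        kind = rng.choice(kinds)
        if kind == "donor_G_with_antisense_PAM":
            if n_exons < 2:
                continue
            ei = rng.randint(1, n_exons - 1)
        elif kind == "acceptor_G_with_antisense_PAM":
            if n_exons < 2:
                continue
            ei = rng.randint(2, n_exons)
        else:
            ei = rng.randint(1, n_exons)
        off = rng.randint(0, exon_lengths[ei - 1] - 1)
        features.append((kind, ei, off))
    return ToyGeneSpec(
        gene_symbol=gene_symbol,
        refseq_id=refseq_id,
        strand=rng.choice("+-"),
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        features=tuple(features),
    )


def make_random_fixture(seed: int, n_genes: int = 1) -> ToyGenome:
    """One deterministic randomized fixture (features may collide; colliding plants are retried without)."""
    rng = random.Random(seed)
    specs = []
    for g in range(n_genes):
        spec = random_gene_spec(rng, f"Gene{seed}_{g}", f"NM_{seed:06d}{g}")
        specs.append(spec)
    # plants can collide (overlap claims) for unlucky offsets; degrade by
    # dropping features until construction succeeds
    while True:
        try:
            return make_toy_genome(specs, seed=seed)
        except FixtureConstructionError:
            specs = [
                ToyGeneSpec(
                    gene_symbol=s.gene_symbol,
                    refseq_id=s.refseq_id,
                    strand=s.strand,
                    exon_lengths=s.exon_lengths,
                    intron_lengths=s.intron_lengths,
                    features=s.features[:-1],
                )
                for s in specs
            ]


# --- key helpers: canonical identity of a candidate for set comparison -----

def ptc_key(c: PtcCandidate) -> PtcKey:
    return (c.protospacer, c.pam, c.target_codon, c.resulting_stop, c.mrna_stop_pos)


def splice_key(c: SpliceCandidate) -> SpliceKey:
    return (c.protospacer, c.pam, c.site_type, c.edited_base_premrna_pos)
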