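"""Enumerate gRNAs whose single C-to-T edit installs a premature stop codon or destroys a splice consensus.

Target-AID deaminates cytosines 17-19 nt from the SpCas9 NGG PAM, i.e. at
protospacer positions 2-4 counted from the PAM-distal end.  Two knockout
routes are searched:

* Premature termination codons (PTC): a sense-strand C->T converting
  CAA->TAA, CAG->TAG or CGA->TGA (the C is codon position 1), or an
  antisense edit (sense G->A) converting TGG->TAG or TGG->TGA.
* Splice-consensus destruction: the G of the intronic GT donor or AG
  acceptor dinucleotide, edited on the antisense strand (sense G->A),
  which removes the targeted exon from the mature mRNA.

Searches run over the pre-mRNA (transcribed region, introns included):
protospacer and PAM are read from the contiguous genomic sequence, so a
window may extend across an exon junction into an intron.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation_io import TranscriptModel, reverse_complement

#: sense-strand codons where a C->T at position 1 yields a stop
SENSE_STOP_CODONS = {"CAA": "TAA", "CAG": "TAG", "CGA": "TGA"}
#: tryptophan codon: antisense editing of the G at position 2 or 3 yields a stop
TRP_CODON = "TGG"

STOP_CODONS = {"TAA", "TAG", "TGA"}

CODON_TO_AA = {"CAA": "Q", "CAG": "Q", "CGA": "R", "TGG": "W"}


@dataclass(frozen=True)
class EditWindowRule:
    """Geometry of the Target-AID editing window relative to the NGG PAM."""

    window_min: int = 17
    window_max: int = 19
    pam_sense: str = "NGG"
    pam_antisense_on_sense: str = "CCN"
    protospacer_len: int = 20


@dataclass(frozen=True)
class PtcCandidate:
    """A gRNA whose single-base edit turns a targetable codon into a stop."""

    protospacer: str
    pam: str
    edit_strand: str  # "sense" | "antisense"
    target_codon: str
    resulting_stop: str
    codon_index: int  # 1-based amino-acid number
    mrna_stop_pos: int  # 0-based first base of the new stop, CDS coordinates
    exon_index: int  # 1-based exon containing the edited base
    premrna_pos: int  # transcript-relative position of the edited base

    @property
    def sequence_with_pam(self) -> str:
        return self.protospacer + self.pam


@dataclass(frozen=True)
class SpliceCandidate:
    """A gRNA whose antisense edit destroys a GT donor or AG acceptor consensus G."""

    protospacer: str
    pam: str
    site_type: str  # "donor" | "acceptor"
    target_exon_index: int  # 1-based exon whose inclusion the edit disrupts
    edited_base_premrna_pos: int

    @property
    def sequence_with_pam(self) -> str:
        return self.protospacer + self.pam


def _exon_index_of(model: TranscriptModel, premrna_pos: int) -> int:
    for i, (s, e) in enumerate(model.rel_exons, start=1):
        if s <= premrna_pos < e:
            return i
    raise ValueError(f"position {premrna_pos} is intronic")


def _sense_windows(premrna: str, q: int, rule: EditWindowRule):
    """Yield (protospacer, pam) for a sense-strand edited base at pre-mRNA position q.

    The PAM starts d nt downstream of the edited base for d in 17..19, so
    the base sits at protospacer position 21-d from the 5' (PAM-distal) end.
    """
    P = rule.protospacer_len
    for d in range(rule.window_min, rule.window_max + 1):
        pam_start = q + d
        if pam_start - P < 0 or pam_start + 3 > len(premrna):
            continue
        pam = premrna[pam_start : pam_start + 3]
        if pam[1:] != "GG":
            continue
        yield premrna[pam_start - P : pam_start], pam


def _antisense_windows(premrna: str, q: int, rule: EditWindowRule):
    """Yield (protospacer, pam) for an antisense edit of the sense-strand G at position q.

    On the sense strand the PAM reads CCN at p..p+2 with the G at
    p+19..p+21; the gRNA matches the antisense strand, so protospacer and
    PAM are reverse complements of the sense slices.
    """
    P = rule.protospacer_len
    for d in range(rule.window_min, rule.window_max + 1):
        p = q - d - 2  # sense position of the PAM's first C; q == p + d + 2
        if p < 0 or p + 3 + P > len(premrna):
            continue
        if premrna[p : p + 2] != "CC":
            continue
        protospacer = reverse_complement(premrna[p + 3 : p + 3 + P])
        pam = reverse_complement(premrna[p : p + 3])
        yield protospacer, pam


def find_ptc_candidates(
    model: TranscriptModel, rule: EditWindowRule = EditWindowRule()
) -> list[PtcCandidate]:
    """Scan the spliced CDS for codons a single Target-AID edit converts to a stop.

    Codons whose three bases span an exon junction are skipped (their
    window geometry on pre-mRNA vs mRNA is ambiguous).  Duplicates with
    identical protospacer+PAM+edit consequence are collapsed.  The final
    (annotated stop) codon is never a target.
    """
    premrna = model.premrna_seq
    cds_lo, cds_hi = model.cds_mrna_bounds()
    cds = model.spliced_mrna()[cds_lo:cds_hi]
    out: list[PtcCandidate] = []
    seen: set[tuple] = set()

    for ci in range(len(cds) // 3 - 1):  # exclude the annotated stop codon
        codon = cds[3 * ci : 3 * ci + 3]
        if codon not in SENSE_STOP_CODONS and codon != TRP_CODON:
            continue
        # pre-mRNA positions of the codon's three bases; require contiguity
        base_pos = [model.mrna_to_premrna(cds_lo + 3 * ci + k) for k in range(3)]
        if base_pos[1] != base_pos[0] + 1 or base_pos[2] != base_pos[0] + 2:
            continue

        if codon in SENSE_STOP_CODONS:
            q = base_pos[0]  # the C at codon position 1
            for protospacer, pam in _sense_windows(premrna, q, rule):
                key = (protospacer, pam, codon, SENSE_STOP_CODONS[codon], 3 * ci)
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    PtcCandidate(
                        protospacer=protospacer,
                        pam=pam,
                        edit_strand="sense",
                        target_codon=codon,
                        resulting_stop=SENSE_STOP_CODONS[codon],
                        codon_index=ci + 1,
                        mrna_stop_pos=3 * ci,
                        exon_index=_exon_index_of(model, q),
                        premrna_pos=q,
                    )
                )
        else:  # TGG: antisense edit of the G at codon position 2 or 3
            for offset, stop in ((1, "TAG"), (2, "TGA")):
                q = base_pos[offset]
                for protospacer, pam in _antisense_windows(premrna, q, rule):
                    key = (protospacer, pam, codon, stop, 3 * ci)
                    if key in seen:
                        continue
                    seen.add(key)
                    out.append(
                        PtcCandidate(
                            protospacer=protospacer,
                            pam=pam,
                            edit_strand="antisense",
                            target_codon=codon,
                            resulting_stop=stop,
                            codon_index=ci + 1,
                            mrna_stop_pos=3 * ci,
                            exon_index=_exon_index_of(model, q),
                            premrna_pos=q,
                        )
                    )
    return out


def find_splice_candidates(
    model: TranscriptModel, rule: EditWindowRule = EditWindowRule()
) -> list[SpliceCandidate]:
    """Find gRNAs editing the consensus G of internal GT-AG splice sites on the antisense strand.

    Destroying the donor G of exon i or the acceptor G of exon j removes
    that exon from the mature transcript.  Sites not conforming to GT
    (donor) or AG (acceptor) are skipped; single-exon models yield nothing.
    """
    if model.n_exons < 2:
        return []
    premrna = model.premrna_seq
    out: list[SpliceCandidate] = []
    seen: set[tuple] = set()

    sites: list[tuple[str, int, int]] = []  # (site_type, edited G pos, target exon)
    for i, (s, e) in enumerate(model.rel_exons, start=1):
        if i < model.n_exons and premrna[e : e + 2] == "GT":
            sites.append(("donor", e, i))
        if i > 1 and premrna[s - 2 : s] == "AG":
            sites.append(("acceptor", s - 1, i))

    for site_type, q, exon_idx in sites:
        for protospacer, pam in _antisense_windows(premrna, q, rule):
            key = (protospacer, pam, site_type, q)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                SpliceCandidate(
                    protospacer=protospacer,
                    pam=pam,
                    site_type=site_type,
                    target_exon_index=exon_idx,
                    edited_base_premrna_pos=q,
                )
            )
    return out
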