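"""Brute-force enumeration oracle for small fixtures.

Re-derives the full candidate and filter logic from first principles so
tests can compare the pipeline against an implementation that shares no
code with it: every 23-mer window on both strands of every transcribed
region is enumerated, the NGG PAM and the 17-19 nt editing window are
checked positionally, and each eligible C-to-T edit is *simulated* —
mutate the pre-mRNA, re-splice, re-read the codon / splice consensus —
rather than classified by pattern.  All filters are then applied
literally, using the same thresholds and boundary conventions as the
pipeline (the thresholds are shared values, the code is not).

O(L * W) by design; refuses inputs above ~50 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = ("TAA", "TAG", "TGA")
_EDITABLE = (1, 2, 3)  # 0-based protospacer indices == 1-based positions 2..4

MAX_ORACLE_INPUT = 50_000

#: (protospacer, pam, target_codon, resulting_stop, cds_stop_pos)
PtcKey = tuple[str, str, str, str, int]
#: (protospacer, pam, site_type, edited_base_premrna_pos)
SpliceKey = tuple[str, str, str, int]


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class TranscriptTruth:
    ptc_pre: set[PtcKey] = field(default_factory=set)
    splice_pre: set[SpliceKey] = field(default_factory=set)
    ptc_post: set[PtcKey] = field(default_factory=set)
    splice_post: set[SpliceKey] = field(default_factory=set)
    #: post-filter key -> (not_in_last_exon, beyond_150, beyond_50_junction,
    #: exon_not_long) or None for single-exon genes
    ptc_flags: dict[PtcKey, tuple[bool, bool, bool, bool] | None] = field(default_factory=dict)


@dataclass
class GroundTruth:
    per_transcript: dict[str, TranscriptTruth] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)


def _parse_annotation(annotation) -> list[tuple]:
    """Accept a refFlat path or pre-split field rows; return raw 11-field tuples."""
    if isinstance(annotation, (str, Path)):
        rows = []
        for line in Path(annotation).read_text().splitlines():
            if line and not line.startswith("#"):
                rows.append(tuple(line.split("\t")))
        return rows
    return [tuple(r) for r in annotation]


def brute_force_oracle(
    genome: dict[str, str],
    annotation,
    thresholds=None,
) -> GroundTruth:
    """Exhaustively derive ground-truth candidate sets for a small genome + annotation.

    ``thresholds`` duck-types the pipeline's RuleThresholds (polyT_motif,
    single_exon_cds_fraction, start_rule_nt, last_junction_rule_nt,
    long_exon_nt); defaults match it.
    """
    if thresholds is None:
        class _T:  # default thresholds, restated independently
            polyT_motif = "TTTT"
            single_exon_cds_fraction = 0.5
            start_rule_nt = 150
            last_junction_rule_nt = 50
            long_exon_nt = 400
        thresholds = _T()

    total = sum(len(s) for s in genome.values())
    if total > MAX_ORACLE_INPUT:
        raise ValueError(f"oracle input {total} nt exceeds {MAX_ORACLE_INPUT} nt by design")

    rows = _parse_annotation(annotation)
    truth = GroundTruth()
    seen_nm: set[tuple[str, str]] = set()
    for row in rows:
        gene, refseq, chrom, strand = row[0], row[1], row[2], row[3]
        if refseq.startswith("NR"):
            continue
        if any(m in chrom for m in ("_alt", "_random", "_fix", "_Un")) or chrom.startswith("chrUn"):
            continue
        if (gene, refseq) in seen_nm:
            continue
        seen_nm.add((gene, refseq))
        tx_s, tx_e = int(row[4]), int(row[5])
        cds_s, cds_e = int(row[6]), int(row[7])
        ex_s = [int(x) for x in row[9].rstrip(",").split(",")]
        ex_e = [int(x) for x in row[10].rstrip(",").split(",")]

        region = genome[chrom][tx_s:tx_e]
        L = tx_e - tx_s
        if strand == "+":
            premrna = region
            exons = [(s - tx_s, e - tx_s) for s, e in zip(ex_s, ex_e)]
            cds_lo_rel, cds_hi_rel = cds_s - tx_s, cds_e - tx_s
        else:
            premrna = _rc(region)
            exons = [(L - (e0 - tx_s), L - (s0 - tx_s)) for s0, e0 in zip(reversed(ex_s), reversed(ex_e))]
            cds_lo_rel, cds_hi_rel = L - (cds_e - tx_s), L - (cds_s - tx_s)

        tt = _transcript_truth(premrna, exons, cds_lo_rel, cds_hi_rel, thresholds)
        if tt is None:
            continue
        truth.per_transcript[refseq] = tt
        truth.gene_of[refseq] = gene
    return truth


def _splice(seq: str, exons: list[tuple[int, int]]) -> str:
    return "".join(seq[s:e] for s, e in exons)


def _mrna_pos(exons: list[tuple[int, int]], pre_pos: int) -> int | None:
    acc = 0
    for s, e in exons:
        if s <= pre_pos < e:
            return acc + (pre_pos - s)
        acc += e - s
    return None


def _pre_pos(exons: list[tuple[int, int]], mrna_pos: int) -> int:
    acc = 0
    for s, e in exons:
        if mrna_pos < acc + (e - s):
            return s + (mrna_pos - acc)
        acc += e - s
    raise IndexError(mrna_pos)


def _transcript_truth(premrna, exons, cds_lo_rel, cds_hi_rel, th) -> TranscriptTruth | None:
    n_exons = len(exons)
    mrna = _splice(premrna, exons)
    cds_lo = _mrna_pos(exons, cds_lo_rel)
    cds_hi_last = _mrna_pos(exons, cds_hi_rel - 1)
    if cds_lo is None or cds_hi_last is None:
        return None
    cds_hi = cds_hi_last + 1
    cds_len = cds_hi - cds_lo
    if cds_len <= 0 or cds_len % 3 != 0:
        return None  # annotation error: dropped, like the preprocessor
    ncod = cds_len // 3
    L = len(premrna)

    tt = TranscriptTruth()
    ptc_records: list[tuple[PtcKey, int]] = []  # key + mrna coord of stop's first base

    def consider_edit(pre_q: int, protospacer: str, pam: str) -> None:
        """Simulate the single-base edit at pre-mRNA position pre_q and record consequences."""
        # edit is C->T on the strand carrying the C; on the sense strand that
        # base reads C (sense edit) or G (antisense edit -> sense G->A)
        base = premrna[pre_q]
        if base == "C":
            new_base = "T"
        elif base == "G":
            new_base = "A"
        else:
            return
        mutated = premrna[:pre_q] + new_base + premrna[pre_q + 1 :]

        # --- PTC consequence: edited base in a CDS codon that becomes a stop
        mq = _mrna_pos(exons, pre_q)
        if mq is not None and cds_lo <= mq < cds_hi:
            ci = (mq - cds_lo) // 3
            if ci < ncod - 1:  # never the annotated stop codon
                codon_m = [cds_lo + 3 * ci + k for k in range(3)]
                codon_p = [_pre_pos(exons, m) for m in codon_m]
                if codon_p[1] == codon_p[0] + 1 and codon_p[2] == codon_p[0] + 2:
                    old = "".join(premrna[p] for p in codon_p)
                    new = "".join(mutated[p] for p in codon_p)
                    if new in _STOPS and old not in _STOPS:
                        key = (protospacer, pam, old, new, 3 * ci)
                        if key not in tt.ptc_pre:
                            tt.ptc_pre.add(key)
                            ptc_records.append((key, cds_lo + 3 * ci))

        # --- splice consequence: consensus G of an internal GT donor / AG acceptor
        for i, (s, e) in enumerate(exons, start=1):
            if i < n_exons and pre_q == e and premrna[e : e + 2] == "GT" and mutated[e] == "A":
                tt.splice_pre.add((protospacer, pam, "donor", pre_q))
            if i > 1 and pre_q == s - 1 and premrna[s - 2 : s] == "AG" and mutated[s - 1] == "A":
                tt.splice_pre.add((protospacer, pam, "acceptor", pre_q))

    # enumerate every 23-mer window on both strands
    for w in range(L - 22):
        window = premrna[w : w + 23]
        if window[21:23] == "GG":  # sense-strand PAM
            for i in _EDITABLE:
                if window[i] == "C":
                    consider_edit(w + i, window[:20], window[20:23])
        if window[0:2] == "CC":  # antisense PAM reads NGG on the reverse strand
            rc = _rc(window)
            for i in _EDITABLE:
                if rc[i] == "C":  # sense base is G
                    consider_edit(w + 22 - i, rc[:20], rc[20:23])

    # --- filters, applied literally ---
    last_exon_mrna_start = sum(e - s for s, e in exons[:-1])
    for key, mrna_stop in ptc_records:
        protospacer = key[0]
        if th.polyT_motif in protospacer:
            continue
        stop_cds_pos = key[4]
        if n_exons == 1:
            if stop_cds_pos < th.single_exon_cds_fraction * cds_len:
                tt.ptc_post.add(key)
                tt.ptc_flags[key] = None
        else:
            # exon containing the stop's first base (mRNA coordinates)
            acc, exon_i, exon_len = 0, None, None
            for j, (s, e) in enumerate(exons, start=1):
                if mrna_stop < acc + (e - s):
                    exon_i, exon_len = j, e - s
                    break
                acc += e - s
            if exon_i == n_exons:
                continue
            flags = (
                True,
                stop_cds_pos >= th.start_rule_nt,
                (last_exon_mrna_start - mrna_stop) > th.last_junction_rule_nt,
                exon_len <= th.long_exon_nt,
            )
            tt.ptc_post.add(key)
            tt.ptc_flags[key] = flags

    for key in tt.splice_pre:
        protospacer, _, site_type, pre_q = key
        if th.polyT_motif in protospacer:
            continue
        # which exon does the edit skip: donor G sits after its exon,
        # acceptor G before it
        target = None
        for i, (s, e) in enumerate(exons, start=1):
            if site_type == "donor" and pre_q == e:
                target = i
            if site_type == "acceptor" and pre_q == s - 1:
                target = i
        if target is None or target <= 1 or target >= n_exons - 1:
            continue
        s, e = exons[target - 1]
        if (e - s) % 3 == 0:
            continue
        tt.splice_post.add(key)

    return tt
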