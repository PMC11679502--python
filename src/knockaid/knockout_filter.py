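"""Reduce candidate gRNAs to experiment-ready ones.

Four rule families, mirroring how a knockout either succeeds or silently
fails:

* poly-T: a TTTT run in the 20-nt spacer terminates pol III transcription,
  so such gRNAs are excluded outright.
* single-exon genes: no nonsense-mediated decay (NMD) is possible, so the
  premature stop must sit in the first 50% of the CDS to truncate enough
  of the protein.
* multi-exon genes: stops in the last exon escape NMD and are excluded;
  survivors carry four boolean NMD-susceptibility flags (not within 150 nt
  of the start codon, more than 50 nt upstream of the last exon junction,
  containing exon not longer than 400 nt, not in the last exon) whose
  conjunction is the Recommended flag.
* splice targets: exon skipping only knocks out when it shifts the frame
  and triggers NMD, so frame-preserving exons (length % 3 == 0) and the
  terminal exons (first, last and second-to-last) are excluded.

Boundary conventions (kept identical in the independent oracle): positions
are the first base of the new stop codon; pos < 150 fails the start rule;
junction distance <= 50 fails the last-junction rule; exon length > 400
fails the long-exon rule; stop position >= 50% of CDS length fails the
single-exon rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

from .annotation_io import TranscriptModel
from .candidate_search import PtcCandidate, SpliceCandidate

C = TypeVar("C", PtcCandidate, SpliceCandidate)


@dataclass(frozen=True)
class RuleThresholds:
    polyT_motif: str = "TTTT"
    single_exon_cds_fraction: float = 0.5
    start_rule_nt: int = 150
    last_junction_rule_nt: int = 50
    long_exon_nt: int = 400


@dataclass(frozen=True)
class NmdFlags:
    """The four NMD-susceptibility criteria; ``recommended`` is their conjunction."""

    not_in_last_exon: bool
    beyond_150nt_of_start: bool
    beyond_50nt_of_last_junction: bool
    exon_not_long: bool

    @property
    def recommended(self) -> bool:
        return (
            self.not_in_last_exon
            and self.beyond_150nt_of_start
            and self.beyond_50nt_of_last_junction
            and self.exon_not_long
        )


def drop_polyT(
    cands: Sequence[C], rule: RuleThresholds = RuleThresholds()
) -> list[C]:
    """Remove candidates whose 20-nt protospacer contains a TTTT run (order preserved)."""
    return [c for c in cands if rule.polyT_motif not in c.protospacer]


def filter_single_exon(
    cands: Sequence[PtcCandidate],
    model: TranscriptModel,
    rule: RuleThresholds = RuleThresholds(),
) -> list[PtcCandidate]:
    """Keep PTCs strictly within the first 50% of the CDS of a single-exon gene."""
    if model.n_exons != 1:
        raise ValueError(f"{model.refseq_id} has {model.n_exons} exons; single-exon rule only")
    lo, hi = model.cds_mrna_bounds()
    cds_len = hi - lo
    cutoff = rule.single_exon_cds_fraction * cds_len
    return [c for c in cands if c.mrna_stop_pos < cutoff]


def _mrna_exon_of_stop(model: TranscriptModel, mrna_stop: int) -> tuple[int, int]:
    """(1-based exon index, exon mRNA length) of the exon holding a spliced-mRNA position."""
    acc = 0
    for i, (s, e) in enumerate(model.rel_exons, start=1):
        length = e - s
        if mrna_stop < acc + length:
            return i, length
        acc += length
    raise IndexError(f"mRNA position {mrna_stop} beyond spliced length {acc}")


def filter_and_flag_multi_exon(
    cands: Sequence[PtcCandidate],
    model: TranscriptModel,
    rule: RuleThresholds = RuleThresholds(),
) -> list[tuple[PtcCandidate, NmdFlags]]:
    """Exclude last-exon PTCs and attach NMD flags to survivors of a multi-exon gene.

    Only the last-exon rule excludes; the start-150nt, last-junction-50nt
    and long-exon rules are reported as flags.
    """
    if model.n_exons < 2:
        raise ValueError(f"{model.refseq_id} has {model.n_exons} exon; multi-exon rule only")
    cds_lo, _ = model.cds_mrna_bounds()
    last_junction = model.mrna_len - (model.rel_exons[-1][1] - model.rel_exons[-1][0])
    out: list[tuple[PtcCandidate, NmdFlags]] = []
    for c in cands:
        mrna_stop = cds_lo + c.mrna_stop_pos  # spliced-mRNA coord of new stop's first base
        exon_i, exon_len = _mrna_exon_of_stop(model, mrna_stop)
        if exon_i == model.n_exons:
            continue
        flags = NmdFlags(
            not_in_last_exon=True,
            beyond_150nt_of_start=c.mrna_stop_pos >= rule.start_rule_nt,
            beyond_50nt_of_last_junction=(last_junction - mrna_stop) > rule.last_junction_rule_nt,
            exon_not_long=exon_len <= rule.long_exon_nt,
        )
        out.append((c, flags))
    return out


def filter_splice(
    cands: Sequence[SpliceCandidate],
    model: TranscriptModel,
    rule: RuleThresholds = RuleThresholds(),
) -> list[SpliceCandidate]:
    """Keep splice targets on internal, frame-shifting exons (indices 2..n-2, length % 3 != 0).

    The first exon is excluded (losing its donor causes intron retention,
    not cassette-exon skipping); the last and second-to-last exons are
    excluded because skipping there does not trigger NMD.
    """
    if model.n_exons < 2:
        raise ValueError(f"{model.refseq_id} has {model.n_exons} exon; splice rule needs >=2")
    n = model.n_exons
    out: list[SpliceCandidate] = []
    for c in cands:
        i = c.target_exon_index
        if i <= 1 or i >= n - 1:
            continue
        s, e = model.rel_exons[i - 1]
        if (e - s) % 3 == 0:
            continue
        out.append(c)
    return out


def run_ptc_pipeline(
    model: TranscriptModel, cands: Sequence[PtcCandidate], rule: RuleThresholds = RuleThresholds()
) -> list[tuple[PtcCandidate, NmdFlags | None]]:
    """Apply poly-T + exon-structure rules; flags are None for single-exon genes."""
    cands = drop_polyT(cands, rule)
    if model.n_exons == 1:
        return [(c, None) for c in filter_single_exon(cands, model, rule)]
    return list(filter_and_flag_multi_exon(cands, model, rule))


def run_splice_pipeline(
    model: TranscriptModel, cands: Sequence[SpliceCandidate], rule: RuleThresholds = RuleThresholds()
) -> list[SpliceCandidate]:
    if model.n_exons < 2:
        return []
    return filter_splice(drop_polyT(cands, rule), model, rule)
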