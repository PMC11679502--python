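"""Resolve queries, merge per-isoform results, and emit report tables.

A query is a gene symbol (all retained isoforms) or a RefSeq accession
(one transcript).  For multi-isoform genes only gRNAs surviving the full
design pipeline in *every* isoform are reported, so one guide knocks out
the whole gene; amino-acid numbers are shown only for single-transcript
queries because they differ between isoforms.  Each row carries the 23-nt
sequence (spacer + PAM) and a CRISPRdirect link for off-target review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .annotation_io import Caches, TranscriptModel
from .candidate_search import (
    CODON_TO_AA,
    EditWindowRule,
    find_ptc_candidates,
    find_splice_candidates,
)
from .knockout_filter import NmdFlags, RuleThresholds, run_ptc_pipeline, run_splice_pipeline

DEFAULT_OUT_DIR = Path("knockaid_data/output")

CSV_COLUMNS = [
    "kind",
    "sequence_with_pam",
    "crisprdirect_url",
    "target_amino_acid",
    "target_exon",
    "recommended",
    "isoforms_covered",
]


@dataclass(frozen=True)
class ReportRow:
    sequence_with_pam: str
    crisprdirect_url: str
    kind: str  # "PTC" | "splice"
    target_amino_acid: str | None = None
    target_exon: int | None = None
    recommended: bool | None = None
    isoforms_covered: tuple[str, ...] = ()


@dataclass
class QueryResult:
    query: str
    ptc_rows: list[ReportRow] = field(default_factory=list)
    splice_rows: list[ReportRow] = field(default_factory=list)

    @property
    def rows(self) -> list[ReportRow]:
        return self.ptc_rows + self.splice_rows


class GeneNotFoundError(KeyError):
    pass


def resolve_query(q: str, caches: Caches) -> list[TranscriptModel]:
    """A RefSeq accession resolves to its single model; a symbol to all retained isoforms."""
    if q in caches.models:
        return [caches.models[q]]
    isoforms = caches.isoforms_of(q)
    if not isoforms:
        raise GeneNotFoundError(f"gene not found: {q!r}")
    return isoforms


def crisprdirect_url(sequence_with_pam: str, assembly_tag: str) -> str:
    """Deterministic CRISPRdirect link for a 23-nt spacer+PAM sequence."""
    if len(sequence_with_pam) != 23 or not re.fullmatch("[ACGT]{23}", sequence_with_pam):
        raise ValueError(
            f"sequence must be 23 uppercase ACGT characters, got {sequence_with_pam!r}"
        )
    return (
        "https://crispr.dbcls.jp/?userseq="
        f"{sequence_with_pam}&pam=NGG&db={assembly_tag}"
    )


@dataclass
class IsoformDesign:
    """Filtered design output for one transcript."""

    model: TranscriptModel
    ptc: list  # list of (PtcCandidate, NmdFlags | None)
    splice: list  # list of SpliceCandidate


def design_for_model(
    model: TranscriptModel,
    thresholds: RuleThresholds = RuleThresholds(),
    window: EditWindowRule = EditWindowRule(),
) -> IsoformDesign:
    """Run search + filters for a single transcript."""
    ptc = run_ptc_pipeline(model, find_ptc_candidates(model, window), thresholds)
    splice = run_splice_pipeline(model, find_splice_candidates(model, window), thresholds)
    return IsoformDesign(model=model, ptc=ptc, splice=splice)


def _aa_label(cand) -> str:
    return f"{CODON_TO_AA[cand.target_codon]}{cand.codon_index}"


def merge_isoforms(per_isoform: list[IsoformDesign], query: str, assembly_tag: str) -> QueryResult:
    """Intersect per-isoform survivors on sequence+PAM so one guide hits every isoform.

    Recommended is True only when True in every isoform that carries NMD
    flags; amino-acid numbers (and splice exon numbers, when isoforms
    disagree) are suppressed for multi-isoform queries.
    """
    if not per_isoform:
        raise ValueError("need at least one isoform result")
    single = len(per_isoform) == 1
    covered = tuple(d.model.refseq_id for d in per_isoform)

    ptc_maps = [{c.sequence_with_pam: (c, f) for c, f in d.ptc} for d in per_isoform]
    common = set(ptc_maps[0])
    for m in ptc_maps[1:]:
        common &= set(m)
    ptc_rows = []
    for seq in sorted(common, key=lambda s: ptc_maps[0][s][0].mrna_stop_pos):
        cand0, _ = ptc_maps[0][seq]
        flags = [f for m in ptc_maps for c, f in [m[seq]] if isinstance(f, NmdFlags)]
        recommended = all(f.recommended for f in flags) if flags else None
        ptc_rows.append(
            ReportRow(
                sequence_with_pam=seq,
                crisprdirect_url=crisprdirect_url(seq, assembly_tag),
                kind="PTC",
                target_amino_acid=_aa_label(cand0) if single else None,
                recommended=recommended,
                isoforms_covered=covered,
            )
        )

    splice_maps = [{c.sequence_with_pam: c for c in d.splice} for d in per_isoform]
    common_s = set(splice_maps[0])
    for m in splice_maps[1:]:
        common_s &= set(m)
    splice_rows = []
    for seq in sorted(common_s, key=lambda s: splice_maps[0][s].edited_base_premrna_pos):
        exons = {m[seq].target_exon_index for m in splice_maps}
        splice_rows.append(
            ReportRow(
                sequence_with_pam=seq,
                crisprdirect_url=crisprdirect_url(seq, assembly_tag),
                kind="splice",
                target_exon=exons.pop() if len(exons) == 1 else None,
                isoforms_covered=covered,
            )
        )
    return QueryResult(query=query, ptc_rows=ptc_rows, splice_rows=splice_rows)


def result_frame(result: QueryResult) -> pd.DataFrame:
    rows = []
    for r in result.rows:
        rows.append(
            {
                "kind": r.kind,
                "sequence_with_pam": r.sequence_with_pam,
                "crisprdirect_url": r.crisprdirect_url,
                "target_amino_acid": r.target_amino_acid,
                "target_exon": r.target_exon,
                "recommended": r.recommended,
                "isoforms_covered": ";".join(r.isoforms_covered),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def format_table(result: QueryResult) -> str:
    """Human-readable report printed to standard output."""
    lines = [f"== {result.query} =="]
    if not result.rows:
        lines.append("(no experiment-ready gRNAs)")
    if result.ptc_rows:
        lines.append("-- premature termination codon gRNAs --")
        for r in result.ptc_rows:
            extras = []
            if r.target_amino_acid:
                extras.append(f"target {r.target_amino_acid}")
            if r.recommended is not None:
                extras.append(f"Recommended={r.recommended}")
            lines.append(f"{r.sequence_with_pam}  {' '.join(extras)}  {r.crisprdirect_url}")
    if r_rows := result.splice_rows:
        lines.append("-- exon-skipping (splice-site) gRNAs --")
        for r in r_rows:
            exon = f"exon {r.target_exon}" if r.target_exon is not None else ""
            lines.append(f"{r.sequence_with_pam}  {exon}  {r.crisprdirect_url}")
    return "\n".join(lines)


def _safe_filename(query: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", query) or "query"


def run_single(
    q: str,
    caches: Caches,
    out_dir: str | Path = DEFAULT_OUT_DIR,
    thresholds: RuleThresholds = RuleThresholds(),
    window: EditWindowRule = EditWindowRule(),
    echo=print,
) -> QueryResult:
    """Design gRNAs for one query, print the table, and write <out_dir>/<query>.csv."""
    models = resolve_query(q, caches)
    designs = [design_for_model(m, thresholds, window) for m in models]
    result = merge_isoforms(designs, q, caches.assembly_tag)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result_frame(result).to_csv(out_dir / f"{_safe_filename(q)}.csv", index=False)
    echo(format_table(result))
    return result


def read_query_list(path: str | Path) -> list[str]:
    """First column of a headerless CSV or Excel file; blank rows skipped."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        df = pd.read_excel(path, header=None, sheet_name=0)
    else:
        df = pd.read_csv(path, header=None)
    if df.empty:
        raise ValueError(f"query list {path} is empty")
    return [str(v).strip() for v in df.iloc[:, 0] if pd.notna(v) and str(v).strip()]


def run_batch(
    list_path: str | Path,
    caches: Caches,
    out_dir: str | Path = DEFAULT_OUT_DIR,
    thresholds: RuleThresholds = RuleThresholds(),
    window: EditWindowRule = EditWindowRule(),
    echo=print,
) -> list[QueryResult]:
    """Process a query list sequentially; unknown genes are reported and skipped."""
    queries = read_query_list(list_path)
    results = []
    for q in queries:
        try:
            results.append(run_single(q, caches, out_dir, thresholds, window, echo=echo))
        except GeneNotFoundError as exc:
            echo(f"skipped: {exc.args[0]}")
    return results


@dataclass
class TargetabilitySummary:
    per_gene: pd.DataFrame  # gene, n_ptc, n_splice, n_total, n_exons_max, targetable
    n_genes: int = 0
    n_targetable: int = 0
    n_ptc_targetable: int = 0
    n_splice_targetable: int = 0
    grna_histogram: dict[int, int] = field(default_factory=dict)  # counts capped at 10
    exon_histogram: dict[int, int] = field(default_factory=dict)  # exon counts capped at 20


def summarize_targetability(
    caches: Caches,
    thresholds: RuleThresholds = RuleThresholds(),
    window: EditWindowRule = EditWindowRule(),
    grna_cap: int = 10,
    exon_cap: int = 20,
) -> TargetabilitySummary:
    """Genome-wide targetability: per-gene gRNA counts and capped histograms.

    A gene is targetable when its merged (all-isoform) output retains at
    least one gRNA of either kind.
    """
    genes = sorted({r.gene_symbol for r in caches.records})
    recs = []
    for gene in genes:
        models = resolve_query(gene, caches)
        designs = [design_for_model(m, thresholds, window) for m in models]
        result = merge_isoforms(designs, gene, caches.assembly_tag)
        n_ptc, n_splice = len(result.ptc_rows), len(result.splice_rows)
        recs.append(
            {
                "gene": gene,
                "n_ptc": n_ptc,
                "n_splice": n_splice,
                "n_total": n_ptc + n_splice,
                "n_exons_max": max(m.n_exons for m in models),
                "targetable": n_ptc + n_splice >= 1,
            }
        )
    df = pd.DataFrame(recs)
    grna_hist: dict[int, int] = {}
    exon_hist: dict[int, int] = {}
    for r in recs:
        grna_hist[min(r["n_total"], grna_cap)] = grna_hist.get(min(r["n_total"], grna_cap), 0) + 1
        exon_hist[min(r["n_exons_max"], exon_cap)] = exon_hist.get(min(r["n_exons_max"], exon_cap), 0) + 1
    return TargetabilitySummary(
        per_gene=df,
        n_genes=len(recs),
        n_targetable=int(df["targetable"].sum()) if len(df) else 0,
        n_ptc_targetable=int((df["n_ptc"] >= 1).sum()) if len(df) else 0,
        n_splice_targetable=int((df["n_splice"] >= 1).sum()) if len(df) else 0,
        grna_histogram=dict(sorted(grna_hist.items())),
        exon_histogram=dict(sorted(exon_hist.items())),
    )
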