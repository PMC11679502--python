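import pytest

from knockaid.annotation_io import RefFlatRecord, build_transcript_model
from knockaid.candidate_search import find_ptc_candidates, find_splice_candidates
from knockaid.knockout_filter import run_ptc_pipeline, run_splice_pipeline
from knockaid.toy_fixtures import ptc_key, splice_key


def records_from_rows(rows):
    """Convert raw refFlat field tuples into RefFlatRecord objects."""
    return [
        RefFlatRecord(
            gene_symbol=r[0],
            refseq_id=r[1],
            chrom=r[2],
            strand=r[3],
            tx_start=int(r[4]),
            tx_end=int(r[5]),
            cds_start=int(r[6]),
            cds_end=int(r[7]),
            exon_count=int(r[8]),
            exon_starts=tuple(int(x) for x in str(r[9]).rstrip(",").split(",")),
            exon_ends=tuple(int(x) for x in str(r[10]).rstrip(",").split(",")),
        )
        for r in rows
    ]


def pipeline_key_sets(model):
    """Pre- and post-filter candidate key sets produced by the pipeline for one model."""
    ptc = find_ptc_candidates(model)
    spl = find_splice_candidates(model)
    post_ptc = run_ptc_pipeline(model, ptc)
    post_spl = run_splice_pipeline(model, spl)
    return {
        "ptc_pre": {ptc_key(c) for c in ptc},
        "splice_pre": {splice_key(c) for c in spl},
        "ptc_post": {ptc_key(c) for c, _ in post_ptc},
        "splice_post": {splice_key(c) for c in post_spl},
        "ptc_post_full": post_ptc,
        "splice_post_full": post_spl,
    }


def models_of(toy):
    """TranscriptModels for every transcript the oracle retained in a toy genome."""
    out = {}
    for rec in records_from_rows(toy.refflat_rows):
        if rec.refseq_id in toy.truth.per_transcript:
            out[rec.refseq_id] = build_transcript_model(rec, toy.genome)
    return out


def mirror_toy(toy):
    """Reverse-complement the chromosome and mirror every annotation row."""
    from knockaid.annotation_io import reverse_complement

    (chrom_name, seq), = toy.genome.items()
    L = len(seq)
    mirrored_rows = []
    for r in toy.refflat_rows:
        tx_s, tx_e = int(r[4]), int(r[5])
        cds_s, cds_e = int(r[6]), int(r[7])
        starts = [int(x) for x in str(r[9]).rstrip(",").split(",")]
        ends = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        new_starts = [L - e for e in reversed(ends)]
        new_ends = [L - s for s in reversed(starts)]
        mirrored_rows.append(
            (
                r[0], r[1], chrom_name,
                "-" if r[3] == "+" else "+",
                L - tx_e, L - tx_s, L - cds_e, L - cds_s,
                r[8],
                ",".join(map(str, new_starts)) + ",",
                ",".join(map(str, new_ends)) + ",",
            )
        )
    return {chrom_name: reverse_complement(seq)}, mirrored_rows


@pytest.fixture
def worked_example_model():
    """Single-exon toy whose only candidate converts CAA (codon 2) to TAA."""
    from knockaid.annotation_io import TranscriptModel

    return TranscriptModel(
        refseq_id="NM_T",
        gene_symbol="ToyT",
        premrna_seq="ATGCAAGTCTCAGCTACTGATCAGG",
        rel_exons=((0, 25),),
        rel_cds_start=0,
        rel_cds_end=21,
        source_strand="+",
    )
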