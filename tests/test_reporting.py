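import pandas as pd
import pytest

from knockaid.annotation_io import TranscriptModel, build_caches, reverse_complement
from knockaid.candidate_search import PtcCandidate, SpliceCandidate
from knockaid.knockout_filter import NmdFlags
from knockaid.reporting import (
    GeneNotFoundError,
    IsoformDesign,
    crisprdirect_url,
    merge_isoforms,
    read_query_list,
    resolve_query,
    run_batch,
    run_single,
    summarize_targetability,
)
from knockaid.toy_fixtures import ToyGeneSpec, make_toy_genome


@pytest.fixture(scope="module")
def toy_caches(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("toyann")
    specs = [
        ToyGeneSpec("Alpha", "NM_A1", "+", (120,), (), (("CAA_with_PAM", 1, 30),)),
        ToyGeneSpec(
            "Bravo", "NM_B1", "-", (90, 100, 90, 90), (40, 40, 40),
            (
                ("acceptor_G_with_antisense_PAM", 2, 0),
                ("donor_G_with_antisense_PAM", 2, 0),
                ("CAA_with_PAM", 1, 40),
            ),
        ),
        ToyGeneSpec("Empty", "NM_E1", "+", (120,), ()),
        ToyGeneSpec("Delta", "NM_D1", "+", (120,), ()),
        ToyGeneSpec("Delta", "NM_D2", "+", (150,), ()),
        ToyGeneSpec("Delta", "NM_D3", "+", (120, 60), (40,)),
        ToyGeneSpec(
            "Many", "NM_M1", "+", (600, 90, 90), (40, 40),
            tuple(("CAA_with_PAM", 1, off) for off in range(30, 560, 60))
            + (("TGG_with_antisense_PAM", 2, 30),),
        ),
    ]
    make_toy_genome(specs, seed=5, out_dir=tmp)
    return build_caches(tmp / "toy.refflat", tmp / "toy.fa", tmp / "caches", assembly_tag="toy")


class TestResolveQuery:
    def test_refseq_id_resolves_to_one_model(self, toy_caches):
        (m,) = resolve_query("NM_A1", toy_caches)
        assert m.refseq_id == "NM_A1"

    def test_symbol_resolves_to_all_isoforms(self, toy_caches):
        models = resolve_query("Delta", toy_caches)
        assert sorted(m.refseq_id for m in models) == ["NM_D1", "NM_D2", "NM_D3"]

    def test_unknown_gene_raises(self, toy_caches):
        with pytest.raises(GeneNotFoundError, match="NoSuchGene"):
            resolve_query("NoSuchGene", toy_caches)


class TestCrisprdirectUrl:
    def test_url_embeds_sequence_pam_and_assembly(self):
        url = crisprdirect_url("GCAAGTCTCAGCTACTGATCAGG", "mm39")
        assert "GCAAGTCTCAGCTACTGATCAGG" in url
        assert "NGG" in url and "mm39" in url

    def test_deterministic(self):
        a = crisprdirect_url("A" * 23, "hg38")
        assert a == crisprdirect_url("A" * 23, "hg38")

    @pytest.mark.parametrize("bad", ["A" * 22, "A" * 24, "N" * 23, "a" * 23])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            crisprdirect_url(bad, "mm39")


def _design(refseq, seqs_flags, splice_seqs=()):
    """Synthetic IsoformDesign with given (spacer23, recommended) pairs."""
    model = TranscriptModel(refseq, "G", "A" * 50, ((0, 50),), 0, 48, "+")
    ptc = []
    for seq23, rec in seqs_flags:
        c = PtcCandidate(seq23[:20], seq23[20:], "sense", "CAA", "TAA", 2, 3, 1, 3)
        flags = NmdFlags(True, rec, True, True) if rec is not None else None
        ptc.append((c, flags))
    spl = [
        SpliceCandidate(s[:20], s[20:], "donor", 2, 10) for s in splice_seqs
    ]
    return IsoformDesign(model=model, ptc=ptc, splice=spl)


SEQ1 = "GCAAGTCTCAGCTACTGATCAGG"
SEQ2 = "TTTTTTTTTTTTTTTTTTTTAGG".replace("T", "A")  # AAAA...AGG


class TestMergeIsoforms:
    def test_grna_in_all_isoforms_kept_with_coverage(self):
        r = merge_isoforms(
            [_design("NM_1", [(SEQ1, True)]), _design("NM_2", [(SEQ1, True)])], "G", "toy"
        )
        (row,) = r.ptc_rows
        assert row.sequence_with_pam == SEQ1
        assert row.isoforms_covered == ("NM_1", "NM_2")
        assert row.recommended is True
        assert row.target_amino_acid is None  # multi-isoform query

    def test_grna_in_one_of_two_isoforms_dropped(self):
        r = merge_isoforms(
            [_design("NM_1", [(SEQ1, True), (SEQ2, True)]), _design("NM_2", [(SEQ2, True)])],
            "G", "toy",
        )
        assert [row.sequence_with_pam for row in r.ptc_rows] == [SEQ2]

    def test_single_isoform_identity_with_amino_acid(self):
        r = merge_isoforms([_design("NM_1", [(SEQ1, True)])], "G", "toy")
        (row,) = r.ptc_rows
        assert row.target_amino_acid == "Q2"
        assert row.isoforms_covered == ("NM_1",)

    def test_recommended_true_only_if_true_in_every_isoform(self):
        r = merge_isoforms(
            [_design("NM_1", [(SEQ1, True)]), _design("NM_2", [(SEQ1, False)])], "G", "toy"
        )
        assert r.ptc_rows[0].recommended is False

    def test_splice_rows_intersect_too(self):
        r = merge_isoforms(
            [_design("NM_1", [], [SEQ1, SEQ2]), _design("NM_2", [], [SEQ1])], "G", "toy"
        )
        assert [row.sequence_with_pam for row in r.splice_rows] == [SEQ1]
        assert r.splice_rows[0].target_exon == 2


class TestRunSingle:
    def test_single_gene_report_and_csv(self, toy_caches, tmp_path):
        r = run_single("Alpha", toy_caches, tmp_path, echo=lambda *_: None)
        assert len(r.ptc_rows) == 1 and len(r.splice_rows) == 0
        (row,) = r.ptc_rows
        assert row.target_amino_acid == "Q9"  # RefSeq-equivalent single-transcript query
        df = pd.read_csv(tmp_path / "Alpha.csv")
        assert len(df) == 1
        assert df.loc[0, "sequence_with_pam"] == row.sequence_with_pam

    def test_splice_rows_present_for_multi_exon_gene(self, toy_caches, tmp_path):
        r = run_single("Bravo", toy_caches, tmp_path, echo=lambda *_: None)
        assert len(r.ptc_rows) == 1 and len(r.splice_rows) == 3
        assert all(row.target_exon == 2 for row in r.splice_rows)

    def test_gene_with_no_grnas_writes_header_only_csv(self, toy_caches, tmp_path):
        r = run_single("Empty", toy_caches, tmp_path, echo=lambda *_: None)
        assert r.rows == []
        df = pd.read_csv(tmp_path / "Empty.csv")
        assert len(df) == 0 and "sequence_with_pam" in df.columns

    def test_csv_round_trips_report_content(self, toy_caches, tmp_path):
        r = run_single("Bravo", toy_caches, tmp_path, echo=lambda *_: None)
        df = pd.read_csv(tmp_path / "Bravo.csv")
        assert list(df["sequence_with_pam"]) == [row.sequence_with_pam for row in r.rows]
        assert list(df["kind"]) == [row.kind for row in r.rows]
        assert list(df["crisprdirect_url"]) == [row.crisprdirect_url for row in r.rows]

    def test_reported_sequences_occur_in_premrna(self, toy_caches, tmp_path):
        for q in ("Alpha", "Bravo", "Many"):
            r = run_single(q, toy_caches, tmp_path, echo=lambda *_: None)
            models = resolve_query(q, toy_caches)
            for row in r.rows:
                assert all(
                    row.sequence_with_pam in m.premrna_seq
                    or reverse_complement(row.sequence_with_pam) in m.premrna_seq
                    for m in models
                )


class TestRunBatch:
    def test_two_gene_csv_batch(self, toy_caches, tmp_path):
        lst = tmp_path / "genes.csv"
        lst.write_text("Alpha\nBravo\n")
        results = run_batch(lst, toy_caches, tmp_path / "out", echo=lambda *_: None)
        assert [r.query for r in results] == ["Alpha", "Bravo"]

    def test_symbol_and_refseq_mixed(self, toy_caches, tmp_path):
        lst = tmp_path / "genes.csv"
        lst.write_text("NM_A1\nBravo\n")
        results = run_batch(lst, toy_caches, tmp_path / "out", echo=lambda *_: None)
        assert len(results) == 2

    def test_unknown_gene_skipped_with_notice(self, toy_caches, tmp_path):
        lst = tmp_path / "genes.csv"
        lst.write_text("Alpha\nNoSuchGene\nBravo\n")
        notices = []
        results = run_batch(lst, toy_caches, tmp_path / "out", echo=notices.append)
        assert len(results) == 2
        assert any("NoSuchGene" in n for n in notices)

    def test_excel_list_first_sheet_first_column(self, toy_caches, tmp_path):
        lst = tmp_path / "genes.xlsx"
        pd.DataFrame([["Alpha"], ["Bravo"]]).to_excel(lst, index=False, header=False)
        assert read_query_list(lst) == ["Alpha", "Bravo"]

    def test_empty_list_raises(self, toy_caches, tmp_path):
        lst = tmp_path / "empty.csv"
        lst.write_text("")
        with pytest.raises(Exception):
            run_batch(lst, toy_caches, tmp_path / "out", echo=lambda *_: None)

    def test_batch_output_equals_single_query_output(self, toy_caches, tmp_path):
        lst = tmp_path / "genes.csv"
        lst.write_text("Bravo\n")
        (batch_r,) = run_batch(lst, toy_caches, tmp_path / "o1", echo=lambda *_: None)
        single_r = run_single("Bravo", toy_caches, tmp_path / "o2", echo=lambda *_: None)
        assert batch_r == single_r


class TestSummarizeTargetability:
    def test_counts_and_capped_histograms(self, toy_caches):
        s = summarize_targetability(toy_caches)
        assert s.n_genes == 5
        assert s.n_targetable == 3  # Alpha, Bravo, Many; Empty and Delta have none
        assert s.n_ptc_targetable == 3
        assert s.n_splice_targetable == 1  # Bravo only
        # Many has 11 gRNAs -> capped into bin 10
        assert max(s.grna_histogram) == 10 and s.grna_histogram[10] == 1
        assert max(s.exon_histogram) <= 20

    def test_targetable_is_union_of_ptc_and_splice_targetable(self, toy_caches):
        s = summarize_targetability(toy_caches)
        df = s.per_gene
        union = ((df["n_ptc"] >= 1) | (df["n_splice"] >= 1)).sum()
        assert s.n_targetable == int(union)
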