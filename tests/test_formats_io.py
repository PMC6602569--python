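import pytest

from allodriver.formats_io import (
    Cohort,
    FormatError,
    Mutation,
    ValidationConfig,
    cohort_from_mutations,
    load_fasta,
    parse_annovar,
    parse_maf,
    parse_mutation_list,
    parse_protein_change,
    read_target_table,
    validate_cohort,
    write_target_table,
)
from allodriver.prioritization import TargetEntry


class TestMutationListGrammar:
    def test_basic_line(self):
        muts, rejected = parse_mutation_list("sample_1;BRAF;V600E")
        assert rejected == []
        (m,) = muts
        assert (m.sample_id, m.gene_symbol, m.ref_aa, m.position, m.alt_aa) == (
            "sample_1", "BRAF", "V", 600, "E",
        )

    def test_blank_input_is_empty(self):
        assert parse_mutation_list("\n\n  \n") == ([], [])

    def test_missing_ref_residue_names_line(self):
        with pytest.raises(FormatError, match="line 1"):
            parse_mutation_list("s1;BRAF;600E")

    def test_error_names_correct_line(self):
        with pytest.raises(FormatError, match="line 2"):
            parse_mutation_list("s1;BRAF;V600E\ns1;KRAS;oops")

    def test_synonymous_rejected_with_reason(self):
        muts, rejected = parse_mutation_list("s1;BRAF;V600V\ns1;BRAF;V600E")
        assert len(muts) == 1
        assert len(rejected) == 1 and "synonymous" in rejected[0]

    def test_crlf_line_endings(self):
        muts, _ = parse_mutation_list("s1;BRAF;V600E\r\ns1;KRAS;G12D\r\n")
        assert [m.change for m in muts] == ["V600E", "G12D"]

    @pytest.mark.parametrize(
        "text,expected",
        [("V600E", ("V", 600, "E")), ("p.V600E", ("V", 600, "E")),
         ("p.Val600Glu", ("V", 600, "E")), ("p.E76K", ("E", 76, "K"))],
    )
    def test_protein_change_variants(self, text, expected):
        assert parse_protein_change(text) == expected


def _write_maf(path, rows, header=("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "HGVSp_Short")):
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestMAF:
    def test_missense_filter(self, tmp_path):
        maf = _write_maf(
            tmp_path / "c.maf",
            [("BRAF", "s1", "Missense_Mutation", "p.V600E"),
             ("TP53", "s1", "Silent", "p.R175R"),
             ("PTPN11", "s1", "Missense_Mutation", "p.E76K")],
        )
        cohort = parse_maf(maf)
        assert cohort.n_mutations() == 2
        m = cohort.samples["s1"][1]
        assert (m.ref_aa, m.position, m.alt_aa) == ("E", 76, "K")

    def test_missing_column_error(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Hugo_Symbol\tTumor_Sample_Barcode\tHGVSp_Short\nBRAF\ts1\tp.V600E\n")
        with pytest.raises(FormatError, match="Variant_Classification"):
            parse_maf(path)

    def test_unparseable_row_skipped(self, tmp_path):
        maf = _write_maf(
            tmp_path / "c.maf",
            [("BRAF", "s1", "Missense_Mutation", "p.V600fs"),
             ("BRAF", "s1", "Missense_Mutation", "p.V600E")],
        )
        assert parse_maf(maf).n_mutations() == 1

    def test_order_preserved_and_multi_sample(self, tmp_path):
        rows = [("G1", "s1", "Missense_Mutation", "p.A2C"),
                ("G2", "s2", "Missense_Mutation", "p.A3C"),
                ("G3", "s1", "Missense_Mutation", "p.A4C")]
        cohort = parse_maf(_write_maf(tmp_path / "c.maf", rows))
        assert [m.gene_symbol for m in cohort.samples["s1"]] == ["G1", "G3"]
        assert list(cohort.samples) == ["s1", "s2"]


class TestAnnovar:
    def test_single_sample_from_stem(self, tmp_path):
        path = tmp_path / "caseA.txt"
        path.write_text(
            "line1\tnonsynonymous SNV\tBRAF:NM_004333:exon15:c.1799T>A:p.V600E\n"
            "line2\tnonsynonymous SNV\tKRAS:NM_033360:exon2:c.35G>A:p.G12D\n"
        )
        cohort = parse_annovar(path)
        assert list(cohort.samples) == ["caseA"]
        assert [m.change for m in cohort.samples["caseA"]] == ["V600E", "G12D"]
        assert cohort.samples["caseA"][0].gene_symbol == "BRAF"

    def test_synonymous_rows_excluded(self, tmp_path):
        path = tmp_path / "s.txt"
        path.write_text(
            "l1\tsynonymous SNV\tBRAF:NM_004333:exon15:c.1797C>T:p.V599V\n"
            "l2\tnonsynonymous SNV\tBRAF:NM_004333:exon15:c.1799T>A:p.V600E\n"
        )
        assert parse_annovar(path).n_mutations() == 1

    def test_no_missense_is_error(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("l1\tsynonymous SNV\tBRAF:NM:exon1:c.1A>G:p.V1V\n")
        with pytest.raises(FormatError, match="no missense"):
            parse_annovar(path)


def _cohort_of_size(n, sample="s1"):
    muts = [Mutation(sample, "G1", "A", i + 1, "C") for i in range(n)]
    return cohort_from_mutations(muts, "LIST")


class TestCohortValidation:
    def test_cap_accepts_2000_rejects_2001(self):
        ok, report = validate_cohort(_cohort_of_size(2000))
        assert "s1" in ok.samples and not report.rejected_samples
        both = Cohort(
            {**_cohort_of_size(2001, "big").samples, **_cohort_of_size(5, "small").samples},
            "LIST",
        )
        kept, report = validate_cohort(both)
        assert list(kept.samples) == ["small"]
        assert report.rejected_samples[0][0] == "big"

    def test_all_rejected_is_error(self):
        with pytest.raises(FormatError, match="empty cohort"):
            validate_cohort(_cohort_of_size(3), ValidationConfig(max_mutations_per_sample=2))

    def test_empty_sample_accepted_with_warning(self):
        cohort = Cohort({"s1": []}, "LIST")
        kept, report = validate_cohort(cohort)
        assert kept.samples["s1"] == [] and report.warnings

    def test_accepted_mutations_unmodified(self):
        cohort = _cohort_of_size(10)
        kept, _ = validate_cohort(cohort)
        assert kept.samples["s1"] == cohort.samples["s1"]


class TestFasta:
    def test_uniprot_header_and_size(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">sp|Q06124|PTN11_HUMAN desc\nMTSRRWFHPN\n>P99999\nACDEFGHIKL\n")
        seqs = load_fasta(path)
        assert set(seqs) == {"Q06124", "P99999"}
        assert seqs["Q06124"] == "MTSRRWFHPN"

    def test_duplicate_accession_error(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">A1\nACDE\n>A1\nACDE\n")
        with pytest.raises(FormatError, match="duplicate"):
            load_fasta(path)

    def test_bad_characters_error(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">A1\nACDEX\n")
        with pytest.raises(FormatError, match="A1"):
            load_fasta(path)


class TestTargetTable:
    def _entries(self):
        return {
            "s1": [
                TargetEntry("s1", "GENE2", "P10001", "E76K", 76, "ALLO_EXP", 0.647),
                TargetEntry("s1", "GENE1", "P10000", "V600E", 600, "ORTHO", 0.55),
            ]
        }

    def test_round_trip(self, tmp_path):
        path = tmp_path / "targets.tsv"
        write_target_table(self._entries(), path)
        df = read_target_table(path)
        assert len(df) == 2
        assert df.loc[0, "Gene/Protein"] == "GENE2"
        assert df.loc[0, "Score"] == "0.647000"
        assert df.loc[1, "Location"] == "600"

    def test_empty_ranking_header_only(self, tmp_path):
        path = tmp_path / "targets.tsv"
        write_target_table({}, path)
        assert len(path.read_text().strip().splitlines()) == 1
        assert read_target_table(path).empty
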