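"""Readers/writers: dialect parsing, stated row filters, round trips."""

import pandas as pd
import pytest

from aontriage import formats_io
from aontriage.formats_io import ParseError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestAssociationSources:
    def test_sysndd_rows_parsed_with_categories_preserved(self, tmp_path):
        p = _write(tmp_path, "s.tsv",
                   "gene_symbol\thgnc_id\tomim_id\tinheritance\tcategory\n"
                   "A1\tHGNC:1\tOMIM:600001\tAD\tdefinitive\n"
                   "A2\tHGNC:2\tOMIM:600002\tAR\tmoderate\n"
                   "A3\tHGNC:3\tOMIM:600003\tAD\tlimited\n")
        t = formats_io.read_association_source(p, "sysndd")
        assert len(t.rows) == 3
        assert list(t.rows["category"]) == ["definitive", "moderate", "limited"]

    def test_ddg2p_brain_cognition_filter(self, tmp_path):
        p = _write(tmp_path, "d.tsv",
                   "gene_symbol\thgnc_id\tdisease_mim\tallelic_requirement\t"
                   "confidence_category\torgan_specificity_list\n"
                   "B1\tHGNC:4\tOMIM:600004\tmonoallelic_autosomal\tstrong\t"
                   "Brain/Cognition;Eye\n"
                   "B2\tHGNC:5\tOMIM:600005\tbiallelic_autosomal\tstrong\tHeart\n")
        t = formats_io.read_association_source(p, "ddg2p")
        assert len(t.rows) == 1
        assert t.rows.iloc[0]["gene"] == "B1"
        assert t.rows.iloc[0]["inheritance"] == "AD"
        assert t.dropped["organ_system"] == 1

    def test_empty_file_with_header_only(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "gene_symbol\thgnc_id\tdisease_id\n")
        t = formats_io.read_association_source(p, "hpo")
        assert len(t.rows) == 0

    def test_missing_gene_column_is_a_parse_error_naming_the_dialect(self, tmp_path):
        p = _write(tmp_path, "bad.tsv", "foo\tbar\n1\t2\n")
        with pytest.raises(ParseError, match="sysndd"):
            formats_io.read_association_source(p, "sysndd")


CLINVAR_HEADER = (
    "VariationID\tName\tGeneSymbol\tClinSigSimple\tChromosome\tStart\tStop\t"
    "ReferenceAlleleVCF\tAlternateAlleleVCF\tPhenotypeIDS\tSubmissions\n"
)


class TestClinVar:
    def test_clinsigsimple_filter(self, tmp_path):
        rows = "".join(
            f"v{i}\tn\tG1\t{sig}\tchr1\t100\t100\tA\tC\tOMIM:600001\t2\n"
            for i, sig in enumerate([1, 0, 1, 0, 1])
        )
        p = _write(tmp_path, "cv.tsv", CLINVAR_HEADER + rows)
        t = formats_io.read_clinvar_summary(p)
        assert len(t.rows) == 3
        assert t.dropped["clinsig_not_1"] == 2

    def test_multiple_omim_ids_with_report_counts(self, tmp_path):
        p = _write(tmp_path, "cv.tsv", CLINVAR_HEADER +
                   "v1\tn\tG1\t1\tchr1\t100\t100\tA\tC\t"
                   "MedGen:C1,OMIM:600001|OMIM:600001|OMIM:600002\t3\n")
        t = formats_io.read_clinvar_summary(p)
        assert t.rows.iloc[0]["omim_counts"] == {
            "OMIM:600001": 2, "OMIM:600002": 1}

    def test_missing_submission_count_defaults_to_one(self, tmp_path, caplog):
        header = CLINVAR_HEADER.replace("\tSubmissions", "")
        p = _write(tmp_path, "cv.tsv", header +
                   "v1\tn\tG1\t1\tchr1\t100\t100\tA\tC\tOMIM:600001\n")
        with caplog.at_level("WARNING"):
            t = formats_io.read_clinvar_summary(p)
        assert t.rows.iloc[0]["submission_count"] == 1
        assert any("submission count" in r.message for r in caplog.records)

    def test_numbersubmitters_fallback(self, tmp_path):
        header = CLINVAR_HEADER.replace("Submissions", "NumberSubmitters")
        p = _write(tmp_path, "cv.tsv", header +
                   "v1\tn\tG1\t1\tchr1\t100\t100\tA\tC\tOMIM:600001\t7\n")
        t = formats_io.read_clinvar_summary(p)
        assert t.rows.iloc[0]["submission_count"] == 7

    def test_assembly_mismatch_is_a_hard_error(self, tmp_path):
        p = _write(tmp_path, "cv.tsv", "#Assembly: GRCh37\n" + CLINVAR_HEADER +
                   "v1\tn\tG1\t1\tchr1\t100\t100\tA\tC\tOMIM:600001\t1\n")
        with pytest.raises(ParseError, match="GRCh37"):
            formats_io.read_clinvar_summary(p)

    def test_coordinates_become_half_open(self, tmp_path):
        p = _write(tmp_path, "cv.tsv", CLINVAR_HEADER +
                   "v1\tn\tG1\t1\tchr1\t100\t102\tAAA\t\tOMIM:600001\t1\n")
        row = formats_io.read_clinvar_summary(p).rows.iloc[0]
        assert (row["start"], row["end"], row["length_bp"]) == (99, 102, 3)


GTF_ATTRS = 'gene_id "G1"; transcript_id "T1"; tag "MANE_Select";'


class TestTranscripts:
    def _gtf(self, tmp_path, lines):
        return _write(tmp_path, "t.gtf", "\n".join(lines) + "\n")

    def test_forward_strand_exons_in_genomic_order(self, tmp_path):
        p = self._gtf(tmp_path, [
            f"chr1\tx\texon\t101\t200\t.\t+\t.\t{GTF_ATTRS}",
            f"chr1\tx\texon\t301\t400\t.\t+\t.\t{GTF_ATTRS}",
            f"chr1\tx\texon\t501\t700\t.\t+\t.\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t151\t200\t.\t+\t0\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t301\t400\t.\t+\t0\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t501\t600\t.\t+\t0\t{GTF_ATTRS}",
        ])
        models = formats_io.read_transcripts(p)
        t = models["G1"]
        assert t.exons == ((100, 200), (300, 400), (500, 700))
        assert (t.cds_start, t.cds_end) == (150, 600)

    def test_reverse_strand_first_exon_is_most_threeprime_genomic(self, tmp_path):
        p = self._gtf(tmp_path, [
            f"chr1\tx\texon\t101\t200\t.\t-\t.\t{GTF_ATTRS}",
            f"chr1\tx\texon\t301\t400\t.\t-\t.\t{GTF_ATTRS}",
            f"chr1\tx\texon\t501\t700\t.\t-\t.\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t151\t650\t.\t-\t0\t{GTF_ATTRS}",
        ])
        t = formats_io.read_transcripts(p)["G1"]
        assert t.exons[0] == (500, 700)  # exon index 1 = most 3' genomic

    def test_only_mane_tagged_transcripts_returned(self, tmp_path):
        other = 'gene_id "G2"; transcript_id "T2";'
        p = self._gtf(tmp_path, [
            f"chr1\tx\texon\t101\t400\t.\t+\t.\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t151\t350\t.\t+\t0\t{GTF_ATTRS}",
            f"chr1\tx\texon\t1101\t1400\t.\t+\t.\t{other}",
            f"chr1\tx\tCDS\t1151\t1350\t.\t+\t0\t{other}",
        ])
        models = formats_io.read_transcripts(p)
        assert set(models) == {"G1"}

    def test_cds_outside_exons_is_a_validation_error(self, tmp_path):
        p = self._gtf(tmp_path, [
            f"chr1\tx\texon\t101\t200\t.\t+\t.\t{GTF_ATTRS}",
            f"chr1\tx\tCDS\t151\t260\t.\t+\t0\t{GTF_ATTRS}",
        ])
        with pytest.raises(ParseError, match="T1"):
            formats_io.read_transcripts(p)


class TestOntologyAndPhenotypes:
    def test_chain_of_four_terms(self, tmp_path):
        p = _write(tmp_path, "o.obo", "\n".join([
            "format-version: 1.2", "ontology: test", "",
            "[Term]", "id: HP:1", "name: a", "",
            "[Term]", "id: HP:2", "name: b", "is_a: HP:1", "",
            "[Term]", "id: HP:3", "name: c", "is_a: HP:2", "",
            "[Term]", "id: HP:4", "name: d", "is_a: HP:3", "",
        ]))
        o = formats_io.read_ontology(p)
        assert len(o.terms) == 4
        assert sum(len(v) for v in o.parents.values()) == 3

    def test_disease_phenotype_table(self, tmp_path):
        p = _write(tmp_path, "p2g.tsv",
                   "hpo_id\thpo_name\tgene_symbol\tdisease_id\n"
                   "HP:1\tx\tG1\tOMIM:600001\n"
                   "HP:2\tx\tG1\tOMIM:600001\n"
                   "HP:1\tx\tG2\tOMIM:600002\n")
        m = formats_io.read_disease_phenotypes(p)
        assert m["OMIM:600001"] == {"HP:1", "HP:2"}
        assert m["OMIM:600002"] == {"HP:1"}


class TestExpressionTadsLists:
    def test_gct_dimensions(self, tmp_path):
        lines = ["#1.2", "3\t3", "Name\tDescription\tT1\tT2\tT3"]
        for g in ["g1", "g2", "g3"]:
            lines.append(f"{g}\tna\t1.0\t2.0\t3.0")
        e = formats_io.read_expression(_write(tmp_path, "e.gct", "\n".join(lines)))
        assert e.tpm.shape == (3, 3)
        assert e.tissues == ["T1", "T2", "T3"]

    def test_duplicate_gene_is_an_error(self, tmp_path):
        lines = ["#1.2", "2\t2", "Name\tDescription\tT1\tT2",
                 "g1\tna\t1\t2", "g1\tna\t3\t4"]
        with pytest.raises(ParseError, match="duplicate"):
            formats_io.read_expression(_write(tmp_path, "e.gct", "\n".join(lines)))

    def test_tads_and_overlap(self, tmp_path):
        p = _write(tmp_path, "t.bed", "chr1\t0\t1000\nchr1\t1000\t2000\nchr2\t0\t500\n")
        tads = formats_io.read_tads(p)
        assert tads.share_tad(("chr1", 100, 200), ("chr1", 800, 900))
        assert not tads.share_tad(("chr1", 100, 200), ("chr1", 1100, 1200))
        assert not tads.share_tad(("chr1", 100, 200), ("chr2", 100, 200))

    def test_gene_list_named_by_header(self, tmp_path):
        p = _write(tmp_path, "l.tsv", "tango\nG1\nG2\n")
        name, genes = formats_io.read_gene_list(p)
        assert name == "tango" and genes == {"G1", "G2"}


class TestProfileRoundTrip:
    def test_write_then_read_identity(self, tmp_path):
        from aontriage import config

        df = pd.DataFrame({
            "subject_type": ["ndd", "variant"],
            "subject_id": ["G1|OMIM:1|AD", "v1"],
            "gene": ["G1", "G1"],
            "submission_count": [3, 2],
            **{s: [True, False] for s in config.STRATEGIES},
            "any_strategy": [True, False],
            "evidence": [{"a": 1}, {"b": [1, 2]}],
        })
        path = tmp_path / "p.tsv"
        formats_io.write_profile_table(df, path)
        back = formats_io.read_profile_table(path)
        pd.testing.assert_frame_equal(back, df)
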