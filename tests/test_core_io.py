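import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirprofiler.core_io import (
    CHROMOSOMES,
    CLASS_LABELS,
    Finding,
    FragileSite,
    FragileSiteCatalog,
    GenomicLocus,
    ParseError,
    SampleSheet,
    StudyRecord,
    format_locus,
    load_literature_studies,
    parse_locus,
    read_annotation,
    read_expression_matrix,
    read_fragile_sites,
    read_sample_sheet,
    read_study_records,
    write_annotation,
    write_expression_matrix,
    write_fragile_sites_bed,
    write_study_records,
)
from tests.conftest import make_matrix, make_sheet


class TestParseLocus:
    @pytest.mark.parametrize(
        "text, chrom, band, start, end, strand",
        [
            ("Chr21q21.1:17911409-17911489 [+]", "21", "q21.1", 17911409, 17911489, "+"),
            ("ChrX:78156691-78156746 [−]", "X", None, 78156691, 78156746, "-"),
            ("Chr10: 105154010-105154158 [−]", "10", None, 105154010, 105154158, "-"),
            ("Chr5q32: 149112388-149112453 [+]", "5", "q32", 149112388, 149112453, "+"),
            ("Chr17p13.1:6920934-6921020 [-]", "17", "p13.1", 6920934, 6921020, "-"),
        ],
    )
    def test_annotation_dialect(self, text, chrom, band, start, end, strand):
        locus = parse_locus(text)
        assert locus == GenomicLocus(chrom, start, end, strand, band)

    @pytest.mark.parametrize(
        "bad",
        [
            "Chr5:100-50 [+]",  # inverted interval
            "5q32:100-200 [+]",  # missing Chr prefix
            "ChrZ:100-200 [+]",  # unknown chromosome
            "Chr5:abc-200 [+]",  # non-numeric coordinate
            "Chr5:100-200",  # missing strand
            "",
        ],
    )
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(ParseError):
            parse_locus(bad)

    @given(
        chrom=st.sampled_from(CHROMOSOMES),
        band=st.one_of(
            st.none(),
            st.builds(
                lambda arm, a, b: f"{arm}{a}" + (f".{b}" if b else ""),
                st.sampled_from("pq"),
                st.integers(1, 39),
                st.one_of(st.none(), st.integers(1, 9)),
            ),
        ),
        start=st.integers(1, 10**8),
        span=st.integers(0, 10**4),
        strand=st.sampled_from(["+", "-"]),
    )
    def test_format_parse_roundtrip(self, chrom, band, start, span, strand):
        locus = GenomicLocus(chrom, start, start + span, strand, band)
        assert parse_locus(format_locus(locus)) == locus

    def test_unicode_minus_formats_as_ascii(self):
        locus = parse_locus("ChrX:10-20 [−]")
        assert "[-]" in format_locus(locus)


class TestExpressionMatrixIO:
    def test_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(0)
        em = make_matrix(rng.lognormal(size=(5, 4)))
        path = tmp_path / "m.tsv"
        write_expression_matrix(em, path)
        back = read_expression_matrix(path)
        assert back.probe_ids == em.probe_ids
        assert back.sample_ids == em.sample_ids
        np.testing.assert_array_equal(back.values, em.values)

    def test_duplicate_probe_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\ts2\npA\t1\t2\npA\t3\t4\n")
        with pytest.raises(ParseError, match="duplicate probe"):
            read_expression_matrix(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\npA\toops\n")
        with pytest.raises(ParseError, match="non-numeric"):
            read_expression_matrix(path)

    def test_sample_missing_from_sheet_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("probe_id\ts1\ts2\npA\t1\t2\n")
        sheet = make_sheet({"s1": "BRCA1-C"})
        with pytest.raises(ParseError, match="absent from sample sheet"):
            read_expression_matrix(path, sheet)

    def test_negative_raw_rejected(self):
        with pytest.raises(ParseError, match=">= 0"):
            make_matrix([[-1.0]])


class TestSampleSheet:
    def test_all_five_class_labels_accepted(self):
        sheet = make_sheet({f"s{i}": c for i, c in enumerate(CLASS_LABELS)})
        assert sheet.class_sizes() == {c: 1 for c in CLASS_LABELS}

    def test_unknown_label_rejected(self):
        with pytest.raises(ParseError, match="unknown class"):
            make_sheet({"s1": "BRCA3-C"})

    def test_duplicate_sample_rejected(self):
        df = pd.DataFrame({"class_label": ["BRCA1-C", "BRCA1-N"]}, index=["s1", "s1"])
        with pytest.raises(ParseError, match="duplicate sample"):
            SampleSheet(data=df)

    def test_covariate_vocabulary_checked(self, tmp_path):
        path = tmp_path / "sheet.csv"
        path.write_text("sample_id,class_label,HER2\ns1,BRCA1-C,maybe\n")
        with pytest.raises(ParseError, match="HER2"):
            read_sample_sheet(path)


class TestFragileSites:
    def test_bed_interval_converted_to_one_based_closed(self, tmp_path):
        path = tmp_path / "sites.bed"
        path.write_text("chr7\t100\t200\tFRA7X\n")
        catalog = read_fragile_sites(path)
        site = catalog.entries[0]
        assert (site.start, site.end, site.name) == (101, 200, "FRA7X")
        assert catalog.contains(GenomicLocus("7", 150, 160, "+"))
        assert catalog.contains(GenomicLocus("7", 200, 300, "+"))  # touches end
        assert not catalog.contains(GenomicLocus("7", 201, 300, "+"))
        assert not catalog.contains(GenomicLocus("8", 150, 160, "+"))

    def test_cytoband_dialect_and_subband_matching(self, tmp_path):
        path = tmp_path / "sites.txt"
        path.write_text("3\tp14.2\tFRA3B\n16\tq23\tFRA16D\n")
        catalog = read_fragile_sites(path)
        assert catalog.contains(GenomicLocus("3", 1, 2, "+", cytoband="p14.2"))
        # a site at a major band covers its sub-bands and vice versa
        assert catalog.contains(GenomicLocus("16", 1, 2, "+", cytoband="q23.2"))
        assert not catalog.contains(GenomicLocus("16", 1, 2, "+", cytoband="q24"))
        assert not catalog.contains(GenomicLocus("16", 1, 2, "+"))  # no band, no coords

    def test_write_read_round_trip(self, tmp_path):
        catalog = FragileSiteCatalog(
            entries=[
                FragileSite("3", "FRA3B", cytoband="p14.2"),
                FragileSite("7", "FRA7X", start=101, end=200),
            ]
        )
        path = tmp_path / "sites.bed"
        write_fragile_sites_bed(catalog, path)
        assert read_fragile_sites(path).entries == catalog.entries

    def test_empty_bed_interval_rejected(self, tmp_path):
        path = tmp_path / "sites.bed"
        path.write_text("chr7\t100\t100\tFRA7X\n")
        with pytest.raises(ParseError):
            read_fragile_sites(path)


class TestAnnotationIO:
    def test_round_trip_with_unknown(self, tmp_path):
        ann = {
            "pA": GenomicLocus("21", 17911409, 17911489, "+", "q21.1"),
            "pB": None,
        }
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        assert read_annotation(path) == ann


class TestStudyRecords:
    def test_six_study_compilation_loads(self):
        records = load_literature_studies()
        sizes = {r.study_name: r.n_samples for r in records}
        assert sizes == {
            "Chen": 24, "Iorio": 110, "Ouyang": 6, "Tahiri": 58, "Tanic": 36, "Yan": 8,
        }
        assert all(r.findings for r in records)

    def test_fold_change_magnitude_convention(self):
        with pytest.raises(ParseError, match="magnitude"):
            Finding("miR-x", "up", fold_change=0.5)

    def test_unknown_direction_token(self):
        with pytest.raises(ParseError, match="direction"):
            Finding("miR-x", "sideways")

    def test_empty_findings_record_is_valid(self, tmp_path):
        path = tmp_path / "studies.csv"
        path.write_text("study,n_samples,mirna,direction,fold_change\nSolo,10,,,\n")
        records = read_study_records(path)
        assert len(records) == 1 and records[0].findings == []

    def test_non_positive_sample_count_rejected(self):
        with pytest.raises(ParseError, match="sample count"):
            StudyRecord("Bad", 0)

    def test_duplicate_finding_rejected(self):
        with pytest.raises(ParseError, match="duplicate finding"):
            StudyRecord("Dup", 5, [Finding("miR-x", "up"), Finding("miR-x", "up")])

    def test_write_read_round_trip(self, tmp_path):
        records = [
            StudyRecord("A", 10, [Finding("miR-1", "up", 2.5), Finding("miR-2", "down")]),
            StudyRecord("B", 3, []),
        ]
        path = tmp_path / "studies.csv"
        write_study_records(records, path)
        back = read_study_records(path)
        assert {r.study_name: r.n_samples for r in back} == {"A": 10, "B": 3}
        a = next(r for r in back if r.study_name == "A")
        assert a.findings == records[0].findings
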