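"""Interval table reading (BED/VCF/custom) and column-appending output."""

import io

import pytest

from annotx.errors import ConfigurationError, TableFormatError
from annotx.table_io import (
    IntervalRecord,
    MalformedLine,
    PassthroughLine,
    TableReader,
    TableSchema,
    read_intervals,
    write_annotated,
)


def records(text, schema):
    return [r for r in read_intervals(io.StringIO(text), schema) if isinstance(r, IntervalRecord)]


def test_bed_line_parsed_half_open(tmp_path):
    (rec,) = records("chr1\t99\t200\tpeak1\n", TableSchema.bed())
    assert (rec.reference, rec.start, rec.end, rec.id) == ("chr1", 100, 200, "peak1")


def test_bed_without_name_column_synthesizes_id():
    (rec,) = records("chr1\t99\t200\n", TableSchema.bed())
    assert rec.id == "chr1:99-200"


def test_vcf_interval_spans_ref_allele():
    text = (
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr2\t1000\trs1\tACG\tA\t.\t.\t.\n"
        "chr2\t2000\t.\tT\tC\t.\t.\t.\n"
    )
    recs = records(text, TableSchema.vcf())
    assert (recs[0].start, recs[0].end, recs[0].id) == (1000, 1002, "rs1")
    assert recs[1].id == "chr2:2000"  # missing ID synthesized


def test_custom_schema_with_psrnatarget_layout():
    """psRNATarget-style TSV: ID in column 1, reference in column 2,
    start/end in columns 7 and 8, 1-based."""
    header = "\t".join(["miRNA_Acc.", "Target_Acc.", "E", "UPE", "s", "e",
                        "Target_start", "Target_end", "rest"])
    row = "\t".join(["3-bna-miR156a", "CDY69014", "2.5", ".", "1", "21",
                     "682", "702", "Cleavage"])
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=7, end_col=8)
    items = list(read_intervals(io.StringIO(header + "\n" + row + "\n"), schema))
    assert isinstance(items[0], PassthroughLine) and items[0].is_header
    rec = items[1]
    assert (rec.id, rec.reference, rec.start, rec.end) == ("3-bna-miR156a", "CDY69014", 682, 702)


def test_custom_zero_based_coordinates_normalized():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, base=0)
    (rec,) = records("x\tchr1\t5\t10\n", schema)
    assert (rec.start, rec.end) == (6, 10)


def test_header_auto_detection_requires_non_numeric_coordinate():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="auto")
    # numeric first row: treated as data, not header
    assert len(records("a\tchr1\t10\t20\nb\tchr1\t30\t40\n", schema)) == 2
    # alphabetic coordinate fields: treated as a header
    assert len(records("id\tref\tstart\tend\na\tchr1\t10\t20\n", schema)) == 1


def test_custom_schema_requires_all_four_columns():
    with pytest.raises(ConfigurationError):
        TableSchema.custom(id_col=1, ref_col=2, start_col=None, end_col=4)


def test_malformed_rows_skipped_and_counted():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="absent")
    text = "a\tchr1\t10\t20\nb\tchr1\n" + "c\tchr1\t5\tnotint\n" + "d\tchr1\t30\t40\n"
    reader = TableReader(io.StringIO(text), schema)
    items = list(reader)
    assert sum(isinstance(i, MalformedLine) for i in items) == 2
    assert reader.n_malformed == 2 and reader.n_rows == 4


def test_mostly_malformed_input_is_fatal():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="absent")
    text = "a,chr1,10,20\nb,chr1,30,40\nc,chr1,50,60\n"  # wrong separator
    with pytest.raises(TableFormatError):
        list(TableReader(io.StringIO(text), schema))


def test_inverted_interval_emitted_flagged_not_skipped():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="absent")
    (rec,) = records("a\tchr1\t50\t20\n", schema)
    assert rec.start is None and rec.invalid_reason


def test_comment_lines_pass_through_unchanged():
    text = "# a comment\nchr1\t0\t10\tx\n"
    items = list(read_intervals(io.StringIO(text), TableSchema.bed()))
    assert isinstance(items[0], PassthroughLine)
    assert items[0].text == "# a comment"


def test_write_appends_columns_and_preserves_original_bytes():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="present")
    in_lines = ["id\tref\tstart\tend", "a\tCDY1\t10\t20", "b\tCDY2\t30\t40"]
    items = list(read_intervals(io.StringIO("\n".join(in_lines) + "\n"), schema))
    out_items = [
        it if isinstance(it, PassthroughLine) else (it, [["G1", "middle"]])
        for it in items
    ]
    buf = io.StringIO()
    write_annotated(out_items, ["annotated_gene_id", "feature_region"], schema, buf)
    out_lines = buf.getvalue().splitlines()
    assert out_lines[0] == in_lines[0] + "\tannotated_gene_id\tfeature_region"
    # stripping the two appended columns reproduces the input exactly
    stripped = ["\t".join(line.split("\t")[:-2]) for line in out_lines]
    assert stripped == in_lines


def test_write_without_input_header_emits_placeholder_header():
    schema = TableSchema.custom(id_col=1, ref_col=2, start_col=3, end_col=4, header="absent")
    items = list(read_intervals(io.StringIO("a\tchr1\t10\t20\n"), schema))
    buf = io.StringIO()
    write_annotated([(items[0], [["."]])], ["feature_region"], schema, buf)
    lines = buf.getvalue().splitlines()
    assert lines[0].startswith("column_1\t") and lines[0].endswith("feature_region")
    assert lines[1] == "a\tchr1\t10\t20\t."


def test_crlf_input_round_trips():
    schema = TableSchema.bed()
    items = list(read_intervals(io.StringIO("chr1\t0\t10\tx\r\n"), schema))
    assert items[0].original_line == "chr1\t0\t10\tx"
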