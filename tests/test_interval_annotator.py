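"""Annotation engine: genomic and transcriptomic modes, intergenic
neighbours, gene-level grouping, attribute/feature selection."""

import pytest

from annotx import AnnotationOptions, Annotator, build_database
from annotx.errors import ConfigurationError
from annotx.table_io import IntervalRecord
from annotx import fixtures as fx


def iv(ref, start, end, id="q1", n=1):
    return IntervalRecord(n, id, ref, start, end, f"{id}\t{ref}\t{start}\t{end}")


SINGLE_GENE_GFF3 = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA;gene_biotype=protein_coding
chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=txA;Parent=geneA;transcript_biotype=protein_coding
chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tParent=txA
"""

TWO_GENE_GFF3 = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=txA;Parent=geneA
chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tParent=txA
chr1\tsrc\tgene\t8000\t9000\t.\t-\t.\tID=geneB
chr1\tsrc\tmRNA\t8000\t9000\t.\t-\t.\tID=txB;Parent=geneB
chr1\tsrc\texon\t8000\t9000\t.\t-\t.\tParent=txB
"""

# spliced length 1244, 5'UTR 1-200, CDS 201-1000, 3'UTR 1001-1244 (one exon)
UTR_CDS_GFF3 = """\
##gff-version 3
chr1\tsrc\tgene\t5000\t6243\t.\t+\t.\tID=geneU
chr1\tsrc\tmRNA\t5000\t6243\t.\t+\t.\tID=txU;Parent=geneU
chr1\tsrc\texon\t5000\t6243\t.\t+\t.\tParent=txU
chr1\tsrc\tfive_prime_utr\t5000\t5199\t.\t+\t.\tParent=txU
chr1\tsrc\tcds\t5200\t5999\t.\t+\t.\tParent=txU
chr1\tsrc\tthree_prime_utr\t6000\t6243\t.\t+\t.\tParent=txU
"""


def test_genomic_single_gene_region_middle(db_from_text):
    db = db_from_text(SINGLE_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chr1", 1500, 1600))
    assert row.get("annotated_gene_id") == "geneA"
    assert row.get("annotated_transcript_id") == "txA"
    # positions 501..601 of a 1001-base transcript: Q3 -> Q3
    assert row.get("feature_region") == "middle"


def test_intergenic_row_with_closest_neighbours(db_from_text):
    db = db_from_text(TWO_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chr1", 5000, 5100))
    assert row.get("annotated_feature_type") == "intergenic"
    assert row.get("closest_gene_left") == "geneA"
    assert row.get("distance_left") == "3000"
    assert row.get("closest_gene_right") == "geneB"
    assert row.get("distance_right") == "2900"
    assert row.get("strand_right") == "-"


def test_interval_before_all_genes_has_no_left_neighbour(db_from_text):
    db = db_from_text(TWO_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chr1", 10, 20))
    assert row.get("closest_gene_left") == "."
    assert row.get("closest_gene_right") == "geneA"


def test_adjacent_gene_distance_is_one(db_from_text):
    db = db_from_text(TWO_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chr1", 2001, 2010))
    assert row.get("distance_left") == "1"


def test_unknown_seqid_yields_lone_intergenic_row(db_from_text):
    db = db_from_text(TWO_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chrUn", 100, 200))
    assert row.get("annotated_feature_type") == "intergenic"
    assert row.get("closest_gene_left") == "." and row.get("closest_gene_right") == "."


def test_transcriptomic_cds_interval(db_from_text):
    db = db_from_text(UTR_CDS_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="transcriptomic"))
    (row,) = ann.annotate(iv("txU", 682, 702))
    assert row.get("cds") == "y"
    assert row.get("five_prime_utr") == "." and row.get("three_prime_utr") == "."
    assert row.get("feature_region") == "middle"
    assert row.get("annotated_gene_id") == "geneU"


def test_transcriptomic_junction_interval_flags_both_features(db_from_text):
    db = db_from_text(UTR_CDS_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="transcriptomic"))
    (row,) = ann.annotate(iv("txU", 150, 250))
    assert row.get("five_prime_utr") == "y" and row.get("cds") == "y"


def test_transcriptomic_unknown_reference_emits_dot_row(db_from_text):
    db = db_from_text(UTR_CDS_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="transcriptomic"))
    (row,) = ann.annotate(iv("CDY_missing", 10, 20))
    assert row.get("annotated_gene_id") == "."
    assert row.get("feature_region") == "."
    assert row.get("annotation_note") == "unknown reference"


def test_transcriptomic_end_beyond_spliced_length_clamped_and_noted(db_from_text):
    db = db_from_text(UTR_CDS_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="transcriptomic"))
    (row,) = ann.annotate(iv("txU", 1200, 1500))
    assert "clamped" in row.get("annotation_note")
    assert row.get("feature_region") == "3 prime"


def test_case_insensitive_transcript_reference(db_from_text):
    db = db_from_text(UTR_CDS_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="transcriptomic"))
    (row,) = ann.annotate(iv("TXU", 682, 702))
    assert row.get("annotated_transcript_id") == "txU"


def test_full_containment_matches_are_subset_of_partial(genome):
    truth, db = genome["truth"], genome["db"]
    cases = fx.generate_intervals(truth, "genomic", 40, seed=3, with_expected=False)
    ann_p = Annotator(db, AnnotationOptions(mode="genomic", containment="partial"))
    ann_f = Annotator(db, AnnotationOptions(mode="genomic", containment="full"))
    for c in cases:
        rec = IntervalRecord(1, c.id, c.reference, c.start, c.end, "x")
        partial = {r.get("annotated_transcript_id") for r in ann_p.annotate(rec)} - {"."}
        full = {r.get("annotated_transcript_id") for r in ann_f.annotate(rec)} - {"."}
        assert full <= partial


def test_gene_level_grouping_ors_flags_and_joins_transcripts(db_from_text):
    text = """\
##gff-version 3
chr1\tsrc\tgene\t100\t1000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=tx1;Parent=geneA
chr1\tsrc\texon\t100\t1000\t.\t+\t.\tParent=tx1
chr1\tsrc\tcds\t100\t500\t.\t+\t.\tParent=tx1
chr1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=tx2;Parent=geneA
chr1\tsrc\texon\t100\t1000\t.\t+\t.\tParent=tx2
chr1\tsrc\tthree_prime_utr\t400\t1000\t.\t+\t.\tParent=tx2
"""
    db = db_from_text(text)
    record = iv("chr1", 450, 460)
    tx_rows = Annotator(db, AnnotationOptions(mode="genomic")).annotate(record)
    assert len(tx_rows) == 2
    gene_ann = Annotator(db, AnnotationOptions(mode="genomic", level="gene"))
    (grouped,) = gene_ann.annotate(record)
    assert grouped.get("annotated_transcript_id") == "tx1,tx2"
    assert grouped.get("cds") == "y" and grouped.get("three_prime_utr") == "y"
    assert grouped.get("annotated_feature_type") == "gene"
    # the (interval, gene) pair set is unchanged by grouping
    assert {r.get("annotated_gene_id") for r in tx_rows} == {grouped.get("annotated_gene_id")}


def test_attribute_selection_limits_columns(db_from_text):
    db = db_from_text(SINGLE_GENE_GFF3)
    ann = Annotator(db, AnnotationOptions(mode="genomic", attributes=["gene_biotype"]))
    assert ann.attribute_columns == ["gene_biotype"]
    assert "transcript_biotype" not in ann.column_names


def test_unknown_attribute_is_fatal_and_names_available(db_from_text):
    db = db_from_text(SINGLE_GENE_GFF3)
    with pytest.raises(ConfigurationError) as err:
        Annotator(db, AnnotationOptions(attributes=["no_such_attr"]))
    assert "gene_biotype" in str(err.value)


def test_unknown_feature_type_selection_is_fatal(db_from_text):
    db = db_from_text(SINGLE_GENE_GFF3)
    with pytest.raises(ConfigurationError):
        Annotator(db, AnnotationOptions(feature_types=["promoter"]))


def test_every_input_row_yields_at_least_one_output_row(genome):
    truth, db = genome["truth"], genome["db"]
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    cases = fx.generate_intervals(truth, "genomic", 40, seed=9, with_expected=False)
    for n, c in enumerate(cases, 1):
        rows = ann.annotate(IntervalRecord(n, c.id, c.reference, c.start, c.end, "x"))
        assert len(rows) >= 1


def test_intronic_genomic_interval_labeled_intronic(db_from_text):
    text = """\
##gff-version 3
chr1\tsrc\tgene\t100\t1000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t100\t1000\t.\t+\t.\tID=tx1;Parent=geneA
chr1\tsrc\texon\t100\t200\t.\t+\t.\tParent=tx1
chr1\tsrc\texon\t800\t1000\t.\t+\t.\tParent=tx1
"""
    db = db_from_text(text)
    ann = Annotator(db, AnnotationOptions(mode="genomic"))
    (row,) = ann.annotate(iv("chr1", 300, 400))
    assert row.get("feature_region") == "intronic"
    assert row.get("exon") == "."
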