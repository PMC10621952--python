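"""Feature database: parsing, lowercasing, hierarchy, queries, persistence."""

import random

import pytest

from annotx import build_database, inspect_hierarchy
from annotx.errors import ParseError, UnknownReferenceError

MINIMAL_GFF3 = """\
##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=t1;Parent=g1
chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tID=e1;Parent=t1
"""


def test_minimal_gff3_builds_three_feature_hierarchy(db_from_text):
    db = db_from_text(MINIMAL_GFF3)
    assert db.count_features() == 3
    h = db.hierarchy()
    assert h.nodes == {"gene", "mrna", "exon"}
    assert ("gene", "mrna") in h.edges and ("mrna", "exon") in h.edges
    rendering = inspect_hierarchy(db)
    assert rendering.splitlines()[0].startswith("gene")
    assert "mrna" in rendering and "exon" in rendering


def test_attribute_keys_lowercased_values_preserved(db_from_text):
    db = db_from_text(
        'chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "G1"; Gene_Biotype "Protein_Coding";\n',
        suffix=".gtf",
    )
    gene = db.fetch_feature("g1")  # ID lookup is case-insensitive
    assert gene is not None and gene.feature_id == "G1"
    assert gene.attributes["gene_biotype"] == "Protein_Coding"  # value untouched
    assert "Gene_Biotype" not in gene.attributes


def test_feature_count_matches_line_count_oracle(genome):
    with open(genome["gtf"]) as fh:
        n_lines = sum(1 for line in fh if line.strip() and not line.startswith("#"))
    assert genome["db"].count_features() == n_lines


def test_hierarchy_attributes_match_raw_file_scan(genome):
    # brute-force scan of the raw GTF: attribute keys seen per feature type
    seen = {}
    with open(genome["gtf"]) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            ftype = fields[2].lower()
            for part in fields[8].split(";"):
                part = part.strip()
                if part:
                    seen.setdefault(ftype, set()).add(part.split(" ")[0].lower())
    attrs = genome["db"].hierarchy().attributes_per_type
    assert {t: set(a) for t, a in attrs.items()} == seen


def test_utr_types_listed_under_transcript(db_from_text):
    db = db_from_text(
        MINIMAL_GFF3
        + "chr1\tsrc\tfive_prime_utr\t1000\t1099\t.\t+\t.\tParent=t1\n"
        + "chr1\tsrc\tthree_prime_utr\t1900\t2000\t.\t+\t.\tParent=t1\n"
    )
    h = db.hierarchy()
    assert ("mrna", "five_prime_utr") in h.edges
    assert ("mrna", "three_prime_utr") in h.edges


@pytest.mark.parametrize(
    "query,expect_hit",
    [((1500, 1600), True),  # containment
     ((2000, 2100), True),  # closed-interval touch at the last base
     ((2001, 2100), False)],
)
def test_fetch_overlapping_closed_interval_arithmetic(db_from_text, query, expect_hit):
    db = db_from_text(MINIMAL_GFF3)
    hits = db.fetch_overlapping("chr1", *query, feature_types=["gene"])
    assert bool(hits) == expect_hit


def test_fetch_overlapping_equals_brute_force(db_from_text):
    rng = random.Random(7)
    lines = ["##gff-version 3"]
    genes = []
    for i in range(50):
        s = rng.randint(1, 20000)
        e = s + rng.randint(0, 800)
        genes.append((f"g{i}", s, e))
        lines.append(f"chr1\tsrc\tgene\t{s}\t{e}\t.\t+\t.\tID=g{i}")
    db = db_from_text("\n".join(lines) + "\n")
    for _ in range(100):
        qs = rng.randint(1, 21000)
        qe = qs + rng.randint(0, 500)
        expected = {g for g, s, e in genes if s <= qe and e >= qs}
        hits = db.fetch_overlapping("chr1", qs, qe)
        assert {f.feature_id for f in hits} == expected
        assert [f.start for f in hits] == sorted(f.start for f in hits)


def test_children_in_genomic_order_and_case_insensitive_tx_lookup(genome):
    truth = genome["truth"]
    t = next(iter(truth.transcripts.values()))
    kids = genome["db"].fetch_children(t.transcript_id)
    assert [k.start for k in kids] == sorted(k.start for k in kids)
    recs = genome["db"].fetch_by_transcript_id(t.transcript_id.lower())
    assert recs.transcript.feature_id == t.transcript_id
    assert recs.gene.feature_id == t.gene_id
    exons = [(c.start, c.end) for c in recs.children if c.feature_type == "exon"]
    assert exons == t.exons


def test_unknown_transcript_raises_recoverable_signal(genome):
    with pytest.raises(UnknownReferenceError):
        genome["db"].fetch_by_transcript_id("no_such_transcript")


def test_persistence_round_trip(genome, tmp_path):
    from annotx import AnnotationDatabase

    path = tmp_path / "anno.db"
    db1 = build_database(genome["gtf"], str(path))
    before = [(f.feature_id, f.start, f.end, f.parent_id, tuple(sorted(f.attributes.items())))
              for f in db1.iter_features()]
    db1.close()
    db2 = AnnotationDatabase.open(str(path))
    after = [(f.feature_id, f.start, f.end, f.parent_id, tuple(sorted(f.attributes.items())))
             for f in db2.iter_features()]
    assert before == after
    assert {f.feature_id for f in db2.fetch_overlapping("chr1", 1, 10**9)} == {
        f.feature_id for f in db2.iter_features() if f.seqid == "chr1"
    }


def test_disk_direct_equals_memory_first(genome, tmp_path):
    from annotx import AnnotationDatabase

    p1, p2 = tmp_path / "m.db", tmp_path / "d.db"
    build_database(genome["gtf"], str(p1), disk_direct=False).close()
    build_database(genome["gtf"], str(p2), disk_direct=True).close()
    d1, d2 = AnnotationDatabase.open(str(p1)), AnnotationDatabase.open(str(p2))
    key = lambda f: (f.seqid, f.start, f.feature_id)
    rows1 = [(f.feature_id, f.feature_type, f.start, f.end, f.parent_id)
             for f in sorted(d1.iter_features(), key=key)]
    rows2 = [(f.feature_id, f.feature_type, f.start, f.end, f.parent_id)
             for f in sorted(d2.iter_features(), key=key)]
    assert rows1 == rows2


def test_dangling_parent_kept_with_warning(db_from_text, caplog):
    db = db_from_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t1\t100\t.\t+\t.\tID=t1;Parent=missing\n"
    )
    assert db.count_features() == 2
    t = db.fetch_feature("t1")
    assert t.parent_id is None


def test_gtf_without_gene_transcript_lines_synthesizes_parents(db_from_text):
    attr = 'gene_id "G1"; transcript_id "T1";'
    db = db_from_text(
        f"chr1\tsrc\texon\t100\t200\t.\t+\t.\t{attr}\n"
        f"chr1\tsrc\texon\t300\t400\t.\t+\t.\t{attr}\n",
        suffix=".gtf",
    )
    tx = db.fetch_feature("T1")
    assert tx is not None and (tx.start, tx.end) == (100, 400)
    gene = db.fetch_feature("G1")
    assert gene is not None and gene.feature_type == "gene"
    assert tx.parent_id == "G1"


def test_fasta_section_and_comments_ignored(db_from_text):
    db = db_from_text(MINIMAL_GFF3 + "##FASTA\n>chr1\nACGT\n")
    assert db.count_features() == 3


def test_malformed_line_is_fatal_with_line_number(tmp_path):
    path = tmp_path / "bad.gff3"
    path.write_text("chr1\tsrc\tgene\tnotanumber\t10\t.\t+\t.\tID=g1\n")
    with pytest.raises(ParseError) as err:
        build_database(str(path))
    assert "line 1" in str(err.value)


def test_empty_database_renders_notice(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text("##gff-version 3\n")
    db = build_database(str(path))
    assert "empty" in inspect_hierarchy(db)
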