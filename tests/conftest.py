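import pytest

from annotx import build_database
from annotx import fixtures as fx


@pytest.fixture(scope="session")
def genome(tmp_path_factory):
    """A small deterministic synthetic genome: truth + GTF/GFF3 + database."""
    d = tmp_path_factory.mktemp("genome")
    spec = fx.GenomeSpec(seed=11, n_chromosomes=2, n_genes=20)
    gtf = d / "genome.gtf"
    gff3 = d / "genome.gff3"
    truth = fx.generate_annotation(spec, gtf_path=str(gtf), gff3_path=str(gff3))
    db = build_database(str(gtf))
    return {"spec": spec, "truth": truth, "gtf": str(gtf), "gff3": str(gff3), "db": db}


@pytest.fixture()
def db_from_text(tmp_path):
    """Build an in-memory database from literal GTF/GFF3 text."""

    def _build(text, suffix=".gff3"):
        path = tmp_path / f"anno{suffix}"
        path.write_text(text)
        return build_database(str(path))

    return _build


#: worked example of annotated miRNA target sites (custom 1-based input,
#: psRNATarget column layout), used for summary tallies: (miRNA id,
#: transcript, start, end, cds, 5'utr, 3'utr, region)
MIRNA_EXAMPLE_ROWS = [
    ("3-bna-miR156a", "CDY69014", 682, 702, "y", ".", ".", "middle"),
    ("67-bna-miR156a", "CDY37684", 463, 483, ".", ".", "y", "3 prime"),
    ("68-bna-miR156a", "CDY57212", 524, 544, ".", ".", "y", "3 prime"),
    ("69-bna-miR156a", "CDX79544", 593, 613, ".", ".", "y", "3 prime"),
    ("70-bna-miR156a", "CDY17204", 642, 662, ".", ".", "y", "3 prime"),
    ("71-bna-miR156a", "CDY34028", 862, 882, "y", ".", ".", "3 prime"),
    ("72-bna-miR156b", "CDX80287", 335, 355, ".", ".", "y", "middle"),
    ("73-bna-miR156c", "CDX80287", 335, 355, ".", ".", "y", "middle"),
]


@pytest.fixture(scope="session")
def mirna_example_rows():
    return MIRNA_EXAMPLE_ROWS
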