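# annotx

Flexible annotation of genomic and transcriptomic intervals with
features from GTF/GFF3 annotation files.

High-throughput analyses constantly produce interval tables — peaks,
variants, predicted miRNA binding sites, cross-linking sites, structure
probing windows — that need biological context: which gene and
transcript does an interval hit, does it fall in the CDS or a UTR, where
along the transcript does it sit, and if it hits nothing, what are its
nearest genes?  `annotx` answers these questions for intervals given in
**genomic coordinates** (chromosome + position, e.g. BED or VCF) *and*
for intervals given in **transcript coordinates** (positions along the
spliced transcript, as produced by tools like psRNATarget that work on
mRNA sequences) — the case most annotators cannot handle at all.

Annotation is column-appending: every line of the input file is
reproduced byte-for-byte with the annotation added as extra columns, so
any column-based table survives the round trip.

## Model

All features of a GTF/GFF3 file are loaded once into a single-file
SQLite database (`annotx create-db`), with feature types and attribute
keys lowercased for case-insensitive querying; the database is a
reusable artifact.  A transcript is modelled as its ordered exon chain;
transcript coordinates count exonic bases 1..L from the 5' end, where
L = Σ(end − start + 1) over exons.  A genomic interval is projected onto
a transcript by counting exonic bases (spliced projection); a transcript
interval maps back to genomic blocks exactly.

The relative region of an interval `[s, e]` within a transcript of
spliced length L is derived from the quartiles q(p) = ⌈4p/L⌉ of its
endpoints:

| label     | rule                                               |
|-----------|----------------------------------------------------|
| `5 prime` | q(s) = 1 and q(e) ≤ 2                              |
| `middle`  | q(s), q(e) ∈ {2, 3}                                |
| `3 prime` | q(s) ≥ 3 and q(e) = 4                              |
| `whole`   | q(s) = 1, q(e) = 4, length ≤ 90% of L              |
| `full`    | q(s) = 1, q(e) = 4, length > 90% of L              |

Intervals overlapping no transcript are marked `intergenic` with the
closest gene on each side and its distance.  Fully intronic intervals
are labelled `intronic`.

## Worked example

Build a database (here from a synthetic annotation produced by the
built-in generator) and annotate a BED file:

```sh
annotx create-db genes.gtf -o genes.db
```

    gene  [gene_biotype, gene_id, gene_name]
    └── transcript  [gene_biotype, gene_id, ..., transcript_id]
        ├── cds
        ├── exon
        ├── five_prime_utr
        └── three_prime_utr

The printed hierarchy lists every feature type and attribute available
for annotation.  Then:

```sh
annotx annotate -d genes.db -i peaks.bed --attributes gene_biotype --features cds
```

```text
column_1  column_2  column_3  column_4  annotated_gene_id  annotated_transcript_id  annotated_feature_type  annotated_chromosome  annotated_transcript_start  annotated_transcript_end  cds  gene_biotype    feature_region
chr1      912       1005      iv1       G00001             G00001.T1                transcript              chr1                  870                         1134                      y    protein_coding  middle
chr1      7014      7296      iv2       G00006             G00006.T1                transcript              chr1                  6590                        7236                      .    lncrna          3 prime
chr1      5865      5921      iv3       G00005             G00005.T1                transcript              chr1                  5539                        6111                      .    protein_coding  intronic
chr1      7844      7940      iv4       .                  .                        intergenic              chr1                  .                           .                         .    .               .
```

Reading the rows: interval `iv1` (BED `chr1:912-1005`, i.e. bases
913–1005 1-based) overlaps transcript `G00001.T1`, hits its CDS
(`cds = y`) and sits in the middle half of the spliced transcript;
`iv3` falls inside an intron of `G00005.T1`; `iv4` overlaps no gene and
is intergenic (its nearest flanking genes and distances appear in the
`closest_gene_left/right` columns further right).  Intervals overlapping
several transcripts get one row per transcript (or one per gene with
`--level gene`).

Transcript-coordinate tables — e.g. psRNATarget output, where column 1
is the miRNA ID, column 2 the target mRNA accession and columns 7/8 the
binding-site start/end within the transcript — are annotated with:

```sh
annotx annotate -d genes.db -i targets.tsv --format custom --mode transcriptomic \
    --id-col 1 --ref-col 2 --start-col 7 --end-col 8
```

Add `--stats report.txt` for per-column category counts (biotypes,
CDS/UTR flags, region labels) of a run.

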