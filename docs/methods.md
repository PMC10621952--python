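# Methods

## Feature database

`annotx create-db` parses a GTF or GFF3 file into a single-file SQLite
database with three tables: `features` (id, type, seqid, span, strand,
parent), `attributes` (key/value pairs per feature) and `meta`.  Line
and attribute-string parsing is delegated to `gffutils`; the schema,
hierarchy computation and query layer are this package's own.  Feature
types and attribute **keys** are lowercased at load time so every later
lookup (feature types, attribute names, reference IDs) is
case-insensitive; attribute **values** are stored verbatim, because they
carry identifiers (`CDY69014`, biotype strings) whose case users expect
back unchanged.

Dialect detection is by file extension first (`.gtf` vs
`.gff`/`.gff3`), falling back to sniffing the attribute column of the
first data line (`key=value` pairs ⇒ GFF3, quoted values ⇒ GTF).
GFF3 parent links come from the `Parent` attribute; GTF files, which in
the wild often lack explicit gene/transcript lines, get missing gene and
transcript records synthesized from the `gene_id`/`transcript_id`
attributes, spanning the extent of their children.  Dangling parent
references are kept (with a warning) as unparented features; duplicate
feature IDs get an ordinal suffix.  Comment/pragma lines are ignored
silently and an embedded `##FASTA` section terminates parsing.

Two build modes exist because they trade memory for time: the default
builds the database in memory and copies it to the output file at the
end (SQLite backup API); `--disk-direct` writes incrementally with a
flat memory profile.  Both produce equivalent databases, and a persisted
database reopens with identical query results, so it is built once per
annotation file and reused.

The feature-type hierarchy (e.g. gene → transcript → exon/cds/UTRs) and
the attribute names observed per type are computed from the stored
parent links and printed at build time; annotation-time selections of
features or attributes are validated against this hierarchy up front,
and an unknown name aborts the run listing what is available.

"Gene" features are recognised by type name (any type ending in `gene`,
covering `gene`, `ncrna_gene`, `pseudogene`, …); "transcript" types are
whatever types occur as direct children of gene features.

## Coordinates

The canonical internal convention is 1-based, end-inclusive — the
native convention of GTF/GFF3 — and conversion happens exactly once at
the table boundary: BED is 0-based half-open, VCF 1-based inclusive
(interval = POS … POS + len(REF) − 1), and custom tables declare their
base (0 or 1) explicitly.

A transcript is its sorted, disjoint exon chain; transcripts with no
exon records fall back to one pseudo-exon spanning the transcript
record.  Transcript coordinates run 1..L from the 5' end: position 1 is
the first base of the genomically-leftmost exon on the plus strand and
of the rightmost exon on the minus strand (the only convention under
which transcript-space positions from sequence-based tools make
biological sense).  Exonic projection is a strict bijection between
exonic genomic positions and 1..L, monotone increasing on `+` and
decreasing on `−`; mapping transcript intervals back to genomic blocks
is its exact inverse, which the test suite exercises as a round-trip
identity on randomized transcripts.

Intronic genomic positions do not error: they project to the *spliced
offset* o — the count of exonic bases 5' of the position — i.e. the
insertion point between transcript positions o and o+1.  Interval
projection returns the smallest transcript interval covering all exonic
bases of the input, flagged `fully_exonic`, `partially_intronic`, or
`fully_intronic` (empty projection at an offset).  One deliberate
choice: an interval whose projection covers the complete spliced
transcript (1..L) is flagged `fully_exonic` even though it necessarily
spans the introns in between — introns interior to a fully covered
transcript are not "missed" sequence from the annotation's point of
view.

## Region classification

Quartile membership uses the ceiling rule q(p) = ⌈4p/L⌉ clamped to
1..4, so a position exactly on a quartile boundary belongs to the lower
quartile.  Two conventions close gaps the quartile arithmetic leaves
open:

* the 5'-terminal base (position 1) is defined to be in Q1.  For
  L ≥ 4 the ceiling formula says so anyway; for degenerate transcripts
  (L < 4) Q1 would otherwise be empty and no interval could ever be
  `whole`/`full`/`5 prime`.  This mirrors the 3' end, where ⌈4L/L⌉ = 4
  puts the terminal base in Q4 for every L.
* the 90% length cut between `whole` and `full` is evaluated in exact
  integer arithmetic (`10·length > 9·L`), strict for `full`, so an
  interval covering exactly 90% of the transcript is `whole` and
  boundary behaviour is reproducible without floating-point ties.

Rules are evaluated in the order full/whole → 5' → 3' → middle;
quartile configurations none of the printed rules cover (e.g. start in
Q1, end in Q3) are resolved by the quartile of the interval midpoint
(Q1 → `5 prime`, Q2/Q3 → `middle`, Q4 → `3 prime`), making the
classifier total — an exhaustive sweep of every interval in every
transcript length up to 40 confirms no unlabeled configuration.
Classification consumes transcript coordinates only, so it is strand-
independent by construction.  In genomic mode the label is computed on
the spliced projection; fully intronic intervals are labelled
`intronic` rather than forced into the five-way scheme, since an empty
projection has no quartiles.

## Annotation semantics

Genomic mode matches every transcript whose span intersects the
interval (`partial`, the default) or contains it (`full`); one output
row per matched transcript, ordered by (gene, transcript), or one per
gene with `--level gene` (transcript IDs comma-joined in genomic order,
child flags OR-ed).  Child-feature flags apply the same containment
policy: `partial` sets a type's flag on any overlap with a feature of
that type under the matched transcript; `full` requires the interval
inside a single feature's span.  In transcriptomic mode child features
are first projected into transcript coordinates and blocks of the same
type merged when adjacent (a CDS split across exon lines is contiguous
in the spliced transcript) before the same overlap/containment test.

Intervals overlapping no transcript produce exactly one `intergenic`
row carrying the nearest gene strictly to the left and right in genomic
coordinate order (strand-agnostic, with both genes' strands reported so
strand-aware upstream/downstream can be derived), with distances as
differences of closed-interval boundaries — an immediately adjacent
gene is at distance 1.  Unknown chromosomes behave as zero matches with
no neighbours; unknown transcript IDs in transcriptomic mode emit the
row with `.` in every annotation column plus a note, and a warning on
standard error.  Transcript-space intervals ending beyond the spliced
length are clamped for classification and noted in the
`annotation_note` column.

Output is strictly column-appending: each input line is reproduced
byte-identically with annotation columns appended (absence encoded
`.`), one header line names the appended columns, and comment lines
pass through untouched.  Summary statistics (per-column category counts
over output rows, plus input/output/intergenic/unannotated totals) go
to a side file or standard error, never into the table.

## Synthetic data generator

`annotx.fixtures` generates deterministic annotations (same seed ⇒
byte-identical GTF and GFF3 describing the same gene set) emulating a
compact plant-like genome: by default 20 genes over 2 chromosomes, 1–3
transcripts per gene, 1–4 exons of 50–300 bp separated by 30–200 bp
introns, intergenic gaps of 200–1000 bp, strands equiprobable, 15%
non-coding transcripts, and coding transcripts carrying a CDS with UTRs
up to a quarter of the spliced length on each side.  These sizes keep
brute-force verification exact and fast while exercising every code
path (multi-exon, both strands, junction-spanning children,
multi-transcript genes).  The generator produces coordinates only — no
sequence — and never overlapping genes, so passing tests say nothing
about overlapping-locus resolution in real annotations; they do
establish the coordinate arithmetic, matching semantics and formats on
which real-data behaviour rests.

Interval sampling covers the informative classes: exonic,
junction-spanning, intronic and intergenic placements in genomic mode;
all five region labels plus lengths straddling the 90% whole/full
boundary in transcript mode.  Expected annotations are computed by an
independent naive path — linear scans over the truth object,
position-list projection, and an enumeration-style quartile
(min q with 4p ≤ qL) instead of the ceiling formula — sharing no code
with the engine, so the oracle-equivalence tests (200 randomized
instances, both modes, both containment policies) are a genuine
cross-check.

## Problem sizes and verification

The default verification runs use 50 random genomes of 5–30 genes with
50 intervals each per mode/containment configuration (10,000 row
comparisons), 1000 randomized cases per coordinate round trip, and
scaling measurements at 1k/5k/10k genes (database build) and
1k/5k/20k intervals (annotation), fitted by least squares; both fits
give R² > 0.99, consistent with the linear design of the SQL span query
plus per-transcript caching.

## Known limitations

* One interval per VCF record (multi-allelic records are not split);
  symbolic ALT alleles are annotated over the REF span only.
* Intergenic neighbours are reported one per side, in coordinate order,
  not per strand.
* Trans-spliced or fusion transcripts and CIGAR-based projection are out
  of scope; exon chains must be disjoint and sorted.
* No set-algebraic interval operations (union/subtract/merge) — this is
  an annotator, not an interval calculus.
* Feature/attribute vocabulary is taken from the file as-is; GFF3 terms
  are not validated against the Sequence Ontology.
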