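"""Deterministic synthetic annotation and interval generator.

Produces GTF and GFF3 files describing the same synthetic gene set, plus
a ground-truth object holding every transcript's exon chain, spliced
length and child-feature coordinates — the oracle data for every test
surface in the package.

Expected annotations are computed here by a deliberately naive,
self-contained path (linear scans over the truth object, position-list
projection, enumeration-style quartiles) that shares no code with the
database or annotation engine, so agreement between the two is a real
cross-check rather than a tautology.

The generator emulates the coordinate structure of a compact plant-like
genome annotation (multi-exon protein-coding genes with UTRs on both
strands, interspersed intergenic gaps).  It produces coordinates only —
no sequence — and no overlapping genes, which real annotations do
contain.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

# ---------------------------------------------------------------------------
# specification


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome annotation.

    The same spec and seed always produce byte-identical files.
    """

    seed: int = 0
    n_chromosomes: int = 2
    n_genes: int = 20
    transcripts_per_gene: Tuple[int, int] = (1, 3)
    exons_per_transcript: Tuple[int, int] = (1, 4)
    exon_length: Tuple[int, int] = (50, 300)
    intron_length: Tuple[int, int] = (30, 200)
    intergenic_gap: Tuple[int, int] = (200, 1000)
    minus_strand_prob: float = 0.5
    noncoding_prob: float = 0.15  # transcripts without CDS/UTR children


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TranscriptTruth:
    transcript_id: str
    gene_id: str
    seqid: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic, sorted, disjoint
    biotype: str
    #: child type -> list of genomic (start, end) blocks
    children: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    #: child type -> (start, end) span in transcript coordinates
    tx_children: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def positions(self) -> List[int]:
        """Genomic positions in transcript (5'→3') order."""
        pos = [g for s, e in self.exons for g in range(s, e + 1)]
        return pos[::-1] if self.strand == "-" else pos


@dataclass
class GeneTruth:
    gene_id: str
    seqid: str
    strand: str
    start: int
    end: int
    biotype: str
    name: str
    transcripts: List[TranscriptTruth] = field(default_factory=list)


@dataclass
class GenomeTruth:
    genes: List[GeneTruth]
    spec: GenomeSpec

    @property
    def transcripts(self) -> Dict[str, TranscriptTruth]:
        return {t.transcript_id: t for g in self.genes for t in g.transcripts}

    def genes_on(self, seqid: str) -> List[GeneTruth]:
        return [g for g in self.genes if g.seqid == seqid]

    @property
    def seqids(self) -> List[str]:
        return sorted({g.seqid for g in self.genes})


# ---------------------------------------------------------------------------
# generation


def _make_transcript(rng: random.Random, spec: GenomeSpec, tx_id: str,
                     gene_id: str, seqid: str, strand: str, start: int,
                     coding: bool) -> TranscriptTruth:
    n_exons = rng.randint(*spec.exons_per_transcript)
    exons = []
    cursor = start
    for i in range(n_exons):
        length = rng.randint(*spec.exon_length)
        exons.append((cursor, cursor + length - 1))
        cursor += length + rng.randint(*spec.intron_length)
    t = TranscriptTruth(
        transcript_id=tx_id, gene_id=gene_id, seqid=seqid, strand=strand,
        exons=exons, biotype="protein_coding" if coding else "lncrna",
    )
    L = t.spliced_length
    if coding and L >= 30:
        utr5 = rng.randint(0, L // 4)
        utr3 = rng.randint(0, L // 4)
        spans = {"cds": (utr5 + 1, L - utr3)}
        if utr5:
            spans["five_prime_utr"] = (1, utr5)
        if utr3:
            spans["three_prime_utr"] = (L - utr3 + 1, L)
    else:
        spans = {}
    t.tx_children = spans
    pos = t.positions()
    t.children["exon"] = list(exons)
    for ctype, (ts, te) in spans.items():
        t.children[ctype] = _runs(sorted(pos[ts - 1 : te]))
    return t


def _runs(sorted_positions: List[int]) -> List[Tuple[int, int]]:
    """Collapse sorted genomic positions into contiguous blocks."""
    blocks: List[List[int]] = []
    for p in sorted_positions:
        if blocks and p == blocks[-1][1] + 1:
            blocks[-1][1] = p
        else:
            blocks.append([p, p])
    return [tuple(b) for b in blocks]


def generate_truth(spec: GenomeSpec) -> GenomeTruth:
    """Generate the synthetic gene set for *spec* (no files written)."""
    rng = random.Random(spec.seed)
    genes: List[GeneTruth] = []
    per_chrom = max(1, spec.n_genes // spec.n_chromosomes)
    gi = 0
    for ci in range(spec.n_chromosomes):
        seqid = f"chr{ci + 1}"
        cursor = rng.randint(*spec.intergenic_gap)
        n_here = per_chrom if ci < spec.n_chromosomes - 1 else spec.n_genes - gi
        for _ in range(n_here):
            gi += 1
            gene_id = f"G{gi:05d}"
            strand = "-" if rng.random() < spec.minus_strand_prob else "+"
            coding = rng.random() >= spec.noncoding_prob
            n_tx = rng.randint(*spec.transcripts_per_gene)
            txs = []
            for ti in range(n_tx):
                tstart = cursor + rng.randint(0, 40)
                txs.append(
                    _make_transcript(rng, spec, f"{gene_id}.T{ti + 1}", gene_id,
                                     seqid, strand, tstart, coding)
                )
            gene = GeneTruth(
                gene_id=gene_id, seqid=seqid, strand=strand,
                start=min(t.start for t in txs), end=max(t.end for t in txs),
                biotype="protein_coding" if coding else "lncrna",
                name=f"GENE{gi}", transcripts=txs,
            )
            genes.append(gene)
            cursor = gene.end + rng.randint(*spec.intergenic_gap)
    return GenomeTruth(genes=genes, spec=spec)


def write_gtf(truth: GenomeTruth, path: str) -> None:
    """Write the gene set as GTF (quoted key-value attributes)."""
    with open(path, "w") as out:
        for g in truth.genes:
            gattr = (f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                     f'gene_biotype "{g.biotype}";')
            out.write(_line(g.seqid, "gene", g.start, g.end, g.strand, gattr))
            for t in g.transcripts:
                tattr = (f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                         f'gene_name "{g.name}"; gene_biotype "{g.biotype}"; '
                         f'transcript_biotype "{t.biotype}";')
                out.write(_line(g.seqid, "transcript", t.start, t.end, t.strand, tattr))
                for ctype in ("exon", "cds", "five_prime_utr", "three_prime_utr"):
                    for (s, e) in t.children.get(ctype, []):
                        out.write(_line(g.seqid, ctype, s, e, t.strand, tattr))


def write_gff3(truth: GenomeTruth, path: str) -> None:
    """Write the same gene set as GFF3 (ID/Parent attributes)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for g in truth.genes:
            out.write(_line(g.seqid, "gene", g.start, g.end, g.strand,
                            f"ID={g.gene_id};Name={g.name};gene_biotype={g.biotype}"))
            for t in g.transcripts:
                out.write(_line(
                    g.seqid, "transcript", t.start, t.end, t.strand,
                    f"ID={t.transcript_id};Parent={g.gene_id};"
                    f"gene_biotype={g.biotype};transcript_biotype={t.biotype}"))
                k = 0
                for ctype in ("exon", "cds", "five_prime_utr", "three_prime_utr"):
                    for (s, e) in t.children.get(ctype, []):
                        k += 1
                        out.write(_line(
                            g.seqid, ctype, s, e, t.strand,
                            f"ID={t.transcript_id}.{ctype}.{k};Parent={t.transcript_id}"))


def _line(seqid, ftype, start, end, strand, attrs) -> str:
    return f"{seqid}\tannotx_fixture\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


def generate_annotation(spec: GenomeSpec, gtf_path: Optional[str] = None,
                        gff3_path: Optional[str] = None) -> GenomeTruth:
    """Generate the gene set and write the requested dialect files."""
    truth = generate_truth(spec)
    if gtf_path:
        write_gtf(truth, gtf_path)
    if gff3_path:
        write_gff3(truth, gff3_path)
    return truth


# ---------------------------------------------------------------------------
# intervals with brute-force expected annotations


@dataclass
class IntervalCase:
    """One query interval with its independently computed expectation."""

    id: str
    reference: str  # seqid (genomic mode) or transcript ID
    start: int  # canonical 1-based inclusive
    end: int
    case_class: str
    #: list of expected per-row dicts (one per matched transcript), or a
    #: single intergenic/unannotated expectation
    expected: List[dict] = field(default_factory=list)


def _naive_quartile(p: int, L: int) -> int:
    return min(q for q in (1, 2, 3, 4) if 4 * p <= q * L)


def _naive_classify(s: int, e: int, L: int) -> str:
    qs = 1 if s == 1 else _naive_quartile(s, L)
    qe = _naive_quartile(e, L)
    span = e - s + 1
    if qs == 1 and qe == 4:
        return "full" if 10 * span > 9 * L else "whole"
    if qs == 1 and qe in (1, 2):
        return "5 prime"
    if qs in (3, 4) and qe == 4:
        return "3 prime"
    if qs in (2, 3) and qe in (2, 3):
        return "middle"
    qm = _naive_quartile((s + e) // 2, L)
    return {1: "5 prime", 4: "3 prime"}.get(qm, "middle")


def _naive_region_genomic(t: TranscriptTruth, s: int, e: int) -> str:
    pos = t.positions()
    idx = [i + 1 for i, g in enumerate(pos) if s <= g <= e]
    if not idx:
        return "intronic"
    return _naive_classify(min(idx), max(idx), t.spliced_length)


def _naive_flags_genomic(t: TranscriptTruth, s: int, e: int, full: bool) -> Dict[str, str]:
    flags = {}
    for ctype, blocks in t.children.items():
        if full:
            hit = any(bs <= s and e <= be for bs, be in blocks)
        else:
            hit = any(bs <= e and be >= s for bs, be in blocks)
        flags[ctype] = "y" if hit else "."
    return flags


def _naive_flags_tx(t: TranscriptTruth, s: int, e: int, full: bool) -> Dict[str, str]:
    flags = {"exon": "y" if not full or (1 <= s and e <= t.spliced_length) else "."}
    for ctype, (ts, te) in t.tx_children.items():
        if full:
            hit = ts <= s and e <= te
        else:
            hit = ts <= e and te >= s
        flags[ctype] = "y" if hit else "."
    return flags


def expected_genomic(truth: GenomeTruth, seqid: str, s: int, e: int,
                     containment: str = "partial") -> List[dict]:
    """Brute-force expectation for one genomic interval: linear scan over
    every transcript, naive projection, naive region rules."""
    full = containment == "full"
    rows = []
    for g in truth.genes_on(seqid):
        for t in g.transcripts:
            if full:
                match = t.start <= s and e <= t.end
            else:
                match = t.start <= e and t.end >= s
            if match:
                rows.append({
                    "transcript_id": t.transcript_id,
                    "gene_id": g.gene_id,
                    "flags": _naive_flags_genomic(t, s, e, full),
                    "region": _naive_region_genomic(t, s, e),
                })
    rows.sort(key=lambda r: (r["gene_id"], r["transcript_id"]))
    if rows:
        return rows
    # intergenic: nearest gene strictly left / right, ties by gene ID
    left = [g for g in truth.genes_on(seqid) if g.end < s]
    right = [g for g in truth.genes_on(seqid) if g.start > e]
    lbest = min(left, key=lambda g: (-g.end, g.gene_id)) if left else None
    rbest = min(right, key=lambda g: (g.start, g.gene_id)) if right else None
    return [{
        "intergenic": True,
        "left": lbest.gene_id if lbest else ".",
        "left_distance": s - lbest.end if lbest else None,
        "right": rbest.gene_id if rbest else ".",
        "right_distance": rbest.start - e if rbest else None,
    }]


def expected_transcriptomic(truth: GenomeTruth, tx_id: str, s: int, e: int,
                            containment: str = "partial") -> List[dict]:
    full = containment == "full"
    t = truth.transcripts.get(tx_id)
    if t is None:
        return [{"unannotated": True}]
    L = t.spliced_length
    e_c = min(e, L)
    return [{
        "transcript_id": t.transcript_id,
        "gene_id": t.gene_id,
        "flags": _naive_flags_tx(t, s, e_c, full),
        "region": _naive_classify(s, e_c, L) if s <= L else ".",
    }]


def generate_intervals(truth: GenomeTruth, mode: str, n: int, seed: int,
                       containment: str = "partial",
                       with_expected: bool = True) -> List[IntervalCase]:
    """Sample *n* query intervals covering the interesting case classes.

    Genomic mode cycles exonic / junction-spanning / intronic /
    intergenic placements; transcriptomic mode spreads intervals over
    the region-label classes including lengths straddling the 90%
    whole/full boundary.  Every case carries its brute-force expectation.
    """
    rng = random.Random(seed)
    cases: List[IntervalCase] = []
    txs = list(truth.transcripts.values())
    if mode == "genomic":
        classes = ["exonic", "junction", "intronic", "intergenic"]
        for i in range(n):
            cls = classes[i % len(classes)]
            iv = _sample_genomic(rng, truth, txs, cls)
            if iv is None:
                continue
            seqid, s, e, cls = iv
            cases.append(IntervalCase(
                id=f"iv{i + 1}", reference=seqid, start=s, end=e, case_class=cls,
                expected=expected_genomic(truth, seqid, s, e, containment)
                if with_expected else []))
    else:
        for i in range(n):
            t = txs[rng.randrange(len(txs))]
            L = t.spliced_length
            s, e = _sample_tx_interval(rng, L, i)
            cases.append(IntervalCase(
                id=f"iv{i + 1}", reference=t.transcript_id, start=s, end=e,
                case_class="tx",
                expected=expected_transcriptomic(truth, t.transcript_id, s, e, containment)
                if with_expected else []))
    covered = {c.case_class for c in cases}
    wanted = {"exonic", "junction", "intronic", "intergenic"} if mode == "genomic" else {"tx"}
    missing = wanted - covered
    if missing:
        import logging
        logging.getLogger("annotx").warning(
            "interval sample of %d left case classes uncovered: %s", n, sorted(missing))
    return cases


def _sample_genomic(rng, truth, txs, cls):
    for _ in range(50):
        t = txs[rng.randrange(len(txs))]
        if cls == "exonic":
            s0, e0 = t.exons[rng.randrange(len(t.exons))]
            a = rng.randint(s0, e0)
            b = rng.randint(a, e0)
            return t.seqid, a, b, cls
        if cls == "junction":
            if len(t.exons) < 2:
                continue
            i = rng.randrange(len(t.exons) - 1)
            a = rng.randint(t.exons[i][0], t.exons[i][1])
            b = rng.randint(t.exons[i + 1][0], t.exons[i + 1][1])
            return t.seqid, a, b, cls
        if cls == "intronic":
            if len(t.exons) < 2:
                continue
            i = rng.randrange(len(t.exons) - 1)
            lo, hi = t.exons[i][1] + 1, t.exons[i + 1][0] - 1
            if lo > hi:
                continue
            a = rng.randint(lo, hi)
            b = rng.randint(a, hi)
            return t.seqid, a, b, cls
        # intergenic: a gap between consecutive gene spans on a chromosome
        seqid = truth.seqids[rng.randrange(len(truth.seqids))]
        genes = sorted(truth.genes_on(seqid), key=lambda g: g.start)
        gaps = []
        prev_end = 0
        for g in genes:
            if g.start - prev_end > 4:
                gaps.append((prev_end + 2, g.start - 2))
            prev_end = max(prev_end, g.end)
        gaps.append((prev_end + 2, prev_end + 500))
        lo, hi = gaps[rng.randrange(len(gaps))]
        a = rng.randint(lo, hi)
        b = rng.randint(a, hi)
        # the sampled gap may still touch a gene on another transcript; the
        # expectation machinery decides the true class either way
        return seqid, a, b, cls
    return None


def _sample_tx_interval(rng, L: int, i: int) -> Tuple[int, int]:
    # every 5th interval probes the whole/full 90% boundary
    if i % 5 == 4 and L >= 10:
        span = (9 * L) // 10 + (i % 2)
        span = max(1, min(span, L))
        return 1, span
    a = rng.randint(1, L)
    b = rng.randint(a, L)
    return a, b


# ---------------------------------------------------------------------------
# verification

_CHILD_TYPES = ("exon", "cds", "five_prime_utr", "three_prime_utr")


def verify_case(rows, case: IntervalCase) -> List[str]:
    """Compare annotator output *rows* with a case's brute-force
    expectation; returns a list of mismatch descriptions (empty = match).

    *rows* are :class:`annotx.interval_annotator.AnnotationRow` objects
    produced at transcript level.
    """
    problems: List[str] = []
    exp = case.expected
    tag = f"{case.id} {case.reference}:{case.start}-{case.end}"
    if exp and exp[0].get("intergenic"):
        if len(rows) != 1:
            return [f"{tag}: expected one intergenic row, got {len(rows)}"]
        r = rows[0]
        if r.get("annotated_feature_type") != "intergenic":
            problems.append(f"{tag}: not marked intergenic")
        for side in ("left", "right"):
            want_id = exp[0][side]
            want_d = exp[0][f"{side}_distance"]
            got_id = r.get(f"closest_gene_{side}")
            got_d = r.get(f"distance_{side}")
            if got_id != want_id:
                problems.append(f"{tag}: {side} gene {got_id} != {want_id}")
            if str(want_d if want_d is not None else ".") != got_d:
                problems.append(f"{tag}: {side} distance {got_d} != {want_d}")
        return problems
    if exp and exp[0].get("unannotated"):
        if len(rows) != 1 or rows[0].get("annotated_transcript_id") != ".":
            problems.append(f"{tag}: expected a single unannotated row")
        return problems
    if len(rows) != len(exp):
        return [f"{tag}: {len(rows)} rows != {len(exp)} expected"]
    for r, x in zip(rows, exp):
        if r.get("annotated_transcript_id") != x["transcript_id"]:
            problems.append(f"{tag}: transcript {r.get('annotated_transcript_id')}"
                            f" != {x['transcript_id']}")
        if r.get("annotated_gene_id") != x["gene_id"]:
            problems.append(f"{tag}: gene {r.get('annotated_gene_id')}"
                            f" != {x['gene_id']}")
        if r.get("feature_region") != x["region"]:
            problems.append(f"{tag}: region {r.get('feature_region')}"
                            f" != {x['region']} ({x['transcript_id']})")
        for t in _CHILD_TYPES:
            want = x["flags"].get(t, ".")
            if r.get(t) != want:
                problems.append(f"{tag}: {t} flag {r.get(t)} != {want}"
                                f" ({x['transcript_id']})")
    return problems


# ---------------------------------------------------------------------------
# table writers (fixture side)


def write_bed(cases: List[IntervalCase], path: str) -> None:
    """Write genomic cases as a BED file (0-based, end-exclusive)."""
    with open(path, "w") as out:
        for c in cases:
            out.write(f"{c.reference}\t{c.start - 1}\t{c.end}\t{c.id}\n")


def write_custom(cases: List[IntervalCase], path: str, separator: str = "\t",
                 header: bool = True) -> None:
    """Write cases as a 1-based custom table: id, reference, two filler
    columns, start, end (so the coordinate columns are 5 and 6)."""
    with open(path, "w") as out:
        if header:
            out.write(separator.join(
                ["feature_id", "reference", "note1", "note2", "start", "end"]) + "\n")
        for c in cases:
            out.write(separator.join(
                [c.id, c.reference, "x", "x", str(c.start), str(c.end)]) + "\n")
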