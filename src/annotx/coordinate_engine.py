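"""Coordinate arithmetic: convention conversion and genome ↔ transcript
projection.

Everything downstream of I/O works in one canonical convention — 1-based,
end-inclusive, the native convention of GTF/GFF3 — so conversion happens
exactly once, at the table boundary.  Transcript ("spliced") coordinates
count exonic bases from the transcript's 5' end: position 1 is the first
base of the first exon on the plus strand, and the first base of the
*last* genomic exon on the minus strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Tuple

from .errors import InvalidIntervalError, OutOfRangeError
from .gff_model import FeatureRecord, TranscriptRecords

# ---------------------------------------------------------------------------
# conventions


@dataclass(frozen=True)
class CoordinateConvention:
    """How a table encodes intervals: counting base and end style."""

    base: int  # 0 or 1
    end_style: str  # "inclusive" or "exclusive"

    def __post_init__(self):
        if self.base not in (0, 1) or self.end_style not in ("inclusive", "exclusive"):
            raise ValueError(f"invalid convention {self}")


#: BED: 0-based, end-exclusive
BED_CONVENTION = CoordinateConvention(0, "exclusive")
#: GTF/GFF3/VCF: 1-based, end-inclusive (the canonical internal form)
GFF_CONVENTION = CoordinateConvention(1, "inclusive")


def normalize(start: int, end: int, convention: CoordinateConvention) -> Tuple[int, int]:
    """Convert an interval to canonical 1-based inclusive form.

    Raises :class:`InvalidIntervalError` for intervals that are empty or
    inverted once normalized.
    """
    s = start + (1 - convention.base)
    e = end + (1 - convention.base)
    if convention.end_style == "exclusive":
        e -= 1
    if s < 1 or e < s:
        raise InvalidIntervalError(
            f"interval ({start}, {end}) is empty or inverted under "
            f"{convention.base}-based {convention.end_style} coordinates"
        )
    return s, e


def denormalize(start: int, end: int, convention: CoordinateConvention) -> Tuple[int, int]:
    """Inverse of :func:`normalize`; restores the declared representation."""
    s = start - (1 - convention.base)
    e = end - (1 - convention.base)
    if convention.end_style == "exclusive":
        e += 1
    return s, e


# ---------------------------------------------------------------------------
# transcript model


@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain plus its child features.

    ``exons`` are genomic ``(start, end)`` pairs, 1-based inclusive,
    pairwise disjoint and sorted by start.  Transcript coordinates run
    1..spliced_length from the 5' end regardless of strand.
    """

    transcript_id: str
    gene_id: Optional[str]
    seqid: str
    strand: str
    exons: List[Tuple[int, int]]
    children: List[FeatureRecord] = field(default_factory=list)
    record: Optional[FeatureRecord] = None

    def __post_init__(self):
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon {s}-{e} inverted")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        # cumulative exonic bases before each exon, for O(log n) lookup
        self._cum = [0]
        for s, e in self.exons:
            self._cum.append(self._cum[-1] + (e - s + 1))
        self._starts = [s for s, _ in self.exons]

    @property
    def spliced_length(self) -> int:
        return self._cum[-1]

    @property
    def genomic_start(self) -> int:
        return self.exons[0][0]

    @property
    def genomic_end(self) -> int:
        return self.exons[-1][1]

    @classmethod
    def from_records(cls, recs: TranscriptRecords) -> "TranscriptModel":
        """Build a model from database records.

        Transcripts without exon lines fall back to a single pseudo-exon
        covering the transcript record's span.
        """
        tx = recs.transcript
        exons = [(c.start, c.end) for c in recs.children if c.feature_type == "exon"]
        if not exons:
            exons = [(tx.start, tx.end)]
        gene_id = recs.gene.feature_id if recs.gene else tx.attributes.get("gene_id")
        return cls(
            transcript_id=tx.feature_id,
            gene_id=gene_id,
            seqid=tx.seqid,
            strand=tx.strand if tx.strand in ("+", "-") else "+",
            exons=exons,
            children=[c for c in recs.children],
            record=tx,
        )

    # -- position arithmetic ------------------------------------------------

    def _exonic_bases_at_or_before(self, g: int) -> int:
        """Number of exonic bases with genomic position ≤ g."""
        i = bisect.bisect_right(self._starts, g) - 1
        if i < 0:
            return 0
        s, e = self.exons[i]
        return self._cum[i] + (min(g, e) - s + 1)

    def is_exonic(self, g: int) -> bool:
        i = bisect.bisect_right(self._starts, g) - 1
        return i >= 0 and self.exons[i][0] <= g <= self.exons[i][1]


@dataclass(frozen=True)
class TxPosition:
    """Result of projecting one genomic position.

    For exonic positions, ``position`` is the 1-based transcript
    coordinate.  For intronic positions, ``offset`` is the number of
    exonic bases 5' of the position (in transcript orientation): the
    position sits between transcript coordinates ``offset`` and
    ``offset + 1``.
    """

    position: Optional[int]
    offset: Optional[int] = None

    @property
    def intronic(self) -> bool:
        return self.position is None


class ProjectionFlag(str, Enum):
    FULLY_EXONIC = "fully_exonic"
    PARTIALLY_INTRONIC = "partially_intronic"
    FULLY_INTRONIC = "fully_intronic"


@dataclass(frozen=True)
class TxInterval:
    """A transcript-space interval, 1-based inclusive."""

    transcript_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise InvalidIntervalError(f"invalid transcript interval {self.start}-{self.end}")


@dataclass(frozen=True)
class Projection:
    """Spliced projection of a genomic interval onto a transcript."""

    interval: Optional[TxInterval]  # None when fully intronic
    flag: ProjectionFlag
    offset: Optional[int] = None  # insertion point for fully intronic input


def genomic_to_tx(model: TranscriptModel, g: int) -> TxPosition:
    """Project one genomic position into transcript coordinates."""
    if not (model.genomic_start <= g <= model.genomic_end):
        raise OutOfRangeError(
            f"{g} outside transcript {model.transcript_id} span "
            f"{model.genomic_start}-{model.genomic_end}"
        )
    n = model._exonic_bases_at_or_before(g)
    L = model.spliced_length
    if model.is_exonic(g):
        return TxPosition(position=n if model.strand == "+" else L - n + 1)
    # intronic: n equals the count of exonic bases strictly before g
    offset = n if model.strand == "+" else L - n
    return TxPosition(position=None, offset=offset)


def project_to_tx(model: TranscriptModel, g_start: int, g_end: int) -> Projection:
    """Project a genomic interval onto the spliced transcript.

    Returns the smallest transcript interval containing all exonic bases
    of the input.  Fully intronic input yields a zero-length insertion
    point between ``offset`` and ``offset + 1``.
    """
    if g_start > g_end:
        raise InvalidIntervalError(f"inverted interval {g_start}-{g_end}")
    s = max(g_start, model.genomic_start)
    e = min(g_end, model.genomic_end)
    if s > e:
        raise OutOfRangeError(
            f"interval {g_start}-{g_end} does not intersect transcript "
            f"{model.transcript_id}"
        )
    n_exonic = model._exonic_bases_at_or_before(e) - model._exonic_bases_at_or_before(s - 1)
    if n_exonic == 0:
        return Projection(None, ProjectionFlag.FULLY_INTRONIC, offset=genomic_to_tx(model, s).offset)
    # transcript coordinates of the outermost exonic bases in the interval
    lo = model._exonic_bases_at_or_before(s - 1) + 1
    hi = model._exonic_bases_at_or_before(e)
    if model.strand == "-":
        L = model.spliced_length
        lo, hi = L - hi + 1, L - lo + 1
    # an interval spanning the complete spliced transcript counts as fully
    # exonic: introns interior to a fully covered transcript are not
    # "missed" sequence
    if n_exonic == e - s + 1 or (lo == 1 and hi == model.spliced_length):
        flag = ProjectionFlag.FULLY_EXONIC
    else:
        flag = ProjectionFlag.PARTIALLY_INTRONIC
    return Projection(TxInterval(model.transcript_id, lo, hi), flag)


def tx_to_genomic(model: TranscriptModel, interval: TxInterval) -> List[Tuple[int, int]]:
    """Map a transcript interval back to genomic blocks.

    Blocks are disjoint, sorted in genomic order, and their lengths sum
    to the interval length; inverse of :func:`project_to_tx` on exonic
    intervals.
    """
    L = model.spliced_length
    if interval.end > L:
        raise OutOfRangeError(
            f"{interval.start}-{interval.end} exceeds spliced length {L} "
            f"of {model.transcript_id}"
        )
    ts, te = interval.start, interval.end
    if model.strand == "-":
        ts, te = L - interval.end + 1, L - interval.start + 1
    blocks = []
    for (s, e), cum in zip(model.exons, model._cum):
        # exon covers spliced (plus-orientation) coords cum+1 .. cum+(e-s+1)
        lo = max(ts, cum + 1)
        hi = min(te, cum + (e - s + 1))
        if lo <= hi:
            blocks.append((s + lo - cum - 1, s + hi - cum - 1))
    return blocks
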