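"""Core annotation engine.

Two modes:

* **genomic** — the interval's reference is a chromosome/scaffold; every
  transcript overlapping the interval is matched (one output row each,
  or one per gene at gene level), child features are flagged by genomic
  overlap, and the region label is computed on the spliced projection of
  the interval into each transcript.  Intervals overlapping no
  transcript are marked ``intergenic`` with their closest gene on either
  side and the distance to each.

* **transcriptomic** — the reference is a transcript ID; the transcript
  and its parent gene are matched directly, child features are projected
  into transcript coordinates and intersected with the interval there,
  and the region label comes straight from the interval's transcript
  coordinates.

Child-feature flags are ``"y"``/``"."`` columns, one per child feature
type.  Under the ``partial`` containment policy (default) any overlap
sets the flag and any transcript overlap is a match; under ``full`` the
interval must lie entirely inside the transcript (and inside a child
feature's span for its flag to be set).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .coordinate_engine import (
    BED_CONVENTION,
    CoordinateConvention,
    ProjectionFlag,
    TranscriptModel,
    project_to_tx,
)
from .errors import ConfigurationError, UnknownReferenceError
from .gff_model import AnnotationDatabase, FeatureRecord, TranscriptRecords
from .region_classifier import RegionLabel, classify
from .table_io import IntervalRecord

log = logging.getLogger("annotx")

MISSING = "."

#: canonical ordering of well-known child-feature flag columns
_CHILD_ORDER = ["exon", "cds", "five_prime_utr", "three_prime_utr",
                "start_codon", "stop_codon"]
#: canonical ordering of well-known attribute columns
_ATTR_ORDER = ["gene_biotype", "gene_name", "transcript_biotype", "transcript_name"]

#: attribute keys that duplicate structural columns; never offered as
#: appended attribute columns
_STRUCTURAL_ATTRS = {"id", "parent", "gene_id", "transcript_id"}

_INTERGENIC_COLUMNS = [
    "closest_gene_left", "distance_left", "strand_left",
    "closest_gene_right", "distance_right", "strand_right",
]


@dataclass
class AnnotationOptions:
    """User-facing knobs of one annotation run."""

    mode: str = "genomic"  # genomic | transcriptomic
    feature_types: Optional[Iterable[str]] = None  # None = ALL child types
    attributes: Optional[Iterable[str]] = None  # None = ALL attributes
    level: str = "transcript"  # transcript | gene
    containment: str = "partial"  # partial | full
    convention: CoordinateConvention = BED_CONVENTION


@dataclass
class AnnotationRow:
    """One output row: the source interval plus appended column values."""

    interval: IntervalRecord
    values: Dict[str, str] = field(default_factory=dict)

    def get(self, column: str) -> str:
        return self.values.get(column, MISSING)


@dataclass
class IntergenicNeighbors:
    left: Optional[FeatureRecord]
    left_distance: Optional[int]
    right: Optional[FeatureRecord]
    right_distance: Optional[int]


class Annotator:
    """Annotates interval records against one feature database.

    The appended column layout is fixed at construction time from the
    database hierarchy and the user's feature/attribute selection, so
    every row of a run has the same columns in the same order.
    """

    def __init__(self, db: AnnotationDatabase, options: Optional[AnnotationOptions] = None):
        self.db = db
        self.options = options or AnnotationOptions()
        self._models: Dict[str, TranscriptModel] = {}
        self._resolve_layout()

    # -- layout ------------------------------------------------------------

    def _resolve_layout(self) -> None:
        hierarchy = self.db.hierarchy()
        tx_types = set(self.db.transcript_types())
        gene_types = set(self.db.gene_types())
        self._tx_types = sorted(tx_types)

        available_children = sorted(
            {c for (p, c) in hierarchy.edges if p in tx_types}
        )
        available_attrs = sorted(
            {
                a
                for t in (tx_types | gene_types)
                for a in hierarchy.attributes_per_type.get(t, [])
                if a not in _STRUCTURAL_ATTRS
            }
        )

        def ordered(selection, available, canonical, what):
            if selection is None:
                chosen = set(available)
            else:
                chosen = {s.lower() for s in selection}
                unknown = chosen - set(available)
                if unknown:
                    raise ConfigurationError(
                        f"unknown {what} {sorted(unknown)}; available: {available}"
                    )
            return [c for c in canonical if c in chosen] + sorted(
                chosen - set(canonical)
            )

        self.child_columns = ordered(
            self.options.feature_types, available_children, _CHILD_ORDER, "feature type(s)"
        )
        self.attribute_columns = ordered(
            self.options.attributes, available_attrs, _ATTR_ORDER, "attribute(s)"
        )

        self.column_names = [
            "annotated_gene_id",
            "annotated_transcript_id",
            "annotated_feature_type",
            "annotated_chromosome",
            "annotated_transcript_start",
            "annotated_transcript_end",
            *self.child_columns,
            *self.attribute_columns,
            "feature_region",
        ]
        if self.options.mode == "genomic":
            self.column_names += _INTERGENIC_COLUMNS
        self.column_names.append("annotation_note")

    # -- public API --------------------------------------------------------

    def annotate(self, record: IntervalRecord) -> List[AnnotationRow]:
        """Annotate one interval; always returns at least one row."""
        if record.start is None:
            return [self._blank_row(record, note=record.invalid_reason or "invalid interval")]
        if self.options.mode == "transcriptomic":
            rows = [self.annotate_transcriptomic(record)]
        else:
            rows = self.annotate_genomic(record)
        if self.options.level == "gene":
            rows = self.group_by_gene(record, rows)
        return rows

    def annotate_rows(self, record: IntervalRecord) -> Tuple[IntervalRecord, List[List[str]]]:
        """Annotate and serialize values in layout order (for the writer)."""
        rows = self.annotate(record)
        return record, [[r.get(c) for c in self.column_names] for r in rows]

    # -- genomic mode ------------------------------------------------------

    def annotate_genomic(self, record: IntervalRecord) -> List[AnnotationRow]:
        s, e = record.start, record.end
        hits = self.db.fetch_overlapping(record.reference, s, e, self._tx_types)
        if self.options.containment == "full":
            hits = [t for t in hits if t.contains(s, e)]
        if not hits:
            return [self._intergenic_row(record)]
        rows = []
        for tx_rec in hits:
            model = self._model_for(tx_rec)
            rows.append(self._transcript_row(record, model, s, e, genomic=True))
        rows.sort(key=lambda r: (r.get("annotated_gene_id"), r.get("annotated_transcript_id")))
        return rows

    def mark_intergenic(self, record: IntervalRecord) -> IntergenicNeighbors:
        """Closest gene strictly left of and strictly right of the interval.

        Distances are differences of closed-interval boundaries: a gene
        ending at ``start − 1`` is at distance 1.
        """
        left = self.db.closest_gene_left(record.reference, record.start)
        right = self.db.closest_gene_right(record.reference, record.end)
        return IntergenicNeighbors(
            left=left,
            left_distance=None if left is None else record.start - left.end,
            right=right,
            right_distance=None if right is None else right.start - record.end,
        )

    # -- transcriptomic mode ----------------------------------------------

    def annotate_transcriptomic(self, record: IntervalRecord) -> AnnotationRow:
        try:
            recs = self.db.fetch_by_transcript_id(record.reference)
        except UnknownReferenceError:
            log.warning("row %d: unknown transcript %r; emitted unannotated",
                        record.row_number, record.reference)
            return self._blank_row(record, note="unknown reference")
        model = self._model_for(recs.transcript, recs)
        L = model.spliced_length
        s, e = record.start, record.end
        note = MISSING
        if s > L:
            return self._transcript_shell_row(
                record, model, region=MISSING, flags={}, note=f"interval beyond spliced length {L}"
            )
        if e > L:
            e = L
            note = f"end clamped to spliced length {L}"
        region = classify(s, e, L)
        flags = self._tx_child_flags(model, s, e)
        return self._transcript_shell_row(record, model, region=str(region),
                                          flags=flags, note=note)

    # -- gene-level grouping ----------------------------------------------

    def group_by_gene(self, record: IntervalRecord, rows: List[AnnotationRow]) -> List[AnnotationRow]:
        """Collapse transcript-level rows of one interval to one row per
        gene: transcript IDs comma-joined in genomic order, child flags
        OR-ed, differing values comma-joined."""
        groups: Dict[str, List[AnnotationRow]] = {}
        for r in rows:
            groups.setdefault(r.get("annotated_gene_id"), []).append(r)
        out = []
        for gene_id in sorted(groups):
            members = groups[gene_id]
            if len(members) == 1 and gene_id == MISSING:
                out.extend(members)
                continue
            members.sort(key=lambda r: (
                int(r.get("annotated_transcript_start")) if r.get("annotated_transcript_start") != MISSING else 0,
                r.get("annotated_transcript_id"),
            ))
            values = dict(members[0].values)
            values["annotated_transcript_id"] = ",".join(
                m.get("annotated_transcript_id") for m in members
            )
            values["annotated_feature_type"] = "gene"
            starts = [int(m.get("annotated_transcript_start")) for m in members
                      if m.get("annotated_transcript_start") != MISSING]
            ends = [int(m.get("annotated_transcript_end")) for m in members
                    if m.get("annotated_transcript_end") != MISSING]
            if starts:
                values["annotated_transcript_start"] = str(min(starts))
                values["annotated_transcript_end"] = str(max(ends))
            for col in self.child_columns:
                values[col] = "y" if any(m.get(col) == "y" for m in members) else MISSING
            for col in self.attribute_columns + ["feature_region"]:
                seen = []
                for m in members:
                    v = m.get(col)
                    if v not in seen:
                        seen.append(v)
                values[col] = ",".join(seen)
            out.append(AnnotationRow(record, values))
        return out

    # -- row builders ------------------------------------------------------

    def _empty_values(self) -> Dict[str, str]:
        return {c: MISSING for c in self.column_names}

    def _blank_row(self, record: IntervalRecord, note: str = MISSING) -> AnnotationRow:
        values = self._empty_values()
        values["annotation_note"] = note or MISSING
        return AnnotationRow(record, values)

    def _intergenic_row(self, record: IntervalRecord) -> AnnotationRow:
        values = self._empty_values()
        values["annotated_feature_type"] = "intergenic"
        values["annotated_chromosome"] = record.reference
        nb = self.mark_intergenic(record)
        if nb.left is not None:
            values["closest_gene_left"] = nb.left.feature_id
            values["distance_left"] = str(nb.left_distance)
            values["strand_left"] = nb.left.strand
        if nb.right is not None:
            values["closest_gene_right"] = nb.right.feature_id
            values["distance_right"] = str(nb.right_distance)
            values["strand_right"] = nb.right.strand
        return AnnotationRow(record, values)

    def _model_for(self, tx_rec: FeatureRecord, recs: Optional[TranscriptRecords] = None) -> TranscriptModel:
        model = self._models.get(tx_rec.feature_id)
        if model is None:
            if recs is None:
                gene = self.db.fetch_feature(tx_rec.parent_id) if tx_rec.parent_id else None
                recs = TranscriptRecords(tx_rec, gene, self.db.fetch_children(tx_rec.feature_id))
            model = TranscriptModel.from_records(recs)
            self._models[tx_rec.feature_id] = model
        return model

    def _attr_value(self, model: TranscriptModel, key: str) -> str:
        tx = model.record
        merged: Dict[str, str] = {}
        if model.gene_id:
            gene = self.db.fetch_feature(model.gene_id)
            if gene is not None:
                merged.update(gene.attributes)
        if tx is not None:
            merged.update(tx.attributes)
        return merged.get(key, MISSING)

    def _transcript_shell_row(
        self,
        record: IntervalRecord,
        model: TranscriptModel,
        region: str,
        flags: Dict[str, bool],
        note: str = MISSING,
    ) -> AnnotationRow:
        values = self._empty_values()
        tx = model.record
        values["annotated_gene_id"] = model.gene_id or MISSING
        values["annotated_transcript_id"] = model.transcript_id
        values["annotated_feature_type"] = tx.feature_type if tx else "transcript"
        values["annotated_chromosome"] = model.seqid
        values["annotated_transcript_start"] = str(tx.start if tx else model.genomic_start)
        values["annotated_transcript_end"] = str(tx.end if tx else model.genomic_end)
        for col in self.child_columns:
            values[col] = "y" if flags.get(col) else MISSING
        for col in self.attribute_columns:
            values[col] = self._attr_value(model, col)
        values["feature_region"] = region
        values["annotation_note"] = note
        return AnnotationRow(record, values)

    def _transcript_row(
        self, record: IntervalRecord, model: TranscriptModel, s: int, e: int, genomic: bool
    ) -> AnnotationRow:
        flags = self._genomic_child_flags(model, s, e)
        proj = project_to_tx(model, s, e)
        if proj.flag is ProjectionFlag.FULLY_INTRONIC:
            region = str(RegionLabel.INTRONIC)
        else:
            region = str(classify(proj.interval.start, proj.interval.end, model.spliced_length))
        return self._transcript_shell_row(record, model, region=region, flags=flags)

    # -- child flags -------------------------------------------------------

    def _genomic_child_flags(self, model: TranscriptModel, s: int, e: int) -> Dict[str, bool]:
        """Flag child types by genomic overlap with ``[s, e]``.

        ``full`` containment requires the interval inside one child
        feature's genomic span."""
        full = self.options.containment == "full"
        flags: Dict[str, bool] = {}
        for child in model.children:
            t = child.feature_type
            if t not in self.child_columns or flags.get(t):
                continue
            hit = child.contains(s, e) if full else child.overlaps(s, e)
            if hit:
                flags[t] = True
        return flags

    def _tx_child_flags(self, model: TranscriptModel, s: int, e: int) -> Dict[str, bool]:
        """Flag child types by transcript-space overlap with ``[s, e]``.

        Each child type's genomic blocks are projected into transcript
        coordinates and merged when adjacent (a CDS split across exons is
        contiguous in the spliced transcript); ``full`` containment
        requires the interval inside one merged block."""
        full = self.options.containment == "full"
        spans: Dict[str, List[Tuple[int, int]]] = {}
        for child in model.children:
            t = child.feature_type
            if t not in self.child_columns:
                continue
            try:
                proj = project_to_tx(model, child.start, child.end)
            except Exception:
                continue
            if proj.interval is None:
                continue
            spans.setdefault(t, []).append((proj.interval.start, proj.interval.end))
        flags: Dict[str, bool] = {}
        for t, blocks in spans.items():
            merged: List[List[int]] = []
            for b in sorted(blocks):
                if merged and b[0] <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], b[1])
                else:
                    merged.append(list(b))
            if full:
                flags[t] = any(ms <= s and e <= me for ms, me in merged)
            else:
                flags[t] = any(ms <= e and me >= s for ms, me in merged)
        return flags
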