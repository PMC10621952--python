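"""Relational feature store built from GTF/GFF3 annotation files.

The store is a single-file SQLite database holding every feature of the
annotation (genes, transcripts, exons, CDS, UTRs, ...) together with its
genomic span, strand, parent link and attributes.  Feature types and
attribute *keys* are lowercased at load time so that every later query is
case-insensitive; attribute *values* (gene and transcript identifiers,
biotypes, names) are stored exactly as given.

The database is created once per annotation file and reused across runs:
it can be built entirely in memory and spilled to disk at the end
(default, fastest) or written incrementally to disk (lower peak memory).

Line-level parsing of both dialects is delegated to :mod:`gffutils`; the
schema, hierarchy computation and query layer live here.
"""

from __future__ import annotations

import logging
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

from gffutils.feature import feature_from_line

from .errors import ParseError, UnknownReferenceError

log = logging.getLogger("annotx")

#: feature types treated as gene-level when computing intergenic
#: neighbours and the gene/transcript hierarchy
_GENE_SUFFIX = "gene"


def _is_gene_type(feature_type: str) -> bool:
    # 'gene', 'ncrna_gene', 'pseudogene', ... all end in "gene"
    return feature_type.endswith(_GENE_SUFFIX)


@dataclass
class FeatureRecord:
    """One annotation feature in canonical form.

    Coordinates are 1-based and end-inclusive, as in GTF/GFF3.
    ``feature_type`` and attribute keys are lowercase by construction.
    """

    feature_id: str
    feature_type: str
    seqid: str
    start: int
    end: int
    strand: str
    parent_id: Optional[str] = None
    attributes: dict = field(default_factory=dict)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and self.end >= start

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class FeatureHierarchy:
    """Observed feature-type hierarchy and per-type attribute names."""

    nodes: set
    edges: set  # (parent_type, child_type)
    attributes_per_type: dict  # type -> sorted list of attribute keys

    def children_of(self, parent_type: str) -> list:
        return sorted(c for (p, c) in self.edges if p == parent_type)

    def render(self) -> str:
        """Indented text tree with the attribute list of each type."""
        if not self.nodes:
            return "(empty database: no features)"
        child_types = {c for (_, c) in self.edges}
        roots = sorted(t for t in self.nodes if t not in child_types)
        lines: list[str] = []

        def describe(t: str) -> str:
            attrs = self.attributes_per_type.get(t, [])
            suffix = f"  [{', '.join(attrs)}]" if attrs else ""
            return f"{t}{suffix}"

        def walk(t: str, prefix: str, seen: set) -> None:
            kids = [c for c in self.children_of(t) if c not in seen]
            for i, c in enumerate(kids):
                last = i == len(kids) - 1
                branch = "└── " if last else "├── "
                lines.append(prefix + branch + describe(c))
                seen.add(c)
                walk(c, prefix + ("    " if last else "│   "), seen)

        seen: set = set(roots)
        for r in roots:
            lines.append(describe(r))
            walk(r, "", seen)
        # types only reachable through cycles or dangling parents
        for t in sorted(self.nodes - seen):
            lines.append(describe(t))
        return "\n".join(lines)


class TranscriptRecords(NamedTuple):
    """Everything needed to build a transcript model."""

    transcript: FeatureRecord
    gene: Optional[FeatureRecord]
    children: list  # FeatureRecord, genomic order


# ---------------------------------------------------------------------------
# parsing


def detect_dialect(path: str) -> str:
    """Return ``'gtf'`` or ``'gff3'`` for *path*.

    The file extension decides when it is unambiguous; otherwise the
    first data line is sniffed: GFF3 attributes use ``key=value`` pairs,
    GTF uses ``key "value";`` pairs.
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".gtf":
        return "gtf"
    if ext in (".gff", ".gff3"):
        return "gff3"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                continue
            attr = fields[8]
            if '"' in attr and "=" not in attr.split('"')[0]:
                return "gtf"
            if "=" in attr:
                return "gff3"
    return "gff3"


def _iter_raw_features(path: str):
    """Yield ``(line_number, gffutils.Feature)`` for every data line.

    Comment/pragma lines are skipped silently; an embedded ``##FASTA``
    section terminates parsing.
    """
    try:
        fh = open(path)
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("##FASTA"):
                break
            if stripped.startswith("#"):
                continue
            if stripped.startswith(">"):  # naked FASTA section
                break
            try:
                yield lineno, feature_from_line(line.rstrip("\r\n"))
            except Exception as exc:
                raise ParseError(f"malformed feature line: {exc}", lineno) from exc


def parse_features(path: str, dialect: Optional[str] = None) -> list:
    """Parse *path* into a list of :class:`FeatureRecord`.

    Lowercases feature types and attribute keys, assigns stable feature
    IDs, links children to parents, and — for GTF input, where gene and
    transcript lines may be absent — synthesizes the missing gene and
    transcript records from the ``gene_id``/``transcript_id`` attributes.
    """
    dialect = dialect or detect_dialect(path)
    records: list[FeatureRecord] = []
    seen_ids: dict[str, int] = {}
    anon_counter = 0

    def unique_id(candidate: str) -> str:
        n = seen_ids.get(candidate, 0)
        seen_ids[candidate] = n + 1
        if n == 0:
            return candidate
        log.warning("duplicate feature ID %r; stored as %r", candidate, f"{candidate}_{n + 1}")
        return f"{candidate}_{n + 1}"

    for lineno, f in _iter_raw_features(path):
        ftype = f.featuretype.lower()
        attrs = {k.lower(): ",".join(v) for k, v in f.attributes.items()}
        if f.start is None or f.end is None:
            raise ParseError("feature without coordinates", lineno)
        if f.start > f.end:
            raise ParseError(f"start {f.start} > end {f.end}", lineno)
        parent: Optional[str] = None
        if dialect == "gff3":
            fid = attrs.get("id")
            if "parent" in attrs:
                parent = attrs["parent"].split(",")[0]
        else:  # gtf
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            if _is_gene_type(ftype):
                fid = gene_id
            elif ftype == "transcript" or tx_id and ftype in ("mrna",):
                fid = tx_id
                parent = gene_id
            elif tx_id is not None:
                fid = None
                parent = tx_id
            else:
                fid = None
                parent = gene_id
        if fid is None:
            anon_counter += 1
            stem = parent or ftype
            fid = f"{stem}:{ftype}:{anon_counter}"
        records.append(
            FeatureRecord(
                feature_id=unique_id(fid),
                feature_type=ftype,
                seqid=f.seqid,
                start=int(f.start),
                end=int(f.end),
                strand=f.strand if f.strand in ("+", "-") else ".",
                parent_id=parent,
                attributes=attrs,
            )
        )

    if dialect == "gtf":
        records = _synthesize_gtf_parents(records)

    # dangling parent references: warn, keep feature with null parent
    known = {r.feature_id for r in records}
    for r in records:
        if r.parent_id is not None and r.parent_id not in known:
            log.warning(
                "feature %r references unknown parent %r; kept unparented",
                r.feature_id,
                r.parent_id,
            )
            r.parent_id = None
    return records


def _synthesize_gtf_parents(records: list) -> list:
    """Create gene/transcript records a GTF file references but lacks."""
    present = {r.feature_id for r in records}
    tx_children: dict[str, list] = {}
    for r in records:
        tx = r.attributes.get("transcript_id")
        if tx and not _is_gene_type(r.feature_type) and r.feature_type != "transcript":
            tx_children.setdefault(tx, []).append(r)

    synthesized: list[FeatureRecord] = []
    for tx_id, kids in tx_children.items():
        if tx_id in present:
            continue
        gene_id = kids[0].attributes.get("gene_id")
        attrs = {"transcript_id": tx_id}
        if gene_id:
            attrs["gene_id"] = gene_id
        for k in kids[0].attributes:
            if k.startswith(("transcript_", "gene_")):
                attrs.setdefault(k, kids[0].attributes[k])
        synthesized.append(
            FeatureRecord(
                feature_id=tx_id,
                feature_type="transcript",
                seqid=kids[0].seqid,
                start=min(k.start for k in kids),
                end=max(k.end for k in kids),
                strand=kids[0].strand,
                parent_id=gene_id,
                attributes=attrs,
            )
        )
        present.add(tx_id)

    all_records = records + synthesized
    gene_children: dict[str, list] = {}
    for r in all_records:
        g = r.attributes.get("gene_id")
        if g and not _is_gene_type(r.feature_type):
            gene_children.setdefault(g, []).append(r)
    for gene_id, kids in gene_children.items():
        if gene_id in present:
            continue
        attrs = {"gene_id": gene_id}
        for k in kids[0].attributes:
            if k.startswith("gene_"):
                attrs.setdefault(k, kids[0].attributes[k])
        synthesized.append(
            FeatureRecord(
                feature_id=gene_id,
                feature_type="gene",
                seqid=kids[0].seqid,
                start=min(k.start for k in kids),
                end=max(k.end for k in kids),
                strand=kids[0].strand,
                parent_id=None,
                attributes=attrs,
            )
        )
        present.add(gene_id)
    return records + synthesized


# ---------------------------------------------------------------------------
# database

_SCHEMA = """
CREATE TABLE features (
    id       TEXT PRIMARY KEY,
    id_lower TEXT NOT NULL,
    type     TEXT NOT NULL,
    seqid    TEXT NOT NULL,
    start    INTEGER NOT NULL,
    end      INTEGER NOT NULL,
    strand   TEXT NOT NULL,
    parent   TEXT
);
CREATE TABLE attributes (
    feature_id TEXT NOT NULL,
    key        TEXT NOT NULL,
    value      TEXT NOT NULL
);
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
"""

_INDEXES = """
CREATE INDEX IF NOT EXISTS idx_feat_span   ON features (seqid, start, end);
CREATE INDEX IF NOT EXISTS idx_feat_lower  ON features (id_lower);
CREATE INDEX IF NOT EXISTS idx_feat_parent ON features (parent);
CREATE INDEX IF NOT EXISTS idx_feat_type   ON features (type);
CREATE INDEX IF NOT EXISTS idx_attr_feat   ON attributes (feature_id);
CREATE INDEX IF NOT EXISTS idx_attr_kv     ON attributes (key, value);
"""


class AnnotationDatabase:
    """Queryable SQLite-backed store of one annotation file's features."""

    def __init__(self, conn: sqlite3.Connection, path: Optional[str] = None):
        self.conn = conn
        self.path = path
        self._hierarchy: Optional[FeatureHierarchy] = None

    # -- construction ------------------------------------------------------

    @classmethod
    def build(
        cls,
        annotation_path: str,
        output_path: Optional[str] = None,
        disk_direct: bool = False,
    ) -> "AnnotationDatabase":
        """Parse *annotation_path* and build (and persist) the database.

        ``disk_direct=False`` builds in memory and copies the finished
        database to *output_path*; ``disk_direct=True`` writes to disk
        from the start, trading speed for a flat memory profile.  With
        ``output_path=None`` the database stays in memory.
        """
        records = parse_features(annotation_path)
        if disk_direct and output_path:
            if os.path.exists(output_path):
                os.remove(output_path)
            conn = sqlite3.connect(output_path)
            build_mode = "disk-direct"
        else:
            conn = sqlite3.connect(":memory:")
            build_mode = "memory-first"
        conn.executescript(_SCHEMA)
        cls._load(conn, records)
        conn.executescript(_INDEXES)
        conn.execute("INSERT INTO meta VALUES ('source_path', ?)", (annotation_path,))
        conn.execute("INSERT INTO meta VALUES ('build_mode', ?)", (build_mode,))
        conn.commit()
        if output_path and not disk_direct:
            if os.path.exists(output_path):
                os.remove(output_path)
            dest = sqlite3.connect(output_path)
            conn.backup(dest)
            conn.close()
            conn = dest
        return cls(conn, output_path)

    @staticmethod
    def _load(conn: sqlite3.Connection, records: Iterable[FeatureRecord]) -> None:
        feat_rows = []
        attr_rows = []
        for r in records:
            feat_rows.append(
                (r.feature_id, r.feature_id.lower(), r.feature_type, r.seqid,
                 r.start, r.end, r.strand, r.parent_id)
            )
            for k, v in r.attributes.items():
                attr_rows.append((r.feature_id, k, v))
        conn.executemany("INSERT INTO features VALUES (?,?,?,?,?,?,?,?)", feat_rows)
        conn.executemany("INSERT INTO attributes VALUES (?,?,?)", attr_rows)

    @classmethod
    def open(cls, path: str) -> "AnnotationDatabase":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return cls(sqlite3.connect(path), path)

    def close(self) -> None:
        self.conn.close()

    # -- row construction --------------------------------------------------

    def _attrs_for(self, feature_ids: Sequence[str]) -> dict:
        out: dict[str, dict] = {fid: {} for fid in feature_ids}
        CHUNK = 500
        ids = list(feature_ids)
        for i in range(0, len(ids), CHUNK):
            chunk = ids[i : i + CHUNK]
            q = ",".join("?" * len(chunk))
            for fid, k, v in self.conn.execute(
                f"SELECT feature_id, key, value FROM attributes WHERE feature_id IN ({q})",
                chunk,
            ):
                out[fid][k] = v
        return out

    def _records_from_rows(self, rows: list) -> list:
        attrs = self._attrs_for([r[0] for r in rows])
        return [
            FeatureRecord(
                feature_id=fid, feature_type=ftype, seqid=seqid,
                start=start, end=end, strand=strand, parent_id=parent,
                attributes=attrs[fid],
            )
            for fid, ftype, seqid, start, end, strand, parent in rows
        ]

    _COLS = "id, type, seqid, start, end, strand, parent"

    # -- queries -----------------------------------------------------------

    def count_features(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM features").fetchone()[0]

    def feature_types(self) -> list:
        return [t for (t,) in self.conn.execute("SELECT DISTINCT type FROM features ORDER BY type")]

    def iter_features(self, feature_types: Optional[Iterable[str]] = None) -> Iterator[FeatureRecord]:
        sql = f"SELECT {self._COLS} FROM features"
        args: tuple = ()
        if feature_types is not None:
            types = [t.lower() for t in feature_types]
            sql += f" WHERE type IN ({','.join('?' * len(types))})"
            args = tuple(types)
        sql += " ORDER BY seqid, start, id"
        rows = self.conn.execute(sql, args).fetchall()
        yield from self._records_from_rows(rows)

    def fetch_overlapping(
        self,
        seqid: str,
        start: int,
        end: int,
        feature_types: Optional[Iterable[str]] = None,
    ) -> list:
        """All features on *seqid* intersecting ``[start, end]`` (1-based,
        closed), ordered by start then feature ID."""
        sql = (
            f"SELECT {self._COLS} FROM features "
            "WHERE seqid = ? AND start <= ? AND end >= ?"
        )
        args = [seqid, end, start]
        if feature_types is not None:
            types = [t.lower() for t in feature_types]
            sql += f" AND type IN ({','.join('?' * len(types))})"
            args.extend(types)
        sql += " ORDER BY start, id"
        return self._records_from_rows(self.conn.execute(sql, args).fetchall())

    def fetch_feature(self, feature_id: str) -> Optional[FeatureRecord]:
        rows = self.conn.execute(
            f"SELECT {self._COLS} FROM features WHERE id_lower = ? ORDER BY id LIMIT 1",
            (feature_id.lower(),),
        ).fetchall()
        return self._records_from_rows(rows)[0] if rows else None

    def fetch_children(self, parent_feature_id: str) -> list:
        parent = self.fetch_feature(parent_feature_id)
        if parent is None:
            return []
        rows = self.conn.execute(
            f"SELECT {self._COLS} FROM features WHERE parent = ? ORDER BY start, end, id",
            (parent.feature_id,),
        ).fetchall()
        return self._records_from_rows(rows)

    def gene_types(self) -> list:
        return [t for t in self.feature_types() if _is_gene_type(t)]

    def transcript_types(self) -> list:
        """Feature types observed as direct children of gene features."""
        gtypes = self.gene_types()
        if not gtypes:
            return [t for t in ("transcript", "mrna") if t in self.feature_types()]
        q = ",".join("?" * len(gtypes))
        rows = self.conn.execute(
            "SELECT DISTINCT c.type FROM features c JOIN features p ON c.parent = p.id "
            f"WHERE p.type IN ({q}) ORDER BY c.type",
            gtypes,
        ).fetchall()
        types = [t for (t,) in rows]
        if not types:
            types = [t for t in ("transcript", "mrna") if t in self.feature_types()]
        return types

    def fetch_by_transcript_id(self, transcript_id: str) -> TranscriptRecords:
        """Resolve *transcript_id* (case-insensitively) to the transcript
        record, its gene, and its child features in genomic order.

        Raises :class:`UnknownReferenceError` when no transcript matches;
        callers treat this as "emit the row unannotated".
        """
        rec = self.fetch_feature(transcript_id)
        if rec is not None and _is_gene_type(rec.feature_type):
            rec = None
        if rec is None:
            # fall back to the transcript_id attribute on transcript rows
            tx_types = self.transcript_types()
            if tx_types:
                q = ",".join("?" * len(tx_types))
                rows = self.conn.execute(
                    f"SELECT {self._COLS} FROM features f JOIN attributes a "
                    "ON a.feature_id = f.id WHERE a.key = 'transcript_id' "
                    f"AND lower(a.value) = ? AND f.type IN ({q}) ORDER BY f.id LIMIT 1",
                    [transcript_id.lower()] + tx_types,
                ).fetchall()
                rec = self._records_from_rows(rows)[0] if rows else None
        if rec is None:
            raise UnknownReferenceError(transcript_id)
        gene = self.fetch_feature(rec.parent_id) if rec.parent_id else None
        children = self.fetch_children(rec.feature_id)
        return TranscriptRecords(rec, gene, children)

    def closest_gene_left(self, seqid: str, pos: int) -> Optional[FeatureRecord]:
        """Gene with the greatest end strictly left of *pos*; ties broken
        by feature ID."""
        gtypes = self.gene_types()
        if not gtypes:
            return None
        q = ",".join("?" * len(gtypes))
        rows = self.conn.execute(
            f"SELECT {self._COLS} FROM features WHERE seqid = ? AND end < ? "
            f"AND type IN ({q}) ORDER BY end DESC, id LIMIT 1",
            [seqid, pos] + gtypes,
        ).fetchall()
        return self._records_from_rows(rows)[0] if rows else None

    def closest_gene_right(self, seqid: str, pos: int) -> Optional[FeatureRecord]:
        gtypes = self.gene_types()
        if not gtypes:
            return None
        q = ",".join("?" * len(gtypes))
        rows = self.conn.execute(
            f"SELECT {self._COLS} FROM features WHERE seqid = ? AND start > ? "
            f"AND type IN ({q}) ORDER BY start ASC, id LIMIT 1",
            [seqid, pos] + gtypes,
        ).fetchall()
        return self._records_from_rows(rows)[0] if rows else None

    # -- hierarchy ---------------------------------------------------------

    def hierarchy(self) -> FeatureHierarchy:
        if self._hierarchy is not None:
            return self._hierarchy
        nodes = set(self.feature_types())
        edges = set(
            self.conn.execute(
                "SELECT DISTINCT p.type, c.type FROM features c "
                "JOIN features p ON c.parent = p.id"
            ).fetchall()
        )
        attrs: dict[str, set] = {}
        for ftype, key in self.conn.execute(
            "SELECT DISTINCT f.type, a.key FROM features f "
            "JOIN attributes a ON a.feature_id = f.id"
        ):
            attrs.setdefault(ftype, set()).add(key)
        self._hierarchy = FeatureHierarchy(
            nodes=nodes,
            edges=edges,
            attributes_per_type={t: sorted(v) for t, v in attrs.items()},
        )
        return self._hierarchy


def build_database(
    annotation_path: str,
    output_path: Optional[str] = None,
    disk_direct: bool = False,
) -> AnnotationDatabase:
    """Parse a GTF/GFF3 file into a persistent annotation database."""
    return AnnotationDatabase.build(annotation_path, output_path, disk_direct)


def inspect_hierarchy(db: AnnotationDatabase) -> str:
    """Render the feature-type hierarchy and per-type attribute lists."""
    return db.hierarchy().render()
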