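"""Post-annotation summary statistics.

Tallies the categorical annotation columns of a finished run — child
feature flags, gene/transcript biotypes and other selected attributes,
and the region label — over *output* rows (after any per-transcript row
multiplication), alongside input/output row totals so the two counting
bases stay distinguishable.  The report goes to a side channel (a file
or standard error), never into the annotated table itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, TextIO

from .interval_annotator import MISSING, AnnotationRow


@dataclass
class AnnotationSummary:
    """Per-column categorical counts plus run totals."""

    counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    rows_in: int = 0
    rows_out: int = 0
    intergenic: int = 0
    unannotated: int = 0

    def table(self, column: str) -> List:
        """(value, count) pairs, count-descending then value-ascending."""
        tab = self.counts.get(column, {})
        return sorted(tab.items(), key=lambda kv: (-kv[1], kv[0]))

    def render(self) -> str:
        lines = [
            "# annotation summary",
            f"input intervals:\t{self.rows_in}",
            f"output rows:\t{self.rows_out}",
            f"intergenic:\t{self.intergenic}",
            f"unannotated:\t{self.unannotated}",
        ]
        for column in self.counts:
            lines.append(f"\n## {column}")
            for value, count in self.table(column):
                lines.append(f"{value}\t{count}")
        return "\n".join(lines) + "\n"

    def write(self, out: TextIO) -> None:
        out.write(self.render())


def summarize(
    rows: Iterable[AnnotationRow],
    columns: Optional[List[str]] = None,
) -> AnnotationSummary:
    """Tally categorical columns over the annotation rows of one run.

    *columns* defaults to every child-flag, attribute and region column
    present in the rows' layout (anything except the structural
    identifier/coordinate columns and the note column).
    """
    summary = AnnotationSummary()
    seen_inputs = set()
    skip = {
        "annotated_gene_id", "annotated_transcript_id", "annotated_chromosome",
        "annotated_transcript_start", "annotated_transcript_end",
        "closest_gene_left", "distance_left", "strand_left",
        "closest_gene_right", "distance_right", "strand_right",
        "annotation_note",
    }
    for row in rows:
        summary.rows_out += 1
        seen_inputs.add(row.interval.row_number)
        ftype = row.get("annotated_feature_type")
        if ftype == "intergenic":
            summary.intergenic += 1
        elif ftype == MISSING:
            summary.unannotated += 1
        cols = columns if columns is not None else [
            c for c in row.values if c not in skip
        ]
        for c in cols:
            tab = summary.counts.setdefault(c, {})
            v = row.get(c)
            tab[v] = tab.get(v, 0) + 1
    summary.rows_in = len(seen_inputs)
    return summary


def summarize_table(path: str, columns: List[str], separator: str = "\t") -> Dict[str, Dict[str, int]]:
    """Tally categorical *columns* of an annotated table on disk.

    Convenience for summarizing a previously written run; the file must
    have a header line naming the columns.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=separator, dtype=str)
    return {
        c: df[c].value_counts().to_dict()
        for c in columns
        if c in df.columns
    }
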