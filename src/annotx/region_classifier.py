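"""Categorical placement of an interval within a transcript.

The label is derived from the quartiles of the spliced transcript that
contain the interval's start and end:

* ``5 prime``  — start in Q1, end in Q1 or Q2
* ``middle``   — start and end in Q2/Q3
* ``3 prime``  — start in Q3 or Q4, end in Q4
* ``whole``    — start in Q1, end in Q4, length ≤ 90% of the transcript
* ``full``     — start in Q1, end in Q4, length > 90% of the transcript

A position p in a transcript of spliced length L belongs to quartile
``ceil(4p/L)``: a position exactly on a quartile boundary counts toward
the lower quartile.  The 90% cut is evaluated in exact integer arithmetic
(``10·length`` vs ``9·L``) so that boundary lengths are reproducible.

Quartile configurations the rules above leave uncovered (e.g. start in
Q1, end in Q3) are resolved by the quartile of the interval midpoint:
Q1 → ``5 prime``, Q2/Q3 → ``middle``, Q4 → ``3 prime``.  Genomic-mode
intervals whose spliced projection is empty (entirely intronic) are
labelled ``intronic`` instead.
"""

from __future__ import annotations

from enum import Enum

from .errors import OutOfRangeError


class RegionLabel(Enum):
    """Relative region of an interval within a transcript."""

    FIVE_PRIME = "5 prime"
    MIDDLE = "middle"
    THREE_PRIME = "3 prime"
    WHOLE = "whole"
    FULL = "full"
    INTRONIC = "intronic"

    def __str__(self) -> str:  # the vocabulary written to output tables
        return self.value


def quartile(p: int, length: int) -> int:
    """Quartile (1..4) of position *p* in a transcript of spliced length
    *length*; boundary positions belong to the lower quartile."""
    if not 1 <= p <= length:
        raise OutOfRangeError(f"position {p} outside 1..{length}")
    return min(4, -(-4 * p // length))


def classify(start: int, end: int, length: int) -> RegionLabel:
    """Label the transcript interval ``[start, end]`` (1-based inclusive)."""
    if not 1 <= start <= end <= length:
        raise OutOfRangeError(f"interval {start}-{end} outside 1..{length}")
    # the 5'-terminal base is in the first quarter by convention; for
    # length >= 4 the ceiling formula already says so, but degenerate
    # transcripts (length < 4) would otherwise have an empty Q1
    qs = 1 if start == 1 else quartile(start, length)
    qe = quartile(end, length)
    span = end - start + 1
    if qs == 1 and qe == 4:
        # strict inequality: exactly 90% of the transcript is still "whole"
        return RegionLabel.FULL if 10 * span > 9 * length else RegionLabel.WHOLE
    if qs == 1 and qe <= 2:
        return RegionLabel.FIVE_PRIME
    if qs >= 3 and qe == 4:
        return RegionLabel.THREE_PRIME
    if qs in (2, 3) and qe in (2, 3):
        return RegionLabel.MIDDLE
    # uncovered configuration: fall back to the midpoint quartile
    qm = quartile((start + end) // 2, length)
    if qm == 1:
        return RegionLabel.FIVE_PRIME
    if qm == 4:
        return RegionLabel.THREE_PRIME
    return RegionLabel.MIDDLE
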