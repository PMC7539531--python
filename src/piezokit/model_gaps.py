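"""Residue-range accounting for homology-model coverage bookkeeping.

Utilities over inclusive 1-based residue ranges: counting residues across a
set of ranges (e.g. loops rebuilt into a cryo-EM structure), the percentage
of a protein they cover, and deriving the modeled fragments that remain when
unresolved regions are cut out of a chain span.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ResidueRangeSet",
    "count_range_residues",
    "coverage_fraction",
    "modeled_fragments",
]


@dataclass(frozen=True)
class ResidueRangeSet:
    """A set of inclusive (start, end) residue ranges, 1-based.

    Ranges are normalized to ascending order on construction; a single
    residue r is the range (r, r).  Overlapping ranges are rejected —
    adjacent ranges (e.g. 1-3 and 4-5) are allowed but not merged.
    """

    ranges: tuple[tuple[int, int], ...]

    def __init__(self, ranges) -> None:
        norm = []
        for r in ranges:
            if isinstance(r, int):
                r = (r, r)
            start, end = int(r[0]), int(r[1])
            if start < 1:
                raise ValueError(f"residue numbers start at 1, got {start}")
            if start > end:
                raise ValueError(f"range start {start} exceeds end {end}")
            norm.append((start, end))
        norm.sort()
        for (s1, e1), (s2, _e2) in zip(norm, norm[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"ranges {s1}-{e1} and starting at {s2} overlap"
                )
        object.__setattr__(self, "ranges", tuple(norm))

    @classmethod
    def parse(cls, text: str) -> "ResidueRangeSet":
        """Parse "601:604,876:879,2547" (also accepts '-' as separator)."""
        ranges = []
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            sep = ":" if ":" in token else "-"
            parts = token.split(sep)
            if len(parts) == 1:
                ranges.append((int(parts[0]), int(parts[0])))
            else:
                ranges.append((int(parts[0]), int(parts[1])))
        return cls(ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    def __iter__(self):
        return iter(self.ranges)


def count_range_residues(rs: ResidueRangeSet) -> int:
    """Total residues covered: sum of (end - start + 1) over the ranges."""
    return sum(end - start + 1 for start, end in rs.ranges)


def coverage_fraction(count: int, total_length: int) -> float:
    """Percentage 100*count/total_length, half-up rounded to one decimal."""
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    pct = Decimal(100 * count) / Decimal(total_length)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def modeled_fragments(
    span: tuple[int, int], excluded: ResidueRangeSet
) -> ResidueRangeSet:
    """Maximal contiguous sub-ranges of ``span`` not covered by ``excluded``.

    ``span`` is inclusive on both ends; every excluded range must lie within
    it.  Returns the fragments in ascending order (possibly empty when the
    exclusions cover the whole span).
    """
    start, end = int(span[0]), int(span[1])
    if start < 1 or start > end:
        raise ValueError(f"invalid span {span}")
    for s, e in excluded:
        if s < start or e > end:
            raise ValueError(f"excluded range {s}-{e} lies outside span {start}-{end}")
    fragments = []
    cursor = start
    for s, e in excluded.ranges:  # already sorted
        if s > cursor:
            fragments.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= end:
        fragments.append((cursor, end))
    return ResidueRangeSet(fragments)
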