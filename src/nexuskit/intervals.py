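"""Genomic interval primitives shared across modules.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  Overlap therefore means ``a.start < b.end and b.start < a.end``
and two intervals touching end-to-start do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"malformed interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint (even widths round down)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least 1 bp of direct intersection (half-open arithmetic)."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))
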