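"""Genomic interval primitives.

Coordinates are 0-based, half-open throughout the library; 1-based closed
only in human-readable region strings (``chr1:1,001-2,000``) and on output
where a format demands it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware genomic interval (0-based, half-open)."""

    contig: str
    start: int
    end: int
    strand: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between intervals in bp; 0 if they overlap or touch."""
        if self.contig != other.contig:
            raise ValueError("distance undefined across contigs")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.contig,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )

    def to_region(self) -> str:
        """1-based closed region string."""
        return f"{self.contig}:{self.start + 1}-{self.end}"

    @classmethod
    def from_region(cls, region: str, strand: str = "+") -> "GenomicInterval":
        m = _REGION_RE.match(region)
        if m is None:
            raise ValueError(f"cannot parse region string {region!r}")
        start = int(m.group(2).replace(",", "")) - 1
        end = int(m.group(3).replace(",", ""))
        return cls(m.group(1), start, end, strand)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.to_region()
        return s if self.strand == "+" else f"{s}[-]"
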