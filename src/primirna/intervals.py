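"""Genomic intervals in 1-based inclusive coordinates.

All coordinates at the package surface follow GFF3/GTF convention:
``start`` and ``end`` are 1-based and both inclusive, so an interval of
length 1 has ``start == end``. Strand is recorded but, by default, ignored
by the overlap/gap algebra; pass ``stranded=True`` to restrict both to
features on compatible strands.
"""

from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A closed interval [start, end] on a named chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / sequence name.
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand : str
        '+', '-' or '.' (unknown). Default '.'.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """True if ``other`` lies entirely within this interval (same chrom)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def span_with(self, other: "GenomicInterval") -> "GenomicInterval":
        """Smallest interval covering both (must share a chromosome)."""
        if self.chrom != other.chrom:
            raise ValueError("cannot span intervals on different chromosomes")
        return GenomicInterval(
            self.chrom,
            min(self.start, other.start),
            max(self.end, other.end),
            self.strand if self.strand == other.strand else ".",
        )


def _strands_compatible(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Unknown strand matches anything; '+' and '-' are incompatible."""
    return a.strand == "." or b.strand == "." or a.strand == b.strand


def overlap_bp(a: GenomicInterval, b: GenomicInterval, *, stranded: bool = False) -> int:
    """Number of bases shared by two intervals (0 if disjoint or on
    different chromosomes; symmetric)."""
    if a.chrom != b.chrom:
        return 0
    if stranded and not _strands_compatible(a, b):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def gap_bp(a: GenomicInterval, b: GenomicInterval, *, stranded: bool = False) -> int | None:
    """Bases strictly between two intervals on the same chromosome.

    Returns 0 when the intervals overlap or abut ([1,100] vs [101,200]),
    and ``None`` (no neighbour relation) when the chromosomes differ or,
    in stranded mode, the strands are incompatible.
    """
    if a.chrom != b.chrom:
        return None
    if stranded and not _strands_compatible(a, b):
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)
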