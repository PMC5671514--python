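"""Read-to-feature assignment with largest-overlap semantics.

Mirrors the quantification configuration the annotation was built for:
only primary alignments are admitted, a minimum mapping quality is
required (default 10), and each read (or fragment, for paired data) is
assigned to the single feature with the largest number of overlapping
bases. Equal-overlap ties are left unassigned and tallied as ambiguous.
Multi-mapping reads are counted once, through their primary record.

Overlap is measured on reference-consuming CIGAR operations with N
(skipped region / intron) treated as a gap and D (deletion) as part of
the aligned span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .features import Biotype, FeatureSet
from .intervals import GenomicInterval

# CIGAR operation codes
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X extend the current block
_REF_SKIP = 3  # N closes the block
_NO_REF = {1, 4, 5, 6}  # I, S, H, P


@dataclass
class AssignmentStats:
    """Record- and fragment-level accounting for one library.

    ``records_total = unmapped + secondary + below_mapq + unknown_chrom
    + malformed_cigar + records_admitted`` and, for single-end data
    where fragment == record, ``records_admitted = assigned + ambiguous
    + no_overlap``.
    """

    records_total: int = 0
    unmapped: int = 0
    secondary: int = 0
    below_mapq: int = 0
    unknown_chrom: int = 0
    malformed_cigar: int = 0
    records_admitted: int = 0
    fragments_total: int = 0
    assigned: int = 0
    ambiguous: int = 0
    no_overlap: int = 0


def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """1-based inclusive reference blocks of the alignment, split at N."""
    blocks: list[tuple[int, int]] = []
    pos = read.reference_start + 1  # to 1-based
    start = None
    for op, length in read.cigartuples or []:
        if op in _REF_CONSUMING:
            if start is None:
                start = pos
            pos += length
        elif op == _REF_SKIP:
            if start is not None:
                blocks.append((start, pos - 1))
                start = None
            pos += length
        elif op in _NO_REF:
            continue
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if start is not None:
        blocks.append((start, pos - 1))
    return blocks


def _feature_overlaps(
    blocks: list[tuple[int, int]],
    chrom: str,
    features: FeatureSet,
    *,
    biotypes: Iterable[Biotype] | None,
) -> dict[str, int]:
    ov: dict[str, int] = {}
    for bstart, bend in blocks:
        iv = GenomicInterval(chrom, bstart, bend)
        for f in features.overlapping(iv, biotypes=biotypes):
            ov[f.id] = ov.get(f.id, 0) + min(bend, f.interval.end) - max(bstart, f.interval.start) + 1
    return ov


def count_reads(
    alignments: str | Path,
    features: FeatureSet,
    *,
    min_mapq: int = 10,
    count_fragments: bool = True,
    biotypes: Iterable[Biotype] | None = None,
) -> tuple[pd.Series, AssignmentStats]:
    """Count reads from a SAM/BAM file against a feature set.

    Returns a counts column indexed by feature id (all features, zeros
    included, sorted by id) and the assignment statistics. With
    ``count_fragments`` (default) records sharing a read name are pooled
    into one fragment whose per-feature overlaps are summed before the
    largest-overlap rule is applied; otherwise every admitted record is
    assigned independently.
    """
    feature_ids = sorted(f.id for f in features)
    counts = {fid: 0 for fid in feature_ids}
    stats = AssignmentStats()
    known_chroms = set(features.chromosomes)
    frag_overlaps: dict[str, dict[str, int]] = {}

    mode = "rb" if str(alignments).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(alignments), mode, check_sq=False) as fh:
        for read in fh:
            stats.records_total += 1
            if read.is_unmapped:
                stats.unmapped += 1
                continue
            if read.is_secondary or read.is_supplementary:
                stats.secondary += 1
                continue
            if read.mapping_quality < min_mapq:
                stats.below_mapq += 1
                continue
            if read.reference_name not in known_chroms:
                stats.unknown_chrom += 1
                continue
            try:
                blocks = _aligned_blocks(read)
            except ValueError:
                stats.malformed_cigar += 1
                continue
            stats.records_admitted += 1
            ov = _feature_overlaps(blocks, read.reference_name, features, biotypes=biotypes)
            if count_fragments:
                pool = frag_overlaps.setdefault(read.query_name, {})
                for fid, n in ov.items():
                    pool[fid] = pool.get(fid, 0) + n
            else:
                _resolve(ov, counts, stats)

    if count_fragments:
        for ov in frag_overlaps.values():
            _resolve(ov, counts, stats)

    column = pd.Series(counts, dtype="int64").sort_index()
    return column, stats


def _resolve(ov: dict[str, int], counts: dict[str, int], stats: AssignmentStats) -> None:
    stats.fragments_total += 1
    if not ov:
        stats.no_overlap += 1
        return
    best = max(ov.values())
    winners = [fid for fid, n in ov.items() if n == best]
    if len(winners) > 1:
        stats.ambiguous += 1
        return
    counts[winners[0]] += 1
    stats.assigned += 1


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with per-sample library
    sizes (the column sums of assigned counts)."""

    counts: pd.DataFrame
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype("int64")
        self.library_sizes = self.library_sizes.astype("int64").reindex(self.counts.columns)

    @classmethod
    def from_frame(cls, counts: pd.DataFrame) -> "CountMatrix":
        return cls(counts=counts, library_sizes=counts.sum(axis=0))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("feature_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)


def merge_columns(columns: Mapping[str, pd.Series]) -> CountMatrix:
    """Assemble per-sample count columns into a CountMatrix.

    All columns must carry the identical feature-id index.
    """
    if not columns:
        raise ValueError("no columns to merge")
    items = list(columns.items())
    ref_index = items[0][1].index
    for name, col in items[1:]:
        if len(col.index) != len(ref_index) or (col.index != ref_index).any():
            raise ValueError(f"sample {name!r}: feature ids do not match the first column")
    frame = pd.DataFrame({name: col for name, col in items})
    return CountMatrix.from_frame(frame)
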