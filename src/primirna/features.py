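"""Annotated genomic features and an indexed container for them."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

from .intervals import GenomicInterval, overlap_bp


class Biotype(str, Enum):
    """Feature classes the pipeline distinguishes.

    The first four describe inputs (reference hairpins, reference genes,
    assembled transcript predictions); ``PRI_MIRNA`` marks the pri-miRNA
    gene models this package itself produces.
    """

    PRE_MIRNA = "pre_miRNA"
    PROTEIN_CODING = "protein_coding"
    NON_CODING = "non_coding"
    TRANSCRIPT_MODEL = "transcript_model"
    PRI_MIRNA = "pri_miRNA"


@dataclass(slots=True)
class GeneFeature:
    """One annotated feature: an id, an interval, a biotype and the
    pass-through attribute map from GFF3 column 9."""

    id: str
    interval: GenomicInterval
    biotype: Biotype
    attributes: dict[str, str] = field(default_factory=dict)


class DuplicateFeatureError(ValueError):
    pass


class FeatureSet:
    """A collection of features with id lookup and per-chromosome
    interval indexes for overlap queries."""

    def __init__(self, features: Iterable[GeneFeature] = ()) -> None:
        self._by_id: dict[str, GeneFeature] = {}
        self._trees: dict[str, IntervalTree] = {}
        for f in features:
            self.add(f)

    def add(self, feature: GeneFeature) -> None:
        if feature.id in self._by_id:
            raise DuplicateFeatureError(f"duplicate feature id {feature.id!r}")
        self._by_id[feature.id] = feature
        iv = feature.interval
        # internal index is half-open; invisible at every interface
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, feature)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self._by_id.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: str) -> GeneFeature:
        return self._by_id[feature_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def by_biotype(self, *biotypes: Biotype) -> list[GeneFeature]:
        wanted = set(biotypes)
        return [f for f in self._by_id.values() if f.biotype in wanted]

    def overlapping(
        self,
        interval: GenomicInterval,
        *,
        biotypes: Iterable[Biotype] | None = None,
        stranded: bool = False,
    ) -> list[GeneFeature]:
        """Features overlapping ``interval`` by at least one base, sorted by
        (start, id) for determinism."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        wanted = set(biotypes) if biotypes is not None else None
        hits = []
        for node in tree.overlap(interval.start, interval.end + 1):
            f: GeneFeature = node.data
            if wanted is not None and f.biotype not in wanted:
                continue
            if stranded and overlap_bp(interval, f.interval, stranded=True) == 0:
                continue
            hits.append(f)
        hits.sort(key=lambda f: (f.interval.start, f.id))
        return hits

    def interval_arrays(
        self, chrom: str, biotype: Biotype
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(starts, ends, ids) for one biotype on one chromosome, for
        vectorised distance computations."""
        feats = [
            f
            for f in self._by_id.values()
            if f.biotype is biotype and f.interval.chrom == chrom
        ]
        feats.sort(key=lambda f: (f.interval.start, f.id))
        starts = np.array([f.interval.start for f in feats], dtype=np.int64)
        ends = np.array([f.interval.end for f in feats], dtype=np.int64)
        return starts, ends, [f.id for f in feats]

    def nearest_gap(
        self,
        interval: GenomicInterval,
        biotype: Biotype,
        *,
        stranded: bool = False,
    ) -> int | None:
        """Smallest ``gap_bp`` from ``interval`` to any feature of
        ``biotype`` on the same chromosome (0 when overlapping); ``None``
        when no such neighbour exists."""
        from .intervals import gap_bp

        best: int | None = None
        starts, ends, ids = self.interval_arrays(interval.chrom, biotype)
        if not stranded and len(starts):
            gaps = np.maximum(
                0,
                np.maximum(starts - interval.end, interval.start - ends) - 1,
            )
            return int(gaps.min())
        for fid in ids:
            g = gap_bp(interval, self.get(fid).interval, stranded=stranded)
            if g is not None and (best is None or g < best):
                best = g
        return best
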