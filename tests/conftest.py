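"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately re-derive expectations by
exhaustive enumeration / brute force, independent of the package's own
index- and formula-based code paths.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from primirna.classify import GroupLabel
from primirna.features import Biotype, FeatureSet, GeneFeature
from primirna.intervals import GenomicInterval


def feat(fid: str, start: int, end: int, biotype: Biotype, chrom: str = "c1",
         strand: str = "+") -> GeneFeature:
    return GeneFeature(fid, GenomicInterval(chrom, start, end, strand), biotype)


# ---------------------------------------------------------------------------
# Brute-force oracles


def oracle_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases by explicit base enumeration."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end + 1)) & set(range(b.start, b.end + 1)))


def oracle_gap(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Bases strictly between two intervals, by enumeration."""
    if a.chrom != b.chrom:
        return None
    if oracle_overlap(a, b) > 0:
        return 0
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    return len([p for p in range(lo + 1, hi) if p > lo and p < hi])


def _touches(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def _between(a: GenomicInterval, b: GenomicInterval) -> int:
    if _touches(a, b):
        return 0
    return max(a.start, b.start) - min(a.end, b.end) - 1


def oracle_classify(
    interval: GenomicInterval,
    member_intervals: list[GenomicInterval],
    coding: list[GenomicInterval],
    noncoding: list[GenomicInterval],
    g2_window: int = 400,
    *,
    model_level: bool = False,
) -> GroupLabel:
    """Positional group by exhaustively scanning every (feature, gene)
    pair, independent of any interval index."""
    if model_level:
        if any(_touches(h, g) for h in member_intervals for g in coding):
            return GroupLabel.G3A
        if any(_touches(interval, g) for g in coding):
            return GroupLabel.G3B
    else:
        if any(_touches(interval, g) for g in coding):
            return GroupLabel.G3A
    if any(_touches(interval, g) for g in noncoding):
        return GroupLabel.G4
    gaps = [_between(interval, g) for g in coding if g.chrom == interval.chrom]
    if gaps and 1 <= min(gaps) <= g2_window:
        return GroupLabel.G2
    return GroupLabel.G1


def oracle_wilcoxon_greater(x, y) -> tuple[float, float]:
    """Exact one-sided rank-sum p by enumerating every assignment of the
    pooled values to the two samples (no ties assumed)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n1 = len(x)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if sum(combo) >= w_obs:
            count += 1
    return float(w_obs), count / total


# ---------------------------------------------------------------------------
# A hand-constructed 10-hairpin annotation covering every group


@pytest.fixture()
def ten_hairpin_annotation() -> tuple[FeatureSet, FeatureSet]:
    """Reference with 10 hairpins and 1 prediction.

    Ground truth by construction: 4 isolated hairpins (G1), 2 hairpins
    200 bp from a coding gene (G2), 2 inside coding genes (G3A), 1
    overlapping a ncRNA (G4) and 1 isolated hairpin whose prediction
    reaches into a coding gene 599 bp away (G3B at model level).
    """
    ref = FeatureSet(
        [
            feat("h1", 1000, 1099, Biotype.PRE_MIRNA),
            feat("h2", 3000, 3099, Biotype.PRE_MIRNA),
            feat("h3", 5000, 5099, Biotype.PRE_MIRNA),
            feat("h4", 7000, 7099, Biotype.PRE_MIRNA),
            feat("geneA", 10000, 12000, Biotype.PROTEIN_CODING),
            feat("h5", 12201, 12300, Biotype.PRE_MIRNA),
            feat("geneB", 15000, 17000, Biotype.PROTEIN_CODING),
            feat("h6", 17201, 17300, Biotype.PRE_MIRNA),
            feat("geneC", 20000, 23000, Biotype.PROTEIN_CODING),
            feat("h7", 21000, 21100, Biotype.PRE_MIRNA),
            feat("geneD", 25000, 28000, Biotype.PROTEIN_CODING),
            feat("h8", 26000, 26100, Biotype.PRE_MIRNA),
            feat("nc1", 30000, 30500, Biotype.NON_CODING),
            feat("h9", 30100, 30200, Biotype.PRE_MIRNA),
            feat("h10", 33000, 33100, Biotype.PRE_MIRNA),
            feat("geneE", 33700, 35000, Biotype.PROTEIN_CODING),
        ]
    )
    pred = FeatureSet([feat("p1", 33000, 33800, Biotype.TRANSCRIPT_MODEL)])
    return ref, pred
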