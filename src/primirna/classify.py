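"""Positional classification of pri-miRNA gene models.

Hairpins (pre-miRNAs) and their candidate gene models are placed into
five positional groups relative to the rest of the annotation:

* **G1** — intergenic;
* **G2** — closest protein-coding gene is 1-400 bp away;
* **G3A** — the hairpin itself overlaps a protein-coding gene;
* **G3B** — the gene model, but not the hairpin, overlaps a
  protein-coding gene (only possible at model level);
* **G4** — overlaps a non-coding gene.

Classification runs in two passes. The hairpin pass (G3B impossible)
decides the model-assignment rule: a G3A hairpin adopts the host
protein-coding gene as its model; otherwise a matched transcript
prediction, when available, provides the model; otherwise the model is
kept identical to the hairpin annotation. The model pass then labels
the final interval. Precedence when several definitions apply is fixed:
G3A > G3B > G4 > G2 > G1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .features import Biotype, FeatureSet, GeneFeature
from .intervals import GenomicInterval, overlap_bp


class GroupLabel(str, Enum):
    G1 = "G1"
    G2 = "G2"
    G3A = "G3A"
    G3B = "G3B"
    G4 = "G4"


GROUP_ORDER = [GroupLabel.G1, GroupLabel.G2, GroupLabel.G3A, GroupLabel.G3B, GroupLabel.G4]

GROUP_DESCRIPTIONS = {
    GroupLabel.G1: "Intergenic region",
    GroupLabel.G2: "Closest protein-coding gene is 1-400 bp away",
    GroupLabel.G3A: "Overlap of pre-miRNA with protein-coding gene",
    GroupLabel.G3B: "Overlap of pri-miRNA with protein-coding gene",
    GroupLabel.G4: "Overlaps with non-coding gene",
}


class SourceRule(str, Enum):
    """How a model's interval was chosen."""

    PREDICTED_TRANSCRIPT = "predicted_transcript"
    HOST_GENE = "host_gene"
    HAIRPIN_FALLBACK = "hairpin_fallback"


@dataclass(slots=True)
class PriMiRNAModel:
    """A final pri-miRNA gene model: 1-2 member hairpins, a positional
    group and the rule that produced its interval."""

    id: str
    interval: GenomicInterval
    group: GroupLabel
    source_rule: SourceRule
    members: list[str]
    conflict_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 2:
            raise ValueError(f"model {self.id}: needs 1-2 members, got {len(self.members)}")
        if (self.source_rule is SourceRule.HOST_GENE) != (self.group is GroupLabel.G3A):
            raise ValueError(
                f"model {self.id}: source_rule host_gene and group G3A must coincide "
                f"(got {self.source_rule.value}, {self.group.value})"
            )


def classify_hairpin(
    pre: GeneFeature,
    genes: FeatureSet,
    *,
    g2_window: int = 400,
    stranded: bool = False,
) -> GroupLabel:
    """Hairpin-level positional group (never G3B)."""
    if pre.biotype is not Biotype.PRE_MIRNA:
        raise ValueError(f"{pre.id}: classify_hairpin needs a pre_miRNA, got {pre.biotype.value}")
    return _classify_interval(pre.interval, genes, g2_window=g2_window, stranded=stranded)


def _classify_interval(
    interval: GenomicInterval,
    genes: FeatureSet,
    *,
    g2_window: int,
    stranded: bool,
) -> GroupLabel:
    if genes.overlapping(interval, biotypes=[Biotype.PROTEIN_CODING], stranded=stranded):
        return GroupLabel.G3A
    if genes.overlapping(interval, biotypes=[Biotype.NON_CODING], stranded=stranded):
        return GroupLabel.G4
    gap = genes.nearest_gap(interval, Biotype.PROTEIN_CODING, stranded=stranded)
    if gap is not None and 1 <= gap <= g2_window:
        return GroupLabel.G2
    return GroupLabel.G1


def classify_model(
    model_interval: GenomicInterval,
    members: list[GeneFeature],
    genes: FeatureSet,
    *,
    g2_window: int = 400,
    stranded: bool = False,
) -> GroupLabel:
    """Model-level positional group; G3B appears only here, when the
    model extends over a coding gene the member hairpins do not touch."""
    for pre in members:
        if genes.overlapping(pre.interval, biotypes=[Biotype.PROTEIN_CODING], stranded=stranded):
            return GroupLabel.G3A
    if genes.overlapping(model_interval, biotypes=[Biotype.PROTEIN_CODING], stranded=stranded):
        return GroupLabel.G3B
    if genes.overlapping(model_interval, biotypes=[Biotype.NON_CODING], stranded=stranded):
        return GroupLabel.G4
    gap = genes.nearest_gap(model_interval, Biotype.PROTEIN_CODING, stranded=stranded)
    if gap is not None and 1 <= gap <= g2_window:
        return GroupLabel.G2
    return GroupLabel.G1


def _largest_overlap_host(
    pre: GeneFeature, genes: FeatureSet, *, stranded: bool
) -> tuple[GeneFeature, bool]:
    """The protein-coding gene with the largest overlap with the hairpin;
    second return value flags a tie (broken by start, then id)."""
    hosts = genes.overlapping(pre.interval, biotypes=[Biotype.PROTEIN_CODING], stranded=stranded)
    scored = sorted(
        hosts,
        key=lambda g: (-overlap_bp(pre.interval, g.interval, stranded=stranded),
                       g.interval.start, g.id),
    )
    best = scored[0]
    tie = len(scored) > 1 and overlap_bp(pre.interval, scored[1].interval, stranded=stranded) == overlap_bp(
        pre.interval, best.interval, stranded=stranded
    )
    return best, tie


def assign_model(
    pre: GeneFeature,
    hairpin_label: GroupLabel,
    prediction: GeneFeature | None,
    genes: FeatureSet,
    *,
    g2_window: int = 400,
    stranded: bool = False,
) -> PriMiRNAModel:
    """Apply the model-assignment rule to a single hairpin.

    G3A hairpins adopt the overlapping protein-coding gene's interval;
    otherwise a matched prediction's interval is used when present, and
    the hairpin's own interval when not.
    """
    flags: list[str] = []
    if hairpin_label is GroupLabel.G3A:
        host, tie = _largest_overlap_host(pre, genes, stranded=stranded)
        if tie:
            flags.append(f"host_gene_overlap_tie:{host.id}")
        interval, rule = host.interval, SourceRule.HOST_GENE
    elif prediction is not None:
        if overlap_bp(pre.interval, prediction.interval) == 0:
            raise ValueError(f"prediction {prediction.id} does not overlap hairpin {pre.id}")
        interval, rule = prediction.interval, SourceRule.PREDICTED_TRANSCRIPT
        if not interval.contains(pre.interval):
            interval = interval.span_with(pre.interval)
            flags.append(f"prediction_partial_overlap:{prediction.id}")
    else:
        interval, rule = pre.interval, SourceRule.HAIRPIN_FALLBACK
    group = classify_model(interval, [pre], genes, g2_window=g2_window, stranded=stranded)
    return PriMiRNAModel(
        id=f"pri-{pre.id}",
        interval=interval,
        group=group,
        source_rule=rule,
        members=[pre.id],
        conflict_flags=flags,
    )


# ---------------------------------------------------------------------------
# Report bookkeeping


@dataclass
class ClassificationReport:
    """Per-group bookkeeping of the annotation build.

    ``hairpins`` counts the hairpin-level pass; the remaining columns
    count final models by their model-level group, split by interval
    source (prediction-derived vs reference-derived, i.e. host gene or
    hairpin kept as-is). Hairpin-level and model-level groups need not
    agree row by row (a model may move group when its interval extends),
    so only the column identities are validated:
    ``final = predicted + reference`` per group, and at totals level
    ``hairpins = final + two-hairpin models``.
    """

    hairpins: dict[GroupLabel, int]
    predicted_models: dict[GroupLabel, int]
    reference_models: dict[GroupLabel, int]
    two_hairpin_models: dict[GroupLabel, int]

    def final_models(self, group: GroupLabel) -> int:
        return self.predicted_models.get(group, 0) + self.reference_models.get(group, 0)

    def total(self, column: dict[GroupLabel, int]) -> int:
        return sum(column.get(g, 0) for g in GROUP_ORDER)

    def validate(self) -> None:
        n_hairpins = self.total(self.hairpins)
        n_final = sum(self.final_models(g) for g in GROUP_ORDER)
        n_two = self.total(self.two_hairpin_models)
        if n_hairpins != n_final + n_two:
            raise ValueError(
                f"report identity violated: {n_hairpins} hairpins != "
                f"{n_final} final models + {n_two} two-hairpin models"
            )


def summarize_report(report: ClassificationReport) -> pd.DataFrame:
    """Render the report as the five group rows plus a Total row.

    Columns: description, n_hairpins, n_predicted_models,
    n_reference_models, n_two_hairpin_models, n_final_models. Raises if
    the bookkeeping identities do not hold.
    """
    report.validate()
    rows = []
    for g in GROUP_ORDER:
        rows.append(
            {
                "group": g.value,
                "description": GROUP_DESCRIPTIONS[g],
                "n_hairpins": report.hairpins.get(g, 0),
                "n_predicted_models": report.predicted_models.get(g, 0),
                "n_reference_models": report.reference_models.get(g, 0),
                "n_two_hairpin_models": report.two_hairpin_models.get(g, 0),
                "n_final_models": report.final_models(g),
            }
        )
    total = {
        "group": "Total",
        "description": "",
        **{
            col: sum(r[col] for r in rows)
            for col in (
                "n_hairpins",
                "n_predicted_models",
                "n_reference_models",
                "n_two_hairpin_models",
                "n_final_models",
            )
        },
    }
    return pd.DataFrame(rows + [total]).set_index("group")


# ---------------------------------------------------------------------------
# Annotation build


@dataclass
class BuildResult:
    models: list[PriMiRNAModel]
    report: ClassificationReport
    merged: FeatureSet
    hairpin_labels: dict[str, GroupLabel]


def _match_predictions(
    hairpins: list[GeneFeature],
    predictions: FeatureSet,
    *,
    stranded: bool,
) -> tuple[dict[str, str], dict[str, list[str]], dict[str, list[str]]]:
    """Best-prediction matching.

    Each hairpin takes the overlapping prediction with the largest
    base overlap (ties: leftmost start, then id). Predictions claimed by
    more than two hairpins keep the two largest overlaps; the rest are
    released to the fallback rules. Returns (hairpin->prediction,
    prediction->members, prediction->conflict flags).
    """
    best: dict[str, str] = {}
    overlap_of: dict[str, int] = {}
    for pre in hairpins:
        cands = predictions.overlapping(
            pre.interval, biotypes=[Biotype.TRANSCRIPT_MODEL], stranded=stranded
        )
        if not cands:
            continue
        scored = sorted(
            cands,
            key=lambda t: (-overlap_bp(pre.interval, t.interval, stranded=stranded),
                           t.interval.start, t.id),
        )
        best[pre.id] = scored[0].id
        overlap_of[pre.id] = overlap_bp(pre.interval, scored[0].interval, stranded=stranded)

    members: dict[str, list[str]] = {}
    for hid, pid in best.items():
        members.setdefault(pid, []).append(hid)
    flags: dict[str, list[str]] = {}
    for pid, hids in list(members.items()):
        if len(hids) > 2:
            hids.sort(key=lambda h: (-overlap_of[h], h))
            dropped = hids[2:]
            members[pid] = sorted(hids[:2])
            flags[pid] = [f"prediction_claimed_by_{len(hids)}_hairpins"]
            for h in dropped:
                del best[h]
        else:
            members[pid] = sorted(hids)
    return best, members, flags


def build_annotation(
    reference: FeatureSet,
    predictions: FeatureSet | None = None,
    *,
    g2_window: int = 400,
    stranded: bool = False,
) -> BuildResult:
    """Build the final pri-miRNA annotation.

    Runs the hairpin pass, matches hairpins to transcript predictions,
    applies the per-group assignment rule, merges models that share an
    interval source (same prediction or same host gene) into two-hairpin
    models, and assembles the merged feature set (all non-hairpin
    reference features plus the new pri-miRNA models). Overlapping final
    models from different sources are flagged, not resolved.
    """
    hairpins = sorted(
        reference.by_biotype(Biotype.PRE_MIRNA),
        key=lambda f: (f.interval.chrom, f.interval.start, f.id),
    )
    if not hairpins:
        raise ValueError("reference contains no pre_miRNA features")
    predictions = predictions if predictions is not None else FeatureSet()

    labels = {
        pre.id: classify_hairpin(pre, reference, g2_window=g2_window, stranded=stranded)
        for pre in hairpins
    }
    best, pred_members, pred_flags = _match_predictions(hairpins, predictions, stranded=stranded)

    # group hairpins by the interval source their rule selects
    host_groups: dict[str, list[GeneFeature]] = {}
    host_tie_flags: dict[str, list[str]] = {}
    pred_groups: dict[str, list[GeneFeature]] = {}
    singletons: list[GeneFeature] = []
    for pre in hairpins:
        if labels[pre.id] is GroupLabel.G3A:
            host, tie = _largest_overlap_host(pre, reference, stranded=stranded)
            host_groups.setdefault(host.id, []).append(pre)
            if tie:
                host_tie_flags.setdefault(host.id, []).append(
                    f"host_gene_overlap_tie:{pre.id}"
                )
        elif pre.id in best:
            pred_groups.setdefault(best[pre.id], []).append(pre)
        else:
            singletons.append(pre)

    models: list[PriMiRNAModel] = []

    def _model_id(member_feats: list[GeneFeature]) -> str:
        return "pri-" + "-".join(f.id for f in member_feats)

    for host_id in sorted(host_groups):
        feats = sorted(host_groups[host_id], key=lambda f: (f.interval.start, f.id))
        chunks = [feats[i : i + 2] for i in range(0, len(feats), 2)]
        shared_flag = (
            [f"host_gene_shared_by_{len(feats)}_hairpins:{host_id}"] if len(feats) > 2 else []
        )
        for chunk in chunks:
            models.append(
                PriMiRNAModel(
                    id=_model_id(chunk),
                    interval=reference.get(host_id).interval,
                    group=GroupLabel.G3A,
                    source_rule=SourceRule.HOST_GENE,
                    members=[f.id for f in chunk],
                    conflict_flags=list(host_tie_flags.get(host_id, [])) + shared_flag,
                )
            )

    for pid in sorted(pred_groups):
        feats = sorted(pred_groups[pid], key=lambda f: (f.interval.start, f.id))
        interval = predictions.get(pid).interval
        flags = list(pred_flags.get(pid, []))
        for f in feats:
            if not interval.contains(f.interval):
                interval = interval.span_with(f.interval)
                flags.append(f"prediction_partial_overlap:{f.id}")
        group = classify_model(interval, feats, reference, g2_window=g2_window, stranded=stranded)
        models.append(
            PriMiRNAModel(
                id=_model_id(feats),
                interval=interval,
                group=group,
                source_rule=SourceRule.PREDICTED_TRANSCRIPT,
                members=[f.id for f in feats],
                conflict_flags=flags,
            )
        )

    for pre in singletons:
        models.append(
            assign_model(pre, labels[pre.id], None, reference,
                         g2_window=g2_window, stranded=stranded)
        )

    models.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.id))

    # flag overlapping final models from different interval sources
    model_fs = FeatureSet()
    for m in models:
        model_fs.add(GeneFeature(m.id, m.interval, Biotype.PRI_MIRNA))
    for m in models:
        for other in model_fs.overlapping(m.interval):
            if other.id != m.id:
                m.conflict_flags.append(f"overlaps_model:{other.id}")

    # bookkeeping
    hairpin_counts = Counter(labels.values())
    predicted = Counter(m.group for m in models if m.source_rule is SourceRule.PREDICTED_TRANSCRIPT)
    referenced = Counter(m.group for m in models if m.source_rule is not SourceRule.PREDICTED_TRANSCRIPT)
    two_hairpin = Counter(m.group for m in models if len(m.members) == 2)
    report = ClassificationReport(
        hairpins={g: hairpin_counts.get(g, 0) for g in GROUP_ORDER},
        predicted_models={g: predicted.get(g, 0) for g in GROUP_ORDER},
        reference_models={g: referenced.get(g, 0) for g in GROUP_ORDER},
        two_hairpin_models={g: two_hairpin.get(g, 0) for g in GROUP_ORDER},
    )
    report.validate()

    merged = FeatureSet()
    for f in reference:
        if f.biotype is not Biotype.PRE_MIRNA:
            merged.add(GeneFeature(f.id, f.interval, f.biotype, dict(f.attributes)))
    for m in models:
        attrs = {
            "group": m.group.value,
            "source_rule": m.source_rule.value,
            "members": ",".join(m.members),
        }
        if m.conflict_flags:
            attrs["conflicts"] = ",".join(m.conflict_flags)
        merged.add(GeneFeature(m.id, m.interval, Biotype.PRI_MIRNA, attrs))

    return BuildResult(models=models, report=report, merged=merged, hairpin_labels=labels)
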