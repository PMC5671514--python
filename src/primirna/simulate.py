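"""Synthetic annotations, counts and alignments with known ground truth.

The generator lays out a single linear chromosome as a sequence of
independent "cassettes", one per pri-miRNA model plus background genes,
separated by gaps larger than the G2 proximity window so every truth
label is unambiguous by construction:

* G1 cassettes hold an isolated hairpin (optionally two, spanned by one
  predicted transcript);
* G2 cassettes pair a protein-coding gene with a hairpin 1-400 bp away;
* G3A cassettes embed the hairpin(s) inside a protein-coding gene;
* G3B cassettes keep the hairpin >400 bp from a coding gene but extend
  its predicted transcript into that gene;
* G4 cassettes overlap the hairpin with a non-coding gene.

Defaults reproduce the study conditions: 325 hairpins forming 318
models (194/26/54/37/7 across G1/G2/G3A/G3B/G4, seven of them with two
hairpins), 77 of which carry transcript predictions (28/7/0/37/5);
four libraries (two wild type, two mutant) at the experiment's
quantified read totals; NB counts at BCV 0.4 with group-specific
up-regulation in the mutant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import GroupLabel, SourceRule
from .counting import CountMatrix
from .features import Biotype, FeatureSet, GeneFeature
from .intervals import GenomicInterval


def _default_hairpins() -> dict[GroupLabel, int]:
    return {
        GroupLabel.G1: 196,
        GroupLabel.G2: 26,
        GroupLabel.G3A: 57,
        GroupLabel.G3B: 38,
        GroupLabel.G4: 8,
    }


def _default_two_hairpin() -> dict[GroupLabel, int]:
    return {
        GroupLabel.G1: 2,
        GroupLabel.G2: 0,
        GroupLabel.G3A: 3,
        GroupLabel.G3B: 1,
        GroupLabel.G4: 1,
    }


def _default_pred_prob() -> dict[GroupLabel, float]:
    # fractions of models carrying an assembled-transcript prediction
    return {
        GroupLabel.G1: 28 / 194,
        GroupLabel.G2: 7 / 26,
        GroupLabel.G3A: 0.0,
        GroupLabel.G3B: 1.0,
        GroupLabel.G4: 5 / 7,
    }


def _default_library_sizes() -> dict[str, int]:
    return {"wt_1": 18_894_161, "wt_2": 19_362_653, "mut_1": 18_580_516, "mut_2": 20_882_004}


def _default_conditions() -> dict[str, str]:
    return {"wt_1": "wt", "wt_2": "wt", "mut_1": "mutant", "mut_2": "mutant"}


def _default_group_lfc() -> dict[GroupLabel, float]:
    # pri-miRNAs accumulate in processing mutants; host-gene (G3A) models
    # are diluted by the protein-coding transcript
    return {
        GroupLabel.G1: 2.0,
        GroupLabel.G2: 2.0,
        GroupLabel.G3A: 0.5,
        GroupLabel.G3B: 2.0,
        GroupLabel.G4: 2.0,
    }


@dataclass
class SimulationConfig:
    """All tunables of the generator; defaults emulate the study."""

    chrom: str = "chr1"
    chrom_length: int = 12_000_000
    hairpins_per_group: dict[GroupLabel, int] = field(default_factory=_default_hairpins)
    two_hairpin_models: dict[GroupLabel, int] = field(default_factory=_default_two_hairpin)
    prediction_probability: dict[GroupLabel, float] = field(default_factory=_default_pred_prob)
    background_coding_genes: int = 1000
    background_noncoding_genes: int = 50
    hairpin_length: tuple[int, int] = (90, 160)
    gene_length: tuple[int, int] = (800, 3000)
    ncrna_length: tuple[int, int] = (300, 1200)
    prediction_extension: tuple[int, int] = (50, 300)
    cassette_gap: tuple[int, int] = (800, 1600)
    g2_window: int = 400
    adversarial: bool = False
    # count model
    library_sizes: dict[str, int] = field(default_factory=_default_library_sizes)
    conditions: dict[str, str] = field(default_factory=_default_conditions)
    bcv: float = 0.4
    group_log2fc: dict[GroupLabel, float] = field(default_factory=_default_group_lfc)
    background_log2fc_sd: float = 0.25
    baseline_log2cpm_mean: float = 3.0
    baseline_log2cpm_sd: float = 2.0

    def n_models(self, group: GroupLabel) -> int:
        return self.hairpins_per_group.get(group, 0) - self.two_hairpin_models.get(group, 0)

    def n_predicted(self, group: GroupLabel) -> int:
        return int(round(self.prediction_probability.get(group, 0.0) * self.n_models(group)))

    def validate(self) -> None:
        for g, n in self.hairpins_per_group.items():
            if n < 0:
                raise ValueError(f"{g.value}: hairpin count must be >= 0")
            two = self.two_hairpin_models.get(g, 0)
            if two < 0 or two > self.n_models(g):
                raise ValueError(f"{g.value}: invalid two-hairpin model count {two}")
        for g, p in self.prediction_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{g.value}: prediction probability {p} outside [0, 1]")
        if self.n_models(GroupLabel.G3B) > 0 and self.n_predicted(GroupLabel.G3B) < self.n_models(GroupLabel.G3B):
            raise ValueError(
                "G3B models require a prediction for every model "
                "(a model cannot extend over a coding gene without one)"
            )
        for g in (GroupLabel.G1, GroupLabel.G4):
            if self.two_hairpin_models.get(g, 0) > self.n_predicted(g):
                raise ValueError(
                    f"{g.value}: two-hairpin models need a shared prediction"
                )
        if self.bcv < 0:
            raise ValueError("bcv must be >= 0")
        if any(n <= 0 for n in self.library_sizes.values()):
            raise ValueError("library sizes must be > 0")
        if set(self.conditions) != set(self.library_sizes):
            raise ValueError("conditions and library_sizes must name the same samples")
        if set(self.conditions.values()) != {"wt", "mutant"}:
            raise ValueError("conditions must use the labels 'wt' and 'mutant'")


@dataclass(slots=True)
class TrueModel:
    members: tuple[str, ...]
    group: GroupLabel
    source_rule: SourceRule

    @property
    def model_id(self) -> str:
        return "pri-" + "-".join(self.members)


@dataclass
class GroundTruth:
    """What the generator placed, for closed-loop checks."""

    hairpin_groups: dict[str, GroupLabel]
    models: list[TrueModel]

    def model_groups(self) -> dict[str, GroupLabel]:
        return {m.model_id: m.group for m in self.models}


@dataclass
class SimulatedAnnotation:
    reference: FeatureSet
    predictions: FeatureSet
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Cassette construction (local 1-based coordinates; may extend left of 1 and
# are shifted on layout)


@dataclass(slots=True)
class _Cassette:
    # (id, start, end, biotype) in local coordinates
    features: list[tuple[str, int, int, Biotype]]
    prediction: tuple[str, int, int] | None
    hairpin_labels: dict[str, GroupLabel]
    model: TrueModel | None


class _IdMaker:
    def __init__(self) -> None:
        self.counters: dict[str, int] = {}

    def __call__(self, prefix: str) -> str:
        self.counters[prefix] = self.counters.get(prefix, 0) + 1
        return f"{prefix}{self.counters[prefix]:05d}"


def _rint(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _build_cassettes(cfg: SimulationConfig, rng: np.random.Generator, ids: _IdMaker) -> list[_Cassette]:
    cassettes: list[_Cassette] = []

    def hairpin(start: int) -> tuple[str, int, int]:
        fid = ids("MIR")
        length = _rint(rng, cfg.hairpin_length)
        return fid, start, start + length - 1

    ext = cfg.prediction_extension

    def plan(group: GroupLabel) -> list[tuple[bool, bool]]:
        """Per model: (two_hairpins, predicted)."""
        n = cfg.n_models(group)
        two = cfg.two_hairpin_models.get(group, 0)
        pred = cfg.n_predicted(group)
        out = []
        for i in range(n):
            is_two = i < two
            # two-hairpin G1/G4 models must be among the predicted ones
            is_pred = i < pred if group is not GroupLabel.G3A else False
            out.append((is_two, is_pred))
        return out

    # --- G1: isolated hairpins -------------------------------------------
    for is_two, is_pred in plan(GroupLabel.G1):
        h1 = hairpin(1)
        feats = [(h1[0], h1[1], h1[2], Biotype.PRE_MIRNA)]
        members = [h1[0]]
        right = h1[2]
        if is_two:
            h2 = hairpin(right + _rint(rng, (100, 300)) + 1)
            feats.append((h2[0], h2[1], h2[2], Biotype.PRE_MIRNA))
            members.append(h2[0])
            right = h2[2]
        pred = None
        if is_pred:
            pred = (ids("PRED"), 1 - _rint(rng, ext), right + _rint(rng, ext))
        elif cfg.adversarial:
            # boundary case: a coding gene exactly 401 bp away keeps G1
            glen = _rint(rng, cfg.gene_length)
            gid = ids("GENE")
            feats.append((gid, right + cfg.g2_window + 2, right + cfg.g2_window + 1 + glen,
                          Biotype.PROTEIN_CODING))
        cassettes.append(
            _Cassette(
                feats,
                pred,
                {m: GroupLabel.G1 for m in members},
                TrueModel(tuple(members), GroupLabel.G1,
                          SourceRule.PREDICTED_TRANSCRIPT if is_pred else SourceRule.HAIRPIN_FALLBACK),
            )
        )

    # --- G2: coding gene 1-400 bp away ------------------------------------
    for _is_two, is_pred in plan(GroupLabel.G2):
        glen = _rint(rng, cfg.gene_length)
        gid = ids("GENE")
        gap = cfg.g2_window if cfg.adversarial else _rint(rng, (1, cfg.g2_window))
        h = hairpin(glen + gap + 1)
        feats = [
            (gid, 1, glen, Biotype.PROTEIN_CODING),
            (h[0], h[1], h[2], Biotype.PRE_MIRNA),
        ]
        # prediction extends away from the gene so the model stays in G2
        pred = (ids("PRED"), h[1], h[2] + _rint(rng, ext)) if is_pred else None
        cassettes.append(
            _Cassette(
                feats,
                pred,
                {h[0]: GroupLabel.G2},
                TrueModel((h[0],), GroupLabel.G2,
                          SourceRule.PREDICTED_TRANSCRIPT if is_pred else SourceRule.HAIRPIN_FALLBACK),
            )
        )

    # --- G3A: hairpin(s) inside a coding gene ------------------------------
    for is_two, _is_pred in plan(GroupLabel.G3A):
        h1 = hairpin(51)
        members = [h1[0]]
        feats = [(h1[0], h1[1], h1[2], Biotype.PRE_MIRNA)]
        right = h1[2]
        if is_two:
            h2 = hairpin(right + _rint(rng, (50, 200)) + 1)
            feats.append((h2[0], h2[1], h2[2], Biotype.PRE_MIRNA))
            members.append(h2[0])
            right = h2[2]
        glen = max(_rint(rng, cfg.gene_length), right + 50)
        gid = ids("GENE")
        feats.insert(0, (gid, 1, glen, Biotype.PROTEIN_CODING))
        cassettes.append(
            _Cassette(
                feats,
                None,
                {m: GroupLabel.G3A for m in members},
                TrueModel(tuple(members), GroupLabel.G3A, SourceRule.HOST_GENE),
            )
        )

    # --- G3B: prediction reaches a coding gene the hairpin does not --------
    for is_two, _is_pred in plan(GroupLabel.G3B):
        h1 = hairpin(1)
        members = [h1[0]]
        feats = [(h1[0], h1[1], h1[2], Biotype.PRE_MIRNA)]
        right = h1[2]
        if is_two:
            h2 = hairpin(right + _rint(rng, (100, 300)) + 1)
            feats.append((h2[0], h2[1], h2[2], Biotype.PRE_MIRNA))
            members.append(h2[0])
            right = h2[2]
        gene_gap = _rint(rng, (cfg.g2_window + 50, cfg.g2_window + 400))
        glen = _rint(rng, cfg.gene_length)
        gid = ids("GENE")
        gstart = right + gene_gap + 1
        feats.append((gid, gstart, gstart + glen - 1, Biotype.PROTEIN_CODING))
        overlap_into_gene = _rint(rng, (50, min(200, glen)))
        pred = (ids("PRED"), h1[1], gstart + overlap_into_gene - 1)
        cassettes.append(
            _Cassette(
                feats,
                pred,
                {m: GroupLabel.G1 for m in members},  # hairpin pass sees intergenic
                TrueModel(tuple(members), GroupLabel.G3B, SourceRule.PREDICTED_TRANSCRIPT),
            )
        )

    # --- G4: overlapping a non-coding gene ---------------------------------
    for is_two, is_pred in plan(GroupLabel.G4):
        h1 = hairpin(21)
        members = [h1[0]]
        feats = [(h1[0], h1[1], h1[2], Biotype.PRE_MIRNA)]
        right = h1[2]
        if is_two:
            h2 = hairpin(right + _rint(rng, (50, 150)) + 1)
            feats.append((h2[0], h2[1], h2[2], Biotype.PRE_MIRNA))
            members.append(h2[0])
            right = h2[2]
        nlen = max(_rint(rng, cfg.ncrna_length), right + 20)
        nid = ids("NC")
        feats.insert(0, (nid, 1, nlen, Biotype.NON_CODING))
        pred = (ids("PRED"), 1 - _rint(rng, ext), right + _rint(rng, ext)) if is_pred else None
        cassettes.append(
            _Cassette(
                feats,
                pred,
                {m: GroupLabel.G4 for m in members},
                TrueModel(tuple(members), GroupLabel.G4,
                          SourceRule.PREDICTED_TRANSCRIPT if is_pred else SourceRule.HAIRPIN_FALLBACK),
            )
        )

    # --- background genes ---------------------------------------------------
    for _ in range(cfg.background_coding_genes):
        glen = _rint(rng, cfg.gene_length)
        cassettes.append(_Cassette([(ids("GENE"), 1, glen, Biotype.PROTEIN_CODING)], None, {}, None))
    for _ in range(cfg.background_noncoding_genes):
        nlen = _rint(rng, cfg.ncrna_length)
        cassettes.append(_Cassette([(ids("NC"), 1, nlen, Biotype.NON_CODING)], None, {}, None))

    return cassettes


def _brute_force_label(
    interval: GenomicInterval,
    hairpin_ivs: list[GenomicInterval],
    coding: list[GenomicInterval],
    noncoding: list[GenomicInterval],
    g2_window: int,
    *,
    model_level: bool,
) -> GroupLabel:
    """Independent exhaustive-scan classification used to validate the
    generator's labels at generation time."""
    from .intervals import gap_bp, overlap_bp

    if model_level:
        for h in hairpin_ivs:
            if any(overlap_bp(h, g) > 0 for g in coding):
                return GroupLabel.G3A
        if any(overlap_bp(interval, g) > 0 for g in coding):
            return GroupLabel.G3B
    else:
        if any(overlap_bp(interval, g) > 0 for g in coding):
            return GroupLabel.G3A
    if any(overlap_bp(interval, g) > 0 for g in noncoding):
        return GroupLabel.G4
    gaps = [gap_bp(interval, g) for g in coding]
    gaps = [g for g in gaps if g is not None]
    if gaps and 1 <= min(gaps) <= g2_window:
        return GroupLabel.G2
    return GroupLabel.G1


def simulate_annotation(config: SimulationConfig, seed: int = 1) -> SimulatedAnnotation:
    """Place all cassettes on the chromosome and return reference
    annotation, transcript predictions and ground truth.

    The truth labels are re-derived by an exhaustive pairwise scan after
    placement; a mismatch (an infeasible or internally inconsistent
    layout) raises rather than returning silently wrong truth.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ids = _IdMaker()
    cassettes = _build_cassettes(config, rng, ids)
    order = rng.permutation(len(cassettes))

    reference = FeatureSet()
    predictions = FeatureSet()
    hairpin_groups: dict[str, GroupLabel] = {}
    models: list[TrueModel] = []

    cursor = 1
    for idx in order:
        cas = cassettes[idx]
        coords = [s for _, s, _, _ in cas.features] + [e for _, _, e, _ in cas.features]
        if cas.prediction is not None:
            coords += [cas.prediction[1], cas.prediction[2]]
        shift = cursor - min(coords)
        for fid, s, e, bt in cas.features:
            reference.add(
                GeneFeature(fid, GenomicInterval(config.chrom, s + shift, e + shift, "+"), bt)
            )
        if cas.prediction is not None:
            pid, ps, pe = cas.prediction
            predictions.add(
                GeneFeature(
                    pid,
                    GenomicInterval(config.chrom, ps + shift, pe + shift, "+"),
                    Biotype.TRANSCRIPT_MODEL,
                    {"transcript_id": pid, "gene_id": pid,
                     "exons": f"{ps + shift}-{pe + shift}"},
                )
            )
        hairpin_groups.update(cas.hairpin_labels)
        if cas.model is not None:
            models.append(cas.model)
        cursor = max(coords) + shift + _rint(rng, config.cassette_gap) + 1
        if cursor > config.chrom_length:
            raise ValueError(
                f"infeasible config: cassettes need > {cursor} bp, "
                f"chromosome is {config.chrom_length} bp"
            )

    truth = GroundTruth(hairpin_groups=hairpin_groups, models=models)
    _validate_truth(reference, predictions, truth, config)
    return SimulatedAnnotation(reference, predictions, truth, config)


def _validate_truth(
    reference: FeatureSet,
    predictions: FeatureSet,
    truth: GroundTruth,
    config: SimulationConfig,
) -> None:
    coding = [f.interval for f in reference.by_biotype(Biotype.PROTEIN_CODING)]
    noncoding = [f.interval for f in reference.by_biotype(Biotype.NON_CODING)]
    for hid, expected in truth.hairpin_groups.items():
        iv = reference.get(hid).interval
        got = _brute_force_label(iv, [iv], coding, noncoding, config.g2_window, model_level=False)
        if got is not expected:
            raise AssertionError(f"generator placed {hid} as {expected.value} but scan says {got.value}")


def write_simulated_annotation(sim: SimulatedAnnotation, out_dir: str | Path) -> dict[str, Path]:
    """Write ref.gff3, pred.gtf and truth.tsv; returns the paths."""
    from .annotation_io import write_gff3, write_gtf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "ref.gff3",
        "predictions": out / "pred.gtf",
        "truth": out / "truth.tsv",
    }
    write_gff3(sim.reference, paths["reference"])
    write_gtf(sim.predictions, paths["predictions"])
    rows = [
        {
            "model_id": m.model_id,
            "members": ",".join(m.members),
            "group": m.group.value,
            "source_rule": m.source_rule.value,
        }
        for m in sim.truth.models
    ]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Count simulation


def simulate_count_matrix(
    baseline_cpm: np.ndarray,
    log2fc: np.ndarray,
    feature_ids: Sequence[str],
    *,
    library_sizes: Mapping[str, int],
    conditions: Mapping[str, str],
    bcv: float,
    seed: int,
) -> CountMatrix:
    """NB counts with mean ``cpm * 2**(lfc * is_mutant) * libsize / 1e6``
    and variance ``mu + bcv**2 * mu**2`` (Poisson at bcv = 0)."""
    rng = np.random.default_rng(seed)
    samples = list(library_sizes)
    mut = np.array([conditions[s] == "mutant" for s in samples], dtype=float)
    libs = np.array([library_sizes[s] for s in samples], dtype=float)
    mu = (
        baseline_cpm[:, None]
        * 2.0 ** (log2fc[:, None] * mut[None, :])
        * libs[None, :]
        / 1e6
    )
    if bcv == 0:
        counts = rng.poisson(mu)
    else:
        phi = bcv**2
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts = rng.poisson(lam)
    frame = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"), columns=samples)
    return CountMatrix.from_frame(frame)


def simulate_counts(
    sim: SimulatedAnnotation,
    seed: int = 1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Counts for the final annotation implied by the ground truth:
    one row per pri-miRNA model (group-specific log2FC) and per
    background gene (log2FC ~ N(0, sd)). Returns the matrix and a truth
    frame (feature_id, kind, group, baseline_cpm, true_log2fc)."""
    cfg = sim.config
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for m in sim.truth.models:
        rows.append({"feature_id": m.model_id, "kind": "pri_miRNA", "group": m.group.value,
                     "true_log2fc": cfg.group_log2fc.get(m.group, 0.0)})
    for f in sorted(sim.reference, key=lambda f: f.id):
        if f.biotype is Biotype.PRE_MIRNA:
            continue
        rows.append({
            "feature_id": f.id,
            "kind": f.biotype.value,
            "group": "",
            "true_log2fc": float(rng.normal(0.0, cfg.background_log2fc_sd)),
        })
    truth = pd.DataFrame(rows).set_index("feature_id")
    truth["baseline_cpm"] = 2.0 ** rng.normal(
        cfg.baseline_log2cpm_mean, cfg.baseline_log2cpm_sd, len(truth)
    )
    matrix = simulate_count_matrix(
        truth["baseline_cpm"].to_numpy(),
        truth["true_log2fc"].to_numpy(),
        list(truth.index),
        library_sizes=cfg.library_sizes,
        conditions=cfg.conditions,
        bcv=cfg.bcv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Alignment simulation


def simulate_alignments(
    features: FeatureSet,
    read_counts: Mapping[str, int],
    path: str | Path,
    *,
    read_length: int = 50,
    seed: int = 1,
    chrom_lengths: Mapping[str, int] | None = None,
    mapq: int = 50,
) -> Path:
    """Write a SAM file with ``read_counts[fid]`` single-end primary
    reads placed uniformly inside each feature. Byte-deterministic for a
    given seed. Raises when a feature is shorter than the read length."""
    rng = np.random.default_rng(seed)
    path = Path(path)
    if chrom_lengths is None:
        chrom_lengths = {}
        for f in features:
            iv = f.interval
            chrom_lengths[iv.chrom] = max(chrom_lengths.get(iv.chrom, 0), iv.end + 1000)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    seq = "A" * read_length
    qual = "I" * read_length
    for fid in sorted(read_counts):
        n = read_counts[fid]
        if n == 0:
            continue
        f = features.get(fid)
        iv = f.interval
        if iv.length < read_length:
            raise ValueError(
                f"feature {fid} (length {iv.length}) is shorter than the read length {read_length}"
            )
        starts = rng.integers(iv.start, iv.end - read_length + 2, size=n)
        for i, s in enumerate(starts):
            lines.append(
                "\t".join(
                    [
                        f"{fid}:{i}",
                        "0",
                        iv.chrom,
                        str(int(s)),
                        str(mapq),
                        f"{read_length}M",
                        "*",
                        "0",
                        "0",
                        seq,
                        qual,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")
    return path
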