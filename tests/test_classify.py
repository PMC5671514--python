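"""Two-pass positional classification and the annotation builder."""

import numpy as np
import pytest

from primirna.classify import (
    ClassificationReport,
    GroupLabel,
    SourceRule,
    assign_model,
    build_annotation,
    classify_hairpin,
    classify_model,
    summarize_report,
)
from primirna.features import Biotype, FeatureSet
from primirna.intervals import GenomicInterval
from primirna.simulate import SimulationConfig, simulate_annotation

from conftest import feat, oracle_classify


def _genes(*features):
    return FeatureSet(features)


class TestHairpinPass:
    def test_hairpin_inside_coding_gene_is_g3a(self):
        genes = _genes(feat("g", 1000, 5000, Biotype.PROTEIN_CODING))
        pre = feat("h", 2000, 2100, Biotype.PRE_MIRNA)
        assert classify_hairpin(pre, genes) is GroupLabel.G3A

    @pytest.mark.parametrize("gap, expected", [(1, GroupLabel.G2), (400, GroupLabel.G2),
                                               (401, GroupLabel.G1)])
    def test_g2_window_boundary(self, gap, expected):
        genes = _genes(feat("g", 1, 1000, Biotype.PROTEIN_CODING))
        pre = feat("h", 1001 + gap, 1100 + gap, Biotype.PRE_MIRNA)
        assert classify_hairpin(pre, genes) is expected

    def test_lone_hairpin_is_g1(self):
        pre = feat("h", 100, 200, Biotype.PRE_MIRNA)
        assert classify_hairpin(pre, FeatureSet()) is GroupLabel.G1

    def test_coding_overlap_beats_noncoding(self):
        genes = _genes(
            feat("g", 1000, 2000, Biotype.PROTEIN_CODING),
            feat("n", 1500, 2500, Biotype.NON_CODING),
        )
        pre = feat("h", 1900, 2100, Biotype.PRE_MIRNA)
        assert classify_hairpin(pre, genes) is GroupLabel.G3A

    def test_noncoding_overlap_beats_proximity(self):
        genes = _genes(
            feat("g", 1, 1000, Biotype.PROTEIN_CODING),
            feat("n", 1150, 1600, Biotype.NON_CODING),
        )
        pre = feat("h", 1201, 1300, Biotype.PRE_MIRNA)  # 200 bp from gene, inside ncRNA
        assert classify_hairpin(pre, genes) is GroupLabel.G4


class TestModelPass:
    def test_prediction_into_coding_gene_is_g3b(self):
        genes = _genes(feat("g", 5000, 8000, Biotype.PROTEIN_CODING))
        pre = feat("h", 3000, 3100, Biotype.PRE_MIRNA)
        model_iv = GenomicInterval("c1", 3000, 5200)
        assert classify_model(model_iv, [pre], genes) is GroupLabel.G3B

    def test_model_equal_to_isolated_hairpin_is_g1(self):
        pre = feat("h", 3000, 3100, Biotype.PRE_MIRNA)
        assert classify_model(pre.interval, [pre], FeatureSet()) is GroupLabel.G1

    def test_model_over_noncoding_gene_is_g4(self):
        genes = _genes(feat("n", 4000, 4400, Biotype.NON_CODING))
        pre = feat("h", 3000, 3100, Biotype.PRE_MIRNA)
        assert classify_model(GenomicInterval("c1", 3000, 4100), [pre], genes) is GroupLabel.G4

    def test_member_overlap_dominates_model_overlap(self):
        genes = _genes(feat("g", 3050, 8000, Biotype.PROTEIN_CODING))
        pre = feat("h", 3000, 3100, Biotype.PRE_MIRNA)
        assert classify_model(GenomicInterval("c1", 2500, 9000), [pre], genes) is GroupLabel.G3A


class TestAssignModel:
    def test_g3a_adopts_host_gene_interval(self):
        genes = _genes(feat("gX", 1000, 5000, Biotype.PROTEIN_CODING))
        pre = feat("h", 2000, 2100, Biotype.PRE_MIRNA)
        m = assign_model(pre, GroupLabel.G3A, None, genes)
        assert (m.interval.start, m.interval.end) == (1000, 5000)
        assert m.source_rule is SourceRule.HOST_GENE and m.group is GroupLabel.G3A

    def test_g3a_two_hosts_takes_largest_overlap(self):
        genes = _genes(
            feat("small", 1990, 2010, Biotype.PROTEIN_CODING),
            feat("big", 1500, 2600, Biotype.PROTEIN_CODING),
        )
        pre = feat("h", 2000, 2100, Biotype.PRE_MIRNA)
        m = assign_model(pre, GroupLabel.G3A, None, genes)
        assert (m.interval.start, m.interval.end) == (1500, 2600)

    def test_host_tie_is_flagged(self):
        genes = _genes(
            feat("a", 1950, 2049, Biotype.PROTEIN_CODING),
            feat("b", 2051, 2150, Biotype.PROTEIN_CODING),
        )
        pre = feat("h", 2000, 2100, Biotype.PRE_MIRNA)  # 50 bp overlap with each
        m = assign_model(pre, GroupLabel.G3A, None, genes)
        assert any("tie" in f for f in m.conflict_flags)

    def test_fallback_keeps_hairpin_coordinates(self):
        pre = feat("h", 1200, 1350, Biotype.PRE_MIRNA)
        m = assign_model(pre, GroupLabel.G1, None, FeatureSet())
        assert m.interval == pre.interval and m.source_rule is SourceRule.HAIRPIN_FALLBACK

    def test_prediction_interval_used_and_contains_hairpin(self):
        pre = feat("h", 1200, 1350, Biotype.PRE_MIRNA)
        pred = feat("p", 900, 2400, Biotype.TRANSCRIPT_MODEL)
        m = assign_model(pre, GroupLabel.G1, pred, FeatureSet())
        assert (m.interval.start, m.interval.end) == (900, 2400)
        assert m.source_rule is SourceRule.PREDICTED_TRANSCRIPT
        assert m.interval.contains(pre.interval)


class TestBuildAnnotation:
    def test_ten_hairpin_fixture_counts(self, ten_hairpin_annotation):
        ref, preds = ten_hairpin_annotation
        build = build_annotation(ref, preds)
        by_group = {g: 0 for g in GroupLabel}
        for m in build.models:
            by_group[m.group] += 1
        assert by_group == {
            GroupLabel.G1: 4,
            GroupLabel.G2: 2,
            GroupLabel.G3A: 2,
            GroupLabel.G3B: 1,
            GroupLabel.G4: 1,
        }
        assert len(build.models) == 10
        table = summarize_report(build.report)
        assert table.loc["Total", "n_final_models"] == 10
        assert table.loc["Total", "n_predicted_models"] == 1

    def test_prediction_spanning_two_hairpins_merges(self):
        ref = FeatureSet(
            [
                feat("h1", 1000, 1100, Biotype.PRE_MIRNA),
                feat("h2", 1400, 1500, Biotype.PRE_MIRNA),
            ]
        )
        preds = FeatureSet([feat("p", 900, 1600, Biotype.TRANSCRIPT_MODEL)])
        build = build_annotation(ref, preds)
        assert len(build.models) == 1
        (m,) = build.models
        assert m.members == ["h1", "h2"]
        assert build.report.two_hairpin_models[GroupLabel.G1] == 1

    def test_shared_host_gene_merges_g3a_hairpins(self):
        ref = FeatureSet(
            [
                feat("g", 1000, 9000, Biotype.PROTEIN_CODING),
                feat("h1", 2000, 2100, Biotype.PRE_MIRNA),
                feat("h2", 6000, 6100, Biotype.PRE_MIRNA),
            ]
        )
        build = build_annotation(ref, FeatureSet())
        assert len(build.models) == 1
        assert build.models[0].members == ["h1", "h2"]
        assert build.models[0].source_rule is SourceRule.HOST_GENE

    def test_no_predictions_all_reference_derived(self, ten_hairpin_annotation):
        ref, _ = ten_hairpin_annotation
        build = build_annotation(ref, FeatureSet())
        assert all(
            m.source_rule in (SourceRule.HAIRPIN_FALLBACK, SourceRule.HOST_GENE)
            for m in build.models
        )
        assert build.report.total(build.report.predicted_models) == 0

    def test_every_hairpin_in_exactly_one_model(self, ten_hairpin_annotation):
        ref, preds = ten_hairpin_annotation
        build = build_annotation(ref, preds)
        members = [h for m in build.models for h in m.members]
        hairpins = {f.id for f in ref.by_biotype(Biotype.PRE_MIRNA)}
        assert sorted(members) == sorted(hairpins)

    def test_merged_set_contains_models_and_genes_but_no_hairpins(self, ten_hairpin_annotation):
        ref, preds = ten_hairpin_annotation
        build = build_annotation(ref, preds)
        assert not build.merged.by_biotype(Biotype.PRE_MIRNA)
        assert len(build.merged.by_biotype(Biotype.PRI_MIRNA)) == 10
        model = build.merged.get(build.models[0].id)
        assert set(model.attributes) >= {"group", "source_rule", "members"}

    def test_empty_hairpin_set_is_error(self):
        ref = FeatureSet([feat("g", 1, 100, Biotype.PROTEIN_CODING)])
        with pytest.raises(ValueError):
            build_annotation(ref, FeatureSet())

    def test_prediction_claimed_by_three_hairpins_keeps_two(self):
        ref = FeatureSet(
            [
                feat("h1", 1000, 1099, Biotype.PRE_MIRNA),
                feat("h2", 1200, 1299, Biotype.PRE_MIRNA),
                feat("h3", 1400, 1449, Biotype.PRE_MIRNA),  # smallest overlap
            ]
        )
        preds = FeatureSet([feat("p", 950, 1500, Biotype.TRANSCRIPT_MODEL)])
        build = build_annotation(ref, preds)
        pred_models = [m for m in build.models if m.source_rule is SourceRule.PREDICTED_TRANSCRIPT]
        assert len(pred_models) == 1
        assert pred_models[0].members == ["h1", "h2"]
        assert any("claimed_by_3" in f for f in pred_models[0].conflict_flags)
        fallback = [m for m in build.models if m.source_rule is SourceRule.HAIRPIN_FALLBACK]
        assert [m.members for m in fallback] == [["h3"]]

    def test_overlapping_models_from_different_sources_flagged(self):
        # h1 adopts the host gene's interval; h2's prediction extends into
        # the same gene, so the two final models overlap and both get flagged
        ref = FeatureSet(
            [
                feat("g", 1000, 5000, Biotype.PROTEIN_CODING),
                feat("h1", 2000, 2100, Biotype.PRE_MIRNA),
                feat("h2", 5600, 5700, Biotype.PRE_MIRNA),
            ]
        )
        preds = FeatureSet([feat("p", 4900, 5750, Biotype.TRANSCRIPT_MODEL)])
        build = build_annotation(ref, preds)
        assert len(build.models) == 2
        assert {m.group for m in build.models} == {GroupLabel.G3A, GroupLabel.G3B}
        assert all(any("overlaps_model" in f for f in m.conflict_flags) for m in build.models)


class TestReportIdentities:
    def test_validate_rejects_inconsistent_totals(self):
        report = ClassificationReport(
            hairpins={GroupLabel.G1: 3},
            predicted_models={GroupLabel.G1: 1},
            reference_models={GroupLabel.G1: 1},
            two_hairpin_models={GroupLabel.G1: 0},
        )
        with pytest.raises(ValueError):
            summarize_report(report)

    def test_single_hairpin_no_genes_total_row(self):
        report = ClassificationReport(
            hairpins={GroupLabel.G1: 1},
            predicted_models={},
            reference_models={GroupLabel.G1: 1},
            two_hairpin_models={},
        )
        table = summarize_report(report)
        total = table.loc["Total"]
        assert list(
            total[["n_hairpins", "n_predicted_models", "n_reference_models",
                   "n_two_hairpin_models", "n_final_models"]]
        ) == [1, 0, 1, 0, 1]


def _random_annotation(rng: np.random.Generator, n_hairpins: int, n_genes: int, n_nc: int):
    """A fully random (unconstrained, possibly ambiguous) annotation."""
    fs = FeatureSet()
    span = 200_000
    for i in range(n_genes):
        s = int(rng.integers(1, span))
        fs.add(feat(f"g{i}", s, s + int(rng.integers(200, 3000)), Biotype.PROTEIN_CODING))
    for i in range(n_nc):
        s = int(rng.integers(1, span))
        fs.add(feat(f"n{i}", s, s + int(rng.integers(100, 1000)), Biotype.NON_CODING))
    hairpins = []
    for i in range(n_hairpins):
        s = int(rng.integers(1, span))
        h = feat(f"h{i}", s, s + int(rng.integers(80, 200)), Biotype.PRE_MIRNA)
        fs.add(h)
        hairpins.append(h)
    return fs, hairpins


def test_classifier_equals_brute_force_oracle_on_random_annotations():
    """Index-backed two-pass classification agrees with an exhaustive
    pairwise scan on random annotations, including ambiguous layouts."""
    rng = np.random.default_rng(123)
    for trial in range(20):
        fs, hairpins = _random_annotation(
            rng,
            n_hairpins=int(rng.integers(5, 60)),
            n_genes=int(rng.integers(5, 120)),
            n_nc=int(rng.integers(0, 30)),
        )
        coding = [f.interval for f in fs.by_biotype(Biotype.PROTEIN_CODING)]
        noncoding = [f.interval for f in fs.by_biotype(Biotype.NON_CODING)]
        for h in hairpins:
            assert classify_hairpin(h, fs) is oracle_classify(h.interval, [h.interval],
                                                              coding, noncoding)
            widened = GenomicInterval(
                h.interval.chrom, max(1, h.interval.start - 300), h.interval.end + 300
            )
            assert classify_model(widened, [h], fs) is oracle_classify(
                widened, [h.interval], coding, noncoding, model_level=True
            )


def test_generator_truth_recovered_on_spaced_configs():
    """With the generator's enforced spacing the builder reproduces the
    ground-truth labels exactly."""
    cfg = SimulationConfig(
        hairpins_per_group={g: 5 for g in GroupLabel},
        two_hairpin_models={g: 0 for g in GroupLabel},
        prediction_probability={
            GroupLabel.G1: 0.5,
            GroupLabel.G2: 0.5,
            GroupLabel.G3A: 0.0,
            GroupLabel.G3B: 1.0,
            GroupLabel.G4: 0.5,
        },
        background_coding_genes=20,
        background_noncoding_genes=5,
    )
    sim = simulate_annotation(cfg, seed=1)
    build = build_annotation(sim.reference, sim.predictions)
    got = {m.id: m.group for m in build.models}
    assert got == sim.truth.model_groups()
    counts = {g: sum(1 for v in got.values() if v is g) for g in GroupLabel}
    assert counts == {g: 5 for g in GroupLabel}
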