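"""Synthetic-data generator: closed loops, determinism and moments."""

import numpy as np
import pytest

from primirna.classify import GroupLabel, build_annotation
from primirna.counting import count_reads
from primirna.features import Biotype, FeatureSet
from primirna.simulate import (
    SimulationConfig,
    simulate_alignments,
    simulate_annotation,
    simulate_count_matrix,
    simulate_counts,
    write_simulated_annotation,
)

from conftest import feat


def small_config(**overrides) -> SimulationConfig:
    base = dict(
        hairpins_per_group={g: 5 for g in GroupLabel},
        two_hairpin_models={g: 0 for g in GroupLabel},
        prediction_probability={
            GroupLabel.G1: 0.4,
            GroupLabel.G2: 0.4,
            GroupLabel.G3A: 0.0,
            GroupLabel.G3B: 1.0,
            GroupLabel.G4: 0.4,
        },
        background_coding_genes=15,
        background_noncoding_genes=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestAnnotationGenerator:
    def test_five_per_group_recovered(self):
        sim = simulate_annotation(small_config(), seed=1)
        assert len(sim.truth.hairpin_groups) == 25
        build = build_annotation(sim.reference, sim.predictions)
        got = {m.id: m.group for m in build.models}
        assert got == sim.truth.model_groups()
        per_group = {g: sum(1 for v in got.values() if v is g) for g in GroupLabel}
        assert per_group == {g: 5 for g in GroupLabel}

    def test_zero_detection_probability_forbids_g3b(self):
        cfg = small_config(
            prediction_probability={g: 0.0 for g in GroupLabel},
        )
        with pytest.raises(ValueError, match="G3B"):
            simulate_annotation(cfg, seed=1)

    def test_zero_detection_without_g3b_gives_empty_predictions(self):
        cfg = small_config(
            hairpins_per_group={
                GroupLabel.G1: 5, GroupLabel.G2: 5, GroupLabel.G3A: 5,
                GroupLabel.G3B: 0, GroupLabel.G4: 5,
            },
            prediction_probability={g: 0.0 for g in GroupLabel},
        )
        sim = simulate_annotation(cfg, seed=1)
        assert len(sim.predictions) == 0

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            write_simulated_annotation(simulate_annotation(cfg, seed=9), tmp_path / sub)
        for name in ("ref.gff3", "pred.gtf", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_changes_layout(self, tmp_path):
        cfg = small_config()
        a = simulate_annotation(cfg, seed=1)
        b = simulate_annotation(cfg, seed=2)
        sa = {(f.id, f.interval.start) for f in a.reference}
        sb = {(f.id, f.interval.start) for f in b.reference}
        assert sa != sb

    def test_infeasible_chromosome_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_annotation(small_config(chrom_length=10_000), seed=1)

    def test_closed_loop_over_many_random_configs(self):
        """Label recovery holds across 10 random feasible configs."""
        rng = np.random.default_rng(77)
        for trial in range(10):
            counts = {g: int(rng.integers(0, 8)) for g in GroupLabel}
            if all(v == 0 for v in counts.values()):
                counts[GroupLabel.G1] = 1
            cfg = small_config(
                hairpins_per_group=counts,
                background_coding_genes=int(rng.integers(5, 40)),
            )
            sim = simulate_annotation(cfg, seed=int(rng.integers(0, 2**31 - 1)))
            if not sim.truth.models:
                continue
            build = build_annotation(sim.reference, sim.predictions)
            assert {m.id: m.group for m in build.models} == sim.truth.model_groups()

    def test_adversarial_boundaries_still_recovered(self):
        sim = simulate_annotation(small_config(adversarial=True), seed=5)
        build = build_annotation(sim.reference, sim.predictions)
        assert {m.id: m.group for m in build.models} == sim.truth.model_groups()


class TestCountGenerator:
    def test_poisson_mean_recovery(self):
        """bcv = 0, large means: sample means match expectations within 1%."""
        n = 10_000
        cpm = np.full(n, 500.0)
        libs = {"s1": 2_000_000, "s2": 2_000_000}
        cond = {"s1": "wt", "s2": "mutant"}
        cm = simulate_count_matrix(cpm, np.zeros(n), [f"g{i}" for i in range(n)],
                                   library_sizes=libs, conditions=cond, bcv=0.0, seed=3)
        mu = 500.0 * 2.0
        assert abs(cm.counts["s1"].mean() / mu - 1) < 0.01
        assert abs(cm.counts["s2"].mean() / mu - 1) < 0.01

    def test_variance_mean_relation_at_bcv_04(self):
        """Regression of (var - mean) on mean^2 recovers the dispersion."""
        rng = np.random.default_rng(21)
        n = 10_000
        cpm = 2.0 ** rng.uniform(2, 9, n)
        libs = {f"s{i}": 2_000_000 for i in range(8)}
        cond = {f"s{i}": "wt" for i in range(4)} | {f"s{i}": "mutant" for i in range(4, 8)}
        cm = simulate_count_matrix(cpm, np.zeros(n), [f"g{i}" for i in range(n)],
                                   library_sizes=libs, conditions=cond, bcv=0.4, seed=22)
        x = cm.counts.to_numpy(float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        keep = m > 20
        slope = np.sum((v - m)[keep] * m[keep] ** 2) / np.sum(m[keep] ** 4)
        assert 0.13 <= slope <= 0.19  # true dispersion 0.16

    def test_group_effects_enter_mutant_means(self):
        sim = simulate_annotation(small_config(), seed=2)
        cm, truth = simulate_counts(sim, seed=3)
        assert set(cm.counts.index) == set(truth.index)
        pri = truth[truth["kind"] == "pri_miRNA"]
        assert len(pri) == len(sim.truth.models)
        assert (pri.loc[pri["group"] != "G3A", "true_log2fc"] == 2.0).all()

    def test_counts_reproducible_by_seed(self):
        sim = simulate_annotation(small_config(), seed=2)
        a, _ = simulate_counts(sim, seed=5)
        b, _ = simulate_counts(sim, seed=5)
        assert (a.counts == b.counts).all().all()


class TestAlignmentGenerator:
    def test_requested_read_numbers_recovered(self, tmp_path):
        fs = FeatureSet(
            [
                feat("A", 1_000, 2_000, Biotype.PRI_MIRNA),
                feat("B", 5_000, 6_500, Biotype.PRI_MIRNA),
                feat("C", 9_000, 9_400, Biotype.PRI_MIRNA),
            ]
        )
        requested = {"A": 12, "B": 40, "C": 7}
        p = simulate_alignments(fs, requested, tmp_path / "r.sam", read_length=50, seed=4)
        counts, stats = count_reads(p, fs)
        assert dict(counts) == requested
        assert stats.ambiguous == 0 and stats.no_overlap == 0

    def test_straddling_read_goes_to_larger_overlap(self, tmp_path):
        # abutting features; a read placed across the boundary with 30/10 split
        fs = FeatureSet(
            [
                feat("L", 1_000, 1_999, Biotype.PRI_MIRNA),
                feat("R", 2_000, 3_000, Biotype.PRI_MIRNA),
            ]
        )
        p = tmp_path / "s.sam"
        p.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:10000\n"
            "rd\t0\tc1\t1970\t50\t40M\t*\t0\t0\t*\t*\n"  # 30 bases in L, 10 in R
        )
        counts, _ = count_reads(p, fs)
        assert counts["L"] == 1 and counts["R"] == 0

    def test_same_seed_identical_sam_bytes(self, tmp_path):
        fs = FeatureSet([feat("A", 100, 700, Biotype.PRI_MIRNA)])
        p1 = simulate_alignments(fs, {"A": 20}, tmp_path / "a.sam", seed=6)
        p2 = simulate_alignments(fs, {"A": 20}, tmp_path / "b.sam", seed=6)
        assert p1.read_bytes() == p2.read_bytes()

    def test_feature_shorter_than_read_is_error(self, tmp_path):
        fs = FeatureSet([feat("tiny", 100, 120, Biotype.PRI_MIRNA)])
        with pytest.raises(ValueError, match="tiny"):
            simulate_alignments(fs, {"tiny": 3}, tmp_path / "t.sam", read_length=50, seed=1)
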