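"""End-to-end orchestration: annotate -> count -> de -> groups/crosstab.

A plain YAML config drives the run; every stage can be toggled and fed
either by the previous stage or by an explicit input path. All outputs
are plain text (GFF3/TSV/JSON/markdown) under one output directory, and
a manifest records every parameter that can alter an output, so a rerun
with the same config and seed reproduces identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .annotation_io import ARAPORT_LIKE_TYPES, read_gff3, read_gtf_transcripts, write_gff3
from .classify import GroupLabel, build_annotation, summarize_report
from .counting import CountMatrix, count_reads, merge_columns
from .de import DispersionModel, estimate_common_dispersion, exact_nb_test, shrink_tagwise, tmm_factors, write_de_tsv, read_de_tsv
from .features import Biotype
from .groups import cross_tabulate, detection_filter, group_shift_tests, group_tests_frame
from .simulate import SimulationConfig, simulate_annotation, simulate_counts, write_simulated_annotation


class PipelineValidationError(ValueError):
    """Raised before any work when the config is inconsistent."""


class StageError(RuntimeError):
    """A stage failed while executing; the message names the stage."""


_STAGES = ("simulate", "annotate", "count", "de", "groups", "crosstab", "report")

_DEFAULT_PARAMS: dict[str, Any] = {
    "g2_window": 400,
    "min_mapq": 10,
    "min_reads": 4,
    "bcv": 0.4,
    "fdr": 0.05,
    "de_mode": "fixed-bcv",  # or "tagwise"
    "tmm": True,
    "strand_aware": False,
    "background": "protein_coding",
}


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: Path = Path("primirna_out")
    stages: dict[str, bool] = field(default_factory=lambda: {s: False for s in _STAGES})
    params: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"seed", "out_dir", "stages", "params", "inputs", "simulate"}
        if unknown:
            raise PipelineValidationError(f"unknown config sections: {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 1)),
            out_dir=Path(raw.get("out_dir", "primirna_out")),
            stages={s: bool(raw.get("stages", {}).get(s, False)) for s in _STAGES},
            params={**_DEFAULT_PARAMS, **(raw.get("params") or {})},
            inputs=raw.get("inputs") or {},
            simulate=raw.get("simulate") or {},
        )
        return cfg

    def param(self, key: str) -> Any:
        return self.params.get(key, _DEFAULT_PARAMS[key])


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise PipelineValidationError(message)


def validate_config(cfg: PipelineConfig) -> None:
    """Check stage dependencies and input existence before any work."""
    on = cfg.stages
    unknown_params = set(cfg.params) - set(_DEFAULT_PARAMS)
    _require(not unknown_params, f"unknown params: {sorted(unknown_params)}")
    if on.get("annotate") and not on.get("simulate"):
        for key in ("reference", "predictions"):
            _require(key in cfg.inputs, f"annotate enabled but inputs.{key} missing")
            _require(Path(cfg.inputs[key]).exists(), f"inputs.{key} does not exist: {cfg.inputs[key]}")
    if on.get("count"):
        _require(
            bool(cfg.inputs.get("alignments")),
            "count enabled but inputs.alignments (sample -> SAM/BAM) missing",
        )
        for name, p in cfg.inputs["alignments"].items():
            _require(Path(p).exists(), f"alignment for sample {name!r} does not exist: {p}")
        _require(on.get("annotate") or "annotation" in cfg.inputs,
                 "count needs the annotate stage or inputs.annotation")
    if on.get("de"):
        _require(
            on.get("count") or on.get("simulate") or "counts" in cfg.inputs,
            "de enabled but no counts source (count stage, simulate stage or inputs.counts)",
        )
        if "counts" in cfg.inputs:
            _require(Path(cfg.inputs["counts"]).exists(),
                     f"inputs.counts does not exist: {cfg.inputs['counts']}")
        _require(
            on.get("simulate") or "conditions" in cfg.inputs,
            "de needs inputs.conditions (sample -> wt|mutant) unless simulate provides them",
        )
    if on.get("groups"):
        _require(on.get("de"), "groups needs the de stage")
        _require(on.get("annotate") or on.get("simulate") or "annotation" in cfg.inputs,
                 "groups needs a merged annotation source")
    if on.get("crosstab"):
        _require(on.get("de") or "de_a" in cfg.inputs, "crosstab needs experiment A DE results")
        for key in ("de_b", "counts_b"):
            _require(key in cfg.inputs, f"crosstab enabled but inputs.{key} missing")
            _require(Path(cfg.inputs[key]).exists(), f"inputs.{key} does not exist: {cfg.inputs[key]}")


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    sim_kwargs = dict(cfg.simulate)
    for key in ("hairpins_per_group", "two_hairpin_models", "prediction_probability", "group_log2fc"):
        if key in sim_kwargs:
            sim_kwargs[key] = {GroupLabel(k): v for k, v in sim_kwargs[key].items()}
    sc = SimulationConfig(**sim_kwargs)
    sc.g2_window = cfg.param("g2_window")
    return sc


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order; returns (and
    writes) the manifest."""
    validate_config(cfg)
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    on = cfg.stages

    merged_fs = None
    counts: CountMatrix | None = None
    conditions: dict[str, str] | None = cfg.inputs.get("conditions")
    de_table: pd.DataFrame | None = None

    sim = None
    if on.get("simulate"):
        try:
            sim_cfg = _simulation_config(cfg)
            sim = simulate_annotation(sim_cfg, seed=cfg.seed)
            paths = write_simulated_annotation(sim, out)
            outputs.update({k: str(p) for k, p in paths.items()})
            sim_counts, sim_truth = simulate_counts(sim, seed=cfg.seed + 1)
            sim_counts.to_tsv(out / "counts.tsv")
            sim_truth.to_csv(out / "counts_truth.tsv", sep="\t", float_format="%.6g")
            outputs["counts"] = str(out / "counts.tsv")
            outputs["counts_truth"] = str(out / "counts_truth.tsv")
            counts = sim_counts
            conditions = conditions or sim_cfg.conditions
        except (ValueError, AssertionError) as exc:
            raise StageError(f"simulate: {exc}") from exc

    if on.get("annotate"):
        try:
            if sim is not None:
                reference, predictions = sim.reference, sim.predictions
            else:
                reference = read_gff3(cfg.inputs["reference"], ARAPORT_LIKE_TYPES)
                predictions = read_gtf_transcripts(cfg.inputs["predictions"])
            build = build_annotation(
                reference,
                predictions,
                g2_window=cfg.param("g2_window"),
                stranded=cfg.param("strand_aware"),
            )
            merged_fs = build.merged
            write_gff3(merged_fs, out / "merged.gff3")
            summarize_report(build.report).to_csv(out / "report.tsv", sep="\t")
            conflicts = [
                {"model_id": m.id, "flags": ";".join(m.conflict_flags)}
                for m in build.models
                if m.conflict_flags
            ]
            pd.DataFrame(conflicts, columns=["model_id", "flags"]).to_csv(
                out / "conflicts.tsv", sep="\t", index=False
            )
            outputs["merged_annotation"] = str(out / "merged.gff3")
            outputs["group_report"] = str(out / "report.tsv")
            outputs["conflicts"] = str(out / "conflicts.tsv")
        except (ValueError, OSError) as exc:
            raise StageError(f"annotate: {exc}") from exc

    if on.get("count"):
        try:
            if merged_fs is None:
                merged_fs = read_gff3(cfg.inputs["annotation"], ARAPORT_LIKE_TYPES)
            columns = {}
            for name in sorted(cfg.inputs["alignments"]):
                col, _stats = count_reads(
                    cfg.inputs["alignments"][name],
                    merged_fs,
                    min_mapq=cfg.param("min_mapq"),
                )
                columns[name] = col
            counts = merge_columns(columns)
            counts.to_tsv(out / "counts.tsv")
            outputs["counts"] = str(out / "counts.tsv")
        except (ValueError, OSError) as exc:
            raise StageError(f"count: {exc}") from exc

    if on.get("de"):
        try:
            if counts is None:
                counts = CountMatrix.read_tsv(cfg.inputs["counts"])
            assert conditions is not None
            samples = counts.sample_ids
            labels = [conditions[s] for s in samples]
            factors = tmm_factors(counts) if cfg.param("tmm") else None
            if cfg.param("de_mode") == "tagwise":
                common = estimate_common_dispersion(counts, labels, norm_factors=factors)
                disp = shrink_tagwise(counts, labels, common, norm_factors=factors)
            else:
                disp = DispersionModel.fixed_bcv(len(counts.feature_ids), cfg.param("bcv")).dispersions
            de_table = exact_nb_test(
                counts, labels, disp, norm_factors=factors, pair=("wt", "mutant")
            )
            write_de_tsv(de_table, out / "de.tsv")
            outputs["de"] = str(out / "de.tsv")
        except (KeyError, ValueError, AssertionError) as exc:
            raise StageError(f"de: {exc}") from exc

    model_groups: dict[str, GroupLabel] | None = None
    if on.get("groups") or on.get("crosstab"):
        src = merged_fs
        if src is None and "annotation" in cfg.inputs:
            src = read_gff3(cfg.inputs["annotation"], ARAPORT_LIKE_TYPES)
        if src is not None:
            model_groups = {
                f.id: GroupLabel(f.attributes["group"])
                for f in src.by_biotype(Biotype.PRI_MIRNA)
            }
        elif sim is not None:
            model_groups = sim.truth.model_groups()

    if on.get("groups"):
        try:
            assert de_table is not None and model_groups is not None
            if cfg.param("background") == "protein_coding" and (merged_fs or sim):
                fs = merged_fs if merged_fs is not None else None
                if fs is not None:
                    background = [f.id for f in fs.by_biotype(Biotype.PROTEIN_CODING)]
                else:
                    background = [
                        f.id for f in sim.reference.by_biotype(Biotype.PROTEIN_CODING)
                    ]
            else:
                background = [f for f in de_table.index if f not in model_groups]
            results, notes = group_shift_tests(de_table, model_groups, background)
            frame = group_tests_frame(results)
            frame.to_csv(out / "group_tests.tsv", sep="\t", float_format="%.6g")
            (out / "group_tests_notes.txt").write_text("".join(n + "\n" for n in notes))
            outputs["group_tests"] = str(out / "group_tests.tsv")
        except (ValueError, AssertionError) as exc:
            raise StageError(f"groups: {exc}") from exc

    if on.get("crosstab"):
        try:
            de_a = de_table if de_table is not None else read_de_tsv(cfg.inputs["de_a"])
            de_b = read_de_tsv(cfg.inputs["de_b"])
            counts_b = CountMatrix.read_tsv(cfg.inputs["counts_b"])
            assert counts is not None and model_groups is not None
            pri_ids = set(model_groups)
            det_a = detection_filter(counts, pri_ids, min_total=cfg.param("min_reads"))
            det_b = detection_filter(counts_b, pri_ids, min_total=cfg.param("min_reads"))
            common = det_a & det_b
            t_all = cross_tabulate(de_a, de_b, common, label_a="expA", label_b="expB")
            t_fdr = cross_tabulate(
                de_a, de_b, common, fdr_filter_a=cfg.param("fdr"),
                label_a="expA", label_b="expB",
            )
            with open(out / "crosstab.tsv", "w") as fh:
                fh.write(f"# common detected pri-miRNAs (no FDR filter): {t_all.n_common}\n")
                t_all.to_frame().to_csv(fh, sep="\t")
                fh.write(f"# common pri-miRNAs with FDR < {cfg.param('fdr')} in experiment A: {t_fdr.n_common}\n")
                t_fdr.to_frame().to_csv(fh, sep="\t")
            outputs["crosstab"] = str(out / "crosstab.tsv")
        except (ValueError, AssertionError, OSError) as exc:
            raise StageError(f"crosstab: {exc}") from exc

    manifest = {
        "package": "primirna",
        "version": __version__,
        "seed": cfg.seed,
        "stages": {s: bool(on.get(s)) for s in _STAGES},
        "params": {k: cfg.params.get(k, v) for k, v in sorted(_DEFAULT_PARAMS.items())},
        "simulate": {str(k): v for k, v in sorted(cfg.simulate.items())},
        "inputs": {k: str(v) for k, v in sorted(cfg.inputs.items())} if cfg.inputs else {},
        "outputs": dict(sorted(outputs.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    if on.get("report"):
        try:
            report = render_report(out / "manifest.json")
            (out / "report.md").write_text(report)
            outputs["report"] = str(out / "report.md")
            manifest["outputs"] = dict(sorted(outputs.items()))
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
                fh.write("\n")
        except (ValueError, OSError, KeyError) as exc:
            raise StageError(f"report: {exc}") from exc

    return manifest


def render_report(manifest_path: str | Path) -> str:
    """Render the run's tables as markdown; regenerating from the same
    manifest yields byte-identical output."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    outputs = manifest["outputs"]
    lines = ["# pri-miRNA annotation run", ""]
    lines += [f"- package: primirna {manifest['version']}", f"- seed: {manifest['seed']}", ""]

    if "group_report" in outputs:
        path = Path(outputs["group_report"])
        if not path.exists():
            raise FileNotFoundError(f"report artifact missing: {path}")
        table = pd.read_csv(path, sep="\t", index_col=0)
        lines.append("## Positional groups of pri-miRNA gene models")
        lines.append("")
        lines.append("```")
        lines.append(table.to_string())
        lines.append("```")
        total = table.loc["Total"]
        lines.append("")
        lines.append(
            f"Bookkeeping: {total['n_final_models']} final models = "
            f"{total['n_predicted_models']} prediction-derived + "
            f"{total['n_reference_models']} reference-derived; "
            f"{total['n_hairpins']} hairpins = {total['n_final_models']} models + "
            f"{total['n_two_hairpin_models']} extra hairpins in two-hairpin models."
        )
        lines.append("")

    if "de" in outputs:
        path = Path(outputs["de"])
        if not path.exists():
            raise FileNotFoundError(f"report artifact missing: {path}")
        de = pd.read_csv(path, sep="\t", index_col=0)
        fdr = manifest["params"]["fdr"]
        sig = de[de["fdr"] < fdr]
        lines.append("## Differential expression (mutant vs wild type)")
        lines.append("")
        lines.append(
            f"{len(de)} features tested; at FDR < {fdr}: "
            f"{int((sig['log2FC'] > 0).sum())} up-regulated, "
            f"{int((sig['log2FC'] < 0).sum())} down-regulated."
        )
        lines.append("")

    if "group_tests" in outputs:
        path = Path(outputs["group_tests"])
        if not path.exists():
            raise FileNotFoundError(f"report artifact missing: {path}")
        gt = pd.read_csv(path, sep="\t", index_col=0)
        lines.append("## Group shift tests (one-sided rank-sum, group above background)")
        lines.append("")
        lines.append("```")
        lines.append(gt.to_string())
        lines.append("```")
        lines.append("")

    if "crosstab" in outputs:
        path = Path(outputs["crosstab"])
        if not path.exists():
            raise FileNotFoundError(f"report artifact missing: {path}")
        lines.append("## Cross-experiment direction of change")
        lines.append("")
        lines.append("```")
        lines.append(path.read_text().rstrip("\n"))
        lines.append("```")
        lines.append("")

    return "\n".join(lines) + "\n"
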