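"""End-to-end screening pipeline: load → fold changes → selections and Venn
overlaps → ortholog pairing and pattern classification → gene-set summaries
→ figures, with a machine-readable run manifest.

Stage order is fixed; any stage error aborts naming the stage. All tabular
outputs are deterministic (no timestamps inside data files); the manifest
carries input/output checksums so a rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import pandas as pd
import yaml

from . import crossspecies, foldchange, io, viz
from .crossspecies import ClassificationParams
from .datamodel import CANONICAL_COMPARISONS, FormatError, ValidationError
from .foldchange import SelectionParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    expression_a: str
    samples_a: str
    expression_b: str
    samples_b: str
    ortholog_map: str
    output_dir: str
    gene_sets: str | None = None
    thresholds: tuple = (1.5, 3.0)
    t_similar: float = 0.2
    t_different: float = 0.4
    t_min: float = 0.2
    top_n: int = 20
    one_to_one: bool = False
    highlight: tuple = ()
    seed: int = 0
    log_level: str = "INFO"

    def classification_params(self) -> ClassificationParams:
        return ClassificationParams(self.t_similar, self.t_different, self.t_min)


_CONFIG_KEYS = {f.name for f in RunConfig.__dataclass_fields__.values()}
_REQUIRED_KEYS = {
    "expression_a", "samples_a", "expression_b", "samples_b", "ortholog_map", "output_dir",
}


def validate_config(path) -> RunConfig:
    """Parse a YAML (or JSON) config file into a RunConfig or raise with all violations.

    The schema is strict: unknown keys are violations, missing required keys
    are violations, and numeric fields are range-checked. Defaults: fold-change
    thresholds 1.5 and 3; pattern thresholds 0.2 / 0.4 / 0.2; top-N 20.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")

    violations: list[str] = []
    for key in sorted(set(raw) - _CONFIG_KEYS):
        violations.append(f"unknown key {key!r}")
    for key in sorted(_REQUIRED_KEYS - set(raw)):
        violations.append(f"missing required key {key!r}")

    checked = {k: v for k, v in raw.items() if k in _CONFIG_KEYS}
    if "thresholds" in checked:
        try:
            checked["thresholds"] = tuple(float(t) for t in checked["thresholds"])
            if any(t <= 0 for t in checked["thresholds"]):
                violations.append("thresholds must be positive")
        except (TypeError, ValueError):
            violations.append("thresholds must be a list of numbers")
    for key in ("t_similar", "t_different", "t_min"):
        if key in checked and (not isinstance(checked[key], (int, float)) or checked[key] < 0):
            violations.append(f"{key} must be a non-negative number")
    if "top_n" in checked and (not isinstance(checked["top_n"], int) or checked["top_n"] < 1):
        violations.append("top_n must be a positive integer")
    if "highlight" in checked:
        checked["highlight"] = tuple(str(g) for g in checked["highlight"])

    if violations:
        raise ValidationError(f"{path}: invalid config: " + "; ".join(violations))
    config = RunConfig(**checked)
    try:
        config.classification_params()
    except ValidationError as exc:
        raise ValidationError(f"{path}: invalid config: {exc}") from exc
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage name."""
    class _Guard:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Guard()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screening pipeline and return the run manifest.

    Writes fold-change tables, threshold selections, Venn counts, the paired
    and labeled ortholog table, gene-set summaries, the coverage report, all
    figures with their sidecar TSVs, and ``manifest.json``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "package_version": _pkg_version("crossexpr"),
        "inputs": {},
        "counts": {},
        "outputs": {},
    }

    with _stage("load"):
        for key in ("expression_a", "samples_a", "expression_b", "samples_b", "ortholog_map"):
            p = Path(getattr(config, key))
            if not p.is_file():
                raise FileNotFoundError(f"{key}: {p} not found")
            manifest["inputs"][key] = _sha256(p)
        ds_a = io.load_expression(config.expression_a, config.samples_a)
        ds_b = io.load_expression(config.expression_b, config.samples_b)
        omap = io.load_ortholog_map(config.ortholog_map)
        if config.one_to_one:
            omap = omap.one_to_one()
        gene_sets = None
        if config.gene_sets:
            p = Path(config.gene_sets)
            if not p.is_file():
                raise FileNotFoundError(f"gene_sets: {p} not found")
            manifest["inputs"]["gene_sets"] = _sha256(p)
            gene_sets = io.load_gene_sets(config.gene_sets)
        manifest["counts"]["genes_a"] = ds_a.n_genes
        manifest["counts"]["genes_b"] = ds_b.n_genes
        manifest["counts"]["ortholog_pairs"] = len(omap)

    with _stage("fold_changes"):
        fc_a = foldchange.compute_fold_changes(ds_a)
        fc_b = foldchange.compute_fold_changes(ds_b)
        io.write_table(fc_a.to_frame(), out_dir / f"fold_changes_{ds_a.species_label}.tsv")
        io.write_table(fc_b.to_frame(), out_dir / f"fold_changes_{ds_b.species_label}.tsv")

    with _stage("selection"):
        selections: dict = {}
        for fc in (fc_a, fc_b):
            for threshold in config.thresholds:
                params = SelectionParams(threshold=threshold)
                lists = {}
                for comp in CANONICAL_COMPARISONS:
                    sel = foldchange.select_genes(fc, comp, params)
                    lists[comp.name] = list(sel["gene_id"])
                    tag = f"{fc.species_label}_{comp.name}_fc{threshold:g}"
                    io.write_table(sel, out_dir / f"selection_{tag}.tsv")
                    manifest["counts"][f"selected_{tag}"] = len(sel)
                selections[(fc.species_label, threshold)] = lists

    with _stage("venn"):
        venn_frames = []
        for (species, threshold), lists in selections.items():
            counts = foldchange.venn_counts(lists)
            frame = counts.to_frame()
            frame.insert(0, "threshold", threshold)
            frame.insert(0, "species", species)
            venn_frames.append(frame)
            viz.build_venn_figure(counts, out_dir / f"venn_{species}_fc{threshold:g}.png")
        io.write_table(pd.concat(venn_frames, ignore_index=True), out_dir / "venn_counts.tsv")

    with _stage("pairing"):
        paired, coverage = crossspecies.pair_fold_changes(fc_a, fc_b, omap)
        labeled = crossspecies.classify_table(paired, config.classification_params())
        io.write_table(labeled, out_dir / "paired_fc.tsv")
        io.write_table(pd.DataFrame([coverage]), out_dir / "coverage_report.tsv")
        counts = crossspecies.label_counts(labeled)
        io.write_table(counts, out_dir / "label_counts.tsv")
        manifest["counts"]["paired_rows"] = len(labeled)
        for _, row in counts.iterrows():
            for label in crossspecies.LABELS:
                manifest["counts"][f"label_{row['comparison']}_{label}"] = int(row[label])

    with _stage("gene_sets"):
        if gene_sets is not None:
            summary = crossspecies.gene_set_summary(labeled, gene_sets, omap)
            io.write_table(summary, out_dir / "geneset_summary.tsv")
            manifest["counts"]["gene_sets"] = len(gene_sets)

    with _stage("figures"):
        for fc, ds in ((fc_a, ds_a), (fc_b, ds_b)):
            spec = viz.build_heatmap(fc, ds, n=config.top_n,
                                     out=out_dir / f"heatmap_{ds.species_label}.png")
            io.write_table(spec.to_frame(), out_dir / f"heatmap_{ds.species_label}.tsv")
            manifest["counts"][f"heatmap_rows_{ds.species_label}"] = len(spec.gene_order)
        if not labeled.empty:
            for comp in CANONICAL_COMPARISONS:
                spec = viz.build_scatter(
                    labeled, comp.name, highlight=list(config.highlight),
                    out=out_dir / f"scatter_{comp.name}.png",
                    species_labels=(ds_a.species_label, ds_b.species_label),
                )
                io.write_table(spec.points, out_dir / f"scatter_{comp.name}.tsv")

    with _stage("manifest"):
        for tsv in sorted(out_dir.glob("*.tsv")):
            manifest["outputs"][tsv.name] = _sha256(tsv)
        manifest["elapsed_seconds"] = round(time.time() - t0, 3)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return manifest
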