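"""End-to-end orchestration with run manifests and resumable stages.

The pipeline composes the library stages in dependency order:
simulate (optional) -> dnb -> trends -> dirac -> enrich -> cluster ->
classify. Every stage writes ordinary module outputs (TSV/JSON) into the
output directory; the manifest records the config snapshot, package
version, per-stage output hashes, seeds and wall-clock times. Re-running
with an identical config skips stages whose outputs already match the
manifest on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import select_k
from .dirac import dirac_table
from .dnb import CriteriaConfig, scan_stages
from .enrich import read_enrichment, scale_scores, sets_containing, ssgsea_scores
from .io import (
    StageDesign,
    read_annotations,
    read_expression_matrix,
    read_gmt,
    write_annotations,
    write_expression_matrix,
    write_gmt,
    write_report,
)
from .nsc import project_cohort, train_projection
from .synth import SimulationConfig, simulate_staged_expression
from .trends import fuzzy_cmeans, stage_profiles

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("metacrit.pipeline")

STAGE_ORDER = ("simulate", "dnb", "trends", "dirac", "enrich", "cluster", "classify")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGE_ORDER
    expression: Path | None = None
    annotations: Path | None = None
    gmt: Path | None = None
    reference_stage: str = "Normal"
    simulate: dict[str, Any] = field(default_factory=dict)
    dnb: dict[str, Any] = field(default_factory=dict)
    trends: dict[str, Any] = field(default_factory=dict)
    dirac: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    classify: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "PipelineConfig":
        def p(key: str) -> Path | None:
            v = raw.get(key)
            if v is None:
                return None
            v = Path(v)
            return v if v.is_absolute() else base / v

        cfg = cls(
            outdir=p("outdir") or base / "metacrit_out",
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", STAGE_ORDER)),
            expression=p("expression"),
            annotations=p("annotations"),
            gmt=p("gmt"),
            reference_stage=str(raw.get("reference_stage", "Normal")),
            simulate=dict(raw.get("simulate", {})),
            dnb=dict(raw.get("dnb", {})),
            trends=dict(raw.get("trends", {})),
            dirac=dict(raw.get("dirac", {})),
            enrich=dict(raw.get("enrich", {})),
            cluster=dict(raw.get("cluster", {})),
            classify=dict(raw.get("classify", {})),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems: list[str] = []
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        if "simulate" not in self.stages:
            if self.expression is None or not Path(self.expression).exists():
                problems.append(f"expression file missing: {self.expression}")
            if self.annotations is None or not Path(self.annotations).exists():
                problems.append(f"annotation file missing: {self.annotations}")
        needs_gmt = {"dirac", "enrich", "cluster", "classify"} & set(self.stages)
        if needs_gmt and "simulate" not in self.stages:
            if self.gmt is None or not Path(self.gmt).exists():
                problems.append(f"GMT file missing: {self.gmt}")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))

    def to_dict(self) -> dict[str, Any]:
        return {
            "outdir": str(self.outdir),
            "seed": self.seed,
            "stages": list(self.stages),
            "expression": None if self.expression is None else str(self.expression),
            "annotations": None if self.annotations is None else str(self.annotations),
            "gmt": None if self.gmt is None else str(self.gmt),
            "reference_stage": self.reference_stage,
            "simulate": self.simulate, "dnb": self.dnb, "trends": self.trends,
            "dirac": self.dirac, "enrich": self.enrich, "cluster": self.cluster,
            "classify": self.classify,
        }


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {"config": self.config, "version": self.version,
                "stages": self.stages}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunManifest":
        return cls(config=dict(d["config"]), version=d["version"],
                   stages=dict(d["stages"]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the requested stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous: dict[str, Any] = {}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config") == config.to_dict():
            previous = prev.get("stages", {})

    manifest = RunManifest(config=config.to_dict(), version=__version__)
    state: dict[str, Any] = {}

    def record(stage: str, outputs: list[Path], started: float) -> None:
        manifest.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.time() - started, 3),
            "seed": _stage_seed(config.seed, stage),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)

    def resumable(stage: str, outputs: list[Path]) -> bool:
        prior = previous.get(stage)
        if not prior:
            return False
        if set(prior["outputs"]) != {p.name for p in outputs}:
            return False
        try:
            ok = all(_sha256(p) == prior["outputs"][p.name] for p in outputs)
        except FileNotFoundError:
            return False
        if ok:
            manifest.stages[stage] = prior
        return ok

    # ---- inputs / simulate -------------------------------------------------
    expr_path = out / "expression.tsv"
    annot_path = out / "annotations.tsv"
    gmt_path = out / "pathways.gmt"
    if "simulate" in config.stages:
        started = time.time()
        sim_outputs = [expr_path, annot_path, gmt_path, out / "truth.json"]
        if not resumable("simulate", sim_outputs):
            seed = _stage_seed(config.seed, "simulate")
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", seed)
            sim = simulate_staged_expression(SimulationConfig(**sim_kwargs))
            write_expression_matrix(sim.expression, expr_path)
            write_annotations(sim.annotations, annot_path)
            from .synth import make_disjoint_pathways

            sets = sim.truth.pathway_sets or make_disjoint_pathways(
                n_sets=8, set_size=25
            )
            write_gmt(sets, gmt_path)
            write_report(
                {
                    "dnb_members": sim.truth.dnb_members,
                    "critical_stage": sim.truth.critical_stage,
                    "trend_assignments": sim.truth.trend_assignments,
                },
                out / "truth.json",
            )
            record("simulate", sim_outputs, started)
            log.info("simulate: wrote %s", expr_path)
        expr = sim_expr = read_expression_matrix(expr_path)
        annotations = read_annotations(annot_path)
        sets = read_gmt(gmt_path)
    else:
        expr = read_expression_matrix(config.expression)
        annotations = read_annotations(config.annotations)
        sets = read_gmt(config.gmt) if config.gmt else None

    design = StageDesign.from_annotations(annotations, config.reference_stage)
    state["expr"], state["design"] = expr, design

    # ---- dnb ---------------------------------------------------------------
    if "dnb" in config.stages:
        started = time.time()
        outputs = [out / "dnb_report.json"]
        if not resumable("dnb", outputs):
            opts = dict(config.dnb)
            criteria = CriteriaConfig(
                mode=opts.pop("criteria", "ratio"),
                seed=_stage_seed(config.seed, "dnb"),
            )
            report = scan_stages(
                expr, design, fold=float(opts.pop("fold", 2.0)),
                min_size=int(opts.pop("min_size", 5)), criteria=criteria,
            )
            write_report(report, outputs[0])
            record("dnb", outputs, started)
            log.info("dnb: selected stage %s (%d members)",
                     report.selected_stage, len(report.dnb_members))
        from .dnb import DNBReport
        from .io import read_report

        state["dnb"] = read_report(outputs[0], DNBReport)

    # ---- trends ------------------------------------------------------------
    if "trends" in config.stages:
        started = time.time()
        outputs = [out / "trends.json"]
        if not resumable("trends", outputs):
            opts = dict(config.trends)
            profiles = stage_profiles(expr, design)
            model = fuzzy_cmeans(
                profiles, c=int(opts.pop("c", 6)), m=float(opts.pop("m", 2.0)),
                seed=_stage_seed(config.seed, "trends"),
            )
            write_report(model, outputs[0])
            record("trends", outputs, started)

    # ---- dirac -------------------------------------------------------------
    if "dirac" in config.stages and sets is not None:
        started = time.time()
        outputs = [out / "rci.tsv"]
        if not resumable("dirac", outputs):
            opts = dict(config.dirac)
            group_col = annotations["group"]
            g_a = list(group_col[group_col == opts.pop("group_a", "tumor")].index)
            g_b = list(group_col[group_col == opts.pop("group_b", "normal")].index)
            table = dirac_table(
                expr, sets, g_a, g_b,
                n_perm=int(opts.pop("n_perm", 200)),
                seed=_stage_seed(config.seed, "dirac"),
            )
            table.to_csv(outputs[0], sep="\t")
            record("dirac", outputs, started)

    # ---- enrich ------------------------------------------------------------
    scores_path = out / "scores.tsv"
    if "enrich" in config.stages and sets is not None:
        started = time.time()
        outputs = [scores_path]
        if not resumable("enrich", outputs):
            opts = dict(config.enrich)
            used = sets
            if opts.pop("dnb_filter", False) and state.get("dnb") is not None:
                members = state["dnb"].dnb_members
                if members:
                    used = sets_containing(sets, members)
            raw = ssgsea_scores(expr, used, alpha=float(opts.pop("alpha", 0.25)))
            scaled = scale_scores(raw, mode=opts.pop("scale", "per_pathway"))
            write_report(scaled, scores_path)
            record("enrich", outputs, started)

    # ---- cluster -----------------------------------------------------------
    clusters_path = out / "clusters.json"
    if "cluster" in config.stages:
        started = time.time()
        outputs = [clusters_path]
        if not resumable("cluster", outputs):
            opts = dict(config.cluster)
            scores = read_enrichment(scores_path, scaled=True)
            tumor = annotations.index[annotations["group"] == "tumor"]
            tumor = [s for s in scores.sample_ids if s in set(tumor)]
            if len(tumor) >= 4:
                scores = scores.subset_samples(tumor)
            k_lo, k_hi = opts.pop("k_range", [2, 8])
            result = select_k(
                scores, range(int(k_lo), int(k_hi) + 1),
                seed=_stage_seed(config.seed, "cluster"),
                iters=int(opts.pop("iters", 200)),
                subsample=float(opts.pop("subsample", 0.8)),
            )
            write_report(result, clusters_path)
            record("cluster", outputs, started)

    # ---- classify (self-projection of the reference cohort) ----------------
    if "classify" in config.stages and sets is not None:
        started = time.time()
        outputs = [out / "nsc_model.json", out / "assignments.tsv"]
        if not resumable("classify", outputs):
            opts = dict(config.classify)
            with open(clusters_path) as fh:
                clusters = json.load(fh)["assignments"]
            labels = {s: f"C{c}" for s, c in clusters.items()}
            train = expr.subset(samples=list(labels))
            model, proj_cfg, _ = train_projection(
                train, sets, labels,
                alignment=opts.pop("alignment", "reference_standardize"),
                alpha=float(opts.pop("alpha", 0.25)),
                cv_folds=int(opts.pop("cv_folds", 5)),
                seed=_stage_seed(config.seed, "classify"),
            )
            write_report(
                {"model": model.to_dict(), "projection": proj_cfg.to_dict()},
                outputs[0],
            )
            predictions, _ = project_cohort(train, sets, model, proj_cfg)
            predictions.to_csv(outputs[1], sep="\t", index_label="sample_id")
            record("classify", outputs, started)

    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
    return manifest
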