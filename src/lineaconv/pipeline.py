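"""End-to-end orchestration of the analysis stages with seeded runs.

Stages run in dependency order — simulate (or load) → reporter
quantification → QC → origin classification → trajectory/patterns → graft
statistics — with per-stage seeds derived from one global seed, all
hand-offs through files under the output directory, and a JSON run report
of parameters and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
import sys
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .classifier import (
    classify_cells,
    select_anchor_cells,
    select_discriminative_genes,
)
from .qc import (
    MarkerFilterConfig,
    QCThresholds,
    apply_qc_filters,
    normalize_counts,
)
from .reporter import ReporterSequence, select_subtranscripts, quantify_reporter_umis
from .synthetic import (
    SimulationConfig,
    simulate_dataset,
    simulate_reporter_pair,
)
from .trajectory import (
    assign_branches,
    extract_patterns,
    find_degs,
    pac_stability,
    trisect_and_select_tc_genes,
)

__all__ = ["PipelineConfig", "StageResult", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "reporter", "qc", "classify", "trajectory")


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the global seed (< 2**31)."""
    h = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


@dataclass
class StageResult:
    stage: str
    status: str
    artifacts: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-friendly flat schema)."""

    outdir: str = "lineaconv_run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    simulation: dict = field(default_factory=dict)
    qc_thresholds: dict = field(default_factory=dict)
    n_anchor_target: int = 70
    n_rf_genes: int = 50
    alpha: float = 0.05
    deg_top_n: int = 1000
    k_patterns: int = 6
    pac_k_range: tuple[int, ...] = (2, 3, 4, 5)
    pac_subsamples: int = 50

    def validate(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"stages: unknown stage names {sorted(unknown)}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed: must be an integer")
        if self.n_anchor_target < 2:
            raise ValueError("n_anchor_target: must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha: must lie in (0, 1)")
        for name in ("n_rf_genes", "deg_top_n", "k_patterns", "pac_subsamples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name}: must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "pac_k_range" in raw:
            raw["pac_k_range"] = tuple(raw["pac_k_range"])
        return cls(**raw)


def _relativize(path: str, outdir: Path) -> str:
    try:
        return str(Path(path).relative_to(outdir))
    except ValueError:
        return path


def _log(msg: str) -> None:
    print(f"[lineaconv] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> list[StageResult]:
    """Run the enabled stages in dependency order; returns stage results and
    writes a machine-readable run report under the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: list[StageResult] = []
    state: dict = {}

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        seed = stage_seed(config.seed, stage)
        _log(f"stage {stage} (seed {seed})")
        try:
            res = _RUNNERS[stage](config, state, seed, outdir)
        except Exception as exc:  # halt downstream dependents
            results.append(StageResult(stage=stage, status=f"failed: {exc}"))
            _log(f"stage {stage} failed: {exc}; downstream stages skipped")
            break
        results.append(res)

    report = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "outdir"  # the report lives inside outdir already
        },
        "stages": [
            {
                "stage": r.stage,
                "status": r.status,
                "artifacts": {
                    k: _relativize(v, outdir) for k, v in r.artifacts.items()
                },
                "summary": r.summary,
            }
            for r in results
        ],
    }
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return results


def _run_simulate(config, state, seed, outdir) -> StageResult:
    sim_cfg = SimulationConfig(**{**config.simulation, "seed": seed})
    ds = simulate_dataset(sim_cfg)
    state["dataset"] = ds
    counts_dir = lio.write_count_dir(ds.adata, outdir / "counts")
    lio.write_assignments_tsv(outdir / "reporter_reads.tsv", ds.reporter_reads)
    red_seq, green_seq, _ = simulate_reporter_pair(seed=seed)
    lio.write_reporter_fasta(
        outdir / "reporters_synthetic.fa",
        ReporterSequence("red", red_seq),
        ReporterSequence("green", green_seq),
    )
    return StageResult(
        stage="simulate",
        status="ok",
        artifacts={"counts": str(counts_dir),
                   "reporter_reads": str(outdir / "reporter_reads.tsv")},
        summary={"n_cells": int(ds.adata.n_obs), "n_genes": int(ds.adata.n_vars),
                 "n_reporter_rows": int(len(ds.reporter_reads))},
    )


def _run_reporter(config, state, seed, outdir) -> StageResult:
    ds = state["dataset"]
    reporters = lio.read_reporter_fasta(outdir / "reporters_synthetic.fa")
    subs = select_subtranscripts(reporters["red"], reporters["green"])
    lio.write_subtranscripts_bed(outdir / "subtranscripts.tsv", subs)
    # quantification uses the simulated assignment table's own id space
    sub_map = {s: "red" for s in ds.config.red_subtranscripts}
    sub_map |= {s: "green" for s in ds.config.green_subtranscripts}
    rexpr = quantify_reporter_umis(ds.reporter_reads, sub_map)
    rexpr.to_csv(outdir / "reporter_expression.csv")
    state["reporter_expr"] = rexpr
    return StageResult(
        stage="reporter",
        status="ok",
        artifacts={"subtranscripts": str(outdir / "subtranscripts.tsv"),
                   "expression": str(outdir / "reporter_expression.csv")},
        summary={"n_subtranscripts": {m: len(v) for m, v in subs.items()},
                 "cells_quantified": int(len(rexpr))},
    )


def _run_qc(config, state, seed, outdir) -> StageResult:
    ds = state["dataset"]
    sets = ds.config.resolved_marker_sets()
    genes = list(ds.adata.var_names)
    mito = [genes[i] for i in sets.get("mito", [])]
    ribo = [genes[i] for i in sets.get("ribo", [])]
    thresholds = QCThresholds(**config.qc_thresholds)
    filtered, qc_table = apply_qc_filters(ds.adata, mito, ribo, thresholds)
    qc_table.to_csv(outdir / "cell_qc.csv")
    norm = normalize_counts(filtered)
    state["norm"] = norm
    return StageResult(
        stage="qc",
        status="ok",
        artifacts={"cell_qc": str(outdir / "cell_qc.csv")},
        summary={"cells_in": int(ds.adata.n_obs), "cells_kept": int(filtered.n_obs)},
    )


def _run_classify(config, state, seed, outdir) -> StageResult:
    norm = state.get("norm")
    if norm is None:
        ds = state["dataset"]
        warnings.warn(
            "QC stage disabled: classifying on log-normalised raw counts",
            stacklevel=2,
        )
        norm = normalize_counts(ds.adata)
    rexpr = state["reporter_expr"].reindex(norm.obs_names, fill_value=0)
    anchors = select_anchor_cells(rexpr, n_target=config.n_anchor_target)
    gene_set = select_discriminative_genes(
        norm, anchors, n_rf_genes=config.n_rf_genes, alpha=config.alpha, seed=seed
    )
    calls = classify_cells(norm, gene_set, anchors)
    calls.to_csv(outdir / "label_calls.csv")
    (outdir / "discriminative_genes.json").write_text(
        json.dumps({"rf_top": list(gene_set.rf_top),
                    "test_selected": list(gene_set.test_selected),
                    "final": list(gene_set.final)}, indent=2)
    )
    state["calls"] = calls
    return StageResult(
        stage="classify",
        status="ok",
        artifacts={"label_calls": str(outdir / "label_calls.csv"),
                   "genes": str(outdir / "discriminative_genes.json")},
        summary={"labels": calls["label"].value_counts().to_dict(),
                 "n_final_genes": len(gene_set.final)},
    )


def _run_trajectory(config, state, seed, outdir) -> StageResult:
    norm = state.get("norm")
    ds = state["dataset"]
    if norm is None:
        norm = normalize_counts(ds.adata)
    expr = np.asarray(norm.X.todense())
    counts = np.asarray(norm.layers["counts"].todense()) if "counts" in norm.layers \
        else np.asarray(ds.adata.X.todense())
    gene_names = list(norm.var_names)

    branches = assign_branches(
        norm.obs["sample"].astype(str), norm.obs["true_branch"].astype(str)
    )
    branch = branches.cell_branch
    degs = find_degs(expr, counts, gene_names, branch,
                     top_n_abundant=config.deg_top_n)
    degs.to_csv(outdir / "degs_branches.csv", index=False)
    deg_genes = list(pd.unique(degs["gene"])) if len(degs) else []
    patterns = []
    if deg_genes:
        patterns = extract_patterns(
            deg_genes, expr, gene_names, branch, k_patterns=config.k_patterns
        )
        pd.DataFrame(
            [(p.pattern_id, g) for p in patterns for g in p.genes],
            columns=["pattern", "gene"],
        ).to_csv(outdir / "patterns.csv", index=False)

    states, degs_tc, tc_genes = trisect_and_select_tc_genes(
        norm.obs["true_pseudotime"].astype(float), expr, counts, gene_names,
        deg_kwargs={"top_n_abundant": config.deg_top_n},
    )
    states.groups.to_frame("state").to_csv(outdir / "pseudotime_states.csv")
    pd.Series(tc_genes, name="gene").to_csv(outdir / "tc_exclusive_genes.csv",
                                            index=False)
    pac = pac_stability(
        expr, config.pac_k_range, n_subsamples=config.pac_subsamples, seed=seed
    )
    pac.to_csv(outdir / "pac.csv")
    return StageResult(
        stage="trajectory",
        status="ok",
        artifacts={"degs": str(outdir / "degs_branches.csv"),
                   "pac": str(outdir / "pac.csv")},
        summary={"n_degs": int(len(degs)),
                 "pattern_sizes": {p.pattern_id: len(p.genes) for p in patterns},
                 "n_tc_exclusive": len(tc_genes),
                 "pac": {int(k): float(v) for k, v in pac.items()}},
    )


_RUNNERS = {
    "simulate": _run_simulate,
    "reporter": _run_reporter,
    "qc": _run_qc,
    "classify": _run_classify,
    "trajectory": _run_trajectory,
}
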