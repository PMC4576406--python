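"""End-to-end pipeline: simulate -> qc -> normalize -> hvg -> cycle -> lineage -> enrichment.

Each stage reads only prior-stage results, all randomness derives from one
root seed (fanned out per stage by stable hashing of stage names, so
toggling one stage never changes another's draws), and a manifest records
checksums, sizes and wall-clock per stage.  Re-running the same config
reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellcycle, enrichment, hvg, lineage, qc, simulate
from .data import DataError, write_count_matrix, write_gene_sets
from .normalize import compute_size_factors, normalize

log = logging.getLogger("hscycle")

STAGE_NAMES = ("simulate", "qc", "normalize", "hvg", "cycle", "lineage", "enrichment")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    outdir: str = "hscycle_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGE_NAMES
    simulate: dict = field(default_factory=dict)
    #: defaults sized for the synthetic demo matrix (~2000 genes); real
    #: deep-coverage data would use QCThresholds' own defaults
    qc: dict = field(
        default_factory=lambda: {"min_total_counts": 100_000, "min_genes_detected": 500}
    )
    cycle: dict = field(default_factory=lambda: {"k": 5, "n_components": 2})
    lineage: dict = field(default_factory=lambda: {"k": 4})
    hvg: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=lambda: {"n_perm": 200})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = set(cfg.stages) - set(STAGE_NAMES)
        if bad:
            raise DataError(f"unknown stages: {sorted(bad)}")
        return cfg


def stage_seed(root_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": asdict(config)}
    state: dict = {}
    written_by_stage: dict[str, list[Path]] = {}

    def write_df(stage: str, df: pd.DataFrame, name: str, index=True):
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")
        written_by_stage.setdefault(stage, []).append(path)
        return path

    for stage in STAGE_NAMES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _run_stage(stage, config, state, outdir, written_by_stage, write_df)
        except Exception as exc:
            for path in written_by_stage.get(stage, []):
                if path.exists():
                    path.rename(path.with_suffix(path.suffix + ".partial"))
            raise PipelineError(stage, exc) from exc
        entry = {
            "status": "ok",
            "wall_seconds": round(time.perf_counter() - t0, 3),
            "outputs": {
                p.name: {"sha256": _sha256(p), "bytes": p.stat().st_size}
                for p in written_by_stage.get(stage, [])
            },
        }
        entry.update(state.get(f"{stage}_summary", {}))
        manifest["stages"][stage] = entry
        log.info("stage %s ok (%.2fs)", stage, entry["wall_seconds"])
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _run_stage(stage, config, state, outdir, written_by_stage, write_df):
    seed = stage_seed(config.seed, stage)
    if stage == "simulate":
        sim_cfg = simulate.default_config(seed=seed, **config.simulate)
        matrix, meta, truth, sets = simulate.simulate_experiment(sim_cfg)
        state.update(matrix=matrix, meta=meta, truth=truth, gene_sets=sets, sim_cfg=sim_cfg)
        path = outdir / "counts.tsv"
        write_count_matrix(matrix, path)
        written_by_stage.setdefault(stage, []).append(path)
        write_df(stage, meta.table, "cell_metadata.tsv", index=False)
        write_df(stage, truth.cells, "sim_truth_cells.tsv", index=False)
        gmt = outdir / "gene_sets.gmt"
        write_gene_sets(sets, gmt)
        written_by_stage[stage].append(gmt)
        state["simulate_summary"] = {
            "n_cells": matrix.n_cells,
            "n_genes": int((~matrix.is_spikein).sum()),
        }
    elif stage == "qc":
        matrix, meta = state["matrix"], state["meta"]
        qc_params = dict(config.qc)
        screen_groups = set(
            qc_params.pop("deletion_screen_groups", state["sim_cfg"].deletion_groups)
        )
        thr = qc.QCThresholds(**qc_params)
        report = qc.compute_qc_metrics(matrix, meta)
        kept = qc.apply_qc_filters(report, thr, screen_groups)
        if not kept:
            raise DataError("0 cells pass QC filters")
        if len(kept) >= 5:
            outliers = qc.pca_outlier_screen(matrix, kept, k_mad=thr.outlier_mad_k)
            kept = [c for c in kept if c not in set(outliers)]
        else:
            outliers = []
        state["kept_cells"] = kept
        state["qc_report"] = report
        write_df(stage, report.table, "qc_report.tsv")
        state["qc_summary"] = {
            "cells_kept": len(kept),
            "pca_outliers": len(outliers),
        }
    elif stage == "normalize":
        matrix = state["matrix"].subset_cells(state["kept_cells"])
        sf = compute_size_factors(matrix)
        norm = normalize(matrix, sf)
        state.update(kept_matrix=matrix, size_factors=sf, norm=norm)
        sf_df = pd.DataFrame(
            {"cell_id": sf.cell_ids, "s_cell": sf.s_cell,
             "s_ercc": sf.s_ercc if sf.s_ercc is not None else np.nan}
        )
        write_df(stage, sf_df, "size_factors.tsv", index=False)
    elif stage == "hvg":
        matrix, sf, norm = state["kept_matrix"], state["size_factors"], state["norm"]
        spike_norm = norm.loc[matrix.gene_ids[matrix.is_spikein]]
        fit = hvg.fit_technical_noise(spike_norm, sf, **config.hvg.get("fit", {}))
        table = hvg.test_highly_variable(
            norm.loc[matrix.gene_ids[~matrix.is_spikein]],
            fit,
            **config.hvg.get("test", {}),
        )
        state.update(tech_fit=fit, hvg_table=table)
        write_df(stage, table, "hvg_table.tsv")
        fit_path = outdir / "technical_noise_fit.json"
        fit_path.write_text(json.dumps(asdict(fit), indent=2))
        written_by_stage[stage].append(fit_path)
        state["hvg_summary"] = {
            "n_highly_variable": int(table["highly_variable"].sum()),
            "a1": fit.a1,
            "alpha0": fit.alpha0,
        }
    elif stage == "cycle":
        _run_cycle_stage(config, state, seed, write_df)
    elif stage == "lineage":
        _run_lineage_stage(config, state, seed, write_df)
    elif stage == "enrichment":
        _run_enrichment_stage(config, state, seed, write_df)


def _groups_series(state) -> pd.Series:
    return state["meta"].groups.reindex(state["kept_cells"])


def _run_cycle_stage(config, state, seed, write_df):
    norm = state["norm"]
    sets = state["gene_sets"]
    groups = _groups_series(state)
    ref_group = config.cycle.get("reference_group") or next(iter(state["sim_cfg"].groups))
    ref_cells = list(groups.index[groups == ref_group])
    other_cells = list(groups.index[groups != ref_group])
    emb = cellcycle.pca_embed(
        norm[ref_cells], sets["cell_cycle"], n_components=config.cycle.get("n_components", 2)
    )
    clusters = cellcycle.cluster_embedding(emb, k=config.cycle.get("k", 5), seed=seed)
    model, ref_assign = cellcycle.assign_cluster_stages(
        clusters, norm[ref_cells], groups=groups
    )
    ref_assign = cellcycle.attach_scores(ref_assign, emb)
    assignments = [ref_assign]
    if other_cells:
        proj = cellcycle.project_and_classify(
            emb, model, norm[other_cells], groups=groups
        )
        assignments.append(proj)
    full = cellcycle.StageAssignment(table=pd.concat([a.table for a in assignments]))
    state.update(embedding=emb, stage_model=model, stage_assignment=full,
                 ref_assignment=ref_assign)
    write_df("cycle", full.table, "stage_assignment.tsv")
    occ = full.occupancy()
    write_df("cycle", occ, "stage_occupancy.tsv")
    summary = {"occupancy": {g: occ.loc[g].round(4).to_dict() for g in occ.index},
               "hierarchical_ari": clusters.ari_hierarchical}
    if other_cells:
        a = cellcycle.StageAssignment(full.table[full.table["group"] != ref_group])
        b = cellcycle.StageAssignment(full.table[full.table["group"] == ref_group])
        comp = cellcycle.compare_occupancy(a, b)
        summary["proliferative_shift"] = {
            "fraction_other": comp.fraction_a,
            "fraction_reference": comp.fraction_b,
            "fisher_p": comp.p_value,
        }
        sf = state["size_factors"]
        if sf.s_ercc is not None:
            activity, tests = cellcycle.transcriptional_activity(
                state["kept_matrix"], sf, full
            )
            write_df("cycle", tests, "transcriptional_activity_tests.tsv", index=False)
    state["cycle_summary"] = summary


def _run_lineage_stage(config, state, seed, write_df):
    norm = state["norm"]
    sets = state["gene_sets"]
    groups = _groups_series(state)
    stages = state["stage_assignment"].table["stage"] if "stage_assignment" in state else None
    emb = lineage.lineage_embed(
        norm, sets["hematopoietic"], sets["cell_cycle"],
        n_components=config.lineage.get("n_components", 2),
    )
    sub = lineage.subgroup_cells(
        emb, norm, k=config.lineage.get("k", 4), seed=seed,
        groups=groups, stages=stages,
    )
    regs = [g for g in lineage.DEFAULT_REGULATORS if g in norm.index]
    state["subgroups"] = sub
    write_df("lineage", sub.table, "lineage_subgroups.tsv")
    summary = {"subgroup_sizes": sub.table["subgroup"].value_counts().to_dict()}
    try:
        cc = lineage.regulator_correlation_clusters(norm, regs)
        write_df("lineage", cc.correlation, "regulator_correlation.tsv")
        summary["regulator_between_cluster_rho"] = cc.between_mean
    except DataError:
        summary["regulator_between_cluster_rho"] = None
    state["lineage_summary"] = summary


def _run_enrichment_stage(config, state, seed, write_df):
    norm = state["norm"]
    sets = state["gene_sets"]
    groups = _groups_series(state)
    sig_names = [n for n in ("CLP_signature", "MegE_signature", "GM_signature")
                 if n in sets]
    summary = {}
    uniq = list(dict.fromkeys(groups))
    if len(uniq) == 2 and sig_names:
        from .data import GeneSetCollection

        bio = state["kept_matrix"]
        bio_norm = norm.loc[bio.gene_ids[~bio.is_spikein]]
        sub = GeneSetCollection(
            sets={n: sets[n] for n in sig_names},
            descriptions={n: sets.descriptions[n] for n in sig_names},
        )
        res = enrichment.gsea(
            bio_norm, groups, sub,
            n_perm=config.enrichment.get("n_perm", 200), seed=seed,
            classes=(uniq[0], uniq[1]),
        )
        write_df("enrichment", res, "gsea_results.tsv")
        summary["gsea"] = {
            n: {"nes": float(res.loc[n, "nes"]), "p": float(res.loc[n, "p_value"])}
            for n in res.index
        }
    if "hvg_table" in state:
        table = state["hvg_table"]
        selected = list(table.index[table["highly_variable"]])
        universe = list(table.index[table["mean"] > 0])
        if selected:
            ora = enrichment.ora_hypergeometric(selected, universe, sets)
            write_df("enrichment", ora, "ora_results.tsv")
            summary["ora_top_set"] = str(ora["p_value"].idxmin())
    state["enrichment_summary"] = summary
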