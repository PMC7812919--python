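"""End-to-end analysis tracks tying the stages together.

Three tracks mirror the three experimental designs:

* ``timecourse`` — panel counts over culture time: normalize → PCA →
  gene-vs-time ranking → geneset signature scores per timepoint;
* ``singlecell`` — single-cell UMI counts: QC filter → CPM/log →
  Louvain clustering → specificity-score marker selection → correlated-
  cluster merging → signature annotation and Wilcoxon markers;
* ``treatment`` — control vs two treatments: per-gene linear-model DE →
  DEG calling → set algebra → cross-treatment quadrants → per-geneset
  modulation percentages.

Each track runs either on user-supplied files or on the synthetic
generators, writes plain-text outputs into an output directory, and is
byte-reproducible for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, differential, qc, signatures, simulate, trajectory
from .errors import ConfigError
from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSetCollection,
    attach_annotation,
    logger,
    read_annotation,
    read_expression_matrix,
    read_genesets,
    write_genesets,
)

TRACKS = ("timecourse", "singlecell", "treatment")


@dataclass
class PipelineRun:
    """Record of one track execution: config snapshot, seed, output paths."""

    track: str
    config: AnalysisConfig
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def _fan_out_seeds(seed: int, n: int) -> list[int]:
    """Derive *n* stage seeds deterministically from one top-level seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def run_track(
    track: str,
    config: AnalysisConfig,
    out_dir: str | Path,
    synthetic: bool = True,
    counts_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    genesets_path: str | Path | None = None,
    seed: int | None = None,
) -> PipelineRun:
    """Run one analysis track and write its outputs under *out_dir*."""
    if track not in TRACKS:
        raise ConfigError(f"unknown track {track!r}; expected one of {TRACKS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else int(seed)
    run = PipelineRun(track=track, config=config, seed=seed)
    config.to_yaml(out / "config.yaml")
    run.outputs["config"] = str(out / "config.yaml")

    if not synthetic and counts_path is None:
        raise ConfigError(f"track {track!r}: provide counts_path or use synthetic=True")

    if track == "timecourse":
        _run_timecourse(run, out, synthetic, counts_path, annotation_path, genesets_path)
    elif track == "singlecell":
        _run_singlecell(run, out, synthetic, counts_path, annotation_path, genesets_path)
    else:
        _run_treatment(run, out, synthetic, counts_path, annotation_path, genesets_path)
    logger.info("pipeline.run_track[%s]: wrote %d outputs to %s", track, len(run.outputs), out)
    return run


def _load_matrix(counts_path, annotation_path) -> ExpressionMatrix:
    m = read_expression_matrix(counts_path)
    if annotation_path is not None:
        m = attach_annotation(m, read_annotation(annotation_path))
    return m


def _truth_to_json(truth: simulate.PlantedTruth) -> dict:
    return {
        "obs_labels": truth.obs_labels.to_dict(),
        "de_genes": truth.de_genes,
        "trend_genes": {g: list(v) for g, v in truth.trend_genes.items()},
        "program_genes": truth.program_genes,
        "transient_genes": truth.transient_genes,
    }


# -- timecourse -----------------------------------------------------------


def default_timecourse_design(
    n_genes: int = 400, n_trend: int = 30, n_transient: int = 15, slope: float = 0.8, seed: int = 0
) -> tuple[dict[str, tuple[str, float]], list[str]]:
    """Planted design emulating the culture timecourse: microglial-marker
    genes trending up, neuronal markers trending down, and an early
    inflammatory transient."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    chosen = rng.choice(n_genes, size=2 * n_trend + n_transient, replace=False)
    up = [genes[i] for i in chosen[:n_trend]]
    down = [genes[i] for i in chosen[n_trend: 2 * n_trend]]
    transient = [genes[i] for i in chosen[2 * n_trend:]]
    trend_spec: dict[str, tuple[str, float]] = {}
    trend_spec.update({g: ("up", slope) for g in up})
    trend_spec.update({g: ("down", slope) for g in down})
    return trend_spec, transient


def _run_timecourse(run, out: Path, synthetic, counts_path, annotation_path, genesets_path):
    cfg = run.config
    seeds = _fan_out_seeds(run.seed, 2)
    if synthetic:
        trend_spec, transient = default_timecourse_design(seed=seeds[0])
        m, truth = simulate.simulate_timecourse_panel(
            n_timepoints=5, n_reps=3, trend_spec=trend_spec, transient_genes=transient,
            seed=seeds[1],
        )
        _write_json(_truth_to_json(truth), out / "truth.json")
        run.outputs["truth"] = str(out / "truth.json")
        gsets = GeneSetCollection(sets={
            "trend_up": [g for g, (d, _) in truth.trend_genes.items() if d == "up"],
            "trend_down": [g for g, (d, _) in truth.trend_genes.items() if d == "down"],
            "transient": list(truth.transient_genes),
        })
    else:
        m = _load_matrix(counts_path, annotation_path)
        gsets = read_genesets(genesets_path) if genesets_path else None
    if "timepoint" not in m.obs_annotation.columns:
        raise ConfigError("timecourse track needs a numeric 'timepoint' annotation")

    cpm = qc.normalize_counts(m, scale=cfg.cpm_scale)
    logm = qc.normalize_counts(m, scale=cfg.cpm_scale, log_transform=True)
    pca = trajectory.run_pca(logm, n_components=min(5, m.n_obs - 1))
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t", index_label="obs_id")
    run.outputs["pca_scores"] = str(out / "pca_scores.tsv")

    covariate = m.obs_annotation["timepoint"].astype(float)
    # trends are log-linear; correlate on the log layer so Pearson sees a line
    ranking = trajectory.rank_genes_by_covariate(logm, covariate, p_cutoff=0.001, use_fdr=True)
    trajectory.write_ranking(ranking, out / "ranking.tsv")
    run.outputs["ranking"] = str(out / "ranking.tsv")
    run.results["n_selected"] = int(ranking["selected"].sum())

    if gsets is not None:
        means = signatures.group_mean_matrix(cpm)
        table = signatures.geneset_group_zscore(means, gsets)
        table.to_tsv(out / "signature_scores.tsv")
        run.outputs["signature_scores"] = str(out / "signature_scores.tsv")
        run.results["signature_scores"] = table.scores
    run.results["ranking"] = ranking
    run.results["pca"] = pca


# -- singlecell -----------------------------------------------------------


def _run_singlecell(run, out: Path, synthetic, counts_path, annotation_path, genesets_path):
    cfg = run.config
    seeds = _fan_out_seeds(run.seed, 2)
    if synthetic:
        populations, genes, programs = simulate.default_populations(seed=seeds[0])
        m, truth = simulate.simulate_single_cell_counts(
            populations, n_genes=len(genes), seed=seeds[1]
        )
        _write_json(_truth_to_json(truth), out / "truth.json")
        run.outputs["truth"] = str(out / "truth.json")
        gsets = GeneSetCollection(sets={k: list(v) for k, v in programs.items()})
    else:
        m = _load_matrix(counts_path, annotation_path)
        if genesets_path is None:
            raise ConfigError("singlecell track on real data needs a genesets GMT")
        gsets = read_genesets(genesets_path)

    filtered, report = qc.filter_cells(
        m, mito_max_frac=cfg.mito_max_frac, min_genes=cfg.min_genes, max_umi=cfg.max_umi
    )
    report.to_json(out / "qc_report.json")
    run.outputs["qc_report"] = str(out / "qc_report.json")

    cpm = qc.normalize_counts(filtered, scale=cfg.cpm_scale)
    logm = qc.normalize_counts(filtered, scale=cfg.cpm_scale, log_transform=True)
    pre = clustering.cluster_cells(
        logm, n_pcs=cfg.n_pcs, n_neighbors=cfg.n_neighbors,
        resolution=cfg.resolution, seed=run.seed,
    )
    profile = clustering.cluster_profile(filtered, pre)
    if pre.k >= 2:
        merged = clustering.merge_correlated_clusters(
            pre, profile, corr_threshold=cfg.merge_corr_threshold,
            top_n=cfg.top_n_markers, min_avg_umi=cfg.min_avg_umi,
        )
    else:
        merged = pre

    table = pd.DataFrame({
        "cluster_pre_merge": pre.labels,
        "cluster_final": merged.labels,
    })
    table.to_csv(out / "assignment.tsv", sep="\t", index_label="obs_id")
    run.outputs["assignment"] = str(out / "assignment.tsv")
    _write_json(merged.provenance, out / "provenance.json")
    run.outputs["provenance"] = str(out / "provenance.json")

    annotation = clustering.annotate_clusters(cpm, merged, gsets)
    annotation["annotation"].to_csv(out / "annotation.tsv", sep="\t", index_label="cluster")
    run.outputs["annotation"] = str(out / "annotation.tsv")
    annotation["signature_scores"].to_tsv(out / "signature_scores.tsv")
    run.outputs["signature_scores"] = str(out / "signature_scores.tsv")
    marker_sets = {}
    for c, res in annotation["markers"].items():
        degs = differential.call_degs(res, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha,
                                      alpha_is_fdr=cfg.alpha_is_fdr)
        if degs.up:
            marker_sets[f"cluster{c}_up"] = sorted(degs.up)
    if marker_sets:
        write_genesets(GeneSetCollection(sets=marker_sets), out / "cluster_markers.gmt")
        run.outputs["cluster_markers"] = str(out / "cluster_markers.gmt")

    run.results.update({
        "qc_report": report, "pre_merge": pre, "merged": merged,
        "annotation": annotation["annotation"],
        "signature_scores": annotation["signature_scores"].scores,
    })


# -- treatment ------------------------------------------------------------


def default_treatment_design(
    n_genes: int = 2000, n_shared: int = 40, n_unique: int = 40, log2fc: float = 2.0, seed: int = 0
) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """Planted two-treatment design: shared, A-only and B-only fold
    changes, half up- and half down-regulated in each block."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    chosen = rng.choice(n_genes, size=n_shared + 2 * n_unique, replace=False)

    def block(idx):
        out = {}
        for j, i in enumerate(idx):
            out[genes[i]] = log2fc if j % 2 == 0 else -log2fc
        return out

    return (
        block(chosen[:n_shared]),
        block(chosen[n_shared: n_shared + n_unique]),
        block(chosen[n_shared + n_unique:]),
    )


def _run_treatment(run, out: Path, synthetic, counts_path, annotation_path, genesets_path):
    cfg = run.config
    seeds = _fan_out_seeds(run.seed, 2)
    if synthetic:
        shared, a_only, b_only = default_treatment_design(seed=seeds[0])
        m, truth = simulate.simulate_treatment_bulk(
            n_per_group=10, shared_de=shared, a_only_de=a_only, b_only_de=b_only, seed=seeds[1]
        )
        _write_json(_truth_to_json(truth), out / "truth.json")
        run.outputs["truth"] = str(out / "truth.json")
        gsets = GeneSetCollection(sets={
            "planted_shared": sorted(shared),
            "planted_a_only": sorted(a_only),
            "planted_b_only": sorted(b_only),
        })
    else:
        m = _load_matrix(counts_path, annotation_path)
        gsets = read_genesets(genesets_path) if genesets_path else None
    if "group" not in m.obs_annotation.columns:
        raise ConfigError("treatment track needs a 'group' annotation")
    groups = m.obs_annotation["group"]
    names = list(dict.fromkeys(groups))
    if len(names) != 3:
        raise ConfigError(f"treatment track expects 3 groups (control, A, B), got {names}")
    control, treat_a, treat_b = names

    cpm = qc.normalize_counts(m, scale=cfg.cpm_scale)
    obs = pd.Series(m.obs_ids, index=m.obs_ids)
    res_a = differential.de_test(cpm, list(obs[groups == treat_a]), list(obs[groups == control]),
                                 mode="linear_model", comparison=f"{treat_a}_vs_{control}")
    res_b = differential.de_test(cpm, list(obs[groups == treat_b]), list(obs[groups == control]),
                                 mode="linear_model", comparison=f"{treat_b}_vs_{control}")
    deg_a = differential.call_degs(res_a, cfg.fc_threshold, cfg.alpha, cfg.alpha_is_fdr)
    deg_b = differential.call_degs(res_b, cfg.fc_threshold, cfg.alpha, cfg.alpha_is_fdr)
    res_a.to_tsv(out / "de_a_vs_control.tsv")
    res_b.to_tsv(out / "de_b_vs_control.tsv")
    run.outputs["de_a"] = str(out / "de_a_vs_control.tsv")
    run.outputs["de_b"] = str(out / "de_b_vs_control.tsv")

    algebra = differential.deg_set_algebra(deg_a, deg_b)
    quads = differential.crosstreatment_quadrants(res_a, res_b, deg_a, deg_b, cfg.fc_threshold)
    quads.to_tsv(out / "quadrants.tsv")
    run.outputs["quadrants"] = str(out / "quadrants.tsv")
    summary = {
        "set_algebra": algebra,
        "quadrant_counts": {k: int(v) for k, v in quads.counts.items()},
        "n_degs_a": deg_a.n_total,
        "n_degs_b": deg_b.n_total,
    }
    _write_json(summary, out / "summary.json")
    run.outputs["summary"] = str(out / "summary.json")

    if gsets is not None:
        modulation = differential.geneset_modulation_percent(quads, gsets)
        modulation.to_csv(out / "geneset_modulation.tsv", sep="\t", index_label="geneset")
        run.outputs["geneset_modulation"] = str(out / "geneset_modulation.tsv")
        run.results["modulation"] = modulation
    run.results.update({
        "res_a": res_a, "res_b": res_b, "deg_a": deg_a, "deg_b": deg_b,
        "algebra": algebra, "quadrants": quads,
    })
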