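"""Synthetic count data with the population structure the pipeline assumes.

Three generators mirror the three experimental designs the pipeline
analyzes:

* :func:`simulate_single_cell_counts` — multi-population single-cell UMI
  counts with planted gene programs (homeostatic, inflammatory, reactive,
  proliferative, neonatal) and a mitochondrial gene block;
* :func:`simulate_timecourse_panel` — panel-style bulk counts over a
  culture timecourse with monotone cell-type-marker trends and an early
  inflammatory transient;
* :func:`simulate_treatment_bulk` — a control/treatment-A/treatment-B
  bulk design with planted shared and treatment-unique fold changes.

All counts are negative-binomial, parameterized by (mean, dispersion) with
``variance = mean + dispersion * mean**2`` — the standard RNA-seq count
model and the one the differential-expression stages assume. Every
generator is a pure function of its specification and seed, and emits a
:class:`PlantedTruth` record sufficient to score recovery without
re-reading the generator inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MITO_PREFIX, ExpressionMatrix

__all__ = [
    "PopulationSpec",
    "PlantedTruth",
    "negative_binomial_counts",
    "make_gene_universe",
    "default_populations",
    "simulate_single_cell_counts",
    "simulate_timecourse_panel",
    "simulate_treatment_bulk",
]


@dataclass
class PopulationSpec:
    """One cell population: its size, baseline expression and gene program.

    ``program_fold`` multiplies the baseline mean of every gene in
    ``program_genes`` for cells of this population; ``dispersion`` is the
    negative-binomial dispersion (variance = mean + dispersion·mean²);
    ``mito_frac_target`` is the expected mitochondrial share of total UMI.
    """

    name: str
    n_cells: int
    baseline_mean: np.ndarray
    program_genes: list[str]
    program_fold: float = 1.0
    dispersion: float = 0.5
    mito_frac_target: float = 0.02

    def __post_init__(self) -> None:
        self.baseline_mean = np.asarray(self.baseline_mean, dtype=float)
        if self.n_cells <= 0:
            raise ConfigError(f"population {self.name!r}: n_cells must be positive")
        if self.program_fold <= 0 or self.dispersion <= 0:
            raise ConfigError(f"population {self.name!r}: fold and dispersion must be > 0")
        if not (0 <= self.mito_frac_target < 1):
            raise ConfigError(f"population {self.name!r}: mito_frac_target must lie in [0, 1)")
        if np.any(self.baseline_mean <= 0):
            raise ConfigError(f"population {self.name!r}: baseline means must be positive")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    obs_labels: pd.Series
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    trend_genes: dict[str, tuple[str, float]] = field(default_factory=dict)
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    transient_genes: list[str] = field(default_factory=list)


def negative_binomial_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma–Poisson draws with variance ``mean + dispersion * mean**2``."""
    mean = np.asarray(mean, dtype=float)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def make_gene_universe(n_genes: int, n_mito: int = 10) -> list[str]:
    """Gene identifiers ``g0001..`` with a trailing ``mt-`` mitochondrial block."""
    if n_mito >= n_genes:
        raise ConfigError("n_mito must be smaller than n_genes")
    body = [f"g{i:05d}" for i in range(1, n_genes - n_mito + 1)]
    mito = [f"{MITO_PREFIX}{i}" for i in range(1, n_mito + 1)]
    return body + mito


def _default_baseline(rng: np.random.Generator, n_genes: int, log_mean: float, log_sd: float) -> np.ndarray:
    return np.exp(rng.normal(log_mean, log_sd, size=n_genes))


def default_populations(
    n_genes: int = 2000,
    seed: int = 0,
    n_cells: int = 300,
    program_size: int = 50,
    program_fold: float = 8.0,
    dispersion: float = 0.5,
    n_mito: int = 10,
) -> tuple[list[PopulationSpec], list[str], dict[str, list[str]]]:
    """Build the study-like five-population single-cell design.

    Homeostatic, inflammatory, reactive, proliferative and neonatal
    populations share one baseline expression profile; each carries a
    disjoint program of ``program_size`` genes up-regulated
    ``program_fold``-fold. Program genes are drawn from the moderately
    expressed baseline stratum so marker selection sees them. Returns the
    population specs, the gene universe, and the program map.
    """
    rng = np.random.default_rng(seed)
    genes = make_gene_universe(n_genes, n_mito=n_mito)
    baseline = _default_baseline(rng, n_genes, log_mean=np.log(0.5), log_sd=1.0)
    names = ["homeostatic", "inflammatory", "reactive", "proliferative", "neonatal"]
    non_mito = n_genes - n_mito
    eligible = np.flatnonzero(baseline[:non_mito] > 0.3)
    needed = program_size * len(names)
    if len(eligible) < needed:
        raise ConfigError("gene universe too small for the requested programs")
    chosen = rng.choice(eligible, size=needed, replace=False)
    programs = {
        name: sorted(genes[i] for i in chosen[k * program_size : (k + 1) * program_size])
        for k, name in enumerate(names)
    }
    populations = [
        PopulationSpec(
            name=name,
            n_cells=n_cells,
            baseline_mean=baseline,
            program_genes=programs[name],
            program_fold=program_fold,
            dispersion=dispersion,
            mito_frac_target=0.02,
        )
        for name in names
    ]
    return populations, genes, programs


def simulate_single_cell_counts(
    populations: list[PopulationSpec],
    n_genes: int,
    seed: int,
    gene_ids: list[str] | None = None,
    n_mito: int = 10,
    libsize_sigma: float = 0.3,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw per-cell UMI counts for a mixture of populations.

    Each cell's gene means are the population baseline, multiplied by the
    program fold on program genes, rescaled on the mitochondrial block to
    hit ``mito_frac_target`` in expectation, and multiplied by a per-cell
    log-normal(0, ``libsize_sigma``) library-size factor.
    """
    if len(populations) < 2:
        raise ConfigError("need at least 2 populations")
    genes = gene_ids if gene_ids is not None else make_gene_universe(n_genes, n_mito=n_mito)
    if len(genes) != n_genes:
        raise ConfigError("gene_ids length does not match n_genes")
    gene_pos = {g: i for i, g in enumerate(genes)}
    program_union: set[str] = set()
    for pop in populations:
        missing = [g for g in pop.program_genes if g not in gene_pos]
        if missing:
            raise ConfigError(
                f"population {pop.name!r}: program genes not in the gene universe: {missing[:5]}"
            )
        program_union |= set(pop.program_genes)
    if n_genes < len(program_union):
        raise ConfigError("n_genes smaller than the union of program genes")
    mito = np.array([g.startswith(MITO_PREFIX) for g in genes], dtype=bool)

    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    obs_ids: list[str] = []
    labels: list[str] = []
    for pop in populations:
        if len(pop.baseline_mean) != n_genes:
            raise ConfigError(f"population {pop.name!r}: baseline_mean length != n_genes")
        mean = pop.baseline_mean.copy()
        if pop.program_genes:
            idx = [gene_pos[g] for g in pop.program_genes]
            mean[idx] *= pop.program_fold
        # retune the mito block so its expected share of total UMI is the target
        if mito.any() and pop.mito_frac_target > 0:
            body_total = mean[~mito].sum()
            target_total = pop.mito_frac_target / (1 - pop.mito_frac_target) * body_total
            mean[mito] *= target_total / mean[mito].sum()
        elif mito.any():
            mean[mito] = 0.0
        size_factors = np.exp(rng.normal(0.0, libsize_sigma, size=pop.n_cells))
        cell_means = mean[:, None] * size_factors[None, :]
        blocks.append(negative_binomial_counts(rng, cell_means, pop.dispersion))
        obs_ids.extend(f"{pop.name}_{i:04d}" for i in range(1, pop.n_cells + 1))
        labels.extend([pop.name] * pop.n_cells)

    values = np.concatenate(blocks, axis=1)
    annotation = pd.DataFrame({"group": labels}, index=obs_ids)
    matrix = ExpressionMatrix(
        values=values, gene_ids=genes, obs_ids=obs_ids, obs_annotation=annotation, layer_tag="raw"
    )
    truth = PlantedTruth(
        obs_labels=pd.Series(labels, index=obs_ids, name="population"),
        program_genes={p.name: list(p.program_genes) for p in populations},
        de_genes={
            f"{p.name}_program": {g: float(np.log2(p.program_fold)) for g in p.program_genes}
            for p in populations
            if p.program_genes and p.program_fold != 1.0
        },
    )
    return matrix, truth


def simulate_timecourse_panel(
    n_timepoints: int,
    n_reps: int,
    trend_spec: dict[str, tuple[str, float]],
    transient_genes: list[str],
    seed: int,
    n_genes: int = 400,
    baseline_mean: np.ndarray | None = None,
    dispersion: float = 0.1,
    timepoints: np.ndarray | None = None,
    transient_amplitude: float = 2.0,
    transient_tau: float = 1.0,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Bulk panel counts over a culture timecourse.

    ``trend_spec`` maps gene id to ``(direction, slope)`` with slope in
    log2 units per week; trend genes change log-linearly and monotonically
    (e.g. microglial markers up, neuronal markers down). ``transient_genes``
    follow a rise-then-decay pulse ``amplitude · (t/τ) · exp(1 − t/τ)`` on
    the log2-mean scale, peaking at ``t = τ`` — the shape of an early
    inflammatory reaction that subsides. Default timepoints are weeks
    1..n_timepoints.
    """
    if n_timepoints < 3:
        raise ConfigError("need at least 3 timepoints")
    if n_reps < 2:
        raise ConfigError("need at least 2 replicates per timepoint")
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, (direction, slope) in trend_spec.items():
        if g not in gene_pos:
            raise ConfigError(f"trend gene {g!r} not in the gene universe")
        if slope == 0:
            raise ConfigError(f"trend gene {g!r} declared with slope 0")
        if direction not in ("up", "down"):
            raise ConfigError(f"trend gene {g!r}: direction must be 'up' or 'down'")
    for g in transient_genes:
        if g not in gene_pos:
            raise ConfigError(f"transient gene {g!r} not in the gene universe")

    rng = np.random.default_rng(seed)
    if baseline_mean is None:
        baseline_mean = _default_baseline(rng, n_genes, log_mean=np.log(50.0), log_sd=1.0)
    baseline_mean = np.asarray(baseline_mean, dtype=float)
    if timepoints is None:
        timepoints = np.arange(1, n_timepoints + 1, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if len(timepoints) != n_timepoints:
        raise ConfigError("timepoints length does not match n_timepoints")

    log2_mean = np.tile(np.log2(baseline_mean)[:, None], (1, n_timepoints))
    for g, (direction, slope) in trend_spec.items():
        signed = abs(slope) if direction == "up" else -abs(slope)
        log2_mean[gene_pos[g], :] += signed * (timepoints - timepoints[0])
    pulse = transient_amplitude * (timepoints / transient_tau) * np.exp(1 - timepoints / transient_tau)
    for g in transient_genes:
        log2_mean[gene_pos[g], :] += pulse

    obs_ids, tp_annot, blocks = [], [], []
    for j, t in enumerate(timepoints):
        mean_t = 2.0 ** log2_mean[:, j]
        counts = negative_binomial_counts(rng, np.tile(mean_t[:, None], (1, n_reps)), dispersion)
        blocks.append(counts)
        obs_ids.extend(f"t{j + 1}_rep{r}" for r in range(1, n_reps + 1))
        tp_annot.extend([t] * n_reps)

    values = np.concatenate(blocks, axis=1)
    annotation = pd.DataFrame(
        {"group": [f"week{t:g}" for t in tp_annot], "timepoint": tp_annot}, index=obs_ids
    )
    matrix = ExpressionMatrix(
        values=values, gene_ids=genes, obs_ids=obs_ids, obs_annotation=annotation, layer_tag="raw"
    )
    truth = PlantedTruth(
        obs_labels=pd.Series(annotation["group"].to_numpy(), index=obs_ids, name="timepoint_group"),
        trend_genes={g: (d, abs(s) if d == "up" else -abs(s)) for g, (d, s) in trend_spec.items()},
        transient_genes=list(transient_genes),
    )
    return matrix, truth


def simulate_treatment_bulk(
    n_per_group: int,
    shared_de: dict[str, float],
    a_only_de: dict[str, float],
    b_only_de: dict[str, float],
    seed: int,
    n_genes: int = 2000,
    baseline_mean: np.ndarray | None = None,
    dispersion: float = 0.1,
    group_names: tuple[str, str, str] = ("control", "treatment_a", "treatment_b"),
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Three-group bulk design: control plus two 24 h treatments.

    ``shared_de`` fold changes apply to both treatments, ``a_only_de`` /
    ``b_only_de`` to one; values are log2 fold changes applied
    multiplicatively to the baseline mean. The three DE maps must be
    disjoint.
    """
    maps = [shared_de, a_only_de, b_only_de]
    all_de: set[str] = set()
    for de_map in maps:
        overlap = all_de & set(de_map)
        if overlap:
            raise ConfigError(f"genes appear in more than one DE map: {sorted(overlap)[:5]}")
        all_de |= set(de_map)

    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    missing = [g for g in all_de if g not in gene_pos]
    if missing:
        raise ConfigError(f"planted DE genes not in the gene universe: {missing[:5]}")

    rng = np.random.default_rng(seed)
    if baseline_mean is None:
        baseline_mean = _default_baseline(rng, n_genes, log_mean=np.log(50.0), log_sd=1.0)
    baseline_mean = np.asarray(baseline_mean, dtype=float)

    def group_mean(de_maps: list[dict[str, float]]) -> np.ndarray:
        mean = baseline_mean.copy()
        for de_map in de_maps:
            for g, lfc in de_map.items():
                mean[gene_pos[g]] *= 2.0 ** lfc
        return mean

    means = {
        group_names[0]: group_mean([]),
        group_names[1]: group_mean([shared_de, a_only_de]),
        group_names[2]: group_mean([shared_de, b_only_de]),
    }
    obs_ids, groups, blocks = [], [], []
    for name in group_names:
        counts = negative_binomial_counts(
            rng, np.tile(means[name][:, None], (1, n_per_group)), dispersion
        )
        blocks.append(counts)
        obs_ids.extend(f"{name}_{r}" for r in range(1, n_per_group + 1))
        groups.extend([name] * n_per_group)

    values = np.concatenate(blocks, axis=1)
    annotation = pd.DataFrame({"group": groups, "treatment": groups}, index=obs_ids)
    matrix = ExpressionMatrix(
        values=values, gene_ids=genes, obs_ids=obs_ids, obs_annotation=annotation, layer_tag="raw"
    )
    a_vs_c = {**shared_de, **a_only_de}
    b_vs_c = {**shared_de, **b_only_de}
    truth = PlantedTruth(
        obs_labels=pd.Series(groups, index=obs_ids, name="group"),
        de_genes={
            f"{group_names[1]}_vs_{group_names[0]}": a_vs_c,
            f"{group_names[2]}_vs_{group_names[0]}": b_vs_c,
        },
    )
    return matrix, truth
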