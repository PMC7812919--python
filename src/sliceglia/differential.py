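"""Differential expression, DEG calling, and DEG set algebra.

Two test modes serve the two data levels: a two-sided Wilcoxon rank-sum
test with tie correction and normal approximation for cell-level data,
and a per-gene linear model on log2(CPM + 1) with a group indicator
(two-sided t-test on the contrast) for population/bulk data. DEGs are
called at |fold change| > 1.5 with p or FDR < 0.05, the thresholds applied
consistently downstream. Fold changes are computed on the CPM scale with
a pseudocount of 1: ``log2fc = log2((mean_a + 1) / (mean_b + 1))``.

Set algebra over DEG sets (per-direction unions, intersections, conserved
fractions) and the cross-treatment quadrant classification (shared /
treatment-unique / discordant up- and down-regulation on the joint
fold-change plane) summarize comparisons across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSetCollection, logger
from .stats import bh_fdr

QUADRANT_CATEGORIES = (
    "shared_up", "shared_down",
    "a_only_up", "a_only_down",
    "b_only_up", "b_only_down",
    "discordant", "unchanged",
)


@dataclass
class DEResult:
    """Per-gene DE statistics for one comparison (A vs B)."""

    table: pd.DataFrame  # columns: log2fc, stat, p_value, fdr, mean_a, mean_b, tested
    comparison: str
    mode: str

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class DEGSet:
    """Up- and down-regulated gene sets with the thresholds that called them."""

    up: set[str]
    down: set[str]
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DEG sets overlap")

    @property
    def n_total(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class QuadrantTable:
    """Per-gene joint classification of two treatment responses."""

    table: pd.DataFrame  # columns: category, log2fc_a, log2fc_b
    counts: pd.Series

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def de_test(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    mode: str = "wilcoxon",
    comparison: str | None = None,
) -> DEResult:
    """Per-gene differential expression between two observation groups.

    Expects a CPM-normalized matrix. ``wilcoxon`` runs a two-sided
    rank-sum test per gene (normal approximation, tie and continuity
    corrected); ``linear_model`` fits expression ~ group on log2(CPM + 1)
    and t-tests the group contrast. Genes with zero counts in both groups
    are excluded from testing and flagged; BH FDR is computed across the
    tested genes.
    """
    if m.layer_tag != "cpm":
        raise ConfigError(f"de_test expects a CPM-normalized matrix, got layer {m.layer_tag!r}")
    if mode not in ("wilcoxon", "linear_model"):
        raise ConfigError(f"unknown DE mode {mode!r}")
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ConfigError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ConfigError("both groups need at least 2 observations")
    lookup = {o: i for i, o in enumerate(m.obs_ids)}
    ia = np.array([lookup[o] for o in group_a])
    ib = np.array([lookup[o] for o in group_b])

    a = m.values[:, ia].astype(float)
    b = m.values[:, ib].astype(float)
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    tested = ~((a.sum(axis=1) == 0) & (b.sum(axis=1) == 0))
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("differential.de_test: %d all-zero genes excluded", n_skipped)

    stat = np.full(m.n_genes, np.nan)
    p = np.full(m.n_genes, np.nan)
    if tested.any():
        if mode == "wilcoxon":
            res = scipy.stats.mannwhitneyu(
                a[tested], b[tested], axis=1, alternative="two-sided", method="asymptotic"
            )
            stat[tested] = res.statistic
            p[tested] = res.pvalue
        else:
            la = np.log2(a[tested] + 1.0)
            lb = np.log2(b[tested] + 1.0)
            na, nb = la.shape[1], lb.shape[1]
            diff = la.mean(axis=1) - lb.mean(axis=1)
            ssa = ((la - la.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            ssb = ((lb - lb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
            df = na + nb - 2
            sp2 = (ssa + ssb) / df
            with np.errstate(invalid="ignore", divide="ignore"):
                t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            t = np.where(sp2 == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
            stat[tested] = t
            p[tested] = 2.0 * scipy.stats.t.sf(np.abs(t), df=df)

    fdr = np.full(m.n_genes, np.nan)
    fdr[tested] = bh_fdr(p[tested])
    table = pd.DataFrame(
        {
            "log2fc": np.log2((mean_a + 1.0) / (mean_b + 1.0)),
            "stat": stat,
            "p_value": p,
            "fdr": fdr,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "tested": tested,
        },
        index=m.gene_ids,
    )
    return DEResult(table=table, comparison=comparison or "a_vs_b", mode=mode)


def call_degs(
    res: DEResult,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    alpha_is_fdr: bool = True,
) -> DEGSet:
    """Call DEGs at |fold change| > ``fc_threshold`` and p (or FDR) < ``alpha``."""
    if fc_threshold <= 0:
        raise ConfigError("fc_threshold must be positive")
    log2_thr = np.log2(fc_threshold)
    sig = res.table["fdr"] if alpha_is_fdr else res.table["p_value"]
    significant = (sig < alpha) & res.table["tested"]
    up = set(res.table.index[significant & (res.table["log2fc"] > log2_thr)])
    down = set(res.table.index[significant & (res.table["log2fc"] < -log2_thr)])
    logger.info("differential.call_degs[%s]: |FC|>%g, %s<%g -> %d up, %d down",
                res.comparison, fc_threshold, "FDR" if alpha_is_fdr else "p", alpha,
                len(up), len(down))
    return DEGSet(up=up, down=down,
                  thresholds={"fc_threshold": fc_threshold, "alpha": alpha,
                              "alpha_is_fdr": alpha_is_fdr})


def deg_set_algebra(set_a: DEGSet, set_b: DEGSet) -> dict[str, dict[str, float]]:
    """Per-direction overlap summary of two DEG sets.

    For each direction reports |A|, |B|, |A∩B|, |A∪B|, |A\\B|, |B\\A| and
    the conserved fraction |A∩B| / |A| (as a percentage).
    """
    out: dict[str, dict[str, float]] = {}
    for direction in ("up", "down"):
        a: set[str] = getattr(set_a, direction)
        b: set[str] = getattr(set_b, direction)
        inter = a & b
        out[direction] = {
            "n_a": len(a),
            "n_b": len(b),
            "n_intersection": len(inter),
            "n_union": len(a | b),
            "n_a_only": len(a - b),
            "n_b_only": len(b - a),
            "conserved_percent": 100.0 * len(inter) / len(a) if a else float("nan"),
        }
    return out


def crosstreatment_quadrants(
    res_a: DEResult,
    res_b: DEResult,
    deg_a: DEGSet,
    deg_b: DEGSet,
    fc_threshold: float = 1.5,
) -> QuadrantTable:
    """Classify every gene by its joint response to two treatments.

    ``shared_up``/``shared_down``: DEG in the same direction in both.
    ``a_only_up`` etc.: DEG in one treatment while not a DEG in the other
    (either |FC| below the threshold there, or not significant).
    ``discordant``: opposite-direction DEGs. Everything else is
    ``unchanged``. Categories partition the shared gene universe.
    """
    if set(res_a.genes) != set(res_b.genes):
        raise ConfigError("quadrant analysis requires a shared gene universe")
    genes = res_a.genes
    lfc_a = res_a.table["log2fc"]
    lfc_b = res_b.table["log2fc"].reindex(genes)

    up_a, dn_a = deg_a.up, deg_a.down
    up_b, dn_b = deg_b.up, deg_b.down
    categories = []
    for g in genes:
        in_a_up, in_a_dn = g in up_a, g in dn_a
        in_b_up, in_b_dn = g in up_b, g in dn_b
        if in_a_up and in_b_up:
            categories.append("shared_up")
        elif in_a_dn and in_b_dn:
            categories.append("shared_down")
        elif (in_a_up and in_b_dn) or (in_a_dn and in_b_up):
            categories.append("discordant")
        elif in_a_up:
            categories.append("a_only_up")
        elif in_a_dn:
            categories.append("a_only_down")
        elif in_b_up:
            categories.append("b_only_up")
        elif in_b_dn:
            categories.append("b_only_down")
        else:
            categories.append("unchanged")
    table = pd.DataFrame(
        {"category": categories, "log2fc_a": lfc_a.to_numpy(), "log2fc_b": lfc_b.to_numpy()},
        index=genes,
    )
    counts = table["category"].value_counts().reindex(QUADRANT_CATEGORIES, fill_value=0)
    counts.name = "n_genes"
    return QuadrantTable(table=table, counts=counts)


def geneset_modulation_percent(
    quadrants: QuadrantTable, genesets: GeneSetCollection
) -> pd.DataFrame:
    """Percentage of each geneset falling in each quadrant category.

    Denominator per geneset: member genes present in the gene universe.
    Percentages across all categories (including ``unchanged``) sum to 100.
    """
    universe = set(quadrants.table.index)
    category = quadrants.table["category"]
    rows = {}
    for set_id, genes in genesets.sets.items():
        members = [g for g in genes if g in universe]
        if not members:
            raise ConfigError(f"geneset {set_id!r} has no genes in the universe")
        member_cat = category.loc[members].value_counts()
        rows[set_id] = {
            cat: 100.0 * member_cat.get(cat, 0) / len(members) for cat in QUADRANT_CATEGORIES
        }
    return pd.DataFrame(rows).T[list(QUADRANT_CATEGORIES)]
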