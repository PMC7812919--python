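"""Graph clustering of cells and the specificity-driven over-clustering fix.

Cells are clustered by Louvain community detection on a k-nearest-neighbor
graph built in PC space (Euclidean distance on log-CPM principal
components, unweighted edges). Because modularity optimization can split
one biological population across clusters, a correction step follows:

1. per cluster, select the top ``top_n`` marker genes with per-cell
   average UMI strictly above ``min_avg_umi``, ranked by the gene's
   expression **specificity score** — its cluster-mean UMI divided by the
   sum of its cluster means across all clusters (each gene's scores sum
   to 1);
2. combine the per-cluster marker lists into one union;
3. correlate every pair of cluster mean-UMI profiles over that union and,
   while any pair correlates above ``corr_threshold`` (default 0.8),
   merge the highest-correlated pair and recompute profiles, markers and
   correlations.

Merges are recorded in a replayable provenance; final labels are
renumbered 0..k−1 by descending cluster size. Annotation assigns each
cluster the geneset with the highest mean z-score signature and reports
one-vs-rest Wilcoxon marker tests.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .differential import DEResult, de_test
from .errors import ConfigError, IdentifierError
from .io import ExpressionMatrix, GeneSetCollection, logger
from .signatures import SignatureScoreTable, geneset_group_zscore, group_mean_matrix
from .trajectory import run_pca


@dataclass
class ClusterAssignment:
    """Observation → cluster labels plus a replayable merge provenance.

    ``labels`` maps every observation to an integer cluster id, contiguous
    0..k−1 in order of descending cluster size. ``provenance`` holds the
    pre-merge labels, the ordered list of merges performed (cluster-id
    pairs with the correlation that triggered them), and the final
    renumbering map, so the pre-merge state can be reconstructed exactly.
    """

    labels: pd.Series
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        observed = sorted(set(self.labels))
        if observed != list(range(self.k)):
            raise ValueError(f"cluster ids must be contiguous 0..{self.k - 1}, got {observed}")

    def cluster_obs(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


@dataclass
class ClusterProfile:
    """Per-cluster average raw UMI per cell, genes × clusters."""

    mean_umi: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if list(self.mean_umi.columns) != list(self.n_cells.index):
            raise ValueError("profile columns and n_cells index disagree")


@dataclass
class SpecificityTable:
    """Gene × cluster expression specificity scores in [0, 1].

    Each gene's scores sum to 1 across clusters; genes with zero mean in
    every cluster have an all-zero row.
    """

    spec: pd.DataFrame


def _renumber_by_size(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Map arbitrary labels to 0..k−1 by descending size (ties: old id)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = sorted(zip(-counts, ids))
    mapping = {int(old): new for new, (_, old) in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels]), mapping


def cluster_cells(
    m: ExpressionMatrix,
    n_pcs: int = 100,
    n_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
) -> ClusterAssignment:
    """Louvain clustering on a kNN graph in PC space.

    Expects a QC-filtered, normalized, log-transformed matrix. PCs are
    computed on centered log expression (no per-gene scaling); the kNN
    graph is Euclidean in PC space with unweighted, symmetrized edges.
    Deterministic for a fixed seed.
    """
    if m.layer_tag != "log":
        raise ConfigError(f"cluster_cells expects a log-layer matrix, got {m.layer_tag!r}")
    if n_neighbors >= m.n_obs:
        raise ConfigError(f"n_neighbors={n_neighbors} must be below the cell count {m.n_obs}")
    max_pcs = min(m.n_obs - 1, m.n_genes)
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds matrix limits; truncated to {max_pcs}", stacklevel=2)
        n_pcs = max_pcs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank truncation inside run_pca is fine here
        pcs = run_pca(m, n_components=n_pcs, center=True).scores.to_numpy()

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {
        (min(i, j), max(i, j))
        for i, row in enumerate(idx)
        for j in row[1:]  # drop self
    }
    graph = igraph.Graph(n=m.n_obs, edges=sorted(edges), directed=False)
    state = random.getstate()
    try:
        random.seed(seed)  # python-igraph draws from Python's random module
        membership = graph.community_multilevel(resolution=resolution).membership
    finally:
        random.setstate(state)
    labels, _ = _renumber_by_size(np.asarray(membership))
    k = int(labels.max()) + 1
    logger.info("clustering.cluster_cells: %d cells, n_pcs=%d, n_neighbors=%d, "
                "resolution=%g -> %d clusters", m.n_obs, n_pcs, n_neighbors, resolution, k)
    return ClusterAssignment(
        labels=pd.Series(labels, index=m.obs_ids, name="cluster"),
        k=k,
        provenance={"merges": [], "pre_merge_labels": {o: int(l) for o, l in zip(m.obs_ids, labels)}},
    )


def cluster_profile(m_raw: ExpressionMatrix, assignment: ClusterAssignment) -> ClusterProfile:
    """Per-cluster mean raw UMI per cell."""
    if m_raw.layer_tag != "raw":
        raise ConfigError("cluster_profile expects the raw layer")
    labels = assignment.labels.reindex(m_raw.obs_ids)
    if labels.isna().any():
        raise IdentifierError("assignment is missing labels for some observations")
    cols, sizes = {}, {}
    for c in range(assignment.k):
        mask = (labels == c).to_numpy()
        cols[c] = m_raw.values[:, mask].mean(axis=1)
        sizes[c] = int(mask.sum())
    return ClusterProfile(
        mean_umi=pd.DataFrame(cols, index=m_raw.gene_ids),
        n_cells=pd.Series(sizes, name="n_cells"),
    )


def specificity_scores(profile: ClusterProfile) -> SpecificityTable:
    """Normalize each gene's cluster means to sum to 1 across clusters."""
    if profile.mean_umi.shape[1] < 2:
        raise ConfigError("specificity scores need at least 2 clusters")
    values = profile.mean_umi.to_numpy(dtype=float)
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        spec = np.where(totals > 0, values / totals, 0.0)
    return SpecificityTable(
        spec=pd.DataFrame(spec, index=profile.mean_umi.index, columns=profile.mean_umi.columns)
    )


def select_cluster_markers(
    profile: ClusterProfile,
    spec: SpecificityTable,
    top_n: int = 100,
    min_avg_umi: float = 0.2,
) -> tuple[dict[int, list[str]], list[str]]:
    """Top specificity-ranked marker genes per cluster, and their union.

    Per cluster: genes with that cluster's mean UMI strictly above
    ``min_avg_umi``, ranked by descending specificity score (ties broken
    by lexicographically smaller gene id), truncated to ``top_n``.
    """
    if list(profile.mean_umi.columns) != list(spec.spec.columns) or not profile.mean_umi.index.equals(
        spec.spec.index
    ):
        raise ConfigError("profile and specificity table must share gene/cluster indexes")
    per_cluster: dict[int, list[str]] = {}
    for c in profile.mean_umi.columns:
        eligible = profile.mean_umi.index[profile.mean_umi[c] > min_avg_umi]
        if eligible.empty:
            raise ConfigError(f"cluster {c}: no genes with average UMI > {min_avg_umi}")
        ranked = sorted(eligible, key=lambda g: (-spec.spec.at[g, c], g))
        per_cluster[int(c)] = ranked[:top_n]
    union = sorted(set().union(*per_cluster.values()))
    return per_cluster, union


def _pair_correlations(
    profile: ClusterProfile, marker_union: list[str], log_scale: bool
) -> pd.DataFrame:
    values = profile.mean_umi.loc[marker_union].to_numpy(dtype=float)
    if log_scale:
        values = np.log1p(values)
    corr = np.corrcoef(values.T)
    return pd.DataFrame(corr, index=profile.mean_umi.columns, columns=profile.mean_umi.columns)


def _merge_profile(profile: ClusterProfile, keep: int, absorb: int) -> ClusterProfile:
    """Exact merged profile: cell-count-weighted mean of the two clusters."""
    n_keep, n_absorb = profile.n_cells[keep], profile.n_cells[absorb]
    merged = (
        profile.mean_umi[keep] * n_keep + profile.mean_umi[absorb] * n_absorb
    ) / (n_keep + n_absorb)
    mean_umi = profile.mean_umi.drop(columns=[absorb]).copy()
    mean_umi[keep] = merged
    n_cells = profile.n_cells.drop(absorb).copy()
    n_cells[keep] = n_keep + n_absorb
    order = [c for c in profile.mean_umi.columns if c != absorb]
    return ClusterProfile(mean_umi=mean_umi[order], n_cells=n_cells[order])


def merge_correlated_clusters(
    assignment: ClusterAssignment,
    profile: ClusterProfile,
    marker_union: list[str] | None = None,
    corr_threshold: float = 0.8,
    top_n: int = 100,
    min_avg_umi: float = 0.2,
    recompute_markers: bool = True,
    log_scale: bool = False,
) -> ClusterAssignment:
    """Iteratively merge cluster pairs whose marker-profile correlation
    exceeds ``corr_threshold``.

    Pearson correlation between cluster mean-UMI profiles is computed over
    the marker union. While any pair exceeds the threshold, the
    highest-correlated pair is merged and profiles, markers (when
    ``recompute_markers``) and correlations are recomputed. With
    ``marker_union`` given and ``recompute_markers`` False, the initial
    union is reused throughout. Labels are renumbered by descending size;
    every merge is recorded in the provenance.
    """
    if marker_union is not None:
        missing = set(marker_union) - set(profile.mean_umi.index)
        if missing:
            raise ConfigError(f"marker genes absent from the profile: {sorted(missing)[:5]}")
        if not marker_union:
            raise ConfigError("marker_union is empty")

    labels = assignment.labels.to_numpy().copy()
    pre_merge = {o: int(l) for o, l in zip(assignment.labels.index, labels)}
    merges: list[dict] = []
    current = ClusterProfile(mean_umi=profile.mean_umi.copy(), n_cells=profile.n_cells.copy())

    while current.mean_umi.shape[1] >= 2:
        if recompute_markers or marker_union is None:
            _, union = select_cluster_markers(
                current, specificity_scores(current), top_n=top_n, min_avg_umi=min_avg_umi
            )
        else:
            union = list(marker_union)
        corr = _pair_correlations(current, union, log_scale)
        np.fill_diagonal(corr.to_numpy(), -np.inf)
        flat = corr.stack()
        best_pair = flat.idxmax()
        best_corr = float(flat.max())
        if not best_corr > corr_threshold:
            break
        keep, absorb = sorted(int(c) for c in best_pair)
        merges.append({"pair": [keep, absorb], "into": keep, "correlation": best_corr})
        logger.info("clustering.merge: clusters %d and %d correlate %.3f > %g; merged",
                    keep, absorb, best_corr, corr_threshold)
        labels[labels == absorb] = keep
        current = _merge_profile(current, keep, absorb)

    final, renumber = _renumber_by_size(labels)
    return ClusterAssignment(
        labels=pd.Series(final, index=assignment.labels.index, name="cluster"),
        k=int(final.max()) + 1,
        provenance={
            "pre_merge_labels": pre_merge,
            "merges": merges,
            "renumber_map": {int(k): int(v) for k, v in renumber.items()},
        },
    )


def replay_merges(pre_merge_labels: pd.Series, provenance: dict) -> pd.Series:
    """Re-apply a recorded merge history to pre-merge labels.

    Reproduces the final labels of :func:`merge_correlated_clusters`
    exactly; used to audit provenance.
    """
    labels = pre_merge_labels.to_numpy().copy()
    for record in provenance["merges"]:
        pair = record["pair"]
        labels[labels == pair[1]] = record["into"]
    renumber = {int(k): int(v) for k, v in provenance.get("renumber_map", {}).items()}
    if renumber:
        labels = np.array([renumber[int(l)] for l in labels])
    return pd.Series(labels, index=pre_merge_labels.index, name="cluster")


def annotate_clusters(
    m: ExpressionMatrix,
    assignment: ClusterAssignment,
    genesets: GeneSetCollection,
    min_cells: int = 3,
    run_marker_test: bool = True,
) -> dict:
    """Annotate clusters by geneset signatures and Wilcoxon marker tests.

    Expects the CPM layer. Per cluster this computes (a) a one-vs-rest
    two-sided Wilcoxon rank-sum marker test with BH FDR and (b) geneset
    mean z-scores with clusters as groups; the annotation is the
    argmax-scoring geneset. Clusters below ``min_cells`` are skipped with
    a warning. Returns ``{"annotation", "signature_scores", "markers"}``.
    """
    if m.layer_tag != "cpm":
        raise ConfigError(f"annotate_clusters expects the CPM layer, got {m.layer_tag!r}")
    if not genesets.sets:
        raise ConfigError("empty geneset collection")
    labels = assignment.labels.reindex(m.obs_ids)
    if labels.isna().any():
        raise IdentifierError("assignment is missing labels for some observations")

    usable = [c for c in range(assignment.k) if (labels == c).sum() >= min_cells]
    for c in range(assignment.k):
        if c not in usable:
            warnings.warn(f"cluster {c} has fewer than {min_cells} cells; annotation skipped",
                          stacklevel=2)
    if len(usable) < 2:
        raise ConfigError("need at least 2 annotatable clusters")

    keep_obs = [o for o in m.obs_ids if labels[o] in usable]
    sub = m.subset_obs(keep_obs)
    groups = labels.loc[keep_obs].astype(int).astype(str)
    group_means = group_mean_matrix(sub, groups=groups)
    score_table: SignatureScoreTable = geneset_group_zscore(group_means, genesets)
    annotation = pd.Series(
        {int(c): score_table.scores[c].idxmax() for c in score_table.scores.columns},
        name="annotation",
    )

    markers: dict[int, DEResult] = {}
    if run_marker_test:
        for c in usable:
            in_c = [o for o in keep_obs if labels[o] == c]
            rest = [o for o in keep_obs if labels[o] != c]
            markers[c] = de_test(sub, in_c, rest, mode="wilcoxon",
                                 comparison=f"cluster{c}_vs_rest")
    return {"annotation": annotation, "signature_scores": score_table, "markers": markers}
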