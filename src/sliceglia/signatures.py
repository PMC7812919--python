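"""Row normalization and geneset signature scoring.

Two readouts drive all heatmap-style analyses:

* **robust center/scale** — per gene (row), subtract the row median and
  divide by the row median absolute deviation (raw MAD, no consistency
  constant);
* **geneset mean z-score** — per gene, z-score its per-group means across
  groups; per geneset and group, average the member genes' z-scores.

Marker genesets for CNS cell types are derived from a gene × cell-type
score table by a strict grand-mean cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import ExpressionMatrix, GeneSetCollection, logger


@dataclass
class SignatureScoreTable:
    """Geneset × group mean z-scores plus the per-set count of genes used."""

    scores: pd.DataFrame
    n_genes_used: pd.Series

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="geneset")


def robust_center_scale_values(values: np.ndarray) -> np.ndarray:
    """Row-wise (x − median) / MAD on a plain array.

    MAD is the raw median absolute deviation. Degenerate rows fall back to
    the row sample standard deviation (ddof=1), then to 1.0, so outputs are
    always finite; a constant row maps to all zeros.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=1, keepdims=True)
    centered = values - med
    mad = np.median(np.abs(centered), axis=1)
    sd = values.std(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(values.shape[0])
    divisor = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    n_fallback = int((mad == 0).sum())
    if n_fallback:
        logger.info("signatures.robust_center_scale: %d rows with MAD=0 used the SD/1.0 fallback",
                    n_fallback)
    return centered / divisor[:, None]


def robust_center_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """RobustCenterScale row normalization of an expression matrix."""
    if m.n_obs < 2:
        raise ConfigError("robust_center_scale needs at least 2 observations")
    return m.with_values(robust_center_scale_values(m.values), "centered")


def group_mean_matrix(m: ExpressionMatrix, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-group mean expression, genes × groups.

    *groups* maps observation id to group label; defaults to the matrix's
    ``group`` annotation column. Group column order follows first
    appearance in the observation order.
    """
    if groups is None:
        if "group" not in m.obs_annotation.columns:
            raise ConfigError("matrix has no 'group' annotation; pass groups explicitly")
        groups = m.obs_annotation["group"]
    groups = groups.reindex(m.obs_ids)
    if groups.isna().any():
        raise ConfigError("group labels missing for some observations")
    order = list(dict.fromkeys(groups))
    cols = {
        g: m.values[:, (groups == g).to_numpy()].mean(axis=1) for g in order
    }
    return pd.DataFrame(cols, index=m.gene_ids)


def geneset_group_zscore(
    group_means: pd.DataFrame, genesets: GeneSetCollection
) -> SignatureScoreTable:
    """Mean z-score per geneset and group.

    Each gene's per-group means are z-scored across groups (sample SD,
    ddof=1); the geneset score for a group is the mean z of the member
    genes found in the matrix. Member genes absent from the matrix are
    skipped and counted; a geneset with no gene present raises, naming
    the set. Genes constant across groups contribute z = 0.
    """
    if group_means.shape[1] < 2:
        raise ConfigError("geneset_group_zscore needs at least 2 groups")
    values = group_means.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    z = pd.DataFrame(z, index=group_means.index, columns=group_means.columns)

    present = set(group_means.index)
    rows, counts = {}, {}
    for set_id, genes in genesets.sets.items():
        used = [g for g in genes if g in present]
        if not used:
            raise ConfigError(f"geneset {set_id!r} has no genes present in the matrix")
        rows[set_id] = z.loc[used].mean(axis=0)
        counts[set_id] = len(used)
        if len(used) < len(genes):
            logger.info("signatures.geneset_group_zscore: set %s used %d of %d genes",
                        set_id, len(used), len(genes))
    scores = pd.DataFrame(rows).T
    scores.columns = group_means.columns
    return SignatureScoreTable(scores=scores, n_genes_used=pd.Series(counts, name="n_genes_used"))


def derive_marker_genesets(
    score_table: pd.DataFrame, cutoff: float = 4.0
) -> GeneSetCollection:
    """Cell-type marker genesets by a strict grand-mean cutoff.

    For each cell-type column, the derived set is the genes scoring
    strictly above *cutoff*. A gene passing in several columns belongs to
    every corresponding set. Cell types with no passing gene are omitted
    with a warning.
    """
    sets: dict[str, list[str]] = {}
    for celltype in score_table.columns:
        passing = score_table.index[score_table[celltype] > cutoff].tolist()
        if not passing:
            warnings.warn(f"cell type {celltype!r}: no genes exceed {cutoff}; set omitted",
                          stacklevel=2)
            continue
        sets[str(celltype)] = [str(g) for g in passing]
    return GeneSetCollection(
        sets=sets, descriptions={s: f"markers with grand mean > {cutoff:g}" for s in sets}
    )
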