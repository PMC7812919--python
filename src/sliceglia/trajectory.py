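"""PCA and gene-versus-covariate ranking.

The ranking regresses each gene on a numeric per-observation covariate —
culture time in weeks, or a principal-component score — reporting the
Pearson correlation, its two-sided p-value (t-transform), the
Benjamini–Hochberg FDR, and a scaled effect size: the regression slope of
the robust-center-scaled expression on the covariate (MAD units per
covariate unit), which puts low- and high-expressed genes on a common
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError
from .io import ExpressionMatrix, logger
from .signatures import robust_center_scale_values
from .stats import bh_fdr


@dataclass
class PCResult:
    """Principal components of observation vectors.

    ``scores`` is observation × component, ``loadings`` gene × component,
    ``var_explained`` the per-component fraction of total variance.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive; signs are otherwise arbitrary.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    var_explained: np.ndarray


def run_pca(m: ExpressionMatrix, n_components: int, center: bool = True) -> PCResult:
    """SVD-based PCA on observation vectors of gene expression."""
    if m.n_obs < 2:
        raise ConfigError("run_pca needs at least 2 observations")
    x = m.values.T.astype(float)
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps)) if s.size else 0
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds matrix rank {rank}; truncating", stacklevel=2
        )
        n_components = rank
    # sign convention: largest-|loading| entry positive per component
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u = u * flip[None, :]
    vt = vt * flip[:, None]
    total_var = (s ** 2).sum()
    k = n_components
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCResult(
        scores=pd.DataFrame((u[:, :k] * s[:k]), index=m.obs_ids, columns=comp_names),
        loadings=pd.DataFrame(vt[:k].T, index=m.gene_ids, columns=comp_names),
        var_explained=(s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k),
    )


def rank_genes_by_covariate(
    m: ExpressionMatrix,
    covariate: pd.Series | np.ndarray,
    p_cutoff: float | None = None,
    r_cutoff: float | None = None,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene Pearson correlation and scaled slope against a covariate.

    Returns a DataFrame indexed by gene with columns ``r``, ``p_value``,
    ``fdr``, ``slope_scaled``, ``direction``, ``tested`` and ``selected``.
    Selection applies the supplied cutoffs: significance (FDR if
    ``use_fdr`` else p) strictly below ``p_cutoff``, and |r| strictly
    above ``r_cutoff`` when given. Genes constant across observations are
    excluded from testing and flagged ``tested=False``.
    """
    if isinstance(covariate, pd.Series):
        covariate = covariate.reindex(m.obs_ids).to_numpy()
    covariate = np.asarray(covariate, dtype=float)
    if covariate.shape != (m.n_obs,):
        raise ConfigError("covariate length does not match the number of observations")
    if len(np.unique(covariate)) < 3:
        raise ConfigError("covariate needs at least 3 distinct values")

    x = m.values.astype(float)
    n = m.n_obs
    gene_sd = x.std(axis=1)
    tested = gene_sd > 0
    n_constant = int((~tested).sum())
    if n_constant:
        logger.info("trajectory.rank_genes_by_covariate: %d constant genes excluded", n_constant)

    t_c = covariate - covariate.mean()
    var_t = (t_c ** 2).mean()
    xc = x - x.mean(axis=1, keepdims=True)
    cov_xt = (xc * t_c[None, :]).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov_xt / (gene_sd * np.sqrt(var_t))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    p = 2.0 * scipy.stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    z = robust_center_scale_values(x)
    slope_scaled = (z - z.mean(axis=1, keepdims=True)) @ t_c / (t_c @ t_c)

    fdr = np.full(m.n_genes, np.nan)
    fdr[tested] = bh_fdr(p[tested])
    result = pd.DataFrame(
        {
            "r": np.where(tested, r, np.nan),
            "p_value": np.where(tested, p, np.nan),
            "fdr": fdr,
            "slope_scaled": slope_scaled,
            "direction": np.where(r > 0, "up", "down"),
            "tested": tested,
        },
        index=m.gene_ids,
    )
    result.loc[~tested, "direction"] = "none"

    selected = tested.copy()
    sig = result["fdr"] if use_fdr else result["p_value"]
    if p_cutoff is not None:
        selected &= (sig < p_cutoff).to_numpy()
    if r_cutoff is not None:
        selected &= (result["r"].abs() > r_cutoff).fillna(False).to_numpy()
    result["selected"] = selected
    return result


def write_ranking(ranking: pd.DataFrame, path) -> None:
    """Ranking TSV sorted by ascending p-value (untested genes last)."""
    ranking.sort_values("p_value", na_position="last").to_csv(path, sep="\t", index_label="gene_id")
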