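"""Cell-level quality filtering and count normalization.

A cell is discarded when mitochondrial genes occupy more than 5% of its
total UMI, when it has fewer than 400 detected genes (count ≥ 1), or when
its total UMI count exceeds 30,000 — boundary semantics are strict in
exactly that sense: a cell at mito fraction 0.05, at 400 genes, or at
30,000 UMI is retained. Normalization rescales each cell to a fixed total
(counts per million by default), optionally followed by log2(x + 1).

Bulk and panel matrices bypass :func:`filter_cells`; :func:`normalize_counts`
applies to them under the same contract.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MITO_PREFIX, ExpressionMatrix, logger


@dataclass
class QCReport:
    """Per-rule discard counts; each cell is attributed to the first rule it
    fails, evaluated in the order mito → min_genes → max_umi."""

    n_input: int
    n_discarded_mito: int = 0
    n_discarded_genes: int = 0
    n_discarded_umi: int = 0
    kept_ids: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def filter_cells(
    m: ExpressionMatrix,
    mito_max_frac: float = 0.05,
    min_genes: int = 400,
    max_umi: int = 30000,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop cells failing any QC rule; the gene set is left unchanged.

    Rules (a cell is discarded when): mitochondrial fraction of total UMI
    strictly exceeds ``mito_max_frac``; number of detected genes (count ≥ 1)
    is strictly below ``min_genes``; total UMI strictly exceeds ``max_umi``.
    """
    if m.layer_tag != "raw":
        raise ValueError(f"filter_cells expects the raw layer, got {m.layer_tag!r}")
    values = m.values
    totals = values.sum(axis=0)
    detected = (values >= 1).sum(axis=0)
    mito = m.mito_mask(mito_prefix)
    if mito.any():
        with np.errstate(invalid="ignore"):
            mito_frac = np.where(totals > 0, values[mito].sum(axis=0) / np.maximum(totals, 1), 0.0)
        fails_mito = mito_frac > mito_max_frac
    else:
        warnings.warn(
            f"no genes with prefix {mito_prefix!r}; mitochondrial QC rule skipped", stacklevel=2
        )
        logger.warning("qc.filter_cells: no mitochondrial genes found; mito rule skipped")
        fails_mito = np.zeros(m.n_obs, dtype=bool)
    fails_genes = detected < min_genes
    fails_umi = totals > max_umi

    report = QCReport(n_input=m.n_obs)
    keep = np.ones(m.n_obs, dtype=bool)
    for j in range(m.n_obs):
        if fails_mito[j]:
            report.n_discarded_mito += 1
            keep[j] = False
        elif fails_genes[j]:
            report.n_discarded_genes += 1
            keep[j] = False
        elif fails_umi[j]:
            report.n_discarded_umi += 1
            keep[j] = False
    report.kept_ids = [o for o, k in zip(m.obs_ids, keep) if k]

    logger.info(
        "qc.filter_cells: mito>%g discarded %d, detected<%d discarded %d, "
        "umi>%d discarded %d; kept %d of %d cells",
        mito_max_frac, report.n_discarded_mito, min_genes, report.n_discarded_genes,
        max_umi, report.n_discarded_umi, report.n_kept, report.n_input,
    )
    if not report.kept_ids:
        warnings.warn("all cells discarded by QC; returning an empty matrix", stacklevel=2)
    return m.subset_obs(report.kept_ids), report


def normalize_counts(
    m: ExpressionMatrix, scale: float = 1e6, log_transform: bool = False
) -> ExpressionMatrix:
    """Rescale every observation to total ``scale`` (CPM for 1e6).

    With ``log_transform``, returns log2(x + 1) of the rescaled values
    (layer ``log``); otherwise layer ``cpm``. Raises on zero-total
    observations, naming the first offender.
    """
    totals = m.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"observation {m.obs_ids[zero[0]]!r} has zero total count")
    values = m.values / totals[None, :] * scale
    tag = "cpm"
    if log_transform:
        values = np.log2(values + 1.0)
        tag = "log"
    logger.info("qc.normalize_counts: scaled %d observations to total %g (log=%s)",
                m.n_obs, scale, log_transform)
    return m.with_values(values, tag)
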