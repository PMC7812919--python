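"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def gene_family_percent(gene_ids, prefixes: tuple[str, ...]) -> int:
    """Integer-rounded percentage of genes belonging to the named families.

    Family membership is by identifier prefix (e.g. ``("Rpl", "Rps")`` for
    the large/small ribosomal protein families).
    """
    genes = list(gene_ids)
    if not genes:
        raise ValueError("empty gene list")
    n_match = sum(any(g.startswith(p) for p in prefixes) for g in genes)
    return round(100 * n_match / len(genes))


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up procedure)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    return multipletests(p_values, method="fdr_bh")[1]
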