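"""Core data model and readers/writers for the formats the pipeline touches.

Orientation convention: genes are rows, observations (cells or samples) are
columns, in memory and in every file dialect. Gene identifiers are matched
case-sensitively by exact string equality.

Supported formats:

* dense TSV — header row of observation ids, first column of gene ids;
* MatrixMarket coordinate MTX (1-based indices) with plain-text gene and
  observation label files, one identifier per line;
* GMT genesets — one set per line: set id, description, member genes,
  tab-separated;
* annotation TSV — first column observation id, optional columns
  ``group``, ``timepoint``, ``batch``, ``treatment``;
* YAML analysis configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .errors import ConfigError, FormatError, IdentifierError

logger = logging.getLogger("sliceglia")

#: Recognized layer tags, in order of the transformations that produce them.
LAYER_TAGS = ("raw", "cpm", "log", "centered")

#: Prefix identifying mitochondrial genes (mouse convention).
MITO_PREFIX = "mt-"

ANNOTATION_FIELDS = ("group", "timepoint", "batch", "treatment")


@dataclass
class ExpressionMatrix:
    """A gene × observation expression matrix with identifiers and annotation.

    Parameters
    ----------
    values
        Dense non-negative matrix, genes as rows. The ``raw`` layer must
        contain only non-negative integers (UMI or read counts).
    gene_ids, obs_ids
        Unique row and column identifiers.
    obs_annotation
        Per-observation fields indexed by ``obs_ids``. Missing fields are
        simply absent columns; nothing is imputed.
    layer_tag
        Which transformation produced ``values``; one of ``raw``, ``cpm``,
        ``log``, ``centered``.
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    obs_annotation: pd.DataFrame = None  # type: ignore[assignment]
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise IdentifierError(f"duplicate gene identifiers: {sorted(dupes)[:5]}")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            dupes = _duplicates(self.obs_ids)
            raise IdentifierError(f"duplicate observation identifiers: {sorted(dupes)[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.obs_ids)} observations"
            )
        if self.layer_tag not in LAYER_TAGS:
            raise ConfigError(f"unknown layer_tag {self.layer_tag!r}; expected one of {LAYER_TAGS}")
        if self.layer_tag == "raw":
            if np.any(self.values < 0):
                raise ValueError("raw layer contains negative entries")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("raw layer contains non-integer entries")
        if self.obs_annotation is None:
            self.obs_annotation = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        else:
            self.obs_annotation = self.obs_annotation.reindex(self.obs_ids)
            self.obs_annotation.index.name = "obs_id"

    # -- basic accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame view, genes as rows."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Positions of *genes* in ``gene_ids``; raises on unknown ids."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise IdentifierError(f"unknown gene identifier {exc.args[0]!r}") from None

    def subset_obs(self, keep_ids: Sequence[str]) -> "ExpressionMatrix":
        """Matrix restricted to *keep_ids*, preserving their given order."""
        lookup = {o: i for i, o in enumerate(self.obs_ids)}
        idx = [lookup[o] for o in keep_ids]
        return ExpressionMatrix(
            values=self.values[:, idx].copy(),
            gene_ids=list(self.gene_ids),
            obs_ids=list(keep_ids),
            obs_annotation=self.obs_annotation.loc[list(keep_ids)].copy(),
            layer_tag=self.layer_tag,
        )

    def with_values(self, values: np.ndarray, layer_tag: str) -> "ExpressionMatrix":
        """Same identifiers and annotation, new value layer."""
        return ExpressionMatrix(
            values=values,
            gene_ids=list(self.gene_ids),
            obs_ids=list(self.obs_ids),
            obs_annotation=self.obs_annotation.copy(),
            layer_tag=layer_tag,
        )

    def mito_mask(self, prefix: str = MITO_PREFIX) -> np.ndarray:
        """Boolean mask over genes flagging the mitochondrial block."""
        return np.array([g.startswith(prefix) for g in self.gene_ids], dtype=bool)


@dataclass
class GeneSetCollection:
    """Named genesets: ``set_id -> ordered unique gene list``."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, genes in self.sets.items():
            if not genes:
                raise FormatError(f"geneset {set_id!r} is empty")
            deduped = list(dict.fromkeys(genes))
            self.sets[set_id] = deduped
        for set_id in self.sets:
            self.descriptions.setdefault(set_id, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]

    def subset(self, set_ids: Iterable[str]) -> "GeneSetCollection":
        ids = list(set_ids)
        return GeneSetCollection(
            sets={s: list(self.sets[s]) for s in ids},
            descriptions={s: self.descriptions.get(s, "") for s in ids},
        )


@dataclass
class AnalysisConfig:
    """All thresholds and parameters used by the pipeline stages.

    Defaults are the values the analysis applies throughout: mitochondrial
    fraction > 5% discards a cell, < 400 detected genes discards a cell,
    > 30,000 total UMI discards a cell, counts-per-million normalization,
    DEG thresholds of |fold change| > 1.5 at p or FDR < 0.05, top 100
    specificity-ranked marker genes with cluster average UMI > 0.2, cluster
    merge at profile correlation > 0.8, and a 100-PC / 20-neighbor /
    resolution 0.5 Louvain clustering.
    """

    mito_max_frac: float = 0.05
    min_genes: int = 400
    max_umi: int = 30000
    cpm_scale: float = 1e6
    fc_threshold: float = 1.5
    alpha: float = 0.05
    alpha_is_fdr: bool = True
    top_n_markers: int = 100
    min_avg_umi: float = 0.2
    merge_corr_threshold: float = 0.8
    n_pcs: int = 100
    n_neighbors: int = 20
    resolution: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("mito_max_frac", "min_genes", "max_umi", "cpm_scale",
                     "fc_threshold", "top_n_markers", "min_avg_umi",
                     "merge_corr_threshold", "n_pcs", "n_neighbors", "resolution"):
            if getattr(self, name) <= 0 and name != "min_avg_umi":
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.min_avg_umi < 0:
            raise ConfigError("min_avg_umi must be non-negative")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **updates) -> "AnalysisConfig":
        return dataclasses.replace(self, **updates)


# -- matrix readers/writers ----------------------------------------------


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    obs_path: str | Path | None = None,
    layer_tag: str = "raw",
) -> ExpressionMatrix:
    """Read a gene × observation matrix from dense TSV or MatrixMarket MTX.

    For MTX, *genes_path* and *obs_path* name the row/column label files
    (one identifier per line); sparse zeros are materialized as explicit 0.
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.suffix == ".mtx" else "tsv"
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy()
        return ExpressionMatrix(
            values=values,
            gene_ids=[str(g) for g in frame.index],
            obs_ids=[str(o) for o in frame.columns],
            layer_tag=layer_tag,
        )
    if format == "mtx":
        if genes_path is None or obs_path is None:
            raise ConfigError("MTX input requires genes_path and obs_path label files")
        try:
            sparse = scipy.io.mmread(path)
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {path}: {exc}") from exc
        values = np.asarray(sparse.todense() if scipy.sparse.issparse(sparse) else sparse)
        gene_ids = _read_labels(genes_path)
        obs_ids = _read_labels(obs_path)
        if values.shape != (len(gene_ids), len(obs_ids)):
            raise FormatError(
                f"MTX declares shape {values.shape} but label files list "
                f"{len(gene_ids)} genes and {len(obs_ids)} observations"
            )
        return ExpressionMatrix(values=values, gene_ids=gene_ids, obs_ids=obs_ids, layer_tag=layer_tag)
    raise ConfigError(f"unknown matrix format {format!r}; expected 'tsv' or 'mtx'")


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
    genes_path: str | Path | None = None,
    obs_path: str | Path | None = None,
) -> None:
    """Write *m* as dense TSV or MTX + label files (the read counterpart)."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
        return
    if format == "mtx":
        if genes_path is None or obs_path is None:
            raise ConfigError("MTX output requires genes_path and obs_path")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        _write_labels(genes_path, m.gene_ids)
        _write_labels(obs_path, m.obs_ids)
        return
    raise ConfigError(f"unknown matrix format {format!r}")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read an observation annotation TSV (first column: observation id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.index.name = "obs_id"
    if frame.index.duplicated().any():
        raise IdentifierError("duplicate observation ids in annotation table")
    return frame


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="obs_id")


def attach_annotation(m: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Attach (a subset of) an annotation table to the matrix observations."""
    missing = set(m.obs_ids) - set(annotation.index)
    if missing:
        raise IdentifierError(f"annotation missing observations: {sorted(missing)[:5]}")
    out = m.with_values(m.values.copy(), m.layer_tag)
    out.obs_annotation = annotation.loc[m.obs_ids].copy()
    return out


# -- genesets -------------------------------------------------------------


def read_genesets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set id, description and ≥1 gene "
                    f"({len(fields)} fields found)"
                )
            set_id, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: geneset {set_id!r} lists no genes")
            if set_id in sets:
                raise IdentifierError(f"{path}:{lineno}: duplicate geneset id {set_id!r}")
            sets[set_id] = genes
            descriptions[set_id] = description
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_genesets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, genes in collection.sets.items():
            desc = collection.descriptions.get(set_id, "")
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


# -- helpers --------------------------------------------------------------


def _read_labels(path: str | Path) -> list[str]:
    with open(path) as fh:
        labels = [line.strip() for line in fh if line.strip()]
    if not labels:
        raise FormatError(f"{path}: empty label file")
    return labels


def _write_labels(path: str | Path, labels: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for label in labels:
            fh.write(f"{label}\n")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for item in items:
        if item in seen:
            dupes.add(item)
        seen.add(item)
    return dupes
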