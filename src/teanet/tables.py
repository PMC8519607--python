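"""Typed containers and plain-text I/O for metabolite/gene tables and networks.

The package works on two matrices:

* :class:`AbundanceMatrix` — samples x metabolite features, strictly positive
  relative intensities from an untargeted LC-MS run, with per-sample metadata
  (accession, variety, optional group, QC flag) and per-feature metadata
  (identification tier, chemical class).
* :class:`ExpressionMatrix` — samples x genes, non-negative FPKM-like values.

Everything is read and written as delimited text (TSV by default) so that
inputs and outputs stay inspectable and diffable.  Missing intensities are
kept as missing (NaN), never silently replaced by zero; downstream
correlation uses pairwise-complete observations.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ParameterError, ValidationError

__all__ = [
    "AbundanceMatrix",
    "ExpressionMatrix",
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "read_expression_table",
    "write_expression_table",
    "write_network",
    "load_config",
]

#: identification tiers, mirroring standard-library/article/database evidence
IDENTIFICATION_TIERS = ("standard-aligned", "literature", "database")

_FLOAT_FMT = "%.12g"  # lossless enough for 12-significant-digit round trips


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dups}")


@dataclass
class AbundanceMatrix:
    """Samples x features intensity grid with sample and feature metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.  All
        entries must be finite and strictly positive, or NaN for missing.
    sample_meta
        DataFrame indexed by sample id.  An ``is_qc`` boolean column is
        required (created as all-False when the frame is omitted); other
        conventional columns are ``accession_id``, ``variety`` and ``group``.
    feature_meta
        DataFrame indexed by feature id; conventional columns are ``tier``
        (one of :data:`IDENTIFICATION_TIERS`) and ``chem_class``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "sample_id"
        self.values.columns.name = "feature_id"
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "feature")

        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.index.copy())
        self.sample_meta = self.sample_meta.copy()
        self.sample_meta.index = self.sample_meta.index.astype(str)
        self.sample_meta.index.name = "sample_id"
        missing = self.values.index.difference(self.sample_meta.index)
        if len(missing):
            raise ValidationError(f"samples without metadata: {missing.tolist()}")
        self.sample_meta = self.sample_meta.loc[self.values.index]
        if "is_qc" not in self.sample_meta.columns:
            self.sample_meta["is_qc"] = False
        qc = self.sample_meta["is_qc"]
        if qc.isna().any():
            raise ValidationError("is_qc must be defined for every sample")
        self.sample_meta["is_qc"] = qc.astype(bool)

        if self.feature_meta is None:
            self.feature_meta = pd.DataFrame(index=self.values.columns.copy())
        self.feature_meta = self.feature_meta.copy()
        self.feature_meta.index = self.feature_meta.index.astype(str)
        self.feature_meta.index.name = "feature_id"
        missing = self.values.columns.difference(self.feature_meta.index)
        if len(missing):
            raise ValidationError(f"features without metadata: {missing.tolist()}")
        self.feature_meta = self.feature_meta.loc[self.values.columns]

        arr = self.values.to_numpy()
        bad = ~(np.isnan(arr) | (np.isfinite(arr) & (arr > 0)))
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                (self.values.index[i], self.values.columns[j], arr[i, j])
                for i, j in zip(rows[:20], cols[:20])
            ]
            raise ValidationError(
                f"non-positive or non-finite intensities at (sample, feature, value): {cells}"
            )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def is_qc(self) -> pd.Series:
        return self.sample_meta["is_qc"]

    def biological(self) -> pd.DataFrame:
        """Intensity rows of non-QC (biological) samples."""
        return self.values.loc[~self.is_qc]

    def qc(self) -> pd.DataFrame:
        """Intensity rows of pooled-QC samples."""
        return self.values.loc[self.is_qc]

    def log10(self, biological_only: bool = False) -> pd.DataFrame:
        vals = self.biological() if biological_only else self.values
        return np.log10(vals)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_qc = int(self.is_qc.sum())
        return (
            f"AbundanceMatrix({self.values.shape[0]} samples"
            f" [{n_qc} QC] x {self.values.shape[1]} features)"
        )


@dataclass
class ExpressionMatrix:
    """Samples x genes grid of non-negative FPKM-like expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.values.index.name = "sample_id"
        self.values.columns.name = "gene_id"
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "gene")
        arr = self.values.to_numpy()
        bad = ~(np.isnan(arr) | (np.isfinite(arr) & (arr >= 0)))
        if bad.any():
            raise ValidationError("expression values must be finite and >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.values.shape[0]} samples x {self.values.shape[1]} genes)"


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _read_grid(path, delimiter: str, transpose: bool, what: str) -> pd.DataFrame:
    try:
        # pandas silently renames duplicate header names; check the raw header
        with open(path) as fh:
            header = fh.readline().rstrip("\r\n").split(delimiter)
        names = header[1:]
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate column id(s) in {what} table: {dups}")
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    except FormatError:
        raise
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"cannot parse {what} table {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_feature_table(
    path,
    meta_path=None,
    feature_meta_path=None,
    delimiter: str = "\t",
    transpose: bool = False,
) -> AbundanceMatrix:
    """Read an intensity table (samples in rows, features in columns).

    ``meta_path``/``feature_meta_path`` point to optional delimited metadata
    tables keyed by sample id and feature id.  ``transpose=True`` accepts the
    features-in-rows dialect.  Empty cells become missing values.
    """
    values = _read_grid(path, delimiter, transpose, "feature")
    _check_unique(values.index, "sample")
    _check_unique(values.columns, "feature")
    sample_meta = None
    if meta_path is not None:
        sample_meta = _read_grid(meta_path, delimiter, False, "sample metadata")
    feature_meta = None
    if feature_meta_path is not None:
        feature_meta = _read_grid(feature_meta_path, delimiter, False, "feature metadata")
    return AbundanceMatrix(values, sample_meta, feature_meta)


def write_feature_table(
    matrix: AbundanceMatrix,
    path,
    meta_path=None,
    feature_meta_path=None,
    delimiter: str = "\t",
) -> None:
    """Write an :class:`AbundanceMatrix` (and optionally its metadata) as text."""
    matrix.values.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)
    if meta_path is not None:
        matrix.sample_meta.to_csv(meta_path, sep=delimiter)
    if feature_meta_path is not None:
        matrix.feature_meta.to_csv(feature_meta_path, sep=delimiter)


def read_expression_table(path, delimiter: str = "\t", transpose: bool = False) -> ExpressionMatrix:
    return ExpressionMatrix(_read_grid(path, delimiter, transpose, "expression"))


def write_expression_table(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.values.to_csv(path, sep=delimiter, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("node_a", "node_b", "r", "q", "mr", "weight")


def _sorted_edges(graph: nx.Graph):
    edges = []
    for a, b, data in graph.edges(data=True):
        a, b = sorted((str(a), str(b)))
        edges.append((a, b, data))
    edges.sort(key=lambda e: (e[0], e[1]))
    return edges


def write_network(net, path, dialect: str = "tsv") -> None:
    """Export a co-occurrence network for Cytoscape or downstream scripts.

    Dialects: ``tsv`` (edge list with r/FDR/MR/weight columns), ``sif``
    (``a interacts b`` lines) and ``graphml`` (node ``kind`` plus all edge
    attributes).  Nodes and edges are emitted in lexicographic order so output
    is byte-stable.
    """
    graph = net.graph if hasattr(net, "graph") else net
    if dialect not in ("tsv", "sif", "graphml"):
        raise ParameterError(f"unknown network dialect: {dialect!r}")
    path = Path(path)
    edges = _sorted_edges(graph)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for a, b, data in edges:
                fh.write(
                    f"{a}\t{b}\t"
                    + "\t".join(_FLOAT_FMT % data.get(k, float("nan")) for k in ("r", "q", "mr", "weight"))
                    + "\n"
                )
    elif dialect == "sif":
        with open(path, "w") as fh:
            for a, b, _ in edges:
                fh.write(f"{a} interacts {b}\n")
    else:  # graphml
        out = nx.Graph()
        for node in sorted(graph.nodes, key=str):
            attrs = {k: v for k, v in graph.nodes[node].items()}
            attrs.setdefault("kind", "metabolite")
            out.add_node(str(node), **attrs)
        for a, b, data in edges:
            out.add_edge(a, b, **{k: float(data.get(k, float("nan"))) for k in ("r", "q", "mr", "weight")})
        nx.write_graphml(out, path)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis thresholds and modes, with field-standard defaults.

    Defaults: fold-change gate 2 (i.e. |log2FC| > 1), FDR gate 0.05,
    PCC gates 0.8 (metabolite-metabolite) / 0.4 (gene-metabolite), decay
    weight floor 0.01, QC correlation threshold 0.99.
    """

    fc_gate: float = 2.0
    fdr_gate: float = 0.05
    pcc_gate_metabolite: float = 0.8
    pcc_gate_gene: float = 0.4
    weight_floor: float = 0.01
    qc_pcc_threshold: float = 0.99
    mr_mode: str = "geometric_mean"
    dam_test: str = "welch"
    k_groups: int = 3
    pca_components: int = 2
    pca_scaling: str = "autoscale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mr_mode not in ("geometric_mean", "product"):
            raise ConfigError(f"mr_mode must be geometric_mean or product, got {self.mr_mode!r}")
        if self.dam_test not in ("welch", "wilcoxon"):
            raise ConfigError(f"dam_test must be welch or wilcoxon, got {self.dam_test!r}")
        if self.pca_scaling not in ("autoscale", "center-only"):
            raise ConfigError(f"pca_scaling must be autoscale or center-only, got {self.pca_scaling!r}")
        for key in ("fc_gate", "fdr_gate", "pcc_gate_metabolite", "pcc_gate_gene", "weight_floor"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"config key {key} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path=None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML run configuration; absent keys fall back to defaults.

    Unknown keys are rejected (naming them) rather than ignored, so typos in a
    threshold name cannot silently run the defaults.
    """
    doc: dict = {}
    if path is not None:
        text = Path(path).read_text() if not isinstance(path, _io.IOBase) else path.read()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config document must be a mapping")
        doc.update(loaded)
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    return RunConfig(**doc)
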