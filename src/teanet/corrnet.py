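"""Mutual-rank correlation networks for metabolites and genes.

Pipeline: all-pairs Pearson correlation (with t-based p-values and
Benjamini-Hochberg FDR over the batch of pairs) -> per-node partner ranks by
signed r, high to low -> mutual rank MR combining rank(A->B) and rank(B->A)
-> exponential decay edge weight ``exp(-(MR - 1) / 100)`` -> threshold-gated
undirected network.  Default gates keep an edge when FDR < 0.05, |r| above
the PCC gate (0.8 for metabolite-metabolite, 0.4 for gene-metabolite) and
weight >= 0.01.

Two MR conventions circulate: the product ``rank_ab * rank_ba`` and its
geometric mean ``sqrt(rank_ab * rank_ba)``.  The decay scale of 100 in the
weight function is calibrated for the geometric mean in the co-expression
literature, so that is the default; ``mode="product"`` gives the literal
product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    ParameterError,
    StructuralError,
)
from .tables import AbundanceMatrix, ExpressionMatrix

__all__ = [
    "pairwise_pcc",
    "corr_pvalue",
    "mutual_rank",
    "decay_weight",
    "mr_ceiling",
    "build_network",
    "gene_metabolite_network",
    "CoNetwork",
    "hubs",
    "components",
    "count_pairs_above",
]

MR_MODES = ("geometric_mean", "product")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def corr_pvalue(r, n):
    """Two-sided p-value for a Pearson r on n samples (Student t, n-2 df).

    ``t = r * sqrt((n - 2) / (1 - r^2))``; |r| = 1 maps to p = 0.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n)
    if np.any(n < 4):
        raise InsufficientDataError("p-values require at least 4 samples per pair")
    if np.any(np.abs(r) > 1 + 1e-12):
        raise DomainError("|r| must be <= 1")
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return p if p.ndim else float(p)


def _bh(p: np.ndarray) -> np.ndarray:
    # step-up BH with monotonicity, in input order (statsmodels-equivalent;
    # kept local to avoid importing the differential module here)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pairwise_pcc(
    values: pd.DataFrame,
    log_transform: bool = True,
    min_n: int = 4,
) -> pd.DataFrame:
    """All unordered-pair Pearson correlations with p and batch-BH q.

    Parameters
    ----------
    values
        Samples x nodes grid (strictly positive if ``log_transform``); NaN
        cells are treated as missing and handled by pairwise-complete
        deletion.
    log_transform
        Correlate log10 intensities (the package-wide convention for
        multiplicative LC-MS data).
    min_n
        Pairs with fewer complete observations are flagged untestable
        (``testable=False``, p = q = NaN) and excluded from the BH batch.

    Returns
    -------
    DataFrame with columns ``node_a, node_b, r, n_used, p, q, testable``,
    one row per unordered pair, ``node_a < node_b`` lexicographically.
    """
    df = pd.DataFrame(values)
    if log_transform:
        arr = df.to_numpy(dtype=float)
        if np.nanmin(arr) <= 0:
            raise DomainError("log transform requires strictly positive values")
        df = np.log10(df)
    # drop zero-variance columns: their correlation is undefined
    sd = df.std(axis=0, ddof=1, skipna=True)
    const = sd.index[(sd == 0) | sd.isna()].tolist()
    if const:
        warnings.warn(f"excluding zero-variance column(s): {const}", stacklevel=2)
        df = df.drop(columns=const)
    nodes = [str(c) for c in df.columns]
    if len(nodes) < 2:
        raise InsufficientDataError("need at least 2 non-constant columns")

    X = df.to_numpy(dtype=float)
    mask = np.isfinite(X)
    if mask.all():
        R = np.corrcoef(X, rowvar=False)
        N = np.full_like(R, X.shape[0], dtype=int)
    else:
        R = df.corr(method="pearson", min_periods=2).to_numpy()
        N = (mask.astype(int).T @ mask.astype(int))

    iu, ju = np.triu_indices(len(nodes), k=1)
    r = np.clip(R[iu, ju], -1.0, 1.0)
    n_used = N[iu, ju].astype(int)
    testable = (n_used >= min_n) & np.isfinite(r)
    p = np.full(len(r), np.nan)
    if testable.any():
        p[testable] = corr_pvalue(r[testable], n_used[testable])
    q = np.full(len(r), np.nan)
    if testable.any():
        q[testable] = _bh(p[testable])
    out = pd.DataFrame(
        {
            "node_a": [nodes[i] for i in iu],
            "node_b": [nodes[j] for j in ju],
            "r": r,
            "n_used": n_used,
            "p": p,
            "q": q,
            "testable": testable,
        }
    )
    swap = out["node_a"] > out["node_b"]
    out.loc[swap, ["node_a", "node_b"]] = out.loc[swap, ["node_b", "node_a"]].to_numpy()
    return out.sort_values(["node_a", "node_b"], ignore_index=True)


# ---------------------------------------------------------------------------
# mutual rank and decay weight
# ---------------------------------------------------------------------------

def decay_weight(mr):
    """Exponential decay edge weight ``w = exp(-(MR - 1) / 100)``.

    Maps MR in [1, inf) onto (0, 1], strictly decreasing; w = 1 iff MR = 1.
    """
    mr_arr = np.asarray(mr, dtype=float)
    if np.any(mr_arr < 1.0):
        raise DomainError("mutual rank must be >= 1")
    w = np.exp(-(mr_arr - 1.0) / 100.0)
    return w if w.ndim else float(w)


def mr_ceiling(weight_floor: float) -> float:
    """Largest MR whose decay weight still clears ``weight_floor``.

    Analytic inversion: ``w >= floor  <=>  MR <= 1 + 100 * ln(1 / floor)``;
    at the default floor 0.01 this is ``1 + 100 ln 100 ~ 461.52``.
    """
    if not (0.0 < weight_floor <= 1.0):
        raise ParameterError("weight_floor must be in (0, 1]")
    return 1.0 + 100.0 * np.log(1.0 / weight_floor)


def _corr_square(corr: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    nodes = sorted(set(corr["node_a"]) | set(corr["node_b"]))
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    R = np.full((k, k), np.nan)
    np.fill_diagonal(R, 1.0)
    seen = np.zeros((k, k), dtype=bool)
    for a, b, r in zip(corr["node_a"], corr["node_b"], corr["r"]):
        i, j = idx[a], idx[b]
        if i == j:
            raise StructuralError(f"self-pair in correlation set: {a}")
        if seen[i, j]:
            raise StructuralError(f"duplicate pair: ({a}, {b})")
        seen[i, j] = seen[j, i] = True
        R[i, j] = R[j, i] = r
    expected = k * (k - 1) // 2
    n_pairs = int(seen[np.triu_indices(k, 1)].sum())
    if n_pairs != expected or not np.isfinite(R).all():
        raise StructuralError(
            f"correlation set must cover all {expected} pairs over {k} nodes with finite r"
        )
    return nodes, R


def mutual_rank(corr: pd.DataFrame, mode: str = "geometric_mean") -> pd.DataFrame:
    """Mutual ranks and decay weights for a complete correlation set.

    For each node ``a``, partners are ranked by r from high to low (signed:
    strong negative correlations rank last); ties get the average rank.
    ``MR = sqrt(rank_ab * rank_ba)`` in ``geometric_mean`` mode, the raw
    product in ``product`` mode.  Output is one row per unordered pair with
    columns ``node_a, node_b, rank_ab, rank_ba, mr, weight``.
    """
    if mode not in MR_MODES:
        raise ParameterError(f"mode must be one of {MR_MODES}, got {mode!r}")
    nodes, R = _corr_square(corr)
    k = len(R)
    # ranks[i, j] = rank of j among i's partners (diagonal excluded)
    ranks = np.zeros((k, k))
    off = ~np.eye(k, dtype=bool)
    for i in range(k):
        ranks[i, off[i]] = stats.rankdata(-R[i, off[i]], method="average")
    iu, ju = np.triu_indices(k, 1)
    rab = ranks[iu, ju]
    rba = ranks[ju, iu]
    prod = rab * rba
    mr = np.sqrt(prod) if mode == "geometric_mean" else prod
    return pd.DataFrame(
        {
            "node_a": [nodes[i] for i in iu],
            "node_b": [nodes[j] for j in ju],
            "rank_ab": rab,
            "rank_ba": rba,
            "mr": mr,
            "weight": decay_weight(mr),
        }
    )


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class CoNetwork:
    """Undirected co-occurrence network of typed metabolite/gene nodes.

    Wraps a :class:`networkx.Graph`; every edge carries the statistics it was
    gated on (``r``, ``q``, ``mr``, ``weight``) and every node a ``kind``.
    Isolated nodes are kept so component sizes partition the full node set.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_kind(self, node: str) -> str:
        return self.graph.nodes[node].get("kind", "metabolite")

    def degree_table(self) -> pd.DataFrame:
        rows = [
            {"node": n, "kind": self.node_kind(n), "degree": d}
            for n, d in self.graph.degree()
        ]
        df = pd.DataFrame(rows, columns=["node", "kind", "degree"])
        return df.sort_values(["degree", "node"], ascending=[False, True], ignore_index=True)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            rows.append({"node_a": a, "node_b": b, **data})
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "r", "q", "mr", "weight"])
        return df.sort_values(["node_a", "node_b"], ignore_index=True)

    def summary(self) -> dict:
        comp_sizes = [len(c) for c in components(self)]
        by_kind = pd.Series([self.node_kind(n) for n in self.graph.nodes])
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "nodes_by_kind": by_kind.value_counts().to_dict() if self.n_nodes else {},
            "component_sizes": comp_sizes,
            "top_hubs": [{"node": n, "degree": d} for n, d in hubs(self, top_k=10)],
        }


def build_network(
    corr: pd.DataFrame,
    edges: pd.DataFrame,
    pcc_gate: float = 0.8,
    fdr_gate: float = 0.05,
    weight_floor: float = 0.01,
    node_kinds: Mapping[str, str] | None = None,
) -> CoNetwork:
    """Gate mutual-rank edges into a network.

    An edge survives iff it is testable, ``q < fdr_gate``, ``|r| > pcc_gate``
    (strict, on the absolute correlation) and ``weight >= weight_floor``.
    All nodes of the correlation set are kept, connected or not.
    """
    if pcc_gate <= 0 or fdr_gate <= 0 or weight_floor <= 0:
        raise ParameterError("gates must be positive")
    merged = corr.merge(edges, on=["node_a", "node_b"], how="inner", validate="one_to_one")
    if len(merged) != len(edges):
        raise StructuralError("correlation set and mutual-rank edges are not aligned")
    keep = (
        merged["testable"]
        & (merged["q"] < fdr_gate)
        & (merged["r"].abs() > pcc_gate)
        & (merged["weight"] >= weight_floor)
    )
    graph = nx.Graph()
    node_kinds = dict(node_kinds or {})
    all_nodes = sorted(set(corr["node_a"]) | set(corr["node_b"]))
    for node in all_nodes:
        graph.add_node(node, kind=node_kinds.get(node, "metabolite"))
    for row in merged[keep].itertuples(index=False):
        graph.add_edge(
            row.node_a,
            row.node_b,
            r=float(row.r),
            q=float(row.q),
            mr=float(row.mr),
            weight=float(row.weight),
        )
    return CoNetwork(graph)


def gene_metabolite_network(
    expr: ExpressionMatrix,
    metab: AbundanceMatrix,
    pathway_genes: Sequence[str],
    pcc_gate: float = 0.4,
    fdr_gate: float = 0.05,
    weight_floor: float = 0.01,
    mr_mode: str = "geometric_mean",
) -> CoNetwork:
    """Co-occurrence network over pathway genes plus all metabolites.

    Gene expression and metabolite intensity profiles are merged over shared
    biological samples; ranks and mutual ranks are computed over the merged
    node set, and every surviving edge type (gene-gene, gene-metabolite,
    metabolite-metabolite) is kept.  With an empty gene list this reduces to
    the metabolite-only network at the given gates.  Expression enters as
    log10(FPKM + 1) (FPKM may be exactly zero); intensities as log10.
    """
    pathway_genes = [str(g) for g in pathway_genes]
    unknown = [g for g in pathway_genes if g not in expr.values.columns]
    if unknown:
        raise KeyError(f"pathway gene(s) not in expression matrix: {unknown}")
    bio = metab.biological()
    shared = bio.index.intersection(expr.values.index)
    if len(shared) == 0:
        raise AlignmentError("no shared samples between expression and abundance matrices")
    if len(shared) < 4:
        raise InsufficientDataError("need at least 4 shared samples")
    metab_log = np.log10(bio.loc[shared])
    collision = set(pathway_genes) & set(metab_log.columns)
    if collision:
        raise StructuralError(f"gene ids collide with feature ids: {sorted(collision)}")
    merged = metab_log
    if pathway_genes:
        expr_log = np.log10(expr.values.loc[shared, pathway_genes] + 1.0)
        merged = pd.concat([metab_log, expr_log], axis=1)
    corr = pairwise_pcc(merged, log_transform=False)
    edges = mutual_rank(corr, mode=mr_mode)
    kinds = {f: "metabolite" for f in metab_log.columns}
    kinds.update({g: "gene" for g in pathway_genes})
    return build_network(
        corr,
        edges,
        pcc_gate=pcc_gate,
        fdr_gate=fdr_gate,
        weight_floor=weight_floor,
        node_kinds=kinds,
    )


# ---------------------------------------------------------------------------
# network queries
# ---------------------------------------------------------------------------

def hubs(net: CoNetwork, top_k: int | None = None, kind: str | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by degree (descending), ties broken lexicographically.

    ``kind`` restricts the ranking to one node type (e.g. the hub *gene* of a
    gene-metabolite network).
    """
    graph = net.graph
    pairs = [
        (n, d)
        for n, d in graph.degree()
        if kind is None or graph.nodes[n].get("kind", "metabolite") == kind
    ]
    pairs.sort(key=lambda nd: (-nd[1], nd[0]))
    return pairs if top_k is None else pairs[:top_k]


def components(net: CoNetwork) -> list[frozenset[str]]:
    """Maximal connected components, largest first (then by smallest member)."""
    comps = [frozenset(c) for c in nx.connected_components(net.graph)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def count_pairs_above(corr: pd.DataFrame, threshold: float, use_abs: bool = True) -> int:
    """Number of unordered pairs with (|r| or r) strictly above ``threshold``."""
    vals = corr["r"].abs() if use_abs else corr["r"]
    return int((vals > threshold).sum())
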