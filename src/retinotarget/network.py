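"""Pearson co-expression network, degree filtering, pathway burden, and the
four-priority candidate ranking.

Edges require |r| > 0.9 (strict) with two-sided P < 0.05 from the t statistic
r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, computed across all samples.
Candidates surviving the degree filter (>= 18 neighbors) are ordered
lexicographically by (1) degree, (2) oncogenic then total pathway burden,
(3) peak M-value, (4) cluster membership — descending at every step, with
residual ties broken by gene_id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PathwayCatalog
from .peaks import CandidateSet

DEFAULT_PCC_MIN = 0.9
DEFAULT_EDGE_P_MAX = 0.05
DEFAULT_DEGREE_MIN = 18


@dataclass
class CorrelationNetwork:
    """Thresholded Pearson graph with per-node degree."""

    graph: nx.Graph
    pcc_min: float
    p_max: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            (min(a, b), max(a, b), d["pcc"], d["p_value"])
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "p_value"])

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))


def pearson_edge_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-test P-value; zero variance -> (nan, 1)."""
    n = len(x)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def build_pcc_network(
    matrix: ExpressionMatrix,
    genes: set[str] | list[str] | None = None,
    pcc_min: float = DEFAULT_PCC_MIN,
    p_max: float = DEFAULT_EDGE_P_MAX,
) -> CorrelationNetwork:
    """All-pairs thresholded Pearson network over the given genes.

    Correlations are taken across all samples (contexts x doses x
    replicates); an edge (a, b) exists iff |r| > pcc_min strictly and
    P < p_max strictly.  Zero-variance genes stay isolated.
    """
    if genes is None:
        gene_list = matrix.gene_ids
    else:
        unknown = set(genes) - set(matrix.gene_ids)
        if unknown:
            raise ValueError(f"genes absent from the matrix: {sorted(unknown)[:5]}")
        gene_list = [g for g in matrix.gene_ids if g in set(genes)]
    x = matrix.values.loc[gene_list].to_numpy(dtype=float)
    n_samples = x.shape[1]
    if n_samples < 3:
        raise ValueError("need >= 3 samples for edge P-values")

    graph = nx.Graph()
    graph.add_nodes_from(gene_list)

    sds = x.std(axis=1)
    ok = sds > 0
    idx_ok = np.flatnonzero(ok)
    if len(idx_ok) >= 2:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x[idx_ok])
        r = np.clip(r, -1.0, 1.0)
        df = n_samples - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(r) * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(t, df=df)
        p[np.abs(r) == 1.0] = 0.0
        iu, ju = np.triu_indices(len(idx_ok), k=1)
        hit = (np.abs(r[iu, ju]) > pcc_min) & (p[iu, ju] < p_max)
        for i, j in zip(iu[hit], ju[hit]):
            a, b = gene_list[idx_ok[i]], gene_list[idx_ok[j]]
            graph.add_edge(a, b, pcc=float(r[i, j]), p_value=float(p[i, j]))
    return CorrelationNetwork(graph=graph, pcc_min=pcc_min, p_max=p_max)


def degree_filter(
    network: CorrelationNetwork, degree_min: int = DEFAULT_DEGREE_MIN
) -> set[str]:
    """Genes with at least ``degree_min`` neighbors (boundary included)."""
    return {g for g, d in network.graph.degree() if d >= degree_min}


def pathway_burden(gene: str, catalog: PathwayCatalog) -> tuple[int, int]:
    """(total pathways containing the gene, oncogenic pathways among them)."""
    hits = catalog.membership(gene)
    onco = sum(1 for pid in hits if catalog.pathways[pid].oncogenic)
    return len(hits), onco


def ego_subnetwork(network: CorrelationNetwork, center: str) -> CorrelationNetwork:
    """Induced subnetwork on the center gene and its direct neighbors."""
    if center not in network.graph:
        raise ValueError(f"gene {center!r} is not a network node")
    nodes = {center} | set(network.graph.neighbors(center))
    return CorrelationNetwork(
        graph=network.graph.subgraph(nodes).copy(),
        pcc_min=network.pcc_min,
        p_max=network.p_max,
    )


def priority_rank(
    candidates: CandidateSet,
    network: CorrelationNetwork,
    catalog: PathwayCatalog,
    memberships: pd.DataFrame,
    top_n: int = 10,
    degree_min: int = DEFAULT_DEGREE_MIN,
) -> pd.DataFrame:
    """Four-priority lexicographic ranking of candidate genes.

    ``memberships`` is the genes x clusters membership matrix; each gene's
    membership evidence is its maximum membership.  Candidates missing from
    the network or below the degree filter are excluded before ranking.
    """
    degrees = network.degree
    rows = []
    for gene in sorted(candidates.genes):
        deg = degrees.get(gene, 0)
        if deg < degree_min:
            continue
        n_pw, onco = pathway_burden(gene, catalog)
        u = (
            float(memberships.loc[gene].max())
            if gene in memberships.index
            else 0.0
        )
        rows.append((gene, deg, n_pw, onco, candidates.peak_m[gene], u))
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "degree", "n_pathways", "oncogenic_pathways",
            "peak_m", "membership",
        ],
    )
    table = table.sort_values(
        by=["degree", "oncogenic_pathways", "n_pathways", "peak_m", "membership",
            "gene_id"],
        ascending=[False, False, False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["priority_rank"] = np.arange(1, len(table) + 1)
    if len(table) < top_n:
        warnings.warn(
            f"only {len(table)} candidates survive the filters (top_n={top_n})"
        )
    return table.head(top_n)
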