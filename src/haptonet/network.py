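"""Co-occurrence network construction and topology.

Pipeline stage order: prevalence/abundance filter -> pairwise Spearman on
relative abundances -> Benjamini-Hochberg FDR across the upper triangle ->
edges where q < alpha and rho >= rho_min (positive-only by default; an
absolute-value policy is available) -> habitat-enrichment classes, Louvain
modules, node- and network-level topological properties.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ZotuTable

__all__ = [
    "NetworkMetrics",
    "filter_zotus",
    "spearman_matrix",
    "bh_adjust",
    "build_network",
    "classify_enrichment",
    "detect_modules",
    "node_metrics",
    "network_metrics",
    "subnetwork",
]


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    diameter: int
    clustering_coefficient: float
    average_path_length: float
    n_components: int
    largest_component_size: int
    largest_component_diameter: int
    largest_component_apl: float

    def to_json(self) -> dict:
        return dict(self.__dict__)


def filter_zotus(
    table: ZotuTable,
    min_rel_abund: float = 1e-4,
    min_prevalence: float = 0.25,
) -> ZotuTable:
    """Drop rare-and-sparse ZOTUs before correlation analysis.

    A ZOTU is deleted only when BOTH conditions hold: its pooled relative
    abundance is below ``min_rel_abund`` (default 0.01%) AND it occurs in
    fewer than ``min_prevalence`` of samples.  Failing a single condition
    keeps it.
    """
    pooled = table.counts.sum(axis=0).astype(float)
    rel = pooled / pooled.sum()
    prevalence = (table.counts > 0).mean(axis=0)
    delete = (rel < min_rel_abund) & (prevalence < min_prevalence)
    if delete.all():
        raise ValueError(
            "filter removed every ZOTU; relax min_rel_abund/min_prevalence"
        )
    return table.select_zotus(~delete)


def spearman_matrix(table: ZotuTable) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and two-sided p between ZOTUs.

    Computed on relative abundances with average ranks on ties; p-values
    use the t approximation.  Pairs involving a zero-variance ZOTU are NaN
    (not-computed).  Requires >= 5 samples.
    """
    if table.n_samples < 5:
        raise ValueError("need >= 5 samples for the correlation screen")
    rel = table.relative_abundance()
    n, m = rel.shape
    ranks = np.apply_along_axis(stats.rankdata, 0, rel)
    sd = ranks.std(axis=0)
    rc = ranks - ranks.mean(axis=0)
    denom = np.sqrt((rc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rc.T @ rc) / np.outer(denom, denom)
    rho = np.clip(rho, -1.0, 1.0)
    rho[sd == 0, :] = np.nan
    rho[:, sd == 0] = np.nan
    np.fill_diagonal(rho, 1.0)
    # two-sided p via the t transform, df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    p = np.where(np.isnan(rho), np.nan, p)
    np.fill_diagonal(p, 0.0)
    return rho, p


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending order, capped
    at 1, returned in the input order.  ``m`` defaults to the number of
    p-values supplied.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    m = k if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def build_network(
    rho: np.ndarray,
    q: np.ndarray,
    zotu_ids: list[str],
    rho_min: float = 0.6,
    alpha: float = 0.01,
    use_abs: bool = False,
) -> nx.Graph:
    """Threshold the correlation matrix into a simple undirected graph.

    Edge (i, j) exists iff ``q_ij < alpha`` and ``rho_ij >= rho_min``
    (``use_abs=True`` admits strong negative correlations too).  Isolated
    nodes are dropped; node insertion order is deterministic.  Edges carry
    ``rho``, ``q`` and ``sign`` attributes.
    """
    rho = np.asarray(rho, dtype=float)
    q = np.asarray(q, dtype=float)
    if rho.shape != q.shape or rho.shape[0] != rho.shape[1]:
        raise ValueError("rho and q must be square matrices of the same shape")
    if rho.shape[0] != len(zotu_ids):
        raise ValueError("zotu_ids length must match matrix size")
    m = rho.shape[0]
    G = nx.Graph()
    strength = np.abs(rho) if use_abs else rho
    for i in range(m):
        for j in range(i + 1, m):
            if np.isnan(rho[i, j]) or np.isnan(q[i, j]):
                continue
            if q[i, j] < alpha and strength[i, j] >= rho_min:
                G.add_edge(
                    zotu_ids[i],
                    zotu_ids[j],
                    rho=float(rho[i, j]),
                    q=float(q[i, j]),
                    sign="+" if rho[i, j] >= 0 else "-",
                )
    return G


def network_edges_from_table(
    table: ZotuTable,
    rho_min: float = 0.6,
    alpha: float = 0.01,
    use_abs: bool = False,
) -> nx.Graph:
    """Convenience: Spearman screen + BH + thresholding in one call."""
    rho, p = spearman_matrix(table)
    iu = np.triu_indices(rho.shape[0], k=1)
    pv = p[iu]
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(pv)
    qv = np.full(pv.shape, np.nan)
    qv[mask] = bh_adjust(pv[mask])
    q[iu] = qv
    q.T[iu] = qv
    np.fill_diagonal(q, 0.0)
    return build_network(rho, q, table.zotu_ids, rho_min, alpha, use_abs)


def classify_enrichment(
    table: ZotuTable,
    habitats: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Habitat-enrichment class per ZOTU (surface / SCM / none).

    Per ZOTU: two-sided rank-sum test of relative abundance between the
    two habitats, BH correction across ZOTUs, class assigned to the
    habitat with the larger mean relative abundance when q < alpha.
    """
    habitats = habitats.loc[table.sample_ids]
    groups = sorted(habitats.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 habitats, got {groups}")
    g0, g1 = groups
    rel = table.relative_abundance()
    in0 = (habitats == g0).to_numpy()
    pvals = np.ones(table.n_zotus)
    means0 = rel[in0].mean(axis=0)
    means1 = rel[~in0].mean(axis=0)
    for j in range(table.n_zotus):
        a, b = rel[in0, j], rel[~in0, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
    qvals = bh_adjust(pvals)
    classes = np.where(
        qvals < alpha, np.where(means0 > means1, g0, g1), "none"
    )
    return pd.DataFrame(
        {
            "zotu_id": table.zotu_ids,
            "p": pvals,
            "q": qvals,
            f"mean_rel_{g0}": means0,
            f"mean_rel_{g1}": means1,
            "enrichment": classes,
        }
    ).set_index("zotu_id")


def detect_modules(
    G: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[dict[str, int], float]:
    """Louvain modules on the unweighted simple graph, seeded.

    Returns (node -> module label, modularity Q); labels are assigned by
    decreasing module size (ties broken by smallest member id).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty network")
    comms = nx.community.louvain_communities(
        G, weight=None, resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = {node: k for k, comm in enumerate(comms) for node in comm}
    q = nx.community.modularity(G, comms, weight=None)
    return labels, float(q)


def node_metrics(G: nx.Graph) -> pd.DataFrame:
    """Degree, normalized betweenness and component-scaled closeness.

    Betweenness is shortest-path betweenness normalized by
    ``(N-1)(N-2)/2``; closeness is computed within each connected
    component as ``(n_c - 1) / sum(d)`` and scaled by ``(n_c - 1)/(N - 1)``
    (the Wasserman-Faust correction).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(G.degree())
    btw = nx.betweenness_centrality(G, normalized=True)
    clo = nx.closeness_centrality(G, wf_improved=True)
    nodes = list(G.nodes())
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        },
        index=pd.Index(nodes, name="zotu_id"),
    )


def network_metrics(G: nx.Graph) -> NetworkMetrics:
    """Network-level topology; path metrics are over reachable pairs only."""
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    e = G.number_of_edges()
    comps = [G.subgraph(c) for c in nx.connected_components(G)]
    largest = max(comps, key=lambda c: c.number_of_nodes())
    diam = 0
    path_sum = 0.0
    pair_count = 0
    for comp in comps:
        if comp.number_of_nodes() < 2:
            continue
        for src, lengths in nx.shortest_path_length(comp):
            for dst, d in lengths.items():
                if src < dst:
                    path_sum += d
                    pair_count += 1
                    diam = max(diam, d)
    apl = path_sum / pair_count if pair_count else 0.0
    if largest.number_of_nodes() >= 2:
        lc_diam = nx.diameter(largest)
        lc_apl = nx.average_shortest_path_length(largest)
    else:
        lc_diam, lc_apl = 0, 0.0
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        average_degree=2.0 * e / n,
        density=2.0 * e / (n * (n - 1)) if n > 1 else 0.0,
        diameter=diam,
        clustering_coefficient=nx.average_clustering(G),
        average_path_length=apl,
        n_components=len(comps),
        largest_component_size=largest.number_of_nodes(),
        largest_component_diameter=lc_diam,
        largest_component_apl=float(lc_apl),
    )


def subnetwork(G: nx.Graph, nodes) -> nx.Graph:
    """Induced subgraph on the given node subset (copied, not a view)."""
    nodes = [n for n in nodes if n in G]
    if not nodes:
        raise ValueError("node subset is disjoint from the network")
    return G.subgraph(nodes).copy()
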