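"""Thresholded Spearman co-occurrence networks over taxon abundances.

Mirrors the standard microbiome workflow: filter genera by relative
abundance (default > 0.01%), compute all pairwise Spearman rank
correlations, keep pairs with |r| above a threshold (default 0.7) and
p below a significance cutoff (default 0.05, no multiple-testing
correction by default; Benjamini-Hochberg available), and summarize the
resulting signed graph with the usual topology metrics (degree,
density, clustering, modularity, path lengths, components).

p-values come from the t approximation for n > 10 samples and from an
exhaustive permutation null for n <= 10, where the approximation is
unreliable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NetworkConfig",
    "CooccurrenceNetwork",
    "filter_taxa",
    "spearman_edges",
    "build_cooccurrence_network",
    "topology",
]

_PERM_CHUNK = 40320  # 8! permutations per vectorized block


@dataclass(frozen=True)
class NetworkConfig:
    """Filtering and thresholding parameters of the network stage.

    ``min_abundance`` is a fraction (0.0001 = 0.01%); ``filter_stat``
    selects whether the mean or the max relative abundance across
    samples is compared against it.
    """

    min_abundance: float = 1e-4
    r_threshold: float = 0.7
    p_threshold: float = 0.05
    correction: str | None = None  # None or "bh"
    filter_stat: str = "mean"      # "mean" or "max"

    def __post_init__(self):
        if not 0 <= self.min_abundance < 1:
            raise ValueError("min_abundance must be a fraction in [0, 1)")
        if not 0 <= self.r_threshold <= 1:
            raise ValueError("r_threshold must be in [0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.correction not in (None, "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.filter_stat not in ("mean", "max"):
            raise ValueError(f"unknown filter statistic {self.filter_stat!r}")


def filter_taxa(table: pd.DataFrame, cfg: NetworkConfig = NetworkConfig()) -> pd.DataFrame:
    """Retain taxa whose mean (or max) relative abundance exceeds the cutoff."""
    if table.empty:
        raise ValueError("abundance table is empty")
    stat = table.mean(axis=0) if cfg.filter_stat == "mean" else table.max(axis=0)
    kept = table.loc[:, stat > cfg.min_abundance]
    if kept.shape[1] == 0:
        raise ValueError(
            f"no taxon exceeds the {cfg.min_abundance:g} abundance cutoff"
        )
    return kept


def _spearman_r(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    # Pearson correlation of midranks = Spearman rho (ties handled)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return math.nan
    return float((xc @ yc) / denom)


def exact_permutation_p(x, y) -> tuple:
    """Spearman rho and exhaustive two-sided permutation p-value.

    Enumerates all n! pairings; feasible for the n <= 10 sample sizes
    it is used for.  p = P(|rho_perm| >= |rho_obs|) including the
    identity, so p >= 1/n!.
    """
    x_rank = stats.rankdata(x)
    y_rank = stats.rankdata(y)
    obs = _spearman_r(x_rank, y_rank)
    if math.isnan(obs):
        return obs, math.nan
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    hits = 0
    total = 0
    perms = itertools.permutations(range(n))
    while True:
        block = np.array(list(itertools.islice(perms, _PERM_CHUNK)), dtype=int)
        if block.size == 0:
            break
        rhos = (yc[block] @ xc) / denom
        hits += int(np.count_nonzero(np.abs(rhos) >= abs(obs) - 1e-12))
        total += block.shape[0]
    return obs, hits / total


def spearman_edges(table: pd.DataFrame, cfg: NetworkConfig = NetworkConfig(),
                   all_pairs: bool = False) -> pd.DataFrame:
    """All taxon pairs passing the |r| and p thresholds.

    Returns a DataFrame (taxon_a, taxon_b, r, p) with taxon_a < taxon_b
    in the table's column order.  Constant taxa are skipped with a
    warning (their rank correlation is undefined).  With
    ``all_pairs=True`` the thresholds are not applied (useful for
    inspecting the full correlation table).
    """
    n = table.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    constant = [c for c in table.columns if table[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"skipping {len(constant)} constant taxa (undefined correlation): "
            f"{constant[:5]}{'...' if len(constant) > 5 else ''}"
        )
    cols = [c for c in table.columns if c not in set(constant)]
    data = table[cols]

    rows = []
    if n > 10:
        rho, pval = stats.spearmanr(data.values)
        rho = np.atleast_2d(rho)
        pval = np.atleast_2d(pval)
        for i, j in itertools.combinations(range(len(cols)), 2):
            rows.append((cols[i], cols[j], float(rho[i, j]), float(pval[i, j])))
    else:
        ranks = {c: stats.rankdata(data[c].values) for c in cols}
        cache: dict = {}
        for a, b in itertools.combinations(cols, 2):
            key = (tuple(ranks[a]), tuple(ranks[b]))
            if key not in cache:
                cache[key] = exact_permutation_p(ranks[a], ranks[b])
            r, p = cache[key]
            rows.append((a, b, r, p))

    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p"])
    if cfg.correction == "bh" and not edges.empty:
        edges["p"] = multipletests(edges["p"].values, method="fdr_bh")[1]
    if all_pairs:
        return edges
    mask = (edges["r"].abs() > cfg.r_threshold) & (edges["p"] < cfg.p_threshold)
    return edges[mask].reset_index(drop=True)


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Signed Spearman graph plus the configuration that built it."""

    graph: nx.Graph
    config: NetworkConfig
    n_taxa_tested: int

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "r": d["r"], "p": d["p"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p"])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)


def build_cooccurrence_network(
    table: pd.DataFrame, cfg: NetworkConfig = NetworkConfig()
) -> CooccurrenceNetwork:
    """Filter, correlate and threshold an abundance table into a network.

    Nodes are the taxa that carry at least one retained edge (isolated
    taxa are not drawn, matching the usual network-figure convention).
    """
    kept = filter_taxa(table, cfg)
    edge_df = spearman_edges(kept, cfg)
    graph = nx.Graph()
    for row in edge_df.itertuples():
        graph.add_edge(row.taxon_a, row.taxon_b, r=row.r, p=row.p, sign=int(np.sign(row.r)))
    # canonical node order for deterministic downstream community detection
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes))
    ordered.add_edges_from(
        (u, v, d) for u, v, d in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    )
    return CooccurrenceNetwork(graph=ordered, config=cfg, n_taxa_tested=kept.shape[1])


def topology(network: CooccurrenceNetwork | nx.Graph) -> dict:
    """Topology metric set of a co-occurrence network.

    Path-based metrics (diameter, average path length) are computed on
    the largest connected component; modularity comes from deterministic
    greedy optimization (values, not community labels, are the
    reproducible quantity).  An empty network yields zeros with an
    ``empty`` flag.
    """
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    metrics = {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "empty": g.number_of_edges() == 0,
    }
    if metrics["empty"]:
        metrics.update(
            positive_edge_ratio=math.nan, average_degree=0.0, density=0.0,
            clustering_coefficient=0.0, modularity=math.nan,
            diameter=0, average_path_length=math.nan,
            connected_components=g.number_of_nodes(), communities=0,
        )
        return metrics

    signs = [d.get("sign", int(np.sign(d.get("r", 1)))) for _, _, d in g.edges(data=True)]
    metrics["positive_edge_ratio"] = float(np.mean([s > 0 for s in signs]))
    degrees = [d for _, d in g.degree()]
    metrics["average_degree"] = float(np.mean(degrees))
    metrics["density"] = nx.density(g)
    metrics["clustering_coefficient"] = nx.average_clustering(g)
    communities = nx.community.greedy_modularity_communities(g)
    metrics["modularity"] = nx.community.modularity(g, communities)
    metrics["communities"] = len(communities)
    components = list(nx.connected_components(g))
    metrics["connected_components"] = len(components)
    giant = g.subgraph(max(components, key=len))
    metrics["diameter"] = nx.diameter(giant)
    metrics["average_path_length"] = nx.average_shortest_path_length(giant)
    return metrics
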