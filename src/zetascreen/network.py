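"""Consensus-clustered functional-similarity networks among screen hits.

Hits with similar readout profiles likely act in the same pathway or complex.
Following a consensus-clustering scheme in the SC3 spirit, two distance
matrices D = 1 - |r| (Pearson and Spearman) are embedded by classical MDS and
partitioned by k-means repeatedly across k values and seeded restarts; the
consensus score of a gene pair is the fraction of runs in which they
co-cluster.  Final cluster labels come from average-linkage hierarchical
clustering of 1 - consensus at the elbow k (maximum second difference of the
total within-cluster sum of squares); edges are kept where consensus >= 0.5,
signed by the Pearson correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["GeneNetwork", "consensus_cluster", "export_network"]


@dataclass
class GeneNetwork:
    """Hit network with consensus edge weights and cluster labels."""

    graph: nx.Graph
    consensus: pd.DataFrame
    clusters: pd.Series
    k_star: int
    wss: dict[int, float] = field(default_factory=dict)

    def cluster_table(self, zeta: pd.Series | None = None) -> pd.DataFrame:
        out = pd.DataFrame({"gene": self.clusters.index, "cluster": self.clusters.to_numpy()})
        if zeta is not None:
            out["zeta"] = zeta.loc[out["gene"]].to_numpy()
        return out


def _classical_mds(D: np.ndarray, n_components: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    q = min(n_components, int(pos.sum()))
    if q == 0:
        return np.zeros((n, 1))
    return vecs[:, :q] * np.sqrt(vals[:q])


def consensus_cluster(
    zm_hits: pd.DataFrame,
    zeta: pd.Series,
    k_range=None,
    n_runs: int = 50,
    seed: int = 0,
    edge_threshold: float = 0.5,
    n_mds_components: int = 10,
) -> GeneNetwork:
    """Consensus clustering of hit genes from their Z-score profiles.

    Parameters
    ----------
    zm_hits : DataFrame, genes x readouts (Z scores restricted to hits).
    zeta : per-gene zeta scores, stored as node size attribute.
    k_range : candidate cluster counts; default 2..min(8, n_hits // 2).
    n_runs : seeded k-means restarts per (distance, k) combination.
    """
    from sklearn.cluster import KMeans

    genes = zm_hits.index
    n = len(genes)
    if n < 10:
        raise ValueError("need >= 10 hits to build a network")
    if k_range is None:
        k_range = range(2, min(8, n // 2) + 1)
    k_range = list(k_range)
    if not k_range or min(k_range) < 2 or max(k_range) > n // 2:
        raise ValueError(f"k_range must lie within [2, n_hits/2]; got {k_range}")

    X = zm_hits.to_numpy(float)
    pear = np.corrcoef(X)
    spear = stats.spearmanr(X, axis=1)[0]
    spear = np.atleast_2d(spear)
    np.fill_diagonal(pear, 1.0)
    np.fill_diagonal(spear, 1.0)

    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    total = 0
    wss: dict[int, list[float]] = {k: [] for k in k_range}
    for corr in (pear, spear):
        D = 1.0 - np.abs(np.clip(corr, -1, 1))
        coords = _classical_mds(D, n_mds_components)
        for k in k_range:
            for _ in range(n_runs):
                km = KMeans(
                    n_clusters=k,
                    n_init=1,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                ).fit(coords)
                lab = km.labels_
                co += lab[:, None] == lab[None, :]
                wss[k].append(float(km.inertia_))
                total += 1
    consensus = co / total
    np.fill_diagonal(consensus, 1.0)

    wss_mean = {k: float(np.mean(v)) for k, v in wss.items()}
    ks = sorted(wss_mean)
    if len(ks) >= 3:
        w = np.array([wss_mean[k] for k in ks])
        second_diff = w[:-2] - 2 * w[1:-1] + w[2:]
        k_star = ks[1 + int(np.argmax(second_diff))]
    else:
        k_star = ks[0]

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k_star, criterion="maxclust")
    clusters = pd.Series(labels, index=genes, name="cluster")

    G = nx.Graph()
    for g in genes:
        G.add_node(
            g,
            zeta=float(zeta.get(g, 0.0)),
            size=float(zeta.get(g, 0.0)),
            cluster=int(clusters[g]),
            color=int(clusters[g]),
        )
    iu = np.triu_indices(n, k=1)
    for a, b in zip(*iu):
        w = consensus[a, b]
        if w >= edge_threshold:
            G.add_edge(
                genes[a],
                genes[b],
                weight=float(w),
                sign="correlated" if pear[a, b] >= 0 else "anti-correlated",
            )

    return GeneNetwork(
        graph=G,
        consensus=pd.DataFrame(consensus, index=genes, columns=genes),
        clusters=clusters,
        k_star=int(k_star),
        wss=wss_mean,
    )


def export_network(net: GeneNetwork, path, fmt: str = "graphml") -> nx.Graph:
    """Write the network (GraphML or GEXF), trimming disconnected nodes.

    Returns the trimmed graph that was written.
    """
    G = net.graph.copy()
    isolated = list(nx.isolates(G))
    G.remove_nodes_from(isolated)
    if G.number_of_edges() == 0:
        warnings.warn("network has no edges; writing an empty graph", stacklevel=2)
    if fmt == "graphml":
        nx.write_graphml(G, str(path))
    elif fmt == "gexf":
        nx.write_gexf(G, str(path))
    else:
        raise ValueError(f"unknown format: {fmt}")
    return G
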