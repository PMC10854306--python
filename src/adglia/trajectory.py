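"""Sample stratification along a spanning-tree pseudotime.

The combined differential-expression signature panel (top up- and
down-regulated genes per contrast) is embedded in a low-dimensional space
(PCA), a set of tree nodes is fitted by alternating centroid updates
(k-means), and a minimum spanning tree is built over the nodes.  Samples are
projected onto their closest point on the tree; pseudotime is the geodesic
distance along the tree from a root placed at one end of the tree's maximum
diameter path.  Branches are the maximal tree paths between nodes of degree
!= 2, and sample clusters are obtained by cutting the largest tree edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


@dataclass
class SignaturePanel:
    """Union of top differential genes across contrasts, with provenance."""
    genes: list[str]
    provenance: pd.DataFrame  # columns: gene, contrast, direction, rank

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel contains duplicate genes")


@dataclass
class TrajectoryResult:
    embedding: pd.DataFrame          # samples x d
    node_coords: np.ndarray          # n_nodes x d
    tree: nx.Graph                   # MST over nodes, edge attr 'weight'
    sample_edge: list[tuple[int, int]]   # tree edge holding each projection
    sample_offset: np.ndarray        # distance from edge's first node
    projection: np.ndarray           # samples x d projected coordinates
    pseudotime: pd.Series | None = None
    branch: pd.Series | None = None
    cluster: pd.Series | None = None
    root: int | None = None
    meta: dict = field(default_factory=dict)


def build_signature_panel(de_tables: dict[str, pd.DataFrame],
                          n_top: int = 100) -> SignaturePanel:
    """Top up- and down-regulated genes per contrast, unioned across contrasts.

    Within each direction (sign of log2FC) genes are ranked by p ascending,
    ties broken by |log2FC| descending then by id; the first ``n_top`` per
    direction enter the panel.  Tables with fewer than ``n_top`` genes in a
    direction contribute all of them (with a warning).
    """
    if not de_tables:
        raise ValueError("no DE tables supplied")
    rows = []
    for contrast, table in de_tables.items():
        if len(table) == 0:
            raise ValueError(f"empty DE table for contrast {contrast!r}")
        t = table.dropna(subset=["logFC", "p"])
        for direction, mask in (("up", t["logFC"] > 0), ("down", t["logFC"] < 0)):
            sub = t[mask].copy()
            if len(sub) < n_top:
                logger.warning("contrast %r has only %d %s-regulated genes",
                               contrast, len(sub), direction)
            order = np.lexsort((sub.index.astype(str),
                                -sub["logFC"].abs().to_numpy(),
                                sub["p"].to_numpy()))
            top = sub.index[order][:n_top]
            for rank, gene in enumerate(top, start=1):
                rows.append((gene, contrast, direction, rank))
    prov = pd.DataFrame(rows, columns=["gene", "contrast", "direction", "rank"])
    genes = list(dict.fromkeys(prov["gene"]))
    return SignaturePanel(genes=genes, provenance=prov)


def embed_and_tree(expr: pd.DataFrame, d: int = 2,
                   n_nodes: int | None = None,
                   random_state: int = 0) -> TrajectoryResult:
    """Embed samples (PCA), fit tree nodes (k-means) and build the MST.

    ``expr`` is genes x samples (panel-restricted, residualized).  Samples
    are projected to their closest point on any tree edge (segment
    projection), which later pseudotime/branch calls consume.
    """
    if expr.shape[0] < 10:
        raise ValueError("need >= 10 panel genes in the expression matrix")
    n_samples = expr.shape[1]
    X = expr.to_numpy(float).T                      # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    d_eff = min(d, n_samples - 1, X.shape[1])
    emb = PCA(n_components=d_eff, random_state=random_state).fit_transform(X)

    if n_nodes is None:
        n_nodes = int(min(50, max(2, n_samples // 3)))
    n_distinct = np.unique(emb, axis=0).shape[0]
    if n_distinct < n_nodes:
        raise ValueError(f"only {n_distinct} distinct samples for "
                         f"{n_nodes} tree nodes")
    km = KMeans(n_clusters=n_nodes, n_init=10, random_state=random_state)
    km.fit(emb)
    nodes = km.cluster_centers_

    dmat = np.sqrt(((nodes[:, None, :] - nodes[None, :, :]) ** 2).sum(-1))
    complete = nx.from_numpy_array(dmat)
    tree = nx.minimum_spanning_tree(complete, weight="weight")

    edges = list(tree.edges())
    sample_edge: list[tuple[int, int]] = []
    sample_offset = np.empty(n_samples)
    projection = np.empty_like(emb)
    for s in range(n_samples):
        best = (np.inf, None, 0.0, None)
        pt = emb[s]
        for (u, v) in edges:
            a, b = nodes[u], nodes[v]
            ab = b - a
            L2 = float(ab @ ab)
            t = 0.0 if L2 == 0 else float(np.clip((pt - a) @ ab / L2, 0, 1))
            proj = a + t * ab
            dist = float(np.linalg.norm(pt - proj))
            if dist < best[0]:
                best = (dist, (u, v), t * np.sqrt(L2), proj)
        sample_edge.append(best[1])
        sample_offset[s] = best[2]
        projection[s] = best[3]

    emb_df = pd.DataFrame(emb, index=expr.columns,
                          columns=[f"dim{i+1}" for i in range(d_eff)])
    return TrajectoryResult(embedding=emb_df, node_coords=nodes, tree=tree,
                            sample_edge=sample_edge,
                            sample_offset=sample_offset,
                            projection=projection)


def compute_pseudotime(traj: TrajectoryResult,
                       root_scores: pd.Series | None = None) -> pd.Series:
    """Geodesic tree distance from a diameter-endpoint root.

    The root is an endpoint of the maximum-weight (diameter) path of the
    tree.  With ``root_scores`` (a per-sample disease-severity-like value)
    the endpoint whose nearby samples have the lower mean score is chosen;
    otherwise the endpoint with the smaller node id (deterministic).
    """
    tree = traj.tree
    if not nx.is_connected(tree):
        raise ValueError("spanning tree is disconnected")
    dist = dict(nx.all_pairs_dijkstra_path_length(tree, weight="weight"))
    diameter, pair = -1.0, None
    for u in sorted(tree.nodes):
        for v, duv in dist[u].items():
            if duv > diameter or (duv == diameter and pair is not None
                                  and (u, v) < pair):
                diameter, pair = duv, (u, v) if u < v else (v, u)
    a, b = pair

    samples = traj.embedding.index

    def _pt_from(root):
        out = np.empty(len(samples))
        for i, (u, v) in enumerate(traj.sample_edge):
            L = tree.edges[u, v]["weight"]
            off = traj.sample_offset[i]
            out[i] = min(dist[root][u] + off, dist[root][v] + (L - off))
        return out

    if root_scores is not None:
        pa, pb = _pt_from(a), _pt_from(b)
        sc = root_scores.reindex(samples).to_numpy(float)
        near_a = pa <= pb
        mean_a = np.nanmean(sc[near_a]) if near_a.any() else np.inf
        mean_b = np.nanmean(sc[~near_a]) if (~near_a).any() else np.inf
        root = a if mean_a <= mean_b else b
    else:
        root = min(a, b)
    pt = _pt_from(root)
    traj.root = root
    traj.meta["diameter_endpoints"] = (a, b)
    traj.pseudotime = pd.Series(pt, index=samples, name="pseudotime")
    return traj.pseudotime


def _branch_decomposition(tree: nx.Graph) -> dict[tuple[int, int], int]:
    """Map each tree edge to a branch id (maximal paths between deg != 2)."""
    breakpoints = [n for n in sorted(tree.nodes) if tree.degree(n) != 2]
    if not breakpoints:                      # cycle-free => at least 2 leaves
        breakpoints = [min(tree.nodes)]
    edge_branch: dict[tuple[int, int], int] = {}
    branch_id = 0
    for bp in breakpoints:
        for nbr in sorted(tree.neighbors(bp)):
            key = (min(bp, nbr), max(bp, nbr))
            if key in edge_branch:
                continue
            # walk the degree-2 chain
            prev, cur = bp, nbr
            chain = [key]
            while tree.degree(cur) == 2:
                nxt = next(n for n in tree.neighbors(cur) if n != prev)
                chain.append((min(cur, nxt), max(cur, nxt)))
                prev, cur = cur, nxt
            for e in chain:
                edge_branch[e] = branch_id
            branch_id += 1
    return edge_branch


def assign_branches(traj: TrajectoryResult,
                    n_clusters: int = 6) -> TrajectoryResult:
    """Assign each sample a branch id and a tree-cut cluster id.

    Branches are maximal paths between nodes of degree != 2; a sample takes
    the branch of the edge holding its projection.  Clusters come from
    removing the ``n_clusters - 1`` largest-weight edges of the tree; the
    sample joins the component containing the nearer endpoint of its edge.
    Cluster ids are canonicalized by ascending mean pseudotime (by size when
    pseudotime has not been computed).
    """
    tree = traj.tree
    if n_clusters > tree.number_of_nodes():
        raise ValueError("n_clusters exceeds number of tree nodes")
    samples = traj.embedding.index

    edge_branch = _branch_decomposition(tree)
    branch = [edge_branch[(min(u, v), max(u, v))]
              for (u, v) in traj.sample_edge]
    traj.branch = pd.Series(branch, index=samples, name="branch")

    cut = tree.copy()
    ranked = sorted(tree.edges(data="weight"),
                    key=lambda e: (-e[2], e[0], e[1]))
    for (u, v, _) in ranked[:n_clusters - 1]:
        cut.remove_edge(u, v)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(cut)):
        for node in comp:
            comp_of[node] = ci
    cluster = []
    for i, (u, v) in enumerate(traj.sample_edge):
        L = tree.edges[u, v]["weight"]
        nearer = u if traj.sample_offset[i] <= L / 2 else v
        cluster.append(comp_of[nearer])
    cluster = pd.Series(cluster, index=samples, name="cluster")

    # canonical ordering
    if traj.pseudotime is not None:
        order = cluster.groupby(cluster).apply(
            lambda idx: traj.pseudotime.loc[idx.index].mean()).sort_values()
    else:
        order = cluster.value_counts().sort_values(ascending=False)
    remap = {old: new for new, old in enumerate(order.index)}
    traj.cluster = cluster.map(remap).rename("cluster")
    return traj


def characterize_clusters(values: pd.DataFrame, clusters: pd.Series,
                          pairs: list[tuple] | None = None,
                          min_size: int = 3) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests of scores/metadata between clusters.

    ``values`` is samples x variables (GSVA-like composite scores, age, ...).
    Undersized clusters are skipped with a reason; constant comparisons are
    reported with missing statistics.
    """
    clusters = clusters.reindex(values.index)
    ids = sorted(clusters.dropna().unique())
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows = []
    for (a, b) in pairs:
        ia = clusters.index[clusters == a]
        ib = clusters.index[clusters == b]
        for var in values.columns:
            xa = values.loc[ia, var].dropna().to_numpy(float)
            xb = values.loc[ib, var].dropna().to_numpy(float)
            if len(xa) < min_size or len(xb) < min_size:
                rows.append((a, b, var, np.nan, np.nan, "undersized_cluster"))
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                rows.append((a, b, var, np.nan, np.nan, "constant_values"))
                continue
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append((a, b, var, float(res.statistic),
                         float(res.pvalue), ""))
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "variable",
                                       "statistic", "p", "reason"])
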