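"""Gene-set enrichment, per-sample scoring, and module annotation.

* ``camera_competitive`` -- the parametric competitive test: in-set vs
  out-of-set comparison of per-gene statistics with the variance of the
  in-set mean inflated by ``VIF = 1 + (m - 1) * rho`` to allow for inter-gene
  correlation.
* ``fisher_overlap`` -- 2x2 exact test of set overlap within a universe.
* ``gsva_like_score`` -- a rank-based single-sample enrichment score (a
  Kolmogorov-Smirnov-style random walk on each sample's gene ranking); the
  composite score for a signature is score(up set) - score(down set).
* ``annotate_modules`` -- cluster functional signatures by their module
  enrichment pattern (average linkage), choose the smallest cluster number
  whose cluster sizes respect configured bounds, assign each module the
  cluster of its most-enriched signature, and label clusters by
  bag-of-words Fisher enrichment of signature-name terms.
* ``keydriver_filter`` -- intersect differential expression, module
  enrichment, and externally supplied hub lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


def camera_competitive(statistics: pd.Series, gene_set,
                       intergene_cor: float = 0.01):
    """Competitive gene-set test with inter-gene-correlation adjustment.

    Compares the mean statistic of set members against the rest of the
    universe with a two-sample t-test whose in-set variance term is inflated
    by ``VIF = 1 + (m - 1) * intergene_cor``.  Returns ``(p, direction)``
    with direction 'up' when the set mean exceeds the background.
    """
    stat = statistics.dropna()
    members = stat.index.isin(set(gene_set))
    m = int(members.sum())
    n_rest = len(stat) - m
    if m < 3 or n_rest < 3:
        raise ValueError("need >= 3 genes in set and background after "
                         "intersection with the universe")
    x_in = stat[members].to_numpy(float)
    x_out = stat[~members].to_numpy(float)
    delta = x_in.mean() - x_out.mean()
    df = len(stat) - 2
    s2 = ((m - 1) * x_in.var(ddof=1) + (n_rest - 1) * x_out.var(ddof=1)) / df
    vif = 1.0 + (m - 1) * intergene_cor
    se = np.sqrt(s2 * (vif / m + 1.0 / n_rest))
    t = delta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(p), ("up" if delta > 0 else "down")


def fisher_overlap(set_a, set_b, universe):
    """Fisher exact test of the overlap of two gene sets in a universe.

    Returns ``(odds_ratio, p)``; the odds ratio is the sample OR with a
    Haldane 0.5 correction when any cell is empty.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    table = np.array([[n11, n10], [n01, n00]], float)
    _, p = stats.fisher_exact(table)
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    return float(odds), float(p)


def _walk_score(order_idx: np.ndarray, member_mask: np.ndarray) -> float:
    """Signed maximum deviation of the KS-style hit/miss random walk."""
    hits = member_mask[order_idx]
    m = hits.sum()
    n = len(hits)
    step_hit = 1.0 / m
    step_miss = 1.0 / (n - m)
    walk = np.cumsum(np.where(hits, step_hit, -step_miss))
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def gsva_like_score(expr: pd.DataFrame, up_set, down_set,
                    min_size: int = 5) -> pd.Series:
    """Per-sample composite enrichment score: up-set walk minus down-set walk.

    ``expr`` is genes x samples (typically covariate-residualized log-CPM).
    Each sample's genes are ranked by expression (descending) and each set
    scored by the signed maximum deviation of the hit/miss walk; scores are
    invariant to monotone transforms of a sample's values.
    """
    up = [g for g in set(up_set) if g in expr.index]
    down = [g for g in set(down_set) if g in expr.index]
    if len(up) < min_size or len(down) < min_size:
        raise ValueError(f"both sets need >= {min_size} genes in the matrix")
    up_mask = expr.index.isin(up)
    down_mask = expr.index.isin(down)
    vals = expr.to_numpy(float)
    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        order = np.argsort(-vals[:, j], kind="stable")
        scores[j] = (_walk_score(order, up_mask)
                     - _walk_score(order, down_mask))
    return pd.Series(scores, index=expr.columns, name="composite_score")


# ---------------------------------------------------------------------------
# module annotation by clustered enrichment patterns
# ---------------------------------------------------------------------------

@dataclass
class ModuleAnnotation:
    k: int
    signature_clusters: pd.Series    # signature -> cluster id
    module_clusters: pd.Series       # module -> cluster id
    cluster_labels: dict[int, list[str]]


_STOPWORDS = {"of", "the", "to", "in", "and", "via", "by", "process",
              "gobp", "gocc", "gomf", "go", "hallmark", "kegg", "reactome"}


def tokenize_signature_name(name: str) -> list[str]:
    toks = re.split(r"[_\W]+", name.lower())
    return [t for t in toks if t and t not in _STOPWORDS and not t.isdigit()]


def _label_terms(names_in: list[str], names_all: list[str],
                 max_terms: int = 3) -> list[str]:
    """Fisher bag-of-words enrichment of name terms for one cluster."""
    in_tokens = [set(tokenize_signature_name(n)) for n in names_in]
    all_tokens = [set(tokenize_signature_name(n)) for n in names_all]
    vocab = set().union(*in_tokens) if in_tokens else set()
    scored = []
    n_in, n_all = len(names_in), len(names_all)
    for term in vocab:
        a = sum(term in t for t in in_tokens)
        b = sum(term in t for t in all_tokens) - a
        table = [[a, n_in - a], [b, (n_all - n_in) - b]]
        _, p = stats.fisher_exact(table, alternative="greater")
        scored.append((p, -a, term))
    scored.sort()
    return [term for _, _, term in scored[:max_terms]]


def annotate_modules(enrich_matrix: pd.DataFrame,
                     size_bounds: tuple[float, float] = (0.002, 0.25),
                     k_range=None) -> ModuleAnnotation:
    """Group signatures by module-enrichment pattern and annotate modules.

    ``enrich_matrix`` holds -log10 enrichment p-values, rows = functional
    signatures, columns = modules.  Signatures are clustered with average
    linkage on Euclidean distance; ``k`` is the smallest cluster count in
    ``k_range`` whose cluster sizes all lie within
    ``[lo * n_signatures, hi * n_signatures]``.  Each module is assigned the
    cluster containing its most-enriched signature, and clusters are
    labelled with their Fisher-enriched name terms.
    """
    M = enrich_matrix.to_numpy(float)
    if not np.all(np.isfinite(M)):
        raise ValueError("enrichment matrix must be finite")
    n_sig = M.shape[0]
    if n_sig < 2:
        raise ValueError("need >= 2 signatures")
    lo, hi = size_bounds
    lo_n = max(1, int(np.ceil(lo * n_sig)))
    hi_n = int(np.floor(hi * n_sig))
    if k_range is None:
        k_range = range(2, n_sig + 1)

    Z = linkage(M, method="average", metric="euclidean")
    chosen = None
    last_violation = ""
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        sizes = pd.Series(labels).value_counts()
        if len(sizes) < 2:
            last_violation = (f"k={k}: produced a single cluster of size "
                              f"{sizes.iloc[0]} > {hi_n} (upper bound)")
            continue
        if sizes.max() == 1:
            last_violation = (f"k={k}: degenerate all-singleton clustering "
                              "(lower bound on grouping)")
            continue
        if sizes.max() > hi_n:
            last_violation = f"k={k}: largest cluster {sizes.max()} > {hi_n}"
            continue
        if sizes.min() < lo_n:
            last_violation = f"k={k}: smallest cluster {sizes.min()} < {lo_n}"
            continue
        chosen = (k, labels)
        break
    if chosen is None:
        raise ValueError("no cluster number satisfies the size bounds; "
                         f"last violation: {last_violation}")
    k, labels = chosen
    sig_clusters = pd.Series(labels, index=enrich_matrix.index,
                             name="cluster")

    # module -> cluster of its most-enriched signature
    best_sig = enrich_matrix.idxmax(axis=0)
    module_clusters = best_sig.map(sig_clusters).rename("cluster")

    names_all = list(enrich_matrix.index.astype(str))
    cluster_labels = {}
    for cl in sorted(set(labels)):
        names_in = [str(s) for s, c in sig_clusters.items() if c == cl]
        cluster_labels[int(cl)] = _label_terms(names_in, names_all)
    return ModuleAnnotation(k=int(k), signature_clusters=sig_clusters,
                            module_clusters=module_clusters,
                            cluster_labels=cluster_labels)


def keydriver_filter(de: pd.DataFrame, module_membership: pd.DataFrame,
                     module_enrichment: pd.Series, hub_lists: dict,
                     fdr_threshold: float = 0.05,
                     enrich_threshold: float = 0.05) -> dict[str, list[str]]:
    """Key drivers per module: DE gene + enriched module + module hub.

    A gene is a key driver of a module when (a) it is significant in the DE
    table (BH FDR <= threshold), (b) its module is significantly enriched
    for the signature, and (c) it appears in the module's externally
    supplied hub list.
    """
    sig_genes = set(de.index[de["fdr"] <= fdr_threshold])
    enriched = {m for m, p in module_enrichment.items() if p <= enrich_threshold}
    out: dict[str, list[str]] = {}
    for module, sub in module_membership.groupby("module"):
        if module not in enriched:
            continue
        genes = set(sub["gene"]) & sig_genes & set(hub_lists.get(module, []))
        if genes:
            out[module] = sorted(genes)
    return out
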