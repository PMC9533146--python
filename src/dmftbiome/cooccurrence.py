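"""Genus co-occurrence networks and the network entropy statistic.

Per DMFT category: Spearman rank correlation between genus relative
abundances, Benjamini-Hochberg FDR adjustment of the pairwise p-values,
pruning to |rho| strictly > 0.5, and an undirected graph whose edges carry
the correlation and a significance flag. Significance is an edge
attribute (edges are "colored" by it), never a pruning criterion.

The entropy statistic is the fraction of retained associations that are
significant after FDR; a high fraction reads as low entropy (non-random
community structure).
"""

from __future__ import annotations

import warnings
from typing import Optional

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

DEFAULT_RHO_THRESHOLD = 0.5
DEFAULT_ALPHA = 0.05


def spearman_matrix(
    genus_table: FeatureTable, p_method: str = "t", n_resamples: int = 9999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Spearman rho and p over genera (columns) of a table.

    Correlations are computed on relative abundances with average-rank
    ties. ``p_method='t'`` uses the large-sample t approximation
    (recommended for n >= 10); ``'permutation'`` uses seeded random
    permutations, for small cohorts. Constant genera get NaN rho/p for
    all their pairs and a warning.
    """
    if genus_table.n_samples < 4:
        raise ValueError("need at least 4 samples for rank correlation")
    if genus_table.n_taxa < 2:
        raise ValueError("need at least 2 genera")
    rel = genus_table.relative_abundance()
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(rel, axis=0)
    if np.ndim(rho) == 0:  # scipy returns scalars for exactly 2 columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[np.nan, float(p)], [float(p), np.nan]])
    rho = np.asarray(rho, dtype=float).copy()
    p = np.asarray(p, dtype=float).copy()
    const = rel.std(axis=0) == 0
    if const.any():
        names = [t for t, c in zip(genus_table.taxon_ids, const) if c]
        warnings.warn(f"constant genera excluded from correlation: {names}")
        rho[const, :] = np.nan
        rho[:, const] = np.nan
        p[const, :] = np.nan
        p[:, const] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, np.nan)  # self-pairs are never tested

    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        n, m = rel.shape
        ranks = stats.rankdata(rel, axis=0)
        for i in range(m):
            if const[i]:
                continue
            for j in range(i + 1, m):
                if const[j]:
                    continue
                obs = abs(rho[i, j])
                count = 0
                rj = ranks[:, j].copy()
                for _ in range(n_resamples):
                    rng.shuffle(rj)
                    r = np.corrcoef(ranks[:, i], rj)[0, 1]
                    if abs(r) >= obs - 1e-12:
                        count += 1
                p[i, j] = p[j, i] = (1 + count) / (1 + n_resamples)
    elif p_method != "t":
        raise ValueError("p_method must be 't' or 'permutation'")
    return rho, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return p_adj.reshape(p.shape)


def build_graph(
    rho: np.ndarray,
    p_adj: np.ndarray,
    genus_names,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    category: Optional[str] = None,
) -> nx.Graph:
    """Prune a correlation matrix into an undirected co-occurrence graph.

    An edge exists for every unordered pair with |rho| strictly above the
    threshold (a pair at exactly 0.5 gets no edge); ``significant`` marks
    edges whose adjusted p is <= alpha. NaN correlations (constant
    genera) never form edges. All genera appear as nodes.
    """
    rho = np.asarray(rho, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    names = list(genus_names)
    if rho.shape != p_adj.shape or rho.shape != (len(names), len(names)):
        raise ValueError("rho / p_adj / genus_names are not aligned")
    g = nx.Graph(category=category, rho_threshold=float(rho_threshold), alpha=float(alpha))
    g.add_nodes_from(names)
    m = len(names)
    n_tested = 0
    for i in range(m):
        for j in range(i + 1, m):
            r = rho[i, j]
            if np.isnan(r):
                continue
            n_tested += 1
            if abs(r) > rho_threshold:
                pa = float(p_adj[i, j])
                g.add_edge(
                    names[i],
                    names[j],
                    rho=float(r),
                    abs_rho=abs(float(r)),
                    p_adj=pa,
                    significant=bool(pa <= alpha),
                )
    g.graph["n_pairs_tested"] = n_tested
    return g


def network_for_table(
    genus_table: FeatureTable,
    rho_threshold: float = DEFAULT_RHO_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    category: Optional[str] = None,
) -> nx.Graph:
    """Spearman -> BH-FDR -> prune, in one call, for one sample group."""
    rho, p = spearman_matrix(genus_table)
    iu = np.triu_indices_from(p, k=1)
    valid = ~np.isnan(p[iu])
    p_adj = np.full_like(p, np.nan)
    flat = np.full(valid.sum(), np.nan)
    flat[:] = bh_fdr(p[iu][valid])
    tmp = np.full(iu[0].size, np.nan)
    tmp[valid] = flat
    p_adj[iu] = tmp
    p_adj[(iu[1], iu[0])] = tmp
    return build_graph(
        rho, p_adj, genus_table.taxon_ids, rho_threshold=rho_threshold, alpha=alpha, category=category
    )


def entropy_statistic(g: nx.Graph, denominator: str = "edges") -> float:
    """Fraction of associations that are FDR-significant.

    ``denominator='edges'`` (default) divides by the retained edges of the
    pruned graph; ``'all_pairs'`` divides by every genus pair tested.
    Reported raw: the caller decides whether a high fraction is "low
    entropy".
    """
    n_sig = sum(1 for _, _, d in g.edges(data=True) if d["significant"])
    if denominator == "edges":
        if g.number_of_edges() == 0:
            raise ValueError("entropy statistic undefined for an edgeless graph")
        return n_sig / g.number_of_edges()
    if denominator == "all_pairs":
        n_pairs = g.graph.get("n_pairs_tested", 0)
        if n_pairs == 0:
            raise ValueError("no tested pairs recorded")
        return n_sig / n_pairs
    raise ValueError("denominator must be 'edges' or 'all_pairs'")


def communities(g: nx.Graph, seed: int = 0) -> list[list[str]]:
    """Greedy modularity communities on |rho| edge weights.

    Deterministic: communities are sorted internally and by (size desc,
    lexicographic first member). Isolated nodes come out as singletons.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if g.number_of_edges() == 0:
        comms = [[n] for n in sorted(g.nodes)]
        return comms
    raw = nx.community.greedy_modularity_communities(g, weight="abs_rho")
    comms = [sorted(c) for c in raw]
    comms.sort(key=lambda c: (-len(c), c[0]))
    return comms


def degree_rank(g: nx.Graph, top_k: int = 50) -> list[str]:
    """Genera ranked by degree centrality, descending, ties lexicographic."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    ranked = sorted(g.nodes, key=lambda n: (-g.degree(n), n))
    return ranked[: min(top_k, len(ranked))]


def write_edge_list(g: nx.Graph, path) -> None:
    """Edge-list TSV: u, v, rho, p_adj, significant."""
    with open(path, "w") as fh:
        fh.write("u\tv\trho\tp_adj\tsignificant\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['rho']:.6g}\t{d['p_adj']:.6g}\t{d['significant']}\n")
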