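"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: direct formula
evaluation, exhaustive enumeration, and per-branch tree walks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def unifrac_pair(counts_u, counts_v, taxa, tree, weighted: bool, normalized: bool = True):
    """UniFrac between two samples by iterating every branch of the tree."""
    idx = {t: i for i, t in enumerate(taxa)}
    counts_u = np.asarray(counts_u, float)
    counts_v = np.asarray(counts_v, float)
    tot_u, tot_v = counts_u.sum(), counts_v.sum()
    num = den = 0.0
    for node in tree.postorder(include_self=False):
        if node.length is None:
            continue
        leaves = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        cu = sum(counts_u[idx[l]] for l in leaves if l in idx)
        cv = sum(counts_v[idx[l]] for l in leaves if l in idx)
        a, b = cu / tot_u, cv / tot_v
        if weighted:
            num += node.length * abs(a - b)
            den += node.length * (a + b)
        else:
            in_u, in_v = cu > 0, cv > 0
            if in_u != in_v:
                num += node.length
            if in_u or in_v:
                den += node.length
    if weighted and not normalized:
        return num
    return num / den if den > 0 else 0.0


def unifrac_matrix(table, tree, weighted: bool, normalized: bool = True) -> np.ndarray:
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = unifrac_pair(
                table.counts[i], table.counts[j], table.taxon_ids, tree, weighted, normalized
            )
    return out


def permanova_f(d2: np.ndarray, labels) -> float:
    """Pseudo-F by direct double loops over the squared-distance matrix."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d2[i, j] for a, i in enumerate(members) for j in members[a + 1 :]
        ) / len(members)
    ss_between = ss_total - ss_within
    return (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))


def permanova_exact_p(d2: np.ndarray, labels) -> tuple[float, float]:
    """Observed pseudo-F and the exact p over all label permutations."""
    f_obs = permanova_f(d2, labels)
    count = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if permanova_f(d2, perm) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total


def spearman_rank_then_pearson(x: np.ndarray) -> np.ndarray:
    """Spearman matrix as Pearson correlation of average ranks."""
    ranks = np.column_stack([rankdata(x[:, j]) for j in range(x.shape[1])])
    return np.corrcoef(ranks, rowvar=False)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up: p_(i) * m / i with a running minimum from the top."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def poisson_loglik_mle(y, X):
    """Poisson log-link ML fit via a generic optimizer (no IRLS)."""
    from scipy.optimize import minimize

    y = np.asarray(y, float)
    X = np.asarray(X, float)

    def negll(beta):
        eta = X @ beta
        return float(np.sum(np.exp(eta)) - y @ eta)

    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(max(y.mean(), 0.1))
    res = minimize(negll, beta0, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    return res.x
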