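"""Alpha and beta diversity, ordination, TVE, and PERMANOVA.

Conventions: Shannon entropy is in nats; Jensen-Shannon is returned as the
divergence (natural log; ln 2 for disjoint supports), with a flag for the
metric square-root form; weighted UniFrac defaults to the normalized
variant so all stock distances live on [0, 1].

TVE — the fraction of (positive) ordination inertia captured by the first
k principal coordinates — is the summary used throughout the influence
analysis; k defaults to 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _scipy_entropy
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .feature_table import FeatureTable

DEFAULT_TVE_K = 5
DEFAULT_N_PERM = 9999


# -- alpha diversity -----------------------------------------------------

def shannon(counts_for_sample) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of one sample's counts."""
    x = np.asarray(counts_for_sample, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single sample's count vector")
    if x.sum() <= 0:
        raise ValueError("all-zero sample has undefined Shannon entropy")
    if np.any(x < 0):
        raise ValueError("negative counts")
    return float(_scipy_entropy(x))  # scipy normalizes and uses ln


def observed_richness(counts_for_sample) -> int:
    """Number of taxa with count > 0."""
    x = np.asarray(counts_for_sample)
    return int(np.count_nonzero(x > 0))


def rarefy_sample(counts_for_sample, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    x = np.asarray(counts_for_sample, dtype=np.int64)
    if depth > x.sum():
        raise ValueError(f"requested depth {depth} exceeds sample depth {x.sum()}")
    return rng.multivariate_hypergeometric(x, depth)


def rarefaction_curve(
    table: FeatureTable,
    depths,
    n_reps: int = 10,
    seed: int = 0,
    metric: str = "observed",
) -> pd.DataFrame:
    """Mean +/- sd alpha diversity per sample at each rarefaction depth.

    Subsampling is without replacement (multivariate hypergeometric),
    seeded. Samples shallower than a requested depth are skipped with a
    warning. Returns a tidy frame (sample_id, depth, mean, sd).
    """
    if metric not in ("observed", "shannon"):
        raise ValueError("metric must be 'observed' or 'shannon'")
    alpha = observed_richness if metric == "observed" else shannon
    rng = np.random.default_rng(seed)
    rows = []
    sample_depths = table.depths()
    for depth in depths:
        for i, sid in enumerate(table.sample_ids):
            if depth > sample_depths[i]:
                warnings.warn(
                    f"sample {sid} (depth {sample_depths[i]}) skipped at "
                    f"rarefaction depth {depth}"
                )
                continue
            vals = [alpha(rarefy_sample(table.counts[i], int(depth), rng)) for _ in range(n_reps)]
            rows.append(
                {
                    "sample_id": sid,
                    "depth": int(depth),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if n_reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "depth", "mean", "sd"])


# -- beta diversity ------------------------------------------------------

def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    rel = table.relative_abundance()
    return DistanceMatrix(squareform(pdist(rel, metric="braycurtis")), ids=table.sample_ids)


def jensen_shannon(table: FeatureTable, metric_form: bool = False) -> DistanceMatrix:
    """Jensen-Shannon divergence (natural log) between sample compositions.

    ``metric_form=True`` returns the square root, which is a true metric.
    """
    rel = table.relative_abundance()
    root = squareform(pdist(rel, metric="jensenshannon"))  # sqrt-JSD, base e
    return DistanceMatrix(root if metric_form else root**2, ids=table.sample_ids)


def unifrac(
    table: FeatureTable,
    tree: TreeNode,
    weighted: bool = False,
    normalized: bool = True,
) -> DistanceMatrix:
    """UniFrac distances between samples over a rooted phylogeny.

    Unweighted UniFrac is the unique-branch-length fraction; weighted
    UniFrac sums branch lengths times abundance-proportion differences and
    is normalized to [0, 1] by default (``normalized=False`` gives the raw
    form). Every taxon in the table must be a leaf of the tree.
    """
    leaves = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in leaves]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    # leaf coverage is checked above, so skbio's validation (which also
    # rejects multifurcating roots that are perfectly fine for UniFrac)
    # is skipped
    kwargs = dict(taxa=list(table.taxon_ids), tree=tree, validate=False)
    if weighted:
        dm = beta_diversity(
            "weighted_unifrac",
            table.counts,
            ids=list(table.sample_ids),
            normalized=normalized,
            **kwargs,
        )
    else:
        dm = beta_diversity(
            "unweighted_unifrac", table.counts, ids=list(table.sample_ids), **kwargs
        )
    return dm


# -- ordination ----------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``eigenvalues`` holds the full descending spectrum (negative values
    reported, not embedded); ``coordinates`` has one column per strictly
    positive eigenvalue, scaled by sqrt(lambda).
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    sample_ids: tuple[str, ...]

    def tve(self, k: int = DEFAULT_TVE_K) -> float:
        return tve(self, k=k)


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling (Gower double-centering + eigendecomposition)."""
    D = np.asarray(d.data, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.size else np.array([], bool)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return OrdinationResult(coords, vals, tuple(d.ids))


def tve(ordination: OrdinationResult, k: int = DEFAULT_TVE_K) -> float:
    """Fraction of positive ordination inertia in the first ``k`` axes.

    Negative eigenvalues are truncated at zero (no Lingoes/Cailliez
    correction). In [0, 1]; monotone non-decreasing in k.
    """
    lam = np.maximum(ordination.eigenvalues, 0.0)
    total = lam.sum()
    if total <= 0:
        raise ValueError("no positive eigenvalues; TVE undefined")
    return float(lam[: max(k, 0)].sum() / total)


# -- PERMANOVA -----------------------------------------------------------

def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ssw = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if idx.size:
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ssw


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is either a sequence of labels aligned with ``d.ids`` or a
    mapping sample_id -> label. Returns pseudo-F, R^2 and the permutation
    p-value with the +1 correction (label permutations, seeded), matching
    the classic adonis decomposition:

        SS_total  = sum_{i<j} d_ij^2 / n
        SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
        pseudo_F  = (SS_between/(g-1)) / (SS_within/(n-g))
    """
    ids = list(d.ids)
    if isinstance(groups, dict):
        labels = np.asarray([groups[s] for s in ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != len(ids):
            raise ValueError("groups length does not match distance matrix")
    uniq = np.unique(labels)
    n, g = len(ids), len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n < 4:
        raise ValueError("PERMANOVA needs at least 4 samples")

    d2 = np.asarray(d.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, labels, uniq)
    ss_between = ss_total - ss_within
    df_between, df_within = g - 1, n - g
    if df_within <= 0 or ss_within <= 0:
        raise ValueError("degenerate grouping (a group equals the whole set?)")
    f_obs = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    count_ge = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        ssw = _ss_within(d2, perm_labels, uniq)
        ssb = ss_total - ssw
        f_perm = (ssb / df_between) / (ssw / df_within) if ssw > 0 else np.inf
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "R2": float(r2), "p": float(p), "n_perm": int(n_perm)}
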