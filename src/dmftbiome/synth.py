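"""Synthetic oral-microbiome cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a cross-sectional caries
cohort: ~88 participants spread over five DMFT severity categories, a
stable high-prevalence shared core of genera, category-specific
low-prevalence accessory ("invader") genera, lognormal library sizes (so
the depth filter has something to drop), and a latent-factor correlation
structure whose strength tunes how many pairwise genus associations are
significant. Every planted quantity is recorded in a truth object so
downstream recovery can be tested without any external data.

Counts for sample s are drawn hierarchically:

    depth_s   ~ round(LogNormal(mu + x_s' beta, sigma))
    log a_s   = log a_base + strength * (Lambda f_s),  f_s ~ N(0, I)
    p_s       ~ Dirichlet(a_s restricted to taxa present in s's category)
    counts_s  ~ Multinomial(depth_s, p_s)

Shared latent factors shift the log-concentrations of the taxa they load
on, inducing positive rank correlation between those taxa; strength = 0
gives (compositionally) independent taxa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

from .feature_table import (
    CATEGORY_ORDER,
    DMFT_RANGES,
    DmftCategory,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    write_metadata,
    write_table,
    write_taxonomy,
    write_tree,
)

# Default cohort proportions: 88 participants, 67% HIV positive, 57%
# female, 42% with periodontitis, mean salivary flow 0.9 ml/min (sd 0.5)
# — typical of an HIV-clinic caries cohort.
DEFAULT_N_PER_CATEGORY = (11, 32, 21, 16, 8)
HIV_POSITIVE_RATE = 0.67
FEMALE_RATE = 0.568
PERIODONTITIS_RATE = 0.42
FLOW_MEAN, FLOW_SD = 0.9, 0.5


@dataclass
class SyntheticDesign:
    """Tunable description of a synthetic cohort.

    Defaults reproduce the cohort conditions the pipeline is meant for:
    five DMFT categories with 11/32/21/16/8 participants, ~160 genera of
    which 60 form a fully prevalent core, lognormal depths with a median
    near 10k reads so that roughly a tenth of samples fall under the
    3,000-read filter, and a moderate latent correlation structure.
    """

    n_per_category: Sequence[int] = DEFAULT_N_PER_CATEGORY
    n_taxa: int = 160
    core_size: int = 60
    core_prevalence_target: float = 1.0
    accessory_rate: float = 0.15
    depth_log_mean: float = 9.2
    depth_log_sd: float = 0.9
    base_concentration: float = 0.5
    accessory_concentration: float = 0.08
    n_latent_factors: int = 4
    factor_strength: float = 1.0
    glm_coefficients: Optional[Mapping[str, object]] = None
    seed: int = 0
    factor_loadings: Optional[np.ndarray] = None  # (n_taxa, n_factors) override

    def validate(self) -> None:
        if self.core_size > self.n_taxa:
            raise ValueError(
                f"core_size ({self.core_size}) exceeds n_taxa ({self.n_taxa})"
            )
        if len(self.n_per_category) != len(CATEGORY_ORDER):
            raise ValueError("n_per_category must have five entries")
        if any(n < 0 for n in self.n_per_category):
            raise ValueError("n_per_category entries must be >= 0")
        for name, val in (
            ("core_prevalence_target", self.core_prevalence_target),
            ("accessory_rate", self.accessory_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.factor_strength < 0:
            raise ValueError("factor_strength must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted structure recorded for recovery tests."""

    core_taxa: frozenset
    accessory_taxa_by_category: dict
    factor_loadings: np.ndarray = field(repr=False)
    glm_coefficients: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "core_taxa": sorted(self.core_taxa),
                "accessory_taxa_by_category": {
                    k: sorted(v) for k, v in self.accessory_taxa_by_category.items()
                },
                "factor_loadings": np.asarray(self.factor_loadings).tolist(),
                "glm_coefficients": self.glm_coefficients,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )


def _taxon_ids(n: int) -> list[str]:
    return [f"g{i:03d}" for i in range(n)]


def _fictional_taxonomy(taxon_ids: Sequence[str]) -> TaxonomyMap:
    # Fixed fictional lineage template: exercises rank aggregation
    # (several genera share each family) without implying real biology.
    lineages = {}
    for i, tid in enumerate(taxon_ids):
        lineages[tid] = (
            "Bacteria",
            f"Phylum{i % 7:02d}",
            f"Class{i % 11:02d}",
            f"Order{i % 17:02d}",
            f"Family{i % 23:02d}",
            f"Genus{i:03d}",
        )
    return TaxonomyMap(lineages)


def generate_tree(taxon_ids: Sequence[str], seed: int) -> TreeNode:
    """Random rooted binary tree over ``taxon_ids`` by successive joins.

    Branch lengths are exponential (mean 0.1). Identical seeds give an
    identical Newick string.
    """
    ids = [str(t) for t in taxon_ids]
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t) for t in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        left.length = float(rng.exponential(0.1))
        right.length = float(rng.exponential(0.1))
        parent = TreeNode(children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _covariate_effect(coeffs: Mapping[str, object], covariate: str, category: str) -> float:
    """Effect size for a covariate: scalar applies everywhere, a mapping
    is per-category."""
    if coeffs is None or covariate not in coeffs:
        return 0.0
    val = coeffs[covariate]
    if isinstance(val, Mapping):
        return float(val.get(category, 0.0))
    return float(val)


def generate_dataset(
    design: SyntheticDesign,
) -> tuple[FeatureTable, SampleMetadata, TaxonomyMap, TreeNode, SyntheticTruth]:
    """Draw a full synthetic cohort from ``design``.

    Returns the count table, clinical metadata, taxonomy, phylogeny, and
    the ground-truth record. Identical seeds give bit-identical outputs.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n_taxa = design.n_taxa
    taxa = _taxon_ids(n_taxa)
    tax = _fictional_taxonomy(taxa)

    core_idx = np.arange(design.core_size)
    noncore_idx = np.arange(design.core_size, n_taxa)
    core_set = frozenset(taxa[i] for i in core_idx)

    # Category-specific accessory pools: disjoint slices of the shuffled
    # non-core taxa, each of size accessory_rate * |non-core|.
    shuffled = noncore_idx.copy()
    rng.shuffle(shuffled)
    per_cat = int(round(design.accessory_rate * len(noncore_idx)))
    accessory_idx: dict[str, np.ndarray] = {}
    pos = 0
    for cat in CATEGORY_ORDER:
        take = shuffled[pos : pos + per_cat]
        accessory_idx[cat.value] = take
        pos += len(take)

    # Latent-factor loadings: each factor loads on a random quarter of
    # the taxa with half-normal weights, unless the design overrides.
    L = design.n_latent_factors
    if design.factor_loadings is not None:
        loadings = np.asarray(design.factor_loadings, dtype=float)
        if loadings.shape != (n_taxa, L):
            raise ValueError(
                f"factor_loadings shape {loadings.shape} != ({n_taxa}, {L})"
            )
    else:
        loadings = np.zeros((n_taxa, L))
        for f in range(L):
            chosen = rng.choice(n_taxa, size=max(1, n_taxa // 4), replace=False)
            loadings[chosen, f] = np.abs(rng.normal(size=chosen.size))

    base_alpha = np.zeros(n_taxa)
    base_alpha[core_idx] = design.base_concentration
    # accessory concentration assigned per category below

    sample_ids: list[str] = []
    categories: list[str] = []
    scores: list[int] = []
    s = 0
    for cat, n_cat in zip(CATEGORY_ORDER, design.n_per_category):
        lo, hi = DMFT_RANGES[cat]
        hi = min(hi, 20)  # observed scores rarely exceed 20
        for _ in range(n_cat):
            sample_ids.append(f"s{s:03d}")
            categories.append(cat.value)
            scores.append(int(rng.integers(lo, hi + 1)))
            s += 1
    n_samples = len(sample_ids)

    hiv = rng.random(n_samples) < HIV_POSITIVE_RATE
    sex_female = rng.random(n_samples) < FEMALE_RATE
    perio = rng.random(n_samples) < PERIODONTITIS_RATE
    flow = np.maximum(rng.normal(FLOW_MEAN, FLOW_SD, n_samples), 0.05)

    coeffs = dict(design.glm_coefficients or {})
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    factors = rng.normal(size=(n_samples, L))

    for i in range(n_samples):
        cat = categories[i]
        alpha = base_alpha.copy()
        acc = accessory_idx[cat]
        alpha[acc] = design.accessory_concentration
        if design.core_prevalence_target < 1.0:
            keep = rng.random(core_idx.size) < design.core_prevalence_target
            alpha[core_idx[~keep]] = 0.0
        shift = design.factor_strength * (loadings @ factors[i])
        present = alpha > 0
        alpha = np.where(present, alpha * np.exp(shift), 0.0)

        lin = (
            _covariate_effect(coeffs, "hiv", cat) * hiv[i]
            + _covariate_effect(coeffs, "sex", cat) * (not sex_female[i])
            + _covariate_effect(coeffs, "periodontitis", cat) * perio[i]
        )
        depth = max(1, int(round(np.exp(rng.normal(design.depth_log_mean + lin, design.depth_log_sd)))))

        p = np.zeros(n_taxa)
        p[present] = rng.dirichlet(alpha[present])
        row = rng.multinomial(depth, p)
        if design.core_prevalence_target >= 1.0:
            # repair: guarantee full core prevalence without changing depth
            zero_core = core_idx[row[core_idx] == 0]
            for t in zero_core:
                donor = int(np.argmax(row))
                if row[donor] <= 1:
                    break
                row[donor] -= 1
                row[t] = 1
        counts[i] = row

    table = FeatureTable(counts, tuple(sample_ids), tuple(taxa))
    meta = SampleMetadata.from_scores(
        {sid: sc for sid, sc in zip(sample_ids, scores)},
        hiv_status=["positive" if h else "negative" for h in hiv],
        sex=["female" if f else "male" for f in sex_female],
        periodontal_status=["periodontitis" if p_ else "gingivitis" for p_ in perio],
        flow_rate=np.round(flow, 3),
    )
    tree = generate_tree(taxa, seed=design.seed + 1)
    truth = SyntheticTruth(
        core_taxa=core_set,
        accessory_taxa_by_category={
            cat: frozenset(taxa[i] for i in idx) for cat, idx in accessory_idx.items()
        },
        factor_loadings=loadings,
        glm_coefficients=coeffs,
        seed=design.seed,
    )
    return table, meta, tax, tree, truth


def write_dataset(
    out_dir: str | Path,
    table: FeatureTable,
    meta: SampleMetadata,
    tax: TaxonomyMap,
    tree: TreeNode,
    truth: SyntheticTruth,
) -> dict[str, str]:
    """Serialize a generated cohort to TSV/Newick/JSON files in ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    write_table(table, paths["table"])
    write_metadata(meta, paths["metadata"])
    write_taxonomy(tax, paths["taxonomy"])
    write_tree(tree, paths["tree"])
    paths["truth"].write_text(truth.to_json())
    return {k: str(v) for k, v in paths.items()}
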