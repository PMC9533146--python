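"""Leave-one-genus-out TVE influence analysis.

For each candidate genus, drop its column from the table (and its leaf
from the phylogeny), recompute the weighted-UniFrac PCoA, and record the
change in TVE against the unperturbed baseline. Drops are one at a time,
never cumulative, so permuting the candidate list cannot change any
delta. The signed delta is perturbed-minus-baseline; callers usually rank
by |delta|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from skbio import TreeNode

from .diversity import DEFAULT_TVE_K, pcoa, tve, unifrac
from .feature_table import FeatureTable

OXYGEN_CLASSES = ("aerobic", "anaerobic", "facultative", "unknown")


@dataclass(frozen=True)
class OxygenAnnotation:
    """Genus -> oxygen-utilization class; unlisted genera are 'unknown'."""

    classes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        fixed = {}
        for genus, cls in self.classes.items():
            if cls not in OXYGEN_CLASSES:
                raise ValueError(f"unknown oxygen class {cls!r} for {genus!r}")
            fixed[str(genus)] = cls
        object.__setattr__(self, "classes", fixed)

    def of(self, genus: str) -> str:
        return self.classes.get(genus, "unknown")

    @classmethod
    def from_file(cls, path) -> "OxygenAnnotation":
        """Two-column TSV: genus <tab> class."""
        mapping = {}
        for ln in Path(path).read_text().splitlines():
            if not ln.strip() or ln.startswith("#"):
                continue
            genus, klass = ln.split("\t")[:2]
            mapping[genus.strip()] = klass.strip()
        return cls(mapping)


@dataclass(frozen=True)
class InfluenceReport:
    """Per-genus signed TVE change for one DMFT category."""

    category: Optional[str]
    baseline_tve: float
    candidates: tuple[str, ...]
    delta_tve: Mapping[str, float]

    def ranked_by_magnitude(self) -> list[str]:
        return sorted(self.candidates, key=lambda g: (-abs(self.delta_tve[g]), g))

    def max_abs_delta(self) -> float:
        return max(abs(v) for v in self.delta_tve.values())

    def to_tsv(self, path, oxygen: Optional[OxygenAnnotation] = None) -> None:
        oxy = oxygen or OxygenAnnotation()
        with open(path, "w") as fh:
            fh.write("genus\tdelta_tve\toxygen_class\n")
            for g in self.candidates:
                fh.write(f"{g}\t{self.delta_tve[g]:.8g}\t{oxy.of(g)}\n")


def _tve_of(table: FeatureTable, tree: TreeNode, k: int) -> float:
    dm = unifrac(table, tree, weighted=True, normalized=True)
    return tve(pcoa(dm), k=k)


def tve_impact(
    table: FeatureTable,
    tree: TreeNode,
    candidates: Sequence[str],
    k: int = DEFAULT_TVE_K,
    category: Optional[str] = None,
) -> InfluenceReport:
    """Leave-one-out TVE deltas for each candidate genus.

    delta(g) = TVE(table without g) - TVE(table). A genus with all-zero
    counts cannot move any sample's branch proportions, so its delta is
    exactly zero. If dropping a genus empties a sample, that sample is
    excluded from the perturbed run with a warning.
    """
    candidates = [str(c) for c in candidates]
    missing = [c for c in candidates if c not in table.taxon_ids]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    leaves = {t.name for t in tree.tips()}
    absent = [c for c in candidates if c not in leaves]
    if absent:
        raise ValueError(f"candidates missing from tree: {absent}")
    if table.n_taxa < 2:
        raise ValueError("dropping the only genus leaves no community")
    if table.n_samples < 4:
        raise ValueError("need at least 4 samples for an ordination")

    baseline = _tve_of(table, tree, k)
    deltas: dict[str, float] = {}
    for g in candidates:
        col = table.counts[:, table.taxon_index(g)]
        if not col.any():
            deltas[g] = 0.0
            continue
        sub = table.drop_taxa([g])
        empty = sub.depths() == 0
        if empty.any():
            dropped = [s for s, e in zip(sub.sample_ids, empty) if e]
            warnings.warn(
                f"dropping {g!r} empties samples {dropped}; excluded from the perturbed run"
            )
            sub = sub.select_samples(
                [s for s, e in zip(sub.sample_ids, empty) if not e]
            )
            if sub.n_samples < 4:
                raise ValueError(f"dropping {g!r} leaves too few samples")
        pruned = tree.shear(list(sub.taxon_ids))
        deltas[g] = _tve_of(sub, pruned, k) - baseline
    return InfluenceReport(category, baseline, tuple(candidates), deltas)


def select_candidates(
    mode: str,
    table: Optional[FeatureTable] = None,
    graph: Optional[nx.Graph] = None,
    top_k: int = 50,
) -> list[str]:
    """Candidate genera for the influence analysis.

    ``mode='abundance'`` ranks by mean relative abundance across samples;
    ``mode='centrality'`` ranks network nodes by degree. Both truncate at
    ``top_k`` (default 50) and break ties lexicographically.
    """
    if mode == "abundance":
        if table is None or table.n_taxa == 0 or table.n_samples == 0:
            raise ValueError("abundance mode needs a non-empty table")
        mean_rel = table.relative_abundance().mean(axis=0)
        ranked = sorted(
            zip(table.taxon_ids, mean_rel), key=lambda tr: (-tr[1], tr[0])
        )
        return [t for t, _ in ranked[: min(top_k, len(ranked))]]
    if mode == "centrality":
        from .cooccurrence import degree_rank

        if graph is None:
            raise ValueError("centrality mode needs a co-occurrence graph")
        return degree_rank(graph, top_k=top_k)
    raise ValueError("mode must be 'abundance' or 'centrality'")
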