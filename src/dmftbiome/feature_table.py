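"""Abundance data model: count tables, taxonomy, sample metadata, and I/O.

The sample x taxon count table is the universal currency of the pipeline.
Counts stay integers throughout; conversion to relative abundance happens
inside downstream operations and is never stored here. Presence of a taxon
in a sample means count > 0.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Maximum possible DMFT score (32 permanent teeth).
MAX_DMFT = 32


class DmftCategory(str, Enum):
    """Severity bins of the decayed/missing/filled-teeth (DMFT) index.

    Boundaries: healthy = 0, low = 1-3, medium = 4-6, high = 7-13,
    extremely_high >= 14.
    """

    healthy = "healthy"
    low = "low"
    medium = "medium"
    high = "high"
    extremely_high = "extremely_high"


#: Integer score range covered by each category (inclusive endpoints).
DMFT_RANGES: dict[DmftCategory, tuple[int, int]] = {
    DmftCategory.healthy: (0, 0),
    DmftCategory.low: (1, 3),
    DmftCategory.medium: (4, 6),
    DmftCategory.high: (7, 13),
    DmftCategory.extremely_high: (14, MAX_DMFT),
}

CATEGORY_ORDER = list(DmftCategory)


def categorize_dmft(score: int) -> DmftCategory:
    """Map a DMFT score to its severity category.

    A score of exactly 14 is extremely_high: the high bin ends at 13, so
    the >=14 boundary is the only partition of the non-negative integers
    consistent with the bin definitions.

    Raises
    ------
    ValueError
        If ``score`` is negative or not an integer.
    """
    if isinstance(score, bool) or not isinstance(score, numbers.Integral):
        raise ValueError(f"DMFT score must be an integer, got {score!r}")
    score = int(score)
    if score < 0:
        raise ValueError(f"DMFT score must be non-negative, got {score}")
    if score == 0:
        return DmftCategory.healthy
    if score <= 3:
        return DmftCategory.low
    if score <= 6:
        return DmftCategory.medium
    if score <= 13:
        return DmftCategory.high
    return DmftCategory.extremely_high


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate {kind} labels: {dups}")


@dataclass(frozen=True)
class FeatureTable:
    """Sample x taxon matrix of non-negative integer counts.

    Row sums are per-sample sequencing depths. Sample and taxon labels are
    unique and aligned with the matrix axes.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (samples x taxa)")
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("counts must be integers")
        counts = counts.astype(np.int64, copy=True)
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be non-negative")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        """Build from a samples-as-rows DataFrame."""
        return cls(df.to_numpy(), tuple(df.index.astype(str)), tuple(df.columns.astype(str)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    # -- basic views ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized float matrix; raises on an all-zero sample."""
        d = self.depths()
        if np.any(d == 0):
            empty = [s for s, ds in zip(self.sample_ids, d) if ds == 0]
            raise ValueError(f"samples with zero depth: {empty}")
        return self.counts / d[:, None]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def taxon_index(self, taxon_id: str) -> int:
        return self.taxon_ids.index(taxon_id)

    # -- subsetting ------------------------------------------------------

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        idx = [self.sample_ids.index(s) for s in keep]
        return FeatureTable(self.counts[idx, :], tuple(keep), self.taxon_ids)

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "FeatureTable":
        drop = set(taxon_ids)
        missing = drop - set(self.taxon_ids)
        if missing:
            raise KeyError(f"taxa not in table: {sorted(missing)}")
        keep = [i for i, t in enumerate(self.taxon_ids) if t not in drop]
        return FeatureTable(
            self.counts[:, keep], self.sample_ids, tuple(self.taxon_ids[i] for i in keep)
        )


def filter_by_depth(table: FeatureTable, min_depth: int) -> FeatureTable:
    """Retain exactly the samples whose total count is >= ``min_depth``.

    The depth filter is inclusive ("at least"), acts on samples, leaves the
    taxon set unchanged, and is idempotent. An empty result is allowed.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    d = table.depths()
    keep = [s for s, ds in zip(table.sample_ids, d) if ds >= min_depth]
    return table.select_samples(keep)


@dataclass(frozen=True)
class TaxonomyMap:
    """taxon_id -> ranked lineage (domain..genus), SILVA-style.

    Empty strings mark unassigned ranks; None is not allowed.
    """

    lineages: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        fixed = {}
        for tid, lin in self.lineages.items():
            lin = tuple(lin)
            if len(lin) != len(RANKS):
                raise ValueError(
                    f"lineage for {tid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )
            if any(r is None for r in lin):
                raise ValueError(f"lineage for {tid!r} contains null ranks")
            fixed[str(tid)] = tuple(str(r) for r in lin)
        object.__setattr__(self, "lineages", fixed)

    def rank_of(self, taxon_id: str, rank: str) -> str:
        return self.lineages[taxon_id][RANKS.index(rank)]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages

    def lineage_string(self, taxon_id: str) -> str:
        return ";".join(self.lineages[taxon_id])


def aggregate_rank(table: FeatureTable, tax: TaxonomyMap, rank: str) -> FeatureTable:
    """Collapse taxa to the distinct lineage labels at ``rank``, summing counts.

    Per-sample totals are conserved exactly. Output taxa are ordered by
    first appearance in the input. Taxa missing from the taxonomy are a
    hard error (all offenders listed).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    missing = [t for t in table.taxon_ids if t not in tax]
    if missing:
        raise KeyError(f"taxa without taxonomy entries: {missing}")
    labels = [tax.rank_of(t, rank) for t in table.taxon_ids]
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, lab in enumerate(labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(j)
    out = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    for k, lab in enumerate(order):
        out[:, k] = table.counts[:, groups[lab]].sum(axis=1)
    return FeatureTable(out, table.sample_ids, tuple(order))


# -- sample metadata ----------------------------------------------------

METADATA_COLUMNS = (
    "dmft_score",
    "dmft_category",
    "hiv_status",
    "sex",
    "periodontal_status",
    "flow_rate",
)

HIV_LEVELS = ("positive", "negative")
SEX_LEVELS = ("female", "male")
PERIO_LEVELS = ("gingivitis", "periodontitis")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample clinical attributes keyed by sample id.

    ``dmft_category`` is always the deterministic function of
    ``dmft_score`` (it is recomputed and checked on construction).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data.copy()
        df.index = df.index.astype(str)
        _check_unique(list(df.index), "sample")
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        scores = df["dmft_score"]
        for sid, sc in scores.items():
            if not float(sc).is_integer() or sc < 0 or sc > MAX_DMFT:
                raise ValueError(f"sample {sid}: invalid DMFT score {sc!r}")
        df["dmft_score"] = scores.astype(int)
        expected = [categorize_dmft(s).value for s in df["dmft_score"]]
        given = [str(c) for c in df["dmft_category"]]
        bad = [i for i, (e, g) in enumerate(zip(expected, given)) if e != g]
        if bad:
            sids = [df.index[i] for i in bad]
            raise ValueError(f"dmft_category inconsistent with dmft_score for {sids}")
        df["dmft_category"] = expected
        for col, levels in (
            ("hiv_status", HIV_LEVELS),
            ("sex", SEX_LEVELS),
            ("periodontal_status", PERIO_LEVELS),
        ):
            bad_levels = set(df[col].astype(str)) - set(levels)
            if bad_levels:
                raise ValueError(f"{col}: unknown levels {sorted(bad_levels)}")
        if (df["flow_rate"].astype(float) < 0).any():
            raise ValueError("flow_rate must be >= 0")
        df["flow_rate"] = df["flow_rate"].astype(float)
        object.__setattr__(self, "data", df)

    @classmethod
    def from_scores(cls, scores: Mapping[str, int], **columns) -> "SampleMetadata":
        """Convenience constructor deriving the category from the score."""
        idx = list(scores)
        df = pd.DataFrame(index=idx)
        df["dmft_score"] = [scores[s] for s in idx]
        df["dmft_category"] = [categorize_dmft(scores[s]).value for s in idx]
        df["hiv_status"] = columns.get("hiv_status", "negative")
        df["sex"] = columns.get("sex", "female")
        df["periodontal_status"] = columns.get("periodontal_status", "gingivitis")
        df["flow_rate"] = columns.get("flow_rate", 0.9)
        return cls(df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def category_of(self, sample_id: str) -> DmftCategory:
        return DmftCategory(self.data.loc[sample_id, "dmft_category"])

    def samples_in_category(self, category: DmftCategory | str) -> list[str]:
        cat = DmftCategory(category).value
        return list(self.data.index[self.data["dmft_category"] == cat])

    def select(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        keep = [s for s in self.data.index if s in set(sample_ids)]
        return SampleMetadata(self.data.loc[keep])


# -- on-disk formats -----------------------------------------------------
#
# Count tables: TSV, taxa as rows by default, leading "#TaxonID" header
# (the common amplicon dialect); orientation="samples" flips on read/write.
# Taxonomy: two columns, taxon id + semicolon-delimited lineage string.
# Metadata: TSV with a sample_id column. Trees: Newick.

TABLE_HEADER = "#TaxonID"


def read_table(path: str | Path, orientation: str = "taxa") -> FeatureTable:
    """Read a count table TSV; ``orientation`` names what the rows are."""
    if orientation not in ("taxa", "samples"):
        raise ValueError("orientation must be 'taxa' or 'samples'")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate row labels {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"{path}: duplicate column labels {dups}")
    try:
        mat = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric count entry ({exc})") from None
    if not np.all(mat == np.floor(mat)):
        bad = np.argwhere(mat != np.floor(mat))[0]
        raise ValueError(
            f"{path}: non-integer count at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    if orientation == "taxa":
        return FeatureTable(mat.T, tuple(df.columns), tuple(df.index))
    return FeatureTable(mat, tuple(df.index), tuple(df.columns))


def write_table(table: FeatureTable, path: str | Path, orientation: str = "taxa") -> None:
    if orientation not in ("taxa", "samples"):
        raise ValueError("orientation must be 'taxa' or 'samples'")
    df = table.to_dataframe()
    if orientation == "taxa":
        df = df.T
        df.index.name = TABLE_HEADER
    else:
        df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate sample rows {dups}")
    df["dmft_score"] = df["dmft_score"].astype(int)
    df["flow_rate"] = df["flow_rate"].astype(float)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.data.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate taxonomy rows {dups}")
    lineages = {}
    for tid, row in df.iterrows():
        parts = [p.strip() for p in str(row.iloc[0]).split(";")]
        if len(parts) < len(RANKS):
            parts += [""] * (len(RANKS) - len(parts))
        lineages[tid] = tuple(parts[: len(RANKS)])
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    rows = {tid: tax.lineage_string(tid) for tid in tax.lineages}
    df = pd.DataFrame({"lineage": rows})
    df.index.name = TABLE_HEADER
    df.to_csv(path, sep="\t")


def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree; parse errors name the offending token."""
    try:
        return TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ValueError(f"{path}: malformed Newick ({exc})") from None


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
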