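"""Pan / core / accessory partitioning along the DMFT severity index.

The core of a sample group is the set of taxa detected (count > 0) in at
least a threshold fraction of its samples (default 85%, inclusive); the
pan is every taxon detected at least once; the accessory ("invaders") is
pan minus core. The DMFT core is the intersection of the per-category
cores. Richness proportions break a category's pan into disjoint groups
against curated genus lists with a fixed precedence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .feature_table import CATEGORY_ORDER, DmftCategory, FeatureTable, SampleMetadata

DEFAULT_PREVALENCE = 0.85


@dataclass(frozen=True)
class GenusGroupLists:
    """Curated genus groups: healthy-mouth flora vs oral-disease-associated.

    Names are case-normalized; the two sets must be disjoint.
    """

    normal_flora: frozenset
    disease_associated: frozenset
    source: str = ""

    def __post_init__(self):
        nf = frozenset(g.strip().lower() for g in self.normal_flora if g.strip())
        da = frozenset(g.strip().lower() for g in self.disease_associated if g.strip())
        overlap = nf & da
        if overlap:
            raise ValueError(f"genera in both lists: {sorted(overlap)}")
        object.__setattr__(self, "normal_flora", nf)
        object.__setattr__(self, "disease_associated", da)

    @classmethod
    def from_files(cls, normal_path, disease_path, source: str = "") -> "GenusGroupLists":
        """Load newline-delimited genus name files ('#' starts a comment)."""

        def _read(p):
            lines = Path(p).read_text().splitlines()
            return frozenset(
                ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
            )

        return cls(_read(normal_path), _read(disease_path), source=source)

    @classmethod
    def empty(cls) -> "GenusGroupLists":
        return cls(frozenset(), frozenset(), source="empty")

    @classmethod
    def default(cls) -> "GenusGroupLists":
        """The editable default lists shipped with the package."""
        from importlib.resources import files

        data = files("dmftbiome") / "data"
        return cls.from_files(
            data / "normal_flora.txt",
            data / "disease_associated.txt",
            source="dmftbiome built-in defaults",
        )


@dataclass(frozen=True)
class CategoryPartition:
    pan: frozenset
    core: frozenset
    accessory: frozenset

    def __post_init__(self):
        if not self.core <= self.pan:
            raise ValueError("core must be a subset of pan")
        if self.accessory != self.pan - self.core:
            raise ValueError("accessory must equal pan minus core")

    @property
    def sizes(self) -> dict:
        return {
            "pan": len(self.pan),
            "core": len(self.core),
            "accessory": len(self.accessory),
        }


@dataclass(frozen=True)
class PartitionResult:
    """Per-category pan/core/accessory partition plus the threshold used."""

    by_category: dict
    prevalence_threshold: float

    def sizes(self) -> dict:
        return {cat: part.sizes for cat, part in self.by_category.items()}


def pan_taxa(table: FeatureTable) -> frozenset:
    """Taxa detected (count > 0) in at least one sample."""
    present = (table.counts > 0).any(axis=0)
    return frozenset(t for t, p in zip(table.taxon_ids, present) if p)


def core_taxa(table: FeatureTable, prevalence_threshold: float = DEFAULT_PREVALENCE) -> frozenset:
    """Taxa whose prevalence attains the threshold (inclusive >=)."""
    if not 0.0 <= prevalence_threshold <= 1.0:
        raise ValueError(f"prevalence threshold must be in [0, 1], got {prevalence_threshold}")
    if table.n_samples == 0:
        raise ValueError("cannot compute core of an empty table")
    prevalence = (table.counts > 0).mean(axis=0)
    return frozenset(
        t
        for t, prev in zip(table.taxon_ids, prevalence)
        if prev >= prevalence_threshold
    )


def partition_by_category(
    table: FeatureTable,
    metadata: SampleMetadata,
    threshold: float = DEFAULT_PREVALENCE,
) -> PartitionResult:
    """Pan/core/accessory per DMFT category (|accessory| = |pan| - |core|)."""
    missing = set(table.sample_ids) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    by_cat = {}
    for cat in CATEGORY_ORDER:
        sids = [s for s in metadata.samples_in_category(cat) if s in set(table.sample_ids)]
        if not sids:
            warnings.warn(f"DMFT category {cat.value!r} has no samples; empty partition")
            by_cat[cat.value] = CategoryPartition(frozenset(), frozenset(), frozenset())
            continue
        sub = table.select_samples(sids)
        pan = pan_taxa(sub)
        core = core_taxa(sub, threshold) & pan
        by_cat[cat.value] = CategoryPartition(pan, core, pan - core)
    return PartitionResult(by_cat, threshold)


def dmft_core(partition: PartitionResult) -> frozenset:
    """Intersection of per-category core sets over non-empty categories."""
    cores = [
        part.core
        for part in partition.by_category.values()
        if part.pan  # skip empty categories
    ]
    if len(cores) < 2:
        raise ValueError("DMFT core needs at least 2 non-empty categories")
    out = cores[0]
    for c in cores[1:]:
        out = out & c
    return out


def richness_proportions(
    category_pan: frozenset,
    shared_core: frozenset,
    lists: GenusGroupLists,
    accessory: frozenset,
) -> dict:
    """Break a category's pan into disjoint richness fractions.

    Each genus is assigned to exactly one group by precedence
    core > accessory > disease_associated > normal_flora > unclassified;
    fractions of |pan| sum to 1.
    """
    if not category_pan:
        raise ValueError("empty pan; proportions undefined")
    groups = {
        "core": 0,
        "accessory": 0,
        "disease_associated": 0,
        "normal_flora": 0,
        "unclassified": 0,
    }
    for genus in category_pan:
        low = genus.strip().lower()
        if genus in shared_core:
            groups["core"] += 1
        elif genus in accessory:
            groups["accessory"] += 1
        elif low in lists.disease_associated:
            groups["disease_associated"] += 1
        elif low in lists.normal_flora:
            groups["normal_flora"] += 1
        else:
            groups["unclassified"] += 1
    n = len(category_pan)
    return {k: v / n for k, v in groups.items()}
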