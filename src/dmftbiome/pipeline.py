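"""Config-driven orchestration of the full DMFT microbiota analysis.

Stage order follows the analysis: depth filter -> rank aggregation ->
diversity + PERMANOVA -> pan/core/accessory partition -> co-occurrence
networks + entropy -> leave-one-out TVE influence -> per-category
quasi-Poisson biomass models. Every output carries a provenance header
(config hash, seed, version) and the JSON summary is byte-identical for
identical config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .biomass_glm import per_category_models
from .cooccurrence import (
    communities,
    degree_rank,
    entropy_statistic,
    network_for_table,
    write_edge_list,
)
from .core_accessory import (
    GenusGroupLists,
    dmft_core,
    partition_by_category,
    richness_proportions,
)
from .diversity import bray_curtis, jensen_shannon, pcoa, permanova, shannon, tve, unifrac
from .feature_table import (
    CATEGORY_ORDER,
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    aggregate_rank,
    filter_by_depth,
    read_metadata,
    read_table,
    read_taxonomy,
    read_tree,
)
from .influence import OxygenAnnotation, select_candidates, tve_impact
from .synth import SyntheticDesign, generate_dataset, write_dataset

log = logging.getLogger("dmftbiome")

STAGES = ("profile", "aggregate", "diversity", "partition", "network", "influence", "glm")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run.

    Defaults are the standard analysis parameters: depth >= 3,000,
    prevalence >= 0.85, |rho| > 0.5, FDR alpha 0.05, TVE over k = 5 axes,
    9,999 PERMANOVA permutations.
    """

    # inputs: file paths, or None to simulate the default synthetic cohort
    table_path: Optional[str] = None
    metadata_path: Optional[str] = None
    taxonomy_path: Optional[str] = None
    tree_path: Optional[str] = None
    table_orientation: str = "taxa"
    # analysis parameters
    rank: str = "genus"
    min_depth: int = 3000
    prevalence_threshold: float = 0.85
    rho_threshold: float = 0.5
    alpha: float = 0.05
    tve_k: int = 5
    n_perm: int = 9999
    influence_mode: str = "centrality"
    influence_top_k: int = 50
    n_families: int = 3
    seed: int = 0
    # resources
    normal_flora_path: Optional[str] = None
    disease_list_path: Optional[str] = None
    oxygen_annotation_path: Optional[str] = None
    out_dir: str = "dmftbiome_out"

    def __post_init__(self):
        if not 0 <= self.prevalence_threshold <= 1:
            raise ValueError("prevalence_threshold must be in [0, 1]")
        if not 0 <= self.rho_threshold < 1:
            raise ValueError("rho_threshold must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_depth < 0 or self.tve_k < 0 or self.n_perm < 1:
            raise ValueError("min_depth/tve_k/n_perm out of range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _write_tsv(path: Path, header: str, lines: list[str], prov: dict) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# dmftbiome v{prov['version']} config={prov['config_hash']} seed={prov['seed']}\n"
        )
        fh.write(header + "\n")
        for ln in lines:
            fh.write(ln + "\n")


def load_inputs(config: PipelineConfig):
    """Read the four inputs, or simulate the default cohort when no paths
    are configured."""
    if config.table_path is None:
        log.info("no input table configured; simulating the default synthetic cohort")
        design = SyntheticDesign(seed=config.seed)
        table, meta, tax, tree, _truth = generate_dataset(design)
        return table, meta, tax, tree
    for name in ("metadata_path", "taxonomy_path", "tree_path"):
        if getattr(config, name) is None:
            raise FileNotFoundError(f"missing required input: {name}")
    table = read_table(config.table_path, orientation=config.table_orientation)
    meta = read_metadata(config.metadata_path)
    tax = read_taxonomy(config.taxonomy_path)
    tree = read_tree(config.tree_path)
    return table, meta, tax, tree


def _genus_lists(config: PipelineConfig) -> GenusGroupLists:
    if config.normal_flora_path and config.disease_list_path:
        return GenusGroupLists.from_files(
            config.normal_flora_path,
            config.disease_list_path,
            source=f"{config.normal_flora_path} + {config.disease_list_path}",
        )
    return GenusGroupLists.empty()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the JSON-able summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    summary: dict = {"provenance": prov, "stages": {}}

    try:
        table, meta, tax, tree = load_inputs(config)
        # -- profile: depth filter ----------------------------------------
        n_before = table.n_samples
        table = filter_by_depth(table, config.min_depth)
        meta = meta.select(table.sample_ids)
        log.info("depth filter >= %d: retained %d/%d samples", config.min_depth, table.n_samples, n_before)
        summary["stages"]["profile"] = {
            "min_depth": config.min_depth,
            "samples_before": n_before,
            "samples_retained": table.n_samples,
            "samples_dropped": n_before - table.n_samples,
        }
        if table.n_samples < 4:
            raise RuntimeError("fewer than 4 samples survive the depth filter")

        # -- aggregate -----------------------------------------------------
        genus = aggregate_rank(table, tax, config.rank)
        family = aggregate_rank(table, tax, "family")
        summary["stages"]["aggregate"] = {
            "rank": config.rank,
            "n_taxa_in": table.n_taxa,
            "n_taxa_out": genus.n_taxa,
        }

        # -- diversity -----------------------------------------------------
        rel_depths = genus.depths()
        alphas = [shannon(genus.counts[i]) for i in range(genus.n_samples)]
        bc = bray_curtis(genus)
        jsd = jensen_shannon(genus)
        uu = unifrac(table, tree, weighted=False)
        wu = unifrac(table, tree, weighted=True, normalized=True)
        ordn = pcoa(wu)
        tve_val = tve(ordn, k=config.tve_k)
        groups = {s: meta.category_of(s).value for s in genus.sample_ids}
        perm = {
            "unweighted_unifrac": permanova(uu, groups, n_perm=config.n_perm, seed=config.seed),
            "bray_curtis": permanova(bc, groups, n_perm=config.n_perm, seed=config.seed),
        }
        summary["stages"]["diversity"] = {
            "mean_depth": float(np.mean(rel_depths)),
            "mean_shannon": float(np.mean(alphas)),
            "tve_weighted_unifrac": tve_val,
            "tve_k": config.tve_k,
            "permanova": perm,
            "mean_jsd": float(np.mean(jsd.condensed_form())),
        }
        _write_tsv(
            out / "alpha_diversity.tsv",
            "sample_id\tdepth\tshannon",
            [f"{s}\t{d}\t{a:.6f}" for s, d, a in zip(genus.sample_ids, rel_depths, alphas)],
            prov,
        )
        for name, dm in (("bray_curtis", bc), ("jsd", jsd), ("unweighted_unifrac", uu), ("weighted_unifrac", wu)):
            dm.write(str(out / f"distance_{name}.tsv"))

        # -- partition -----------------------------------------------------
        part = partition_by_category(genus, meta, threshold=config.prevalence_threshold)
        shared = dmft_core(part)
        lists = _genus_lists(config)
        proportions = {}
        for cat in CATEGORY_ORDER:
            cp = part.by_category[cat.value]
            if not cp.pan:
                continue
            proportions[cat.value] = richness_proportions(cp.pan, shared, lists, cp.accessory)
        summary["stages"]["partition"] = {
            "prevalence_threshold": config.prevalence_threshold,
            "sizes": part.sizes(),
            "dmft_core_size": len(shared),
            "richness_proportions": proportions,
            "genus_lists_source": lists.source,
        }
        (out / "partition.json").write_text(
            json.dumps(
                {
                    "provenance": prov,
                    "sizes": part.sizes(),
                    "dmft_core": sorted(shared),
                    "by_category": {
                        c: {k: sorted(getattr(p, k)) for k in ("pan", "core", "accessory")}
                        for c, p in part.by_category.items()
                    },
                },
                indent=2,
                sort_keys=True,
            )
        )

        # -- network -------------------------------------------------------
        net_block = {}
        graphs = {}
        for cat in CATEGORY_ORDER:
            sids = meta.samples_in_category(cat)
            sub = genus.select_samples(sids)
            if sub.n_samples < 4:
                warnings.warn(f"category {cat.value!r}: too few samples for a network")
                continue
            keep = [t for t, nz in zip(sub.taxon_ids, (sub.counts > 0).any(axis=0)) if nz]
            sub = sub.select_samples(sub.sample_ids).drop_taxa(
                [t for t in sub.taxon_ids if t not in set(keep)]
            )
            g = network_for_table(
                sub, rho_threshold=config.rho_threshold, alpha=config.alpha, category=cat.value
            )
            graphs[cat.value] = g
            entry = {
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
            }
            if g.number_of_edges() > 0:
                entry["entropy_fraction_significant"] = entropy_statistic(g)
                entry["n_communities"] = len(communities(g, seed=config.seed))
                entry["top_degree"] = degree_rank(g, top_k=10)
                write_edge_list(g, out / f"network_{cat.value}.tsv")
            net_block[cat.value] = entry
        summary["stages"]["network"] = net_block

        # -- influence -----------------------------------------------------
        observed = genus.drop_taxa(
            [t for t, nz in zip(genus.taxon_ids, (genus.counts > 0).any(axis=0)) if not nz]
        )
        if config.influence_mode == "centrality":
            pooled = network_for_table(
                observed, rho_threshold=config.rho_threshold, alpha=config.alpha
            )
            candidates = select_candidates(
                "centrality", graph=pooled, top_k=config.influence_top_k
            )
        else:
            candidates = select_candidates(
                "abundance", table=genus, top_k=config.influence_top_k
            )
        genus_tree = _rank_tree(tree, table, tax, config.rank)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = tve_impact(genus, genus_tree, candidates, k=config.tve_k)
        oxy = (
            OxygenAnnotation.from_file(config.oxygen_annotation_path)
            if config.oxygen_annotation_path
            else OxygenAnnotation()
        )
        report.to_tsv(out / "influence.tsv", oxygen=oxy)
        summary["stages"]["influence"] = {
            "mode": config.influence_mode,
            "n_candidates": len(candidates),
            "baseline_tve": report.baseline_tve,
            "max_abs_delta_tve": report.max_abs_delta(),
            "top_influential": report.ranked_by_magnitude()[:10],
        }

        # -- glm -----------------------------------------------------------
        fam_order = select_candidates("abundance", table=family, top_k=config.n_families)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparison = per_category_models(
                genus, meta, family_table=family, families=fam_order, alpha=config.alpha
            )
        glm_block = {}
        for cat, fit in comparison.fits.items():
            glm_block[cat] = {
                "n_obs": fit.n_obs,
                "dispersion": fit.dispersion,
                "converged": fit.converged,
                "coefficients": {
                    k: (None if np.isnan(v) else float(v))
                    for k, v in fit.coefficients.items()
                },
                "p_values": {
                    k: (None if np.isnan(v) else float(v))
                    for k, v in fit.p_values.items()
                },
            }
        summary["stages"]["glm"] = {
            "outcome": "total_counts",
            "families": fam_order,
            "skipped_categories": list(comparison.skipped),
            "fits": glm_block,
        }
        comparison.table(alpha=config.alpha).to_csv(out / "glm_comparison.tsv", sep="\t")
    except Exception as exc:
        stage = len(summary["stages"])
        stage_name = STAGES[stage] if stage < len(STAGES) else "finalize"
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc

    payload = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(payload)
    return summary


def _rank_tree(tree, table: FeatureTable, tax: TaxonomyMap, rank: str):
    """Collapse the input-taxon tree to one representative leaf per rank label.

    The representative is the first member taxon; its leaf is renamed to
    the rank label so aggregated tables stay tree-compatible.
    """
    rep: dict[str, str] = {}
    for t in table.taxon_ids:
        lab = tax.rank_of(t, rank)
        rep.setdefault(lab, t)
    sheared = tree.shear(list(rep.values()))
    inverse = {v: k for k, v in rep.items()}
    for tip in sheared.tips():
        tip.name = inverse[tip.name]
    return sheared


def simulate_to_dir(design: SyntheticDesign, out_dir) -> dict:
    """Generate the synthetic cohort and serialize it (CLI `simulate`)."""
    table, meta, tax, tree, truth = generate_dataset(design)
    return write_dataset(out_dir, table, meta, tax, tree, truth)
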