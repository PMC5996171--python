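"""Full-analysis orchestration: curation -> diversity -> networks -> hubs.

One declarative configuration drives the whole run. The three network
scopes are sample subsets, not separate code paths: (i) all niches,
(ii) bulk + rhizosphere (the soil-associated microbiome), and
(iii) rhizosphere + root (the root-associated microbiome); each scope gets
the full 12-network sweep (4 significance cutoffs x 3 taxonomic levels)
and its own hub consensus.

Outputs are plain TSV/GraphML/JSON under a single run directory, plus a
manifest (seeds, parameters, version, input checksums) sufficient to
re-run the pipeline. Runs are byte-reproducible given (inputs, config).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, cooccurrence, diversity, feature_table, hubnet
from .cooccurrence import BONFERRONI, EdgeSet, classify_edges, edge_sweep
from .feature_table import (
    FeatureTable,
    RelativeAbundanceTable,
    collapse_taxonomy,
    concat_relative,
    exclude_lineages,
    filter_min_total_fraction,
    network_prefilter,
    niche_sharing,
    rarefy,
    read_feature_table,
    to_relative,
)
from .hubnet import HubReport, build_network, call_hubs, export_graphml

logger = logging.getLogger(__name__)

SCENARIOS: dict[str, tuple[str, ...]] = {
    "all_niches": ("bulk", "rhizosphere", "root"),
    "bulk_rhizosphere": ("bulk", "rhizosphere"),
    "rhizosphere_root": ("rhizosphere", "root"),
}


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Defaults reproduce the study's stated settings: 0.1% bleed-through
    filter, rarefaction to the smallest per-kingdom library ("auto-min"),
    5% prevalence and 1% max-abundance network prefilter, significance
    cutoffs {0.01, 0.001, 0.0001, Bonferroni}, outlier p = 0.1, taxonomic
    levels {genus, family, order}, 999 PERMANOVA permutations.
    """

    # inputs
    bacteria_counts: str = ""
    eukaryote_counts: str = ""
    metadata: str = ""
    bacteria_tree: str | None = None
    eukaryote_tree: str | None = None
    # curation
    exclude_bacteria: tuple[str, ...] = ("Chloroplast", "Mitochondria")
    exclude_eukaryotes: tuple[str, ...] = ("Archaeplastida", "Plantae", "Unassigned")
    min_total_fraction: float = 0.001
    rarefaction_depth: int | str = "auto-min"  # per-kingdom smallest library
    # network prefilter
    min_prevalence: float = 0.05
    min_max_abundance: float = 0.01
    min_reads: int = 0
    # networks
    levels: tuple[str, ...] = ("genus", "family", "order")
    cutoffs: tuple = (0.01, 0.001, 0.0001, BONFERRONI)
    n_iter: int = 1000
    n_bins: int | None = None
    outlier_p: float = 0.1
    min_cutoffs: int = 2
    min_levels: int = 2
    scenarios: tuple[str, ...] = tuple(SCENARIOS)
    # diversity
    permanova_permutations: int = 999
    # misc
    seed: int = 0
    output_dir: str = "rhizonet_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude_bacteria", "exclude_eukaryotes", "levels", "cutoffs", "scenarios"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _derive_seeds(seed: int, labels: Sequence[str]) -> dict[str, int]:
    """Stable per-stage integer seeds derived from the master seed."""
    rng = np.random.default_rng(seed)
    return {label: int(rng.integers(0, 2**31 - 1)) for label in labels}


def curate_kingdom(
    ft: FeatureTable,
    exclude_patterns: Sequence[str],
    min_total_fraction: float,
    rarefaction_depth: int | str,
    seed: int,
) -> tuple[FeatureTable, dict]:
    """Exclusion -> bleed-through filter -> rarefaction for one kingdom."""
    report: dict = {}
    if exclude_patterns:
        ft, rep = exclude_lineages(ft, list(exclude_patterns))
        report["excluded_taxa"] = rep.taxa_removed
        report["excluded_reads"] = rep.reads_removed
    ft, rep = filter_min_total_fraction(ft, min_total_fraction)
    report["bleedthrough_taxa_removed"] = rep.taxa_removed
    if rarefaction_depth == "auto-min":
        depth = int(ft.sample_sums().min())
    else:
        depth = int(rarefaction_depth)
    ft, rep = rarefy(ft, depth, seed=seed)
    report["rarefaction_depth"] = depth
    report["dropped_samples"] = rep.dropped_samples
    return ft, report


def _subset_samples(ft: FeatureTable, niches: Sequence[str]) -> FeatureTable:
    keep = [s for s in ft.samples if ft.metadata.loc[s, "niche"] in set(niches)]
    return FeatureTable(
        counts=ft.counts[keep], taxonomy=ft.taxonomy, metadata=ft.metadata
    )


@dataclass
class ScenarioResult:
    name: str
    edge_sets: dict[str, list[EdgeSet]]  # level -> sweep
    networks: dict[str, dict[str, hubnet.CooccurrenceNetwork]]
    hub_report: HubReport
    edge_class_summary: pd.DataFrame


def run_scenario(
    name: str,
    bacteria: FeatureTable,
    eukaryotes: FeatureTable,
    cfg: RunConfig,
    seeds: Mapping[str, int],
) -> ScenarioResult:
    """Run the 12-network sweep and hub consensus on one sample scope."""
    niches = SCENARIOS[name]
    ft_b = _subset_samples(bacteria, niches)
    ft_e = _subset_samples(eukaryotes, niches)
    edge_sets: dict[str, list[EdgeSet]] = {}
    networks: dict[str, dict[str, hubnet.CooccurrenceNetwork]] = {}
    lineages: dict[str, str] = {}
    class_rows = []
    for level in cfg.levels:
        parts, kingdoms, abund = [], {}, {}
        for ft, kd in ((ft_b, "bacteria"), (ft_e, "eukaryote")):
            rel = network_prefilter(
                to_relative(collapse_taxonomy(ft, level)),
                min_prevalence=cfg.min_prevalence,
                min_max_abundance=cfg.min_max_abundance,
                min_reads=cfg.min_reads,
            )
            parts.append(rel)
            kingdoms.update({t: kd for t in rel.taxa})
            abund.update(rel.proportions.mean(axis=1).to_dict())
        combined = concat_relative(parts)
        lineages.update({t: str(v) for t, v in combined.taxonomy.items()})
        sweep = edge_sweep(
            combined,
            kingdoms,
            cutoffs=cfg.cutoffs,
            n_iter=cfg.n_iter,
            seed=seeds[f"sweep:{name}:{level}"],
            level=level,
            n_bins=cfg.n_bins,
        )
        edge_sets[level] = sweep
        networks[level] = {
            es.cutoff_label: build_network(es, abundances=abund, kingdoms=kingdoms)
            for es in sweep
        }
        for es in sweep:
            summary = classify_edges(es)
            for cls in cooccurrence.KINGDOM_PAIR_CLASSES:
                class_rows.append(
                    dict(
                        level=level,
                        cutoff_label=es.cutoff_label,
                        kingdom_pair=cls,
                        n_edges=summary.counts[cls],
                        pct_of_edges=summary.class_percentages[cls],
                        n_positive=summary.sign_counts[cls]["positive"],
                        n_negative=summary.sign_counts[cls]["negative"],
                        pct_positive=summary.sign_percentages[cls]["positive"],
                    )
                )
    hub_report = call_hubs(
        networks,
        p=cfg.outlier_p,
        min_cutoffs=cfg.min_cutoffs,
        min_levels=cfg.min_levels,
        lineages=lineages,
    )
    return ScenarioResult(
        name=name,
        edge_sets=edge_sets,
        networks=networks,
        hub_report=hub_report,
        edge_class_summary=pd.DataFrame(class_rows),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    """
    inputs = {
        "bacteria_counts": cfg.bacteria_counts,
        "eukaryote_counts": cfg.eukaryote_counts,
        "metadata": cfg.metadata,
    }
    for label, path in list(inputs.items()):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"stage=read: missing input {label}: {path!r}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    seed_labels = ["rarefy:bacteria", "rarefy:eukaryotes", "permanova"]
    for name in cfg.scenarios:
        for level in cfg.levels:
            seed_labels.append(f"sweep:{name}:{level}")
    seeds = _derive_seeds(cfg.seed, seed_labels)

    # --- curation ---------------------------------------------------------
    ft_b = read_feature_table(cfg.bacteria_counts, cfg.metadata)
    ft_e = read_feature_table(cfg.eukaryote_counts, cfg.metadata)
    ft_b, rep_b = curate_kingdom(
        ft_b, cfg.exclude_bacteria, cfg.min_total_fraction,
        cfg.rarefaction_depth, seeds["rarefy:bacteria"],
    )
    ft_e, rep_e = curate_kingdom(
        ft_e, cfg.exclude_eukaryotes, cfg.min_total_fraction,
        cfg.rarefaction_depth, seeds["rarefy:eukaryotes"],
    )
    feature_table.write_feature_table(ft_b, out / "curated_bacteria.tsv")
    feature_table.write_feature_table(ft_e, out / "curated_eukaryotes.tsv")

    # --- composition & diversity -----------------------------------------
    sharing_rows = []
    for ft, kd in ((ft_b, "bacteria"), (ft_e, "eukaryotes")):
        summ = niche_sharing(ft)
        for region, count in sorted(summ.region_counts.items(), key=lambda kv: sorted(kv[0])):
            sharing_rows.append(
                dict(
                    kingdom=kd,
                    region="+".join(sorted(region)),
                    n_taxa=count,
                    pct_of_union=summ.percentages[region],
                )
            )
    pd.DataFrame(sharing_rows).to_csv(out / "niche_sharing.tsv", sep="\t", index=False)

    perm_rows = []
    for ft, kd, tree in (
        (ft_b, "bacteria", cfg.bacteria_tree),
        (ft_e, "eukaryotes", cfg.eukaryote_tree),
    ):
        diversity.alpha_diversity_table(ft).to_csv(
            out / f"alpha_{kd}.tsv", sep="\t", index_label="sample", float_format="%.10g"
        )
        rel = to_relative(ft)
        dm = diversity.bray_curtis(rel)
        dm.write(out / f"braycurtis_{kd}.tsv")
        if tree:
            dmu = diversity.weighted_unifrac(ft, diversity.read_newick(tree))
            dmu.write(out / f"weighted_unifrac_{kd}.tsv")
            beta = dmu
        else:
            beta = dm
        pc = diversity.pcoa(beta, k=2)
        pc.coordinates.to_csv(
            out / f"pcoa_{kd}.tsv", sep="\t", index_label="sample", float_format="%.10g"
        )
        for factor in ("niche", "habitat"):
            groups = ft.metadata.loc[ft.samples, factor]
            res = diversity.permanova(
                beta, groups, n_perm=cfg.permanova_permutations, seed=seeds["permanova"]
            )
            perm_rows.append(
                dict(
                    kingdom=kd,
                    factor=factor,
                    metric="weighted_unifrac" if tree else "bray_curtis",
                    r_squared=round(res.r_squared, 6),
                    p_value=res.p_value,
                    pseudo_f=round(res.pseudo_f, 6),
                    n_permutations=res.n_permutations,
                )
            )
    pd.DataFrame(perm_rows).to_csv(out / "permanova.tsv", sep="\t", index=False)

    # --- networks per scenario --------------------------------------------
    for name in cfg.scenarios:
        res = run_scenario(name, ft_b, ft_e, cfg, seeds)
        sdir = out / f"scenario_{name}"
        sdir.mkdir(exist_ok=True)
        for level, sweep in res.edge_sets.items():
            for es in sweep:
                es.write(sdir / f"edges_{level}_{es.cutoff_label}.tsv")
                net = res.networks[level][es.cutoff_label]
                hubnet.annotate_hub_flags(net, res.hub_report)
                export_graphml(net, sdir / f"network_{level}_{es.cutoff_label}.graphml")
        res.hub_report.write(sdir / "hub_flags.tsv")
        res.hub_report.hub_at_level.to_csv(sdir / "hub_at_level.tsv", sep="\t", index=False)
        res.hub_report.consensus.to_csv(sdir / "hub_consensus.tsv", sep="\t")
        res.edge_class_summary.to_csv(sdir / "edge_classes.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "seeds": seeds,
        "curation": {"bacteria": rep_b, "eukaryotes": rep_e},
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
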