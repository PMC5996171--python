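"""Synthetic two-kingdom amplicon communities with planted ground truth.

The generator emulates the sampling design of a soil-microbiome survey:
three niches (bulk soil, rhizosphere, root) crossed with two habitats
(managed field, forest), sequenced separately for bacteria (16S) and
eukaryotes (18S). Each kingdom is an independent composition: per-taxon
latent log-abundances receive a niche effect (species sorting), shared
latent factors implementing planted pairwise dependencies and hub
structure, and i.i.d. noise; counts are then drawn multinomially at a
log-normally distributed sequencing depth, which makes the tables
compositional by construction.

A planted positive pair loads a shared standard-normal factor with the
same sign in both taxa, a negative pair with opposite signs; a planted hub
shares one factor with each of its k neighbors. Loadings are on the
correlation scale: a pair with loading ``l`` has latent correlation
``l**2`` (and ``-l**2`` for a negative pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .feature_table import FeatureTable, write_feature_table, write_metadata

NICHES = ("bulk", "rhizosphere", "root")
HABITATS = ("managed", "forest")


@dataclass
class PlantedEdge:
    taxon_a: str
    taxon_b: str
    sign: int  # +1 or -1
    loading: float = 0.99

    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.taxon_a, self.taxon_b)))


@dataclass
class PlantedHub:
    taxon: str
    neighbors: list[str]
    loading: float = 1.0  # hub's own loading on the shared factor
    neighbor_loading: float = 0.80
    neighbor_signs: list[int] | None = None  # defaults to alternating +/-


def _default_edges() -> list[PlantedEdge]:
    return [
        PlantedEdge("Bac_OTU00", "Bac_OTU01", +1, 0.99),
        PlantedEdge("Euk_OTU00", "Euk_OTU01", +1, 0.99),
        PlantedEdge("Bac_OTU02", "Euk_OTU02", +1, 0.99),  # inter-kingdom positive
        PlantedEdge("Bac_OTU03", "Euk_OTU03", -1, 0.99),  # inter-kingdom negative
        PlantedEdge("Bac_OTU04", "Euk_OTU04", -1, 0.99),  # inter-kingdom negative
    ]


def _default_hubs() -> list[PlantedHub]:
    return [
        PlantedHub(
            "Bac_OTU05",
            neighbors=[
                "Bac_OTU06",
                "Bac_OTU07",
                "Bac_OTU08",
                "Bac_OTU09",
                "Euk_OTU05",
                "Euk_OTU06",
                "Euk_OTU07",
                "Euk_OTU08",
            ],
        )
    ]


@dataclass
class GeneratorConfig:
    """Study-design and effect-size parameters of the generator.

    Defaults give the canonical fixture: 3 niches x 2 habitats x 5 samples
    (30 samples), 40 taxa per kingdom, 3 planted positive and 2 planted
    negative pairwise dependencies, and 1 planted hub with 8 neighbors.
    """

    n_per_cell: int = 5  # samples per (niche, habitat) cell
    n_taxa: int = 40  # per kingdom
    depth_log_mean_bacteria: float = math.log(7136.0)
    depth_log_mean_eukaryotes: float = math.log(1922.0)
    depth_log_sd: float = 0.3
    base_log_sd: float = 1.0  # spread of per-taxon baseline log-abundance
    niche_effect_sd: float = 0.4  # log-scale shift of responsive taxa vs bulk
    niche_responsive_fraction: float = 0.3
    noise_sd: float = 0.8  # sd of the per-taxon stochastic log component
    planted_base_boost: float = 1.0  # log-units added to planted taxa baselines
    planted_edges: list[PlantedEdge] = field(default_factory=_default_edges)
    planted_hubs: list[PlantedHub] = field(default_factory=_default_hubs)
    seed: int = 0

    # taxonomy granularity (per kingdom): unique genus per OTU; the first
    # n_singleton_lineages OTUs (where planted structures live by default)
    # get singleton families/orders so planted truth stays well defined
    # after collapsing, while background OTUs share families and orders
    n_singleton_lineages: int = 10
    n_background_families: int = 15
    n_background_orders: int = 8

    def validate(self, taxa: Sequence[str]) -> None:
        names = set(taxa)
        for e in self.planted_edges:
            if e.taxon_a not in names or e.taxon_b not in names:
                raise ValueError(f"planted edge names unknown: {e}")
            if not 0 < e.loading <= 1:
                raise ValueError("edge loadings must lie in (0, 1]")
        for h in self.planted_hubs:
            if h.taxon not in names or any(nb not in names for nb in h.neighbors):
                raise ValueError(f"planted hub names unknown: {h.taxon}")
            if len(h.neighbors) >= 2 * self.n_taxa:
                raise ValueError("hub neighbor count must be below the taxon count")
            if not 0 < h.loading <= 1 or not 0 < h.neighbor_loading <= 1:
                raise ValueError("hub loadings must lie in (0, 1]")


@dataclass
class SyntheticTruth:
    """Planted structure of a generated community, for recovery tests."""

    planted_edges: list[PlantedEdge]
    planted_hubs: list[PlantedHub]
    niche_effects: pd.DataFrame  # taxa x niches, log-scale shifts
    config: GeneratorConfig

    def planted_pairs(self) -> dict[tuple[str, str], int]:
        """Planted pairwise dependencies: canonical pair -> sign."""
        return {e.pair(): e.sign for e in self.planted_edges}

    def hub_taxa(self) -> list[str]:
        return [h.taxon for h in self.planted_hubs]

    def dependent_pairs(self) -> set[tuple[str, str]]:
        """All pairs sharing at least one latent factor (incl. the
        neighbor-neighbor pairs induced by a hub factor)."""
        pairs: set[tuple[str, str]] = set(self.planted_pairs())
        for h in self.planted_hubs:
            members = [h.taxon] + list(h.neighbors)
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(tuple(sorted((members[i], members[j]))))
        return pairs


@dataclass
class SyntheticCommunity:
    bacteria: FeatureTable  # 16S
    eukaryotes: FeatureTable  # 18S
    tree_bacteria: str  # newick
    tree_eukaryotes: str
    truth: SyntheticTruth


def _taxon_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_OTU{i:02d}" for i in range(n)]


def _lineage_indices(i: int, n_singleton: int, n_bg_families: int, n_bg_orders: int) -> tuple[int, int]:
    """(family index, order index) for OTU ``i`` in one kingdom."""
    if i < n_singleton:
        return i, i
    fam = n_singleton + (i - n_singleton) % n_bg_families
    order = n_singleton + (fam - n_singleton) % n_bg_orders
    return fam, order


def _lineages(
    prefix: str, domain: str, n: int, n_singleton: int, n_bg_families: int, n_bg_orders: int
) -> pd.Series:
    """Six-rank lineages with consistent nesting: genus unique per OTU;
    the first ``n_singleton`` OTUs occupy singleton families/orders,
    background OTUs share ``n_bg_families`` families nested in
    ``n_bg_orders`` orders."""
    rows = {}
    for i in range(n):
        fam, order = _lineage_indices(i, n_singleton, n_bg_families, n_bg_orders)
        cls = order % 5
        phy = cls % 2
        rows[f"{prefix}_OTU{i:02d}"] = ";".join(
            [
                domain,
                f"{prefix}Phy{phy}",
                f"{prefix}Cls{cls}",
                f"{prefix}Ord{order}",
                f"{prefix}Fam{fam:02d}",
                f"{prefix}Gen{i:02d}",
            ]
        )
    return pd.Series(rows)


def _sample_frame(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = {}
    codes = {"bulk": "Bulk", "rhizosphere": "Rhizo", "root": "Root"}
    hcodes = {"managed": "Mng", "forest": "Frst"}
    for hab in HABITATS:
        for niche in NICHES:
            for i in range(cfg.n_per_cell):
                sid = f"{hcodes[hab]}{codes[niche]}{i:02d}"
                rows[sid] = dict(
                    niche=niche,
                    habitat=hab,
                    yield_class="none" if hab == "forest" else ("high" if i % 2 == 0 else "low"),
                )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.rename(columns={"yield_class": "yield"})
    return df


def generate_community(cfg: GeneratorConfig | None = None) -> SyntheticCommunity:
    """Draw one community pair (16S + 18S tables, trees, and truth).

    Deterministic given ``cfg.seed``: the same config yields byte-identical
    tables.
    """
    cfg = cfg or GeneratorConfig()
    taxa_b = _taxon_names("Bac", cfg.n_taxa)
    taxa_e = _taxon_names("Euk", cfg.n_taxa)
    all_taxa = taxa_b + taxa_e
    cfg.validate(all_taxa)
    rng = np.random.default_rng(cfg.seed)

    meta = _sample_frame(cfg, rng)
    samples = list(meta.index)
    n_s = len(samples)
    n_t = len(all_taxa)
    tidx = {t: i for i, t in enumerate(all_taxa)}

    # baseline log-abundance per taxon; planted taxa sit above the median,
    # as observed for real hub/keystone groups
    base = rng.normal(0.0, cfg.base_log_sd, size=n_t)
    planted_taxa = {e.taxon_a for e in cfg.planted_edges} | {e.taxon_b for e in cfg.planted_edges}
    for h in cfg.planted_hubs:
        planted_taxa.add(h.taxon)
        planted_taxa.update(h.neighbors)
    for t in planted_taxa:
        base[tidx[t]] = abs(base[tidx[t]]) + cfg.planted_base_boost

    # niche effects (species sorting): a responsive subset shifts in
    # rhizosphere/root relative to bulk
    effects = np.zeros((n_t, len(NICHES)))
    responsive = rng.random(n_t) < cfg.niche_responsive_fraction
    for k, niche in enumerate(NICHES):
        if niche == "bulk":
            continue
        effects[responsive, k] = rng.normal(0.0, cfg.niche_effect_sd, size=responsive.sum())
    niche_effects = pd.DataFrame(effects, index=all_taxa, columns=list(NICHES))

    # latent factor loadings: taxa x factors, signed, correlation scale
    loadings: list[np.ndarray] = []
    for e in cfg.planted_edges:
        lam = np.zeros(n_t)
        lam[tidx[e.taxon_a]] = e.loading
        lam[tidx[e.taxon_b]] = e.sign * e.loading
        loadings.append(lam)
    for h in cfg.planted_hubs:
        lam = np.zeros(n_t)
        lam[tidx[h.taxon]] = h.loading
        signs = h.neighbor_signs or [1 if i % 2 == 0 else -1 for i in range(len(h.neighbors))]
        for nb, s in zip(h.neighbors, signs):
            lam[tidx[nb]] = s * h.neighbor_loading
        loadings.append(lam)
    L = np.column_stack(loadings) if loadings else np.zeros((n_t, 0))
    shared_var = (L**2).sum(axis=1)
    if np.any(shared_var > 1):
        raise ValueError("summed squared loadings exceed 1 for some taxon")
    idio = np.sqrt(1.0 - shared_var)

    # latent log-abundances and multinomial counts, per sample
    z = rng.normal(size=(L.shape[1], n_s)) if L.shape[1] else np.zeros((0, n_s))
    eps = rng.normal(size=(n_t, n_s))
    latent = L @ z + idio[:, None] * eps
    niche_idx = np.array([NICHES.index(meta.loc[s, "niche"]) for s in samples])
    logab = base[:, None] + effects[:, niche_idx] + cfg.noise_sd * latent

    counts = np.zeros((n_t, n_s), dtype=np.int64)
    depth_means = (cfg.depth_log_mean_bacteria, cfg.depth_log_mean_eukaryotes)
    for kingdom_slice, dmean in zip(
        (slice(0, cfg.n_taxa), slice(cfg.n_taxa, n_t)), depth_means
    ):
        depths = np.maximum(
            rng.lognormal(dmean, cfg.depth_log_sd, size=n_s).astype(np.int64), 500
        )
        sub = logab[kingdom_slice]
        p = np.exp(sub - sub.max(axis=0))
        p = p / p.sum(axis=0)
        for j in range(n_s):
            counts[kingdom_slice, j] = rng.multinomial(depths[j], p[:, j])

    tax_b = _lineages(
        "Bac", "Bacteria", cfg.n_taxa,
        cfg.n_singleton_lineages, cfg.n_background_families, cfg.n_background_orders,
    )
    tax_e = _lineages(
        "Euk", "Eukaryota", cfg.n_taxa,
        cfg.n_singleton_lineages, cfg.n_background_families, cfg.n_background_orders,
    )
    meta_b = meta.assign(marker="16S")
    meta_e = meta.assign(marker="18S")
    ft_b = FeatureTable(
        counts=pd.DataFrame(counts[: cfg.n_taxa], index=taxa_b, columns=samples),
        taxonomy=tax_b,
        metadata=meta_b,
    )
    ft_e = FeatureTable(
        counts=pd.DataFrame(counts[cfg.n_taxa :], index=taxa_e, columns=samples),
        taxonomy=tax_e,
        metadata=meta_e,
    )
    truth = SyntheticTruth(
        planted_edges=list(cfg.planted_edges),
        planted_hubs=list(cfg.planted_hubs),
        niche_effects=niche_effects,
        config=cfg,
    )
    tree_b = generate_tree(taxa_b, seed=int(rng.integers(2**31 - 1)))
    tree_e = generate_tree(taxa_e, seed=int(rng.integers(2**31 - 1)))
    return SyntheticCommunity(
        bacteria=ft_b, eukaryotes=ft_e, tree_bacteria=tree_b, tree_eukaryotes=tree_e, truth=truth
    )


def generate_tree(taxa: Sequence[str], seed: int, mean_branch: float = 0.1) -> str:
    """Random rooted binary tree over the given leaves, newick string.

    Topology by recursive random bipartition; branch lengths i.i.d.
    exponential with mean ``mean_branch``.
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    rng = np.random.default_rng(seed)

    def build(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.exponential(mean_branch):.6f}"
        k = int(rng.integers(1, len(leaves)))
        order = rng.permutation(len(leaves))
        left = [leaves[i] for i in order[:k]]
        right = [leaves[i] for i in order[k:]]
        return f"({build(left)},{build(right)}):{rng.exponential(mean_branch):.6f}"

    k = int(rng.integers(1, len(taxa)))
    order = rng.permutation(len(taxa))
    left = [taxa[i] for i in order[:k]]
    right = [taxa[i] for i in order[k:]]
    return f"({build(left)},{build(right)});"


def collapsed_name(taxon: str, level: str, cfg: GeneratorConfig | None = None) -> str:
    """Collapsed-table identifier of a generated OTU at a taxonomic level.

    Maps e.g. ``Bac_OTU05`` to ``BacGen05`` / ``BacFam05`` / ``BacOrd5``,
    following the same lineage scheme the generator emits; used to locate
    planted truth in collapsed tables.
    """
    cfg = cfg or GeneratorConfig()
    prefix, idx = taxon.split("_OTU")
    i = int(idx)
    fam, order = _lineage_indices(
        i, cfg.n_singleton_lineages, cfg.n_background_families, cfg.n_background_orders
    )
    if level == "genus":
        return f"{prefix}Gen{i:02d}"
    if level == "family":
        return f"{prefix}Fam{fam:02d}"
    if level == "order":
        return f"{prefix}Ord{order}"
    raise ValueError(f"unknown level {level!r}")


FIXTURE_SEED = 20180614


def write_fixtures(outdir, seed: int = FIXTURE_SEED) -> SyntheticCommunity:
    """Write the canonical fixture set (tables, metadata, trees, truth).

    3 niches x 2 habitats x 5 samples, 40 + 40 taxa, 3 planted positive and
    2 planted negative edges, 1 planted hub. Deterministic given ``seed``.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(seed=seed)
    com = generate_community(cfg)
    write_feature_table(com.bacteria, out / "bacteria_counts.tsv")
    write_feature_table(com.eukaryotes, out / "eukaryote_counts.tsv")
    write_metadata(com.bacteria, out / "metadata.tsv")
    (out / "bacteria_tree.nwk").write_text(com.tree_bacteria + "\n")
    (out / "eukaryote_tree.nwk").write_text(com.tree_eukaryotes + "\n")

    edges = pd.DataFrame(
        [
            dict(taxon_a=e.pair()[0], taxon_b=e.pair()[1], sign=e.sign, loading=e.loading)
            for e in com.truth.planted_edges
        ]
    )
    edges.to_csv(out / "truth_edges.tsv", sep="\t", index=False)
    hubs = pd.DataFrame(
        [
            dict(
                taxon=h.taxon,
                neighbors=",".join(h.neighbors),
                loading=h.loading,
                neighbor_loading=h.neighbor_loading,
            )
            for h in com.truth.planted_hubs
        ]
    )
    hubs.to_csv(out / "truth_hubs.tsv", sep="\t", index=False)

    echo = asdict(cfg)
    with open(out / "generator_config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    return com
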