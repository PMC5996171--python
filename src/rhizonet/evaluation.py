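"""Recovery and calibration metrics against planted synthetic truth.

Utilities that run the network stages on generated communities and score
the result against the generator's ground truth: Bonferroni edge
sensitivity with sign agreement, false-edge counts among pairs sharing no
latent factor, hub-consensus recovery, and type-I error of the ReBoot
p-value under a null community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cooccurrence import edge_sweep, reboot_pvalue
from .feature_table import (
    collapse_taxonomy,
    concat_relative,
    network_prefilter,
    to_relative,
)
from .hubnet import build_network, call_hubs
from .synthetic_data import (
    GeneratorConfig,
    SyntheticCommunity,
    collapsed_name,
    generate_community,
)

LEVELS = ("genus", "family", "order")


def _level_tables(com: SyntheticCommunity, level: str):
    parts, kingdoms = [], {}
    for ft, kd in ((com.bacteria, "bacteria"), (com.eukaryotes, "eukaryote")):
        rel = network_prefilter(to_relative(collapse_taxonomy(ft, level)))
        parts.append(rel)
        kingdoms.update({t: kd for t in rel.taxa})
    return concat_relative(parts), kingdoms


def module_taxa(com: SyntheticCommunity) -> set[str]:
    """Taxa belonging to any planted structure (edges, hubs + neighbors)."""
    out: set[str] = set()
    for e in com.truth.planted_edges:
        out.update(e.pair())
    for h in com.truth.planted_hubs:
        out.add(h.taxon)
        out.update(h.neighbors)
    return out


@dataclass
class RecoveryResult:
    """Planted-structure recovery scores for one generated community."""

    n_planted: int
    n_recovered: int  # at Bonferroni, with the correct sign
    false_edges: int  # Bonferroni edges between factor-independent pairs
    n_bonferroni_edges: int
    hub_found: bool
    background_false_hubs: int  # consensus entities outside planted structures
    consensus_entities: list[str]

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


def evaluate_recovery(
    cfg: GeneratorConfig,
    n_iter: int = 200,
    sweep_seed: int | None = None,
) -> RecoveryResult:
    """Generate one community and score planted-edge and hub recovery.

    Edge recovery is scored at the genus level (where planted pairs are
    individual nodes) against the Bonferroni cutoff; hub recovery applies
    the full two-tier consensus over all three levels. A "false" edge is a
    Bonferroni edge between two taxa that share no latent factor; a
    "background false hub" is a consensus entity containing no planted
    taxon (planted hub *neighbors* genuinely carry elevated connectivity,
    so their co-calls are reported via ``consensus_entities`` instead).
    """
    com = generate_community(cfg)
    truth = com.truth
    sweep_seed = cfg.seed + 10_000 if sweep_seed is None else sweep_seed

    networks = {}
    lineages: dict[str, str] = {}
    result: dict = {}
    for level in LEVELS:
        rel, kingdoms = _level_tables(com, level)
        lineages.update({t: str(v) for t, v in rel.taxonomy.items()})
        sweep = edge_sweep(rel, kingdoms, n_iter=n_iter, seed=sweep_seed, level=level)
        networks[level] = {es.cutoff_label: build_network(es) for es in sweep}
        if level == "genus":
            bon = sweep[-1]
            got = {(e.taxon_a, e.taxon_b): e.sign for e in bon.edges}
            planted = {
                tuple(sorted((collapsed_name(a, level, cfg), collapsed_name(b, level, cfg)))): s
                for (a, b), s in truth.planted_pairs().items()
            }
            hits = sum(
                1
                for pair, sign in planted.items()
                if got.get(pair) == ("positive" if sign > 0 else "negative")
            )
            dependent = {
                tuple(sorted((collapsed_name(a, level, cfg), collapsed_name(b, level, cfg))))
                for (a, b) in truth.dependent_pairs()
            }
            result["n_planted"] = len(planted)
            result["n_recovered"] = hits
            result["false_edges"] = sum(1 for pair in got if pair not in dependent)
            result["n_bonferroni_edges"] = len(bon.edges)

    report = call_hubs(networks, lineages=lineages)
    module_names = {
        collapsed_name(t, level, cfg) for t in module_taxa(com) for level in LEVELS
    }
    truth_hub_names = {
        collapsed_name(t, level, cfg) for t in truth.hub_taxa() for level in LEVELS
    }
    hub_nodes = set(report.consensus_hub_nodes())
    background = 0
    for _, row in report.consensus[report.consensus["consensus_hub"]].iterrows():
        members = {m.split(":", 1)[1] for m in row["members"].split(";")}
        if not members & module_names:
            background += 1
    return RecoveryResult(
        hub_found=bool(hub_nodes & truth_hub_names),
        background_false_hubs=background,
        consensus_entities=report.consensus_hubs(),
        **result,
    )


@dataclass
class ReplicateSummary:
    edge_sensitivity: float
    hub_recovery_rate: float
    mean_background_false_hubs: float
    mean_false_edges: float
    n_replicates: int


def replicate_recovery(
    n_replicates: int = 20,
    n_iter: int = 200,
    base_seed: int = 0,
    **config_overrides,
) -> ReplicateSummary:
    """Recovery metrics aggregated over replicate generator seeds."""
    results = [
        evaluate_recovery(
            GeneratorConfig(seed=base_seed + k, **config_overrides), n_iter=n_iter
        )
        for k in range(n_replicates)
    ]
    total_planted = sum(r.n_planted for r in results)
    return ReplicateSummary(
        edge_sensitivity=sum(r.n_recovered for r in results) / total_planted,
        hub_recovery_rate=float(np.mean([r.hub_found for r in results])),
        mean_background_false_hubs=float(np.mean([r.background_false_hubs for r in results])),
        mean_false_edges=float(np.mean([r.false_edges for r in results])),
        n_replicates=n_replicates,
    )


def null_config(seed: int) -> GeneratorConfig:
    """Generator config with no dependencies at all (pure null)."""
    return GeneratorConfig(
        seed=seed,
        planted_edges=[],
        planted_hubs=[],
        niche_effect_sd=0.0,
        niche_responsive_fraction=0.0,
        planted_base_boost=0.0,
    )


def type_one_error(
    n_pairs: int = 200,
    n_iter: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null taxon pairs with ReBoot p below ``alpha``.

    Pairs are drawn from the bacterial table of null communities
    (independent taxa within one compositional table, so the permutation-
    renormalization correction is actually exercised).
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    tested = 0
    community_seed = 0
    while tested < n_pairs:
        cfg = null_config(int(rng.integers(0, 2**31 - 1)))
        com = generate_community(cfg)
        rel = to_relative(com.bacteria)
        R = rel.proportions.to_numpy(dtype=float)
        n_taxa = R.shape[0]
        pairs = [(i, j) for i in range(n_taxa) for j in range(i + 1, n_taxa)]
        order = rng.permutation(len(pairs))
        for k in order[: min(50, n_pairs - tested)]:
            i, j = pairs[k]
            res = reboot_pvalue(R, i, j, n_iter=n_iter, seed=int(rng.integers(0, 2**31 - 1)))
            if not res.degenerate:
                rejected += res.p_raw < alpha
                tested += 1
        community_seed += 1
    return rejected / tested
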