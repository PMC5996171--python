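"""Signed co-occurrence networks, centralities, and hub-taxon calling.

A hub taxon is a node that is simultaneously an outlier on degree,
betweenness centrality, and closeness centrality relative to a normal fit
of the node population of its own network. The two-tier consensus rule:
a taxon is a hub *at a taxonomic level* when it is an all-three-metric
outlier in at least ``min_cutoffs`` (default 2) of the four
significance-cutoff networks at that level, and a *consensus hub* when it
is a level hub at ``min_levels`` (default 2) of the three taxonomic levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .cooccurrence import EdgeSet
from .feature_table import RelativeAbundanceTable

logger = logging.getLogger(__name__)

METRICS = ("degree", "betweenness", "closeness")


@dataclass
class CooccurrenceNetwork:
    """Signed undirected graph for one (level, cutoff) combination.

    Edge weight is |NC-score| with the sign kept as an attribute; node
    attribute ``abundance`` is the taxon's mean relative abundance across
    samples. By default the node set is the edge-incident taxa (isolated
    prefiltered taxa may be added via ``include_isolated``).
    """

    graph: nx.Graph
    cutoff_label: str
    level: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    e: EdgeSet,
    abundances: Mapping[str, float] | pd.Series | None = None,
    kingdoms: Mapping[str, str] | None = None,
    include_isolated: Iterable[str] = (),
) -> CooccurrenceNetwork:
    """Assemble the signed undirected graph from a filtered edge set."""
    g = nx.Graph()
    for tx in include_isolated:
        g.add_node(tx)
    for rec in e.edges:
        if g.has_edge(rec.taxon_a, rec.taxon_b):
            raise ValueError(f"duplicate edge {rec.taxon_a}--{rec.taxon_b}")
        g.add_edge(
            rec.taxon_a,
            rec.taxon_b,
            weight=abs(rec.nc),
            nc=rec.nc,
            sign=rec.sign,
            p_raw=rec.p_raw,
            kingdom_pair=rec.kingdom_pair,
        )
    for node in g.nodes:
        if abundances is not None:
            g.nodes[node]["abundance"] = float(abundances[node])
        if kingdoms is not None and node in kingdoms:
            g.nodes[node]["kingdom"] = kingdoms[node]
    return CooccurrenceNetwork(graph=g, cutoff_label=e.cutoff_label, level=e.level)


def centralities(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Degree, normalized betweenness, and harmonic closeness per node.

    Paths are computed on the unweighted topology (signs and edge weights
    ignored). Betweenness is normalized by ``(N-1)(N-2)/2``; closeness is
    harmonic (sum of inverse distances, well defined on disconnected
    graphs) normalized by ``N-1``.
    """
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        return pd.DataFrame(columns=["degree", "betweenness", "closeness"])
    betw = nx.betweenness_centrality(g, normalized=True) if n > 2 else {v: 0.0 for v in g}
    harm = nx.harmonic_centrality(g)
    denom = max(n - 1, 1)
    rows = {
        v: dict(
            degree=g.degree(v),
            betweenness=betw[v],
            closeness=harm[v] / denom,
        )
        for v in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.sort_index()


def normal_outlier_threshold(values, p: float = 0.1) -> float:
    """Upper-tail outlier threshold from a normal fit: ``mean + z_{1-p} sd``.

    Values strictly above the threshold are outliers. With zero sample
    variance the threshold is +inf (no outliers), mirroring the degenerate
    contract.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to fit")
    sd = float(v.std(ddof=1))
    if sd == 0:
        return float("inf")
    return float(v.mean() + norm.ppf(1 - p) * sd)


def outlier_flags(cent: pd.DataFrame, p: float = 0.1) -> pd.DataFrame:
    """Per-node boolean outlier flag for each centrality metric."""
    flags = {}
    for metric in METRICS:
        vals = cent[metric].to_numpy(dtype=float)
        if len(vals) < 3:
            flags[metric] = pd.Series(False, index=cent.index)
            continue
        thr = normal_outlier_threshold(vals, p)
        flags[metric] = cent[metric] > thr
    return pd.DataFrame(flags, index=cent.index)


@dataclass
class HubReport:
    """Outlier flags per network, per-level hub calls, and consensus hubs.

    ``consensus`` has one row per consensus entity — level hubs from
    different taxonomic levels are identified with each other through
    lineage nesting (a genus hub and its family/order ancestors are the
    same taxon at different granularities) — with the member level hubs,
    the number of supporting levels, and the consensus flag.
    """

    flags: pd.DataFrame  # per (level, cutoff, node): centralities + outlier flags
    hub_at_level: pd.DataFrame  # per (level, node): cutoff support + hub_at_level
    consensus: pd.DataFrame  # per consensus entity: members, n_levels, consensus_hub

    def consensus_hubs(self) -> list[str]:
        """Consensus entity keys flagged as hubs."""
        c = self.consensus
        return sorted(c.index[c["consensus_hub"]])

    def consensus_hub_nodes(self) -> list[str]:
        """All level-hub node names belonging to a flagged consensus entity."""
        c = self.consensus
        names: set[str] = set()
        for members in c.loc[c["consensus_hub"], "members"]:
            names.update(m.split(":", 1)[1] for m in members.split(";"))
        return sorted(names)

    def level_hubs(self, level: str) -> list[str]:
        h = self.hub_at_level
        sel = h[(h["level"] == level) & h["hub_at_level"]]
        return sorted(sel["node"])

    def write(self, path) -> None:
        self.flags.to_csv(path, sep="\t", index=False, float_format="%.10g")


#: lineage depth used to identify hubs across taxonomic levels
#: (domain;phylum;class;order — the coarsest collapsible rank)
_CONSENSUS_RANK_DEPTH = 4


def _consensus_key(node: str, lineages: Mapping[str, str] | None) -> str:
    if lineages is None or node not in lineages or not str(lineages[node]).strip():
        return node
    parts = [p.strip() for p in str(lineages[node]).split(";") if p.strip()]
    return ";".join(parts[:_CONSENSUS_RANK_DEPTH])


def call_hubs(
    networks: Mapping[str, Mapping[str, CooccurrenceNetwork]],
    p: float = 0.1,
    min_cutoffs: int = 2,
    min_levels: int = 2,
    lineages: Mapping[str, str] | None = None,
) -> HubReport:
    """Apply the two-tier hub consensus rule across cutoffs and levels.

    ``networks`` maps level -> cutoff_label -> network. Thresholds are
    fitted per network on that network's own node population; a taxon
    absent from a network is simply a non-outlier there. A level with
    fewer than ``min_cutoffs`` non-empty networks yields no hubs (warned).

    Because node identifiers differ between collapse levels (a genus node
    and the family node containing it), cross-level consensus matches
    level hubs through their shared lineage prefix down to the order rank
    when ``lineages`` is supplied; without lineages, plain node-name
    identity is used.
    """
    flag_rows = []
    level_outlier_counts: dict[str, dict[str, int]] = {}
    for level, by_cutoff in networks.items():
        nonempty = sum(1 for net in by_cutoff.values() if net.n_nodes > 0)
        counts: dict[str, int] = {}
        for cutoff, net in by_cutoff.items():
            cent = centralities(net)
            if cent.empty:
                continue
            fl = outlier_flags(cent, p)
            for node in cent.index:
                all_three = bool(fl.loc[node].all())
                flag_rows.append(
                    dict(
                        level=level,
                        cutoff_label=cutoff,
                        node=node,
                        degree=cent.loc[node, "degree"],
                        betweenness=cent.loc[node, "betweenness"],
                        closeness=cent.loc[node, "closeness"],
                        degree_outlier=bool(fl.loc[node, "degree"]),
                        betweenness_outlier=bool(fl.loc[node, "betweenness"]),
                        closeness_outlier=bool(fl.loc[node, "closeness"]),
                        all_three_outlier=all_three,
                    )
                )
                if all_three:
                    counts[node] = counts.get(node, 0) + 1
        if nonempty < min_cutoffs:
            warnings.warn(
                f"level {level!r} has only {nonempty} non-empty networks; no hubs called",
                stacklevel=2,
            )
            counts = {}
        level_outlier_counts[level] = counts

    flags = pd.DataFrame(
        flag_rows,
        columns=[
            "level",
            "cutoff_label",
            "node",
            "degree",
            "betweenness",
            "closeness",
            "degree_outlier",
            "betweenness_outlier",
            "closeness_outlier",
            "all_three_outlier",
        ],
    )
    hub_rows = []
    entity_levels: dict[str, set[str]] = {}
    entity_members: dict[str, list[str]] = {}
    for level, counts in level_outlier_counts.items():
        nodes = set()
        for net in networks[level].values():
            nodes.update(net.graph.nodes)
        for node in sorted(nodes):
            is_hub = counts.get(node, 0) >= min_cutoffs
            hub_rows.append(
                dict(level=level, node=node, n_cutoffs_outlier=counts.get(node, 0), hub_at_level=is_hub)
            )
            if is_hub:
                key = _consensus_key(node, lineages)
                entity_levels.setdefault(key, set()).add(level)
                entity_members.setdefault(key, []).append(f"{level}:{node}")
    hub_at_level = pd.DataFrame(
        hub_rows, columns=["level", "node", "n_cutoffs_outlier", "hub_at_level"]
    )
    keys = sorted(entity_levels)
    consensus = pd.DataFrame(
        {
            "members": [";".join(sorted(entity_members[k])) for k in keys],
            "n_levels": [len(entity_levels[k]) for k in keys],
            "consensus_hub": [len(entity_levels[k]) >= min_levels for k in keys],
        },
        index=pd.Index(keys, name="entity"),
    )
    return HubReport(flags=flags, hub_at_level=hub_at_level, consensus=consensus)


def cluster_abundance(
    r: RelativeAbundanceTable, node_set: Sequence[str], niche_column: str = "niche"
) -> pd.Series:
    """Per-niche mean of the summed relative abundance of a taxon set."""
    missing = [v for v in node_set if v not in r.proportions.index]
    if missing:
        raise ValueError(f"taxa not in table: {missing}")
    niches = r.niche_of()
    if len(node_set) == 0:
        return pd.Series({n: 0.0 for n in sorted(niches.unique())})
    summed = r.proportions.loc[list(node_set)].sum(axis=0)
    return summed.groupby(niches).mean().sort_index()


# ---------------------------------------------------------------------------
# GraphML round-trip
# ---------------------------------------------------------------------------

def export_graphml(net: CooccurrenceNetwork, path) -> None:
    """Write the network (with node/edge attributes) as GraphML."""
    g = net.graph.copy()
    g.graph["cutoff_label"] = net.cutoff_label
    g.graph["level"] = net.level
    nx.write_graphml(g, path)


def read_graphml(path) -> CooccurrenceNetwork:
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    return CooccurrenceNetwork(
        graph=g,
        cutoff_label=g.graph.get("cutoff_label", ""),
        level=g.graph.get("level", ""),
    )


def annotate_hub_flags(net: CooccurrenceNetwork, report: HubReport) -> None:
    """Attach centralities and hub flags as node attributes (for export)."""
    cent = centralities(net)
    cons = report.consensus
    for node in net.graph.nodes:
        if node in cent.index:
            net.graph.nodes[node]["degree"] = int(cent.loc[node, "degree"])
            net.graph.nodes[node]["betweenness"] = float(cent.loc[node, "betweenness"])
            net.graph.nodes[node]["closeness"] = float(cent.loc[node, "closeness"])
        net.graph.nodes[node]["consensus_hub"] = bool(
            node in cons.index and cons.loc[node, "consensus_hub"]
        )
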