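"""Feature-table I/O, validation, curation, and niche-sharing summaries.

The feature table is the substrate of the whole pipeline: a taxa x samples
matrix of non-negative integer marker-gene counts (one table per kingdom,
e.g. a 16S table for bacteria and an 18S table for eukaryotes), a
semicolon-delimited ranked lineage per taxon, and per-sample metadata
(niche in {bulk, rhizosphere, root}, habitat, yield, marker).

Curation follows the standard amplicon workflow: exclusion of host/organelle
lineages, removal of run-bleed-through taxa (< 0.1% of total reads),
rarefaction to a common depth, taxonomic collapsing, conversion to relative
abundance, and a prevalence/abundance prefilter ahead of network inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NICHES = ("bulk", "rhizosphere", "root")

#: rank order of a semicolon-delimited lineage string
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

COLLAPSIBLE_RANKS = ("order", "family", "genus")


class FeatureTableError(ValueError):
    """Raised when a table or metadata file violates the format contract."""


@dataclass
class FeatureTable:
    """Taxa x samples integer count matrix with lineages and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon ID, columns are sample IDs, values are
        non-negative integers.
    taxonomy
        Series mapping taxon ID -> semicolon-delimited ranked lineage
        (``domain;phylum;class;order;family;genus``; trailing ranks may be
        empty or absent).
    metadata
        DataFrame indexed by sample ID with at least a ``niche`` column.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate taxon identifiers: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise FeatureTableError(f"duplicate sample identifiers: {dups}")
        arr = c.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise FeatureTableError("counts must be numeric")
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
            if bad.size:
                i, j = bad[0]
                raise FeatureTableError(
                    "counts must be non-negative integers; offending cell "
                    f"(taxon={c.index[i]!r}, sample={c.columns[j]!r}) = {arr[i, j]!r}"
                )
        missing_meta = [s for s in c.columns if s not in self.metadata.index]
        if missing_meta:
            raise FeatureTableError(
                f"samples missing from metadata: {missing_meta}"
            )
        if "niche" not in self.metadata.columns:
            raise FeatureTableError("metadata lacks a 'niche' column")
        niches = self.metadata.loc[list(c.columns), "niche"]
        bad_niche = sorted(set(niches) - set(NICHES))
        if bad_niche:
            raise FeatureTableError(
                f"unknown niche labels {bad_niche}; expected one of {NICHES}"
            )
        extra = [t for t in c.index if t not in self.taxonomy.index]
        if extra:
            raise FeatureTableError(f"taxa missing from taxonomy: {extra}")

    # -- conveniences -----------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def niche_of(self) -> pd.Series:
        """Niche label per sample, aligned to the count columns."""
        return self.metadata.loc[self.samples, "niche"]

    def _replace(self, counts: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(
            counts=counts,
            taxonomy=self.taxonomy.loc[counts.index],
            metadata=self.metadata,
        )


@dataclass
class RelativeAbundanceTable:
    """Per-sample proportions derived from a :class:`FeatureTable`.

    ``taxon_totals`` carries the source read totals so read-floor filters
    can still be applied after normalization; ``zero_samples`` flags samples
    whose column summed to zero (left as all-zero columns).
    """

    proportions: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame
    taxon_totals: pd.Series | None = None
    zero_samples: list[str] = field(default_factory=list)
    #: False after taxa have been filtered out (column sums then fall below 1)
    complete: bool = True

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < -1e-12 or arr.max() > 1 + 1e-9:
                raise FeatureTableError("proportions must lie in [0, 1]")
            sums = arr.sum(axis=0)
            nonzero = [
                s for s in self.proportions.columns if s not in set(self.zero_samples)
            ]
            idx = [self.proportions.columns.get_loc(s) for s in nonzero]
            if idx and self.complete and not np.allclose(sums[idx], 1.0, atol=1e-9):
                raise FeatureTableError("non-degenerate sample columns must sum to 1")
            if idx and not self.complete and sums[idx].max() > 1 + 1e-9:
                raise FeatureTableError("column sums cannot exceed 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def samples(self) -> list[str]:
        return list(self.proportions.columns)

    def niche_of(self) -> pd.Series:
        return self.metadata.loc[self.samples, "niche"]


@dataclass
class FilterReport:
    """What a curation step removed: taxa, reads, and (for rarefy) samples."""

    taxa_removed: int = 0
    reads_removed: int = 0
    removed_taxa: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


@dataclass
class NicheSharingSummary:
    """Venn-style decomposition of taxa across niches.

    ``region_counts`` maps each non-empty niche subset (frozenset) to the
    number of taxa present in exactly that subset; ``totals`` gives the
    per-niche taxon count; ``percentages`` is region count / union * 100
    rounded to the nearest integer.
    """

    region_counts: dict[frozenset, int]
    totals: dict[str, int]
    union_size: int
    percentages: dict[frozenset, int]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(
    counts_path,
    metadata_path,
    taxonomy_column: str = "taxonomy",
) -> FeatureTable:
    """Read a classic tab-separated OTU table plus a sample-metadata table.

    The counts file has taxon IDs in the first column, one column per sample
    and a lineage column named ``taxonomy_column`` (or, failing that, the
    last column). The metadata file is keyed by sample ID and must provide a
    ``niche`` column.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0, comment=None, dtype=str)
    raw.index = raw.index.astype(str)
    cols = list(raw.columns)
    if taxonomy_column in cols:
        tax_col = taxonomy_column
    else:
        tax_col = cols[-1]
        logger.info("no %r column; treating last column %r as lineage", taxonomy_column, tax_col)
    taxonomy = raw[tax_col].fillna("").astype(str)
    counts = raw.drop(columns=[tax_col])
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise FeatureTableError(f"non-numeric count value: {exc}") from exc
    arr = counts.to_numpy()
    bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
    if bad.size:
        i, j = bad[0]
        raise FeatureTableError(
            "counts must be non-negative integers; offending cell "
            f"(taxon={counts.index[i]!r}, sample={counts.columns[j]!r}) = {arr[i, j]!r}"
        )
    counts = counts.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None
    taxonomy.index.name = None
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    metadata.index = metadata.index.astype(str)
    metadata.index.name = None
    return FeatureTable(counts=counts, taxonomy=taxonomy, metadata=metadata)


def write_feature_table(t: FeatureTable, counts_path, taxonomy_column: str = "taxonomy") -> None:
    """Write the classic OTU-table TSV (taxa sorted lexicographically,
    sample columns in input order, lineage as the last column)."""
    out = t.counts.sort_index()
    out = out.copy()
    out[taxonomy_column] = t.taxonomy.loc[out.index]
    out.to_csv(counts_path, sep="\t", index_label="#OTU_ID")


def write_metadata(t: FeatureTable, path) -> None:
    t.metadata.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def exclude_lineages(
    t: FeatureTable, patterns: Sequence[str]
) -> tuple[FeatureTable, FilterReport]:
    """Remove taxa whose lineage contains any of the given substrings.

    Matching is case-insensitive on the full lineage string. The pattern
    ``"Unassigned"`` additionally matches taxa with an empty lineage, so host
    plastid reads (``Chloroplast``), plant 18S reads
    (``Archaeplastida``/``Plantae``) and unassigned OTUs can all be dropped
    with one call.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    pats = [p.lower() for p in patterns]
    match_unassigned = any(p == "unassigned" for p in pats)

    def hit(taxon: str) -> bool:
        lin = str(t.taxonomy.loc[taxon])
        low = lin.lower()
        if match_unassigned and low.strip() in ("", "unassigned", "unclassified"):
            return True
        return any(p in low for p in pats)

    removed = [tx for tx in t.taxa if hit(tx)]
    reads = int(t.counts.loc[removed].to_numpy().sum()) if removed else 0
    kept = t.counts.drop(index=removed)
    report = FilterReport(
        taxa_removed=len(removed), reads_removed=reads, removed_taxa=removed
    )
    logger.info("exclude_lineages: removed %d taxa / %d reads", len(removed), reads)
    return t._replace(kept), report


def filter_min_total_fraction(
    t: FeatureTable, min_fraction: float = 0.001
) -> tuple[FeatureTable, FilterReport]:
    """Drop taxa holding strictly fewer than ``min_fraction`` of all reads.

    The threshold is computed on the grand total *before* removal (default
    0.1%, the usual compensation for MiSeq run-to-run bleed-through).
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must be in [0, 1)")
    threshold = min_fraction * t.grand_total
    totals = t.counts.sum(axis=1)
    removed = totals.index[totals < threshold].tolist()
    kept = t.counts.drop(index=removed)
    if kept.shape[0] == 0:
        warnings.warn("filter_min_total_fraction removed every taxon", stacklevel=2)
    report = FilterReport(
        taxa_removed=len(removed),
        reads_removed=int(totals.loc[removed].sum()),
        removed_taxa=removed,
    )
    return t._replace(kept), report


def rarefy(
    t: FeatureTable, depth: int, seed: int
) -> tuple[FeatureTable, FilterReport]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (and listed in the
    report) rather than raising, mirroring the usual practice of discarding
    the shallowest libraries before normalization. Deterministic given
    ``seed``; a sample sitting exactly at ``depth`` is returned unchanged.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = t.sample_sums()
    dropped = [s for s in t.samples if sums[s] < depth]
    kept_samples = [s for s in t.samples if sums[s] >= depth]
    out = {}
    for s in kept_samples:
        col = t.counts[s].to_numpy(dtype=np.int64)
        if sums[s] == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=t.counts.index, dtype=np.int64)
    counts = counts[kept_samples]
    if dropped:
        logger.info("rarefy: dropped %d samples below depth %d: %s", len(dropped), depth, dropped)
    report = FilterReport(dropped_samples=dropped)
    return t._replace(counts), report


def _split_lineage(lineage: str) -> list[str]:
    parts = [p.strip() for p in str(lineage).split(";")]
    # drop trailing empties so "a;b;;" resolves to depth 2
    while parts and parts[-1] == "":
        parts.pop()
    return parts


def collapse_taxonomy(t: FeatureTable, level: str) -> FeatureTable:
    """Sum counts over taxa sharing the lineage prefix down to ``level``.

    Taxa unresolved at ``level`` are kept, grouped under their deepest
    resolved name suffixed ``_unresolved`` (groups like the bacterial clade
    "Ellin6513" that are not formal genera thus survive collapsing).
    The grand total is conserved.
    """
    if level not in COLLAPSIBLE_RANKS:
        raise ValueError(f"level must be one of {COLLAPSIBLE_RANKS}, got {level!r}")
    depth = LINEAGE_RANKS.index(level) + 1

    keys: dict[str, tuple[str, str]] = {}  # taxon -> (group key, group lineage)
    for tx in t.taxa:
        parts = _split_lineage(t.taxonomy.loc[tx])
        if len(parts) >= depth and parts[depth - 1] != "":
            prefix = parts[:depth]
            name = prefix[-1]
        else:
            prefix = parts
            base = prefix[-1] if prefix else "Unassigned"
            name = f"{base}_unresolved"
        keys[tx] = (";".join(prefix) + ("" if len(parts) >= depth and parts[depth - 1] != "" else "|u"), name)

    # group by full prefix; use the short name as ID, disambiguating clashes
    groups: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    for tx, (key, name) in keys.items():
        groups.setdefault(key, []).append(tx)
        names[key] = name
    name_counts: dict[str, int] = {}
    for key in groups:
        name_counts[names[key]] = name_counts.get(names[key], 0) + 1

    rows, tax, ids = [], [], []
    for key, members in groups.items():
        name = names[key]
        if name_counts[name] > 1:  # same short name under different prefixes
            name = key.replace("|u", "_unresolved")
        ids.append(name)
        rows.append(t.counts.loc[members].sum(axis=0))
        tax.append(key.split("|")[0])
    counts = pd.DataFrame(rows, index=ids)[t.samples].astype(np.int64)
    taxonomy = pd.Series(tax, index=ids)
    return FeatureTable(counts=counts, taxonomy=taxonomy, metadata=t.metadata)


def to_relative(t: FeatureTable) -> RelativeAbundanceTable:
    """Divide each sample column by its total; all-zero samples are flagged."""
    sums = t.sample_sums()
    zero = [s for s in t.samples if sums[s] == 0]
    denom = sums.replace(0, 1)
    props = t.counts.div(denom, axis=1).astype(float)
    return RelativeAbundanceTable(
        proportions=props,
        taxonomy=t.taxonomy.loc[t.counts.index],
        metadata=t.metadata,
        taxon_totals=t.counts.sum(axis=1),
        zero_samples=zero,
    )


def network_prefilter(
    r: RelativeAbundanceTable,
    min_prevalence: float = 0.05,
    min_max_abundance: float = 0.01,
    min_reads: int = 0,
) -> RelativeAbundanceTable:
    """Prevalence/abundance prefilter applied before co-occurrence testing.

    Removes taxa present (proportion > 0) in fewer than ``min_prevalence``
    of the samples; removes taxa whose relative abundance stays below
    ``min_max_abundance`` in every sample; optionally removes taxa whose
    source read total is <= ``min_reads``.
    """
    props = r.proportions
    n = props.shape[1]
    keep = pd.Series(True, index=props.index)
    if n and min_prevalence > 0:
        prevalence = (props > 0).sum(axis=1) / n
        keep &= prevalence >= min_prevalence
    if min_max_abundance > 0:
        keep &= props.max(axis=1) >= min_max_abundance
    if min_reads > 0:
        if r.taxon_totals is None:
            raise ValueError("min_reads filter requires source taxon totals")
        keep &= r.taxon_totals.loc[props.index] > min_reads
    kept = props.loc[keep[keep].index]
    return RelativeAbundanceTable(
        proportions=kept,
        taxonomy=r.taxonomy.loc[kept.index],
        metadata=r.metadata,
        taxon_totals=None if r.taxon_totals is None else r.taxon_totals.loc[kept.index],
        zero_samples=list(r.zero_samples),
        complete=False,
    )


def concat_relative(tables: Sequence[RelativeAbundanceTable]) -> RelativeAbundanceTable:
    """Stack per-kingdom relative-abundance tables over the same samples.

    Each kingdom is its own sequencing composition, so tables are
    normalized separately and only then concatenated for pair testing.
    Proportions are rescaled by 1/k so the combined columns stay within
    [0, 1]; the rescaling is rank-preserving per taxon and cancels in the
    ReBoot renormalization, so downstream scores are unaffected.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    samples = tables[0].samples
    for t in tables[1:]:
        if t.samples != samples:
            raise FeatureTableError("tables must share the same sample columns")
    all_taxa = [tx for t in tables for tx in t.taxa]
    if len(all_taxa) != len(set(all_taxa)):
        raise FeatureTableError("taxon identifiers collide across tables")
    k = len(tables)
    props = pd.concat([t.proportions for t in tables]) / k
    taxonomy = pd.concat([t.taxonomy.loc[t.taxa] for t in tables])
    totals = None
    if all(t.taxon_totals is not None for t in tables):
        totals = pd.concat([t.taxon_totals.loc[t.taxa] for t in tables])
    return RelativeAbundanceTable(
        proportions=props,
        taxonomy=taxonomy,
        metadata=tables[0].metadata,
        taxon_totals=totals,
        zero_samples=sorted({s for t in tables for s in t.zero_samples}),
        complete=False,
    )


# ---------------------------------------------------------------------------
# Niche sharing (Venn regions)
# ---------------------------------------------------------------------------

def sharing_percentages(
    region_counts: Mapping[frozenset, int]
) -> dict[frozenset, int]:
    """Nearest-integer percentages of the union for each Venn region."""
    union = sum(region_counts.values())
    if union == 0:
        return {k: 0 for k in region_counts}
    return {k: int(round(100.0 * v / union)) for k, v in region_counts.items()}


def niche_sharing(t: FeatureTable, niche_column: str = "niche") -> NicheSharingSummary:
    """Count taxa specific to and shared among niches (Venn regions).

    A taxon is "present" in a niche when it has a non-zero count in at least
    one sample of that niche; each taxon is assigned to the region of the
    exact niche subset it occupies.
    """
    niches = t.metadata.loc[t.samples, niche_column]
    present: dict[str, np.ndarray] = {}
    uniq = sorted(niches.unique())
    if len(uniq) < 2:
        raise ValueError("niche_sharing requires at least two niches")
    for niche in uniq:
        cols = [s for s in t.samples if niches[s] == niche]
        present[niche] = (t.counts[cols].to_numpy() > 0).any(axis=1)

    region_counts: dict[frozenset, int] = {}
    arr = np.column_stack([present[n] for n in uniq])
    for row in arr:
        members = frozenset(n for n, f in zip(uniq, row) if f)
        if members:
            region_counts[members] = region_counts.get(members, 0) + 1
    totals = {n: int(present[n].sum()) for n in uniq}
    union = int(arr.any(axis=1).sum())
    return NicheSharingSummary(
        region_counts=region_counts,
        totals=totals,
        union_size=union,
        percentages=sharing_percentages(region_counts),
    )
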