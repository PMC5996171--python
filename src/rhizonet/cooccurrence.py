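"""Checkerboard-score (NC-score) co-occurrence with compositional correction.

Relative abundances within a sequenced sample sum to one, so naive
correlations between taxa are biased negative. The approach implemented
here scores each taxon pair with an N-dimensional checkerboard score — a
concordance statistic computed on equal-frequency bin-discretized
profiles — and assesses significance by comparing a bootstrap distribution
of the score against a permutation null in which the two profiles are
shuffled across samples and every sample column of the *full* table is
renormalized to sum one (the "ReBoot" construction). The renormalization
re-injects the compositional coupling into the null, so spurious
closure-induced association is discounted.

Edges surviving a significance cutoff form the signed co-occurrence
network; the sweep over cutoffs {0.01, 0.001, 0.0001, Bonferroni} at each
taxonomic level yields the nested network family used for hub calling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .feature_table import RelativeAbundanceTable

BONFERRONI = "bonferroni"
DEFAULT_CUTOFFS = (0.01, 0.001, 0.0001, BONFERRONI)

KINGDOM_PAIR_CLASSES = ("bacteria-bacteria", "eukaryote-eukaryote", "inter-kingdom")


def default_n_bins(n_samples: int) -> int:
    """Sturges-style bin count: ``ceil(log2(n) + 1)``."""
    if n_samples < 2:
        raise ValueError("need at least two samples to bin")
    return math.ceil(math.log2(n_samples) + 1)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedProfile:
    """Equal-frequency bin index per sample for one taxon profile."""

    bins: np.ndarray  # integer bin index in [0, n_bins-1] per sample
    n_bins: int
    degenerate: bool = False  # constant input profile


def _bin_rows(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning of each row; ties share the bin of their
    average rank. Works on a 1-D vector or a stack of rows."""
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    n = arr.shape[1]
    ranks = rankdata(arr, axis=1, method="average")
    bins = np.floor((ranks - 1.0) * n_bins / n).astype(np.int64)
    return np.clip(bins, 0, n_bins - 1)


def bin_profile(x, n_bins: int | None = None) -> BinnedProfile:
    """Discretize one relative-abundance profile into equal-frequency bins.

    Bin boundaries come from the profile's own ranks, so any monotone
    transformation of the values yields identical bins. A constant profile
    collapses into bin 0 and is flagged degenerate.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("bin_profile expects a 1-D profile")
    n = arr.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    b = default_n_bins(n) if n_bins is None else int(n_bins)
    if b < 2:
        raise ValueError("n_bins must be >= 2")
    degenerate = bool(np.all(arr == arr[0]))
    bins = np.zeros(n, dtype=np.int64) if degenerate else _bin_rows(arr, b)[0]
    return BinnedProfile(bins=bins, n_bins=b, degenerate=degenerate)


# ---------------------------------------------------------------------------
# NC-score
# ---------------------------------------------------------------------------

_KENDALL_KERNEL_CACHE: dict[int, np.ndarray] = {}


def _kendall_kernel(n_bins: int) -> np.ndarray:
    """(B^2, B^2) matrix M[(a,b),(c,d)] = sign(a-c) * sign(b-d)."""
    m = _KENDALL_KERNEL_CACHE.get(n_bins)
    if m is None:
        s = np.sign(np.arange(n_bins)[:, None] - np.arange(n_bins)[None, :]).astype(float)
        m = np.einsum("ac,bd->abcd", s, s).reshape(n_bins**2, n_bins**2)
        _KENDALL_KERNEL_CACHE[n_bins] = m
    return m


def _nc_from_bin_rows(xb: np.ndarray, yb: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Checkerboard score for each row pair of two (m, n) bin matrices.

    For every unordered sample pair, a strict agreement in bin order in
    both profiles is concordant (+1), a strict disagreement (a 2x2
    checkerboard) is discordant (-1), ties count zero; the score is
    ``(C - D) / (n(n-1)/2)``. Computed as a quadratic form over the joint
    bin contingency table, which is equivalent to enumerating all pairs.
    """
    xb = np.atleast_2d(xb)
    yb = np.atleast_2d(yb)
    m, n = xb.shape
    b = int(max(xb.max(), yb.max())) + 1 if n_bins is None else int(n_bins)
    kernel = _kendall_kernel(b)
    code = (xb.astype(np.int64) * b + yb.astype(np.int64)) + np.arange(m)[:, None] * b * b
    counts = np.bincount(code.ravel(), minlength=m * b * b).reshape(m, b * b).astype(float)
    tot = ((counts @ kernel) * counts).sum(axis=1)
    return tot / (n * (n - 1))  # ordered pairs double-count the n(n-1)/2 pairs


def nc_score(a: BinnedProfile, b: BinnedProfile) -> float:
    """NC-score between two binned profiles, in [-1, 1].

    Degenerate (constant) profiles score 0.
    """
    if a.bins.size != b.bins.size:
        raise ValueError("profiles must cover the same samples")
    if a.n_bins != b.n_bins:
        raise ValueError("profiles must use the same bin count")
    if a.degenerate or b.degenerate:
        return 0.0
    return float(_nc_from_bin_rows(a.bins[None, :], b.bins[None, :], a.n_bins)[0])


# ---------------------------------------------------------------------------
# ReBoot significance
# ---------------------------------------------------------------------------

@dataclass
class RebootResult:
    nc_obs: float
    p_raw: float
    z: float
    mean_null: float
    var_null: float
    mean_boot: float
    var_boot: float
    degenerate: bool = False


def reboot_pvalue(
    table: np.ndarray | pd.DataFrame,
    ix: int,
    iy: int,
    n_iter: int = 1000,
    seed: int | None = None,
    n_bins: int | None = None,
) -> RebootResult:
    """Permutation-renormalization significance for one taxon pair.

    ``table`` is the full taxa x samples relative-abundance matrix the pair
    lives in (the remaining rows define the compositional context). The
    null distribution permutes the two profiles independently across
    samples and renormalizes every sample column to its original total
    before rescoring; the bootstrap distribution rescores on samples drawn
    with replacement. The two-sided p-value comes from the normal tail of

        z = (mean_boot - mean_null) / sd_null,

    i.e. the bootstrap-stabilized observed score referred to the scale of
    the renormalized permutation null. Deterministic given ``seed``.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    R = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    x = R[ix].astype(float)
    y = R[iy].astype(float)
    n = x.size
    b = default_n_bins(n) if n_bins is None else int(n_bins)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return RebootResult(0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, degenerate=True)

    nc_obs = float(_nc_from_bin_rows(_bin_rows(x, b), _bin_rows(y, b), b)[0])
    rng = np.random.default_rng(seed)

    # --- permutation null with per-sample renormalization
    rest = R.sum(axis=0) - x - y  # contribution of all other taxa per sample
    perm_x = np.argsort(rng.random((n_iter, n)), axis=1)
    perm_y = np.argsort(rng.random((n_iter, n)), axis=1)
    xp = x[perm_x]
    yp = y[perm_y]
    colsum = rest[None, :] + xp + yp
    colsum[colsum == 0] = 1.0
    null_scores = _nc_from_bin_rows(_bin_rows(xp / colsum, b), _bin_rows(yp / colsum, b), b)

    # --- bootstrap of the observed score
    idx = rng.integers(0, n, size=(n_iter, n))
    boot_scores = _nc_from_bin_rows(_bin_rows(x[idx], b), _bin_rows(y[idx], b), b)

    mean_null = float(null_scores.mean())
    var_null = float(null_scores.var(ddof=1))
    mean_boot = float(boot_scores.mean())
    var_boot = float(boot_scores.var(ddof=1))
    if var_null <= 0:
        return RebootResult(nc_obs, 1.0, 0.0, mean_null, var_null, mean_boot, var_boot, True)
    z = (mean_boot - mean_null) / math.sqrt(var_null)
    p = float(2.0 * norm.sf(abs(z)))
    return RebootResult(nc_obs, p, z, mean_null, var_null, mean_boot, var_boot)


# ---------------------------------------------------------------------------
# Edge sweep
# ---------------------------------------------------------------------------

@dataclass
class EdgeRecord:
    """One significant taxon pair (taxon_a < taxon_b lexicographically)."""

    taxon_a: str
    taxon_b: str
    nc: float
    p_raw: float
    sign: str  # "positive" | "negative"
    kingdom_pair: str

    def __post_init__(self) -> None:
        if self.taxon_a >= self.taxon_b:
            raise ValueError("EdgeRecord requires taxon_a < taxon_b")
        expected = "positive" if self.nc > 0 else "negative"
        if self.sign != expected:
            raise ValueError(f"sign {self.sign!r} inconsistent with nc={self.nc}")


@dataclass
class EdgeSet:
    """Edges retained at one (taxonomic level, significance cutoff)."""

    edges: list[EdgeRecord]
    cutoff_label: str  # "p0.01" | "p0.001" | "p0.0001" | "bonferroni"
    level: str
    m_tested: int
    p_threshold: float

    def __post_init__(self) -> None:
        pairs = [(e.taxon_a, e.taxon_b) for e in self.edges]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate taxon pairs in EdgeSet")

    def pair_set(self) -> set[tuple[str, str]]:
        return {(e.taxon_a, e.taxon_b) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    taxon_a=e.taxon_a,
                    taxon_b=e.taxon_b,
                    nc=e.nc,
                    p_raw=e.p_raw,
                    sign=e.sign,
                    kingdom_pair=e.kingdom_pair,
                    cutoff_label=self.cutoff_label,
                    level=self.level,
                )
                for e in self.edges
            ],
            columns=[
                "taxon_a",
                "taxon_b",
                "nc",
                "p_raw",
                "sign",
                "kingdom_pair",
                "cutoff_label",
                "level",
            ],
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def kingdom_pair_class(ka: str, kb: str) -> str:
    if ka == kb == "bacteria":
        return "bacteria-bacteria"
    if ka == kb == "eukaryote":
        return "eukaryote-eukaryote"
    return "inter-kingdom"


def cutoff_label(cutoff) -> str:
    return BONFERRONI if cutoff == BONFERRONI else f"p{cutoff:g}"


def edge_sweep(
    r: RelativeAbundanceTable,
    kingdoms: Mapping[str, str],
    cutoffs: Sequence = DEFAULT_CUTOFFS,
    n_iter: int = 1000,
    seed: int = 0,
    level: str = "genus",
    alpha: float = 0.05,
    n_bins: int | None = None,
) -> list[EdgeSet]:
    """Test every unordered taxon pair and filter at each cutoff.

    The p-value of each pair is computed once and reused across cutoffs;
    the cutoffs only filter, so edge sets are nested. The Bonferroni
    threshold is ``alpha / m_tested`` with the family = all pairs tested at
    this taxonomic level after prefiltering.
    """
    taxa = r.taxa
    if len(taxa) < 2:
        raise ValueError("edge_sweep needs at least two taxa")
    unmapped = [t for t in taxa if t not in kingdoms]
    if unmapped:
        raise ValueError(f"taxa without a kingdom assignment: {unmapped}")
    R = r.proportions.to_numpy(dtype=float)
    m = len(taxa) * (len(taxa) - 1) // 2
    master = np.random.default_rng(seed)
    pair_seeds = master.integers(0, 2**31 - 1, size=m)

    records: list[tuple[EdgeRecord, float]] = []
    k = 0
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            res = reboot_pvalue(R, i, j, n_iter=n_iter, seed=int(pair_seeds[k]), n_bins=n_bins)
            k += 1
            if res.degenerate or res.nc_obs == 0:
                continue
            a, b_ = sorted((taxa[i], taxa[j]))
            rec = EdgeRecord(
                taxon_a=a,
                taxon_b=b_,
                nc=res.nc_obs,
                p_raw=res.p_raw,
                sign="positive" if res.nc_obs > 0 else "negative",
                kingdom_pair=kingdom_pair_class(kingdoms[taxa[i]], kingdoms[taxa[j]]),
            )
            records.append((rec, res.p_raw))

    out = []
    for cutoff in cutoffs:
        thr = alpha / m if cutoff == BONFERRONI else float(cutoff)
        edges = [rec for rec, p in records if p < thr]
        out.append(
            EdgeSet(
                edges=edges,
                cutoff_label=cutoff_label(cutoff),
                level=level,
                m_tested=m,
                p_threshold=thr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Edge classification
# ---------------------------------------------------------------------------

@dataclass
class EdgeClassSummary:
    """Counts and nearest-integer percentages by kingdom-pair class and sign."""

    counts: dict[str, int]
    class_percentages: dict[str, int]
    sign_counts: dict[str, dict[str, int]]
    sign_percentages: dict[str, dict[str, int]]  # within-class positive/negative
    total: int


def classify_edges(edges: EdgeSet | Iterable[EdgeRecord]) -> EdgeClassSummary:
    """Summarize an edge set by kingdom-pair class and correlation sign.

    Reports each class's share of all edges and, within each class, the
    positive/negative split, all rounded to the nearest integer percent.
    """
    recs = list(edges.edges) if isinstance(edges, EdgeSet) else list(edges)
    counts = {c: 0 for c in KINGDOM_PAIR_CLASSES}
    signs = {c: {"positive": 0, "negative": 0} for c in KINGDOM_PAIR_CLASSES}
    for e in recs:
        if e.kingdom_pair not in counts:
            raise ValueError(f"unknown kingdom-pair class {e.kingdom_pair!r}")
        counts[e.kingdom_pair] += 1
        signs[e.kingdom_pair][e.sign] += 1
    total = sum(counts.values())
    class_pct = {
        c: (0 if total == 0 else int(round(100.0 * v / total))) for c, v in counts.items()
    }
    sign_pct = {}
    for c in KINGDOM_PAIR_CLASSES:
        ct = counts[c]
        sign_pct[c] = {
            s: (0 if ct == 0 else int(round(100.0 * signs[c][s] / ct)))
            for s in ("positive", "negative")
        }
    return EdgeClassSummary(
        counts=counts,
        class_percentages=class_pct,
        sign_counts=signs,
        sign_percentages=sign_pct,
        total=total,
    )
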