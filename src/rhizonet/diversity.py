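"""Alpha/beta diversity, ordination, PERMANOVA, and differential abundance.

Covers the community-ecology statistics used alongside network inference:
observed richness and bias-corrected Chao1, Shannon diversity (base-2 by
default) and Simpson evenness, Bray-Curtis and normalized weighted UniFrac
distances, classical PCoA, single-factor PERMANOVA (Adonis) with permutation
p-values, and Welch-t differential abundance with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable, RelativeAbundanceTable


class DiversityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def observed_richness(counts) -> int:
    """Number of taxa with a non-zero count."""
    c = np.asarray(counts)
    return int((c > 0).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1(F1-1) / (2(F2+1))``.

    F1 and F2 are the singleton and doubleton counts; the bias-corrected
    form stays defined when no doubletons are observed. An all-zero sample
    returns 0.
    """
    c = np.asarray(counts)
    if np.any(c < 0):
        raise DiversityError("counts must be non-negative")
    s_obs = observed_richness(c)
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity ``H = -sum p_i log_base p_i`` (bits by default)."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise DiversityError("shannon undefined for an all-zero sample")
    p = c[c > 0] / c.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def simpson_evenness(counts) -> float:
    """Simpson evenness: inverse Simpson index divided by observed richness."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise DiversityError("simpson_evenness undefined for an all-zero sample")
    p = c / c.sum()
    inv_simpson = 1.0 / float((p**2).sum())
    return inv_simpson / observed_richness(c)


def alpha_diversity_table(t: FeatureTable) -> pd.DataFrame:
    """Per-sample richness, Chao1, Shannon (bits), and Simpson evenness."""
    rows = {}
    for s in t.samples:
        col = t.counts[s].to_numpy()
        if col.sum() == 0:
            rows[s] = dict(richness=0, chao1=0.0, shannon=np.nan, simpson_evenness=np.nan)
        else:
            rows[s] = dict(
                richness=observed_richness(col),
                chao1=chao1(col),
                shannon=shannon(col),
                simpson_evenness=simpson_evenness(col),
            )
    return pd.DataFrame.from_dict(rows, orient="index").loc[t.samples]


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise DiversityError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DiversityError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise DiversityError("distance matrix diagonal must be zero")
        if d.size and d.min() < 0:
            raise DiversityError("distances must be non-negative")
        self.values = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def bray_curtis(r: RelativeAbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples of a proportion table."""
    x = r.proportions.to_numpy(dtype=float).T  # samples x taxa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-zero pairs
        d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(labels=r.samples, values=d)


def read_newick(path_or_string):
    """Parse a rooted newick tree (quoted labels tolerated).

    Branches with no length are assigned length 1.0 with a warning, so
    topology-only trees remain usable.
    """
    import io

    from skbio import TreeNode

    s = path_or_string
    if isinstance(s, str) and s.strip().endswith(";"):
        tree = TreeNode.read(io.StringIO(s), convert_underscores=False)
    else:
        tree = TreeNode.read(str(s), convert_underscores=False)
    patched = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
            patched += 1
    tree.length = None  # root branch does not contribute
    if patched:
        warnings.warn(f"{patched} branches had no length; defaulted to 1.0", stacklevel=2)
    return tree


def weighted_unifrac(t: FeatureTable, tree) -> DistanceMatrix:
    """Normalized weighted UniFrac distance between all sample pairs.

    For each branch ``b`` with length ``l_b`` and descendant proportion
    ``A_b``/``B_b`` in the two samples,
    ``d = sum_b l_b |A_b - B_b| / sum_b l_b (A_b + B_b)``.
    Every table taxon must be a leaf of the (rooted) tree; extra leaves are
    allowed and simply carry zero weight.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    leaf_names = {leaf.name for leaf in tree.tips()}
    missing = [tx for tx in t.taxa if tx not in leaf_names]
    if missing:
        raise DiversityError(f"taxa missing from tree: {missing}")

    sums = t.sample_sums().replace(0, 1)
    props = t.counts.div(sums, axis=1)
    n = len(t.samples)

    # per-branch descendant proportion for every sample, by postorder sweep
    branch_lengths = []
    branch_props = []  # each: vector over samples
    acc: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (
                props.loc[node.name].to_numpy(dtype=float)
                if node.name in props.index
                else np.zeros(n)
            )
        else:
            vec = np.zeros(n)
            for child in node.children:
                vec = vec + acc[id(child)]
        acc[id(node)] = vec
        if not node.is_root() and node.length is not None:
            branch_lengths.append(float(node.length))
            branch_props.append(vec)

    L = np.asarray(branch_lengths)
    P = np.asarray(branch_props)  # branches x samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = float((L * np.abs(P[:, i] - P[:, j])).sum())
            den = float((L * (P[:, i] + P[:, j])).sum())
            d[i, j] = d[j, i] = 0.0 if den == 0 else num / den
    return DistanceMatrix(labels=t.samples, values=d)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes
    explained: np.ndarray  # fraction of positive eigenvalue mass per axis
    eigenvalues: np.ndarray
    negative_eigenvalue_mass: float


def pcoa(d: DistanceMatrix, k: int = 2) -> PCoAResult:
    """Classical multidimensional scaling (principal coordinates).

    Double-centers ``-d^2/2``, eigendecomposes, clips negative eigenvalues
    to zero (their mass is reported), and returns the top-``k`` axes ordered
    by eigenvalue. Requesting more axes than the rank returns fewer, with a
    warning.
    """
    dm = d.values
    n = dm.shape[0]
    b = -0.5 * dm**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ b @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg_mass = float(-evals[evals < 0].sum())
    pos = np.clip(evals, 0, None)
    rank = int((pos > max(1e-10 * pos.max(), 1e-12)).sum()) if pos.max() > 0 else 0
    if k > rank:
        warnings.warn(f"requested {k} axes but rank is {rank}; returning {rank}", stacklevel=2)
        k = rank
    coords = evecs[:, :k] * np.sqrt(pos[:k])
    total = pos.sum() if pos.sum() > 0 else 1.0
    return PCoAResult(
        coordinates=pd.DataFrame(
            coords, index=d.labels, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        explained=pos[:k] / total,
        eigenvalues=evals,
        negative_eigenvalue_mass=neg_mass,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    r_squared: float
    p_value: float
    pseudo_f: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise DiversityError("R^2 must lie in [0, 1]")


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Total and within-group sums of squares from squared distances."""
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.flatnonzero(codes == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    return ss_total, ss_within


def permanova(
    d: DistanceMatrix,
    groups,
    n_perm: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Single-factor PERMANOVA (Adonis) on a distance matrix.

    ``R^2 = SS_between / SS_total`` where ``SS_total = sum_{i<j} d_ij^2 / n``
    and the within-group term is the analogous per-group sum. The p-value is
    the permutation estimate ``(1 + #{F_perm >= F_obs}) / (n_perm + 1)``,
    which can never return zero. Passing ``n_perm="exact"`` enumerates every
    label permutation (small n only) and reports the exact fraction.
    """
    labels = pd.Series(list(groups))
    if len(labels) != len(d.labels):
        raise DiversityError("group labels must match distance matrix samples")
    codes, uniques = pd.factorize(labels)
    a = len(uniques)
    if a < 2:
        raise DiversityError("PERMANOVA requires at least two groups")
    n = len(labels)
    d2 = d.values**2

    def pseudo_f(c: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2, c, a)
        ss_between = ss_total - ss_within
        if ss_within <= 1e-300 or n - a <= 0:
            f = math.inf if ss_between > 0 else 0.0
        else:
            f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = 0.0 if ss_total == 0 else ss_between / ss_total
        return f, r2

    f_obs, r2 = pseudo_f(codes)
    if n_perm == "exact":
        hits = 0
        count = 0
        for perm in itertools.permutations(range(n)):
            f_p, _ = pseudo_f(codes[list(perm)])
            hits += f_p >= f_obs - 1e-12
            count += 1
        p = hits / count
        n_used = count
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(int(n_perm)):
            f_p, _ = pseudo_f(rng.permutation(codes))
            hits += f_p >= f_obs - 1e-12
        p = (1 + hits) / (int(n_perm) + 1)
        n_used = int(n_perm)
    return PermanovaResult(
        r_squared=min(max(r2, 0.0), 1.0), p_value=p, pseudo_f=f_obs, n_permutations=n_used
    )


# ---------------------------------------------------------------------------
# Differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DiffAbundanceResult:
    table: pd.DataFrame  # taxon-indexed: effect, p_value, q_value, zero_variance


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH FDR adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def diff_abundance(
    r: RelativeAbundanceTable,
    group_a,
    group_b,
    min_reads: int = 0,
) -> DiffAbundanceResult:
    """Per-taxon Welch two-sided t-test on proportions with BH correction.

    Taxa whose source read total is <= ``min_reads`` are dropped before
    testing (a strict > floor, e.g. >250 reads for 16S, >50 for 18S).
    A taxon with zero variance in both groups gets p = 1 and is flagged
    instead of raising.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise DiversityError("both groups need >= 2 samples")
    props = r.proportions
    if min_reads > 0:
        if r.taxon_totals is None:
            raise DiversityError("min_reads requires source taxon totals")
        keep = r.taxon_totals.loc[props.index] > min_reads
        props = props.loc[keep[keep].index]
    a = props[group_a].to_numpy(dtype=float)
    b = props[group_b].to_numpy(dtype=float)
    effect = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    q = benjamini_hochberg(p)
    table = pd.DataFrame(
        {
            "effect": effect,
            "p_value": p,
            "q_value": q,
            "zero_variance": zero_var,
        },
        index=props.index,
    )
    return DiffAbundanceResult(table=table)
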