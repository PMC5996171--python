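import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rhizonet import diversity as div
from rhizonet.feature_table import FeatureTable, to_relative
from rhizonet.synthetic_data import generate_tree

from conftest import make_metadata


def _table(mat, taxa, samples, niches):
    counts = pd.DataFrame(mat, index=taxa, columns=samples)
    tax = pd.Series({t: "L" for t in taxa})
    return FeatureTable(counts, tax, make_metadata(samples, niches))


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

class TestAlpha:
    def test_chao1_formula(self):
        # S_obs=4, F1=2, F2=1 -> 4 + 2*1/(2*2)
        assert div.chao1([1, 1, 2, 3]) == 4.5

    def test_chao1_no_singletons_is_observed(self):
        assert div.chao1([2, 3, 4]) == 3

    def test_chao1_never_below_observed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(0, 5, size=12)
            if c.sum():
                assert div.chao1(c) >= div.observed_richness(c)

    def test_chao1_all_zero(self):
        assert div.chao1([0, 0]) == 0.0

    def test_shannon_two_equal_classes_is_one_bit(self):
        assert div.shannon([5, 5]) == pytest.approx(1.0)

    def test_single_taxon_degenerate(self):
        assert div.shannon([7]) == pytest.approx(0.0)
        assert div.simpson_evenness([7]) == pytest.approx(1.0)

    def test_shannon_brute_force(self):
        counts = np.array([4, 2, 2])
        p = counts / counts.sum()
        expected = -sum(pi * math.log2(pi) for pi in p)
        assert div.shannon(counts) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(div.DiversityError):
            div.shannon([0, 0])
        with pytest.raises(div.DiversityError):
            div.simpson_evenness([0, 0])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = _table(
            [[5, 5, 0], [5, 5, 0], [0, 0, 10]],
            ["a", "b", "c"],
            ["s1", "s2", "s3"],
            ["bulk", "bulk", "root"],
        )
        d = div.bray_curtis(to_relative(t))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_matches_hand_summation(self):
        rng = np.random.default_rng(3)
        x = rng.random(6)
        y = rng.random(6)
        x, y = x / x.sum(), y / y.sum()
        expected = np.abs(x - y).sum() / (x + y).sum()
        counts = np.column_stack([(x * 1e6).astype(int), (y * 1e6).astype(int)])
        t = _table(counts, [f"t{i}" for i in range(6)], ["s1", "s2"], ["bulk", "root"])
        d = div.bray_curtis(to_relative(t))
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-4)

    def test_bounds_and_symmetry(self, canonical_community):
        d = div.bray_curtis(to_relative(canonical_community.bacteria))
        assert d.values.min() >= 0 and d.values.max() <= 1
        np.testing.assert_allclose(d.values, d.values.T)


# ---------------------------------------------------------------------------
# Weighted UniFrac
# ---------------------------------------------------------------------------

def _brute_force_unifrac(newick, table):
    """Independent oracle: dendropy traversal, explicit branch enumeration."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    props = table.counts.div(table.counts.sum(axis=0).replace(0, 1), axis=1)
    samples = list(table.samples)
    n = len(samples)
    d = np.zeros((n, n))
    branches = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        leaves = {lf.taxon.label for lf in edge.head_node.leaf_iter()}
        length = edge.length if edge.length is not None else 1.0
        branches.append((length, leaves))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for length, leaves in branches:
                a = sum(props.loc[t, samples[i]] for t in table.taxa if t in leaves)
                b = sum(props.loc[t, samples[j]] for t in table.taxa if t in leaves)
                num += length * abs(a - b)
                den += length * (a + b)
            d[i, j] = d[j, i] = num / den if den else 0.0
    return d


class TestWeightedUnifrac:
    four_leaf = "((A:1.0,B:2.0):1.5,(C:1.0,D:3.0):0.5);"

    def _t(self, mat, samples=("s1", "s2"), niches=("bulk", "root")):
        return _table(mat, ["A", "B", "C", "D"], list(samples), list(niches))

    def test_identical_samples_zero(self):
        t = self._t([[2, 2], [3, 3], [1, 1], [4, 4]])
        d = div.weighted_unifrac(t, self.four_leaf)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_subtrees_distance_one(self):
        t = self._t([[5, 0], [5, 0], [0, 5], [0, 5]])
        d = div.weighted_unifrac(t, "((A:1,B:1):1,(C:1,D:1):1);")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_branch_enumeration_oracle(self):
        t = self._t([[4, 1], [0, 3], [5, 5], [1, 0]])
        d = div.weighted_unifrac(t, self.four_leaf)
        expected = _brute_force_unifrac(self.four_leaf, t)
        np.testing.assert_allclose(d.values, expected, atol=1e-12)

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6])
    def test_random_trees_against_oracle_and_skbio(self, n_leaves):
        from skbio import TreeNode
        from skbio.diversity.beta import weighted_unifrac as sk_wu
        import io

        rng = np.random.default_rng(n_leaves)
        taxa = [f"t{i}" for i in range(n_leaves)]
        newick = generate_tree(taxa, seed=n_leaves)
        mat = rng.integers(0, 30, size=(n_leaves, 3))
        mat[:, 0] += 1
        t = _table(mat, taxa, ["s1", "s2", "s3"], ["bulk", "rhizosphere", "root"])
        d = div.weighted_unifrac(t, newick)
        np.testing.assert_allclose(
            d.values, _brute_force_unifrac(newick, t), atol=1e-10
        )
        sk_tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
        for i, j in itertools.combinations(range(3), 2):
            sk = sk_wu(
                t.counts.to_numpy()[:, i],
                t.counts.to_numpy()[:, j],
                taxa=taxa,
                tree=sk_tree,
                normalized=True,
            )
            assert d.values[i, j] == pytest.approx(sk, abs=1e-10)

    def test_missing_taxon_listed(self):
        t = self._t([[1, 1], [1, 1], [1, 1], [1, 1]])
        with pytest.raises(div.DiversityError, match="D"):
            div.weighted_unifrac(t, "((A:1,B:1):1,C:1);")


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPCoA:
    def test_three_equidistant_points(self):
        d = div.DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))
        res = div.pcoa(d, k=2)
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(5)
        pts = rng.random((7, 3))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = div.pcoa(div.DistanceMatrix([f"p{i}" for i in range(7)], dm), k=3)
        coords = res.coordinates.to_numpy()
        back = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(back, dm, atol=1e-8)

    def test_collinear_points_single_axis(self):
        xs = np.array([0.0, 1.0, 2.0, 5.0])
        dm = np.abs(xs[:, None] - xs[None, :])
        with pytest.warns(UserWarning):
            res = div.pcoa(div.DistanceMatrix(list("abcd"), dm), k=2)
        assert res.coordinates.shape[1] == 1
        axis = res.coordinates.iloc[:, 0].to_numpy()
        np.testing.assert_allclose(np.abs(axis[:, None] - axis[None, :]), dm, atol=1e-8)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _oracle_permanova_f(dm, labels):
    """Independent pseudo-F computed with plain loops."""
    n = len(labels)
    groups = sorted(set(labels))
    a = len(groups)
    ss_total = sum(dm[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        m = len(members)
        if m > 1:
            ss_within += (
                sum(dm[i, j] ** 2 for i, j in itertools.combinations(members, 2)) / m
            )
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total


class TestPermanova:
    def test_maximal_separation_r2_one(self):
        # two tight groups, all between-group distance
        dm = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                dm[i, j] = dm[j, i] = 1.0
        res = div.permanova(
            div.DistanceMatrix(list("abcd"), dm), ["g1", "g1", "g2", "g2"], n_perm=99, seed=0
        )
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        pts = rng.random((6, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = ["x", "x", "x", "y", "y", "y"]
        res = div.permanova(div.DistanceMatrix(list("abcdef"), dm), labels, n_perm="exact")
        f_obs, r2 = _oracle_permanova_f(dm, labels)
        assert res.pseudo_f == pytest.approx(f_obs)
        assert res.r_squared == pytest.approx(r2)
        hits = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            f_p, _ = _oracle_permanova_f(dm, [labels[i] for i in perm])
            hits += f_p >= f_obs - 1e-12
            total += 1
        assert res.p_value == pytest.approx(hits / total)

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM, permanova as sk_permanova

        rng = np.random.default_rng(1)
        pts = rng.random((9, 3))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = div.permanova(div.DistanceMatrix([str(i) for i in range(9)], dm), labels, n_perm=99, seed=0)
        sk = sk_permanova(SkDM(dm, [str(i) for i in range(9)]), grouping=labels, permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"])

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        high_p = 0
        for _ in range(100):
            pts = rng.random((10, 2))
            dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            res = div.permanova(
                div.DistanceMatrix([str(i) for i in range(10)], dm),
                labels, n_perm=99, seed=int(rng.integers(2**31)),
            )
            high_p += res.p_value > 0.05
        assert high_p >= 90

    def test_p_never_zero(self):
        dm = np.zeros((4, 4))
        for i in (0, 1):
            for j in (2, 3):
                dm[i, j] = dm[j, i] = 1.0
        res = div.permanova(div.DistanceMatrix(list("abcd"), dm), ["x", "x", "y", "y"], n_perm=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_single_group_rejected(self):
        dm = np.zeros((3, 3))
        with pytest.raises(div.DiversityError):
            div.permanova(div.DistanceMatrix(list("abc"), dm), ["g", "g", "g"])


# ---------------------------------------------------------------------------
# Differential abundance + BH
# ---------------------------------------------------------------------------

class TestDiffAbundance:
    def _rel(self, mat, samples, niches):
        t = _table(mat, [f"t{i}" for i in range(len(mat))], samples, niches)
        return to_relative(t)

    def test_identical_groups_p_one(self):
        mat = [[10, 20, 10, 20], [30, 10, 30, 10], [5, 5, 5, 5]]
        rel = self._rel(mat, ["a1", "a2", "b1", "b2"], ["bulk"] * 2 + ["root"] * 2)
        res = div.diff_abundance(rel, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(res.table["p_value"], 1.0)

    def test_bh_hand_computation(self):
        np.testing.assert_allclose(
            div.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        q = div.benjamini_hochberg(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_min_reads_floor_strict(self):
        mat = np.array([[50, 50, 100, 50], [1000, 900, 800, 1000]])
        rel = self._rel(mat, ["a1", "a2", "b1", "b2"], ["bulk"] * 2 + ["root"] * 2)
        res = div.diff_abundance(rel, ["a1", "a2"], ["b1", "b2"], min_reads=250)
        assert "t0" not in res.table.index  # 250 total reads: dropped (strict >)
        assert "t1" in res.table.index

    def test_zero_variance_flagged_not_raised(self):
        mat = np.array([[10, 10, 10, 10], [10, 20, 15, 25]])
        rel = self._rel(mat, ["a1", "a2", "b1", "b2"], ["bulk"] * 2 + ["root"] * 2)
        res = div.diff_abundance(rel, ["a1", "a2"], ["b1", "b2"])
        # t0 proportions vary only through t1; construct exact zero variance
        mat2 = np.array([[10, 10, 10, 10], [10, 10, 10, 10]])
        rel2 = self._rel(mat2, ["a1", "a2", "b1", "b2"], ["bulk"] * 2 + ["root"] * 2)
        res2 = div.diff_abundance(rel2, ["a1", "a2"], ["b1", "b2"])
        assert res2.table["zero_variance"].all()
        assert (res2.table["p_value"] == 1.0).all()
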