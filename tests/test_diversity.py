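"""Diversity metrics against closed forms and exhaustive branch oracles."""

import numpy as np
import pytest

from holoshare import AsvCountTable, DistanceMatrix, PhylogeneticTree
from holoshare.diversity import (
    bray_curtis,
    jaccard,
    observed_richness,
    pcoa,
    shannon,
    unifrac_unweighted,
    unifrac_weighted,
)
from holoshare.synthetic_data import _random_tree


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def branch_leafsets(tree: PhylogeneticTree):
    """(length, subtended leaf set) for every non-root branch, by explicit
    enumeration — the independent oracle for both UniFrac variants."""
    out = []
    for node in tree.tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append((float(node.length), leaves))
    return out


def oracle_unifrac(table, tree, weighted):
    branches = branch_leafsets(tree)
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for length, leaves in branches:
                cols = [table.asv_index(a) for a in leaves if a in set(table.asv_ids)]
                if weighted:
                    pa = rel[i, cols].sum() if cols else 0.0
                    pb = rel[j, cols].sum() if cols else 0.0
                    num += length * abs(pa - pb)
                    den += length * (pa + pb)
                else:
                    ina = any(table.counts[i, c] > 0 for c in cols)
                    inb = any(table.counts[j, c] > 0 for c in cols)
                    num += length * (ina != inb)
                    den += length * (ina or inb)
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return d


def random_fixture(seed, n_leaves=12, n_samples=4):
    rng = np.random.default_rng(seed)
    asvs = [f"L{k:02d}" for k in range(n_leaves)]
    tree = _random_tree(asvs, rng)
    counts = rng.integers(0, 40, size=(n_samples, n_leaves))
    counts[:, 0] += 1  # no zero-total samples
    table = AsvCountTable([f"s{i}" for i in range(n_samples)], asvs, counts)
    return table, tree


# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

class TestAlpha:
    def test_observed_richness(self):
        assert observed_richness([5, 0, 1, 2]) == 3
        assert observed_richness([0, 0]) == 0

    def test_richness_never_increases_under_rarefaction(self, small_herd):
        from holoshare.filtering import rarefy

        table = small_herd[0]
        rare = rarefy(table, 500, seed=3)
        for s in rare.sample_ids:
            assert observed_richness(rare.sample_counts(s)) <= observed_richness(
                table.sample_counts(s)
            )

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10, 10, 10, 10], np.log(4)),
            ([7, 0, 0], 0.0),
            ([6, 4], 0.6730116670092565),  # -0.6 ln 0.6 - 0.4 ln 0.4
        ],
    )
    def test_shannon_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_zero_total_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


# ---------------------------------------------------------------------------
# Jaccard / Bray-Curtis
# ---------------------------------------------------------------------------

class TestJaccardBray:
    def test_jaccard_set_example(self):
        t = AsvCountTable(["x", "y"], list("abcd"), [[1, 1, 1, 0], [0, 1, 1, 1]])
        assert jaccard(t).data[0, 1] == pytest.approx(0.5)  # 1 - 2/4

    def test_identical_and_disjoint(self):
        t = AsvCountTable(
            ["x", "y", "z"], list("abcd"), [[2, 3, 0, 0], [2, 3, 0, 0], [0, 0, 1, 4]]
        )
        d = jaccard(t).data
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_jaccard_matches_set_oracle(self, small_herd):
        from itertools import combinations

        table = small_herd[0].select_samples(small_herd[0].sample_ids[:15])
        d = jaccard(table)
        sets = {
            s: {a for a, c in zip(table.asv_ids, table.sample_counts(s)) if c > 0}
            for s in table.sample_ids
        }
        for s1, s2 in combinations(table.sample_ids, 2):
            expected = 1 - len(sets[s1] & sets[s2]) / len(sets[s1] | sets[s2])
            i, j = table.sample_index(s1), table.sample_index(s2)
            assert d.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bray_formula_example(self):
        t = AsvCountTable(["x", "y"], ["a", "b"], [[6, 4], [2, 8]])
        assert bray_curtis(t).data[0, 1] == pytest.approx(0.4)  # (4+4)/20

    def test_bray_identical_and_disjoint(self):
        t = AsvCountTable(
            ["x", "y", "z"], list("abcd"), [[6, 4, 0, 0], [6, 4, 0, 0], [0, 0, 3, 3]]
        )
        d = bray_curtis(t).data
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_bray_zero_total_rejected(self):
        t = AsvCountTable(["x", "y"], ["a"], [[1], [0]])
        with pytest.raises(ValueError):
            bray_curtis(t)

    def test_quantitative_jaccard_transform(self):
        t = AsvCountTable(["x", "y"], ["a", "b"], [[6, 4], [2, 8]])
        b = 0.4
        assert jaccard(t, quantitative=True).data[0, 1] == pytest.approx(
            2 * b / (1 + b)
        )


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

class TestUniFrac:
    def test_two_leaf_disjoint_samples(self):
        tree = PhylogeneticTree.from_newick("(A:1,B:1);")
        t = AsvCountTable(["x", "y"], ["A", "B"], [[3, 0], [0, 5]])
        assert unifrac_unweighted(t, tree).data[0, 1] == pytest.approx(1.0)
        assert unifrac_weighted(t, tree).data[0, 1] == pytest.approx(1.0)

    def test_identical_profiles_zero(self):
        tree = PhylogeneticTree.from_newick("((A:1,B:2):0.5,C:3);")
        t = AsvCountTable(["x", "y"], ["A", "B", "C"], [[3, 1, 2], [3, 1, 2]])
        assert unifrac_unweighted(t, tree).data[0, 1] == 0.0
        assert unifrac_weighted(t, tree).data[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_missing_asv_listed(self):
        tree = PhylogeneticTree.from_newick("(A:1,B:1);")
        t = AsvCountTable(["x", "y"], ["A", "Z"], [[3, 1], [1, 2]])
        with pytest.raises(ValueError, match="Z"):
            unifrac_unweighted(t, tree)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_branch_oracle(self, seed):
        table, tree = random_fixture(seed)
        np.testing.assert_allclose(
            unifrac_unweighted(table, tree).data,
            oracle_unifrac(table, tree, weighted=False),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            unifrac_weighted(table, tree).data,
            oracle_unifrac(table, tree, weighted=True),
            atol=1e-12,
        )

    @pytest.mark.parametrize("seed", [3, 4])
    def test_star_tree_reductions(self, seed):
        # unit-branch star tree: unweighted UniFrac == Jaccard and
        # weighted UniFrac == Bray-Curtis, exactly
        rng = np.random.default_rng(seed)
        asvs = [f"L{k}" for k in range(10)]
        tree = PhylogeneticTree.from_newick(
            "(" + ",".join(f"{a}:1" for a in asvs) + ");"
        )
        # equal depths (as after rarefaction): the weighted reduction is on
        # relative abundances, which then coincide with count Bray-Curtis
        counts = np.vstack(
            [rng.multinomial(1000, rng.dirichlet(np.ones(10))) for _ in range(5)]
        )
        table = AsvCountTable([f"s{i}" for i in range(5)], asvs, counts)
        np.testing.assert_allclose(
            unifrac_unweighted(table, tree).data, jaccard(table).data, atol=1e-12
        )
        np.testing.assert_allclose(
            unifrac_weighted(table, tree).data, bray_curtis(table).data, atol=1e-12
        )

    def test_agrees_with_skbio(self):
        # independent implementation cross-check on a small fixture
        import skbio.diversity

        table, tree = random_fixture(5, n_leaves=8, n_samples=3)
        sk = skbio.diversity.beta_diversity(
            "unweighted_unifrac",
            table.counts,
            ids=table.sample_ids,
            taxa=table.asv_ids,
            tree=tree.tree,
        )
        np.testing.assert_allclose(
            unifrac_unweighted(table, tree).data, sk.data, atol=1e-10
        )


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

class TestPcoa:
    def test_reconstructs_euclidean_distances(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        rec = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=-1
        )
        np.testing.assert_allclose(rec, d, atol=1e-9)

    def test_all_zero_distances(self):
        res = pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_eigenvalues_descending_and_proportions(self, small_herd):
        from holoshare.filtering import rarefy

        table = rarefy(small_herd[0].select_samples(small_herd[0].sample_ids[:10]), 500, 0)
        res = pcoa(bray_curtis(table))
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_positive_eigenvalue_sum_matches_skbio(self, small_herd):
        import skbio.stats.ordination
        from skbio import DistanceMatrix as SkDM

        from holoshare.filtering import rarefy

        table = rarefy(small_herd[0].select_samples(small_herd[0].sample_ids[:10]), 500, 0)
        dm = bray_curtis(table)
        res = pcoa(dm)
        sk = skbio.stats.ordination.pcoa(SkDM(dm.data, ids=dm.ids))
        ours = res.eigenvalues[res.eigenvalues > 0].sum()
        theirs = sk.eigvals[sk.eigvals > 0].sum()
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_deterministic_sign_convention(self):
        pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(["a", "b", "c"], d))
        for k in range(res.coordinates.shape[1]):
            i = np.argmax(np.abs(res.coordinates[:, k]))
            assert res.coordinates[i, k] > 0
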