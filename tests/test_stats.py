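"""Permutation statistics, Ward clustering and ARI."""

import warnings

import numpy as np
import pandas as pd
import pytest

from holoshare import AsvCountTable, DistanceMatrix
from holoshare.stats import (
    adjusted_rand_index,
    anova_tukey,
    betadisper_test,
    cluster_stability,
    permanova,
    ward_clusters,
)
from tests.conftest import make_meta


def euclidean_dm(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return DistanceMatrix(ids, d)


def grouping_frame(ids, labels, **extra):
    df = pd.DataFrame({"grp": labels}, index=ids)
    for k, v in extra.items():
        df[k] = v
    return df


class TestPermanova:
    def test_exhaustive_enumeration_separated_fixture(self):
        # two tight groups of 3 with between-distance 10, within-distance 1:
        # of the C(6,3)=20 assignments only the true split and its mirror
        # reach the observed F, i.e. 72 of the 720 orderings -> p = 0.1
        d = np.full((6, 6), 10.0)
        d[:3, :3] = 1.0
        d[3:, 3:] = 1.0
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d)
        meta = grouping_frame(dm.ids, ["a"] * 3 + ["b"] * 3)
        res = permanova(dm, meta, ["grp"], permutations="exhaustive")
        assert res.table.loc["grp", "p"] == pytest.approx(0.1, abs=1e-12)
        assert res.n_permutations == 719

    def test_single_level_factor_zero_df(self):
        dm = euclidean_dm(np.random.default_rng(0).normal(size=(5, 2)))
        meta = grouping_frame(dm.ids, ["same"] * 5)
        res = permanova(dm, meta, ["grp"], n_perm=99, seed=0)
        assert res.table.loc["grp", "df"] == 0
        assert np.isnan(res.table.loc["grp", "F"])

    def test_equals_classical_anova_on_euclidean(self):
        # PERMANOVA term SS on Euclidean distances = classical between-group
        # SS summed over coordinates; F matches too
        rng = np.random.default_rng(42)
        labels = np.repeat(["a", "b", "c"], [6, 5, 7])
        pts = rng.normal(size=(18, 3)) + np.array(
            [{"a": 0, "b": 1.5, "c": -1}[l] for l in labels]
        )[:, None]
        dm = euclidean_dm(pts)
        meta = grouping_frame(dm.ids, labels)
        res = permanova(dm, meta, ["grp"], n_perm=99, seed=1)
        grand = pts.mean(axis=0)
        ss_b = sum(
            (labels == g).sum() * ((pts[labels == g].mean(axis=0) - grand) ** 2).sum()
            for g in "abc"
        )
        ss_w = sum(
            ((pts[labels == g] - pts[labels == g].mean(axis=0)) ** 2).sum()
            for g in "abc"
        )
        assert res.table.loc["grp", "SumOfSqs"] == pytest.approx(ss_b, abs=1e-9)
        f_classic = (ss_b / 2) / (ss_w / 15)
        assert res.table.loc["grp", "F"] == pytest.approx(f_classic, abs=1e-9)

    def test_ss_partition_and_r2_sum(self, small_herd):
        from holoshare.diversity import bray_curtis
        from holoshare.filtering import rarefy

        table, meta, _, _ = small_herd
        sub = table.select_samples(meta.non_control_ids[:40])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dm = bray_curtis(rarefy(sub, 500, 0))
        res = permanova(dm, meta, ["site", "time"], n_perm=99, seed=0)
        t = res.table
        assert t.loc[["site", "time", "Residual"], "SumOfSqs"].sum() == pytest.approx(
            t.loc["Total", "SumOfSqs"], rel=1e-9
        )
        assert t.loc[["site", "time", "Residual"], "R2"].sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_bit_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.normal(size=(12, 2)))
        meta = grouping_frame(dm.ids, ["a", "b", "c"] * 4)
        r1 = permanova(dm, meta, ["grp"], n_perm=199, seed=5)
        r2 = permanova(dm, meta, ["grp"], n_perm=199, seed=5)
        assert r1.table.equals(r2.table)

    def test_missing_covariate_samples_dropped(self):
        rng = np.random.default_rng(4)
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        cov = [0.1, 0.2, np.nan, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
        meta = grouping_frame(dm.ids, ["a", "b"] * 5, cov=cov)
        with pytest.warns(UserWarning, match="missing"):
            res = permanova(dm, meta, ["grp", "cov"], n_perm=99, seed=0)
        assert res.table.loc["Total", "df"] == 8  # 9 samples - 1

    def test_marginal_mode_single_term_matches_sequential(self):
        rng = np.random.default_rng(5)
        dm = euclidean_dm(rng.normal(size=(12, 2)))
        meta = grouping_frame(dm.ids, ["a", "b", "c"] * 4)
        seq = permanova(dm, meta, ["grp"], n_perm=99, seed=0, method="sequential")
        mar = permanova(dm, meta, ["grp"], n_perm=99, seed=0, method="marginal")
        assert seq.table.loc["grp", "SumOfSqs"] == pytest.approx(
            mar.table.loc["grp", "SumOfSqs"], rel=1e-12
        )


class TestBetadisper:
    def test_zero_dispersion_group(self):
        pts = np.vstack([np.tile([1.0, 2.0], (4, 1)), np.random.default_rng(0).normal(size=(4, 2))])
        dm = euclidean_dm(pts)
        res = betadisper_test(dm, ["dup"] * 4 + ["spread"] * 4, n_perm=99, seed=0)
        np.testing.assert_allclose(res.distances.iloc[:4], 0.0, atol=1e-9)

    def test_euclidean_distances_to_group_mean(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        dm = euclidean_dm(pts)
        res = betadisper_test(dm, labels, n_perm=99, seed=0)
        for g, idx in (("a", slice(0, 5)), ("b", slice(5, 10))):
            centroid = pts[idx].mean(axis=0)
            expected = np.linalg.norm(pts[idx] - centroid, axis=1)
            np.testing.assert_allclose(res.distances.iloc[idx], expected, atol=1e-9)

    def test_size_one_group_excluded(self):
        rng = np.random.default_rng(2)
        dm = euclidean_dm(rng.normal(size=(7, 2)))
        with pytest.warns(UserWarning, match="size-1"):
            res = betadisper_test(dm, ["a"] * 3 + ["b"] * 3 + ["lonely"], n_perm=99, seed=0)
        assert res.excluded_groups == ("lonely",)
        assert len(res.distances) == 6

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        dm = euclidean_dm(rng.normal(size=(12, 2)))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = betadisper_test(dm, labels, n_perm=199, seed=7)
        r2 = betadisper_test(dm, labels, n_perm=199, seed=7)
        assert r1.p_value == r2.p_value


class TestAnovaTukey:
    def test_identical_groups(self):
        res = anova_tukey([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_tukey_equals_t_test(self):
        # with k=2 the studentized range q = sqrt(2)|t|, so the Tukey
        # adjusted p equals the two-sided pooled-variance t-test p
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 1, 12)
        res = anova_tukey(np.concatenate([x, y]), ["x"] * 9 + ["y"] * 12)
        t_p = sps.ttest_ind(x, y, equal_var=True).pvalue
        assert res.pairwise.loc[0, "p_adj"] == pytest.approx(t_p, abs=1e-9)

    def test_matches_statsmodels_three_groups(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(9)
        vals = np.concatenate(
            [rng.normal(0, 1, 8), rng.normal(1, 1, 10), rng.normal(2, 1, 6)]
        )
        labels = ["a"] * 8 + ["b"] * 10 + ["c"] * 6
        res = anova_tukey(vals, labels)
        sm = pairwise_tukeyhsd(vals, labels)
        np.testing.assert_allclose(
            res.pairwise["p_adj"].to_numpy(), sm.pvalues, atol=1e-8
        )

    def test_zero_within_variance_flagged(self):
        res = anova_tukey([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res.zero_within_variance
        assert res.p_value == 0.0

    def test_null_rejection_rate_nominal(self):
        # balanced 3x10 normal null: empirical size near 0.05
        rng = np.random.default_rng(10)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        rej = sum(
            anova_tukey(rng.normal(size=30), labels).p_value < 0.05
            for _ in range(500)
        )
        se = np.sqrt(0.05 * 0.95 / 500)
        assert abs(rej / 500 - 0.05) < 3 * se


class TestWard:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
        labels = ward_clusters(euclidean_dm(pts), 2)
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_equals_n(self):
        dm = euclidean_dm(np.random.default_rng(1).normal(size=(4, 2)))
        labels = ward_clusters(dm, 4)
        assert sorted(labels) == [1, 2, 3, 4]

    def test_k_out_of_range(self):
        dm = euclidean_dm(np.zeros((3, 2)))
        with pytest.raises(ValueError):
            ward_clusters(dm, 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_merge_sequence_matches_ess_oracle(self, seed):
        # brute-force oracle: greedy merges minimising the increase in total
        # within-cluster sum of squares, computed from coordinates
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 2))
        ids = [f"s{i}" for i in range(8)]
        dm = euclidean_dm(pts, ids)
        clusters = {i: [i] for i in range(8)}
        for k in range(7, 0, -1):
            # oracle merge at this step
            best = None
            for a in sorted(clusters):
                for b in sorted(clusters):
                    if a >= b:
                        continue
                    pa, pb = pts[clusters[a]], pts[clusters[b]]
                    na, nb = len(pa), len(pb)
                    delta = (
                        na * nb / (na + nb)
                        * ((pa.mean(axis=0) - pb.mean(axis=0)) ** 2).sum()
                    )
                    key = (delta, min(ids[min(clusters[a])], ids[min(clusters[b])]))
                    if best is None or key < best[0]:
                        best = (key, a, b)
            _, a, b = best
            clusters[a] = sorted(clusters[a] + clusters[b])
            del clusters[b]
            expected = np.empty(8, dtype=int)
            for lab, c in enumerate(
                sorted(clusters, key=lambda c: ids[min(clusters[c])]), start=1
            ):
                expected[clusters[c]] = lab
            got = ward_clusters(dm, k).to_numpy()
            assert adjusted_rand_index(got, expected) == pytest.approx(1.0)

    def test_matches_scipy_on_euclidean_fixture(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        dm = euclidean_dm(pts)
        ours = ward_clusters(dm, 3).to_numpy()
        theirs = fcluster(linkage(pdist(pts), method="ward"), 3, criterion="maxclust")
        assert adjusted_rand_index(ours, theirs) == pytest.approx(1.0)


class TestAri:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == pytest.approx(1.0)

    def test_crossed_partitions_minus_half(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_symmetric_and_label_invariant(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 4, 30)
        assert adjusted_rand_index(a, b) == pytest.approx(adjusted_rand_index(b, a))
        relabel = {0: "w", 1: "x", 2: "y", 3: "z"}
        assert adjusted_rand_index(a, [relabel[v] for v in b]) == pytest.approx(
            adjusted_rand_index(a, b)
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 5, 40)
            b = rng.integers(0, 5, 40)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_mismatched_sample_sets_rejected(self):
        s1 = pd.Series([1, 2], index=["a", "b"])
        s2 = pd.Series([1, 2], index=["a", "c"])
        with pytest.raises(ValueError):
            adjusted_rand_index(s1, s2)


class TestClusterStability:
    def test_identical_communities_across_times_give_ari_one(self):
        # 8 animals, 1 site, 2 time points, identical per-animal profiles
        rng = np.random.default_rng(0)
        profiles = rng.integers(1, 100, size=(8, 6))
        rows, counts = {}, []
        for t in ("1M", "3M"):
            for i in range(8):
                sid = f"A{i:02d}_oral_{t}"
                rows[sid] = (f"A{i:02d}", "oral", t, "G1")
                counts.append(profiles[i])
        meta = make_meta(rows)
        table = AsvCountTable(
            list(rows), [f"x{j}" for j in range(6)], np.array(counts)
        )
        out = cluster_stability(table, meta, k=3)
        assert len(out) == 1
        assert out.loc[0, "ari"] == pytest.approx(1.0)

    def test_turnover_degrades_stability(self):
        # tau=0 herds keep higher consecutive-time ARI than tau=0.5 herds
        from holoshare import SyntheticConfig, generate_herd

        means = {}
        for tau in (0.0, 0.5):
            aris = []
            for seed in range(5):
                cfg = SyntheticConfig(
                    n_animals=12, pool_size=150, site_pool_size=50,
                    time_turnover=tau, sites=("oral",), n_controls=0,
                    n_kitome=0, kit_load=0.0, jitter_sigma=0.2, seed=seed,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    table, meta, _, _ = generate_herd(cfg)
                    out = cluster_stability(table, meta, k=3)
                aris.extend(out["ari"])
            means[tau] = np.mean(aris)
        assert means[0.0] > means[0.5]
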