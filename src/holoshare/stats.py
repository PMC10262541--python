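"""Permutation statistics, clustering and partition comparison.

PERMANOVA partitions the variation of a distance matrix among ordered model
terms.  With Gower-centered inner products ``G = -1/2 C D^2 C`` and nested
hat matrices ``H_k`` of the designs up to term k, the sequential sum of
squares of term k is ``tr(H_k G) - tr(H_{k-1} G)``; the pseudo-F is the
usual mean-square ratio against the residual, and p-values come from
permuting the rows/columns of D jointly.  A marginal-SS mode is available
because with several covariates in one model the term order is a modelling
choice.

The homogeneity-of-dispersion test embeds samples by principal coordinates
(keeping negative eigen-axes separately), measures each sample's distance
to its group centroid as ``sqrt(max(0, ||x-c||²_pos - ||x-c||²_neg))``,
and tests the one-way F on those distances by permuting group labels,
followed by Tukey HSD pairwise comparisons.

Ward clustering follows the ward.D2 convention (Lance-Williams recurrence
on squared dissimilarities, results in original distance units) with a
deterministic tie-break on the lexicographically smallest pair of cluster
representative IDs, so cluster labels are reproducible across platforms.
The Adjusted Rand Index is the Hubert-Arabie chance-corrected form.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats as sps

from .io_model import AsvCountTable, DistanceMatrix, SampleMetadata

__all__ = [
    "PermanovaResult",
    "permanova",
    "DispersionResult",
    "betadisper_test",
    "AnovaTukeyResult",
    "anova_tukey",
    "ward_clusters",
    "adjusted_rand_index",
    "cluster_stability",
]

# Relative slack when comparing permuted statistics to the observed one, so
# that permutations reproducing the observed partition are counted as ties
# despite floating-point noise.
_F_EPS = 1e-9


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, SumOfSqs, R2, F, p
    n_permutations: int
    seed: int | None
    method: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PermanovaResult(method={self.method!r})\n{self.table}"


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * c @ (d ** 2) @ c
    return (g + g.T) / 2.0


def _term_block(col: pd.Series) -> np.ndarray:
    """Design columns for one term: centered covariate or dummy-coded factor."""
    if pd.api.types.is_numeric_dtype(col) and not isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        v = col.to_numpy(dtype=float)
        return (v - v.mean())[:, None]
    levels = sorted(pd.unique(col.astype(str)))
    # drop the first level: the intercept absorbs it
    return np.column_stack(
        [(col.astype(str) == lev).to_numpy(dtype=float) for lev in levels[1:]]
    ) if len(levels) > 1 else np.zeros((len(col), 0))


def _orth_bases(blocks: list[np.ndarray], n: int) -> list[np.ndarray]:
    """Orthonormal bases of the nested designs [1], [1,X1], [1,X1,X2], ..."""
    bases = []
    x = np.ones((n, 1)) / math.sqrt(n)
    bases.append(x)
    acc = np.ones((n, 1))
    for b in blocks:
        acc = np.hstack([acc, b])
        q = scipy.linalg.orth(acc)
        bases.append(q)
    return bases


def _trace_forms(g: np.ndarray, bases: list[np.ndarray]) -> np.ndarray:
    """tr(Q_k Q_k' G) for each nested basis Q_k."""
    return np.array([float(np.sum(q * (g @ q))) for q in bases])


def permanova(
    dm: DistanceMatrix,
    meta: SampleMetadata | pd.DataFrame,
    terms: list[str],
    n_perm: int = 9999,
    seed: int | None = 0,
    method: str = "sequential",
    permutations: str = "random",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``terms`` are metadata column names, fitted in order (sequential SS) or
    each adjusted for all others (``method="marginal"``).  Samples with
    missing values in any used term are dropped.  ``permutations`` may be
    ``"exhaustive"`` to enumerate every ordering (n <= 8 samples).
    """
    if n_perm < 99 and permutations != "exhaustive":
        raise ValueError("use at least 99 permutations")
    if method not in ("sequential", "marginal"):
        raise ValueError(f"unknown SS method {method!r}")
    df = meta.df if isinstance(meta, SampleMetadata) else meta
    missing = [t for t in terms if t not in df.columns]
    if missing:
        raise ValueError(f"terms not in metadata: {missing}")
    ids = [s for s in dm.ids if s in df.index]
    sub = df.loc[ids, terms]
    ok = ~sub.isna().any(axis=1)
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} sample(s) with missing term values"
        )
    ids = list(sub.index[ok])
    sub = sub.loc[ids]
    d = dm.submatrix(ids).data
    n = len(ids)
    g = _gower_center(d)
    ss_total = float(np.trace(g))

    blocks = [_term_block(sub[t]) for t in terms]
    bases = _orth_bases(blocks, n)
    ranks = np.array([q.shape[1] for q in bases])
    dfs = np.diff(ranks)
    df_res = n - ranks[-1]
    if method == "marginal":
        drop_one = [
            _orth_bases([b for i, b in enumerate(blocks) if i != k], n)[-1]
            for k in range(len(terms))
        ]
        dfs = np.array([ranks[-1] - q.shape[1] for q in drop_one])

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        tr = _trace_forms(gmat, bases)
        ss_res = float(np.trace(gmat)) - tr[-1]
        if method == "sequential":
            ss_terms = np.diff(tr)
        else:
            # marginal: SS_k = tr(H_full G) - tr(H_{-k} G)
            ss_terms = np.array(
                [tr[-1] - float(np.sum(q * (gmat @ q))) for q in drop_one]
            )
        return ss_terms, ss_res

    ss_terms, ss_res = stats_for(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_terms = np.where(dfs > 0, ss_terms / np.where(dfs > 0, dfs, 1), np.nan)
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        f_obs = ms_terms / ms_res

    exceed = np.zeros(len(terms))
    n_done = 0
    if df_res > 0:
        if permutations == "exhaustive":
            if n > 8:
                raise ValueError("exhaustive permutations limited to n <= 8")
            perms = [p for p in itertools.permutations(range(n))][1:]  # skip identity
        else:
            rng = np.random.default_rng(seed)
            perms = [rng.permutation(n) for _ in range(n_perm)]
        for p in perms:
            idx = np.asarray(p)
            gp = g[np.ix_(idx, idx)]
            ss_t, ss_r = stats_for(gp)
            with np.errstate(invalid="ignore", divide="ignore"):
                f_p = (ss_t / np.where(dfs > 0, dfs, 1)) / (ss_r / df_res)
            for k in range(len(terms)):
                if dfs[k] > 0 and f_p[k] >= f_obs[k] - _F_EPS * max(1.0, abs(f_obs[k])):
                    exceed[k] += 1
        n_done = len(perms)

    pvals = np.where(
        (dfs > 0) & (df_res > 0), (1.0 + exceed) / (1.0 + n_done), np.nan
    )
    rows = []
    for k, t in enumerate(terms):
        rows.append(
            {
                "df": int(dfs[k]),
                "SumOfSqs": float(ss_terms[k]),
                "R2": float(ss_terms[k] / ss_total) if ss_total > 0 else np.nan,
                "F": float(f_obs[k]) if dfs[k] > 0 and df_res > 0 else np.nan,
                "p": float(pvals[k]) if not np.isnan(pvals[k]) else np.nan,
            }
        )
    rows.append(
        {
            "df": int(df_res),
            "SumOfSqs": float(ss_res),
            "R2": float(ss_res / ss_total) if ss_total > 0 else np.nan,
            "F": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"df": n - 1, "SumOfSqs": ss_total, "R2": 1.0, "F": np.nan, "p": np.nan}
    )
    out = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(out, n_done, seed, method)


# ---------------------------------------------------------------------------
# Homogeneity of multivariate dispersion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispersionResult:
    distances: pd.Series         # per-sample distance to its group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame       # Tukey HSD adjusted p per group pair
    n_permutations: int
    seed: int | None
    excluded_groups: tuple[str, ...] = field(default=())


def _dispersion_distances(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Distances to group centroids in the signed PCoA embedding."""
    g = _gower_center(d)
    evals, evecs = scipy.linalg.eigh(g)
    tol = max(np.abs(evals).max(), 1.0) * 1e-12
    pos = evals > tol
    neg = evals < -tol
    xp = evecs[:, pos] * np.sqrt(evals[pos])
    xn = evecs[:, neg] * np.sqrt(-evals[neg])
    d2 = np.zeros(d.shape[0])
    for lab in np.unique(labels):
        m = labels == lab
        cp = xp[m].mean(axis=0) if xp.size else np.zeros(0)
        cn = xn[m].mean(axis=0) if xn.size else np.zeros(0)
        d2[m] = ((xp[m] - cp) ** 2).sum(axis=1) - ((xn[m] - cn) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def _oneway_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    k = 0
    for lab in np.unique(labels):
        v = values[labels == lab]
        ss_b += len(v) * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
        k += 1
    df_b = k - 1
    df_w = len(values) - k
    if df_w <= 0 or ss_w == 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / df_b) / (ss_w / df_w)


def betadisper_test(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = 0,
) -> DispersionResult:
    """Permutation test of homogeneity of multivariate dispersion.

    ``grouping`` is a sequence or Series (indexed by sample ID) of group
    labels aligned to ``dm``.  Groups of size 1 are excluded with a
    warning; at least two groups of size >= 2 are required.
    """
    if isinstance(grouping, pd.Series):
        labels = grouping.reindex(dm.ids).to_numpy()
    else:
        labels = np.asarray(list(grouping))
    if len(labels) != len(dm.ids):
        raise ValueError("grouping length does not match the distance matrix")
    labels = labels.astype(str)
    sizes = pd.Series(labels).value_counts()
    small = tuple(sorted(sizes.index[sizes < 2]))
    if small:
        warnings.warn(f"excluding size-1 group(s): {list(small)}")
    keep = ~np.isin(labels, small)
    ids = [s for s, k in zip(dm.ids, keep) if k]
    labels = labels[keep]
    if len(pd.unique(labels)) < 2:
        raise ValueError("need at least two groups with >= 2 members")
    d = dm.submatrix(ids).data
    dist = _dispersion_distances(d, labels)
    f_obs = _oneway_f(dist, labels)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = _oneway_f(dist, rng.permutation(labels))
        if f_p >= f_obs - _F_EPS * max(1.0, abs(f_obs)):
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)

    tukey = _tukey_pairwise(dist, labels)
    return DispersionResult(
        distances=pd.Series(dist, index=ids, name="distance_to_centroid"),
        group_means=pd.Series(dist, index=labels).groupby(level=0).mean(),
        f_statistic=float(f_obs),
        p_value=float(p),
        pairwise=tukey,
        n_permutations=n_perm,
        seed=seed,
        excluded_groups=small,
    )


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame
    zero_within_variance: bool = False


def _tukey_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Tukey HSD adjusted p-values from the studentized-range distribution.

    Unequal group sizes use the Tukey-Kramer standard error
    ``sqrt(MSE/2 * (1/n_i + 1/n_j))``.
    """
    groups = {lab: values[labels == lab] for lab in sorted(pd.unique(labels))}
    k = len(groups)
    n = len(values)
    df_w = n - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df_w if df_w else np.nan
    rows = []
    for (la, va), (lb, vb) in itertools.combinations(groups.items(), 2):
        diff = va.mean() - vb.mean()
        if mse > 0:
            se = math.sqrt(mse / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            q = abs(diff) / se
            padj = float(np.clip(sps.studentized_range.sf(q, k, df_w), 0.0, 1.0))
        else:
            padj = 0.0 if diff != 0 else 1.0
        rows.append({"group1": la, "group2": lb, "diff": diff, "p_adj": padj})
    return pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj"])


def anova_tukey(values, grouping) -> AnovaTukeyResult:
    """Classical one-way ANOVA followed by Tukey HSD pairwise comparisons."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(list(grouping)).astype(str)
    if len(values) != len(labels):
        raise ValueError("values and grouping differ in length")
    uniq = pd.unique(labels)
    if len(uniq) < 2 or any((labels == u).sum() < 2 for u in uniq):
        raise ValueError("need >= 2 groups with >= 2 values each")
    groups = [values[labels == u] for u in uniq]
    zero_var = all(np.allclose(v, v.mean()) for v in groups)
    if zero_var:
        means = np.array([v.mean() for v in groups])
        if np.allclose(means, means[0]):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0  # p below machine floor, flagged
    else:
        f, p = sps.f_oneway(*groups)
    return AnovaTukeyResult(
        f_statistic=float(f),
        p_value=float(p),
        pairwise=_tukey_pairwise(values, labels),
        zero_within_variance=zero_var,
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_clusters(dm: DistanceMatrix, k: int) -> pd.Series:
    """Agglomerative Ward (ward.D2) clustering cut to exactly k clusters.

    Operates on squared dissimilarities with the Lance-Williams update; at
    every step the merge minimising the Ward distance is chosen, ties
    broken by the lexicographically smallest pair of cluster representative
    IDs (a cluster is represented by its smallest member ID).  Labels 1..k
    are assigned by representative order.
    """
    n = len(dm.ids)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    d2 = dm.data.astype(float) ** 2
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    reps: dict[int, str] = {i: dm.ids[i] for i in range(n)}
    active = sorted(members)
    while len(active) > k:
        best = None
        for a, b in itertools.combinations(active, 2):
            key = (d2[a, b], *sorted((reps[a], reps[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        na, nb = len(members[a]), len(members[b])
        dab = d2[a, b]
        for c in active:
            if c in (a, b):
                continue
            nc = len(members[c])
            d2[a, c] = d2[c, a] = (
                (na + nc) * d2[a, c] + (nb + nc) * d2[b, c] - nc * dab
            ) / (na + nb + nc)
        members[a] = members[a] + members[b]
        reps[a] = min(reps[a], reps[b])
        del members[b], reps[b]
        active = sorted(members)
    order = sorted(active, key=lambda c: reps[c])
    labels = np.empty(n, dtype=int)
    for lab, c in enumerate(order, start=1):
        labels[members[c]] = lab
    return pd.Series(labels, index=dm.ids, name="cluster")


# ---------------------------------------------------------------------------
# Adjusted Rand Index and cluster stability
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels1, labels2) -> float:
    """Hubert-Arabie Adjusted Rand Index between two partitions.

    Accepts arrays (same order) or Series (aligned by index; mismatched
    index sets are an error).  Degenerate identical partitions (all one
    cluster, or all singletons) score 1.
    """
    if isinstance(labels1, pd.Series) and isinstance(labels2, pd.Series):
        if set(labels1.index) != set(labels2.index):
            raise ValueError("partitions cover different sample sets")
        labels2 = labels2.reindex(labels1.index)
    a = np.asarray(list(labels1))
    b = np.asarray(list(labels2))
    if len(a) != len(b):
        raise ValueError("partitions cover different sample sets")
    n = len(a)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(np.array([n]))[0]
    if total == 0:
        return 1.0
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cluster_stability(
    table: AsvCountTable,
    meta: SampleMetadata,
    k: int = 5,
    sites: list[str] | None = None,
    times: list[str] | None = None,
) -> pd.DataFrame:
    """Temporal stability of per-site animal clusterings.

    For every site, animals are clustered (Ward on Bray-Curtis of their
    per-animal community profiles) independently at each time point; the
    ARI between consecutive time points, restricted to animals present at
    both, quantifies cluster conservation.  Pairs with fewer than k common
    animals are skipped with a warning.
    """
    from .core_sharing import build_communities

    df = meta.df
    nc = df[~df["is_control"]]
    sites = sites or sorted(nc["site"].unique())
    times = times or [t for t in ("-1W", "1M", "3M", "7M") if t in set(nc["time"])]
    rows = []
    for site in sites:
        labels_by_time: dict[str, pd.Series] = {}
        for time in times:
            comms = build_communities(table, meta, time, [site])
            profiles = {
                animal: rel for (animal, _), (asvs, rel) in comms.items() if asvs
            }
            if len(profiles) < 2:
                continue
            prof = pd.DataFrame(profiles).T.fillna(0.0)
            # Bray-Curtis on relative abundances (equal "depth" of 1 per animal)
            x = prof.to_numpy()
            from scipy.spatial.distance import pdist, squareform

            num = squareform(pdist(x, metric="cityblock"))
            den = x.sum(axis=1)[:, None] + x.sum(axis=1)[None, :]
            dmat = DistanceMatrix(list(prof.index), num / den)
            if len(prof) >= k:
                labels_by_time[time] = ward_clusters(dmat, k)
        for t1, t2 in zip(times[:-1], times[1:]):
            if t1 not in labels_by_time or t2 not in labels_by_time:
                continue
            common = sorted(set(labels_by_time[t1].index) & set(labels_by_time[t2].index))
            if len(common) < k:
                warnings.warn(
                    f"site {site}: fewer than k={k} animals shared between "
                    f"{t1} and {t2}; skipped"
                )
                continue
            ari = adjusted_rand_index(
                labels_by_time[t1].loc[common], labels_by_time[t2].loc[common]
            )
            rows.append(
                {"site": site, "time1": t1, "time2": t2, "n_animals": len(common), "ari": ari}
            )
    return pd.DataFrame(rows, columns=["site", "time1", "time2", "n_animals", "ari"])
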