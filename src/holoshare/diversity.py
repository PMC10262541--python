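"""Alpha diversity, beta-diversity dissimilarities and principal coordinates.

Four dissimilarities are provided, matching the repertoire of the analysis:
binary Jaccard, Bray-Curtis, unweighted UniFrac and (normalized by default)
weighted UniFrac.  All are computed here from first principles rather than
delegated, since the exact variants matter:

* Jaccard is presence/absence: ``1 - |A∩B| / |A∪B]``.  A quantitative
  variant ``2B/(1+B)`` of Bray-Curtis B is available for comparison.
* Bray-Curtis is ``Σ|x_i - y_i| / Σ(x_i + y_i)`` on counts, which equals
  the relative-abundance form when sample depths are equal (i.e. after
  rarefaction, where the analysis applies it).
* UniFrac propagates per-sample presence (unweighted) or relative-abundance
  mass (weighted) up the tree once, then combines branch contributions
  pairwise.  On a star tree with unit branch lengths, unweighted UniFrac
  reduces exactly to Jaccard and weighted UniFrac to Bray-Curtis.

Principal-coordinates analysis (classical MDS) double-centers the squared
distances and eigendecomposes; negative eigenvalues are reported but their
axes excluded, and no Cailliez/Lingoes correction is applied by default so
the ordination stays faithful to the raw dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .io_model import AsvCountTable, DistanceMatrix, PhylogeneticTree

__all__ = [
    "observed_richness",
    "shannon",
    "alpha_diversity_table",
    "jaccard",
    "bray_curtis",
    "unifrac_unweighted",
    "unifrac_weighted",
    "pcoa",
    "OrdinationResult",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def observed_richness(counts) -> int:
    """Number of ASVs with a positive count in one sample."""
    counts = np.asarray(counts)
    if counts.size and counts.min() < 0:
        raise ValueError("counts must be non-negative")
    return int((counts > 0).sum())


def shannon(counts) -> float:
    """Shannon entropy H = -Σ p_i ln p_i (natural log), over positive counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for a zero-total sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity_table(table: AsvCountTable):
    """Per-sample observed richness and Shannon index as a DataFrame."""
    import pandas as pd

    rows = {
        s: {
            "observed_richness": observed_richness(table.counts[i]),
            "shannon": shannon(table.counts[i]),
        }
        for i, s in enumerate(table.sample_ids)
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


# ---------------------------------------------------------------------------
# Non-phylogenetic beta diversity
# ---------------------------------------------------------------------------

def jaccard(table: AsvCountTable, quantitative: bool = False) -> DistanceMatrix:
    """Jaccard distance between samples.

    Binary by default (on positive-count ASV sets).  With
    ``quantitative=True`` returns ``2B/(1+B)`` where B is Bray-Curtis.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if quantitative:
        b = bray_curtis(table).data
        return DistanceMatrix(table.sample_ids, 2.0 * b / (1.0 + b))
    pres = (table.counts > 0).astype(float)
    inter = pres @ pres.T
    sizes = pres.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    if np.any(union == 0):
        warnings.warn("all-zero sample pair: Jaccard distance defined as 0")
        d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


def bray_curtis(table: AsvCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity Σ|x-y| / Σ(x+y) on counts."""
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero total reads")
    x = table.counts.astype(float)
    num = squareform(pdist(x, metric="cityblock"))
    den = totals[:, None] + totals[None, :]
    d = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _branch_arrays(table: AsvCountTable, tree: PhylogeneticTree):
    """Per-branch (length, per-sample presence, per-sample mass) arrays.

    One post-order pass computes, for every non-root branch, which samples
    have any descendant ASV present and how much relative abundance each
    sample places under the branch.  Tree tips absent from the table carry
    zero mass; table ASVs absent from the tree are an error.
    """
    missing = sorted(set(table.asv_ids) - set(tree.leaf_names))
    if missing:
        raise ValueError(f"ASVs absent from the tree: {missing}")
    n = table.n_samples
    totals = table.sample_totals().astype(float)
    safe_totals = np.where(totals > 0, totals, 1.0)
    rel = table.counts / safe_totals[:, None]
    pres = table.counts > 0

    lengths: list[float] = []
    pres_rows: list[np.ndarray] = []
    mass_rows: list[np.ndarray] = []
    # postorder: children are processed before parents, accumulate upward
    node_pres: dict[int, np.ndarray] = {}
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in table._aidx:
                j = table.asv_index(node.name)
                p = pres[:, j].copy()
                m = rel[:, j].copy()
            else:
                p = np.zeros(n, dtype=bool)
                m = np.zeros(n, dtype=float)
        else:
            p = np.zeros(n, dtype=bool)
            m = np.zeros(n, dtype=float)
            for child in node.children:
                p |= node_pres.pop(id(child))
                m += node_mass.pop(id(child))
        node_pres[id(node)] = p
        node_mass[id(node)] = m
        if node.parent is not None:  # non-root branches only
            lengths.append(float(node.length))
            pres_rows.append(p)
            mass_rows.append(m)
    L = np.asarray(lengths)
    P = np.vstack(pres_rows).astype(float) if pres_rows else np.zeros((0, n))
    M = np.vstack(mass_rows) if mass_rows else np.zeros((0, n))
    return L, P, M


def unifrac_unweighted(table: AsvCountTable, tree: PhylogeneticTree) -> DistanceMatrix:
    """Unweighted UniFrac: unshared branch length over total covered length."""
    L, P, _ = _branch_arrays(table, tree)
    s = L @ P                      # per-sample covered branch length
    m = (P * L[:, None]).T @ P     # shared covered length per pair
    num = s[:, None] + s[None, :] - 2.0 * m
    den = s[:, None] + s[None, :] - m
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    if np.any(den == 0):
        warnings.warn("sample pair covering no branch length: UniFrac defined as 0")
        d[den == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(table.sample_ids, d)


def unifrac_weighted(
    table: AsvCountTable, tree: PhylogeneticTree, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac on relative-abundance mass under each branch.

    Raw form is ``Σ_b L_b |p_A(b) - p_B(b)|``; the normalized form divides
    by ``Σ_b L_b (p_A(b) + p_B(b))``.
    """
    totals = table.sample_totals()
    if np.any(totals == 0):
        bad = table.sample_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"sample {bad!r} has zero total reads")
    L, _, M = _branch_arrays(table, tree)
    x = (M * L[:, None]).T  # samples x branches, length-weighted mass
    num = squareform(pdist(x, metric="cityblock")) if x.shape[0] > 1 else np.zeros((1, 1))
    if not normalized:
        return DistanceMatrix(table.sample_ids, num)
    t = x.sum(axis=1)
    den = t[:, None] + t[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / den
    d[den == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` has one column per strictly positive eigenvalue;
    ``eigenvalues`` reports the full spectrum (descending, negatives
    included); ``proportion_explained`` is computed over the positive part.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers -D²/2, eigendecomposes symmetrically and scales the
    eigenvectors of positive eigenvalues by sqrt(eigenvalue).  Axes are
    ordered by descending eigenvalue with a deterministic sign convention:
    the largest-magnitude loading of each axis is positive.
    """
    if not isinstance(dm, DistanceMatrix):
        raise ValueError("pcoa expects a DistanceMatrix")
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    g = (g + g.T) / 2.0
    evals, evecs = scipy.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(np.abs(evals).max(), 1.0) * 1e-12 if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, k])))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return OrdinationResult(
        ids=tuple(dm.ids),
        coordinates=coords,
        eigenvalues=evals,
        proportion_explained=prop,
    )
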