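"""Herd-level core microbiota and within-animal cross-site ASV sharing.

The unit of analysis is the *animal-site community*: the set of ASVs an
animal carries at one body site and time point, with their relative
abundances.  Milk is sampled per quarter; quarters are aggregated by
summing counts per animal/time before presence and abundance are computed
(union semantics), so sharing is measured at the animal level.

Core microbiota: an ASV is core for a (site, time) stratum iff the
fraction of animals (with a community in the stratum) in which its
relative abundance exceeds ``abn_core`` (default 0.01%) is at least
``prev_core`` (default 50%).  Both the abundance cutoff and whether the
prevalence comparison is strict are configurable.

Sharing: for every animal and site combination at one time point, the
shared ASVs are the intersection of the animal's communities.  A pairwise
record carries the intersection size, the two directional fractions
(|A∩B|/|A| and |A∩B|/|B| — each site's own community size is the
denominator) and the summed relative abundance of the shared ASVs in each
site.  A multi-way "occurrence" is a tuple (ASV, animal, time, site
combination) with the ASV present in every site of the combination.

Presence means count > 0 in the filtered, UNrarefied table; rarefaction is
reserved for diversity metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import AsvCountTable, SampleMetadata

__all__ = [
    "animal_site_community",
    "build_communities",
    "CoreSet",
    "core_microbiota",
    "SharingReport",
    "pairwise_sharing",
    "multiway_sharing",
    "herd_core_overlap",
]


# ---------------------------------------------------------------------------
# Animal-site communities
# ---------------------------------------------------------------------------

def animal_site_community(
    table: AsvCountTable,
    meta: SampleMetadata,
    animal: str,
    site: str,
    time: str,
) -> tuple[set[str], pd.Series]:
    """ASV set and relative abundances of one animal's community.

    Quarter samples (milk) are summed before computing presence and
    relative abundance.  Raises ``ValueError`` when no sample exists for
    the (animal, site, time) triple.
    """
    sids = [
        s
        for s in meta.samples_where(animal_id=animal, site=site, time=time)
        if s in set(table.sample_ids)
    ]
    if not sids:
        raise ValueError(f"no sample for ({animal}, {site}, {time})")
    counts = table.counts[[table.sample_index(s) for s in sids]].sum(axis=0)
    total = counts.sum()
    present = np.flatnonzero(counts > 0)
    asvs = {table.asv_ids[j] for j in present}
    rel = pd.Series(
        counts[present] / total if total > 0 else np.zeros(len(present)),
        index=[table.asv_ids[j] for j in present],
        dtype=float,
    ).sort_index()
    return asvs, rel


def build_communities(
    table: AsvCountTable,
    meta: SampleMetadata,
    time: str,
    sites: list[str] | None = None,
) -> dict[tuple[str, str], tuple[set[str], pd.Series]]:
    """All animal-site communities at one time point; missing ones skipped."""
    df = meta.df
    nc = df[~df["is_control"] & (df["time"] == time)]
    sites = sites or sorted(nc["site"].unique())
    table_samples = set(table.sample_ids)
    out: dict[tuple[str, str], tuple[set[str], pd.Series]] = {}
    for (animal, site), grp in nc.groupby(["animal_id", "site"], sort=True):
        if site not in sites:
            continue
        if not any(s in table_samples for s in grp.index):
            continue  # all samples of the triple were filtered out
        out[(str(animal), str(site))] = animal_site_community(
            table, meta, str(animal), str(site), time
        )
    return out


# ---------------------------------------------------------------------------
# Core microbiota
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreSet:
    """Core ASVs of one (site, time) stratum with their evidence."""

    site: str
    time: str
    core_asvs: frozenset[str]
    evidence: pd.DataFrame          # per core ASV: prevalence, mean rel. abundance
    n_total_asvs: int               # ASVs present in >= 1 animal community
    per_animal_core_fraction: pd.Series

    @property
    def n_core(self) -> int:
        return len(self.core_asvs)

    @property
    def core_fraction(self) -> float:
        return self.n_core / self.n_total_asvs if self.n_total_asvs else 0.0


def core_microbiota(
    table: AsvCountTable,
    meta: SampleMetadata,
    site: str,
    time: str,
    abn_core: float = 1e-4,
    prev_core: float = 0.5,
    strict_prevalence: bool = False,
) -> CoreSet:
    """Core ASVs of a (site, time) stratum.

    An ASV is core iff the fraction of animals whose community holds it at
    relative abundance strictly above ``abn_core`` is >= ``prev_core``
    (strictly > with ``strict_prevalence``).
    """
    comms = {
        a: c for (a, s), c in build_communities(table, meta, time, [site]).items()
    }
    if len(comms) < 2:
        raise ValueError(f"stratum ({site}, {time}) has fewer than 2 animal communities")
    n_animals = len(comms)
    hits: dict[str, int] = {}
    abund: dict[str, list[float]] = {}
    union: set[str] = set()
    for _, (asvs, rel) in sorted(comms.items()):
        union |= asvs
        for asv, r in rel.items():
            abund.setdefault(asv, []).append(float(r))
            if r > abn_core:
                hits[asv] = hits.get(asv, 0) + 1
    core = set()
    for asv, h in hits.items():
        prev = h / n_animals
        if (prev > prev_core) if strict_prevalence else (prev >= prev_core):
            core.add(asv)
    evidence = pd.DataFrame(
        {
            "prevalence": {a: hits.get(a, 0) / n_animals for a in sorted(core)},
            "mean_rel_abundance": {
                # mean over all animals in the stratum (absences count as 0)
                a: float(sum(abund.get(a, [])) / n_animals)
                for a in sorted(core)
            },
        }
    ).rename_axis("asv_id")
    per_animal = pd.Series(
        {
            a: (len(asvs & core) / len(asvs) if asvs else 0.0)
            for a, (asvs, _) in sorted(comms.items())
        },
        name="core_fraction",
        dtype=float,
    )
    return CoreSet(
        site=site,
        time=time,
        core_asvs=frozenset(core),
        evidence=evidence,
        n_total_asvs=len(union),
        per_animal_core_fraction=per_animal,
    )


# ---------------------------------------------------------------------------
# Sharing
# ---------------------------------------------------------------------------

@dataclass
class SharingReport:
    """Within-animal cross-site sharing records at one time point."""

    time: str
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    multiway: pd.DataFrame = field(default_factory=pd.DataFrame)
    tallies: dict[int, int] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def pair_summary(self) -> pd.DataFrame:
        """Per site-pair mean/median of the sharing quantities."""
        if self.pairwise.empty:
            return pd.DataFrame()
        num = self.pairwise.drop(columns=["animal"])
        return num.groupby(["site1", "site2"]).agg(["mean", "median"])


def pairwise_sharing(
    table: AsvCountTable,
    meta: SampleMetadata,
    time: str,
    sites: list[str] | None = None,
) -> SharingReport:
    """Shared-ASV statistics for every animal and unordered site pair."""
    comms = build_communities(table, meta, time, sites)
    animals = sorted({a for a, _ in comms})
    site_list = sites or sorted({s for _, s in comms})
    rows = []
    skipped = []
    tally2 = 0
    for animal in animals:
        for s1, s2 in itertools.combinations(site_list, 2):
            c1 = comms.get((animal, s1))
            c2 = comms.get((animal, s2))
            if c1 is None or c2 is None:
                skipped.append((animal, f"{s1}|{s2}"))
                continue
            (a1, r1), (a2, r2) = c1, c2
            shared = a1 & a2
            tally2 += len(shared)
            rows.append(
                {
                    "animal": animal,
                    "site1": s1,
                    "site2": s2,
                    "n_shared": len(shared),
                    "fraction_in_site1": len(shared) / len(a1) if a1 else 0.0,
                    "fraction_in_site2": len(shared) / len(a2) if a2 else 0.0,
                    "relabund_in_site1": float(r1.reindex(sorted(shared)).fillna(0).sum()),
                    "relabund_in_site2": float(r2.reindex(sorted(shared)).fillna(0).sum()),
                }
            )
    report = SharingReport(
        time=time,
        pairwise=pd.DataFrame(
            rows,
            columns=[
                "animal",
                "site1",
                "site2",
                "n_shared",
                "fraction_in_site1",
                "fraction_in_site2",
                "relabund_in_site1",
                "relabund_in_site2",
            ],
        ),
        tallies={2: tally2},
        skipped=skipped,
    )
    return report


def multiway_sharing(
    table: AsvCountTable,
    meta: SampleMetadata,
    time: str,
    sites: list[str] | None = None,
) -> SharingReport:
    """Three- and four-way sharing occurrences within animals.

    An occurrence is an (ASV, animal, time, site-combination) tuple with
    the ASV present in every site of the combination; tallies count
    occurrences per combination size.  The report also carries, per ASV,
    the number of animals in which it is shared by >= 3 sites.
    """
    comms = build_communities(table, meta, time, sites)
    animals = sorted({a for a, _ in comms})
    site_list = sites or sorted({s for _, s in comms})
    rows = []
    tallies = {2: 0, 3: 0, 4: 0}
    for animal in animals:
        have = [s for s in site_list if (animal, s) in comms]
        for size in (2, 3, 4):
            for combo in itertools.combinations(have, size):
                shared = set.intersection(*(comms[(animal, s)][0] for s in combo))
                tallies[size] += len(shared)
                if size >= 3:
                    for asv in sorted(shared):
                        rows.append(
                            {
                                "animal": animal,
                                "time": time,
                                "n_sites": size,
                                "sites": "|".join(combo),
                                "asv": asv,
                            }
                        )
    multiway = pd.DataFrame(rows, columns=["animal", "time", "n_sites", "sites", "asv"])
    return SharingReport(time=time, multiway=multiway, tallies=tallies)


def multiway_asv_animal_counts(report: SharingReport) -> pd.Series:
    """Per ASV, the number of animals in which it is shared by >= 3 sites."""
    if report.multiway.empty:
        return pd.Series(dtype=int)
    return (
        report.multiway.groupby("asv")["animal"].nunique().sort_values(ascending=False)
    )


# ---------------------------------------------------------------------------
# Core overlap across sites and times
# ---------------------------------------------------------------------------

def herd_core_overlap(cores: list[CoreSet]) -> dict:
    """Cross-site core overlap and within-site temporal persistence.

    Returns a dict with a Venn-style ``membership`` table (core ASV x
    site), ``n_shared_by_k`` counts of core ASVs found in exactly k sites
    at a fixed time, and ``persistence`` records: per site, the fraction of
    core ASVs at one time that are still core at the next provided time.
    """
    if len(cores) < 2:
        raise ValueError("need at least two CoreSets")
    by_time: dict[str, list[CoreSet]] = {}
    for c in cores:
        by_time.setdefault(c.time, []).append(c)
    membership_frames = {}
    shared_by_k = {}
    for time, group in sorted(by_time.items()):
        union = sorted(set().union(*(set(c.core_asvs) for c in group)))
        mem = pd.DataFrame(
            {c.site: [a in c.core_asvs for a in union] for c in group},
            index=pd.Index(union, name="asv_id"),
        )
        membership_frames[time] = mem
        counts = mem.sum(axis=1).value_counts().to_dict() if union else {}
        shared_by_k[time] = {int(k): int(v) for k, v in sorted(counts.items())}
    by_site: dict[str, list[CoreSet]] = {}
    for c in cores:
        by_site.setdefault(c.site, []).append(c)
    persistence_rows = []
    time_order = {t: i for i, t in enumerate(("-1W", "1M", "3M", "7M"))}
    for site, group in sorted(by_site.items()):
        group = sorted(group, key=lambda c: time_order.get(c.time, 99))
        for c1, c2 in zip(group[:-1], group[1:]):
            if not c1.core_asvs:
                continue
            kept = len(c1.core_asvs & c2.core_asvs)
            persistence_rows.append(
                {
                    "site": site,
                    "time1": c1.time,
                    "time2": c2.time,
                    "n_core_time1": len(c1.core_asvs),
                    "n_persisting": kept,
                    "persistence": kept / len(c1.core_asvs),
                }
            )
    return {
        "membership": membership_frames,
        "n_shared_by_k": shared_by_k,
        "persistence": pd.DataFrame(
            persistence_rows,
            columns=["site", "time1", "time2", "n_core_time1", "n_persisting", "persistence"],
        ),
    }
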