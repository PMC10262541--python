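"""Synthetic herd generator with planted ground truth.

Generates ASV count tables, metadata and trees with the statistical
structure the downstream analysis assumes: site-specific communities drawn
from site templates, a planted herd core per site, animal-private ASVs,
within-animal cross-site transfer at a tunable rate, single-step temporal
turnover, kit contaminants ("kitome") carried into real samples in inverse
proportion to site biomass, and multinomial sequencing noise.

The defaults emulate the design of the motivating field study: 45 lactating
cows sampled at four body sites (oral, nasal, vaginal, milk) at four time
points, with negative extraction controls sequenced alongside.  Milk has
the lowest bacterial biomass, so it receives the largest contaminant read
fraction; negative controls contain contaminant reads only.

Every random draw flows from one seeded generator in a documented order, so
identical (config, seed) pairs yield bit-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    GROUPS,
    SITES,
    TIMEPOINTS,
    AsvCountTable,
    PhylogeneticTree,
    SampleMetadata,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TransferRecord",
    "generate_herd",
    "truth_sharing_fraction",
]


def _default_biomass() -> dict[str, float]:
    # Relative bacterial load per site.  Milk lowest, so contaminant
    # carry-over (kit_load * min_biomass / biomass) is ~15% in milk, ~5% in
    # vaginal and ~1.5% in oral/nasal samples at the default kit_load.
    return {"oral": 1.0, "nasal": 1.0, "vaginal": 0.3, "milk": 0.1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generative herd model.

    Attributes
    ----------
    n_animals : number of animals in the herd.
    sites, timepoints : sampled body sites and occasions.
    pool_size : size P of the global template ASV pool.
    site_pool_size : number S of template ASVs per site (S <= P).
    f_core : fraction of each site template planted as herd core; the
        ``ceil(f_core * S)`` most abundant template ASVs are core and occur
        in every animal.
    occupancy : probability a non-core template ASV occurs in a given animal.
    f_share : per-ASV probability of within-animal transfer, per ordered
        site pair.
    transfer_scale : multiplicative abundance factor applied on transfer.
    n_private : animal-private ASVs added per animal-site community.
    time_turnover : fraction of each community replaced (lowest abundance
        first) between consecutive time points.
    lognormal_params : (mu, sigma) of template/private abundances.
    jitter_sigma : sigma of the animal-specific log-normal abundance jitter.
    n_controls : number of negative control samples.
    n_kitome : number K of planted kit-contaminant ASVs.
    kit_load : expected contaminant read fraction in the lowest-biomass site.
    biomass : per-site relative biomass; carry-over scales inversely with it.
    depth_lognormal : (mu, sigma) of per-sample sequencing depth (floor 200).
    milk_quarters : milk samples per animal/time (quarters); 1 by default.
    dirichlet_precision : optional Dirichlet overdispersion of sample
        compositions before multinomial sampling (None = plain multinomial).
    disjoint_templates : carve the site templates out of disjoint blocks of
        the pool (requires P >= n_sites * S); used for controlled
        no-baseline-overlap experiments.
    seed : PRNG seed.
    """

    n_animals: int = 45
    sites: tuple[str, ...] = SITES
    timepoints: tuple[str, ...] = TIMEPOINTS
    pool_size: int = 400
    site_pool_size: int = 120
    f_core: float = 0.1
    occupancy: float = 0.25
    f_share: float = 0.1
    transfer_scale: float = 0.25
    n_private: int = 10
    time_turnover: float = 0.1
    lognormal_params: tuple[float, float] = (0.0, 1.25)
    jitter_sigma: float = 0.5
    n_controls: int = 8
    n_kitome: int = 25
    kit_load: float = 0.15
    biomass: Mapping[str, float] = field(default_factory=_default_biomass)
    depth_lognormal: tuple[float, float] = (9.2, 0.8)
    milk_quarters: int = 1
    dirichlet_precision: float | None = None
    disjoint_templates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_core", "occupancy", "f_share", "time_turnover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not 1 <= self.site_pool_size <= self.pool_size:
            raise ValueError("need pool_size >= site_pool_size >= 1")
        for name in ("n_animals", "n_private", "n_controls", "n_kitome", "milk_quarters"):
            v = getattr(self, name)
            if v < 0 or (name in ("n_animals", "milk_quarters") and v < 1):
                raise ValueError(f"{name}={v} is out of range")
        if self.kit_load < 0:
            raise ValueError("kit_load must be >= 0")
        if self.disjoint_templates and self.pool_size < len(self.sites) * self.site_pool_size:
            raise ValueError("disjoint templates need pool_size >= n_sites * site_pool_size")
        for s in self.sites:
            if s not in self.biomass:
                raise ValueError(f"biomass missing for site {s!r}")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class TransferRecord:
    animal: str
    time: str
    source_site: str
    target_site: str
    asv: str


@dataclass
class GroundTruth:
    """Planted structure of one generated herd.

    ``communities`` holds the realized pre-noise relative abundances per
    (animal, site, time); sharing oracles are computed on these, not on the
    noisy counts.
    """

    kitome_asvs: frozenset[str]
    core_asvs: dict[str, frozenset[str]]
    transfers: list[TransferRecord]
    communities: dict[tuple[str, str, str], dict[str, float]]
    config: SyntheticConfig

    def to_json(self, path) -> None:
        obj = {
            "kitome_asvs": sorted(self.kitome_asvs),
            "core_asvs": {s: sorted(v) for s, v in self.core_asvs.items()},
            "transfers": [
                [t.animal, t.time, t.source_site, t.target_site, t.asv]
                for t in self.transfers
            ],
            "communities": {
                "|".join(k): {a: v for a, v in sorted(comm.items())}
                for k, comm in self.communities.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_json(cls, path, config: SyntheticConfig | None = None) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            obj = json.load(fh)
        return cls(
            kitome_asvs=frozenset(obj["kitome_asvs"]),
            core_asvs={s: frozenset(v) for s, v in obj["core_asvs"].items()},
            transfers=[TransferRecord(*t) for t in obj["transfers"]],
            communities={
                tuple(k.split("|")): dict(v) for k, v in obj["communities"].items()
            },
            config=config or SyntheticConfig(),
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_herd(
    config: SyntheticConfig,
) -> tuple[AsvCountTable, SampleMetadata, PhylogeneticTree, GroundTruth]:
    """Draw one synthetic herd.

    Steps, in fixed PRNG order: site templates and planted cores; animal
    scores and group assignment; per-animal base communities; within-animal
    transfers; temporal turnover; contamination; multinomial read sampling;
    random bifurcating tree over all ASVs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = cfg.lognormal_params
    sites = list(cfg.sites)
    times = list(cfg.timepoints)
    animals = [f"A{i + 1:02d}" for i in range(cfg.n_animals)]

    # -- step 1: pool, site templates, planted cores ----------------------
    pool = [f"ASV{i + 1:04d}" for i in range(cfg.pool_size)]
    if cfg.disjoint_templates:
        perm = rng.permutation(cfg.pool_size)
        chosen = {
            site: perm[i * cfg.site_pool_size : (i + 1) * cfg.site_pool_size]
            for i, site in enumerate(sites)
        }
    else:
        chosen = {
            site: rng.choice(cfg.pool_size, size=cfg.site_pool_size, replace=False)
            for site in sites
        }
    templates: dict[str, list[tuple[str, float]]] = {}
    core_asvs: dict[str, frozenset[str]] = {}
    n_core = math.ceil(cfg.f_core * cfg.site_pool_size)
    for site in sites:
        abund = rng.lognormal(mu, sigma, size=cfg.site_pool_size)
        tmpl = [(pool[i], float(a)) for i, a in zip(chosen[site], abund)]
        ranked = sorted(tmpl, key=lambda t: (-t[1], t[0]))
        core_asvs[site] = frozenset(a for a, _ in ranked[:n_core])
        templates[site] = tmpl

    # -- animal-level covariates ------------------------------------------
    sm_scores = rng.normal(0.0, 1.0, size=cfg.n_animals)
    bc_scores = rng.normal(0.0, 1.0, size=cfg.n_animals)
    group_of = _assign_groups(cfg.n_animals)

    # -- step 2: base communities at the first time point ------------------
    t0 = times[0]
    communities: dict[tuple[str, str, str], dict[str, float]] = {}
    private_counter = 0
    for animal in animals:
        for site in sites:
            comm: dict[str, float] = {}
            tmpl = templates[site]
            core = core_asvs[site]
            keep = rng.random(len(tmpl)) < cfg.occupancy
            for (asv, ab), k in zip(tmpl, keep):
                if asv in core or k:
                    comm[asv] = ab
            for _ in range(cfg.n_private):
                private_counter += 1
                comm[f"PRIV{private_counter:05d}_{animal}_{site}"] = float(
                    rng.lognormal(mu, sigma)
                )
            jit = rng.lognormal(0.0, cfg.jitter_sigma, size=len(comm))
            for asv, j in zip(list(comm), jit):
                comm[asv] *= float(j)
            communities[(animal, site, t0)] = comm

    # -- step 3: within-animal cross-site transfers ------------------------
    transfers: list[TransferRecord] = []
    base_snapshot = {
        (a, s): dict(communities[(a, s, t0)]) for a in animals for s in sites
    }
    for animal in animals:
        for src, tgt in itertools.permutations(sites, 2):
            source = base_snapshot[(animal, src)]
            asvs = list(source)
            mask = rng.random(len(asvs)) < cfg.f_share
            target = communities[(animal, tgt, t0)]
            for asv, m in zip(asvs, mask):
                if m:
                    target[asv] = target.get(asv, 0.0) + source[asv] * cfg.transfer_scale
                    transfers.append(TransferRecord(animal, t0, src, tgt, asv))

    # -- step 4: temporal turnover -----------------------------------------
    for ti in range(1, len(times)):
        time = times[ti]
        for animal in animals:
            for site in sites:
                prev = communities[(animal, site, times[ti - 1])]
                comm = dict(prev)
                n_replace = int(math.floor(cfg.time_turnover * len(comm)))
                if n_replace:
                    victims = sorted(comm.items(), key=lambda t: (t[1], t[0]))[:n_replace]
                    for asv, _ in victims:
                        del comm[asv]
                    for _ in range(n_replace):
                        private_counter += 1
                        comm[f"PRIV{private_counter:05d}_{animal}_{site}"] = float(
                            rng.lognormal(mu, sigma)
                        )
                jit = rng.lognormal(0.0, cfg.jitter_sigma, size=len(comm))
                for asv, j in zip(list(comm), jit):
                    comm[asv] *= float(j)
                communities[(animal, site, time)] = comm

    # -- step 5: contamination ---------------------------------------------
    if cfg.n_controls > 0 and (cfg.kit_load <= 0.0 or cfg.n_kitome == 0):
        raise ValueError(
            "no contaminant mass: negative controls would be empty; "
            "set n_controls=0 or use kit_load>0 with n_kitome>0"
        )
    kit_ids = [f"KIT{i + 1:03d}" for i in range(cfg.n_kitome)]
    kit_w = rng.lognormal(mu, sigma, size=cfg.n_kitome)
    kit_profile = kit_w / kit_w.sum() if cfg.n_kitome else kit_w
    min_biomass = min(cfg.biomass[s] for s in sites)

    # -- step 6: read sampling ---------------------------------------------
    all_asvs = sorted(
        set().union(*(set(c) for c in communities.values())) | set(kit_ids)
    )
    aidx = {a: j for j, a in enumerate(all_asvs)}
    mud, sigd = cfg.depth_lognormal

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_rows: list[np.ndarray] = []

    def _draw_counts(prob_asvs: list[str], probs: np.ndarray) -> np.ndarray:
        depth = max(200, int(round(rng.lognormal(mud, sigd))))
        p = probs / probs.sum()
        if cfg.dirichlet_precision is not None:
            p = rng.dirichlet(cfg.dirichlet_precision * p)
        counts = rng.multinomial(depth, p)
        row = np.zeros(len(all_asvs), dtype=np.int64)
        for asv, c in zip(prob_asvs, counts):
            row[aidx[asv]] = c
        return row

    for ai, animal in enumerate(animals):
        for site in sites:
            carry = cfg.kit_load * min_biomass / cfg.biomass[site]
            for time in times:
                comm = communities[(animal, site, time)]
                casvs = sorted(comm)
                rel = np.array([comm[a] for a in casvs], dtype=float)
                rel = rel / rel.sum()
                if cfg.n_kitome and carry > 0:
                    prob_asvs = casvs + kit_ids
                    probs = np.concatenate([(1.0 - carry) * rel, carry * kit_profile])
                else:
                    prob_asvs, probs = casvs, rel
                n_reps = cfg.milk_quarters if site == "milk" else 1
                for q in range(n_reps):
                    sid = f"{animal}_{site}_{time}"
                    quarter = pd.NA
                    if site == "milk" and cfg.milk_quarters > 1:
                        quarter = f"Q{q + 1}"
                        sid = f"{sid}_{quarter}"
                    sample_ids.append(sid)
                    count_rows.append(_draw_counts(prob_asvs, probs))
                    meta_rows.append(
                        {
                            "animal_id": animal,
                            "site": site,
                            "time": time,
                            "group": group_of[ai],
                            "sm_score": float(sm_scores[ai]),
                            "bc_score": float(bc_scores[ai]),
                            "quarter": quarter,
                            "is_control": False,
                        }
                    )

    for c in range(cfg.n_controls):
        sid = f"CTRL{c + 1:02d}"
        sample_ids.append(sid)
        count_rows.append(_draw_counts(kit_ids, kit_profile.copy()))
        meta_rows.append(
            {
                "animal_id": pd.NA,
                "site": "control",
                "time": pd.NA,
                "group": pd.NA,
                "sm_score": np.nan,
                "bc_score": np.nan,
                "quarter": pd.NA,
                "is_control": True,
            }
        )

    table = AsvCountTable(sample_ids, all_asvs, np.vstack(count_rows))
    meta = SampleMetadata(pd.DataFrame(meta_rows, index=sample_ids))

    # -- step 7: random bifurcating tree over all ASVs ---------------------
    tree = _random_tree(all_asvs, rng)

    truth = GroundTruth(
        kitome_asvs=frozenset(kit_ids),
        core_asvs=core_asvs,
        transfers=transfers,
        communities={
            k: {a: v / tot for a, v in comm.items()}
            for k, comm in communities.items()
            if (tot := sum(comm.values())) > 0
        },
        config=cfg,
    )
    return table, meta, tree, truth


def _assign_groups(n_animals: int) -> list[str]:
    # Calving-batch proportions of the emulated design (18/15/12 of 45).
    n1 = int(round(n_animals * 18 / 45))
    n2 = int(round(n_animals * 15 / 45))
    sizes = [n1, n2, n_animals - n1 - n2]
    out: list[str] = []
    for g, size in zip(GROUPS, sizes):
        out.extend([g] * size)
    return out


def _random_tree(leaf_names: Sequence[str], rng: np.random.Generator) -> PhylogeneticTree:
    """Random bifurcating tree by uniform pair joining, exponential lengths."""
    frags = [str(n) for n in leaf_names]
    if len(frags) == 1:
        return PhylogeneticTree.from_newick(f"({frags[0]}:1.0);")
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        la, lb = rng.exponential(0.1, size=2)
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a}:{la:.10g},{b}:{lb:.10g})")
    return PhylogeneticTree.from_newick(frags[0] + ";")


# ---------------------------------------------------------------------------
# Sharing oracle on the ground truth
# ---------------------------------------------------------------------------

def truth_sharing_fraction(
    truth: GroundTruth,
    table: AsvCountTable,
    meta: SampleMetadata,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Exact per-animal/time shared fractions from the pre-noise communities.

    For the site pair ``(s1, s2)`` and each animal/time where both
    communities exist, returns the shared ASV count and the two directional
    fractions |A∩B|/|A| and |A∩B|/|B| computed on the realized (pre-noise)
    community supports.
    """
    s1, s2 = pair
    truth_animals = {k[0] for k in truth.communities}
    meta_animals = set(meta.df.loc[~meta.df["is_control"], "animal_id"].dropna())
    if truth_animals != meta_animals:
        raise ValueError("metadata animals do not match the ground truth herd")
    if not set(meta.sample_ids) <= set(table.sample_ids) and not set(
        table.sample_ids
    ) <= set(meta.sample_ids):
        raise ValueError("count table and metadata reference different samples")
    rows = []
    for animal in sorted(truth_animals):
        for time in truth.config.timepoints:
            ka, kb = (animal, s1, time), (animal, s2, time)
            if ka not in truth.communities or kb not in truth.communities:
                continue
            a = set(truth.communities[ka])
            b = set(truth.communities[kb])
            shared = a & b
            rows.append(
                {
                    "animal": animal,
                    "time": time,
                    "n_shared": len(shared),
                    f"fraction_in_{s1}": len(shared) / len(a) if a else 0.0,
                    f"fraction_in_{s2}": len(shared) / len(b) if b else 0.0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["animal", "time", "n_shared", f"fraction_in_{s1}", f"fraction_in_{s2}"],
    )
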