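"""ASV/sample filtering, kitome decontamination and rarefaction.

The filtering chain applies, in this fixed order:

1. low-abundance / low-prevalence ASV removal,
2. kitome (negative-control contaminant) detection and removal,
3. discarding samples left with too few reads,

and rarefaction is applied afterwards, only for diversity computations.

An ASV is removed by step 1 iff its pooled relative abundance is below
``abn_stratum`` in every (site x time) stratum OR below ``abn_overall``
overall, OR its prevalence is below ``prev_site`` within every site OR it
occurs in fewer than ``prev_min_samples`` samples overall.  Inequalities
are strict.  "Pooled" relative abundance of an ASV in a stratum is the
stratum-summed reads of the ASV divided by the stratum's total reads; a
``mean_per_sample`` switch evaluates the mean of per-sample fractions
instead, for sensitivity analysis.

An ASV is flagged as kitome iff its prevalence among negative-control
samples exceeds ``kit_prev`` (strictly) AND its pooled relative abundance
in the controls exceeds its pooled relative abundance over all non-control
samples combined.

Control samples are excluded from the abundance/prevalence denominators of
step 1; they enter only the kitome rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AsvCountTable, RemovalLog, SampleMetadata

__all__ = [
    "FilterThresholds",
    "filter_low_abundance_prevalence",
    "detect_kitome",
    "remove_asvs",
    "filter_samples_min_reads",
    "rarefy",
    "reads_removed_fraction",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the filtering chain (strict inequalities throughout)."""

    abn_stratum: float = 1e-5   # pooled rel. abundance per (site x time) stratum
    abn_overall: float = 5e-5   # pooled rel. abundance over all samples
    prev_site: float = 0.05     # prevalence within a site
    prev_min_samples: int = 3   # minimum number of occupied samples overall
    min_reads: int = 1000       # minimum per-sample read total
    kit_prev: float = 0.5       # control prevalence above which kitome rule applies

    def __post_init__(self) -> None:
        for name in ("abn_stratum", "abn_overall", "prev_site", "kit_prev"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if self.prev_min_samples < 1 or self.min_reads < 1:
            raise ValueError("prev_min_samples and min_reads must be positive")


def _pooled_rel(counts: np.ndarray, mean_per_sample: bool) -> np.ndarray:
    """Relative abundance of each ASV over a block of samples.

    Pooled mode sums reads before normalising; mean mode averages per-sample
    fractions (zero-total samples contribute nothing).
    """
    if counts.size == 0:
        return np.zeros(counts.shape[1] if counts.ndim == 2 else 0)
    if mean_per_sample:
        totals = counts.sum(axis=1, keepdims=True).astype(float)
        ok = totals[:, 0] > 0
        if not ok.any():
            return np.zeros(counts.shape[1])
        return (counts[ok] / totals[ok]).mean(axis=0)
    total = counts.sum()
    if total == 0:
        return np.zeros(counts.shape[1])
    return counts.sum(axis=0) / total


def filter_low_abundance_prevalence(
    table: AsvCountTable,
    meta: SampleMetadata,
    th: FilterThresholds = FilterThresholds(),
    mean_per_sample: bool = False,
) -> tuple[AsvCountTable, RemovalLog]:
    """Remove rare ASVs by the four abundance/prevalence clauses.

    Returns the filtered table and a log recording, for every removed ASV,
    which clauses fired together with the measured values.
    """
    df = meta.df.loc[[s for s in table.sample_ids if s in meta.df.index]]
    nc_ids = [s for s in table.sample_ids if s in df.index and not df.loc[s, "is_control"]]
    nc_pos = np.array([table.sample_index(s) for s in nc_ids], dtype=int)
    counts_nc = table.counts[nc_pos] if nc_pos.size else np.zeros((0, table.n_asvs), dtype=np.int64)
    sites = df.loc[nc_ids, "site"]
    times = df.loc[nc_ids, "time"]

    # clause A1: below abn_stratum in every non-empty (site x time) stratum
    strata_rels = []
    for (site, time), idx in pd.Series(range(len(nc_ids)), index=nc_ids).groupby(
        [sites.values, times.values]
    ):
        block = counts_nc[idx.to_numpy()]
        if block.sum() == 0:
            warnings.warn(f"stratum ({site}, {time}) has no reads; skipped")
            continue
        strata_rels.append(_pooled_rel(block, mean_per_sample))
    if strata_rels:
        max_stratum_rel = np.max(np.vstack(strata_rels), axis=0)
        below_all_strata = max_stratum_rel < th.abn_stratum
    else:
        max_stratum_rel = np.zeros(table.n_asvs)
        below_all_strata = np.zeros(table.n_asvs, dtype=bool)

    # clause A2: below abn_overall over all non-control samples pooled
    overall_rel = _pooled_rel(counts_nc, mean_per_sample)
    below_overall = overall_rel < th.abn_overall

    # clause B1: prevalence below prev_site within every site
    site_prevs = []
    for site, idx in pd.Series(range(len(nc_ids)), index=nc_ids).groupby(sites.values):
        block = counts_nc[idx.to_numpy()]
        site_prevs.append((block > 0).mean(axis=0))
    if site_prevs:
        max_site_prev = np.max(np.vstack(site_prevs), axis=0)
        rare_all_sites = max_site_prev < th.prev_site
    else:
        max_site_prev = np.zeros(table.n_asvs)
        rare_all_sites = np.zeros(table.n_asvs, dtype=bool)

    # clause B2: present in fewer than prev_min_samples samples overall
    n_present = (counts_nc > 0).sum(axis=0)
    too_few = n_present < th.prev_min_samples

    removed = (below_all_strata | below_overall) | (rare_all_sites | too_few)

    log = RemovalLog()
    for j in np.flatnonzero(removed):
        clauses = []
        if below_all_strata[j]:
            clauses.append("low_abundance_stratum")
        if below_overall[j]:
            clauses.append("low_abundance_overall")
        if rare_all_sites[j]:
            clauses.append("low_prevalence_site")
        if too_few[j]:
            clauses.append("low_prevalence_overall")
        log.add(
            table.asv_ids[j],
            "asv",
            clauses[0],
            {
                "clauses": clauses,
                "max_stratum_rel_abundance": float(max_stratum_rel[j]),
                "overall_rel_abundance": float(overall_rel[j]),
                "max_site_prevalence": float(max_site_prev[j]),
                "n_samples_present": int(n_present[j]),
            },
        )
    out = table.drop_asvs([table.asv_ids[j] for j in np.flatnonzero(removed)])
    return out, log


def detect_kitome(
    table: AsvCountTable,
    meta: SampleMetadata,
    th: FilterThresholds = FilterThresholds(),
    mean_per_sample: bool = False,
) -> tuple[set[str], pd.DataFrame]:
    """Flag kit-contaminant ASVs from negative controls.

    Returns the flagged ASV set and a per-ASV evidence table (control
    prevalence, control pooled relative abundance, combined body-site
    pooled relative abundance, flag).
    """
    ctrl_ids = [s for s in table.sample_ids if s in meta.df.index and meta.df.loc[s, "is_control"]]
    if not ctrl_ids:
        raise ValueError("kitome detection requires at least one control sample")
    nc_ids = [s for s in table.sample_ids if s in meta.df.index and not meta.df.loc[s, "is_control"]]
    ctrl = table.counts[[table.sample_index(s) for s in ctrl_ids]]
    other = (
        table.counts[[table.sample_index(s) for s in nc_ids]]
        if nc_ids
        else np.zeros((0, table.n_asvs), dtype=np.int64)
    )
    prev_ctrl = (ctrl > 0).mean(axis=0)
    rel_ctrl = _pooled_rel(ctrl, mean_per_sample)
    rel_other = _pooled_rel(other, mean_per_sample)
    flagged = (prev_ctrl > th.kit_prev) & (rel_ctrl > rel_other)
    evidence = pd.DataFrame(
        {
            "control_prevalence": prev_ctrl,
            "control_rel_abundance": rel_ctrl,
            "other_rel_abundance": rel_other,
            "flagged": flagged,
        },
        index=pd.Index(table.asv_ids, name="asv_id"),
    )
    return {table.asv_ids[j] for j in np.flatnonzero(flagged)}, evidence


def remove_asvs(
    table: AsvCountTable,
    asvs: set[str] | list[str],
    log: RemovalLog | None = None,
    rule_id: str = "kitome",
) -> tuple[AsvCountTable, RemovalLog]:
    """Remove the given ASV columns, logging per-ASV reads removed."""
    asvs = sorted(set(asvs))
    unknown = set(asvs) - set(table.asv_ids)
    if unknown:
        raise ValueError(f"unknown ASV IDs: {sorted(unknown)}")
    log = log if log is not None else RemovalLog()
    for a in asvs:
        j = table.asv_index(a)
        log.add(a, "asv", rule_id, {"reads_removed": int(table.counts[:, j].sum())})
    return table.drop_asvs(asvs), log


def reads_removed_fraction(before: AsvCountTable, after: AsvCountTable) -> pd.Series:
    """Per-sample fraction of reads removed between two filtering states."""
    tb = pd.Series(before.sample_totals(), index=before.sample_ids, dtype=float)
    ta = pd.Series(after.sample_totals(), index=after.sample_ids, dtype=float)
    ta = ta.reindex(tb.index, fill_value=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 1.0 - ta / tb
    return frac.fillna(0.0)


def filter_samples_min_reads(
    table: AsvCountTable,
    th: FilterThresholds = FilterThresholds(),
) -> tuple[AsvCountTable, RemovalLog]:
    """Discard samples with strictly fewer than ``min_reads`` total reads."""
    totals = table.sample_totals()
    log = RemovalLog()
    drop = []
    for i in np.flatnonzero(totals < th.min_reads):
        sid = table.sample_ids[i]
        drop.append(sid)
        log.add(sid, "sample", "min_reads", {"total_reads": int(totals[i])})
    out = table.drop_samples(drop)
    if out.n_samples == 0:
        warnings.warn("no samples remain after the min-reads filter")
    return out, log


def rarefy(table: AsvCountTable, depth: int, seed: int) -> AsvCountTable:
    """Subsample each sample's reads to ``depth`` without replacement.

    Samples whose total is below ``depth`` are dropped (with a warning).
    Per-sample draws are multivariate hypergeometric, so the subsample is a
    uniform draw of ``depth`` reads without replacement; deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = [i for i in range(table.n_samples) if totals[i] >= depth]
    dropped = [table.sample_ids[i] for i in range(table.n_samples) if totals[i] < depth]
    if dropped:
        warnings.warn(
            f"{len(dropped)} sample(s) below rarefaction depth {depth} dropped: "
            + ", ".join(dropped[:5])
            + ("..." if len(dropped) > 5 else "")
        )
    rows = np.empty((len(keep), table.n_asvs), dtype=np.int64)
    for r, i in enumerate(keep):
        rows[r] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return AsvCountTable([table.sample_ids[i] for i in keep], table.asv_ids, rows)
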