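"""End-to-end pipeline: simulate/ingest -> filter -> decontaminate ->
rarefy -> diversity -> statistics -> core/sharing.

Stage order is fixed: low-abundance/prevalence filter, kitome removal,
min-reads filter; then the rarefied branch (alpha diversity, beta
distances, ordination, PERMANOVA, dispersion, clustering stability) and the
unrarefied branch (core microbiota, sharing).  Every intermediate artifact
is written to the run directory and hashed into a manifest; per-stage seeds
are derived from the master seed by hashing the stage name, so adding a
stage never perturbs the randomness of earlier ones.

Re-running with the same config and seed is byte-identical, except for the
wall-time entries of the manifest; ``runs_identical`` compares two run
directories accordingly.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core_sharing, diversity, filtering, stats
from .io_model import (
    AsvCountTable,
    DistanceMatrix,
    PhylogeneticTree,
    RemovalLog,
    SampleMetadata,
    read_asv_table,
    read_metadata,
    read_tree,
    write_asv_table,
    write_metadata,
    write_tree,
)
from .synthetic_data import GroundTruth, SyntheticConfig, generate_herd, truth_sharing_fraction

__all__ = [
    "PipelineConfig",
    "RunResult",
    "run_pipeline",
    "validate_against_truth",
    "stage_seed",
    "runs_identical",
]

_BETA_METRICS = ("jaccard", "bray_curtis", "unifrac", "wunifrac")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    outdir: Path
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    table_path: Path | None = None
    metadata_path: Path | None = None
    tree_path: Path | None = None
    thresholds: filtering.FilterThresholds = field(
        default_factory=filtering.FilterThresholds
    )
    rarefy_depth: int | None = None  # None = minimum retained sample total
    beta_metrics: tuple[str, ...] = _BETA_METRICS
    permanova_terms: tuple[str, ...] = (
        "group",
        "site",
        "time",
        "sm_score",
        "bc_score",
        "animal_id",
    )
    n_permutations: int = 999
    cluster_k: int = 5
    core_abundance: float = 1e-4
    core_prevalence: float = 0.5

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.synthetic is None and self.table_path is None:
            raise ValueError("provide either a SyntheticConfig or input paths")
        unknown = set(self.beta_metrics) - set(_BETA_METRICS)
        if unknown:
            raise ValueError(f"unknown beta metrics: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "PipelineConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh) or {}
        syn = obj.pop("synthetic", None)
        if syn is not None:
            syn = SyntheticConfig(**syn)
        th = obj.pop("thresholds", None)
        if th is not None:
            th = filtering.FilterThresholds(**th)
        if outdir is not None:
            obj["outdir"] = outdir
        if seed is not None:
            obj["seed"] = seed
        for key in ("beta_metrics", "permanova_terms"):
            if key in obj:
                obj[key] = tuple(obj[key])
        return cls(
            synthetic=syn,
            thresholds=th or filtering.FilterThresholds(),
            **obj,
        )


@dataclass
class RunResult:
    """In-memory products of one pipeline run."""

    manifest: dict
    table_raw: AsvCountTable
    table_filtered: AsvCountTable
    table_rarefied: AsvCountTable
    meta: SampleMetadata
    tree: PhylogeneticTree
    removal_log: RemovalLog
    kitome: set[str]
    distances: dict[str, DistanceMatrix]
    permanova: dict[str, stats.PermanovaResult]
    dispersion: dict[str, stats.DispersionResult]
    stability: pd.DataFrame
    cores: list[core_sharing.CoreSet]
    sharing: dict[str, core_sharing.SharingReport]
    truth: GroundTruth | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis; returns results and writes all artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def finish_stage(name: str, t0: float, outputs: list[Path], seed: int | None = None):
        manifest["stages"].append(
            {
                "stage": name,
                "seed": seed,
                "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
                "wall_time_s": round(_time.perf_counter() - t0, 4),
            }
        )

    # -- stage 1: ingest / simulate ---------------------------------------
    t0 = _time.perf_counter()
    truth = None
    if config.synthetic is not None:
        syn = config.synthetic.with_seed(stage_seed(config.seed, "simulate"))
        table, meta, tree, truth = generate_herd(syn)
    else:
        table = read_asv_table(config.table_path)
        meta = read_metadata(config.metadata_path)
        tree = read_tree(config.tree_path)
    write_asv_table(table, out / "table_raw.tsv")
    write_metadata(meta, out / "metadata.tsv")
    write_tree(tree, out / "tree.nwk")
    outputs = [out / "table_raw.tsv", out / "metadata.tsv", out / "tree.nwk"]
    if truth is not None:
        truth.to_json(out / "truth.json")
        outputs.append(out / "truth.json")
    finish_stage("ingest", t0, outputs, stage_seed(config.seed, "simulate"))

    # -- stage 2: abundance/prevalence filter ------------------------------
    t0 = _time.perf_counter()
    log = RemovalLog()
    table_f, log1 = filtering.filter_low_abundance_prevalence(
        table, meta, config.thresholds
    )
    log.extend(log1)
    finish_stage("filter_abundance_prevalence", t0, [])

    # -- stage 3: kitome removal -------------------------------------------
    t0 = _time.perf_counter()
    kitome, evidence = filtering.detect_kitome(table_f, meta, config.thresholds)
    evidence.to_csv(out / "kitome_evidence.tsv", sep="\t")
    before_kit = table_f
    table_f, log = filtering.remove_asvs(table_f, kitome, log)
    filtering.reads_removed_fraction(before_kit, table_f).rename(
        "fraction_reads_removed"
    ).to_csv(out / "kitome_reads_removed.tsv", sep="\t", index_label="sample_id")
    finish_stage(
        "kitome_removal",
        t0,
        [out / "kitome_evidence.tsv", out / "kitome_reads_removed.tsv"],
    )

    # -- stage 4: min-reads sample filter ----------------------------------
    t0 = _time.perf_counter()
    table_f, log4 = filtering.filter_samples_min_reads(table_f, config.thresholds)
    log.extend(log4)
    if table_f.n_samples == 0:
        log.write_tsv(out / "removal_log.tsv")
        raise RuntimeError("pipeline halted at stage min_reads: no samples remain")
    write_asv_table(table_f, out / "table_filtered.tsv")
    log.write_tsv(out / "removal_log.tsv")
    finish_stage(
        "min_reads", t0, [out / "table_filtered.tsv", out / "removal_log.tsv"]
    )

    # -- stage 5: rarefaction + alpha diversity ----------------------------
    t0 = _time.perf_counter()
    depth = config.rarefy_depth or int(table_f.sample_totals().min())
    rare_seed = stage_seed(config.seed, "rarefy")
    table_r = filtering.rarefy(table_f, depth, rare_seed)
    write_asv_table(table_r, out / "table_rarefied.tsv")
    alpha = diversity.alpha_diversity_table(table_r)
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    finish_stage(
        "rarefy_alpha",
        t0,
        [out / "table_rarefied.tsv", out / "alpha_diversity.tsv"],
        rare_seed,
    )

    # -- stage 6: beta diversity, ordination, PERMANOVA, dispersion --------
    t0 = _time.perf_counter()
    nc_ids = [s for s in table_r.sample_ids if s in set(meta.non_control_ids)]
    table_beta = table_r.select_samples(nc_ids)
    distances: dict[str, DistanceMatrix] = {}
    perm_results: dict[str, stats.PermanovaResult] = {}
    disp_results: dict[str, stats.DispersionResult] = {}
    beta_files: list[Path] = []
    perm_seed = stage_seed(config.seed, "permanova")
    disp_seed = stage_seed(config.seed, "betadisper")
    for metric in config.beta_metrics:
        if metric == "jaccard":
            dmat = diversity.jaccard(table_beta)
        elif metric == "bray_curtis":
            dmat = diversity.bray_curtis(table_beta)
        elif metric == "unifrac":
            dmat = diversity.unifrac_unweighted(table_beta, tree)
        else:
            dmat = diversity.unifrac_weighted(table_beta, tree)
        distances[metric] = dmat
        dmat.write_tsv(out / f"distance_{metric}.tsv")
        ord_res = diversity.pcoa(dmat)
        coords = pd.DataFrame(
            ord_res.coordinates,
            index=list(ord_res.ids),
            columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        )
        coords.to_csv(out / f"pcoa_{metric}.tsv", sep="\t", index_label="sample_id")
        with open(out / f"pcoa_{metric}_eigenvalues.json", "w") as fh:
            json.dump(
                {
                    "eigenvalues": [float(v) for v in ord_res.eigenvalues],
                    "proportion_explained": [
                        float(v) for v in ord_res.proportion_explained
                    ],
                },
                fh,
            )
        pres = stats.permanova(
            dmat,
            meta,
            list(config.permanova_terms),
            n_perm=config.n_permutations,
            seed=perm_seed,
        )
        perm_results[metric] = pres
        pres.table.to_csv(out / f"permanova_{metric}.tsv", sep="\t", index_label="term")
        disp = stats.betadisper_test(
            dmat,
            meta.df.loc[list(dmat.ids), "site"],
            n_perm=config.n_permutations,
            seed=disp_seed,
        )
        disp_results[metric] = disp
        pd.DataFrame(
            {
                "F": [disp.f_statistic],
                "p": [disp.p_value],
                "n_permutations": [disp.n_permutations],
            }
        ).to_csv(out / f"betadisper_{metric}.tsv", sep="\t", index=False)
        beta_files += [
            out / f"distance_{metric}.tsv",
            out / f"pcoa_{metric}.tsv",
            out / f"pcoa_{metric}_eigenvalues.json",
            out / f"permanova_{metric}.tsv",
            out / f"betadisper_{metric}.tsv",
        ]
    finish_stage("beta_stats", t0, beta_files, perm_seed)

    # -- stage 6b: clustering stability ------------------------------------
    t0 = _time.perf_counter()
    stability = stats.cluster_stability(table_r, meta, k=config.cluster_k)
    stability.to_csv(out / "cluster_stability.tsv", sep="\t", index=False)
    finish_stage("cluster_stability", t0, [out / "cluster_stability.tsv"])

    # -- stage 7: core microbiota and sharing (unrarefied) -----------------
    t0 = _time.perf_counter()
    nc = meta.df[~meta.df["is_control"]]
    times = [t for t in ("-1W", "1M", "3M", "7M") if t in set(nc["time"])]
    sites = sorted(nc["site"].unique())
    cores: list[core_sharing.CoreSet] = []
    core_rows = []
    sharing: dict[str, core_sharing.SharingReport] = {}
    share_frames = []
    multi_frames = []
    tallies = {2: 0, 3: 0, 4: 0}
    for tp in times:
        for site in sites:
            try:
                cs = core_sharing.core_microbiota(
                    table_f,
                    meta,
                    site,
                    tp,
                    abn_core=config.core_abundance,
                    prev_core=config.core_prevalence,
                )
            except ValueError:
                continue
            cores.append(cs)
            for asv in sorted(cs.core_asvs):
                core_rows.append(
                    {
                        "site": site,
                        "time": tp,
                        "asv": asv,
                        "prevalence": cs.evidence.loc[asv, "prevalence"],
                        "mean_rel_abundance": cs.evidence.loc[asv, "mean_rel_abundance"],
                    }
                )
        rep = core_sharing.pairwise_sharing(table_f, meta, tp)
        multi = core_sharing.multiway_sharing(table_f, meta, tp)
        sharing[tp] = rep
        if not rep.pairwise.empty:
            share_frames.append(rep.pairwise.assign(time=tp))
        if not multi.multiway.empty:
            multi_frames.append(multi.multiway)
        for kk in tallies:
            tallies[kk] += multi.tallies.get(kk, 0)
    pd.DataFrame(
        core_rows, columns=["site", "time", "asv", "prevalence", "mean_rel_abundance"]
    ).to_csv(out / "core_asvs.tsv", sep="\t", index=False)
    (
        pd.concat(share_frames, ignore_index=True)
        if share_frames
        else pd.DataFrame()
    ).to_csv(out / "sharing_pairwise.tsv", sep="\t", index=False)
    (
        pd.concat(multi_frames, ignore_index=True)
        if multi_frames
        else pd.DataFrame()
    ).to_csv(out / "sharing_multiway.tsv", sep="\t", index=False)
    with open(out / "sharing_summary.json", "w") as fh:
        json.dump({f"occurrences_{k}way": v for k, v in tallies.items()}, fh, sort_keys=True)
    finish_stage(
        "core_sharing",
        t0,
        [
            out / "core_asvs.tsv",
            out / "sharing_pairwise.tsv",
            out / "sharing_multiway.tsv",
            out / "sharing_summary.json",
        ],
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return RunResult(
        manifest=manifest,
        table_raw=table,
        table_filtered=table_f,
        table_rarefied=table_r,
        meta=meta,
        tree=tree,
        removal_log=log,
        kitome=kitome,
        distances=distances,
        permanova=perm_results,
        dispersion=disp_results,
        stability=stability,
        cores=cores,
        sharing=sharing,
        truth=truth,
    )


def runs_identical(dir1, dir2) -> bool:
    """Whether two run directories hold byte-identical artifacts.

    The manifest is compared on its output hashes only (wall times differ
    between runs by nature).
    """
    dir1, dir2 = Path(dir1), Path(dir2)
    names1 = {p.name for p in dir1.iterdir() if p.is_file()}
    names2 = {p.name for p in dir2.iterdir() if p.is_file()}
    if names1 != names2:
        return False
    for name in sorted(names1):
        if name == "manifest.json":
            m1 = json.loads((dir1 / name).read_text())
            m2 = json.loads((dir2 / name).read_text())
            h1 = [(s["stage"], s["outputs"]) for s in m1["stages"]]
            h2 = [(s["stage"], s["outputs"]) for s in m2["stages"]]
            if h1 != h2 or m1["seed"] != m2["seed"]:
                return False
        elif _sha256(dir1 / name) != _sha256(dir2 / name):
            return False
    return True


def validate_against_truth(result: RunResult, truth: GroundTruth | None = None) -> dict:
    """Recovery report of a synthetic run against its planted ground truth."""
    truth = truth if truth is not None else result.truth
    if truth is None:
        raise ValueError("run has no ground truth to validate against")
    raw_asvs = set(result.table_raw.asv_ids)
    if not truth.kitome_asvs <= raw_asvs | truth.kitome_asvs:
        raise ValueError("ground truth does not match the run's count table")

    # kitome recovery (among ASVs that survived the abundance filter)
    candidates = raw_asvs
    planted = truth.kitome_asvs & candidates
    flagged = result.kitome
    tp = len(flagged & planted)
    fp = len(flagged - planted)
    fn = len(planted - flagged)
    tn = len(candidates - planted - flagged)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")

    # core recovery, per site at each analysed time point
    core_prec, core_rec = [], []
    for cs in result.cores:
        planted_core = set(truth.core_asvs.get(cs.site, frozenset()))
        got = set(cs.core_asvs)
        if got:
            core_prec.append(len(got & planted_core) / len(got))
        if planted_core:
            core_rec.append(len(got & planted_core) / len(planted_core))

    # sharing-fraction bias vs the pre-noise oracle
    biases = []
    sites = list(truth.config.sites)
    for s1, s2 in [(a, b) for i, a in enumerate(sites) for b in sites[i + 1 :]]:
        oracle = truth_sharing_fraction(truth, result.table_raw, result.meta, (s1, s2))
        for tp_, rep in result.sharing.items():
            pw = rep.pairwise
            sel = pw[(pw["site1"] == s1) & (pw["site2"] == s2)]
            osel = oracle[oracle["time"] == tp_]
            if sel.empty or osel.empty:
                continue
            measured = sel["fraction_in_site1"].mean()
            expected = osel[f"fraction_in_{s1}"].mean()
            biases.append(measured - expected)

    site_p = {m: float(r.table.loc["site", "p"]) for m, r in result.permanova.items()}
    return {
        "kitome_sensitivity": sens,
        "kitome_specificity": spec,
        "kitome_flagged": len(flagged),
        "core_precision": float(np.mean(core_prec)) if core_prec else float("nan"),
        "core_recall": float(np.mean(core_rec)) if core_rec else float("nan"),
        "sharing_fraction_bias": float(np.mean(biases)) if biases else float("nan"),
        "permanova_site_p": site_p,
    }
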