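# holoshare

Analysis toolkit for multi-body-site microbiota surveys of dairy herds:
16S amplicon count tables from the mouth, nose, vagina and milk of the same
animals, sampled repeatedly through lactation, with negative extraction
controls sequenced alongside.

The questions it answers are the ones such longitudinal designs pose:

* **Which ASVs are kit contaminants?**  Extraction/amplification kits leave
  a "kitome" that dominates low-biomass samples (milk above all).  An ASV
  is flagged iff its prevalence in the negative controls exceeds 50% *and*
  its pooled relative abundance in the controls exceeds that over all body
  sites combined.
* **How do site, time, animal and host genetics shape the communities?**
  Jaccard, Bray–Curtis and (un)weighted UniFrac dissimilarities, classical
  PCoA/MDS, PERMANOVA with sequential sums of squares
  (`SS_k = tr(H_k G) − tr(H_{k−1} G)` on the Gower-centered matrix
  `G = −½ C D² C`), and a permutation test of homogeneity of multivariate
  dispersion — all implemented from first principles and verified against
  exhaustive enumeration oracles.
* **Is there a herd core?**  Core ASVs per site/time: relative abundance
  above 0.01% in at least 50% of the animals.
* **How much do body sites of the *same* animal share?**  Per animal, time
  point and site pair: shared ASV counts, the two directional fractions
  `|A∩B|/|A|` and `|A∩B|/|B|`, and the summed relative abundance of the
  shared ASVs in each site; plus 3-way/4-way sharing occurrence tallies.
* **Are animal clusterings stable over time?**  Ward (ward.D2) clustering
  of Bray–Curtis profiles per site and time, compared across consecutive
  time points with the Hubert–Arabie Adjusted Rand Index.

Because real surveys require heavyweight upstream processing (denoising,
chimera removal, taxonomy, tree inference), the package ships a
**synthetic herd generator** that emulates the full design — 45 animals ×
4 sites × 4 time points, site-specific template communities, planted herd
cores, animal-private ASVs, a tunable within-animal cross-site transfer
rate, temporal turnover, planted kit contaminants whose carry-over scales
inversely with site biomass, and multinomial sequencing noise — together
with the ground truth needed to score every downstream stage.

## Worked example

```python
from holoshare import (SyntheticConfig, generate_herd, filter_low_abundance_prevalence,
                       detect_kitome, remove_asvs, filter_samples_min_reads, rarefy)
from holoshare.diversity import bray_curtis
from holoshare.stats import permanova
from holoshare.core_sharing import core_microbiota, pairwise_sharing

cfg = SyntheticConfig(n_animals=12, pool_size=200, site_pool_size=60, seed=4)
table, meta, tree, truth = generate_herd(cfg)
print(f"raw: {table.n_samples} samples x {table.n_asvs} ASVs")

table, log = filter_low_abundance_prevalence(table, meta)
kitome, evidence = detect_kitome(table, meta)
table, log = remove_asvs(table, kitome, log)
table, log_min = filter_samples_min_reads(table)
print(f"filtered: {table.n_samples} samples x {table.n_asvs} ASVs "
      f"({len(kitome)} kitome ASVs removed)")

rare = rarefy(table, int(table.sample_totals().min()), seed=1)
res = permanova(bray_curtis(rare.select_samples(meta.non_control_ids)),
                meta, ["group", "site", "time"], n_perm=999, seed=1)
print(res.table.round(3))

core = core_microbiota(table, meta, site="oral", time="1M")
print(f"oral core at 1M: {core.n_core} of {core.n_total_asvs} ASVs "
      f"({100 * core.core_fraction:.1f}%)")

sharing = pairwise_sharing(table, meta, time="1M").pairwise
on = sharing[(sharing.site1 == "nasal") & (sharing.site2 == "oral")]
print(f"oral ASVs also found in the same cow's nose: "
      f"mean {100 * on.fraction_in_site2.mean():.1f}%, max {100 * on.fraction_in_site2.max():.1f}%")
```

prints

```
raw: 200 samples x 1117 ASVs
filtered: 192 samples x 591 ASVs (24 kitome ASVs removed)
           df  SumOfSqs     R2       F      p
group       2     1.905  0.026   5.018  0.001
site        3    35.892  0.493  63.037  0.001
time        3     0.212  0.003   0.373  1.000
Residual  183    34.732  0.477     NaN    NaN
Total     191    72.741  1.000     NaN    NaN
oral core at 1M: 10 of 215 ASVs (4.7%)
oral ASVs also found in the same cow's nose: mean 20.4%, max 27.3%
```

Reading the output: the kitome rule recovered 24 of the 25 planted
contaminants; the anatomical site explains ~49% of Bray–Curtis variation
in this small herd (p at the permutation floor of 0.001 with 999
permutations) while sampling time, with the default 10% turnover, explains
little; only ~5% of the oral ASVs found in the herd are core, yet an
individual cow's mouth shares on average a fifth of its ASVs with its own
nose — the contrast between scarce herd-level sharing and substantial
within-animal sharing that motivates the toolkit.

A CLI mirrors the library (`holoshare simulate|filter|rarefy|alpha|beta|
permanova|betadisper|cluster|core|share|run`); `holoshare run --config
cfg.yaml` executes the whole pipeline into a run directory with a hashed
manifest, byte-reproducible for a fixed config and seed.

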