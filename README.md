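# gnotodiff

Multi-tissue differential metabolomics for germ-free versus
conventionally-raised mice.

## The problem

Untargeted LC–MS profiling of tissues from germ-free (GF) and
murine-pathogen-free (MPF) mice produces feature tables of tens of thousands
of molecular features (an aligned *m/z* × retention-time peak per analytical
mode) measured across many tissues with few replicates per group. Comparing
the two colonization states tissue by tissue poses three recurring problems
that this package addresses as one tested, reproducible pipeline:

1. **Ambiguous zeros.** A zero intensity can mean true absence of a
   metabolite (structural zero) or a missed detection of a low-abundance one
   (dropout). Calling group-exclusive metabolites — the headline biology in
   a gnotobiotic comparison — is entirely a function of how zeros are
   resolved.
2. **Tiny group sizes.** With n = 5 mice per group, asymptotic rank tests
   are badly calibrated; the exact null distribution must be enumerated.
3. **Many parallel comparisons.** Each tissue tests every feature, so
   significance calling needs FDR control plus practical filters (effect
   size, intensity, identifiability) before presence calls, volcano
   classification, and clustering.

The intended users are computational metabolomics practitioners who need a
scriptable, auditable version of this analysis rather than a GUI workflow.

## Methods at the core

For each feature and tissue, with replicate vectors x⁽ᴳᶠ⁾ and x⁽ᴹᴾᶠ⁾:

- **False-zero imputation** (per group, per tissue), with a 60% zero-fraction
  cut and an intensity threshold of 10,000 counts:
  - *rule 1*: zero fraction > 60% → all values set to 0 (true absence);
  - *rule 2*: zero fraction < 60% and non-zero values below 10,000 → all 0;
  - *rule 3*: zero fraction < 60% and non-zero values above 10,000 → zeros
    replaced by the mean of the non-zero replicates (false zeros).
- **Fold change** FC = x̄⁽ᴳᶠ⁾ / x̄⁽ᴹᴾᶠ⁾, so FC > 1 means higher in GF. A
  zero denominator or numerator yields a GF-only / MPF-only exclusivity flag
  rather than an infinite ratio (a finite ε-floor mode is available).
- **Exact Mann–Whitney U test**: the two-sided p value is computed by
  complete enumeration of all C(10, 5) = 252 relabelings of the pooled
  mid-ranks, so ties are handled exactly and the smallest attainable p with
  5 + 5 tie-free replicates is 2/252 ≈ 0.0079.
- **Benjamini–Hochberg FDR** within each tissue's batch of tested features:
  q(i) = min over p(j) ≥ p(i) of m·p(j)/rank(j).
- **Inclusion filter** (conjunctive): FC ≥ 1.3 in either direction (or
  exclusive), p ≤ 0.05, q ≤ 0.05, maximum raw abundance ≥ 100,000, MS/MS
  spectrum present, retention time ≥ 0.7 min.
- **Volcano classification** per tissue class: highlighted iff q < 0.1 and
  FC outside (0.005, 200) for cecum/colon, (0.01, 100) for
  duodenum/jejunum/ileum, (0.033, 30) for all other tissues; coordinates are
  (log₂ FC, −log₁₀ q).
- **Clustering**: rows z-scored as (x − x̄_row)/SD_row, then Euclidean
  k-means (k = 10 by default, k-means++ with 25 restarts) over the
  filter-passing features; **PCA** of the unscaled, column-centered matrix
  gives the sample-level overview.

A synthetic-data generator produces feature tables with the same design (4
analytical modes, 13 tissues × 2 groups × 5 replicates, log-normal
intensities, tissue effects larger than group effects, structural and
dropout zeros, planted fold changes and exclusives) together with the
ground truth of every planted effect, so every downstream stage can be
scored exactly.

## Worked example

```python
from gnotodiff import (SimulationConfig, simulate_feature_table, impute_table,
                       differential_all_tissues, apply_inclusion_filter,
                       tabulate_tissue_summary)

cfg = SimulationConfig(tissues=("cecum", "liver"),
                       n_features_per_mode={"RP+": 1000, "HILIC-": 500},
                       seed=1)
table, truth = simulate_feature_table(cfg)
imputed, audit = impute_table(table)
records = differential_all_tissues(imputed)
significant = apply_inclusion_filter(records, imputed.feature_meta)
summary = tabulate_tissue_summary(significant, records, imputed)
```

This prints (via the obvious `print` statements):

```
features: 1500, samples: 20
imputation cells touched: 2082 (rule 3 repairs: 24)
significant records: 246 of 3000
tissue  n_detected  n_significant  n_gf_only  n_mpf_only  n_shared
 cecum        1036            119         18          23        78
 liver        1034            127         19          25        83
```

Reading: of 1500 simulated features, ~69% are detected in each tissue (the
generator plants 30% tissue-level absence); 2082 (feature, tissue, group)
cells contained at least one zero and were resolved by the imputation rules,
24 of them repaired as false zeros (rule 3). After exact testing, FDR and
the inclusion filter, each tissue retains ~120 significant features,
partitioned into GF-exclusive, MPF-exclusive and shared — the same
accounting used for the per-tissue significance bar charts in a gnotobiotic
study.

The same funnel is available from the shell:

```bash
gnotodiff simulate --seed 1 --out data/
gnotodiff validate data/features.tsv data/samples.tsv
gnotodiff run-all --seed 1 --out run/
```

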